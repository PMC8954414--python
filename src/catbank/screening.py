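"""Descriptive item screening for an ordinal item pool.

Implements the exclusion filters applied before IRT calibration: high
missing-value rates (> 70%), extreme skewness (> 95% of responses in one
category or |g1| > 4), and inter-item redundancy (Pearson r > 0.70), plus
Cronbach's alpha for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import as_matrix, observed_mask

__all__ = [
    "reverse_code",
    "describe_items",
    "inter_item_correlations",
    "ScreeningThresholds",
    "ScreeningReport",
    "apply_screening",
    "cronbach_alpha",
]


def reverse_code(responses, reverse_items, n_categories: int) -> pd.DataFrame:
    """Flip the code of reverse-worded items (x -> K-1-x), keeping gaps."""
    df = responses.copy() if isinstance(responses, pd.DataFrame) else pd.DataFrame(as_matrix(responses))
    for item in reverse_items:
        col = item if isinstance(item, str) else df.columns[item]
        v = df[col].to_numpy(dtype=float)
        obs = np.isfinite(v) & (v >= 0)
        v[obs] = (n_categories - 1) - v[obs]
        df[col] = v
    return df


def describe_items(responses, n_categories: int, reverse_items=()) -> pd.DataFrame:
    """Per-item descriptives: mean, SD, floor/ceiling/missing %, skewness.

    Reverse-coded items are described after reversal.  Skewness is the
    bias-adjusted Fisher-Pearson g1; it is reported as NaN (and flagged) for
    items with fewer than 3 distinct observed values.
    """
    df = reverse_code(responses, reverse_items, n_categories)
    x = as_matrix(df)
    obs = observed_mask(x)
    rows = []
    for i, col in enumerate(df.columns):
        v = x[obs[:, i], i]
        rec = {"item_id": str(col), "missing_pct": 100.0 * (1 - obs[:, i].mean())}
        if v.size >= 2:
            rec["mean"] = float(v.mean())
            rec["sd"] = float(v.std(ddof=1))
            rec["floor_pct"] = float(100.0 * (v == 0).mean())
            rec["ceiling_pct"] = float(100.0 * (v == n_categories - 1).mean())
            shares = np.bincount(v.astype(int), minlength=n_categories) / v.size
            rec["max_category_pct"] = float(100.0 * shares.max())
            if len(np.unique(v)) >= 2 and v.size >= 3:
                rec["skewness"] = float(stats.skew(v, bias=False))
                rec["skew_defined"] = True
            else:
                rec["skewness"] = np.nan
                rec["skew_defined"] = False
        else:
            rec.update(mean=np.nan, sd=np.nan, floor_pct=np.nan, ceiling_pct=np.nan,
                       max_category_pct=np.nan, skewness=np.nan, skew_defined=False)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("item_id")
    return out[["mean", "sd", "floor_pct", "ceiling_pct", "missing_pct",
                "max_category_pct", "skewness", "skew_defined"]]


def inter_item_correlations(responses, reverse_items=(), n_categories: int | None = None,
                            min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of the integer codes.

    Cells with fewer than ``min_pairs`` complete observations are NaN.
    """
    if reverse_items and n_categories is None:
        raise ValueError("n_categories needed to reverse-code items")
    df = reverse_code(responses, reverse_items, n_categories or 0) if reverse_items \
        else (responses.copy() if isinstance(responses, pd.DataFrame) else pd.DataFrame(as_matrix(responses)))
    masked = df.where(pd.DataFrame(observed_mask(df), index=df.index, columns=df.columns))
    corr = masked.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ScreeningThresholds:
    missing_pct: float = 70.0
    max_category_pct: float = 95.0
    abs_skewness: float = 4.0
    correlation: float = 0.70


@dataclass
class ScreeningReport:
    retained: list[str]
    excluded: dict[str, str]                       # item -> primary reason code
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    cronbach_alpha: float | None = None
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)


def apply_screening(desc: pd.DataFrame, corr: pd.DataFrame,
                    thresholds: ScreeningThresholds | None = None) -> ScreeningReport:
    """Apply the exclusion filters and resolve redundant pairs.

    Reasons (one primary reason per exclusion, in precedence order):
    ``MISSING_GT_70`` — missing share above the missing threshold;
    ``SKEW_EXTREME`` — > 95% of responses in one category or |skewness| > 4;
    ``REDUNDANT_PAIR`` — inter-item correlation above the cutoff; the pair
    member with the higher mean correlation to all other items is dropped
    (ties: higher missing rate, then higher item index).  Deterministic and
    idempotent on its own output.
    """
    th = thresholds or ScreeningThresholds()
    items = [str(i) for i in desc.index]
    excluded: dict[str, str] = {}

    for it in items:
        row = desc.loc[it]
        if row["missing_pct"] > th.missing_pct:
            excluded[it] = "MISSING_GT_70"
        elif (np.isfinite(row.get("max_category_pct", np.nan))
              and row["max_category_pct"] > th.max_category_pct) or \
             (np.isfinite(row.get("skewness", np.nan))
              and abs(row["skewness"]) > th.abs_skewness):
            excluded[it] = "SKEW_EXTREME"

    alive = [it for it in items if it not in excluded]
    pairs = []
    for ai, a in enumerate(alive):
        for b in alive[ai + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > th.correlation:
                pairs.append((a, b, float(r)))
    pairs.sort(key=lambda t: -t[2])

    def mean_corr(it: str) -> float:
        others = [o for o in items if o != it]
        vals = corr.loc[it, others].abs()
        return float(vals.mean(skipna=True))

    for a, b, _r in pairs:
        if a in excluded or b in excluded:
            continue
        ka = (mean_corr(a), desc.loc[a, "missing_pct"], items.index(a))
        kb = (mean_corr(b), desc.loc[b, "missing_pct"], items.index(b))
        drop = a if ka > kb else b
        excluded[drop] = "REDUNDANT_PAIR"

    retained = [it for it in items if it not in excluded]
    return ScreeningReport(retained=retained, excluded=excluded,
                           flagged_pairs=pairs, thresholds=th)


def cronbach_alpha(responses) -> float:
    """Cronbach's alpha on listwise-complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total).
    Returns NaN if the total score has zero variance.
    """
    x = as_matrix(responses)
    if x.shape[1] < 2:
        raise ValueError("cronbach_alpha: need >= 2 items")
    complete = observed_mask(x).all(axis=1)
    x = x[complete]
    if x.shape[0] < 2:
        raise ValueError("cronbach_alpha: need >= 2 complete rows")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        return float("nan")
    return float(k / (k - 1) * (1 - item_var / total_var))
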