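"""Computerized adaptive testing over a calibrated GPCM item bank.

The algorithm: pick the starting item by maximum Fisher information (MFI)
at the prior mean, score the response by EAP, keep selecting the most
informative unadministered item at the current trait estimate, and stop
once the standard error of measurement (SEM = posterior SD) falls below
the stopping threshold (0.33 / 0.44 / 0.55 correspond to reliabilities
0.89 / 0.81 / 0.70 on a unit-variance trait), the bank is exhausted, or a
maximum item count is hit.  Whole-cohort simulation reports accuracy
(correlation with full-bank EAP scores) and precision (RMSE on the latent
scale) per stopping scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codes import coded
from .bank import ItemBank
from .gpcm import (default_grid, gpcm_prob, item_information, prior_weights,
                   transform_score)

__all__ = [
    "CATConfig",
    "CATTrace",
    "select_start_item",
    "next_item",
    "run_cat",
    "impute_missing",
    "simulate_cat",
    "reliability_to_sem",
    "sem_to_reliability",
]


def reliability_to_sem(reliability: float) -> float:
    """SEM implied by a reliability coefficient on a unit-variance trait."""
    return float(np.sqrt(1.0 - reliability))


def sem_to_reliability(sem: float) -> float:
    """Reliability implied by an SEM on a unit-variance trait."""
    return float(1.0 - sem ** 2)


@dataclass
class CATConfig:
    stop_sem: float = 0.33
    max_items: int | None = None       # default: bank size
    start_theta: float = 0.0
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stop_sem <= 0:
            raise ValueError("stop_sem must be > 0")
        if self.max_items is not None and self.max_items < 1:
            raise ValueError("max_items must be >= 1")


@dataclass
class CATTrace:
    administered: list[str]
    interim: list[tuple[float, float]]  # (theta, sem) after each response
    theta: float
    sem: float
    score_0_100: float
    stop_reason: str                    # SEM_MET | BANK_EXHAUSTED | MAX_ITEMS


def select_start_item(bank: ItemBank, theta0: float = 0.0) -> str:
    """MFI starting item: most informative at ``theta0`` (ties: lowest index)."""
    if len(bank) == 0:
        raise ValueError("select_start_item: empty bank")
    info = [float(item_information(np.array(theta0), it)) for it in bank]
    return bank.ids[int(np.argmax(info))]


def next_item(administered, bank: ItemBank, theta: float) -> str:
    """Most informative unadministered item at the current estimate."""
    done = set(administered)
    best_id, best_info = None, -np.inf
    for it in bank:
        if it.id in done:
            continue
        info = float(item_information(np.array(theta), it))
        if info > best_info + 1e-12:
            best_id, best_info = it.id, info
    if best_id is None:
        raise ValueError("next_item: no unadministered items remain")
    return best_id


def _eap_on_grid(ll: np.ndarray, grid: np.ndarray, w: np.ndarray):
    post = w * np.exp(ll - ll.max())
    post /= post.sum()
    theta = float(post @ grid)
    var = float(post @ grid ** 2 - theta ** 2)
    return theta, float(np.sqrt(max(var, 0.0)))


def run_cat(pattern, bank: ItemBank, config: CATConfig | None = None) -> CATTrace:
    """Administer the CAT to one complete response pattern.

    ``pattern`` must supply a response for every item the selector might
    pick (impute first when simulating from incomplete data).  The final
    estimate is the EAP over administered items only.
    """
    config = config or CATConfig()
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape[0] != len(bank):
        raise ValueError("pattern length must equal bank size")
    grid = config.grid if config.grid is not None else default_grid()
    w = prior_weights(grid)
    log_probs = {it.id: np.log(gpcm_prob(grid, it.discrimination, it.thresholds))
                 for it in bank}
    max_items = config.max_items or len(bank)

    administered: list[str] = []
    interim: list[tuple[float, float]] = []
    ll = np.zeros(len(grid))
    theta, sem = config.start_theta, float("inf")
    stop_reason = "BANK_EXHAUSTED"
    while True:
        if len(administered) == len(bank):
            stop_reason = "BANK_EXHAUSTED"
            break
        if len(administered) >= max_items:
            stop_reason = "MAX_ITEMS"
            break
        item_id = (select_start_item(bank, config.start_theta) if not administered
                   else next_item(administered, bank, theta))
        idx = bank.index_of(item_id)
        resp = pattern[idx]
        if not (np.isfinite(resp) and resp >= 0):
            raise ValueError(f"run_cat: no response available for item {item_id}")
        ll = ll + log_probs[item_id][:, int(resp)]
        theta, sem = _eap_on_grid(ll, grid, w)
        administered.append(item_id)
        interim.append((theta, sem))
        if sem < config.stop_sem:
            stop_reason = "SEM_MET"
            break
    lo = bank.transform.get("theta_lo", -4.0)
    hi = bank.transform.get("theta_hi", 4.0)
    return CATTrace(administered=administered, interim=interim, theta=theta,
                    sem=sem, score_0_100=float(transform_score(theta, lo, hi)),
                    stop_reason=stop_reason)


def impute_missing(responses, bank: ItemBank, mode: str = "modal",
                   seed: int | None = None):
    """Fill unobserved cells from the IRT model at each person's EAP theta.

    ``mode='modal'`` (deterministic) fills the most probable category;
    ``mode='sample'`` draws from the category probabilities (seeded).
    Persons with no observed response are scored at the prior mean and
    reported in the returned flag list.
    """
    from .gpcm import eap_scores

    X = coded(responses)
    theta, _ = eap_scores(responses, bank)
    rng = np.random.default_rng(seed)
    out = X.astype(float)
    flags = [int(i) for i in np.flatnonzero((X >= 0).sum(axis=1) == 0)]
    for j, it in enumerate(bank):
        holes = X[:, j] < 0
        if not holes.any():
            continue
        P = gpcm_prob(theta[holes], it.discrimination, it.thresholds)
        if mode == "modal":
            fill = np.argmax(P, axis=1)
        elif mode == "sample":
            u = rng.random(P.shape[0])
            fill = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        else:
            raise ValueError(f"impute_missing: unknown mode {mode!r}")
        out[holes, j] = fill
    if isinstance(responses, pd.DataFrame):
        out = pd.DataFrame(out, columns=responses.columns, index=responses.index)
    return out, flags


@dataclass
class CATEvaluation:
    table: pd.DataFrame                 # one row per stopping scenario
    traces: dict[float, list[CATTrace]] = field(default_factory=dict)


def simulate_cat(responses, bank: ItemBank, scenarios=(0.33, 0.44, 0.55),
                 config: CATConfig | None = None, keep_traces: bool = False
                 ) -> CATEvaluation:
    """Simulate the CAT over a completed cohort for each stopping rule.

    Per scenario: mean +/- SD of the 0-100 CAT scores, the correlation r and
    the latent-scale RMSE between CAT estimates and full-bank EAP estimates,
    and the mean number of items administered.
    """
    from .gpcm import eap_scores

    base = config or CATConfig()
    X = coded(responses)
    if not (X >= 0).all():
        raise ValueError("simulate_cat: responses must be complete (impute first)")
    n = X.shape[0]
    grid = base.grid if base.grid is not None else default_grid()
    full_theta, _ = eap_scores(responses, bank, grid=grid)

    rows = []
    all_traces: dict[float, list[CATTrace]] = {}
    for sem in scenarios:
        cfg = CATConfig(stop_sem=sem, max_items=base.max_items,
                        start_theta=base.start_theta, grid=grid)
        traces = [run_cat(X[i], bank, cfg) for i in range(n)]
        cat_theta = np.array([t.theta for t in traces])
        scores = np.array([t.score_0_100 for t in traces])
        n_items = np.array([len(t.administered) for t in traces])
        if n < 2 or np.std(cat_theta) == 0 or np.std(full_theta) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(cat_theta, full_theta)[0, 1])
        rows.append({
            "stop_sem": sem,
            "mean_score": float(scores.mean()),
            "sd_score": float(scores.std(ddof=1)) if n > 1 else float("nan"),
            "r": r,
            "rmse": float(np.sqrt(((cat_theta - full_theta) ** 2).mean())),
            "mean_items": float(n_items.mean()),
        })
        if keep_traces:
            all_traces[sem] = traces
    return CATEvaluation(table=pd.DataFrame(rows), traces=all_traces)
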