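"""Synthetic response-data generator for the calibration/CAT pipeline.

Emulates a patient-experience survey cohort: a few hundred respondents
answering ~24 five-point Likert items driven by one latent trait, with the
statistical wrinkles the pipeline has to survive — redundant item pairs,
reverse-coded items, per-item missingness, an explicit "not applicable"
choice, grouping variables (sex, age split, care setting, diagnosis) and
injectable differential item functioning (DIF).

Responses follow the generalized partial credit model at each person's true
trait; traits are standard normal within group, plus configured group
offsets.  Every draw is controlled by the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._codes import NOT_APPLICABLE
from .bank import Item, ItemBank
from .gpcm import gpcm_prob

__all__ = [
    "GroupSpec",
    "DIFSpec",
    "SimulationConfig",
    "TrueParameters",
    "generate_bank",
    "simulate_responses",
    "study_like_config",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""


@dataclass
class GroupSpec:
    """A grouping variable: level labels, proportions, latent-mean offsets."""

    name: str
    levels: list[str]
    proportions: list[float]
    offsets: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.proportions):
            raise ConfigError(f"group_specs[{self.name}]: levels/proportions length mismatch")
        if abs(sum(self.proportions) - 1.0) > 1e-8:
            raise ConfigError(f"group_specs[{self.name}]: proportions must sum to 1")
        if self.offsets is None:
            self.offsets = [0.0] * len(self.levels)
        if len(self.offsets) != len(self.levels):
            raise ConfigError(f"group_specs[{self.name}]: offsets length mismatch")


@dataclass
class DIFSpec:
    """Inject DIF on one item for one group level.

    ``uniform_shift`` moves every step threshold (threshold units); the
    ``slope_factor`` multiplies the discrimination (non-uniform DIF).
    """

    item: int
    group: str
    level: str
    uniform_shift: float = 0.0
    slope_factor: float = 1.0


@dataclass
class SimulationConfig:
    n_persons: int = 458
    n_items: int = 24
    n_categories: int = 5
    seed: int = 0
    # discriminations: log-normal, clamped into discrimination_range
    discrimination_logmean: float = 0.35
    discrimination_logsd: float = 0.45
    discrimination_range: tuple[float, float] = (0.7, 3.4)
    # ordered step thresholds: item centers uniform in threshold_range,
    # steps spread around the center then clamped back into the range
    threshold_range: tuple[float, float] = (-2.2, 0.7)
    threshold_spread: float = 0.9
    group_specs: list[GroupSpec] = field(default_factory=list)
    dif_specs: list[DIFSpec] = field(default_factory=list)
    redundancy_specs: list[tuple[int, int]] = field(default_factory=list)
    redundancy_copy_prob: float = 0.85
    missing_rate_per_item: float | list[float] = 0.0
    na_rate_per_item: float | list[float] = 0.0
    reverse_coded: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons: must be >= 1")
        if self.n_items < 1:
            raise ConfigError("n_items: must be >= 1")
        if self.n_categories < 2:
            raise ConfigError("n_categories: must be >= 2")
        lo, hi = self.discrimination_range
        if not (0 < lo < hi):
            raise ConfigError("discrimination_range: need 0 < lo < hi")
        lo, hi = self.threshold_range
        if not lo < hi:
            raise ConfigError("threshold_range: need lo < hi")
        if self.discrimination_logsd <= 0:
            raise ConfigError("discrimination_logsd: must be > 0")
        for name, rate in (("missing_rate_per_item", self.missing_rate_per_item),
                           ("na_rate_per_item", self.na_rate_per_item)):
            rates = np.atleast_1d(np.asarray(rate, dtype=float))
            if np.any(rates < 0) or np.any(rates > 1):
                raise ConfigError(f"{name}: rates must lie in [0, 1]")
            if rates.size not in (1, self.n_items):
                raise ConfigError(f"{name}: scalar or one rate per item")
        names = {g.name for g in self.group_specs}
        for d in self.dif_specs:
            if not (0 <= d.item < self.n_items):
                raise ConfigError(f"dif_specs: unknown item index {d.item}")
            if d.group not in names:
                raise ConfigError(f"dif_specs: unknown group {d.group!r}")
            spec = next(g for g in self.group_specs if g.name == d.group)
            if d.level not in spec.levels:
                raise ConfigError(f"dif_specs: unknown level {d.level!r} of group {d.group!r}")
        for i, j in self.redundancy_specs:
            if not (0 <= i < self.n_items and 0 <= j < self.n_items) or i == j:
                raise ConfigError(f"redundancy_specs: bad pair ({i}, {j})")
        for k in self.reverse_coded:
            if not (0 <= k < self.n_items):
                raise ConfigError(f"reverse_coded: unknown item index {k}")

    def item_rates(self, which: str) -> np.ndarray:
        rate = getattr(self, which)
        rates = np.atleast_1d(np.asarray(rate, dtype=float))
        return np.full(self.n_items, rates[0]) if rates.size == 1 else rates

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["reverse_coded"] = sorted(self.reverse_coded)
        d["redundancy_specs"] = [list(p) for p in self.redundancy_specs]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["group_specs"] = [GroupSpec(**g) for g in d.get("group_specs", [])]
        d["dif_specs"] = [DIFSpec(**s) for s in d.get("dif_specs", [])]
        d["redundancy_specs"] = [tuple(p) for p in d.get("redundancy_specs", [])]
        d["reverse_coded"] = frozenset(d.get("reverse_coded", []))
        for key in ("discrimination_range", "threshold_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrueParameters:
    """Generating values: per-person traits and per-item GPCM parameters."""

    theta_true: np.ndarray
    a_true: np.ndarray
    b_true: list[np.ndarray]


def generate_bank(config: SimulationConfig) -> tuple[TrueParameters, ItemBank]:
    """Draw a reproducible item bank inside the configured parameter ranges.

    Discriminations are log-normal clamped to ``discrimination_range``;
    each item gets ordered step thresholds spread around a random center
    within ``threshold_range``.  ``theta_true`` is filled by
    :func:`simulate_responses`; here it is returned empty.
    """
    rng = np.random.default_rng(config.seed)
    lo_a, hi_a = config.discrimination_range
    a = np.clip(rng.lognormal(config.discrimination_logmean, config.discrimination_logsd,
                              config.n_items), lo_a, hi_a)
    lo_b, hi_b = config.threshold_range
    K = config.n_categories
    bs: list[np.ndarray] = []
    centers = rng.uniform(lo_b + 0.15 * (hi_b - lo_b), hi_b - 0.15 * (hi_b - lo_b),
                          config.n_items)
    for i in range(config.n_items):
        if K == 2:
            steps = np.array([centers[i]])
        else:
            offsets = np.sort(rng.normal(0.0, config.threshold_spread, K - 1))
            offsets -= offsets.mean()
            steps = centers[i] + offsets
        steps = np.clip(steps, lo_b, hi_b)
        # keep steps strictly increasing after clamping
        for k in range(1, len(steps)):
            steps[k] = max(steps[k], steps[k - 1] + 1e-3)
        if steps[-1] > hi_b:
            steps -= steps[-1] - hi_b
        bs.append(steps)

    for i, j in config.redundancy_specs:   # duplicate latent behaviour
        a[j] = np.clip(a[i] * (1 + rng.normal(0, 0.01)), lo_a, hi_a)
        bs[j] = bs[i] + rng.normal(0, 0.01, len(bs[i]))

    items = [
        Item(id=f"item{i+1}", n_categories=K, discrimination=float(a[i]),
             thresholds=[float(v) for v in bs[i]],
             reverse_coded=(i in config.reverse_coded))
        for i in range(config.n_items)
    ]
    params = TrueParameters(theta_true=np.empty(0), a_true=a, b_true=bs)
    return params, ItemBank(items)


def _draw_categories(rng: np.random.Generator, P: np.ndarray) -> np.ndarray:
    """Sample one category per row of a probability matrix."""
    u = rng.random(P.shape[0])
    return (P.cumsum(axis=1) < u[:, None]).sum(axis=1)


def simulate_responses(params: TrueParameters, config: SimulationConfig
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the response matrix and the person-level group table.

    Draws traits (standard normal plus group offsets), samples each response
    from GPCM category probabilities (with DIF-modified parameters for
    affected group members), forces redundant pairs to co-vary, injects
    missing/not-applicable cells completely at random per item, and emits
    reverse-coded items in their collected (reversed) orientation.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, m, K = config.n_persons, config.n_items, config.n_categories

    groups = pd.DataFrame(index=pd.RangeIndex(n, name="person"))
    offsets = np.zeros(n)
    for g in config.group_specs:
        lab = rng.choice(len(g.levels), size=n, p=g.proportions)
        groups[g.name] = [g.levels[v] for v in lab]
        offsets += np.asarray(g.offsets)[lab]

    theta = rng.normal(0.0, 1.0, n) + offsets
    params.theta_true = theta

    X = np.empty((n, m), dtype=float)
    for i in range(m):
        a_i = np.full(n, params.a_true[i])
        b_i = np.tile(params.b_true[i], (n, 1))
        for d in config.dif_specs:
            if d.item != i:
                continue
            sel = (groups[d.group] == d.level).to_numpy()
            a_i[sel] *= d.slope_factor
            b_i[sel] += d.uniform_shift
        # category probabilities person by person (parameters vary with DIF)
        steps = a_i[:, None] * (theta[:, None] - b_i)
        z = np.concatenate([np.zeros((n, 1)), np.cumsum(steps, axis=1)], axis=1)
        z -= z.max(axis=1, keepdims=True)
        P = np.exp(z)
        P /= P.sum(axis=1, keepdims=True)
        X[:, i] = _draw_categories(rng, P)

    for i, j in config.redundancy_specs:
        copy = rng.random(n) < config.redundancy_copy_prob
        X[copy, j] = X[copy, i]

    for i in config.reverse_coded:
        X[:, i] = (K - 1) - X[:, i]

    miss = config.item_rates("missing_rate_per_item")
    na = config.item_rates("na_rate_per_item")
    for i in range(m):
        u = rng.random(n)
        X[u < miss[i], i] = np.nan
        X[(u >= miss[i]) & (u < miss[i] + na[i]), i] = NOT_APPLICABLE

    cols = [f"item{i+1}" for i in range(m)]
    return pd.DataFrame(X, columns=cols, index=groups.index), groups


def study_like_config(seed: int = 0, n_persons: int = 458) -> SimulationConfig:
    """Default config emulating the study cohort the pipeline targets.

    ~460 respondents, 24 five-category items, one dominant trait; sex /
    age-split / care-setting / diagnosis groupings with the cohort's level
    proportions; five reverse-worded items; three disjoint redundant pairs
    (so screening drops three items and retains 21); per-item missingness
    mostly low with two high-missing items.
    """
    rng = np.random.default_rng(seed + 977)
    miss = np.round(rng.uniform(0.0, 0.06, 24), 3)
    miss[2], miss[5] = 0.28, 0.24          # two chronically skipped items
    return SimulationConfig(
        n_persons=n_persons,
        n_items=24,
        n_categories=5,
        seed=seed,
        # moderate discriminations (mostly 0.7-1.6): population inter-item
        # correlations stay ~0.3-0.6, so only the injected redundant pairs
        # clear the 0.70 screening cutoff even with n~458 sampling noise
        discrimination_logmean=0.0,
        discrimination_logsd=0.25,
        discrimination_range=(0.7, 1.8),
        group_specs=[
            GroupSpec("sex", ["men", "women"], [0.61, 0.39]),
            GroupSpec("age_group", ["young", "old"], [0.5, 0.5]),
            GroupSpec("care_setting", ["outpatient", "inpatient"], [0.84, 0.16]),
            GroupSpec("diagnosis", ["schizophrenia", "bipolar", "depression"],
                      [0.65, 0.20, 0.15]),
        ],
        redundancy_specs=[(4, 5), (14, 15), (16, 17)],
        missing_rate_per_item=[float(v) for v in miss],
        na_rate_per_item=0.01,
        reverse_coded=frozenset({6, 7, 8, 9, 11}),
    )
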