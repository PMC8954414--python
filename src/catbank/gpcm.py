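"""Generalized partial credit model: calibration, scoring and diagnostics.

The GPCM gives the probability of response category k (k = 0..K-1) to item i
at trait level theta as

    P_ik(theta) ∝ exp( Σ_{v=1..k} a_i (theta − b_iv) ),   empty sum for k = 0,

with discrimination a_i > 0 and step thresholds b_iv.  The partial credit
model (PCM) is the equal-slope special case.  Calibration is maximum marginal
likelihood via EM over a fixed quadrature grid with a standard-normal latent
density; persons are scored by expected-a-posteriori (EAP) estimation under
the same N(0,1) prior, and the posterior SD is reported as the standard error
of measurement (SEM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._codes import coded
from .bank import Item, ItemBank

__all__ = [
    "gpcm_prob",
    "default_grid",
    "prior_weights",
    "fit_gpcm",
    "CalibrationResult",
    "ModelComparison",
    "compare_models",
    "infit_mnsq",
    "item_information",
    "test_information",
    "information_share",
    "eap_score",
    "eap_scores",
    "ThetaEstimate",
    "transform_score",
    "inverse_transform_score",
    "collapse_categories",
    "suggest_collapsing",
    "low_discrimination_items",
]


# ---------------------------------------------------------------------------
# response model

def gpcm_prob(theta, a: float, thresholds) -> np.ndarray:
    """Category probability vector(s) under the GPCM.

    Parameters
    ----------
    theta : float or array
        Latent trait value(s).
    a : float
        Item discrimination, > 0.
    thresholds : sequence of K-1 floats
        Step parameters b_1..b_{K-1}; need not be ordered.

    Returns
    -------
    ndarray with shape ``theta.shape + (K,)``; rows sum to one.
    """
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(thresholds, dtype=float)
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(b)) or not np.isfinite(a):
        raise ValueError("gpcm_prob: non-finite input")
    if a <= 0:
        raise ValueError("gpcm_prob: discrimination must be > 0")
    steps = a * (theta[..., None] - b)          # (..., K-1)
    z = np.concatenate([np.zeros(theta.shape + (1,)), np.cumsum(steps, axis=-1)], axis=-1)
    z -= z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=-1, keepdims=True)


def default_grid(n_points: int = 61, lo: float = -4.0, hi: float = 4.0) -> np.ndarray:
    """Equally spaced quadrature grid on the latent scale."""
    return np.linspace(lo, hi, n_points)


def prior_weights(grid: np.ndarray) -> np.ndarray:
    """Standard-normal quadrature weights, renormalized on the grid."""
    w = stats.norm.pdf(grid)
    return w / w.sum()


def _bank_log_probs(bank: ItemBank, grid: np.ndarray) -> list[np.ndarray]:
    return [np.log(gpcm_prob(grid, it.discrimination, it.thresholds)) for it in bank]


def _posterior(X: np.ndarray, log_probs: list[np.ndarray], log_w: np.ndarray):
    """Posterior over grid nodes per person, plus the marginal log-likelihood.

    X is (N, I) int with -9 for unobserved cells.
    """
    n, n_items = X.shape
    ll = np.zeros((n, len(log_w)))
    for i in range(n_items):
        xi = X[:, i]
        obs = xi >= 0
        if obs.any():
            ll[obs] += log_probs[i][:, xi[obs]].T
    joint = ll + log_w
    m = joint.max(axis=1, keepdims=True)
    p = np.exp(joint - m)
    s = p.sum(axis=1, keepdims=True)
    return p / s, float((m + np.log(s)).sum())


# ---------------------------------------------------------------------------
# calibration (MMLE-EM)

def _item_objective(params_a: float, b: np.ndarray, r: np.ndarray, grid: np.ndarray):
    """Expected complete-data log-likelihood for one item and its gradient.

    r is the (Q, K) table of expected response counts per node/category from
    the E-step.  Returns (f, grad_a, grad_b).
    """
    K = r.shape[1]
    a = params_a
    steps = a * (grid[:, None] - b)             # (Q, K-1)
    z = np.concatenate([np.zeros((len(grid), 1)), np.cumsum(steps, axis=1)], axis=1)
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    P = ez / ez.sum(axis=1, keepdims=True)
    logP = np.log(np.clip(P, 1e-300, None))
    f = float((r * logP).sum())
    nq = r.sum(axis=1)
    G = r - nq[:, None] * P                      # d f / d z_qk
    B = np.concatenate([[0.0], np.cumsum(b)])    # B_k = Σ_{v<=k} b_v
    kk = np.arange(K)
    grad_a = float((G * (kk * grid[:, None] - B)).sum())
    # d z_qk / d b_v = -a for k >= v
    tail = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]  # tail[:, v] = Σ_{k>=v} G_qk
    grad_b = -a * tail[:, 1:].sum(axis=0)
    return f, grad_a, grad_b


def _update_item(r: np.ndarray, grid: np.ndarray, a0: float, b0: np.ndarray,
                 fix_a: float | None = None) -> tuple[float, np.ndarray]:
    """M-step maximization for one item (L-BFGS-B, analytic gradient)."""
    K = r.shape[1]
    if fix_a is not None:
        def neg(b):
            f, _, gb = _item_objective(fix_a, b, r, grid)
            return -f, -gb
        res = optimize.minimize(neg, b0, jac=True, method="L-BFGS-B",
                                bounds=[(-8.0, 8.0)] * (K - 1))
        return fix_a, res.x

    def neg(p):
        f, ga, gb = _item_objective(p[0], p[1:], r, grid)
        return -f, -np.concatenate([[ga], gb])

    res = optimize.minimize(neg, np.concatenate([[a0], b0]), jac=True,
                            method="L-BFGS-B",
                            bounds=[(0.02, 20.0)] + [(-8.0, 8.0)] * (K - 1))
    return float(res.x[0]), res.x[1:]


@dataclass
class CalibrationResult:
    bank: ItemBank
    log_likelihood: float
    n_params: int
    aic: float
    bic: float
    n_persons: int
    n_cycles: int
    converged: bool
    infit: dict[str, float] = field(default_factory=dict)
    model: str = "GPCM"


def _initial_steps(counts: np.ndarray) -> np.ndarray:
    """Threshold start values from marginal category proportions."""
    K = len(counts)
    p = (counts + 0.5) / (counts.sum() + 0.5 * K)
    cum = np.clip(np.cumsum(p)[:-1], 0.01, 0.99)
    return np.asarray(stats.norm.ppf(cum), dtype=float)


def fit_gpcm(responses, n_categories=None, item_ids=None, equal_slopes: bool = False,
             grid: np.ndarray | None = None, max_cycles: int = 500, tol: float = 1e-4,
             compute_infit: bool = True) -> CalibrationResult:
    """Calibrate a GPCM (or PCM with ``equal_slopes``) by MMLE-EM.

    Missing and not-applicable cells are dropped from the affected item's
    likelihood term (ignorable missingness).  The latent density is fixed at
    N(0,1) on the quadrature grid, which also identifies the scale.

    Categories a person never used are still part of the model; an analysis
    category that is entirely unobserved for an item is collapsed away with a
    warning before fitting.
    """
    import pandas as pd

    if item_ids is None and isinstance(responses, pd.DataFrame):
        item_ids = [str(c) for c in responses.columns]
    X = coded(responses)
    n, n_items = X.shape
    if item_ids is None:
        item_ids = [f"item{i+1}" for i in range(n_items)]
    if n_categories is None:
        n_categories = [int(X[:, i][X[:, i] >= 0].max()) + 1 if (X[:, i] >= 0).any() else 2
                        for i in range(n_items)]
    elif np.isscalar(n_categories):
        n_categories = [int(n_categories)] * n_items
    n_categories = list(n_categories)

    # auto-collapse analysis categories with zero observations
    collapse_maps: list[list[int] | None] = [None] * n_items
    for i in range(n_items):
        xi = X[:, i]
        obs = xi >= 0
        counts = np.bincount(xi[obs], minlength=n_categories[i])
        if (counts == 0).any():
            seen = np.flatnonzero(counts > 0)
            if len(seen) < 2:
                raise ValueError(f"item {item_ids[i]}: fewer than 2 observed categories")
            warnings.warn(f"item {item_ids[i]}: unobserved categories collapsed before fitting")
            remap = np.searchsorted(seen, np.clip(xi, seen[0], seen[-1]))
            X[:, i] = np.where(obs, remap, -9)
            full_map = np.searchsorted(seen, np.clip(np.arange(n_categories[i]), seen[0], seen[-1]))
            collapse_maps[i] = [int(v) for v in full_map]
            n_categories[i] = len(seen)

    if grid is None:
        grid = default_grid()
    log_w = np.log(prior_weights(grid))

    a = np.ones(n_items)
    bs = []
    counts_i = []
    for i in range(n_items):
        xi = X[:, i]
        c = np.bincount(xi[xi >= 0], minlength=n_categories[i]).astype(float)
        counts_i.append(c)
        bs.append(_initial_steps(c))

    onehots = []
    for i in range(n_items):
        xi = X[:, i]
        obs = xi >= 0
        oh = np.zeros((n, n_categories[i]))
        oh[np.flatnonzero(obs), xi[obs]] = 1.0
        onehots.append(oh)

    loglik = -np.inf
    converged = False
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        log_probs = [np.log(gpcm_prob(grid, a[i], bs[i])) for i in range(n_items)]
        post, loglik = _posterior(X, log_probs, log_w)
        old = np.concatenate([a] + bs)

        rs = [post.T @ onehots[i] for i in range(n_items)]       # (Q, K_i)
        if equal_slopes:
            for i in range(n_items):
                _, bs[i] = _update_item(rs[i], grid, a[0], bs[i], fix_a=a[0])

            def neg_a(av):
                return -sum(_item_objective(av, bs[i], rs[i], grid)[0] for i in range(n_items))
            res = optimize.minimize_scalar(neg_a, bounds=(0.02, 20.0), method="bounded")
            a[:] = res.x
        else:
            for i in range(n_items):
                a[i], bs[i] = _update_item(rs[i], grid, a[i], bs[i])

        if np.max(np.abs(np.concatenate([a] + bs) - old)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fit_gpcm: EM did not converge within max_cycles; returning last iterate")

    log_probs = [np.log(gpcm_prob(grid, a[i], bs[i])) for i in range(n_items)]
    _, loglik = _posterior(X, log_probs, log_w)

    items = [
        Item(id=item_ids[i], n_categories=n_categories[i], discrimination=float(a[i]),
             thresholds=[float(v) for v in bs[i]], collapse_map=collapse_maps[i])
        for i in range(n_items)
    ]
    bank = ItemBank(items)
    if equal_slopes:
        n_params = 1 + sum(k - 1 for k in n_categories)
    else:
        n_params = sum(k for k in n_categories)
    result = CalibrationResult(
        bank=bank,
        log_likelihood=loglik,
        n_params=n_params,
        aic=-2 * loglik + 2 * n_params,
        bic=-2 * loglik + n_params * np.log(n),
        n_persons=n,
        n_cycles=cycle,
        converged=converged,
        model="PCM" if equal_slopes else "GPCM",
    )
    if compute_infit:
        thetas = eap_scores(X, bank, grid=grid)[0]
        result.infit = infit_mnsq(X, bank, thetas)
    return result


@dataclass
class ModelComparison:
    chi2: float
    df: int
    p_value: float
    delta_aic: float
    delta_bic: float


def compare_models(pcm: CalibrationResult, gpcm: CalibrationResult) -> ModelComparison:
    """Likelihood-ratio test of GPCM against its nested equal-slope PCM."""
    if pcm.bank.ids != gpcm.bank.ids:
        raise ValueError("compare_models: fits are not on the same item set")
    if pcm.n_persons != gpcm.n_persons:
        raise ValueError("compare_models: fits are not on the same data")
    chi2 = max(2.0 * (gpcm.log_likelihood - pcm.log_likelihood), 0.0)
    df = len(gpcm.bank) - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return ModelComparison(chi2=chi2, df=df, p_value=p,
                           delta_aic=gpcm.aic - pcm.aic, delta_bic=gpcm.bic - pcm.bic)


# ---------------------------------------------------------------------------
# fit diagnostics

def infit_mnsq(responses, bank: ItemBank, thetas: np.ndarray) -> dict[str, float]:
    """Information-weighted mean-square residual fit per item.

    infit_i = Σ_n (x_ni − E_ni)² / Σ_n W_ni with expectation E and variance W
    taken under the fitted model at each person's trait estimate; values near
    1 indicate fit, the conventional acceptance band being [0.7, 1.3].
    """
    X = coded(responses)
    thetas = np.asarray(thetas, dtype=float)
    out: dict[str, float] = {}
    for i, it in enumerate(bank):
        xi = X[:, i]
        obs = xi >= 0
        if not obs.any():
            out[it.id] = np.nan
            continue
        P = gpcm_prob(thetas[obs], it.discrimination, it.thresholds)  # (n_obs, K)
        k = np.arange(it.n_categories)
        E = P @ k
        W = P @ k**2 - E**2
        denom = W.sum()
        out[it.id] = float(((xi[obs] - E) ** 2).sum() / denom) if denom > 0 else np.nan
    return out


def low_discrimination_items(bank: ItemBank, floor: float = 0.50) -> list[str]:
    """Items whose fitted discrimination falls below the acceptance floor."""
    return [it.id for it in bank if it.discrimination < floor]


# ---------------------------------------------------------------------------
# information

def item_information(theta, item: Item) -> np.ndarray:
    """Fisher information of one item: I(θ) = a² · Var(category | θ)."""
    P = gpcm_prob(theta, item.discrimination, item.thresholds)
    k = np.arange(item.n_categories)
    E = P @ k
    return item.discrimination ** 2 * (P @ k**2 - E**2)


def test_information(bank: ItemBank, grid) -> np.ndarray:
    """Sum of item information functions evaluated on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    return np.sum([item_information(grid, it) for it in bank], axis=0)


def information_share(bank: ItemBank, lo: float, hi: float,
                      full_range: tuple[float, float] = (-6.0, 6.0),
                      n_points: int = 1201) -> float:
    """Fraction of total test information lying in [lo, hi].

    Both integrals use the trapezoid rule on a dense grid over ``full_range``.
    """
    if lo >= hi:
        raise ValueError("information_share: lo must be < hi")
    grid = np.linspace(*full_range, n_points)
    info = test_information(bank, grid)
    total = np.trapezoid(info, grid)
    inside = (grid >= lo) & (grid <= hi)
    return float(np.trapezoid(info[inside], grid[inside]) / total)


# ---------------------------------------------------------------------------
# scoring

@dataclass
class ThetaEstimate:
    theta: float
    sem: float
    score_0_100: float
    n_items_used: int


def transform_score(theta, lo: float = -4.0, hi: float = 4.0):
    """Affine 0-100 score: theta clipped to [lo, hi], then mapped linearly."""
    t = np.clip(np.asarray(theta, dtype=float), lo, hi)
    return (t - lo) / (hi - lo) * 100.0


def inverse_transform_score(score, lo: float = -4.0, hi: float = 4.0):
    """Inverse of :func:`transform_score` inside the clip range."""
    return np.asarray(score, dtype=float) / 100.0 * (hi - lo) + lo


def eap_scores(responses, bank: ItemBank, grid: np.ndarray | None = None):
    """Vectorized EAP point estimates and SEMs for a whole response matrix.

    Returns ``(theta, sem)`` arrays of length n_persons.  All-missing rows
    get the prior mean and SD.
    """
    X = coded(responses)
    if X.shape[1] != len(bank):
        raise ValueError("responses and bank have different item counts")
    if grid is None:
        grid = default_grid()
    log_w = np.log(prior_weights(grid))
    for i, it in enumerate(bank):
        xi = X[:, i]
        bad = (xi >= it.n_categories)
        if bad.any():
            raise ValueError(f"response outside category range for item {it.id}")
    log_probs = _bank_log_probs(bank, grid)
    post, _ = _posterior(X, log_probs, log_w)
    theta = post @ grid
    var = post @ grid**2 - theta**2
    return theta, np.sqrt(np.clip(var, 0.0, None))


def eap_score(pattern, bank: ItemBank, grid: np.ndarray | None = None) -> ThetaEstimate:
    """EAP estimate for one response pattern (missing responses allowed)."""
    pattern = np.asarray(pattern, dtype=float).reshape(1, -1)
    if pattern.shape[1] != len(bank):
        raise ValueError("pattern length must equal bank size")
    theta, sem = eap_scores(pattern, bank, grid=grid)
    n_used = int((np.isfinite(pattern) & (pattern >= 0)).sum())
    lo = bank.transform.get("theta_lo", -4.0)
    hi = bank.transform.get("theta_hi", 4.0)
    return ThetaEstimate(theta=float(theta[0]), sem=float(sem[0]),
                         score_0_100=float(transform_score(theta[0], lo, hi)),
                         n_items_used=n_used)


# ---------------------------------------------------------------------------
# category collapsing

def collapse_categories(responses, item: int | str, merge_map) -> "np.ndarray":
    """Recode one item's categories with an order-preserving merge map.

    ``merge_map[orig] = new`` must be non-decreasing and cover 0..K'-1 with
    K' >= 2.  Unobserved cells pass through untouched.  Returns a copy.
    """
    import pandas as pd

    merge_map = list(merge_map)
    if any(merge_map[i] > merge_map[i + 1] for i in range(len(merge_map) - 1)):
        raise ValueError("merge map must preserve category order")
    tgt = sorted(set(merge_map))
    if tgt != list(range(len(tgt))) or len(tgt) < 2:
        raise ValueError("merge map must be onto 0..K'-1 with at least 2 categories")

    if isinstance(responses, pd.DataFrame):
        out = responses.copy()
        col = item if isinstance(item, str) else out.columns[item]
        v = out[col].to_numpy(dtype=float)
        obs = np.isfinite(v) & (v >= 0)
        v[obs] = np.asarray(merge_map, dtype=float)[v[obs].astype(int)]
        out[col] = v
        return out
    out = np.array(responses, dtype=float)
    v = out[:, item]
    obs = np.isfinite(v) & (v >= 0)
    v[obs] = np.asarray(merge_map, dtype=float)[v[obs].astype(int)]
    out[:, item] = v
    return out


def suggest_collapsing(bank: ItemBank, responses=None, grid: np.ndarray | None = None) -> dict[str, list[int]]:
    """Propose merge maps for categories that are never modal.

    A category is never modal if its fitted probability curve is nowhere the
    maximum over a dense theta grid (monotonicity inspection of the item
    characteristic curves).  Such a category is merged into the adjacent
    category with the higher marginal observed frequency (higher category
    index on ties or when responses are not supplied).
    """
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 401)
    X = coded(responses) if responses is not None else None
    proposals: dict[str, list[int]] = {}
    for i, it in enumerate(bank):
        K = it.n_categories
        P = gpcm_prob(grid, it.discrimination, it.thresholds)
        modal = set(np.argmax(P, axis=1).tolist())
        never = [k for k in range(K) if k not in modal]
        if not never:
            continue
        if X is not None:
            xi = X[:, i]
            freq = np.bincount(xi[xi >= 0], minlength=K).astype(float)
        else:
            freq = np.zeros(K)
        modal_sorted = sorted(modal)

        def target(k: int) -> int:
            # walk toward the adjacent side with higher marginal frequency
            # until a modal category absorbs the merge
            left = freq[k - 1] if k > 0 else -np.inf
            right = freq[k + 1] if k < K - 1 else -np.inf
            d = -1 if left > right else 1
            j = k + d
            while j not in modal:
                j += d
                if j < 0 or j >= K:
                    d = -d
                    j = k + d
            return j

        flat = [k if k in modal else target(k) for k in range(K)]
        if len(modal_sorted) < 2:
            continue
        proposals[it.id] = [modal_sorted.index(v) for v in flat]
    return proposals
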