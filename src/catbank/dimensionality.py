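"""Ordinal dimensionality assessment: polychoric correlations, factor
analysis, parallel analysis, discrepancy-based fit indices, bifactor
indices and local-independence (residual-correlation) checks.

The factoring route is minimum-residual (minres) least squares on the
polychoric correlation matrix, with maximum-likelihood discrepancy-based
RMSEA/CFI/TLI.  This is a documented approximation to categorical-CFA
estimators (e.g. WLSMV) used by commercial SEM software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._codes import as_matrix, observed_mask

__all__ = [
    "polychoric_pair",
    "polychoric_matrix",
    "FactorSolution",
    "efa",
    "parallel_analysis",
    "FitIndices",
    "fit_indices",
    "BifactorIndices",
    "bifactor_indices",
    "residual_correlations",
    "split_half",
]


# ---------------------------------------------------------------------------
# polychoric correlation (two-step estimator)

_INF = 8.5   # effective infinity for normal thresholds


def _margin_thresholds(counts: np.ndarray) -> np.ndarray:
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(np.clip(cum, 1e-6, 1 - 1e-6))


def _cell_probs(tx: np.ndarray, ty: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a bivariate normal over the threshold grid."""
    ax = np.concatenate([[-_INF], tx, [_INF]])
    ay = np.concatenate([[-_INF], ty, [_INF]])
    gx, gy = np.meshgrid(ax, ay, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]],
                                    allow_singular=True)
    F = mvn.cdf(pts).reshape(gx.shape)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-12, None)


def polychoric_pair(x, y) -> float:
    """Two-step polychoric correlation of two ordinal code vectors.

    Thresholds come from the univariate margins; the correlation maximizes
    the bivariate-normal likelihood of the pairwise contingency table.
    Pairs with an empty table return NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & (x >= 0) & np.isfinite(y) & (y >= 0)
    x, y = x[ok].astype(int), y[ok].astype(int)
    if x.size < 3 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return float("nan")
    kx, ky = x.max() + 1, y.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (x, y), 1.0)
    tx = _margin_thresholds(table.sum(axis=1))
    ty = _margin_thresholds(table.sum(axis=0))

    def neg(rho: float) -> float:
        return -(table * np.log(_cell_probs(tx, ty, rho))).sum()

    res = optimize.minimize_scalar(neg, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-5})
    return float(res.x)


def polychoric_matrix(responses) -> pd.DataFrame:
    """Symmetric polychoric correlation matrix with unit diagonal.

    Undefined cells (empty pairwise tables, degenerate margins) stay NaN;
    a warning lists them.
    """
    df = responses if isinstance(responses, pd.DataFrame) else pd.DataFrame(as_matrix(responses))
    cols = [str(c) for c in df.columns]
    x = as_matrix(df)
    m = x.shape[1]
    out = np.eye(m)
    bad = []
    for i in range(m):
        for j in range(i + 1, m):
            r = polychoric_pair(x[:, i], x[:, j])
            if np.isnan(r):
                bad.append((cols[i], cols[j]))
            out[i, j] = out[j, i] = r
    if bad:
        warnings.warn(f"polychoric_matrix: undefined cells for pairs {bad}")
    return pd.DataFrame(out, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# minres factor analysis

@dataclass
class FactorSolution:
    n_factors: int
    loadings: np.ndarray                 # (items, n_factors)
    eigenvalues: np.ndarray              # of the analyzed correlation matrix
    explained_variance_first: float      # share of total variance, factor 1
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    n_obs: int | None
    fit: "FitIndices | None"
    residuals: np.ndarray = field(default=None)  # observed - implied, zero diag

    @property
    def eigenvalue_ratio(self) -> float:
        ev = self.eigenvalues
        return float(ev[0] / ev[1]) if len(ev) > 1 and ev[1] > 0 else float("inf")


def _smooth_corr(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal (logged)."""
    w, V = np.linalg.eigh(R)
    if w.min() > 1e-9:
        return R
    warnings.warn("correlation matrix not positive semi-definite; smoothed")
    w = np.clip(w, 1e-8, None)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _minres_loadings(R: np.ndarray, m: int) -> np.ndarray:
    """Minimum-residual factoring: optimize uniquenesses, loadings by eigen."""
    p = R.shape[0]

    def loadings_given_psi(psi: np.ndarray) -> np.ndarray:
        Rs = R - np.diag(psi)
        w, V = np.linalg.eigh(Rs)
        idx = np.argsort(w)[::-1][:m]
        lam = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
        return lam

    def objective(psi: np.ndarray) -> float:
        lam = loadings_given_psi(psi)
        resid = R - lam @ lam.T
        np.fill_diagonal(resid, 0.0)
        return float((resid ** 2).sum()) / 2

    psi0 = np.full(p, 1.0 - 0.5)
    res = optimize.minimize(objective, psi0, method="L-BFGS-B",
                            bounds=[(0.005, 0.995)] * p,
                            options={"maxiter": 500})
    if not res.success and "ABNORMAL" in str(res.message):
        raise RuntimeError(f"minres factoring failed to converge: {res.message}")
    lam = loadings_given_psi(res.x)
    # sign convention: majority-positive columns
    for j in range(lam.shape[1]):
        if lam[:, j].sum() < 0:
            lam[:, j] = -lam[:, j]
    return lam


def _ml_discrepancy(R: np.ndarray, Sigma: np.ndarray) -> float:
    p = R.shape[0]
    sign, logdet_S = np.linalg.slogdet(Sigma)
    _, logdet_R = np.linalg.slogdet(R)
    inv = np.linalg.solve(Sigma, R)
    return float(logdet_S - logdet_R + np.trace(inv) - p)


def efa(corr, n_factors: int, n_obs: int | None = None) -> FactorSolution:
    """Minres factor analysis of a correlation matrix.

    ``n_factors = 0`` fits the independence model.  When ``n_obs`` is given,
    maximum-likelihood discrepancy chi-squares and RMSEA/CFI/TLI are
    computed against the independence baseline.
    """
    R = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if np.isnan(R).any():
        raise ValueError("efa: correlation matrix has undefined cells")
    R = _smooth_corr(R)
    p = R.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(R))[::-1]

    if n_factors > 0:
        lam = _minres_loadings(R, n_factors)
        Sigma = lam @ lam.T
        np.fill_diagonal(Sigma, 1.0)
    else:
        lam = np.zeros((p, 0))
        Sigma = np.eye(p)

    resid = R - lam @ lam.T
    np.fill_diagonal(resid, 0.0)
    df_model = ((p - n_factors) ** 2 - p - n_factors) // 2
    df_baseline = p * (p - 1) // 2

    chi2_m = chi2_b = np.nan
    fi = None
    if n_obs is not None:
        chi2_m = (n_obs - 1) * _ml_discrepancy(R, Sigma)
        chi2_b = (n_obs - 1) * _ml_discrepancy(R, np.eye(p))
        if df_model > 0:
            fi = fit_indices(chi2_m, df_model, chi2_b, df_baseline, n_obs)

    return FactorSolution(
        n_factors=n_factors, loadings=lam, eigenvalues=eigenvalues,
        explained_variance_first=float(eigenvalues[0] / p),
        chi2_model=float(chi2_m), df_model=df_model,
        chi2_baseline=float(chi2_b), df_baseline=df_baseline,
        n_obs=n_obs, fit=fi, residuals=resid,
    )


def parallel_analysis(responses, n_reps: int = 100, quantile: float = 95.0,
                      seed: int = 0, corr_method: str = "pearson") -> int:
    """Retained factor count by permutation parallel analysis.

    Observed eigenvalues are compared with the given percentile of
    eigenvalues from ``n_reps`` column-wise permutations of the data
    (breaking inter-item structure while keeping margins).  Pearson
    correlations by default; ``corr_method='polychoric'`` is available but
    much slower.
    """
    df = responses if isinstance(responses, pd.DataFrame) else pd.DataFrame(as_matrix(responses))
    x = as_matrix(df)

    def corrmat(arr: np.ndarray) -> np.ndarray:
        d = pd.DataFrame(arr)
        d = d.where(pd.DataFrame(observed_mask(arr)))
        if corr_method == "polychoric":
            return polychoric_matrix(d).to_numpy()
        c = d.corr(min_periods=3).to_numpy()
        np.fill_diagonal(c, 1.0)
        return np.nan_to_num(c, nan=0.0)

    obs_ev = np.sort(np.linalg.eigvalsh(_smooth_corr(corrmat(x))))[::-1]
    rng = np.random.default_rng(seed)
    null = np.empty((n_reps, x.shape[1]))
    for r in range(n_reps):
        perm = np.column_stack([rng.permutation(x[:, j]) for j in range(x.shape[1])])
        null[r] = np.sort(np.linalg.eigvalsh(_smooth_corr(corrmat(perm))))[::-1]
    thresh = np.percentile(null, quantile, axis=0)
    n_keep = 0
    for k in range(x.shape[1]):
        if obs_ev[k] > thresh[k]:
            n_keep += 1
        else:
            break
    return n_keep


# ---------------------------------------------------------------------------
# fit indices

@dataclass
class FitIndices:
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    tli: float


def fit_indices(chi2_model: float, df_model: int, chi2_baseline: float,
                df_baseline: int, n: int, ci_level: float = 0.90) -> FitIndices:
    """RMSEA (with CI by non-central chi-square inversion), CFI and TLI.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    CFI   = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    TLI   = ((chi2_b/df_b) - (chi2_m/df_m)) / ((chi2_b/df_b) - 1).
    """
    if df_baseline <= 0:
        raise ValueError("fit_indices: baseline df must be > 0")
    if df_model <= 0:
        raise ValueError("fit_indices: model df must be > 0")
    if chi2_model < 0 or chi2_baseline < 0:
        raise ValueError("fit_indices: discrepancies must be >= 0")

    d_m = max(chi2_model - df_model, 0.0)
    d_b = max(chi2_baseline - df_baseline, 0.0)
    rmsea = float(np.sqrt(d_m / (df_model * (n - 1))))
    denom = max(d_b, d_m)
    cfi = 1.0 if denom == 0 else float(1.0 - d_m / denom)
    cfi = min(cfi, 1.0)
    ratio_b = chi2_baseline / df_baseline
    ratio_m = chi2_model / df_model
    tli = 1.0 if ratio_b <= 1.0 else float((ratio_b - ratio_m) / (ratio_b - 1.0))
    tli = min(tli, 1.0)

    lo_p = (1 + ci_level) / 2
    hi_p = (1 - ci_level) / 2

    def bound(target: float) -> float:
        # noncentrality lam with ncx2.cdf(chi2, df, lam) = target
        if stats.chi2.cdf(chi2_model, df_model) < target:
            return 0.0
        f = lambda lam: stats.ncx2.cdf(chi2_model, df_model, lam) - target
        hi = max(chi2_model * 2, 10.0)
        while f(hi) > 0:
            hi *= 2
        return optimize.brentq(f, 1e-10, hi)

    lam_lo = bound(lo_p)
    lam_hi = bound(hi_p)
    scale = df_model * (n - 1)
    ci = (float(np.sqrt(lam_lo / scale)), float(np.sqrt(lam_hi / scale)))
    return FitIndices(rmsea=rmsea, rmsea_ci=ci, cfi=cfi, tli=tli)


# ---------------------------------------------------------------------------
# bifactor indices

@dataclass
class BifactorIndices:
    omega_h: float
    omega_hs: list[float]
    ecv_general: float                   # percent
    ecv_groups: list[float]              # percent


def bifactor_indices(general_loadings, group_loadings) -> BifactorIndices:
    """Omega-hierarchical and explained-common-variance of a bifactor model.

    ``group_loadings`` is (items, n_groups) with at most one non-zero entry
    per item (orthogonal bifactor structure).

    ECV_general = sum(lam_g^2) / sum(all lam^2) * 100;
    omega_h = (sum lam_g)^2 / [(sum lam_g)^2 + sum_s (sum lam_s)^2 + sum(1-h^2)].
    """
    g = np.asarray(general_loadings, dtype=float)
    S = np.atleast_2d(np.asarray(group_loadings, dtype=float))
    if S.size == 0:
        S = np.zeros((len(g), 0))
    if S.shape[0] != len(g):
        S = S.T
    if np.any((S != 0).sum(axis=1) > 1):
        raise ValueError("bifactor_indices: an item loads on more than one group factor")

    common = g @ g + (S ** 2).sum()
    h2 = g ** 2 + (S ** 2).sum(axis=1)
    uniq = np.clip(1.0 - h2, 0.0, None).sum()
    group_sumsq = [(S[:, s].sum()) ** 2 for s in range(S.shape[1])]
    total = g.sum() ** 2 + sum(group_sumsq) + uniq
    omega_h = float(g.sum() ** 2 / total) if total > 0 else float("nan")

    omega_hs = []
    for s in range(S.shape[1]):
        members = S[:, s] != 0
        gsum = g[members].sum() ** 2
        ssum = S[members, s].sum() ** 2
        usum = np.clip(1.0 - h2[members], 0.0, None).sum()
        tot = gsum + ssum + usum
        omega_hs.append(float(ssum / tot) if tot > 0 else float("nan"))

    ecv_general = float(100.0 * (g @ g) / common) if common > 0 else float("nan")
    ecv_groups = [float(100.0 * (S[:, s] ** 2).sum() / common) for s in range(S.shape[1])]
    return BifactorIndices(omega_h=omega_h, omega_hs=omega_hs,
                           ecv_general=ecv_general, ecv_groups=ecv_groups)


# ---------------------------------------------------------------------------
# local independence

def residual_correlations(corr, solution: FactorSolution, threshold: float = 0.20):
    """Pairs whose residual correlation exceeds the local-dependence cutoff.

    Residual = observed - model-implied (Lambda Lambda' off-diagonals).
    Returns ``(flagged, suggestion)``: pairs sorted by descending |residual|
    and the item with the largest summed absolute residual among flagged
    pairs (None when nothing is flagged).
    """
    R = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    names = list(corr.columns) if isinstance(corr, pd.DataFrame) else \
        [f"item{i+1}" for i in range(R.shape[0])]
    implied = solution.loadings @ solution.loadings.T
    resid = R - implied
    np.fill_diagonal(resid, 0.0)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(resid[i, j]) > threshold:
                flagged.append((names[i], names[j], float(resid[i, j])))
    flagged.sort(key=lambda t: -abs(t[2]))
    suggestion = None
    if flagged:
        load = {}
        for a, b, r in flagged:
            load[a] = load.get(a, 0.0) + abs(r)
            load[b] = load.get(b, 0.0) + abs(r)
        suggestion = max(load, key=lambda k: (load[k], k))
    return flagged, suggestion


def split_half(n_persons: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random half-split of person indices (EFA half, CFA half)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_persons)
    half = n_persons // 2
    return np.sort(perm[:half]), np.sort(perm[half:])
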