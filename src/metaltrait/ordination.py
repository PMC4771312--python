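"""Multivariate layer: ordination of trait count matrices and the
permutation statistics around it.

Covers Bray-Curtis dissimilarity, PCA (with a deterministic sign
convention), envfit-style vector/factor fitting with permutation p-values,
a permutation test for unequal group dispersion in ordination space,
Spearman correlation screens with Benjamini-Hochberg correction, and
Pearson's chi-squared for categorical associations. All permutation
p-values use the add-one estimator, so the smallest attainable p is
1/(n_permutations + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationModel",
    "EnvfitResult",
    "DispersionResult",
    "bray_curtis",
    "pca",
    "pcoa_scores",
    "envfit",
    "dispersion_test",
    "spearman_screen",
    "chi_squared",
    "benjamini_hochberg",
]


class ZeroVarianceError(ValueError):
    pass


@dataclass
class OrdinationModel:
    scores: pd.DataFrame  # samples x axes
    loadings: pd.DataFrame  # features x axes
    eigenvalues: np.ndarray  # non-increasing
    proportion_explained: np.ndarray
    centered: bool
    scaled: bool


@dataclass
class EnvfitResult:
    variable: str
    kind: str  # "vector" | "factor"
    direction: np.ndarray | None
    r_squared: float
    p_perm: float


@dataclass
class DispersionResult:
    F: float
    p_perm: float
    group_mean_distance: dict


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities of a non-negative count matrix.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); symmetric, zero diagonal,
    bounded in [0, 1]. All-zero rows make the index undefined and raise.
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    if (X.sum(axis=1) == 0).any():
        raise ZeroVarianceError("all-zero row: Bray-Curtis undefined")
    D = squareform(pdist(X, metric="braycurtis"))
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(D, index=matrix.index, columns=matrix.index)
    return pd.DataFrame(D)


def pca(matrix, center: bool = True, scale: bool = False) -> OrdinationModel:
    """Principal components by SVD of the (centered, optionally scaled) matrix.

    Sign convention: within each loading vector the largest-magnitude entry
    is made positive, so results are reproducible across runs and platforms.
    Eigenvalues are the per-axis variances (sum equals total variance).
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(matrix)
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ZeroVarianceError("constant feature with scale=True")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic signs
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    eig = s**2 / (n - 1)
    axes = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(U * s, index=df.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=df.columns, columns=axes)
    return OrdinationModel(scores, loadings, eig, eig / eig.sum(), center, scale)


def pcoa_scores(dissimilarity: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Principal-coordinate embedding of a dissimilarity matrix (scikit-bio)."""
    from skbio.stats.ordination import pcoa as _pcoa

    res = _pcoa(dissimilarity.to_numpy(), number_of_dimensions=n_axes)
    out = res.samples.iloc[:, :n_axes].copy()
    out.index = dissimilarity.index
    out.columns = [f"PCo{k + 1}" for k in range(out.shape[1])]
    return out


def envfit(
    scores,
    variable,
    kind: str | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    n_axes: int = 2,
    name: str = "variable",
) -> EnvfitResult:
    """Fit an external variable to ordination axes, scoring fit by R².

    Continuous variables are regressed on the first ``n_axes`` axes
    (R² = 1 - SSres/SStot; direction = unit coefficient vector). Categorical
    variables score R² = 1 - SSwithin/SStotal of the scores around level
    centroids. Significance comes from permuting the variable across samples
    (add-one estimator).
    """
    S = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    S = S[:, :n_axes]
    v = np.asarray(variable)
    if len(v) != S.shape[0]:
        raise ValueError("variable length must equal sample count")
    if kind is None:
        kind = "vector" if np.issubdtype(v.dtype, np.number) else "factor"
    rng = np.random.default_rng(seed)
    if kind == "vector":
        v = v.astype(float)
        if np.ptp(v) == 0:
            raise ZeroVarianceError("constant variable")
        r2, beta = _vector_r2(S, v, return_beta=True)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        stat = lambda vv: _vector_r2(S, vv)
    elif kind == "factor":
        levels, codes = np.unique(v, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("factor needs at least two levels")
        r2 = _factor_r2(S, codes, len(levels))
        direction = None
        stat = lambda vv: _factor_r2(S, vv, len(levels))
        v = codes
    else:
        raise ValueError(f"unknown kind {kind!r}")
    exceed = 0
    for _ in range(n_permutations):
        if stat(rng.permutation(v)) >= r2:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return EnvfitResult(name, kind, direction, float(r2), float(p))


def _vector_r2(S, v, return_beta=False):
    Sc = S - S.mean(axis=0)
    vc = v - v.mean()
    beta, *_ = np.linalg.lstsq(Sc, vc, rcond=None)
    resid = vc - Sc @ beta
    r2 = 1.0 - (resid @ resid) / (vc @ vc)
    return (r2, beta) if return_beta else r2


def _factor_r2(S, codes, n_levels):
    ss_tot = ((S - S.mean(axis=0)) ** 2).sum()
    ss_within = 0.0
    for k in range(n_levels):
        grp = S[codes == k]
        if len(grp):
            ss_within += ((grp - grp.mean(axis=0)) ** 2).sum()
    return 1.0 - ss_within / ss_tot


def dispersion_test(
    scores,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Permutation test for unequal multivariate dispersion between groups.

    Each sample's distance to its group centroid in the ordination space is
    computed; a one-way F statistic on those distances measures dispersion
    difference, with significance from permuting group labels. Equivalent in
    spirit to a homogeneity-of-dispersion test on ordination scores.
    """
    S = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for k, lev in enumerate(levels):
        if (codes == k).sum() < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 members")
    rng = np.random.default_rng(seed)

    def distances(codes_):
        d = np.empty(len(codes_))
        for k in range(len(levels)):
            mask = codes_ == k
            cen = S[mask].mean(axis=0)
            d[mask] = np.linalg.norm(S[mask] - cen, axis=1)
        return d

    def fstat(d, codes_):
        grand = d.mean()
        ssb = sum(
            (codes_ == k).sum() * (d[codes_ == k].mean() - grand) ** 2
            for k in range(len(levels))
        )
        ssw = sum(((d[codes_ == k] - d[codes_ == k].mean()) ** 2).sum() for k in range(len(levels)))
        dfb, dfw = len(levels) - 1, len(d) - len(levels)
        return (ssb / dfb) / (ssw / dfw) if ssw > 0 else np.inf

    d_obs = distances(codes)
    F = fstat(d_obs, codes)
    exceed = 0
    for _ in range(n_permutations):
        pc = rng.permutation(codes)
        if fstat(distances(pc), pc) >= F:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    means = {lev: float(d_obs[codes == k].mean()) for k, lev in enumerate(levels)}
    return DispersionResult(float(F), float(p), means)


def spearman_screen(data: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Spearman rank correlation (average ranks for ties) for requested pairs.

    Two-sided p-values; BH q-values across the testable pairs. Pairs with a
    constant variable are flagged (NaN rho/p) and excluded from the BH pool.
    """
    rows = []
    for x, y in pairs:
        xv, yv = data[x].to_numpy(dtype=float), data[y].to_numpy(dtype=float)
        if len(xv) < 3:
            raise ValueError("need at least 3 observations")
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append({"x": x, "y": y, "rho": np.nan, "p": np.nan, "constant": True})
            continue
        rho, p = stats.spearmanr(xv, yv)
        rows.append({"x": x, "y": y, "rho": float(rho), "p": float(p), "constant": False})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = ~out["constant"]
    if ok.any():
        out.loc[ok, "q"] = benjamini_hochberg(out.loc[ok, "p"].to_numpy())
    return out


def chi_squared(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson's chi-squared test of independence on a contingency table."""
    T = np.asarray(table, dtype=float)
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: expected counts undefined")
    res = stats.chi2_contingency(T, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH q-values: q_i = min_{j>=i} (m * p_(j) / j), input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
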