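"""Distance-matrix statistics and community descriptors.

Bray-Curtis dissimilarity, (partial) Mantel tests, multiple regression on
distance matrices, dissimilarity-vs-environment regressions, Levins' niche
breadth, rank-sum group comparisons, and CCA-based variation partitioning of
community composition into environmental and spatial components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from .errors import ConsistencyError, DegenerateInputError
from .io import OtuTable, relative_abundance


# ---------------------------------------------------------------------------
# distance matrices

def _as_matrix(d) -> np.ndarray:
    m = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConsistencyError("distance matrix must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ConsistencyError("distance matrix must be symmetric")
    return m


def _condensed(d) -> np.ndarray:
    m = _as_matrix(d)
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def bray_curtis(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, sum|x-y| / sum(x+y)."""
    df = table.data if isinstance(table, OtuTable) else table
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    d = squareform(pdist(x, metric="braycurtis"))
    zero = x.sum(axis=1) == 0
    if zero.any():
        d[np.ix_(zero, zero)] = np.nan
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=df.index, columns=df.index)


def value_distance(values) -> pd.DataFrame:
    """1-D Euclidean (absolute difference) distance matrix of a variable."""
    s = pd.Series(values, dtype=float)
    v = s.to_numpy()
    d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=s.index, columns=s.index)


def euclidean_distance(df: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Euclidean distance over (optionally z-scored) numeric columns."""
    x = df.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=df.index, columns=df.index)


# ---------------------------------------------------------------------------
# Mantel family

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _perm_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(n)


def mantel(d1, d2, n_perm: int = 999, seed: int | None = None,
           alternative: str = "two-sided") -> MantelResult:
    """Mantel test: Pearson correlation of unfolded distance matrices with
    simultaneous row/column permutation of the second matrix."""
    m1, m2 = _as_matrix(d1), _as_matrix(d2)
    if m1.shape != m2.shape:
        raise ConsistencyError("matrices must share shape")
    v1, v2 = _condensed(m1), _condensed(m2)
    ok = np.isfinite(v1) & np.isfinite(v2)
    v1, v2 = v1[ok], v2[ok]
    if v1.std() == 0 or v2.std() == 0:
        raise DegenerateInputError("constant distance matrix: r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        p = _perm_indices(n, rng)
        v2p = m2[np.ix_(p, p)][iu][ok]
        r_perm = np.corrcoef(v1, v2p)[0, 1]
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "less":
            count += r_perm <= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    p_val = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p_val), n_perm=n_perm)


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), controls])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_mantel(d1, d2, controls, n_perm: int = 999,
                   seed: int | None = None,
                   alternative: str = "two-sided") -> MantelResult:
    """Partial Mantel: correlation of d1 and d2 after removing the linear
    effect of the control matrices; permutes d1's rows/columns."""
    if not controls:
        return mantel(d1, d2, n_perm=n_perm, seed=seed,
                      alternative=alternative)
    m1, m2 = _as_matrix(d1), _as_matrix(d2)
    ctrl = np.column_stack([_condensed(c) for c in controls])
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(ctrl)), ctrl])) < ctrl.shape[1] + 1:
        import warnings
        warnings.warn("collinear control matrices; partial r may be unstable")
    v1, v2 = _condensed(m1), _condensed(m2)
    r1 = _residualize(v1, ctrl)
    r2 = _residualize(v2, ctrl)
    if r1.std() == 0 or r2.std() == 0:
        r_obs = 0.0
    else:
        r_obs = float(np.corrcoef(r1, r2)[0, 1])
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        p = _perm_indices(n, rng)
        v1p = m1[np.ix_(p, p)][iu]
        r1p = _residualize(v1p, ctrl)
        if r1p.std() == 0 or r2.std() == 0:
            r_perm = 0.0
        else:
            r_perm = np.corrcoef(r1p, r2)[0, 1]
        if alternative == "greater":
            count += r_perm >= r_obs
        elif alternative == "less":
            count += r_perm <= r_obs
        else:
            count += abs(r_perm) >= abs(r_obs)
    return MantelResult(r=r_obs, p=float((count + 1) / (n_perm + 1)),
                        n_perm=n_perm)


@dataclass
class MrmResult:
    coefficients: pd.Series   # intercept + one per predictor
    p_values: pd.Series
    r_squared: float
    r_squared_p: float
    n_perm: int


def mrm(response, predictors: dict | list, n_perm: int = 999,
        seed: int | None = None) -> MrmResult:
    """Multiple regression on distance matrices: OLS of the unfolded response
    on unfolded predictors, with p-values from row/column permutations of the
    response matrix."""
    if isinstance(predictors, dict):
        names = list(predictors.keys())
        mats = list(predictors.values())
    else:
        names = [f"x{i + 1}" for i in range(len(predictors))]
        mats = list(predictors)
    mr = _as_matrix(response)
    y = _condensed(mr)
    X = np.column_stack([np.ones(len(y))] + [_condensed(m) for m in mats])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design: collinear predictors among {names}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    sse = float(((y - fitted) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rng = np.random.default_rng(seed)
    n = mr.shape[0]
    iu = np.triu_indices(n, k=1)
    exceed = np.zeros(len(beta))
    r2_exceed = 0
    for _ in range(n_perm):
        p = _perm_indices(n, rng)
        yp = mr[np.ix_(p, p)][iu]
        bp, *_ = np.linalg.lstsq(X, yp, rcond=None)
        fp = X @ bp
        ssep = float(((yp - fp) ** 2).sum())
        sstp = float(((yp - yp.mean()) ** 2).sum())
        r2p = 1.0 - ssep / sstp if sstp > 0 else 0.0
        exceed += np.abs(bp) >= np.abs(beta)
        r2_exceed += r2p >= r2
    labels = ["intercept"] + names
    pvals = (exceed + 1) / (n_perm + 1)
    return MrmResult(coefficients=pd.Series(beta, index=labels),
                     p_values=pd.Series(pvals, index=labels),
                     r_squared=r2,
                     r_squared_p=float((r2_exceed + 1) / (n_perm + 1)),
                     n_perm=n_perm)


# ---------------------------------------------------------------------------
# dissimilarity vs environmental difference

@dataclass
class PolyFit:
    order: int
    coefficients: np.ndarray  # ascending powers
    r_squared: float
    slope_p: float


def dissimilarity_env_regression(community_dist, env_values,
                                 orders=(1, 2)) -> dict[int, PolyFit]:
    """Regress pairwise community dissimilarity on pairwise |env difference|
    with polynomial fits of the requested orders."""
    dcom = _condensed(community_dist)
    denv = _condensed(value_distance(env_values))
    ok = np.isfinite(dcom) & np.isfinite(denv)
    dcom, denv = dcom[ok], denv[ok]
    if len(dcom) < 3:
        raise DegenerateInputError("need at least 3 pairs")
    if denv.std() == 0:
        raise DegenerateInputError("environmental differences are constant")
    out = {}
    for order in orders:
        X = np.column_stack([denv ** k for k in range(order + 1)])
        beta, *_ = np.linalg.lstsq(X, dcom, rcond=None)
        fitted = X @ beta
        sst = ((dcom - dcom.mean()) ** 2).sum()
        r2 = 1.0 - ((dcom - fitted) ** 2).sum() / sst if sst > 0 else np.nan
        slope_p = np.nan
        if order == 1:
            _, _, _, slope_p, _ = sps.linregress(denv, dcom)
        out[order] = PolyFit(order=order, coefficients=beta,
                             r_squared=float(r2), slope_p=float(slope_p))
    return out


# ---------------------------------------------------------------------------
# niche breadth

@dataclass
class NicheBreadthResult:
    b: pd.Series       # Levins' B per OTU
    b_com: pd.Series   # community-level mean B over OTUs present


def levins_niche_breadth(table: OtuTable) -> NicheBreadthResult:
    """Levins' B_j = 1 / sum_i P_ij^2 with P_ij the share of OTU j's total
    abundance found in community i; B_com averages B over taxa present."""
    df = table.data
    totals = df.sum(axis=0)
    present = totals > 0
    sub = df.loc[:, present]
    p = sub.div(totals[present], axis=1)
    b = 1.0 / (p ** 2).sum(axis=0)
    b.name = "levins_b"
    occ = sub > 0
    b_com = pd.Series(
        {sid: b[occ.loc[sid]].mean() if occ.loc[sid].any() else np.nan
         for sid in df.index}, name="b_com")
    return NicheBreadthResult(b=b, b_com=b_com)


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney with tie correction)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        import warnings
        warnings.warn("all values tied; p set to 1")
        return 0.0, 1.0
    # exact null distribution when feasible; normal approximation with tie
    # correction otherwise
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 25) else "asymptotic"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# variation partitioning (PCA env axes + dbMEM spatial axes + CCA)

@dataclass
class VpaResult:
    pure_env: float
    pure_space: float
    shared: float
    residual: float
    total_explained: float
    n_env_axes: int
    n_mem_axes: int


def kaiser_guttman_axes(env_table: pd.DataFrame) -> np.ndarray:
    """PCA scores of z-scored variables, keeping axes with eigenvalue above
    the mean eigenvalue."""
    x = env_table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = s ** 2 / max(len(z) - 1, 1)
    keep = eig > eig.mean()
    if not keep.any():
        keep[np.argmax(eig)] = True
    return (u * s)[:, keep]


def dbmem_axes(geo_dist) -> np.ndarray:
    """Distance-based Moran eigenvector maps with positive spatial
    autocorrelation; truncation at the longest minimum-spanning-tree edge."""
    d = _as_matrix(geo_dist)
    n = d.shape[0]
    mst = minimum_spanning_tree(d).toarray()
    thr = mst[mst > 0].max() if (mst > 0).any() else 1.0
    dt = np.where(d <= thr, d, 4.0 * thr)
    np.fill_diagonal(dt, 0.0)
    a = -0.5 * dt ** 2
    h = np.eye(n) - np.ones((n, n)) / n
    g = h @ a @ h
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # connectivity for Moran's I: within truncation distance
    w = ((d <= thr) & ~np.eye(n, dtype=bool)).astype(float)
    e_i = -1.0 / (n - 1)
    keep = []
    for k in range(n):
        if eigval[k] <= 1e-8 * max(abs(eigval[0]), 1.0):
            continue
        v = eigvec[:, k] - eigvec[:, k].mean()
        denom = (v ** 2).sum()
        if denom == 0 or w.sum() == 0:
            continue
        moran = n / w.sum() * (v @ w @ v) / denom
        if moran > e_i:
            keep.append(k)
    if not keep:
        return np.empty((n, 0))
    return eigvec[:, keep]


def _cca_inertia(counts: np.ndarray, X: np.ndarray | None) -> tuple[float, float]:
    """(total, constrained) chi-square inertia of the community table given a
    predictor matrix; X=None gives (total, 0)."""
    total_sum = counts.sum()
    p = counts / total_sum
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    keep_r = r > 0
    keep_c = c > 0
    p = p[np.ix_(keep_r, keep_c)]
    r = r[keep_r]
    c = c[keep_c]
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    total = float((qbar ** 2).sum())
    if X is None or X.shape[1] == 0:
        return total, 0.0
    X = X[keep_r]
    # row-weighted regression of qbar on the predictors
    wsqrt = np.sqrt(r)[:, None]
    xc = X - (r[:, None] * X).sum(axis=0) / r.sum()
    xw = wsqrt * xc
    xw = np.column_stack([wsqrt.ravel(), xw])
    beta, *_ = np.linalg.lstsq(xw, qbar, rcond=None)
    fitted = xw @ beta
    # remove the weighted-mean component (it is 0 for qbar by construction)
    constrained = float((fitted ** 2).sum())
    return total, min(constrained, total)


def variation_partitioning(table: OtuTable, env_table: pd.DataFrame,
                           geo_dist) -> VpaResult:
    """Partition community inertia into pure environmental, pure spatial,
    shared, and residual fractions via CCA on PCA env axes and dbMEM axes."""
    counts = table.counts.astype(float)
    if counts.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    E = kaiser_guttman_axes(env_table)
    S = dbmem_axes(geo_dist)
    n = counts.shape[0]
    max_pred = max(n - 2, 1)
    if E.shape[1] + S.shape[1] > max_pred:
        import warnings
        warnings.warn("more predictors than samples support; truncating")
        e_keep = min(E.shape[1], max_pred // 2 + 1)
        E = E[:, :e_keep]
        S = S[:, :max(max_pred - e_keep, 0)]
    total, i_e = _cca_inertia(counts, E)
    _, i_s = _cca_inertia(counts, S)
    _, i_es = _cca_inertia(counts, np.column_stack([E, S]) if S.size else E)
    ab = i_e / total
    bc = i_s / total
    abc = i_es / total
    shared = ab + bc - abc  # may be slightly negative (suppression)
    pure_e = abc - bc
    pure_s = abc - ab
    residual = 1.0 - abc
    return VpaResult(pure_env=pure_e, pure_space=pure_s, shared=shared,
                     residual=residual, total_explained=abc,
                     n_env_axes=E.shape[1], n_mem_axes=S.shape[1])
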