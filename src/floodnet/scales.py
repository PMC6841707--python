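"""Multi-scale variance decomposition and space-vs-environment partitioning.

Three complementary tools locate the spatial scale at which floodplain
variables are organised:

* a nested random-effects model (biome / floodplain / zone / habitat /
  residual) fitted by REML gives per-variable variance components and their
  percentage shares;
* distance-based Moran eigenvector maps (db-MEM) turn site coordinates into
  orthogonal spatial predictors at all resolvable wavelengths;
* redundancy analysis with forward selection and adjusted-R2 variance
  partitioning splits community variation into unique environmental, unique
  spatial, shared, and residual fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from floodnet.core import EnvTable, SampleHierarchy, ValidationError

NESTED_LEVELS = ("biome", "floodplain", "zone", "habitat")


@dataclass
class VarianceComponents:
    variable: str
    variances: pd.Series  # index: biome, floodplain, zone, habitat, residual
    percents: pd.Series  # same index, sums to 100
    loglik: float
    low_replication: tuple[str, ...] = ()  # levels with < 3 units (weakly identified)


@dataclass
class SpatialEigenvectors:
    vectors: pd.DataFrame  # sites x MEMs, centred and orthonormal
    eigenvalues: np.ndarray
    truncation: float


@dataclass
class VariancePartition:
    env_unique: float  # [a]
    shared: float  # [b]
    space_unique: float  # [c]
    residual: float  # [d]
    adj_r2_env: float
    adj_r2_space: float
    adj_r2_full: float


# ---------------------------------------------------------------------------
# Nested variance-component analysis (REML)
# ---------------------------------------------------------------------------

def _nested_design(h: SampleHierarchy) -> list[np.ndarray]:
    """Indicator matrices for the four nested random levels.

    Units at each level are labelled by the full path down to that level, so
    e.g. "riffle" in two different floodplains is two distinct habitat units.
    """
    t = h.table
    zs = []
    path = None
    for level in NESTED_LEVELS:
        labels = t[level].astype(str)
        path = labels if path is None else path + "/" + labels
        codes, _ = pd.factorize(path)
        z = np.zeros((len(t), codes.max() + 1))
        z[np.arange(len(t)), codes] = 1.0
        zs.append(z)
    return zs


def _reml_nll(log_var: np.ndarray, y: np.ndarray, A: list[np.ndarray]) -> float:
    from scipy.linalg import cho_factor, cho_solve

    v = np.exp(log_var)
    n = len(y)
    V = v[-1] * np.eye(n)
    for s2, a in zip(v[:-1], A):
        V += s2 * a
    try:
        cf = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return 1e12
    logdet = 2 * np.log(np.diag(cf[0])).sum()
    rhs = np.column_stack([y, np.ones(n)])
    sol = cho_solve(cf, rhs, check_finite=False)  # [V^-1 y, V^-1 1]
    Vi_y, Vi_1 = sol[:, 0], sol[:, 1]
    xtvx = Vi_1.sum()  # X = 1 (intercept only)
    beta = Vi_y.sum() / xtvx
    resid = y - beta
    Vi_r = Vi_y - beta * Vi_1
    return 0.5 * (logdet + np.log(xtvx) + resid @ Vi_r)


def _ems_start(y: np.ndarray, zs: list[np.ndarray]) -> np.ndarray:
    """Rough method-of-moments starting values from sequential group means."""
    out = []
    for z in zs:
        means = (z.T @ y) / z.sum(axis=0)
        fitted = z @ means
        out.append(max(np.var(fitted - fitted.mean()), 1e-4))
    out.append(max(np.var(y - zs[-1] @ ((zs[-1].T @ y) / zs[-1].sum(axis=0))), 1e-4))
    return np.array(out)


def vca(
    env: EnvTable,
    h: SampleHierarchy,
    variable: str,
    log_transform: bool = True,
) -> VarianceComponents:
    """REML variance components of one variable over the nested hierarchy.

    Negative components cannot occur (variances are optimised on the log
    scale and floored); shares are percentages of the summed components.
    Levels with fewer than 3 units are flagged ``low_replication`` — with two
    biomes the biome variance is only weakly identified.
    """
    y = env.table.loc[h.sample_ids, variable].to_numpy(dtype=float)
    if log_transform:
        y = np.log(y + 1e-9)
    zs = _nested_design(h)
    low = tuple(
        level for level, z in zip(NESTED_LEVELS, zs) if z.shape[1] < 3
    )
    A = [z @ z.T for z in zs]
    start = _ems_start(y, zs)
    scale = max(np.var(y), 1e-12)
    x0 = np.log(np.clip(start, scale * 1e-6, None))
    res = minimize(
        _reml_nll,
        x0,
        args=(y, A),
        method="L-BFGS-B",
        bounds=[(np.log(scale) - 30, np.log(scale) + 10)] * 5,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    polish = minimize(
        _reml_nll,
        res.x,
        args=(y, A),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
    )
    if polish.fun <= res.fun:
        res.x, res.fun = polish.x, polish.fun
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise ValidationError(
            f"VCA REML failed to converge for {variable!r}: |grad| = {np.linalg.norm(res.jac):.2e}"
        )
    v = np.exp(res.x)
    v[v < scale * 1e-5] = 0.0  # collapse boundary estimates to zero
    names = list(NESTED_LEVELS) + ["residual"]
    variances = pd.Series(v, index=names, name=variable)
    percents = 100 * variances / variances.sum()
    return VarianceComponents(
        variable=variable,
        variances=variances,
        percents=percents,
        loglik=-res.fun,
        low_replication=low,
    )


def vca_table(env: EnvTable, h: SampleHierarchy, variables=None, **kw) -> pd.DataFrame:
    """Percentage variance shares for several variables (one row per variable)."""
    cols = variables if variables is not None else env.variables
    rows = {v: vca(env, h, v, **kw).percents for v in cols}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# db-MEM
# ---------------------------------------------------------------------------

def build_dbmem(coords: np.ndarray, tol: float = 1e-9) -> SpatialEigenvectors:
    """Distance-based Moran eigenvector maps from projected site coordinates.

    The Euclidean distance matrix is truncated at t = the longest edge of the
    minimum spanning tree (which keeps all sites connected); larger distances
    are replaced by 4t.  PCoA of the truncated matrix yields eigenvectors;
    only positive-eigenvalue vectors (positive spatial autocorrelation at
    some scale) are retained, centred and orthonormal.
    """
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or len(xy) < 3:
        raise ValidationError("need >= 3 sites with 2-D coordinates")
    d = squareform(pdist(xy))
    if d.max() == 0:
        raise ValidationError("all sites identical")
    mst = minimum_spanning_tree(d).toarray()
    t = mst.max()
    dt = np.where(d > t, 4 * t, d)
    n = len(xy)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dt**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > tol * max(abs(vals[0]), 1.0)
    vecs = vecs[:, keep]
    vecs = vecs - vecs.mean(axis=0)
    norms = np.linalg.norm(vecs, axis=0)
    vecs = vecs / norms
    for a in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, a])))
        if vecs[j, a] < 0:
            vecs[:, a] = -vecs[:, a]
    return SpatialEigenvectors(
        vectors=pd.DataFrame(vecs, columns=[f"MEM{i + 1}" for i in range(vecs.shape[1])]),
        eigenvalues=vals[keep],
        truncation=float(t),
    )


# ---------------------------------------------------------------------------
# RDA, forward selection, variance partitioning
# ---------------------------------------------------------------------------

def _r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """RDA R2: share of total variance of centred Y explained by projection on X."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    ss_tot = (Yc**2).sum()
    if ss_tot == 0:
        raise ValidationError("response matrix has no variation")
    return float((fit**2).sum() / ss_tot), Yc - fit


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment; p = number of predictor columns."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda_adj_r2(Y: np.ndarray, X: np.ndarray) -> float:
    r2, _ = _r2(np.asarray(Y, float), np.asarray(X, float))
    return adjusted_r2(r2, len(Y), np.linalg.matrix_rank(X - X.mean(axis=0)))


def _perm_pseudo_f(
    Y: np.ndarray, W: np.ndarray | None, x: np.ndarray, n_perm: int, rng
) -> float:
    """Permutation p for adding predictor x given included set W (Freedman-Lane)."""
    n = len(Y)
    if W is None or W.shape[1] == 0:
        Yr = Y - Y.mean(axis=0)
        q = 0
    else:
        _, Yr = _r2(Y, W)
        q = np.linalg.matrix_rank(W - W.mean(axis=0))

    def pseudo_f(Yres: np.ndarray) -> float:
        r2_add, resid = _r2(Yres, x.reshape(-1, 1))
        df_res = n - q - 1 - 1
        if df_res <= 0:
            return np.inf
        return (r2_add / 1) / ((1 - r2_add) / df_res)

    f_obs = pseudo_f(Yr)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(Yr[rng.permutation(n)]) >= f_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def forward_select_rda(
    Y: np.ndarray | pd.DataFrame,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Forward selection of RDA predictors with the double stopping rule.

    A candidate enters if its conditional permutation p <= alpha AND the
    cumulative adjusted R2 stays at or below the global (all-predictor)
    model's adjusted R2.  If the global model itself is not significant the
    selection is empty (with a warning).
    """
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    Xdf = pd.DataFrame(X)
    n = len(Y)
    global_adj = rda_adj_r2(Y, Xdf.to_numpy())
    p_global = _global_p(Y, Xdf.to_numpy(), n_perm, rng)
    if p_global > alpha:
        warnings.warn("global RDA model not significant; empty selection", stacklevel=2)
        return []
    selected: list[str] = []
    remaining = list(Xdf.columns)
    while remaining:
        W = Xdf[selected].to_numpy() if selected else None
        best = None
        for c in remaining:
            cand = np.column_stack([W, Xdf[[c]].to_numpy()]) if W is not None else Xdf[[c]].to_numpy()
            adj = rda_adj_r2(Y, cand)
            if best is None or adj > best[1]:
                best = (c, adj)
        c, adj = best
        if adj > global_adj + 1e-12:
            break
        p = _perm_pseudo_f(Y, W, Xdf[c].to_numpy(dtype=float), n_perm, rng)
        if p > alpha:
            break
        selected.append(c)
        remaining.remove(c)
    return selected


def _global_p(Y: np.ndarray, X: np.ndarray, n_perm: int, rng) -> float:
    n = len(Y)
    q = np.linalg.matrix_rank(X - X.mean(axis=0))

    def pseudo_f(Yp):
        r2, _ = _r2(Yp, X)
        df_res = n - q - 1
        if df_res <= 0:
            return np.inf
        return (r2 / q) / ((1 - r2) / df_res)

    f_obs = pseudo_f(Y)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(Y[rng.permutation(n)]) >= f_obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def varpart(
    Y: np.ndarray | pd.DataFrame,
    X_env: np.ndarray | pd.DataFrame,
    X_spatial: np.ndarray | pd.DataFrame,
) -> VariancePartition:
    """Adjusted-R2 variance partitioning of Y between two predictor sets.

    Fractions follow the Peres-Neto et al. convention: [a] unique
    environmental, [b] shared, [c] unique spatial, [d] residual, obtained by
    subtraction from the adjusted R2 of the env-only, space-only and combined
    models.  Unique/shared fractions may come out slightly negative and are
    reported as computed.
    """
    Y = np.asarray(Y, dtype=float)
    E = np.atleast_2d(np.asarray(X_env, dtype=float))
    S = np.atleast_2d(np.asarray(X_spatial, dtype=float))
    if E.shape[0] != len(Y):
        E = E.T
    if S.shape[0] != len(Y):
        S = S.T
    if E.shape[1] == 0 or S.shape[1] == 0:
        raise ValidationError("both predictor sets must be non-empty")
    full = np.column_stack([E, S])
    rank = np.linalg.matrix_rank(full - full.mean(axis=0))
    if rank >= len(Y) - 1:
        raise ValidationError("full model rank-deficient: too many predictors for n")
    ab = rda_adj_r2(Y, E)
    bc = rda_adj_r2(Y, S)
    abc = rda_adj_r2(Y, full)
    a = abc - bc
    c = abc - ab
    b = ab - a
    d = 1.0 - abc
    return VariancePartition(
        env_unique=a,
        shared=b,
        space_unique=c,
        residual=d,
        adj_r2_env=ab,
        adj_r2_space=bc,
        adj_r2_full=abc,
    )
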