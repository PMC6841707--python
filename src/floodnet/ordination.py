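"""Ordination and group-comparison statistics.

PCA is computed by NIPALS iteration, which tolerates missing cells — the
standard choice for field chemistry tables with occasional censored values.
NMDS minimises Kruskal stress-1 by non-metric SMACOF (isotonic regression of
dissimilarities followed by a Guttman transform), with one PCoA start plus
random restarts.  ANOSIM contrasts between- vs within-group dissimilarity
ranks; envfit projects environmental variables into ordination space with
permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from floodnet.core import ValidationError


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples x axes
    loadings: pd.DataFrame | None = None  # variables x axes (PCA)
    explained: np.ndarray | None = None  # per-axis explained variance fraction (PCA)
    stress: float | None = None  # Kruskal stress-1 (NMDS)
    meta: dict = field(default_factory=dict)


@dataclass
class GroupDispersion:
    centroids: pd.DataFrame  # group x axes
    distances: pd.Series  # per-sample distance to own group centroid
    summary: pd.DataFrame  # per-group mean distance and CV


# ---------------------------------------------------------------------------
# NIPALS PCA
# ---------------------------------------------------------------------------

def nipals_pca(
    x: pd.DataFrame,
    n_axes: int = 2,
    max_iter: int = 20_000,
    tol: float = 1e-28,
) -> OrdinationResult:
    """PCA by NIPALS iteration, tolerating missing (NaN) cells.

    ``x`` should already be log-transformed/standardized as appropriate.
    Each axis is extracted by alternating score/loading regressions over the
    observed cells, then deflated.  Sign convention: the largest-|loading|
    element of each axis is positive.  On complete data this matches the
    eigendecomposition of the covariance matrix.
    """
    X = np.asarray(x, dtype=float)
    n, p = X.shape
    n_axes = min(n_axes, p, n - 1)
    mask = np.isfinite(X)
    if not mask.any():
        raise ValidationError("empty matrix")
    Xc = np.where(mask, X, 0.0)
    # centre on observed cells
    colmean = Xc.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
    R = np.where(mask, X - colmean, 0.0)
    total_var = (R**2).sum()
    scores = np.zeros((n, n_axes))
    loadings = np.zeros((p, n_axes))
    explained = np.zeros(n_axes)
    for a in range(n_axes):
        t = R[:, np.argmax((R**2).sum(axis=0))].copy()
        if not np.any(t):
            break
        for it in range(max_iter):
            # p = R't / t't over observed cells
            denom_p = (mask * t[:, None] ** 2).sum(axis=0)
            pvec = (R * t[:, None]).sum(axis=0) / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            denom_t = (mask * pvec[None, :] ** 2).sum(axis=1)
            t_new = (R * pvec[None, :]).sum(axis=1) / np.where(denom_t > 0, denom_t, 1.0)
            if np.sum((t_new - t) ** 2) < tol * max(np.sum(t_new**2), 1e-300):
                t = t_new
                break
            t = t_new
        else:
            raise ValidationError(f"NIPALS failed to converge on axis {a + 1}")
        j = int(np.argmax(np.abs(pvec)))
        if pvec[j] < 0:
            pvec, t = -pvec, -t
        R = R - np.where(mask, np.outer(t, pvec), 0.0)
        scores[:, a] = t
        loadings[:, a] = pvec
        explained[a] = (t**2).sum() / total_var if total_var > 0 else 0.0
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    idx = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(n)
    cols = x.columns if isinstance(x, pd.DataFrame) else pd.RangeIndex(p)
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=idx, columns=axes),
        loadings=pd.DataFrame(loadings, index=cols, columns=axes),
        explained=explained,
        meta={"method": "nipals"},
    )


def group_dispersion(ord_scores: pd.DataFrame, groups: pd.Series) -> GroupDispersion:
    """Distance of each site to its group centroid in ordination space.

    The per-group mean distance and its coefficient of variation quantify
    environmental heterogeneity (betadisper-style, on retained axes).
    Singleton groups get distance 0 and an undefined (NaN) CV.
    """
    groups = pd.Series(groups).reindex(ord_scores.index)
    cents = ord_scores.groupby(groups).mean()
    diffs = ord_scores.to_numpy() - cents.loc[groups].to_numpy()
    dist = pd.Series(np.linalg.norm(diffs, axis=1), index=ord_scores.index, name="dist")
    rows = []
    for g, d in dist.groupby(groups):
        mean = d.mean()
        cv = d.std(ddof=1) / mean if (len(d) > 1 and mean > 0) else np.nan
        rows.append({"group": g, "n": len(d), "mean_dist": mean, "cv_dist": cv})
    return GroupDispersion(
        centroids=cents, distances=dist, summary=pd.DataFrame(rows).set_index("group")
    )


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress1(d_flat: np.ndarray, conf_d: np.ndarray, iso: IsotonicRegression) -> tuple[float, np.ndarray]:
    dhat = iso.fit_transform(d_flat, conf_d)
    denom = (conf_d**2).sum()
    if denom == 0:
        return 1.0, dhat
    return float(np.sqrt(((conf_d - dhat) ** 2).sum() / denom)), dhat


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int | np.random.Generator = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Runs non-metric SMACOF from a PCoA start plus ``n_starts - 1`` random
    starts and keeps the lowest-stress configuration, centred and rotated to
    its principal axes.  The stress trajectory of the winning start is
    monotone non-increasing (majorization guarantee) and is kept in ``meta``.
    """
    D = np.asarray(d, dtype=float)
    if not np.isfinite(D).all():
        raise ValidationError("non-finite dissimilarities")
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    d_flat = D[iu]
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression()
    order = np.argsort(d_flat)

    def run(x0: np.ndarray):
        x = x0 - x0.mean(axis=0)
        scale = np.sqrt((x**2).sum())
        if scale > 0:
            x /= scale
        trajectory = []
        prev = np.inf
        x_prev = x
        for _ in range(max_iter):
            diff = x[:, None, :] - x[None, :, :]
            cd = np.sqrt((diff**2).sum(-1))[iu]
            stress, dhat = _stress1(d_flat[order], cd[order], iso)
            if stress > prev:  # majorization overshoot: keep previous config
                x, stress = x_prev, prev
                break
            trajectory.append(stress)
            if prev - stress < tol:
                break
            prev = stress
            x_prev = x
            # Guttman transform with disparities dhat (unsorted back)
            dh = np.zeros_like(cd)
            dh[order] = dhat
            W = np.zeros((n, n))
            ratio = np.divide(dh, cd, out=np.zeros_like(dh), where=cd > 0)
            W[iu] = ratio
            W += W.T
            B = -W
            np.fill_diagonal(B, W.sum(axis=1))
            x = B @ x / n
            x -= x.mean(axis=0)
            norm = np.sqrt((x**2).sum())
            if norm > 0:
                x /= norm
        return stress, x, trajectory

    starts = [_pcoa_coords(D, k)]
    starts += [rng.standard_normal((n, k)) for _ in range(max(0, n_starts - 1))]
    best = None
    for x0 in starts:
        stress, x, traj = run(x0)
        if best is None or stress < best[0]:
            best = (stress, x, traj)
    stress, x, traj = best
    # rotate to principal axes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    x = x @ vt.T
    for a in range(x.shape[1]):  # deterministic sign
        j = int(np.argmax(np.abs(x[:, a])))
        if x[j, a] < 0:
            x[:, a] = -x[:, a]
    idx = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    return OrdinationResult(
        scores=pd.DataFrame(x, index=idx, columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=stress,
        meta={"method": "nmds", "n_starts": n_starts, "trajectory": traj},
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim_r(d: np.ndarray, labels: np.ndarray) -> float:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)."""
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    within = labels[iu[0]] == labels[iu[1]]
    if within.all() or not within.any():
        raise ValidationError("need both within- and between-group pairs")
    return float((ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4))


def anosim(
    d: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> dict:
    """ANOSIM with a permutation p-value ((b+1)/(m+1) estimator)."""
    D = np.asarray(d, dtype=float)
    labels = np.asarray(pd.Series(groups))
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValidationError("need >= 2 groups")
    if (counts < 2).any():
        raise ValidationError("every group needs >= 2 members")
    r_obs = anosim_r(D, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anosim_r(D, rng.permutation(labels)) >= r_obs:
            hits += 1
    return {"R": r_obs, "p": (hits + 1) / (n_perm + 1), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(
    ord_scores: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Least-squares fit of environmental variables onto ordination scores.

    Per variable: regression on the (centred) site scores gives r-squared and
    an arrow direction (normalised coefficients, conventionally scaled by
    sqrt(r2) for plotting); the p-value permutes the variable's rows.
    Constant variables get r2 = 0, p = 1.
    """
    S = ord_scores.to_numpy(dtype=float)
    S = S - S.mean(axis=0)
    n = S.shape[0]
    rng = np.random.default_rng(seed)
    # hat matrix pieces reused across variables and permutations
    pinv = np.linalg.pinv(S)
    rows = []
    for var in env.columns:
        y = env[var].to_numpy(dtype=float)
        yc = y - y.mean()
        ss_tot = (yc**2).sum()
        if ss_tot <= 0:
            rows.append({"variable": var, "r2": 0.0, "p": 1.0, "dx": 0.0, "dy": 0.0})
            continue
        beta = pinv @ yc
        fit = S @ beta
        r2 = float((fit**2).sum() / ss_tot)
        perm_r2 = np.empty(n_perm)
        for b in range(n_perm):
            yp = yc[rng.permutation(n)]
            fitp = S @ (pinv @ yp)
            perm_r2[b] = (fitp**2).sum() / ss_tot
        p = (np.sum(perm_r2 >= r2) + 1) / (n_perm + 1)
        direction = beta / np.linalg.norm(beta) if np.linalg.norm(beta) > 0 else beta
        arrow = direction * np.sqrt(r2)
        rows.append(
            {
                "variable": var,
                "r2": r2,
                "p": float(p),
                "dx": float(arrow[0]),
                "dy": float(arrow[1]) if len(arrow) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
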