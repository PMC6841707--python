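"""Colwell predictability of discharge series and habitat-diversity summaries.

Colwell's information-theoretic decomposition treats a periodic environmental
series as a contingency table of time states (months of the year here) by
magnitude classes.  Predictability P splits into constancy C (the flow is
always in the same class) and contingency M (the class is predictable *from*
the season — the seasonality signal that dams erode).  All three lie in
[0, 1] with P = C + M exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from floodnet.core import FlowSeries, SampleHierarchy, ValidationError


@dataclass
class ColwellResult:
    P: float
    C: float
    M: float
    n_time_states: int
    n_flow_classes: int
    contingency: np.ndarray  # (time states, flow classes)

    def __post_init__(self) -> None:
        assert abs(self.P - (self.C + self.M)) < 1e-12
        assert -1e-12 <= self.C <= 1 + 1e-12 and -1e-12 <= self.M <= 1 + 1e-12


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def colwell_from_table(table: np.ndarray) -> ColwellResult:
    """Colwell P/C/M from a time-state x flow-class contingency table."""
    N = np.asarray(table, dtype=float)
    if N.ndim != 2:
        raise ValidationError("contingency table must be 2-D")
    total = N.sum()
    if total == 0:
        raise ValidationError("empty contingency table")
    t, s = N.shape
    if s < 1:
        raise ValidationError("degenerate class structure: no flow classes")
    col = N.sum(axis=1) / total  # time-state marginal
    row = N.sum(axis=0) / total  # flow-class marginal
    if s == 1 or (row > 0).sum() == 1:
        # single occupied class: perfectly constant flow (the limit C -> 1)
        return ColwellResult(P=1.0, C=1.0, M=0.0, n_time_states=t, n_flow_classes=s, contingency=N)
    hx = _entropy(col)
    hy = _entropy(row)
    hxy = _entropy(N.ravel() / total)
    logs = np.log(s)
    C = 1.0 - hy / logs
    M = (hx + hy - hxy) / logs
    # clip infinitesimal negatives from float entropy sums
    C = min(max(C, 0.0), 1.0)
    M = min(max(M, 0.0), 1.0 - C) if C + M > 1.0 else max(M, 0.0)
    return ColwellResult(P=C + M, C=C, M=M, n_time_states=t, n_flow_classes=s, contingency=N)


def _monthly_means(f: FlowSeries) -> pd.DataFrame:
    df = pd.DataFrame({"q": f.discharge}, index=f.dates)
    g = df.groupby([df.index.year, df.index.month])["q"].mean()
    g.index.names = ["year", "month"]
    return g.reset_index()


def _log2_classes(values: np.ndarray, n_max: int = 11) -> np.ndarray:
    """Scale-free log2 binning about the series mean (Colwell 1974 convention).

    Class k holds values in [mean*2^(k-1), mean*2^k); zeros join the lowest
    class.  Because the reference is the series' own mean, multiplying all
    discharges by a constant leaves class labels unchanged.
    """
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        raise ValidationError("non-positive mean discharge")
    with np.errstate(divide="ignore"):
        k = np.floor(np.log2(np.where(v > 0, v / mean, np.nan))).astype(float)
    k = np.where(np.isnan(k), -n_max, k)
    return np.clip(k, -n_max, n_max).astype(int)


def colwell(
    f: FlowSeries,
    time_states: str = "month",
    flow_classes: str = "log2",
    n_class_bins: int = 11,
) -> ColwellResult:
    """Colwell predictability of a discharge series.

    Defaults: time states are the 12 calendar months of monthly-mean
    discharge; flow classes are log2 bins of mean-scaled monthly means.
    Requires at least two complete annual cycles.
    """
    if time_states != "month":
        raise ValidationError(f"unsupported time_states {time_states!r}")
    m = _monthly_means(f)
    n_years = m.groupby("month")["year"].nunique().min()
    if len(m) < 24 or n_years < 2:
        raise ValidationError("need >= 2 complete annual cycles")
    if flow_classes == "log2":
        classes = _log2_classes(m["q"].to_numpy(), n_max=n_class_bins)
    elif flow_classes == "none":  # pre-binned integer series
        classes = m["q"].to_numpy().astype(int)
    else:
        raise ValidationError(f"unsupported flow_classes {flow_classes!r}")
    labels = np.unique(classes)
    table = np.zeros((12, len(labels)))
    cls_idx = {c: j for j, c in enumerate(labels)}
    for month, c in zip(m["month"], classes):
        table[month - 1, cls_idx[c]] += 1
    return colwell_from_table(table)


def colwell_bootstrap(
    f: FlowSeries,
    n_boot: int = 999,
    seed: int | np.random.Generator = 0,
    **colwell_kwargs,
) -> dict:
    """Year-block bootstrap of Colwell's M.

    Whole calendar years are resampled with replacement (preserving
    within-year seasonality), M recomputed per replicate; returns the point
    estimate, bootstrap SE, and the percentile 95% CI.
    """
    rng = np.random.default_rng(seed)
    m = _monthly_means(f)
    pivot = m.pivot(index="year", columns="month", values="q").dropna()
    if len(pivot) < 3:
        raise ValidationError("need >= 3 complete years for a year-block bootstrap")
    point = colwell(f, **colwell_kwargs).M
    mat = pivot.to_numpy()  # (years, 12) monthly means
    n_years = mat.shape[0]
    months = np.tile(np.arange(12), n_years)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        values = mat[rng.integers(0, n_years, size=n_years)].ravel()
        classes = _log2_classes(values)
        labels, cls = np.unique(classes, return_inverse=True)
        table = np.zeros((12, len(labels)))
        np.add.at(table, (months, cls), 1)
        reps[b] = colwell_from_table(table).M
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {
        "M": point,
        "se": float(reps.std(ddof=1)),
        "ci": (float(lo), float(hi)),
        "replicates": reps,
    }


def habitat_diversity(h: SampleHierarchy, floodplain: str) -> float:
    """Shannon H (natural log) of habitat-type frequencies within a floodplain."""
    if floodplain not in set(h.table["floodplain"]):
        raise ValidationError(f"unknown floodplain {floodplain!r}")
    freqs = h.table.loc[h.table["floodplain"] == floodplain, "habitat"].value_counts(normalize=True)
    p = freqs.to_numpy()
    return float(-(p * np.log(p)).sum())
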