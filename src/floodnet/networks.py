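"""Co-occurrence network inference, keystone taxa, and null-model screening.

Edges are significant Pearson correlations of relative abundances between
taxon pairs (|r| >= 0.6 and p <= 0.01 by default); before any network is
interpreted, a C-score test against a fixed-row/fixed-column null certifies
that co-occurrence structure is non-random.  Node importance combines degree,
closeness, and betweenness centrality; taxa exceeding the 75th percentile of
all three are flagged keystone.  Modules are found by modularity
maximisation; per-network summaries mirror the standard complexity table
(nodes, edges, centrality medians, keystones, edge signs by zone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from floodnet.core import CountTable, SampleHierarchy, ValidationError


@dataclass
class CScoreResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_null: int


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph  # nodes = taxa; edge attrs: r, p, sign
    edges: pd.DataFrame  # taxon_a, taxon_b, r, p, sign
    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)  # metrics filled later
    group: str | None = None
    r_threshold: float = 0.6
    p_max: float = 0.01

    def validate_edges(self) -> None:
        if len(self.edges):
            assert (self.edges["r"].abs() >= self.r_threshold - 1e-12).all()
            assert (self.edges["p"] <= self.p_max + 1e-12).all()
        assert not any(a == b for a, b in self.graph.edges())


# ---------------------------------------------------------------------------
# C-score null-model screening
# ---------------------------------------------------------------------------

def cscore(m: np.ndarray) -> float:
    """Stone & Roberts C-score: mean checkerboard units over taxon pairs.

    For taxa i, j with site totals r_i, r_j sharing S_ij sites,
    CU_ij = (r_i - S_ij)(r_j - S_ij); the C-score is the mean over pairs.
    """
    m = np.asarray(m, dtype=bool).astype(np.int64)
    r = m.sum(axis=1)
    S = m @ m.T
    cu = np.multiply.outer(r, r) - r[:, None] * S.T - r[None, :] * S + S * S
    # (r_i - S)(r_j - S) computed via expansion; take upper triangle
    iu = np.triu_indices(len(r), 1)
    return float(cu[iu].mean())


try:  # numba accelerates the swap chain ~100x; plain Python fallback kept
    from numba import njit
except ImportError:  # pragma: no cover
    njit = lambda *a, **k: (lambda f: f)


@njit(cache=True)
def _swap_kernel(m, picks, n_swaps):  # pragma: no cover - jit-compiled
    done = 0
    for t in range(picks.shape[0]):
        a, b, c, d = picks[t, 0], picks[t, 1], picks[t, 2], picks[t, 3]
        if a == b or c == d:
            continue
        if m[a, c] == 1 and m[b, d] == 1 and m[a, d] == 0 and m[b, c] == 0:
            m[a, c] = 0
            m[b, d] = 0
            m[a, d] = 1
            m[b, c] = 1
            done += 1
        elif m[a, c] == 0 and m[b, d] == 0 and m[a, d] == 1 and m[b, c] == 1:
            m[a, c] = 1
            m[b, d] = 1
            m[a, d] = 0
            m[b, c] = 0
            done += 1
        if done >= n_swaps:
            break
    return done


def _swap_chain(m: np.ndarray, n_swaps: int, rng) -> np.ndarray:
    """Sequential checkerboard swaps preserving row and column totals."""
    m = m.copy()
    rows, cols = m.shape
    done = 0
    attempts = 0
    max_attempts = 500 * n_swaps + 20_000
    while done < n_swaps and attempts < max_attempts:
        size = int(min(max(20 * (n_swaps - done), 1000), 400_000))
        picks = np.empty((size, 4), dtype=np.int64)
        picks[:, 0] = rng.integers(0, rows, size)
        picks[:, 1] = rng.integers(0, rows, size)
        picks[:, 2] = rng.integers(0, cols, size)
        picks[:, 3] = rng.integers(0, cols, size)
        done += _swap_kernel(m, picks, n_swaps - done)
        attempts += size
    return m


def cscore_test(
    t: CountTable | np.ndarray,
    n_null: int = 999,
    seed: int | np.random.Generator = 0,
    burn_in: int | None = None,
    thin: int | None = None,
) -> CScoreResult:
    """Two-sided C-score test against the fixed-fixed (swap) null model.

    The presence/absence matrix is randomised by sequential checkerboard
    swaps that preserve both taxon (row) and site (column) totals; after a
    burn-in, null matrices are sampled every ``thin`` successful swaps.
    Degenerate rows (all-present or all-absent) carry no information under
    this null and are excluded with a warning.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    m = t.counts.to_numpy() if isinstance(t, CountTable) else np.asarray(t)
    m = (m > 0).astype(np.int64)
    keep = (m.sum(axis=1) > 0) & (m.sum(axis=1) < m.shape[1])
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} degenerate (all-present/all-absent) rows",
            stacklevel=2,
        )
    m = m[keep]
    if m.shape[0] < 2:
        raise ValidationError("fewer than 2 informative taxa")
    rng = np.random.default_rng(seed)
    n_cells = m.size
    burn_in = burn_in if burn_in is not None else max(5 * n_cells, 1000)
    thin = thin if thin is not None else max(n_cells, 100)
    obs = cscore(m)
    cur = _swap_chain(m, burn_in, rng)
    null = np.empty(n_null)
    for b in range(n_null):
        cur = _swap_chain(cur, thin, rng)
        null[b] = cscore(cur)
    mu, sd = null.mean(), null.std(ddof=1)
    ses = (obs - mu) / sd if sd > 0 else 0.0
    ge = np.sum(null >= obs)
    le = np.sum(null <= obs)
    p = min(1.0, 2 * min(ge + 1, le + 1) / (n_null + 1))
    return CScoreResult(observed=obs, null_mean=float(mu), null_sd=float(sd), ses=float(ses), p=float(p), n_null=n_null)


# ---------------------------------------------------------------------------
# Network inference
# ---------------------------------------------------------------------------

def infer_network(
    t: CountTable,
    r_threshold: float = 0.6,
    p_max: float = 0.01,
    min_samples: int = 10,
    group: str | None = None,
    use_relative: bool = True,
    clr: bool = False,
) -> CooccurrenceNetwork:
    """Correlation-threshold co-occurrence network over one sample group.

    Pearson r is computed across samples per taxon pair on relative
    abundances (set ``clr=True`` for a centred log-ratio transform instead);
    an edge is kept iff |r| >= ``r_threshold`` and its t-test p-value (two-
    sided, n-2 df) <= ``p_max``.  Taxa with no surviving edge are excluded.
    """
    n = t.shape[1]
    if n < min_samples:
        raise ValidationError(f"insufficient replication: {n} samples < {min_samples}")
    if clr:
        x = t.counts.to_numpy(dtype=float) + 0.5
        logx = np.log(x / x.sum(axis=0, keepdims=True))
        mat = logx - logx.mean(axis=0, keepdims=True)
    elif use_relative:
        mat = t.relative_abundance().to_numpy()
    else:
        mat = t.counts.to_numpy(dtype=float)
    sd = mat.std(axis=1)
    taxa = np.array(t.taxon_ids)
    informative = sd > 0
    mat = mat[informative]
    taxa = taxa[informative]
    if len(taxa) < 2:
        raise ValidationError("fewer than 2 variable taxa")
    r = np.corrcoef(mat)
    np.fill_diagonal(r, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(r) >= 1 - 1e-12] = 0.0
    iu = np.triu_indices(len(taxa), 1)
    keep = (np.abs(r[iu]) >= r_threshold) & (p[iu] <= p_max)
    rows = []
    g = nx.Graph()
    for a, b in zip(iu[0][keep], iu[1][keep]):
        rows.append(
            {
                "taxon_a": taxa[a],
                "taxon_b": taxa[b],
                "r": r[a, b],
                "p": p[a, b],
                "sign": "positive" if r[a, b] > 0 else "negative",
            }
        )
        g.add_edge(taxa[a], taxa[b], r=float(r[a, b]), p=float(p[a, b]), weight=abs(float(r[a, b])))
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "sign"])
    rel = t.relative_abundance().mean(axis=1)
    for node in g.nodes():
        g.nodes[node]["rel_abundance"] = float(rel[node])
    net = CooccurrenceNetwork(graph=g, edges=edges, group=group, r_threshold=r_threshold, p_max=p_max)
    net.validate_edges()
    return net


def node_metrics(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Degree, closeness, and betweenness centrality per node.

    Closeness uses the Wasserman-Faust within-component scaling
    ((n_reach-1)/(n-1) factor) so values remain comparable across the
    disconnected components these thresholded networks typically have;
    betweenness is Brandes, normalised; paths are unweighted.
    """
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValidationError("need >= 2 nodes")
    k = dict(g.degree())
    cc = nx.closeness_centrality(g, wf_improved=True)
    bc = nx.betweenness_centrality(g, normalized=True)
    df = pd.DataFrame(
        {
            "degree": pd.Series(k, dtype=float),
            "closeness": pd.Series(cc),
            "betweenness": pd.Series(bc),
        }
    )
    df.index.name = "taxon"
    net.nodes = df
    return df


def keystone_taxa(net: CooccurrenceNetwork) -> list[str]:
    """Taxa strictly above the within-network 75th percentile of k, CC and BC.

    Percentiles use linear interpolation; ties at the percentile do not
    qualify (a regular graph has no keystones).  Networks with < 4 nodes
    return an empty set with a warning.
    """
    if net.nodes is None or net.nodes.empty:
        node_metrics(net)
    m = net.nodes
    if len(m) < 4:
        warnings.warn("fewer than 4 nodes: keystone set empty", stacklevel=2)
        return []
    q = m.quantile(0.75, interpolation="linear")
    flag = (m["degree"] > q["degree"]) & (m["closeness"] > q["closeness"]) & (m["betweenness"] > q["betweenness"])
    net.nodes = m.assign(keystone=flag)
    return list(m.index[flag])


def detect_modules(
    net: CooccurrenceNetwork,
    method: str = "greedy-newman",
    seed: int | np.random.Generator = 0,
    small_fraction: float = 0.025,
) -> dict:
    """Module partition by modularity maximisation, with Q of the partition.

    ``greedy-newman`` is the agglomerative greedy maximisation of Newman
    modularity Q = sum_i (e_ii - a_i^2); ``louvain`` is the seeded Louvain
    heuristic.  Modules holding fewer than ``small_fraction`` of the nodes
    are flagged small.  An edgeless network trivially has every node in its
    own module and Q = 0.
    """
    g = net.graph
    n = g.number_of_nodes()
    if g.number_of_edges() == 0:
        partition = {node: i for i, node in enumerate(g.nodes())}
        return {"partition": partition, "Q": 0.0, "n_modules": n, "small_modules": []}
    if method == "greedy-newman":
        communities = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        rng = np.random.default_rng(seed)
        communities = nx.community.louvain_communities(g, seed=int(rng.integers(2**31)))
    else:
        raise ValidationError(f"unknown method {method!r}")
    communities = [set(c) for c in communities]
    q = nx.community.modularity(g, communities)
    partition = {node: i for i, c in enumerate(communities) for node in c}
    small = [i for i, c in enumerate(communities) if len(c) < small_fraction * n]
    if net.nodes is not None and not net.nodes.empty:
        net.nodes = net.nodes.assign(module=pd.Series(partition).reindex(net.nodes.index))
    return {
        "partition": partition,
        "Q": float(q),
        "n_modules": len(communities),
        "small_modules": small,
    }


def modularity_q(g: nx.Graph, partition: dict) -> float:
    """Newman Q of an arbitrary partition (definitional recomputation)."""
    groups: dict = {}
    for node, mod in partition.items():
        groups.setdefault(mod, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values())))


# ---------------------------------------------------------------------------
# Zone summaries
# ---------------------------------------------------------------------------

def zone_affinity(t: CountTable, h: SampleHierarchy) -> pd.Series:
    """Zone where each taxon's mean relative abundance is higher."""
    rel = t.relative_abundance()
    zones = h.table.loc[t.sample_ids, "zone"]
    means = rel.T.groupby(zones).mean().T  # taxa x zones
    present = [z for z in ("main-channel", "off-channel") if z in means.columns]
    if len(present) < 2:
        return pd.Series("undetermined", index=t.taxon_ids, name="zone_affinity")
    aff = means.idxmax(axis=1)
    aff[means["main-channel"] == means["off-channel"]] = "undetermined"
    return aff.rename("zone_affinity")


def zone_edge_summary(net: CooccurrenceNetwork, h: SampleHierarchy, t: CountTable) -> dict:
    """Edge-sign and zone-affinity summary of a network (complexity-table row).

    Reports % positive/negative edges, same-zone vs cross-zone counts by
    sign, and a keystone-by-zone cross-tab.  Nodes whose affinity cannot be
    determined are excluded from the zone counts.
    """
    aff = zone_affinity(t, h)
    e = net.edges
    n_edges = len(e)
    out = {
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": n_edges,
        "pct_positive": 100.0 * (e["sign"] == "positive").mean() if n_edges else np.nan,
        "pct_negative": 100.0 * (e["sign"] == "negative").mean() if n_edges else np.nan,
    }
    counts = {("positive", True): 0, ("positive", False): 0, ("negative", True): 0, ("negative", False): 0}
    for _, row in e.iterrows():
        za, zb = aff.get(row["taxon_a"], "undetermined"), aff.get(row["taxon_b"], "undetermined")
        if "undetermined" in (za, zb):
            continue
        counts[(row["sign"], za == zb)] += 1
    out.update(
        {
            "same_zone_positive": counts[("positive", True)],
            "cross_zone_positive": counts[("positive", False)],
            "same_zone_negative": counts[("negative", True)],
            "cross_zone_negative": counts[("negative", False)],
        }
    )
    if net.nodes is not None and "keystone" in getattr(net.nodes, "columns", []):
        ks = net.nodes.index[net.nodes["keystone"]]
        out["keystones_by_zone"] = aff.reindex(ks).value_counts().to_dict()
    return out


def network_summary(net: CooccurrenceNetwork) -> dict:
    """Median (IQR) of node metrics plus counts — one complexity-table row."""
    m = net.nodes if net.nodes is not None and not net.nodes.empty else node_metrics(net)
    ks = keystone_taxa(net)
    mods = detect_modules(net)

    def med_iqr(col: str) -> tuple[float, float, float]:
        v = m[col]
        return float(v.median()), float(v.quantile(0.25)), float(v.quantile(0.75))

    return {
        "group": net.group,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "degree_med_iqr": med_iqr("degree"),
        "closeness_med_iqr": med_iqr("closeness"),
        "betweenness_med_iqr": med_iqr("betweenness"),
        "n_keystone": len(ks),
        "pct_positive": 100.0 * (net.edges["sign"] == "positive").mean() if len(net.edges) else np.nan,
        "pct_negative": 100.0 * (net.edges["sign"] == "negative").mean() if len(net.edges) else np.nan,
        "modularity_Q": mods["Q"],
        "n_modules": mods["n_modules"],
    }
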