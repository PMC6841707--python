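"""End-to-end orchestration: prepare -> flow -> diversity -> ordination ->
scales -> networks, with seeds derived per stage and tabular outputs
mirroring the study-style summary tables (variance components, flow
predictability, diversity, ordination scores, variance partitioning, network
complexity)."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from floodnet import core, diversity, flow, networks, ordination, scales
from floodnet.core import CountTable, EnvTable, FlowSeries, SampleHierarchy


@dataclass
class RunConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    env_path: str | None = None
    flow_paths: dict = field(default_factory=dict)  # floodplain -> gauge TSV
    scenario: str | None = None  # generate inputs instead of reading them
    out_dir: str = "out"
    seed: int = 0
    min_prevalence_fraction: float = 0.25
    min_total_reads: int = 20
    rarefaction_depth: int = 10_000
    collapse_level: str = "family"
    n_perm: int = 199
    n_boot: int = 199
    nmds_starts: int = 8
    r_threshold: float = 0.6
    p_max: float = 0.01
    network_group: str = "sub_biome"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def pearson_summary(x, y, label: str) -> dict:
    """Headline bivariate association: Pearson r with its t-test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return {"association": label, "n": int(ok.sum()), "r": np.nan, "p": np.nan}
    r, p = stats.pearsonr(x[ok], y[ok])
    return {"association": label, "n": int(ok.sum()), "r": float(r), "p": float(p)}


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write stage outputs under ``out_dir``.

    The pipeline is a pure function of (inputs, config, seed): every
    stochastic stage receives a recorded sub-seed derived from the global
    seed, and each written table is stamped with the config digest.
    """
    out = Path(cfg.out_dir)
    seeds = _sub_seeds(cfg.seed, 8)
    report: dict = {"config_digest": cfg.digest(), "seeds": seeds}

    # -- inputs -------------------------------------------------------------
    stage = "inputs"
    try:
        if cfg.scenario is not None:
            from floodnet.simulate import gen_scenario

            sc = gen_scenario(cfg.scenario, seed=seeds[0])
            counts, h, env, flows = sc["counts"], sc["hierarchy"], sc["env"], sc["flows"]
            truth = sc["truth"]
            flow_regime = truth.flow_regime
            sub_biome = truth.sub_biome
        else:
            counts = core.read_count_table(cfg.counts_path)
            h = core.read_metadata(cfg.metadata_path)
            env = core.read_env_table(cfg.env_path)
            flows = {fp: FlowSeries.from_tsv(p, river=fp) for fp, p in cfg.flow_paths.items()}
            flow_regime, sub_biome = {}, {}

        # -- prepare --------------------------------------------------------
        stage = "prepare"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prepared = core.filter_taxa(counts, cfg.min_prevalence_fraction, cfg.min_total_reads)
            prepared = core.rarefy(prepared, cfg.rarefaction_depth, seed=seeds[1])
            prepared = core.collapse_taxa(prepared, cfg.collapse_level)
        h_used = h.subset(prepared.sample_ids)
        env_used = EnvTable(env.table.loc[prepared.sample_ids])
        report["n_taxa"], report["n_samples"] = prepared.shape

        # -- flow -----------------------------------------------------------
        stage = "flow"
        flow_rows = []
        for fp, fs in flows.items():
            boot = flow.colwell_bootstrap(fs, n_boot=cfg.n_boot, seed=seeds[2])
            flow_rows.append(
                {
                    "floodplain": fp,
                    "M": boot["M"],
                    "se": boot["se"],
                    "ci_lo": boot["ci"][0],
                    "ci_hi": boot["ci"][1],
                    "regime": flow_regime.get(fp, "unknown"),
                    "habitat_H": flow.habitat_diversity(h_used, fp)
                    if fp in set(h_used.table["floodplain"])
                    else np.nan,
                }
            )
        flow_table = pd.DataFrame(flow_rows).set_index("floodplain") if flow_rows else pd.DataFrame()
        report["flow"] = flow_table

        # -- diversity ------------------------------------------------------
        stage = "diversity"
        alpha = diversity.shannon_alpha(prepared)
        beta_rows = []
        for fp in h_used.floodplains:
            ids = h_used.samples_in(floodplain=fp)
            if len(ids) < 3:
                continue
            sub = prepared.subset_samples(ids)
            inc = diversity.multi_site_beta(sub, mode="incidence")
            pair = diversity.beta_partition(sub, mode="incidence")
            tri = pair.total.to_numpy()[np.triu_indices(len(ids), 1)]
            beta_rows.append(
                {
                    "floodplain": fp,
                    "beta_sor_multi": inc["total"],
                    "turnover_multi": inc["turnover"],
                    "nestedness_multi": inc["nestedness"],
                    "beta_sor_pairwise_mean": float(np.nanmean(tri)),
                }
            )
        beta_table = pd.DataFrame(beta_rows).set_index("floodplain")
        guild_frac = diversity.guild_fractions(prepared, "heterocystous-cyanobacteria") \
            if prepared.guild is not None and (prepared.guild == "heterocystous-cyanobacteria").any() \
            else pd.Series(np.nan, index=prepared.sample_ids)
        report["alpha"] = alpha
        report["beta"] = beta_table

        # -- ordination -----------------------------------------------------
        stage = "ordination"
        envx = env_used.log_standardized()
        pca = ordination.nipals_pca(envx, n_axes=2)
        disp = ordination.group_dispersion(pca.scores, h_used.table["floodplain"])
        bc = diversity.bray_curtis(prepared)
        nm = ordination.nmds(bc, k=2, n_starts=cfg.nmds_starts, seed=seeds[3])
        groups = h_used.table["floodplain"]
        anosim_fp = ordination.anosim(bc, groups, n_perm=cfg.n_perm, seed=seeds[4])
        fit = ordination.envfit(nm.scores, env_used.table, n_perm=cfg.n_perm, seed=seeds[5])
        report["pca"] = pca
        report["dispersion"] = disp.summary
        report["nmds_stress"] = nm.stress
        report["anosim_floodplain"] = anosim_fp
        report["envfit"] = fit

        # -- scales ---------------------------------------------------------
        stage = "scales"
        vca_tab = scales.vca_table(env_used, h_used)
        mem = scales.build_dbmem(h_used.coords())
        Y = diversity.hellinger(prepared.counts.to_numpy(dtype=float).T)
        Xs = mem.vectors.set_index(pd.Index(h_used.sample_ids))
        sel_s = scales.forward_select_rda(Y, Xs, n_perm=cfg.n_perm, seed=seeds[6])
        sel_e = scales.forward_select_rda(Y, envx, n_perm=cfg.n_perm, seed=seeds[7])
        if sel_s and sel_e:
            part = scales.varpart(Y, envx[sel_e], Xs[sel_s])
            report["varpart"] = part
        else:
            report["varpart"] = None
        report["vca"] = vca_tab
        report["selected_space"] = sel_s
        report["selected_env"] = sel_e

        # -- networks -------------------------------------------------------
        stage = "networks"
        if cfg.network_group == "sub_biome" and sub_biome:
            grouping = h_used.table["floodplain"].map(sub_biome)
        else:
            grouping = h_used.table["biome"]
        net_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for grp in sorted(grouping.dropna().unique()):
                ids = list(grouping.index[grouping == grp])
                if len(ids) < 10:
                    continue
                sub = prepared.subset_samples(ids)
                cs = networks.cscore_test(sub, n_null=99, seed=seeds[4])
                net = networks.infer_network(sub, cfg.r_threshold, cfg.p_max, group=grp)
                if net.graph.number_of_nodes() < 2:
                    net_rows.append({"group": grp, "n_nodes": 0, "n_edges": 0, "cscore_ses": cs.ses})
                    continue
                summary = networks.network_summary(net)
                summary.update(networks.zone_edge_summary(net, h_used, sub))
                summary["cscore_ses"] = cs.ses
                summary["cscore_p"] = cs.p
                net_rows.append(summary)
        net_table = pd.DataFrame(net_rows).set_index("group") if net_rows else pd.DataFrame()
        report["networks"] = net_table

        # -- headline associations ------------------------------------------
        stage = "associations"
        assoc = []
        if len(flow_table):
            common = flow_table.dropna(subset=["habitat_H"])
            assoc.append(pearson_summary(common["M"], common["habitat_H"], "M_vs_habitat_H"))
            hetero = disp.summary["cv_dist"].reindex(common.index)
            assoc.append(pearson_summary(common["M"], hetero, "M_vs_env_heterogeneity"))
        assoc.append(
            pearson_summary(
                np.log(env_used.table["NP"]), guild_frac.reindex(env_used.table.index), "logNP_vs_cyano_fraction"
            )
        )
        report["associations"] = pd.DataFrame(assoc).set_index("association")
    except Exception as exc:
        _write_outputs(out, report, partial=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _write_outputs(out, report)
    return report


def _write_outputs(out: Path, report: dict, partial: bool = False) -> None:
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_digest": report.get("config_digest"), "seeds": report.get("seeds"), "partial": partial}
    with open(out / "run.json", "w") as fh:
        json.dump(stamp, fh, indent=1)
    for key in ("flow", "beta", "vca", "networks", "envfit", "dispersion", "associations"):
        obj = report.get(key)
        if isinstance(obj, pd.DataFrame) and len(obj):
            obj.to_csv(out / f"{key}.tsv", sep="\t")
    alpha = report.get("alpha")
    if isinstance(alpha, pd.Series):
        alpha.to_csv(out / "alpha.tsv", sep="\t")
    pca = report.get("pca")
    if pca is not None:
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    vp = report.get("varpart")
    if vp is not None:
        with open(out / "varpart.json", "w") as fh:
            json.dump(
                {
                    "env_unique": vp.env_unique,
                    "shared": vp.shared,
                    "space_unique": vp.space_unique,
                    "residual": vp.residual,
                },
                fh,
                indent=1,
            )
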