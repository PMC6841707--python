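"""Synthetic floodplain scenarios with known ground truth.

The generator emulates the structure of a multi-floodplain biofilm survey:

* a four-level sampling hierarchy (2 biomes, 10 floodplains, 2 lateral zones,
  10 habitat types with replicates) where free-flowing rivers carry the full
  habitat spectrum and dam-regulated ones a reduced set;
* daily discharge with a snowmelt-season harmonic (free-flowing) or a
  flattened seasonal signal plus irregular operation pulses (dammed);
* water chemistry built from independent Gaussian effects at each nested
  scale, with per-variable variance shares configurable (defaults follow the
  observed pattern: floodplain-scale dominance for most solutes, habitat- and
  residual-scale dominance for ammonium, chlorophyll-a and benthic organic
  matter) and molar N:P derived from the generated TN and TP; the three
  sub-biome N:P regimes (N-limited ~1.8, N-rich ~12.7, grassland ~30.7) enter
  as TN mean shifts;
* communities whose log-abundances combine a log-normal baseline, niche
  responses to standardised environmental axes (heterocystous cyanobacteria
  respond negatively to log N:P), latent co-abundance factors that define
  true network modules (loading signs set association signs), a zone-affinity
  offset, and multinomial read sampling.

Everything is a pure function of (config, seed); `GroundTruth` records the
generating parameters so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from floodnet.core import (
    CountTable,
    EnvTable,
    FlowSeries,
    MAIN_CHANNEL_HABITATS,
    OFF_CHANNEL_HABITATS,
    HABITAT_ZONE,
    SampleHierarchy,
    ValidationError,
)

#: Default per-variable variance shares (%) across
#: biome / floodplain / zone / habitat / residual scales.
DEFAULT_VARIANCE_FRACTIONS: dict[str, tuple[float, ...]] = {
    "DOC": (0, 63, 4, 13, 20),
    "NH4": (0, 0, 13, 0, 87),
    "NO3": (0, 60, 4, 2, 34),
    "DON": (0, 64, 3, 3, 30),
    "TN": (11, 63, 9, 0, 17),
    "SRP": (0, 73, 0, 21, 6),
    "TP": (0, 87, 1, 9, 4),  # rounds to 101; renormalised at construction
    "chla": (0, 8, 0, 13, 79),
    "BOM": (0, 0, 8, 19, 73),
}

#: Sub-biome molar N:P regime means.
DEFAULT_NP_REGIMES = {"n-limited": 1.8, "n-rich": 12.7, "grassland": 30.7}

#: Reference concentrations (central values on the natural scale).
REF_LEVELS = {
    "DOC": 3.0,  # mg C/L
    "NH4": 8.0,  # ug N/L
    "NO3": 30.0,  # ug N/L
    "DON": 100.0,  # ug N/L
    "TN": 300.0,  # ug N/L
    "SRP": 5.0,  # ug P/L
    "TP": 20.0,  # ug P/L
    "chla": 3.0,  # mg/m2
    "BOM": 20.0,  # g AFDM/m2
}

REDUCED_HABITATS = ("riffle", "run", "pool", "backwater")  # dammed floodplains


@dataclass
class ModuleSpec:
    """One latent co-abundance factor: member taxa and signed loadings.

    ``baseline_shift`` moves the members' log-baseline: an abundant module
    (positive shift) dominates the read pool, so compositional closure turns
    its mixed-sign dynamics into strong negative fraction-correlations; a
    rare module (negative shift) leaves closure negligible and its
    associations purely positive.
    """

    taxa: list[int]
    loadings: list[float]
    baseline_shift: float = 0.0
    baseline_sd: float | None = None  # override the global baseline spread


@dataclass
class ScenarioConfig:
    name: str = "default"
    n_montane: int = 6
    n_grassland: int = 4
    n_rep: int = 3  # samples per habitat unit
    uniform_habitats: bool = False  # all floodplains get the full habitat set
    variance_fractions: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCE_FRACTIONS))
    total_log_variance: float = 0.5  # per-variable variance on the log scale
    np_regimes: dict = field(default_factory=lambda: dict(DEFAULT_NP_REGIMES))
    n_taxa: int = 60
    n_cyano: int = 6  # heterocystous
    n_other_cyano: int = 6
    n_diatom: int = 12
    cyano_np_slope: float = -1.0  # response of heterocystous cyanos to z(log N:P)
    niche_slope_sd: float = 0.3  # background taxon responses to env axes
    baseline_sd: float = 1.0  # log-normal taxon baseline spread
    taxon_noise_sd: float = 0.5  # per-taxon per-sample residual (log scale)
    modules: list[ModuleSpec] = field(default_factory=list)
    zone_offsets: dict = field(default_factory=dict)  # taxon index -> +/- main-channel offset
    zone_offset_amp: float = 0.5
    read_depth: int = 20_000
    read_depth_sigma: float = 0.15  # lognormal spread of depth
    flow_years: int = 10

    def __post_init__(self) -> None:
        for var, fr in self.variance_fractions.items():
            fr = np.asarray(fr, dtype=float)
            if len(fr) != 5 or (fr < 0).any():
                raise ValidationError(f"{var}: need 5 non-negative variance fractions")
            total = fr.sum()
            if abs(total - 100) > 1.5:
                raise ValidationError(f"{var}: variance fractions sum to {total}, not 100")
            self.variance_fractions[var] = tuple(100 * fr / total)
        for nm in ("n_montane", "n_grassland", "n_rep", "n_taxa"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"{nm} must be positive")

    # -- presets ------------------------------------------------------------
    @classmethod
    def preset(cls, name: str) -> "ScenarioConfig":
        """Named scenario presets.

        ``null``: exchangeable taxa (no niche, no modules).
        ``two-module``: two clean positive-loading modules (recovery tests).
        ``n-limited``: one dominant mixed-sign factor with opposite zone
        affinities plus three small modules — sparser, more negative, more
        modular networks.
        ``n-rich`` / ``grassland``: one large all-positive module — dense,
        positive, weakly modular networks.
        """
        cfg = cls(name=name)
        if name == "null":
            cfg.cyano_np_slope = 0.0
            cfg.niche_slope_sd = 0.0
            cfg.modules = []
            return cfg
        cfg.taxon_noise_sd = 0.3  # structured presets: tighter taxon noise
        if name == "two-module":
            cfg.niche_slope_sd = 0.0
            cfg.cyano_np_slope = 0.0
            cfg.modules = [
                ModuleSpec(list(range(0, 10)), [1.4] * 10, baseline_shift=-1.0),
                ModuleSpec(list(range(10, 20)), [1.4] * 10, baseline_shift=-1.0),
            ]
        elif name == "n-limited":
            # An abundant guild (heterocystous cyanos on the + side) whose two
            # halves occupy opposite lateral zones, plus three small rare
            # modules.  The bimodal zone exchange of an abundant group is what
            # produces strong NEGATIVE fraction-correlations (a lognormal
            # factor alone cannot: its negative Pearson is capped near
            # -1/CV^2); the dominant module's factor loading is therefore kept
            # small so within-zone spread does not dilute the anticorrelation.
            # Within a single sub-biome the N:P range is narrow, so the cyano
            # sorting slope is weak here (the default scenario, spanning all
            # three regimes, carries the full slope of -1).
            cfg.niche_slope_sd = 0.1
            cfg.cyano_np_slope = -0.3
            cfg.taxon_noise_sd = 0.3
            cfg.np_regimes = {k: 1.8 for k in cfg.np_regimes}
            dom = list(range(0, 10))
            signs = [0.4] * 5 + [-0.4] * 5
            cfg.modules = [ModuleSpec(dom, signs, baseline_shift=0.9, baseline_sd=0.25)]
            for k in range(3):
                taxa = list(range(10 + 4 * k, 14 + 4 * k))
                cfg.modules.append(ModuleSpec(taxa, [1.2] * 4, baseline_shift=-1.5))
            cfg.zone_offsets = {i: (1 if s > 0 else -1) for i, s in zip(dom, signs)}
            cfg.zone_offset_amp = 1.6
        elif name in ("n-rich", "grassland"):
            # one large RARE positively-loaded module (rare so compositional
            # closure neither distorts its positive associations nor couples
            # the unstructured taxa): dense, positive, weakly modular
            cfg.niche_slope_sd = 0.1
            cfg.cyano_np_slope = -0.3
            cfg.taxon_noise_sd = 0.35
            regime = 12.7 if name == "n-rich" else 30.7
            cfg.np_regimes = {k: regime for k in cfg.np_regimes}
            cfg.modules = [ModuleSpec(list(range(0, 35)), [0.9] * 35, baseline_shift=-2.0)]
            cfg.zone_offsets = {i: 1 for i in range(0, 35)}
            cfg.zone_offset_amp = 0.4
        elif name == "default":
            cfg.modules = [
                ModuleSpec(list(range(0, 12)), [1.3] * 12, baseline_shift=-0.5),
                ModuleSpec(list(range(12, 20)), [1.3] * 4 + [-1.3] * 4, baseline_shift=0.5),
            ]
            cfg.zone_offsets = {i: (1 if i % 2 else -1) for i in range(0, 20)}
        else:
            raise ValidationError(f"unknown preset {name!r}")
        return cfg


@dataclass
class GroundTruth:
    variance_fractions: dict
    niche_slopes: dict  # taxon -> (slope on z(log N:P), slope on z(log DOC))
    module_of: dict  # taxon -> module index or None
    loading_of: dict  # taxon -> signed loading or 0
    zone_affinity: dict  # taxon -> main-channel | off-channel | none
    flow_regime: dict  # floodplain -> free-flowing | dammed
    sub_biome: dict  # floodplain -> n-limited | n-rich | grassland
    guild: dict  # taxon -> guild label

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def make_hierarchy(cfg: ScenarioConfig, seed: int | np.random.Generator = 0) -> tuple[SampleHierarchy, dict, dict]:
    """Sampling design: samples, their hierarchy labels, and coordinates.

    Montane floodplains M1..M3 form the N-limited sub-biome, M4..M6 the
    N-rich one; grassland floodplains are their own sub-biome.  Dammed rivers
    (all grassland plus the last montane) carry a reduced habitat set unless
    ``uniform_habitats`` is on.  Returns (hierarchy, flow_regime, sub_biome).
    """
    rng = np.random.default_rng(seed)
    rows = []
    flow_regime: dict[str, str] = {}
    sub_biome: dict[str, str] = {}
    fp_centers: dict[str, tuple[float, float]] = {}
    fps = [("montane", f"M{i + 1}") for i in range(cfg.n_montane)]
    fps += [("grassland", f"G{i + 1}") for i in range(cfg.n_grassland)]
    for idx, (biome, fp) in enumerate(fps):
        if biome == "montane":
            i = int(fp[1:]) - 1
            half = max(1, cfg.n_montane // 2)
            sub_biome[fp] = "n-limited" if i < half else "n-rich"
            dammed = i == cfg.n_montane - 1
            cx = rng.uniform(0, 200_000)
        else:
            sub_biome[fp] = "grassland"
            dammed = True
            cx = rng.uniform(300_000, 500_000)
        flow_regime[fp] = "dammed" if dammed else "free-flowing"
        cy = rng.uniform(0, 300_000)
        fp_centers[fp] = (cx, cy)
        habitats = (
            MAIN_CHANNEL_HABITATS + OFF_CHANNEL_HABITATS
            if (cfg.uniform_habitats or not dammed)
            else REDUCED_HABITATS
        )
        for hab in habitats:
            for r in range(cfg.n_rep):
                rows.append(
                    {
                        "sample_id": f"{fp}-{hab}-{r + 1}",
                        "biome": biome,
                        "floodplain": fp,
                        "zone": HABITAT_ZONE[hab],
                        "habitat": hab,
                        "x": cx + rng.uniform(-2000, 2000),
                        "y": cy + rng.uniform(-2000, 2000),
                    }
                )
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleHierarchy(table), flow_regime, sub_biome


# ---------------------------------------------------------------------------
# Flow
# ---------------------------------------------------------------------------

def gen_flow(
    years: int = 10,
    regime: str = "free-flowing",
    seed: int | np.random.Generator = 0,
    river: str = "synthetic",
    mean_log_q: float = 3.0,
    amplitude: float | None = None,
    noise_sd: float | None = None,
    ar_rho: float = 0.7,
) -> FlowSeries:
    """Daily discharge: seasonal harmonic + AR(1) noise on the log scale.

    Free-flowing rivers get a strong snowmelt harmonic (amplitude >> noise);
    dammed rivers a nearly flat harmonic plus irregular square operation
    pulses.  Needs >= 2 years (two full cycles for predictability analysis).
    """
    if years < 2:
        raise ValidationError("need >= 2 years of flow")
    if regime not in ("free-flowing", "dammed"):
        raise ValidationError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    n = 365 * years
    doy = np.arange(n) % 365
    if regime == "free-flowing":
        a = 1.2 if amplitude is None else amplitude
        sd = 0.25 if noise_sd is None else noise_sd
    else:
        a = 0.12 if amplitude is None else amplitude
        sd = 0.35 if noise_sd is None else noise_sd
    # peak near day 150 (late-spring snowmelt)
    seasonal = a * np.cos(2 * np.pi * (doy - 150) / 365)
    eps = np.empty(n)
    eps[0] = rng.normal(0, sd)
    innov = rng.normal(0, sd * np.sqrt(1 - ar_rho**2), n)
    for i in range(1, n):
        eps[i] = ar_rho * eps[i - 1] + innov[i]
    logq = mean_log_q + seasonal + eps
    if regime == "dammed":
        n_pulses = rng.poisson(4 * years)
        for _ in range(n_pulses):
            start = rng.integers(0, n)
            dur = rng.integers(10, 40)
            amp = rng.uniform(0.3, 1.0) * rng.choice([-1, 1])
            logq[start : start + dur] += amp
    dates = pd.date_range("2001-01-01", periods=n, freq="D")
    return FlowSeries(river, dates, np.exp(logq))


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

def gen_env(
    cfg: ScenarioConfig,
    hierarchy: SampleHierarchy,
    seed: int | np.random.Generator = 0,
    sub_biome: dict | None = None,
) -> EnvTable:
    """Nested-variance chemistry table.

    Each variable's log value is a grand mean plus independent Gaussian
    effects per biome, floodplain, zone and habitat unit (variances
    proportional to the configured percentage shares of
    ``total_log_variance``) plus residual noise.  TN means shift per
    sub-biome so that molar N:P matches the configured regimes; N:P itself is
    computed from the generated TN and TP.
    """
    rng = np.random.default_rng(seed)
    t = hierarchy.table
    n = len(t)
    paths = {}
    path = None
    for level in ("biome", "floodplain", "zone", "habitat"):
        labels = t[level].astype(str)
        path = labels if path is None else path + "/" + labels
        paths[level] = pd.factorize(path)[0]
    values = {}
    for var, fr in cfg.variance_fractions.items():
        sd = np.sqrt(np.asarray(fr) / 100 * cfg.total_log_variance)
        y = np.full(n, np.log(REF_LEVELS[var]))
        for lvl_i, level in enumerate(("biome", "floodplain", "zone", "habitat")):
            codes = paths[level]
            effects = rng.normal(0, sd[lvl_i], codes.max() + 1)
            y = y + effects[codes]
        y = y + rng.normal(0, sd[4], n)
        values[var] = y
    if sub_biome:
        # shift mean log TN so molar (TN/14)/(TP/31) matches the N:P regime
        tp_ref = REF_LEVELS["TP"]
        for fp, sb in sub_biome.items():
            target = cfg.np_regimes[sb]
            mask = (t["floodplain"] == fp).to_numpy()
            values["TN"] = np.where(
                mask,
                values["TN"] - np.log(REF_LEVELS["TN"]) + np.log(target * (14 / 31) * tp_ref),
                values["TN"],
            )
    df = pd.DataFrame({v: np.exp(y) for v, y in values.items()}, index=t.index)
    df["NP"] = (df["TN"] / 14.0) / (df["TP"] / 31.0)
    df = df[["DOC", "NH4", "NO3", "DON", "TN", "SRP", "TP", "NP", "chla", "BOM"]]
    return EnvTable(df)


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def _guilds(cfg: ScenarioConfig) -> list[str]:
    g = (
        ["heterocystous-cyanobacteria"] * cfg.n_cyano
        + ["other-cyanobacteria"] * cfg.n_other_cyano
        + ["diatom"] * cfg.n_diatom
    )
    g += ["other"] * (cfg.n_taxa - len(g))
    return g[: cfg.n_taxa]


def gen_community(
    cfg: ScenarioConfig,
    env: EnvTable,
    hierarchy: SampleHierarchy,
    seed: int | np.random.Generator = 0,
) -> tuple[CountTable, GroundTruth]:
    """Multinomial read table from a latent log-abundance model.

    Expected log-abundance per taxon and sample = log-normal baseline +
    niche slopes x standardised environmental axes (z of log N:P and log
    DOC) + module loadings x per-sample latent factors + zone-affinity
    offset + taxon-level noise; reads are drawn multinomially at a
    log-normally distributed depth.  Guild order: heterocystous
    cyanobacteria first, then other cyanobacteria, diatoms, the rest.
    """
    rng = np.random.default_rng(seed)
    t = hierarchy.table
    n_samples = len(t)
    nt = cfg.n_taxa
    guilds = _guilds(cfg)
    # environmental axes (z-scored logs)
    z_np = np.log(env.table["NP"].to_numpy(dtype=float))
    z_np = (z_np - z_np.mean()) / (z_np.std() or 1.0)
    z_doc = np.log(env.table["DOC"].to_numpy(dtype=float))
    z_doc = (z_doc - z_doc.mean()) / (z_doc.std() or 1.0)
    slopes = rng.normal(0, cfg.niche_slope_sd, (nt, 2))
    for i, g in enumerate(guilds):
        if g == "heterocystous-cyanobacteria":
            slopes[i, 0] = cfg.cyano_np_slope
        elif g == "other-cyanobacteria":
            slopes[i, 0] = cfg.cyano_np_slope / 2
    baseline = rng.normal(0, cfg.baseline_sd, nt)
    logit = baseline[:, None] + slopes @ np.vstack([z_np, z_doc])
    module_of: dict[int, int | None] = {i: None for i in range(nt)}
    loading_of: dict[int, float] = {i: 0.0 for i in range(nt)}
    for m_idx, mod in enumerate(cfg.modules):
        factor = rng.normal(0, 1.0, n_samples)
        for taxon, lam in zip(mod.taxa, mod.loadings):
            if mod.baseline_sd is not None:  # re-draw with the module's spread
                logit[taxon] -= baseline[taxon]
                baseline[taxon] = rng.normal(0, mod.baseline_sd)
                logit[taxon] += baseline[taxon]
            logit[taxon] += lam * factor + mod.baseline_shift
            module_of[taxon] = m_idx
            loading_of[taxon] = lam
    is_main = (t["zone"] == "main-channel").to_numpy()
    zone_truth: dict[int, str] = {i: "none" for i in range(nt)}
    for taxon, sign in cfg.zone_offsets.items():
        off = cfg.zone_offset_amp * sign
        logit[taxon] += np.where(is_main, off, -off)
        zone_truth[taxon] = "main-channel" if sign > 0 else "off-channel"
    logit += rng.normal(0, cfg.taxon_noise_sd, (nt, n_samples))
    if not np.isfinite(logit).all():
        raise ValidationError("non-finite expected log-abundance")
    p = np.exp(logit - logit.max(axis=0, keepdims=True))
    p /= p.sum(axis=0, keepdims=True)
    depths = np.maximum(
        rng.lognormal(np.log(cfg.read_depth), cfg.read_depth_sigma, n_samples), 100
    ).astype(np.int64)
    counts = np.empty((nt, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(depths[j], p[:, j])
    taxa = [f"T{i + 1:03d}" for i in range(nt)]
    phylum = {
        "heterocystous-cyanobacteria": "Cyanobacteria",
        "other-cyanobacteria": "Cyanobacteria",
        "diatom": "Bacillariophyta",
        "other": "Proteobacteria",
    }
    lineage = pd.Series(
        [f"{phylum[g]};Order{i // 5 + 1};Family{i + 1}" for i, g in enumerate(guilds)],
        index=taxa,
    )
    guild = pd.Series(guilds, index=taxa)
    table = CountTable(
        pd.DataFrame(counts, index=taxa, columns=t.index), lineage=lineage, guild=guild
    )
    truth = GroundTruth(
        variance_fractions={k: list(v) for k, v in cfg.variance_fractions.items()},
        niche_slopes={taxa[i]: tuple(slopes[i]) for i in range(nt)},
        module_of={taxa[i]: module_of[i] for i in range(nt)},
        loading_of={taxa[i]: loading_of[i] for i in range(nt)},
        zone_affinity={taxa[i]: zone_truth[i] for i in range(nt)},
        flow_regime={},
        sub_biome={},
        guild={taxa[i]: guilds[i] for i in range(nt)},
    )
    return table, truth


def gen_scenario(name: str = "default", seed: int = 0, cfg: ScenarioConfig | None = None):
    """One-call scenario: hierarchy, flow per floodplain, chemistry, community.

    Returns a dict with keys hierarchy, flows, env, counts, truth, config.
    Sub-seeds for each stage are derived from ``seed`` so stages are
    individually reproducible.
    """
    cfg = cfg if cfg is not None else ScenarioConfig.preset(name)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    hierarchy, flow_regime, sub_biome = make_hierarchy(cfg, seed=int(seeds[0]))
    flows = {
        fp: gen_flow(cfg.flow_years, regime, seed=int(seeds[1]) + i, river=fp)
        for i, (fp, regime) in enumerate(sorted(flow_regime.items()))
    }
    env = gen_env(cfg, hierarchy, seed=int(seeds[2]), sub_biome=sub_biome)
    counts, truth = gen_community(cfg, env, hierarchy, seed=int(seeds[3]))
    truth.flow_regime = flow_regime
    truth.sub_biome = sub_biome
    return {
        "hierarchy": hierarchy,
        "flows": flows,
        "env": env,
        "counts": counts,
        "truth": truth,
        "config": cfg,
    }
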