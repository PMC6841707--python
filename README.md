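# floodnet

Niche-partitioning analysis of river-floodplain biofilm microbiomes.

River floodplains pack many aquatic habitat types — riffles, pools,
springbrooks, backwaters, ponds — into small areas, and dams that flatten the
seasonal flood pulse tend to erase that habitat mosaic. `floodnet` asks what
that means for the epilithic-biofilm microbiome: starting from an
OTU-by-sample count table plus a four-level sampling hierarchy
(biome > floodplain > lateral zone > habitat), water chemistry, and daily
discharge records, it quantifies

* **flow predictability** — Colwell's information-theoretic decomposition
  P = C + M of a monthly discharge contingency table, where the seasonality
  component M is what impoundment erodes (with a year-block bootstrap);
* **multi-scale environmental variance** — REML variance components of each
  chemistry variable across the nested spatial scales;
* **α/β diversity** — Shannon H′, Bray-Curtis, and the Baselga partition of
  β diversity into species *turnover* vs *nestedness* (pairwise and
  multi-site, incidence and abundance modes), plus per-taxon SCBD / per-site
  LCBD contributions;
* **ordination** — NIPALS PCA (missing-cell tolerant), betadisper-style
  environmental heterogeneity, non-metric MDS (Kruskal stress-1), ANOSIM,
  and envfit vector fitting;
* **space vs environment** — db-MEM spatial eigenvectors, RDA forward
  selection with the double stopping rule, and adjusted-R² variance
  partitioning ([a] env unique, [b] shared, [c] space unique, [d] residual);
* **co-occurrence networks** — C-score screening against a fixed-fixed null,
  correlation-threshold networks (|r| ≥ 0.6, p ≤ 0.01 on read fractions),
  degree/closeness/betweenness, keystone taxa (above the 75th percentile of
  all three), Newman modularity, and same- vs cross-zone edge-sign summaries.

A synthetic-data generator (`floodnet.simulate`) produces flow series,
nested chemistry tables, and multinomial communities with *known* variance
fractions, niche slopes, module membership and zone affinities, so every
stage is verifiable without the study's raw sequence data. See
`docs/methods.md` for the models and design choices.

## Worked example

Run the full pipeline on the built-in synthetic scenario:

```sh
floodnet run --scenario default --seed 1 --out out/demo
```

This writes per-stage TSV/JSON tables under `out/demo/` and prints the
network complexity summary. With seed 1 the variance-component table
(`vca.tsv`, % of variance per scale) begins

```
      biome  floodplain  zone   habitat  residual
DOC    1.0        66.8    5.5      11.8      14.8
NH4    1.6         0.0   14.4       0.0      84.0
NO3    0.0        59.8    5.1       5.9      29.1
```

— recovering the generator's truth that most solute variation sits at the
floodplain scale (DOC truth: 0/63/4/13/20) while ammonium is mostly
residual. `flow.tsv` lists Colwell's M per river with bootstrap CIs; dammed
rivers (e.g. G1, M ≈ 0.09) come out far less seasonal than free-flowing ones,
and `associations.tsv` reports the headline Pearson correlations (habitat
diversity vs M, cyanobacterial read fraction vs N:P, …).

The sub-biome network contrast is clearest between the dedicated presets:

```sh
floodnet simulate --scenario n-limited --seed 3 --out out/nl
floodnet network --counts out/nl/counts.tsv --meta out/nl/metadata.tsv \
    --group biome --out out/nl/net
```

In paired runs the N-limited world yields networks with fewer nodes and
edges, a large negative-edge share concentrated on cross-zone taxon pairs,
and higher modularity than the N-rich world (typical values: 22 nodes /
63 edges / 40% negative / Q ≈ 0.49 versus 35 / 420 / 0% / Q ≈ 0.08) — the
directional pattern expected when nitrogen limitation favours an abundant,
zonally segregated cyanobacterial guild.

## Library use

```python
from floodnet import read_count_table, read_metadata, filter_taxa, rarefy, collapse_taxa
from floodnet.networks import cscore_test, infer_network, network_summary

t = collapse_taxa(rarefy(filter_taxa(read_count_table("counts.tsv")), 10_000, seed=0))
print(cscore_test(t, n_null=999, seed=0).ses)
net = infer_network(t, r_threshold=0.6, p_max=0.01)
print(network_summary(net))
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on the
default synthetic scenario (generation → preparation → flow → diversity →
ordination → scales → networks) and writes its result file:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
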