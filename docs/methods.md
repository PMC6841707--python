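# Methods

`floodnet` reimplements, as a tested pipeline, the analysis chain used to ask
whether river-floodplain biofilm microbiomes partition niches across nested
spatial scales (biome > floodplain > lateral zone > habitat), and how flow
regime and water chemistry organise community structure and co-occurrence
networks. This note documents the models, the choices made where the design
was open, and what the synthetic world does and does not establish.

## Flow predictability (Colwell P = C + M)

A daily discharge series is reduced to monthly means and cross-classified as
a 12 x s contingency table of calendar month by flow-magnitude class. Classes
are log2 bins relative to the series' own mean (so the statistic is invariant
to units and to rescaling of discharge). With H(X), H(Y), H(XY) the Shannon
entropies of the month marginal, class marginal, and joint table:

    C = 1 − H(Y)/log s        (constancy)
    M = (H(X) + H(Y) − H(XY))/log s   (contingency/seasonality)
    P = C + M                 (predictability)

Choices: time resolution (monthly) and binning (log2 about the mean) are not
dictated by the analysis being reproduced and are configurable; both are the
classical convention. A series whose monthly means fall in a single class is
returned as the constant limit (C=1, M=0) rather than an error, which keeps
the zero-variance bootstrap well defined. Uncertainty on M comes from a
year-block bootstrap (whole calendar years resampled with replacement,
default 999 replicates), preserving within-year seasonal structure.

## Table preparation

Standard 16S-style hygiene, downstream of OTU picking: taxa present in fewer
than 25% of samples **or** carrying fewer than 20 total reads are removed
(the stricter reading of an ambiguous and/or rule; a flag switches to
either-retains); samples are rarefied to a common depth (default 10,000) by a
single seeded without-replacement draw; OTUs are optionally collapsed to a
lineage rank (family by default), summing counts and propagating guild tags
when unanimous. Counts stay integer until relative-abundance conversion.

## Diversity

Alpha diversity is Shannon H' (natural log). Pairwise dissimilarity is
Bray-Curtis. Beta diversity is partitioned after Baselga into turnover
(species replacement) and nestedness (subset loss) components, in both
incidence mode (Sorensen = Simpson + nestedness) and abundance mode
(Bray-Curtis = balanced variation + abundance gradient), pairwise and
multi-site. Because the aggregation behind a reported pairwise range can be
either the mean of pairwise values or the multi-site statistic, both are
emitted. Per-taxon (SCBD) and per-sample (LCBD) contributions to beta
diversity use the total-variance decomposition of the Hellinger-transformed
table; the transform is configurable.

## Ordination and group statistics

PCA is computed by NIPALS iteration so occasional missing chemistry cells are
tolerated; on complete data it equals the eigendecomposition (tested to
1e-8). Variables are log-transformed and z-scored upstream. Environmental
heterogeneity of a floodplain is the mean and CV of the distance from its
sites to the floodplain centroid in PCA space.

NMDS is non-metric SMACOF: isotonic regression of configuration distances on
the observed dissimilarity order, followed by a Guttman transform, tracking
Kruskal stress-1. One PCoA start plus seeded random restarts (default 20);
the winning configuration is centred, rotated to principal axes, and
sign-fixed. The recorded stress trajectory is non-increasing by construction
(an overshooting majorization step reverts and stops).

ANOSIM uses the rank statistic R = (mean between − mean within)/(n(n−1)/4)
with a seeded permutation p-value; envfit regresses each variable on the site
scores, reporting r² with a row-permutation p. All permutation p-values use
the (b+1)/(m+1) estimator, so p is never zero.

## Scale partitioning

Variance components for each chemistry variable come from a nested
random-effects model (biome / floodplain-in-biome / zone-in-floodplain /
habitat-in-zone / residual) fitted by REML: the marginal covariance is a sum
of level indicator cross-products, optimised over log-variances (L-BFGS-B
plus a Nelder-Mead polish). Variances cannot go negative; shares are
percentages of the summed components. With only two biomes the biome
component is weakly identified and flagged `low_replication`. On balanced
designs with interior optima the estimates equal the classical
expected-mean-squares estimator (tested to 1e-6). Note an intrinsic limit:
shares estimated from few units (10 floodplains; 3 replicates per habitat
unit) carry sampling noise of several percentage points that no estimator
removes.

Spatial predictors are distance-based Moran eigenvector maps: Euclidean
distances truncated at the longest minimum-spanning-tree edge (distances
beyond it set to 4t), double-centred, eigendecomposed; positive-eigenvalue
vectors are kept, centred and orthonormal. db-MEMs are built jointly across
floodplains so they can act as regional spatial predictors.

RDA on the Hellinger-transformed community table uses forward selection with
the double stopping rule (candidate permutation p <= alpha and cumulative
adjusted R² not exceeding the global model's), gated by a global-model
permutation test. Variance partitioning reports adjusted-R² fractions
(environment unique, shared, space unique, residual); slightly negative
unique/shared fractions are reported as computed.

## Co-occurrence networks

Before interpretation, a C-score test (mean checkerboard units over taxon
pairs) against a fixed-row/fixed-column null (sequential checkerboard swaps,
burn-in then thinned sampling; numba-accelerated) certifies non-random
co-occurrence. Networks connect taxon pairs whose Pearson correlation of
relative abundances satisfies |r| >= 0.6 (inclusive) with two-sided t-test
p <= 0.01; no multiple-testing correction by default (a BH flag exists), no
compositional transform by default (a CLR flag exists) — matching the
analysis being reproduced. Node metrics are degree, Wasserman-Faust scaled
closeness (comparable across the disconnected components these graphs have),
and normalised Brandes betweenness. Keystone taxa strictly exceed the
within-network 75th percentile (linear interpolation) of all three metrics —
so regular graphs have none. Modules maximise Newman modularity (greedy
agglomeration by default, seeded Louvain optional); modules under 2.5% of
nodes are flagged small. Zone affinity of a node is the lateral zone
(main- vs off-channel) where its mean relative abundance is higher; edge
summaries count same- vs cross-zone pairs by sign.

## The synthetic world

Every stage is testable against a generator whose ground truth is recorded.

* **Hierarchy**: 2 biomes, 10 floodplains (6 montane, 4 grassland), 2 lateral
  zones, 10 habitat types (5 per zone), 3 samples per habitat unit.
  Dam-regulated rivers (all grassland plus one montane) carry a reduced
  habitat set, so habitat diversity co-varies with flow regime as in real
  floodplain networks.
* **Flow**: log-discharge = mean + seasonal harmonic + AR(1) noise;
  free-flowing rivers have amplitude >> noise (snowmelt peak), dammed rivers
  a flattened harmonic plus irregular square operation pulses.
* **Chemistry**: each variable is built from independent Gaussian effects per
  nested level with variance shares set per variable (defaults follow the
  observed pattern: floodplain-scale dominance for most solutes; habitat and
  residual dominance for ammonium, chlorophyll-a and benthic organic matter;
  the TP profile prints as 101% after rounding and is renormalised). Molar
  N:P is computed from generated TN and TP; the three sub-biome regimes
  (~1.8, ~12.7, ~30.7) enter as TN mean shifts.
* **Communities**: log-abundance = log-normal baseline + niche slopes times
  standardised environmental axes (heterocystous cyanobacteria slope on
  log N:P is −1 in the default scenario) + latent-factor module structure +
  zone-affinity offset + taxon noise; reads are multinomial at log-normally
  distributed depth (~20,000).

### Preset design (and why it looks the way it does)

Working in read fractions has two consequences that shaped the presets.
First, a *rare* co-varying module keeps its positive associations intact
(closure is negligible), whereas an *abundant* one cancels its own signal
through the denominator. Second, strongly negative Pearson correlations of
fractions cannot come from anti-correlated lognormal factors (the achievable
correlation is capped near −1/CV²); they arise when an abundant group's
halves occupy opposite zones, so fractions trade bimodally.

* `n-limited`: an abundant 10-taxon guild (heterocystous cyanos on the
  positive side) split across zones with a small shared factor, plus three
  small rare modules — few nodes, few edges, a large negative-edge share
  (mostly cross-zone), high modularity.
* `n-rich` / `grassland`: one large rare positively loaded module — many
  nodes and edges, almost all positive, weak modularity.
* `two-module`: two clean rare modules, no niche slopes — used for module-
  and edge-recovery scoring.
* `null`: exchangeable taxa, no structure — type-I checks end to end.

Within a single-sub-biome preset the N:P regime is constant and the cyano
sorting slope is reduced to −0.3: niche slopes act on *standardised* axes, so
a full −1 slope inside a narrow-regime world would inject implausibly large
shared read-pool swings and wire every taxon into the network. The default
scenario spans all three regimes with the full slope and is the world used
for slope-sign recovery.

What a green test does **not** establish: the generator draws level effects
as independent Gaussians (no spatial autocorrelation within floodplains
beyond the hierarchy, no temporal dynamics, no taxon-taxon mechanistic
interaction), read depth is well above the rarefaction threshold, and taxa
are far fewer (60) than a real family table — so absolute network sizes are
not comparable to field values, only directions and recoveries are.

## Numerical conventions

Seeds: every stochastic stage takes a seed or Generator; the pipeline derives
recorded sub-seeds from one global seed, making a run a pure function of
(inputs, config, seed). Permutation p-values: (b+1)/(m+1). NIPALS converges
on relative score change < 1e-28 (needed to match the eigendecomposition at
1e-8). REML floors boundary variances at zero at 1e-5 of the response
variance. NMDS convergence: stress change < 1e-7. Percentile definitions use
linear interpolation throughout. Ties in keystone percentiles exclude the
tied nodes (strict inequality).
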