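# Methods

## Measurement model

The unit of measurement is an *allocation vector*: for one indicator, year
and weighting dimension, parallel arrays of region weights `w_i > 0`,
absolute resource amounts `r_i ≥ 0` and densities `y_i = r_i / w_i`.
Published panels report densities per 1,000 population; amounts are recovered
as `density × population / 1000` and kept fractional — both the Gini and the
Theil index operate on continuous quantities, and integer rounding would
visibly corrupt coefficients at the ~0.05 level that population-dimension
analyses produce. Because amounts are derived from populations in both
dimensions, total amounts are identical across dimensions for a given slice;
only the weights switch (persons ↔ km²).

### Gini coefficient

The textbook density formula `G = ΣΣ|y_i − y_j| / (2n²μ)` is unweighted, yet
the quantities of interest here are population- and area-weighted. The
package implements the standard weighted generalization

    G = Σ_i Σ_j w_i w_j |y_i − y_j| / (2 W² μ),   W = Σ w_i,  μ = Σ r_i / W,

which reduces to the unweighted form for equal weights, and independently
computes G as `1 − Σ_k (x_k − x_{k−1})(y_k + y_{k−1})` from the grouped
Lorenz polyline. The two are algebraically the same statistic; the suite
asserts their agreement to 1e−12 on random instances, which guards both
implementations at once. Equity grading uses the conventional bands with the
boundary convention [0, 0.3) most fair, [0.3, 0.4] normal, (0.4, 0.6]
warning, (0.6, 1] danger — 0.4 is assigned to "normal" because the warning
band is customarily described as *above* 0.4.

### Lorenz construction

Regions are sorted by density ascending, ties broken by region id. The Gini
value is provably invariant to the tie order, so the tie-break fixes only the
plotted vertex sequence. Cumulative shares are clamped to exactly 1 at the
final vertex to absorb summation rounding. An all-zero amount vector has no
Lorenz curve and is rejected.

### Theil-L index and decomposition

With weight shares `P_i` and resource shares `Y_i`,
`T = Σ P_i ln(P_i / Y_i)` (mean log deviation). Natural log is used — the
standard for Theil-L; the base rescales the total and both components
identically, so contribution ratios are base-invariant, which makes the
ratios the safest quantity to compare across published analyses whatever
base they used. Decomposition over a partition: the between component is the
same formula on group aggregate shares; each group's internal index is
computed on shares renormalized within the group and weighted by the group's
weight share. Additivity `T = T_between + T_within` is an algebraic identity
and is asserted internally at 1e−9 (observed error ~1e−16); the test-suite
checks 1e−12.

Degenerate inputs: a unit (or group) with positive weight and zero resources
makes the index undefined and is a hard error — epsilon-padding would leak
into the decomposition silently. A zero-weight unit contributes nothing.
When T = 0 the contribution ratios are undefined; the API returns an explicit
perfect-equality marker instead of numbers.

### Label conventions

The western-China reference analysis defines "intragroup" as the
minority/nonminority comparison and "intergroup" as the within-province one —
the reverse of standard usage — and its two published tables follow the two
conventions inconsistently (the component table's `T_intra` column holds the
within-group component; the ratio table's `T_intra` column holds the
between-group *share*). All package field names are standard
(`between`/`within`); the packaged reference CSVs are stored under standard
names with the swap already applied, and ratio exports carry both label
conventions side by side. The published geographic-nurses component rows are
internally inconsistent (components do not sum to the printed total) and are
treated as a printing error: packaged verbatim, never asserted against.

## Panel contract

`ResourcePanel` validates on construction and fails fast, naming the first
offending row: unique (region, year, indicator), complete indicator coverage
for every (region, year), strictly positive populations and areas,
non-negative finite densities, and a group label that is stable across years.
The packaged western-China fixture carries the published densities verbatim
(two decimals, 12 regions × 5 years × 3 indicators) with the five autonomous
regions labelled `minority`; its populations and land areas are deliberately
unset, because they are not part of the published record — reproducing the
published weighted tables requires user-supplied yearbook attributes (the
published record does not state whether "total population" is year-end,
mid-year or census-adjusted; the package does not guess). One province is
spelled Shaanxi throughout, the only reading consistent with the density
table.

The planning-target benchmark (beds 6, physicians 2.5, nurses 3.14 per 1,000;
all overridable, including a nurse target of 3.16 that appears in some
statements of the plan) applies a strict `density ≥ target` rule. Verbal
hedges such as a region "basically meeting" a target at 5.96 < 6 are not
encoded.

Trend summaries report first-vs-last-year deltas with per-step signs and a
direction verdict: `up`/`down` when every step is weakly monotone with a
non-zero net change, `flat` for constant series, `mixed` otherwise. No
statistical inference is attached to trends.

## Synthetic generator

`ScenarioSpec`/`generate_panel` emulate the *shape* of the study panels: 12
regions in a 5 + 7 two-group split, years 2014–2018, lognormal populations
(mean 3.2e7 persons, log-sd 0.8) and land areas (mean 5.6e5 km², log-sd 1.3)
at provincial scales matching the real range (~3.4–83 M persons,
~0.07–1.2 M km²), and per-capita densities around bed/physician/nurse levels
(6, 2.4, 2.8 per 1,000) with controllable lognormal dispersion (default
log-sd 0.1, giving equal-weight Ginis near the observed population-dimension
level of ~0.05). A `drift` factor scales dispersion per year; a
`group_density_ratio` injects a between-group component; `two_point` and
`dirichlet` density models cover extreme-concentration and share-based
designs. All randomness flows from a single integer seed through one
generator stream, so identical specs give identical panels.

`two_point_allocation(w)` is the exact-G construction (G = w with Lorenz
vertices (0,0), (w,0), (1,1)) used as the closed-form oracle.
`calibrate_dispersion` bisects the lognormal log-sd so the *mean sample*
Gini at a given panel size matches a target: the objective is estimated over
replicate panels with common random numbers, making it deterministic and
monotone; it solves for the expectation, not per-draw exactness.

The `population_vs_area_contrast` scenario (density log-sd 0.05, area log-sd
1.5) reproduces the study's central qualitative finding by construction:
population-dimension Ginis below 0.1 coexisting with geographic-dimension
Ginis above the 0.6 danger band, driven purely by how unevenly people sit on
the land.

What the generator does **not** emulate: spatial autocorrelation, real
population/area magnitudes per named province, demographic change over years
(attributes are held constant), correlated indicators, or measurement error
in yearbook counts. Passing tests on synthetic panels therefore demonstrates
the correctness and calibration behaviour of the statistics, not the
empirical levels of any real province.

## Problem sizes and determinism

The test-suite and the acceptance script use 200 random allocations
(2–30 regions) for the dual-route and additivity checks, 500 replicates for
calibration (target 0.63 recovered within ±0.01 in expectation, verified on
an independent seed), 20 replicate panels for the contrast scenario, and the
full 2 × 3 × 5 grid of the packaged panel for pipeline runs — sizes at which
every stage completes in seconds. Exports are byte-deterministic for equal
inputs; the run log records the configuration, not timestamps.

## Limitations

Only the Theil-L (mean-log-deviation) member of the generalized-entropy
family is implemented — no Theil-T, Atkinson or concentration index, no
smoothed or parametric Lorenz fitting, and no efficiency (DEA) or spatial
accessibility modelling. The two-group decomposition is exact for any k, but
the bundled study design is two groups; contribution ratios for near-zero
totals are numerically meaningless and are marked undefined rather than
reported.
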