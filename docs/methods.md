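# Methods

This note documents the models, parameter choices and numerical
conventions behind `deepfd`, in the order the pipeline runs them.

## Synthetic community model

The generator (`deepfd.synthetic`) emulates a stratified stereo-video
survey: seven depth strata (50, 100, 300, 500, 700, 900, 1200 m) crossed
with seven locations whose latitudes are evenly spaced over 29–51 °S
(station coordinates are not part of the public design, so even spacing
is used). Two shallow southern cells are left unoccupied so the default
grid has 47 of 49 cells, matching the survey's footprint.

*Occupancy.* Each species receives a Gaussian depth niche (centre
uniform over stratum indices, width 1.6 strata). Expected occurrence
richness per cell is 10.8 species, declining 25 % per normalized depth
unit (richness falls with depth in deep-sea fish assemblages); realized
richness is Poisson. This yields ≈ 500 species-by-cell occurrences from
144 species, the scale of the survey.

*Traits.* Species means are multivariate normal around a community
centroid with per-trait variance `sigma2_S` (diagonal by default; an
optional correlation matrix is exposed). Individuals scatter around
their species mean with variance `sigma2_I`. Both variances are in
units of a per-trait scale (a few percent of the centroid value), so
the same `sigma2` settings apply to ratio traits and to total length.
Defaults `sigma2_I = 1`, `sigma2_S = 2` put the individual share of
within-cell variance at 1/3, in the 30–40 % range typical of
within-assemblage partitions of fish morphology. Two gradient knobs —
`sigma2_I_depth_slope` and `sigma2_S_lat_slope` — add a linear change in
the effective variances along the normalized gradients; they default to
0 and are switched on only in the recovery scenarios. Cell-level
between-species dispersion is adjusted by shrinking species-mean
deviations multiplicatively, which preserves species identities and
rankings across cells.

*Sampling.* About 31 % of occurrences carry in-situ measured
individuals, 2 + Poisson(2.32) of them (capped at 15), giving ≈ 3.3
measured species per cell and ≈ 4.3 individuals per species per cell.
Every species also carries two museum specimens drawn around its global
mean, guaranteeing that the hierarchical resampling can always resolve
an occurrence.

*Measurement layer.* The 8 traits are inverted into 15 raw lengths.
Head depth, head length, caudal-peduncle depth, pectoral base depth and
two filler measurements follow a log-scale allometry on total length
(`log X = a + log TL + eps`, noise sd 0.02); all remaining lengths are
solved exactly from the trait ratios, so deriving traits from the
generated measurements reproduces the input table to ≈ 1e-15. The
allometric noise is what makes imputation non-trivial but learnable.
Missingness is completely at random (MCAR) over the 15 measurement
cells; the pipeline applies it only to video records, since museum
specimens are complete by construction.

What the generator does **not** emulate: measurement error from
photogrammetry, non-random missingness (e.g. fins obscured in specific
postures), phylogenetic correlation among species means, and abundance
structure. Passing tests therefore demonstrate correctness of the
computations and estimator calibration under the stated statistical
model, not robustness to those real-data features.

## Trait derivation and normalization

Traits follow the ratio definitions listed in the README; jaw length is
the mean of upper and lower jaw lengths relative to head length. All
but total length are scale-free. Normalization is a z-score with the
sample (n−1) standard deviation computed across the *entire* table
(replicate table at species level, full individual dataset at
individual level), never per cell — metrics are compared across cells,
so they must share one scale. Total length enters untransformed by
default; a `log_total_length` flag applies log10 first (the choice
affects FHV and distances, and is deliberately exposed rather than
fixed).

## Imputation

Eligibility: ≤ 3 of 15 measurements missing *and* ≥ 5 complete
conspecific records pooled across video and museum sources. The imputer
is the missForest scheme implemented over scikit-learn random forests,
trained per species on complete conspecifics only: missing entries are
initialized with column means, each incomplete column is regressed on
the other 14 (columns visited in order of increasing missingness), and
iteration stops when the normalized squared difference between
successive imputations first increases (the previous sweep is kept) or
after `max_iter`. Defaults are 300 trees, 20 iterations, 20 runs
averaged per value; the analysis drivers use 3 runs of 100 trees, which
pilot runs showed leaves the run-to-run spread an order of magnitude
below the imputation error itself. A per-measurement out-of-bag RMSE on
the training pool accompanies each imputed value. Imputed values are
lengths and must be positive; a non-positive imputation is rejected
back to missing and flagged rather than clamped (it does not occur
under the synthetic model).

## Resampling

One individual per species-by-cell occurrence, drawn uniformly from the
highest-priority non-empty pool: same cell → same depth stratum (any
location) → anywhere on video → museum. Draws are independent across
occurrences and replicates, so one individual may represent its species
in several cells — the field protocol's counts imply the same reuse.
The museum fallback applies per occurrence. Unresolvable occurrences
abort by default (`on_unresolvable="drop"` is available). Replicate
count defaults to 100; the analysis drivers use 25, which leaves the
replicate-mean standard error of every index far below between-cell
differences at the synthetic problem size. Metrics undefined in a
replicate (e.g. FHV with too few species) are excluded from that
metric's mean and the exclusion count is reported.

## Diversity indices

MPFD, MNND, VPFD and VNND are computed from the Euclidean distance
matrix among a cell's species in normalized 8-trait space; variances use
the n−1 denominator throughout (consistent with the unbiased variance
components below). MPFD/MNND require 2 species, VPFD/VNND require 3;
smaller cells report the metric as missing with a flag.

FHV: a PCA is fit once per replicate table on all rows (centred,
covariance-based — identical to correlation-based after z-scoring),
with the sign of each axis fixed so its largest-magnitude loading is
positive; each cell's species are scored in that common space. The
hypervolume is the Lebesgue volume of the region where the Gaussian
product-kernel density with per-axis Silverman bandwidths,
`h_j = sd_j · (4/(n(d+2)))^(1/(d+4))`, exceeds the threshold `t` chosen
as the 5 % quantile of the density over draws from itself (so the
retained region encloses 95 % of probability mass). The volume is
estimated by importance sampling from the density: for `Y ~ f`,
`E[1{f(Y) ≥ t}/f(Y)] = vol{f ≥ t}`, giving an unbiased estimate with a
reported Monte-Carlo standard error. Default effort is 10 000 samples
per data point (2000 in the analysis drivers); both stages are seeded.
FHV needs ≥ 5 points (points must exceed the 4 dimensions) and rejects
degenerate clouds with zero spread in any axis. The estimator is
translation-invariant and scales as `c^4` under coordinate scaling `c`,
which the tests verify against its own Monte-Carlo error and against a
dense-grid integration oracle. Note the "loose wrap" is generous by
construction: for 500 uniform points on the unit 4-cube the 95 %-mass
superlevel set of the Silverman-bandwidth KDE has volume ≈ 2.6, not 1 —
the Gaussian kernel extends the region well beyond the data in four
dimensions. Comparisons of FHV across cells are meaningful; absolute
volumes are estimator-specific.

## Variance partitioning

Within each cell, the one-way distance partition uses the identities
`SS_total = (1/N)·Σ_{i<j} d²_ij` and
`SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij` on squared Euclidean
distances, with `SS_species = SS_total − SS_within`, degrees of freedom
`a−1` and `N−a`. Because squared Euclidean distances add over
coordinates, the multivariate sums of squares equal the sums of the
per-trait univariate ANOVA quantities exactly; the components
`σ²_I = MS_res` and `σ²_S = (MS_species − MS_res)/n0` are therefore the
multivariate analogues of the classical unbiased estimators, and the
tests verify unbiasedness by simulation (500 cells, truth recovered
within 5 %). Singleton species are retained — they inform the grand
mean and the between-species sum of squares. Negative `σ²_S` estimates
are reported raw and clamped at zero only inside Prop.I, preserving
unbiasedness of the component while keeping Prop.I in (0, 1]. No
permutation p-values are computed; the partition is used for
estimation, not testing. MPFD.I pools conspecific pairs across species
within the cell by default (`per_species_mean` gives the alternative
averaging).

## Gradient models

Depth and latitude are standardized and expanded into orthogonal
polynomial bases (QR of the Vandermonde matrix, columns scaled to unit
sample sd), so the linear coefficient is unchanged by adding curvature
terms. For each metric and each fixed gradient, candidate degrees 1–3
are fit by maximum likelihood with a random intercept per level of the
other gradient, compared by AIC, and the winner refit by REML (random
intercepts only; a random-slope variant exists behind a flag but the
design motivates none). Variance explained follows the
fixed/random/residual decomposition: marginal
`R² = σ²_f/(σ²_f+σ²_r+σ²_e)` with `σ²_f` the variance of the
fixed-effect predictions, conditional `R²` adds `σ²_r`. A singular or
failed mixed fit degrades to fixed-effects OLS with a flag. VPFD and
VNND are log10-transformed before modelling (strongly right-skewed).
Significance is reported at 0.05 per metric without multiplicity
correction, matching how such gradient suites are conventionally read.

Interaction rule: when both selected marginal models are linear, an OLS
with depth, latitude and their product tests the interaction directly.
Otherwise the surface is fit with the orthogonal main-effect bases plus
a tensor-product interaction block capped at 3 columns (products of
first- and second-order terms), tested jointly by an F-test — an
unpenalized surface with exactly ≤ 3 interaction degrees of freedom,
chosen over a penalized smoother because the grid offers only 7 × 7
support points and a fixed small basis keeps the test exact and
dependency-free. Fewer than 20 cells forces the linear branch with a
flag.

## Problem sizes and determinism

Defaults follow the study protocol (100 replicate tables, 20 imputation
runs of 300 trees, 10 000 Monte-Carlo samples per point). The analysis
drivers and the acceptance script run scaled versions — 25 replicates,
3 × 100-tree imputation runs, 2000 samples per point, 20 recovery
simulations — sizes at which every reported mean is stable to well
within the differences being interpreted. One base seed deterministically
derives per-stage seeds (`PipelineConfig.stage_seeds`), and identical
configurations reproduce byte-identical outputs.

## Known limitations

- MCAR missingness and conspecific-only training mean the imputation
  results say nothing about informative missingness or species with few
  complete records (those are correctly refused, not rescued).
- FHV values depend on bandwidth rule, threshold convention and
  dimensionality; only like-for-like comparisons are meaningful.
- The variance components assume exchangeable individuals within
  species per cell; size/ontogeny structure within species would appear
  as inflated σ²_I.
- With 7 levels per random factor, REML variance estimates are noisy;
  conditional R² should be read qualitatively.
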