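# deepfd

Functional-diversity analysis of fish communities along depth and
latitude gradients.

Communities can change in two distinct ways as environments become more
extreme: the *volume* of occupied trait space can shrink (abiotic
filtering) and the *packing* of species within it can loosen (biotic
interactions such as competition). Telling these apart requires a suite
of complementary indices rather than a single richness number, and —
because individuals of the same species also differ — a principled split
of trait variance into intraspecific and interspecific components.
`deepfd` implements that full workflow for individual-level fish
morphometrics sampled over a depth-by-latitude grid (seven strata from
50 to 1200 m crossed with seven locations from 29 to 51 °S, 47 occupied
cells), together with a synthetic-data generator that reproduces the
design with known ground truth, so every stage is testable end to end.

## The method

1. **Traits.** Eight functional traits are derived from 15 raw length
   measurements per fish (mm): total length `TL`; eye size `Ed/Hd`; oral
   gape position `Mo/Hd`; jaw length `(Uj+Lj)/(2·Hl)`; elongation
   `TL/mBd`; eye position `Eh/Hd`; caudal-peduncle throttling `CFd/CPd`;
   pectoral-fin position `PFi/PFb`. Trait tables are z-scored
   (n−1 denominator) table-wide before any distance computation.
2. **Imputation.** Records missing ≤ 3 of 15 measurements, for species
   with ≥ 5 complete records pooled across video and museum data, are
   filled by iterative random-forest imputation (missForest scheme,
   300 trees, ≤ 20 iterations) trained on complete conspecifics;
   20 independent runs are averaged.
3. **Resampling.** Each species-by-cell occurrence is represented by one
   randomly drawn complete individual, preferring (a) the same cell,
   (b) the same depth, (c) anywhere on video, (d) a museum specimen;
   100 replicate tables are built and metrics averaged across them.
4. **Diversity indices** per cell, from Euclidean distances in
   normalized 8-trait space: MPFD (mean pairwise distance), MNND (mean
   nearest-neighbour distance), VPFD and VNND (variances of those
   distances), and FHV — the volume of the region of the first four
   principal-component axes where a Gaussian kernel density (per-axis
   Silverman bandwidths) exceeds the threshold retaining 95 % of
   probability mass.
5. **Variance partitioning.** Within each cell, a one-way PERMANOVA on
   Euclidean distances among individuals (species as the factor) yields
   `σ²_I = MS_res`, `σ²_S = (MS_species − MS_res)/n0` with
   `n0 = (1/(a−1))·[Σn_i − Σn_i²/Σn_i]`, and
   `Prop.I = σ²_I/(σ²_S + σ²_I)`; MPFD.I is the mean conspecific
   pairwise distance. These are the multivariate analogues of the
   classical unbiased ANOVA variance components.
6. **Gradient models.** Every metric is regressed on depth (latitude
   random intercept) and on latitude (depth random intercept) with
   orthogonal polynomial terms up to degree 3, AIC degree selection and
   REML refit, reporting marginal and conditional R²; the
   depth×latitude interaction uses a product-term linear model when both
   marginal fits are linear, otherwise a tensor-product surface capped
   at 3 degrees of freedom.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (seed as optional argument) and write their tables under
`results/`:

```
$ python analysis/01_simulate.py 1
simulated 890 individuals (602 video, 288 museum), 497 species-by-cell occurrences
measured richness 3.51 species/cell, 4.18 individuals/species/cell
424 measurement values masked (3.2%)

$ python analysis/02_impute.py 1
583 complete, 178 eligible, 129 ineligible records
imputed 246 values; median run-to-run sd 0.263 mm
derived traits for 761 complete individuals (129 dropped as still incomplete)

$ python analysis/03_resample_metrics.py 1
25 replicate tables of 497 occurrences
first 4 principal components explain 57.5%-59.7% of trait variance
...

$ python analysis/04_partition.py
partitioned 41 cells (36 with a defined Prop.I)
mean Prop.I = 0.362 (generator truth sigma2_I/(sigma2_I+sigma2_S) = 0.333)

$ python analysis/06_validate_recovery.py 1
variance-component recovery over 200 balanced cells:
  sigma2_I total 8.002 (truth 8)
  sigma2_S total 31.695 (truth 32)
  Prop.I        0.206 (truth 0.2)
gradient recovery over 20 communities with built-in trends:
  MPFD.I-depth positive & significant: 20/20
  MPFD-latitude negative & significant: 19/20
```

The numbers mean: the generator reproduces the field design's scale
(≈3.5 measured species per cell, ≈4.2 individuals per species); the
eligibility rule admits 178 of 307 incomplete records and the imputer
fills them stably; a third of within-cell trait variance is attributed
to individuals, matching the generator's σ²_I/(σ²_I+σ²_S) = 1/3; and on
data with known gradients the pipeline recovers the rising intraspecific
variability with depth and the falling between-species dispersion with
latitude essentially every time.

The same stages are available as a CLI (`deepfd simulate|derive|impute|
resample|metrics|partition|trends|run-all`) and as one call,
`deepfd.pipeline.run_pipeline(PipelineConfig(...))`.

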