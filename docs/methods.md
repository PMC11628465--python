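# Methods

This note documents the models, numerical choices and limitations behind
`microsig`, in the spirit of the model documentation of simulation and
statistics packages.

## Event ingest and gating

Events are used on the raw instrument scale throughout: no logicle, asinh
or log display transform is applied before clustering (an optional asinh
flag exists on the SOM trainer but defaults off). Gating applies three
steps in a fixed order — scatter noise gate, DNA-positivity gate,
downsampling — and the composition equals the stepwise application row for
row.

* **Noise gate**: keep events with FSC > 1 *and* SSC > 1 (MFI units).
* **DNA gate**: keep events with DNA-dye intensity > 10. Acquisition
  protocols for microbiota samples typically record only DNA-positive
  events, so this gate is usually a no-op on real files; it is still
  applied by default so that TSV exports or differently gated files are
  handled identically.
* Comparisons are strict (`>`): an event exactly at a threshold is
  excluded. The alternative (`>=`) changes results only on the measure-zero
  set of events exactly at the boundary.
* **Downsampling**: uniform, without replacement, seeded, to 3×10⁴ events
  per sample by default. Samples with fewer events are used in full with a
  warning rather than rejected — there is no principled minimum, and the
  warning keeps the decision auditable.

FCS support is a deliberately minimal FCS 3.1 reader/writer for LIST-mode
floating-point data (the subset this package writes and typical cytometers
can export); integer/log-amplified parameters and multi-dataset files are
out of scope. TSV event tables (tab-separated, header row, `.` decimal) are
the fixture-friendly alternative.

## SOM phenotype fingerprinting

The quantizer is the classic online Kohonen algorithm on a hexagonal
lattice (row-offset coordinates, all six neighbors at unit distance) with a
Gaussian neighborhood kernel exp(−d²_grid/2σ²).

* **Grid**: 45×45 per panel by default, i.e. 2025 clusters per panel and a
  4050-dimensional two-panel fingerprint. Grid size is a config knob; the
  fingerprint dimension is always 2·rows·cols.
* **Schedules**: learning rate decays linearly 0.05 → 0.01 over all
  presentation steps; the neighborhood radius decays linearly from half the
  grid diagonal to 0.2. The end radius follows the convention of the
  classic SOM implementations, which anneal the neighborhood to (near)
  zero; at σ = 0.2 the nearest-neighbor weight is exp(−12.5), so the final
  phase is effectively winner-only online quantization. An end radius of 1
  was tried and rejected: it keeps neighboring prototypes coupled strongly
  enough that the final quantization error often exceeds that of the
  sampled initialization, defeating the quantizer.
* **Determinism**: the initial codebook is a seeded sample of distinct
  training events (hence training refuses fewer events than grid cells) and
  the presentation order is a seeded permutation per epoch; retraining with
  identical inputs and seed is bitwise identical. Holding that order fixed,
  the stored order of training events is irrelevant.
* **Assignment**: nearest codebook row by Euclidean distance, ties broken
  toward the lowest cluster index. The implementation uses the expanded
  ‖w‖² − 2x·w form in chunks for speed; on training-scale data this agrees
  exactly with exhaustive search (verified against a brute-force oracle).
* **Occupancy rule**: the 0.05%-of-training-cells occupancy check (150
  cells of 3×10⁵) is a report, not a constraint — it informs map sizing and
  flags over-provisioned grids, but never triggers automatic retraining.
* **Quantization quality**: with a sensibly provisioned map (≳50–100
  training events per node) the default schedule does not worsen the mean
  quantization error relative to the sampled initialization; a fixed-seed
  regression test checks this. Heavily over-provisioned maps on tiny
  training sets can violate it — a property of SOM smoothing, not a bug.

Per-sample fingerprints concatenate the two panels' relative cluster
abundances (each block sums to 1 whenever at least one event mapped; an
empty panel yields an all-zero block plus a warning). Cluster marker
profiles for heatmap-style inspection are per-channel min–max normalized
across clusters, with constant channels set to zero by convention.

## Taxa tables

Counts are total-sum scaled per sample (zero-sum samples are excluded with
a warning). Filtering keeps taxa present (> 0) in at least 5% of samples
*and* with mean relative abundance ≥ 10⁻⁴. The "less than 0.01%" abundance
phrasing is read as a mean across samples; a per-sample maximum rule is
available via `abundance_rule="max"`. Prevalence is computed across all
samples of the input table (not per cohort). After column removal, rows are
re-normalized so that Bray–Curtis retains its [0, 1] compositional
interpretation; renormalization preserves within-sample rank order of the
retained taxa. Batch correction is not implemented; an externally corrected
table can be supplied in its place.

## Signature selection

* **Pre-filter**: two-sided Wilcoxon rank-sum per feature, *unadjusted*
  p ≤ α (default 0.05). Unadjusted filtering is the point — the RFE stage
  is what controls the false positives that survive. A
  Benjamini–Hochberg flag exists but defaults off and is recorded in
  provenance when used. The p-value uses full enumeration of all
  C(n₁+n₂, n₁) label assignments of the pooled ranks when both groups have
  ≤ 10 samples (exact under ties), otherwise the tie-corrected normal
  approximation with continuity correction.
* **RFE**: within each of 10 stratified CV folds, a random forest
  (100 trees, seeded) is fitted, features are ranked by impurity
  importance, and the model is recursively refitted down a subset-size grid
  (powers of two plus the full set) while held-out balanced accuracy is
  recorded. The final size maximizes mean held-out balanced accuracy (ties
  go to the smaller set); features are ordered by consensus mean
  elimination rank across folds, index as final tie-break. Everything is
  seeded; identical seeds give identical signatures.
* A known identifiability limit: when planted informative features are
  individually strong and mutually redundant, held-out accuracy saturates
  below the full informative set and best-accuracy sizing legitimately
  returns a subset. "Recover every informative feature" is therefore not a
  property any accuracy-driven sizing rule can guarantee; the package's
  benchmark asserts ≥ 80% recovery instead.
* **gFC**: mean difference of the two groups' quantiles over the grid
  {0.1, …, 0.9}, linear-interpolation quantile rule. Antisymmetric by
  construction; equals the shift for a pure location shift. The case label
  is always explicit config, never inferred from ordering.

## Beta-diversity evaluation

* **Bray–Curtis** on nonnegative rows; a pair of all-zero samples is an
  undefined 0/0 and is defined as distance 0 with a warning so batch runs
  cannot crash.
* **PCoA** is classical scaling: double-center −½D², eigendecompose
  (`eigh`), coordinates = eigenvectors·√λ on positive-eigenvalue axes.
  Negative eigenvalues (Bray–Curtis is non-Euclidean) are reported, not
  corrected; axis "% variance" is taken over positive eigenvalues only.
* **PERMANOVA**: one factor, SS_total = Σd²/n over all pairs, SS_within
  from within-group pairs, R² = SS_between/SS_total, pseudo-F with (g−1,
  n−g) degrees of freedom, p = (1 + #{F_perm ≥ F_obs})/(1 + N) under
  seeded free label permutation (no strata). An exact-enumeration variant
  over all distinct label arrangements is provided for small n. Note that
  with sampled permutations the minimal attainable p is 1/(N+1) and a
  permutation can coincide with the observed grouping by chance.
* **Distance to reference**: for each query sample, the mean of its
  pairwise Bray–Curtis dissimilarities to every reference sample on the
  signature-restricted matrix. This stays in dissimilarity units bounded by
  [0, 1] (matching distance-style axes), unlike a centroid distance in
  ordination space; the signature restriction intentionally does *not*
  re-normalize rows, since the signature is evaluated as a sub-composition
  profile. Group-wise comparisons of these per-sample distances use
  unpaired two-sided Wilcoxon tests, unadjusted.

## Age stratification and pipeline

Default age bins: group 1 = [1, 5], group 2 = [6, 11], group 3 = [12, ∞)
years, inclusive on both edges; samples outside all bins are flagged and
excluded from strata. Signatures are computed overall (unstratified labels)
and independently within each stratum; each is evaluated by PERMANOVA on
full vs. signature-restricted matrices and by the distance-to-control
statistic. An externally supplied signature file can be cross-applied to
the cohort with the same distance statistic, grouped by age stratum. The
run manifest hashes the config and every output; identical configs are
byte-identical end to end.

## Synthetic cohorts

The generator defines the package's study conditions.

* **Flow**: each panel has 8 latent phenotype populations with fixed
  geometry (means log₁₀ 0.8–3.5, per-channel SD 0.12–0.28, drawn once from
  a constant geometry seed so conditions are stable across runs; scatter
  and DNA means sit above the gates). An event samples a population by
  weight, then independent log-normal intensities per channel — the
  simplest model that reproduces positive, right-skewed event clouds while
  keeping binomial/closed-form oracles. Per-sample population weights are
  drawn Dirichlet(base_weights × 100), giving ~20% coefficient of variation
  of a 0.2-weight population: without this inter-individual variability,
  every control sample is identical up to counting noise and any planted
  effect produces R² ≈ 1. The two panels are simulated independently (they
  are separately stained aliquots; no cell-level linkage exists).
* **Taxa**: base composition rank⁻¹·³ over 150 taxa (power-law-like, as in
  stool communities); per sample, composition ~ Dirichlet(base × 100) and
  counts ~ Multinomial at a depth uniform in [2×10⁴, 5×10⁴].
* **Planted effects**: case samples in the named age groups get population
  weights multiplied (then renormalized) and/or marker-channel mean
  log-intensities shifted; taxa get natural-log fold effects on the base
  composition before renormalization. The ground-truth record lists exactly
  what was perturbed.
* **Default scale**: 10 case + 10 control per age group (30 per arm), 10⁴
  events/sample, 8 populations/panel, 150 taxa — desk-scale while staying
  above statistical noise.

**Planted benchmark conditions.** The recovery experiment plants effects
only in age stratum 2 (30 vs 30 there, 15 vs 15 elsewhere): two populations
up-weighted 1.5× (one per panel) and eight taxa at log-fold 1.2, chosen in
a moderate-abundance band (ranks 12–50, ≈ 0.2–1.1% relative abundance) with
depletion on the abundant half and enrichment on the rare half. These
magnitudes were calibrated once, at design time, to the regime in which
multi-feature signatures are scientifically meaningful: every planted
effect is individually detectable by the rank-sum filter at n = 30/30, yet
no single feature separates the cohorts on its own (much stronger effects
make one taxon a perfect classifier, collapsing the RFE to a 1–2 feature
signature; depleting an already-rare taxon pushes it under the detection
floor). Under these conditions the full-matrix PERMANOVA R² falls around
0.04–0.15 and the signature-restricted R² around 0.2–0.4, as the
acceptance script measures. The benchmark runs
the experiment at a scaled-down SOM (6×6 per panel, 5×10⁴ pooled training
events, 5×10³ mapped events/sample), the package's desk-scale default for
repeated-seed experiments; grid size only changes fingerprint granularity,
not the logic under test.

**What the generator does not model** — and hence what passing tests do not
establish about real data: spectral spillover/compensation, doublets,
acquisition-time drift and anchor-sample variability; correlated marker
channels within a population; phylogenetic correlation among taxa,
batch effects, or zero-inflation beyond what Dirichlet-multinomial
sampling produces; any cell-level linkage between the two staining panels.

## Known limitations

* The RFE consensus is a mean rank across folds; with very few surviving
  features the subset-size grid degenerates to {1, 2, 4, full} and sizing
  granularity is coarse.
* PERMANOVA here is single-factor with free permutation; no strata or
  multi-factor designs.
* The FCS layer does not read integer or log-amplified acquisitions.
* Mapped events per sample (after downsampling) bound the resolution of
  fingerprint abundances; clusters rarer than ~1/n_mapped are recorded as
  zeros sample-wise.
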