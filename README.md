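# microsig

Age-stratified intestinal-microbiota signatures from single-cell flow
cytometry and taxonomic profiles.

`microsig` implements a cohort-analysis pipeline for
studies that characterize the gut microbiota two ways at once: by
species-level 16S amplicon count tables, and by *multi-parameter microbiota
flow cytometry* (mMFC) — per-bacterium measurements of scatter, DNA content,
host-immunoglobulin coating (IgA1/IgA2/IgM/IgG) and lectin binding
(PNA/WGA/STL/ConA) acquired in two staining panels. It is aimed at
microbiome researchers who want to derive and transfer case/control
signatures while treating patient age as a first-class stratification
variable rather than a nuisance covariate.

## What the pipeline computes

1. **Phenotype fingerprinting.** Gated, untransformed events (noise gate
   FSC/SSC > 1, DNA⁺ gate > 10 MFI, downsampling to 3×10⁴ cells/sample)
   are quantized by a per-panel self-organizing map — a hexagonal Kohonen
   lattice with Gaussian neighborhood exp(−d²/2σ²) — trained on 3×10⁵
   pooled cells. With the default 45×45 grids each sample becomes a
   4050-dimensional vector of relative cluster abundances (2025 clusters
   per panel), its *microbiota phenotype fingerprint*.
2. **Taxa normalization.** Count tables are total-sum scaled, filtered at
   5% prevalence and 0.01% mean relative abundance, and re-normalized.
3. **Signature selection.** For any feature matrix (fingerprints or taxa)
   and a two-cohort labeling: a per-feature two-sided Wilcoxon rank-sum
   pre-filter at unadjusted α = 0.05, then recursive feature elimination
   under 10-fold cross-validation with a random-forest importance ranking;
   the subset size maximizing mean held-out balanced accuracy wins and
   features are ordered by their consensus (mean across folds) rank. Each
   selected feature is annotated with the generalized fold change,
   gFC = mean over a quantile grid q ∈ {0.1,…,0.9} of
   [Q_case(q) − Q_control(q)].
4. **Evaluation and transfer.** Bray–Curtis dissimilarity
   BC(x,y) = 1 − 2Σᵢmin(xᵢ,yᵢ)/Σᵢ(xᵢ+yᵢ), principal-coordinates analysis,
   one-factor PERMANOVA (R² = SS_between/SS_total, permutation p), and the
   per-sample transfer statistic: the mean Bray–Curtis distance of each
   query sample to every sample of a reference cohort, computed on the
   signature-restricted matrix and compared across age groups by unpaired
   Wilcoxon tests.

Cohorts are stratified into age groups 1–5, 6–11 and ≥ 12 years (inclusive
bounds), and signatures are derived overall and per stratum.

Because study data of this kind are patient-derived, the package ships a
first-class synthetic-cohort generator: two panels of 7-channel event
clouds as log-normal mixtures of latent phenotype populations with
per-sample Dirichlet weight variability, and Dirichlet-multinomial taxa
counts — both with *planted*, age-stratified case/control effects and an
exact ground-truth record, so every downstream stage can be validated
against known truth.

## Worked example

Derive the stratum-2 taxa signature from a synthetic cohort with effects
planted only in age group 2 (30 cases vs 30 controls there; eight taxa
shifted by a natural-log fold of 1.2):

```python
import numpy as np
from microsig import (TaxaTable, normalize_total, filter_prevalence_abundance,
                      FeatureMatrix, wilcoxon_filter, rfe_select, RFEConfig,
                      assemble_signature, bray_curtis, permanova,
                      apply_signature, simulate_taxa_counts)
from microsig.experiments import planted_design
from microsig.synthetic import metadata_frame

design = planted_design(seed=7)
counts, meta, truth = simulate_taxa_counts(design)
filt = filter_prevalence_abundance(
    normalize_total(TaxaTable.from_frame(counts, stage="counts")))
mat = FeatureMatrix(list(filt.sample_ids), list(filt.taxon_labels),
                    filt.values, feature_kind="taxon")

df = metadata_frame(meta)
g2 = df[df.age_group == 2]
sub = mat.subset_samples(list(g2.sample_id))
labels = g2.cohort.to_numpy()

kept, pvals = wilcoxon_filter(sub, labels, alpha=0.05)
sig = assemble_signature(
    kept, rfe_select(kept, labels, RFEConfig(seed=7)), labels, "case")
print(f"{len(mat.feature_ids)} taxa -> {len(kept.feature_ids)} after "
      f"Wilcoxon filter -> {len(sig.feature_ids)} in the signature")
planted = set(truth["planted_taxa"])
print("planted taxa recovered:",
      f"{len(planted & set(sig.feature_ids))}/{len(planted)}")

r2_full = permanova(bray_curtis(sub), labels, 999, seed=7).r_squared
r2_sig = permanova(bray_curtis(apply_signature(sig, sub)), labels, 999,
                   seed=7).r_squared
print(f"PERMANOVA R2: all taxa {r2_full:.3f} -> signature {r2_sig:.3f}")
```

prints

```
150 taxa -> 17 after Wilcoxon filter -> 8 in the signature
planted taxa recovered: 7/8
PERMANOVA R2: all taxa 0.046 -> signature 0.254
```

The Wilcoxon filter keeps the planted taxa plus a handful of α-level false
positives, the RFE prunes those away, and restricting the Bray–Curtis
matrix to the signature sharpens the cohort separation (R² 0.046 → 0.254) —
the behavior that motivates two-stage selection in the first place.

The same analysis runs from the shell: `microsig simulate`, `microsig
taxa-filter`, `microsig signature-select`, `microsig eval-sigdist`, or the
whole study shape at once with `microsig pipeline-run --config cfg.yaml`
(see `microsig --help`).

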