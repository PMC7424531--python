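# ttnsight

Tumor mutation burden (TMB) — the number of somatic mutations in a tumor —
predicts response to immune-checkpoint therapy, but measuring it requires
whole-exome or large-panel sequencing. Because mutation counts in very long
genes track the genome-wide burden, the mutation count within a *single*
long gene (TTN, the longest human coding gene) can serve as an inexpensive
TMB surrogate. `ttnsight` implements that analysis end to end for
count-based mutation data:

- **TMB profiling** (`ttnsight.tmb`): per-sample burden over exonic and
  splice-site SNVs and indels (synonymous included; intronic excluded),
  per-gene SNV/indel counts, CDS-length/GC-normalized mutation rates and
  the replication-timing association.
- **Gene sweep** (`ttnsight.sweep`): for every gene g, Pearson
  ρ(count_g, TMB) with per-tumor-type Bonferroni (×33) family-wise
  correction, the CDS-length/count relation, and random 2–25-gene set
  comparisons.
- **Tumor-only somatic filtering** (`ttnsight.somatic_filter`): caller-label,
  population-database, panel-of-normals and depth filters, then a
  Gaussian-kernel density f(x) = (nh)⁻¹ Σᵢ K((x−xᵢ)/h) fitted to PASS
  variant allele fractions with the exact Silverman bandwidth
  h = (4σ⁵/3n)^(1/5); a germline-risk call is discarded when f(VAF) ≈ 0
  (below ε = 10⁻³) unless rescued by concordant SIFT/PolyPhen-2 damaging
  annotations.
- **Immune enrichment** (`ttnsight.enrichment`): samples ranked by the
  immunostimulatory score (mean log₂(x+1) of IFNG, IL2, IL12A, IL12B,
  IL15, TNF); a KS-style running sum steps +√((N−G)/G) at mutated samples
  and −√(G/(N−G)) otherwise; the prefix maximum (max ES) is calibrated by
  label-shuffle permutations, p̃ = B⁻¹ Σ_b I(maxES₀ ≤ maxES_b).
- **MSI-H classification** (`ttnsight.classifier`): the five TTN features
  (SNV, indel, SNV+indel, indel/(SNV+indel), indel/SNV), a random forest
  under pooled 10-fold cross-validation (one ROC over held-out
  probabilities), the permutation AUC p-value
  p̃ = B⁻¹ Σ_b I(AUC₀ ≤ AUC_b), the ≥2-of-5-loci MSI PCR rule, HGI/LGI
  grouping and a paired DeLong AUC comparison.
- **Synthetic cohorts** (`ttnsight.synthetic`): three-subgroup cohorts
  (low-instability ≈60 mut/exome; indel-enriched MSI-H ≈1200; POLE
  proofreading-mutant SNV ultra-mutators ≈5000) with per-gene rates ∝ CDS
  length, optional replication-time modulation, truth-labeled tumor-only
  variant calls and burden-coupled expression — every stage is testable
  without controlled-access data.

The `analysis/` scripts run the study sequence over a simulated cohort:
`01_simulate_cohort.py` → `02_filter_variants.py` → `03_profile_tmb.py` →
`04_gene_sweep.py` → `05_immune_enrichment.py` → `06_msi_classifier.py`,
writing tables under `results/`.

## Worked example

```python
import pandas as pd
from ttnsight import (CohortSpec, generate_mutation_cohort, profile_samples,
                      correlation_sweep, build_features, cv_classify)

spec = CohortSpec(n_samples={"LGI": 70, "MSI_H": 25, "POLE": 5},
                  n_genes=300, seed=20_000)
mutations, metadata, annotations = generate_mutation_cohort(spec)
profiles = profile_samples(mutations, metadata)

sweep = correlation_sweep(profiles)
print(sweep.head(2)[["gene", "rho", "rank_by_rho"]].to_string(index=False))

features = build_features(profiles, "TTN")
labels = pd.Series((profiles.metadata["msi_status"] == "MSI_H").astype(int).to_numpy(),
                   index=profiles.samples)
cv = cv_classify(features, labels, folds=10, b=0, seed=101, n_estimators=100)
print(f"pooled 10-fold CV AUC {cv.auc_0:.3f}")
```

prints

```
  gene      rho  rank_by_rho
   TTN 0.999063            1
G00217 0.992042            2
pooled 10-fold CV AUC 0.978
```

TTN ranks first among 300 genes because its mutation count is the least
noisy thinning of each sample's total burden (largest CDS share), and the
indel-enriched MSI-H subgroup is recovered almost perfectly from the five
TTN count features alone.

A command line mirrors the stages
(`ttn-tmb run|synth-cohort|somatic-filter|tmb-profile|gene-sweep|mut-enrich|msi-classify`).

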