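# Methods

## Scientific setting

Tumor mutation burden (TMB) is counted, not normalized to megabases: every
SNV and indel in exonic regions or splice sites qualifies, synonymous
(silent) mutations included, intronic and unclassifiable records excluded.
Non-coding-transcript (`RNA`) exon variants count toward TMB — targeted
panels report them within the protein-coding-region totals — and a config
hook in the reader dialect allows dropping them. The count within a single
gene is the surrogate statistic of interest; all analyses below operate on
these counts.

## Tumor-only somatic filtering

Without a matched normal, caller output mixes somatic and germline
variants. The cascade (in order): keep PASS/germline_risk caller labels
only → drop population-database and panel-of-normals hits → depth rule →
drop intronic calls → kernel-density adjudication → annotation rescue.

*Depth rule.* A call is removed if total depth < 30, or an SNV has < 3 alt
reads, or an indel has < 5 alt reads. The printed source rule is ambiguous
about AND/OR precedence; removal on any single failure is the conservative
clinical-filtering reading and the one adopted here.

*Kernel density.* The VAFs of a sample's PASS calls are taken as the
somatic distribution and fitted with a Gaussian kernel density using the
exact Silverman bandwidth h = (4σ⁵/3n)^(1/5), σ the ddof=1 sample SD
(scipy's 1-D "silverman" rule reduces to the same expression and is used
as an independent oracle in tests). The fit is per sample: VAF location is
purity-driven and purity is sample-specific. A germline_risk call with
f(VAF) < ε is discarded; ε defaults to 10⁻³ because a unit-mass density
more than ~4 bandwidths from every support point falls below 10⁻³ at
typical n, so "f ≈ 0" and "outside the somatic cloud" coincide. With < 2
distinct PASS VAFs no density exists and germline_risk calls are retained
unchanged (logged). Discarded calls are rescued when SIFT says deleterious
AND PolyPhen-2 says probably/possibly damaging; rescue applies only to
density-discarded calls. POLE calls are pathogenic only inside the
exonuclease domain (default residues 268–471, configurable; no coordinates
are fixed by the source analysis).

Operating characteristics depend on the separation between the somatic VAF
mode (purity/2) and the germline clusters at 0.5 and 1.0 relative to the
read-sampling noise: at purity 0.6 and depth 200 the heterozygous-germline
lower tail overlaps the f ≥ ε region, so a residual germline leakage of
roughly 5–10% is intrinsic; homozygous (VAF ≈ 1) germline calls are
essentially always removed. Sensitivity and leakage are therefore reported
as means over seeded replicates, not single draws.

## Per-gene rates, FLAGS and replication timing

Cohort-wide gene counts are normalized as count/CDS and count/(CDS·GC);
the GC-joint form is the simplest joint exposure normalization (no formula
is fixed by the source analysis). Unmutated annotated genes enter rate
tables at 0 — required for unbiased replication-time correlations. The
FLAGS comparison is a paired Wilcoxon signed-rank over strata (e.g. tumor
types), comparing the target gene's rate with the mean rate of other
FLAGS-like long genes and of the remaining genes. Replication-time
association is Pearson by default.

Numerical caveat: on zero-effect synthetic cohorts the rate–replication
correlation over *all* genes shows a small negative bias, because
short-CDS genes have right-skewed Poisson rates and (in the generator)
earlier replication times; restricting to well-measured genes (count ≥ 20)
removes it, and the invariant test does exactly that.

## Correlation sweep

Pearson on raw counts (the published analysis plots raw counts; no log
transform). The per-sample total includes the tested gene's own count; a
leave-gene-out variant is available for sensitivity analysis. Genes with
zero count variance are skipped. Family-wise correction multiplies the raw
p by the number of strata tested (default 33, the pan-cancer tumor-type
panel), capped at 1. Rho ties rank by smaller p, then gene symbol. The
random gene-set sweep draws sets of 2–25 genes uniformly and scores each
set's summed count by ρ with TMB and by ROC AUC for a binary label.

## Enrichment statistic

With N samples ranked by decreasing immunostimulatory score and G of them
mutated, the running sum steps +√((N−G)/G) at mutated samples and
−√(G/(N−G)) elsewhere; it ends at 0 identically since
G·√((N−G)/G) = (N−G)·√(G/(N−G)). The statistic is the prefix maximum
(non-negative; negative deviations are not scored), bounded by √(G(N−G))
with equality iff the mutated samples occupy the top G ranks. Score ties
rank by sample id (stable, deterministic). The permutation null reassigns
the G labels uniformly; p̃ = B⁻¹ Σ I(maxES₀ ≤ maxES_b) with no +1
smoothing, so p may be 0 (reported as < 1/B). Because the indicator uses
≤, tie mass on the max-ES lattice makes p conservative; for small N·G the
null mean of p sits visibly above 1/2, which the calibration tests take
into account by using configurations with negligible tie mass.

## MSI-H classifier

Features are the surrogate gene's SNV count, indel count, total, index 1 =
indel/(SNV+indel) and index 2 = indel/SNV. Both indices are defined as 0
when their denominator is 0, keeping all features finite; an indel-only
sample is still fully described by index 1 = 1 and the counts. The model
is a random forest (bagged decision trees, 500 trees by default; no
clinical covariates). Evaluation is pooled 10-fold cross-validation: each
sample predicted exactly once on held-out data, one ROC/AUC over the
pooled probabilities. Folds are stratified by class so every training
split contains both classes — a deliberate deviation from plain random
splitting, toggleable via `stratified=False`; the fold count is capped by
the minority-class size. The permutation p reruns the complete CV per
label shuffle: p̃ = B⁻¹ Σ I(AUC₀ ≤ AUC_b). The formula is B-agnostic;
release-scale runs use B = 10,000, while the test suite and the
acceptance script use B = 200 with forests of 10–100 trees and 10–20
replicates — sizes chosen so the full suite completes in minutes while
binomial tolerances stay meaningful. The paired AUC comparison is the
DeLong test (the source analysis names no method; DeLong is the field
standard), cross-checked against R's pROC implementation. MSI PCR calls
use the five-locus rule (≥2 unstable = MSI-H, 1 = MSI-L, 0 = MSS); MSI-L
and MSS collapse to non-MSI, and the HGI group is MSI-H plus non-MSI POLE
exonuclease-domain mutants.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
sequence-level realism. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| subgroup sizes | LGI 60, MSI-H 25, POLE 5 | MSI-enriched multi-type cohort shape |
| mean TMB | 60 / 1200 / 5000 | low-instability, MSI-H hypermutated, POLE ultra-mutated exome magnitudes |
| indel fraction | 0.05 / 0.30 / 0.01 | MSI-H is indel-enriched; POLE indels nearly absent |
| TMB dispersion | NB shape 5 | empirical TMB is overdispersed |
| gene universe | 2000 genes, lognormal CDS (median ≈ 1.5 kb) | scaled-down exome keeping the tracking gene's CDS share small (~2%) |
| tracking gene CDS | 100 kb | longest coding gene, ~3× the runner-up |
| somatic VAF | Beta around purity/2, concentration 500 | clonal model: biological spread (SD ≈ 0.02) below read-sampling noise at panel depths |
| germline VAF | 0.5 / 1.0 mixture, hom fraction 1/3 | ≈2:1 het:hom ratio of a typical genome |
| purity | 0.6 | mid-range surgical specimen |

Per-sample totals are negative binomial; gene assignment is multinomial
with probability ∝ CDS × exp(effect · z(replication time)); the tracking
gene's count is thus a binomial thinning of the total — exactly the
mechanism that makes a long gene a burden surrogate. SNV classes follow a
fixed missense-dominated spectrum; indels split 80/20
frameshift/in-frame. Expression coupling adds a fixed log₂ shift to the
six immunostimulatory genes in mutated samples. One seed expands into
per-stage substreams, so adding a stage never perturbs earlier streams and
fixed seeds give byte-identical outputs.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: sequence-context mutational signatures,
positional clustering within genes, copy-number-distorted VAFs, subclonal
architecture, panel capture bias, and any TTN-specific rate elevation
beyond CDS length (the generator's FLAGS comparison is null by
construction). Correlations in real cohorts are lower than the synthetic
near-1 values because real burden spans fewer orders of magnitude within a
tumor type.

## Degenerate inputs and tie-breaks

Constant inputs to correlations raise instead of returning NaN; duplicate
annotation rows keep the longest CDS; unknown mutation classes map to
`Other` (excluded from TMB) with a warning; identical-group rank tests
return p = 1; density fitting requires ≥ 2 distinct PASS VAFs (σ < 10⁻¹²
treated as degenerate).

## Known limitations

The published pan-cancer/validation numbers (ρ = 0.917/0.936, external
AUC 0.873, max ES 455.8) require the TCGA MC3 and controlled-access
cohort data and are outside desk scale; the package validates the
machinery on count-exact reconstructions of the published summaries and on
synthetic cohorts with known truth. The panel fixtures reproduce marginal
class counts only — their sample assignments are arbitrary. The
kernel-density filter's leakage floor at moderate purity is described
above and is a property of the method, not of the implementation.
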