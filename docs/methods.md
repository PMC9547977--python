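# Methods

This note documents the statistical models, the synthetic-cohort
generator, the numerical choices, and the design decisions behind
`kraswt`. Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; no external data are required.

## Statistics kernel

`kraswt.stats` is written from first principles so that every routine can
be checked against an independent oracle:

* **Fisher exact (2×2, two-sided).** The conditional distribution of the
  top-left cell given the margins is hypergeometric; masses are computed
  via log-gamma. The two-sided p sums all masses not exceeding the
  observed table's mass, with a relative tolerance of 1e−7 when comparing
  masses (the point-probability rule used by standard statistical
  software). The statistic is the sample odds ratio with the 0 → ∞
  convention. The test suite verifies equality with direct enumeration on
  **every** table with total N ≤ 40.
* **Hypergeometric tail.** P(X ≥ k), normalized so the point masses sum
  to 1 within 1e−12.
* **Benjamini–Hochberg.** Standard step-up with monotonicity enforced by
  a reverse cumulative minimum; input order preserved. Applied per
  analysis family: per-gene mutation tests (one family per event class),
  DE genes, enrichment per direction, confounder scans per covariate.
* **Rank tests.** Wilcoxon rank-sum and signed-rank use the normal
  approximation with tie correction and a 0.5 continuity correction for
  all n; cohort sizes here (≥ 9 per group) make exact enumeration
  unnecessary, and the permutation comparison lives in the tests, where
  agreement within 0.02 is asserted. Spearman uses midranks with the
  t-approximation; one-way ANOVA is the standard F test.
* Type-I error of each test is verified to sit within ±0.015 of the 0.05
  nominal level over 10,000 simulated null replicates.

## Differential expression

Counts are modelled per gene as negative binomial with variance
μ + αμ². The GLM uses a log link with per-sample offsets log s_j, where
s_j are median-of-ratios size factors rescaled to geometric mean 1. The
design is intercept + batch indicator(s) + group indicator with
mutant = 0, wildtype = 1, so positive log2 fold changes mean higher
expression in KRAS-wildtype tumors.

Dispersion estimation is deliberately simpler than the empirical-Bayes
machinery of dedicated DE packages: per-gene method-of-moments estimates
(clipped to [1e−8, 10]) are shrunk toward a log-linear trend of log α on
log mean, interpolating on the log scale with weight 0.5 (exposed as
`shrinkage`). This preserves the calibration and power behavior the test
suite checks (null type-I error within ±0.02 of 0.05; planted |L2FC| = 3
genes at n = 9 vs 54 recovered with sensitivity ≥ 0.9 and FDR ≤ 0.1 over
200 replicates) without replicating any specific package's internals.
No independent filtering and no fold-change shrinkage are applied — the
signature thresholds (adjusted p < 0.005 **and** |L2FC| > 2.5, both
strict) are applied to raw Wald estimates.

IRLS is vectorized across genes (batched 3×3 normal-equation solves),
runs at most 100 iterations to a relative deviance tolerance of 1e−8,
clips the linear predictor to ±30, and flags non-converged genes, which
are excluded from the BH family.

## Copy-number analysis

A gene is **amplified** in a sample when any overlapping segment has
total copy number ≥ 2× the tumor ploidy (boundary inclusive) and
**homozygously deleted** when any overlapping segment has total CN
< 0.5 — real-valued CN from purity-corrected callers rarely hits exactly
0, so a half-copy threshold stands in for "homozygous deletion".
Any-overlap mapping matches the behavior of interval-intersection tools
used for such annotation. Gene-level SNV/indel presence is per patient
and ignores consequence class; the TMB cascade applies its own
consequence filter independently.

Spatial analysis tiles chromosomes with non-overlapping 100 kb bins
(final partial bin to the chromosome end). A bin covered by several
segments takes the status of the segment with the greatest overlap, ties
resolved toward the higher total CN — the least surprising aggregation,
verified against a per-base majority-vote oracle on 1,000 random
segmentations. Bins with no overlapping segment are `no_data` and are
excluded from group-frequency denominators. A sample is called
**arm-amplified** when ≥ 70% of its informative arm bins are amplified;
the event planted by the generator is a whole-arm gain, so the call is
insensitive to this threshold (exposed in config) over a wide range.

## Consensus clustering

Fifty subsampled repetitions (80% of samples, all features) are each
clustered hierarchically (average linkage) on 1 − Pearson correlation
distance and cut at every candidate k (2…6). The consensus matrix holds
per-pair co-clustering rates among co-sampled repetitions. k is selected
from the area A(k) under the consensus-CDF: Δ(2) = A(2),
Δ(k) = (A(k) − A(k−1))/A(k−1), and k* is the largest candidate with
Δ(k) > 0.05 (threshold exposed; the full Δ table is always emitted for
manual override).

The Δ rule alone cannot recognize a structureless cohort: measured on
iid-noise data, the relative area increase stays above 0.05 through
maxK. A **PAC instability guard** therefore runs alongside it: if the
proportion of ambiguous consensus entries (those in (0.1, 0.9)) exceeds
0.35 at every candidate k, there is no reproducible structure to count,
and the smallest k is reported with a low-confidence flag. The 0.35 cut
was calibrated on null simulations, where the minimum PAC over k is
≈ 0.40 for iid noise and ≈ 0 for planted blob structure.

Final labels cut the dendrogram of the consensus distance 1 − M at k*,
renumbered by decreasing cluster size. Cluster–annotation enrichment
uses two-sided Fisher tests on in-cluster × in-category tables with BH
across all (cluster, category) pairs. Confound checks report a one-way
ANOVA of tumor content across clusters and flag any cluster in which one
RNA-seq batch exceeds 90% of members (suppressed for single-batch
cohorts). No batch correction is applied before clustering — with
batches nested within cancer types, correction would remove true
between-type signal — the confound report substitutes for it.

## Subtyping

The basal-like probability of a sample is a top-scoring-pairs logistic
score: per pair an indicator of whether the basal-associated gene
out-ranks its partner within the sample (ties count 0, conservative
toward classical; unmeasured pairs are dropped with a warning), combined
as logistic(intercept + Σ wᵢ·indᵢ). Scores stratify samples into
basal-like (> 0.75), classical (< 0.25) and intermediate ([0.25, 0.75]),
both boundaries falling to intermediate. Classifier pairs and weights
are data, not an algorithm of this package: they load from an editable
TSV, and the packaged default is a synthetic classifier matched to the
generator's basal/classical modules (users supply published parameters
for real data).

Metabolic subtype calls use the quadrant rule on per-sample median
z-scored expression of the glycolytic and cholesterogenic gene modules
relative to cohort medians (both high → mixed, both at-or-below →
quiescent; a fully degenerate cohort collapses to quiescent).
Scheme-based assignment (three- or four-class) runs consensus clustering
on z-scored scheme genes at fixed k and labels each cluster by its
highest mean module score; this replaces a manual dendrogram-cutting
step with a deterministic rule — a deliberate departure from the
semi-automatic procedure, at the cost of no analyst override.

## Survival

Kaplan–Meier curves, the log-rank test and Cox proportional hazards come
from lifelines behind this module's interface; ties use the Efron
correction (the common default; the tie method is otherwise
unidentified). Forward selection scores each remaining candidate by the
Wald p of its coefficient when added to the model so far, admits the
best candidate while that p < 0.1, and always reports the exposure of
interest (KRAS status) in the final model. Wald-based entry keeps the
selection criterion consistent with the reported statistics (a
likelihood-ratio criterion would be the natural alternative).
Trial-enrolled patients are excluded through a generic boolean column,
and rows with missing covariates are dropped with a log entry.

## Proteomics

The protein matrix is treated as already-normalized log2 intensity (an
optional median-centering switch exists). Group contrasts use a
limma-style moderated t: per-gene pooled variances are shrunk toward a
scaled-F prior whose degrees of freedom and scale are method-of-moments
estimates from the spread of log sample variances; moderated
t = Δmean / (s̃·√(1/n₁+1/n₂)) on d₀ + d_g degrees of freedom. The
peptide-count-dependent variance model of dedicated proteomics DE tools
is **not** replicated — peptide counts are not part of the input
contract — and the limits d₀ → 0 (ordinary t) and d₀ → ∞ (pooled z) are
verified in tests. Genes quantified in fewer than 2 samples per group
are excluded. mRNA–protein concordance is the Spearman correlation of
per-gene mean mRNA versus mean protein across shared genes; a per-gene
(across-sample) aggregation is available behind a flag since either
reading of "correlated across genes" is defensible.

## Synthetic cohort

The generator emulates the study conditions, not the study data. Default
composition: 63 mPDAC (14% wildtype → 9 samples), 14 cholangiocarcinoma,
63 colorectal adenocarcinoma. Its genome is a reduced eight-chromosome
layout (chr1 25 Mb with a 10 Mb p-arm; chr8 15 Mb; chr2–7 12 Mb each;
2,000 genes with 8 kb bodies), which keeps 100 kb binning and interval
operations desk-sized while preserving every coordinate convention of
the real formats.

Planted structure and defaults:

* **Expression.** NB counts (dispersion α = 0.1, variance μ + αμ²),
  lognormal library sizes (σ = 0.25), three RNA-seq batches distributed
  unevenly (no batch1 in mPDAC, no batch3 in CRC) with ±0.5 log2 offsets
  on a fixed 20% gene subset. A 40-gene signature (16 up, 24 down at
  |L2FC| = 3) is shared by wildtype mPDAC and CCA; CRC carries an
  orthogonal ±2 pattern over the same genes so it clusters apart; 15
  mutant samples form a basal-like group (+2 on the 12 basal module
  genes, which are part of the down-signature) and the remaining mutants
  a classical group (+2 on a separate classical module and +1.5 on the
  non-basal down genes, giving both mutant subgroups coherent profiles —
  the four planted clusters: CRC / wildtype+CCA / basal / classical).
  Basal and classical pair genes share baselines so the rank-based
  subtype classifier reflects the modules rather than arbitrary
  abundances.
* **Mutations.** Gene-level presence: TP53 at 11.1% (wildtype) vs 81.5%
  (mutant), KRAS 0%/100%, SMAD4 and CDKN2A near-equal, MUC16 planted
  wildtype-enriched at 80%/10%, plus 40 background genes at 8%. The TMB
  layer tops up passing variants to Poisson counts matching 2.4 (wildtype)
  and 1.5 (mutant) mutations/Mb and adds, per filter class, a known
  number of variants that fail exactly that filter (15% of the passing
  count each), giving the cascade a complete truth record.
* **Copy number.** Per-sample ploidy uniform on [1.8, 4.2]; background
  segments near ploidy (capped below the amplification threshold); broad
  chr1q gains at 2·ploidy + U(0,1) in 50% of wildtype mPDAC, chr8q in
  33%, chr1q in 20% of CCA, 5% background elsewhere; CDKN2A focal
  homozygous deletions (CN 0) in 20% of samples. Carriers receive a
  +0.5 log2 dosage offset on chr1q gene expression.
* **Clinical.** Exponential survival (baseline median 14 months) with the
  wildtype hazard scaled by exp(planted log HR), default log 0.25;
  independent uniform censoring on (0, 60) months; wildtype patients
  younger (51.4 vs 60.9 years) with lower CA19-9 (median 58 vs 4,900);
  three mutant patients flagged excluded-from-OS.
* **Fusions.** In-frame, high-confidence oncogenic fusions in 6/9
  wildtype mPDAC and 3/14 CCA (NRG1/FGFR2/NTRK2/BRAF partner pairs),
  none elsewhere; low-confidence or out-of-frame passenger events are
  scattered everywhere for the filter to remove.
* **Protein.** A 40% gene subset (plus the chr1q drivers) with per-gene
  abundance correlated to log mRNA baseline at ρ = 0.3, per-sample
  deviations carrying half of the planted log2 effects, N(0, 0.4) noise
  and 15% missingness.

Everything is drawn from one seeded generator in a fixed order, so a
seed reproduces every layer byte-identically, and a truth record ties
each planted effect to the emitted entities.

**What the generator does not emulate:** mutational signatures and
positional hotspots, subclonal copy number and tumor purity, correlated
gene–gene expression beyond the planted modules, non-proportional
hazards, informative censoring, peptide-level proteomics artifacts.
Passing recovery tests therefore demonstrates that each stage measures
what it claims under its own model assumptions — not that those
assumptions hold in any real cohort.

## Problem sizes used in tests

The DE calibration suite runs 200 replicates of 2,000 genes at the
study's 9-vs-54 design (50 replicates in the acceptance script);
consensus recovery runs the full 140-sample cohort at 50 repetitions;
oracle enumeration covers all 2×2 tables with N ≤ 40; hazard-ratio
recovery uses n = 300 with 100-replicate coverage and selection nulls.
These sizes were chosen to make sampling error small relative to the
asserted tolerances.

## Known limitations

* Exact Wilcoxon and conditional-MLE odds ratios are not implemented
  (normal approximations and sample odds ratios are reported).
* The enrichment universe defaults to the DE-tested genes; other
  defensible universes (all annotated genes, expressed genes) are a
  config change.
* The consensus PAC guard is a heuristic; borderline-noise cohorts near
  the 0.35 boundary should be judged from the emitted Δ table and
  consensus matrices.
* Printed p-values from a real cohort depend on that cohort's private
  data; the package reproduces printed *contingency-table* statistics
  exactly and validates everything else by parameter recovery.
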