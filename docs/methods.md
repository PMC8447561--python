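# Methods

This note documents the statistical procedures `lipophen` implements, the
generative model behind its synthetic cohorts, the numerical choices, and
what the packaged tests do and do not establish about real data.

## Clustering model

Patients are clustered, not features. Each patient i is represented by the
profile of their z-scored features; the dissimilarity is

    d(i, j) = 1 − ρ_spearman(profile_i, profile_j) ∈ [0, 2],

with average ranks for ties. A profile with zero rank variance (all features
tied) has undefined correlation and is rejected with the patient named rather
than silently assigned. Because ranks are taken *across features within a
patient*, features must be on a common scale before the distance is
meaningful — hence the mandatory z-normalization — and any transformation
that preserves the within-profile rank order (for example adding a constant
to every feature) is invisible to the distance. The test fixtures plant
cluster structure as distinct random profile *patterns*, not uniform shifts,
for exactly this reason.

Ward linkage runs on these dissimilarities through the Lance–Williams
recurrence in its squared-update convention: pairwise squared heights start
at d² and the merge of A∪B against K updates as

    S[A∪B, K] = ((n_A+n_K) S[A,K] + (n_B+n_K) S[B,K] − n_K S[A,B]) / (n_A+n_B+n_K),

with the reported merge height √S. For Euclidean inputs this is exactly
Ward's minimum-variance criterion; on a correlation dissimilarity it is a
heuristic — a well-behaved and widely used one, but without the
variance-decomposition guarantee. We keep the combination because it is the
phenotyping protocol being implemented, and we verify the implementation in
two independent ways: against a naive O(n³) re-scan agglomerator that
recomputes every cluster distance from the original dissimilarities at every
step (the centroid identity ‖c_A−c_B‖² = mean d²(A,B) − mean d²(A,A)/2 −
mean d²(B,B)/2), and against `scipy.cluster.hierarchy.linkage`.

Determinism needs no seed: ties in the merge order are broken by the lowest
(i, j) pair where clusters are indexed by their lowest-index member, and the
whole derivation pipeline processes rows in sorted patient-id order, so any
permutation of the input rows yields identical phenotype assignments.

k-selection diagnostics are the within-cluster sum of squares per k (elbow)
and the Calinski–Harabasz variance ratio CH(k) = [B/(k−1)]/[W/(n−k)]
computed on the z-matrix with Euclidean geometry. W = 0 (perfectly compact
clusters) returns +inf with a warning. Dendrogram "left/right" is a drawing
convention, so the semantic labels anchor on data: the k = 2 cluster with
the lower median HDL-C — the top discriminating feature — is
Hypolipoprotein; median ties fall back to the lower mean, then the cluster
index, with a warning.

## Signature and replication protocol

The signature stores, per feature: cluster means, the two-sided t statistic
and p-value, a significance tier (p < 0.05, p < 0.0001), and the direction
sign(normo mean − hypo mean), together with the scaler parameters (per-feature
mean, SD with the n−1 denominator, median, and the ±3 SD cap) fitted on the
derivation cohort. Welch's unequal-variance t-test is the default — cluster
variances plainly differ for most markers — with Student's variant behind a
flag for sensitivity analysis. All tested features are retained in the
signature (the replication protocol re-uses the fixed 15-feature list);
"selected" means tier ≥ p < 0.05, and feature ranking for "top contributors"
uses |t| descending, the natural magnitude of the signature's own tests.

Projection of a new cohort: eligibility first (a patient missing strictly
more than ⌊0.20·|F|⌋ of the signature features — more than 3 of 15 — is
excluded, with the reason recorded), then median imputation, then
z-normalization with the *derivation* means and scales, outliers capped at
±3 SD, then the Spearman/Ward clustering is rebuilt and cut at k = 2.
Two points were genuinely open and are exposed as switches:

* **Imputation source.** Pure transfer uses the stored derivation medians
  (default); `impute_source="replication"` uses the projected cohort's own
  medians instead.
* **Derivation capping.** The ±3 SD clamp belongs to the replication
  protocol; the derivation run is uncapped by default (`cap_derivation`
  enables it). The self-projection identity — projecting the derivation
  cohort through its own signature reproduces its labels bit-exactly —
  holds when these preprocessing switches match and the derivation
  clustering used the signature feature list.

Replication concordance re-tests each signature feature between the projected
clusters, flags significance at the exact Bonferroni quotient 0.05/|F|
(0.003333… for 15 features; published tables sometimes print a rounded
threshold), and records per-feature direction agreement with derivation.

## Outcome definitions and univariate statistics

The primary outcome partitions every complete record exactly once:
**early death** = in-hospital death within 14 days of sepsis onset
(death_day is 1-based, "within 2 weeks" means ≤ 14); **CCI** = ICU stay
strictly > 14 days with continued organ dysfunction at day 14, or a shorter
stay discharged to LTAC, another hospital, or hospice; **rapid recovery** =
everything else. "Continued organ dysfunction" has no agreed quantitative
definition, so it is a required boolean input — a long ICU stay with that
field missing raises an indeterminate-adjudication error instead of
defaulting. LDL-C may be derived by the Friedewald relation TC − HDL-C −
TG/5, which is invalid at triglycerides ≥ 400 mg/dL; the bound is enforced
by default and can be switched off.

Group comparisons: Wilcoxon rank-sum for continuous variables (exact when
both arms have ≤ 25 tie-free observations, otherwise the tie-corrected
normal approximation; the two branches agree within 0.01 at the crossover),
Pearson chi-square for categorical variables with Fisher's exact test when
any *observed* 2×2 cell is below 5 (the expected-count convention is a
flag; for r×c tables with small cells scipy offers no exact test, so
chi-square is used and the result flagged). Bonferroni thresholds are the
exact quotients 0.05/m with the family size m recorded in every result.
AUC uses the rank-based Mann–Whitney estimator with ties counted ½, verified
against brute-force pair counting.

## LASSO prediction

The binary outcome is CCI-or-early-death vs. rapid recovery, on complete
cases over the 29 candidate predictors with ApoA-I log-transformed. The
design is standardized; λ runs over a 30-point geometric grid from the KKT
bound λ_max = max|Zᵀ(y − ȳ)|/n down to λ_max·10⁻³, and the minimum of
seeded 10-fold cross-validated binomial deviance selects λ. Nonzero
coefficients form the selected set; a plain logistic refit (statsmodels,
Newton-type) on the *unstandardized* selected columns yields odds ratios with
95 % Wald intervals — per measurement unit for linear features and per
log-unit for ApoA-I. Possible separation (huge coefficients or non-finite
standard errors) is flagged rather than hidden; fewer than 10 events raises
a warning. The λ → 0 limit of the penalized fit matches the unpenalized
maximum likelihood to 10⁻⁶, checked against an independent Newton fit.

The primary ROC predictor for the phenotype is binary cluster membership
(hypo = 1); because a continuous score is sometimes preferable and the
choice is not canonical, `continuous_cluster_score` provides the signed
projection onto the hypo→normo centroid axis in z-space as an alternative.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised. Its structure:

* **Two latent phenotypes** with prevalence 58/168 (derivation) and 26/86
  (replication).
* **Continuous biomarkers** are log-normal (linear for vitals, age, APACHE
  II): latent value = μ_pheno + σ·z with z standard normal, exponentiated
  for log-scale features, so exp(μ) is the phenotype median. The μ are the
  reported per-cluster medians for the 15 signature features; markers
  without per-cluster summaries are anchored to the overall cohort medians
  with a phenotype contrast (×1.8 hypo / ×0.65 normo for the inflammatory
  panel; derivation values, replication slightly higher overall).
  Triglycerides get near-equal medians (130 vs. 115 mg/dL) — no cluster
  difference is reported for them — with a slight hypo elevation consistent
  with their positive coupling to severity.
* **Correlation** comes from a single latent severity factor g shared by all
  features: corr = LLᵀ + diag(1−L²) with signed loadings (lipids negative;
  endothelial, inflammatory and triglycerides positive; systolic BP
  negative). This is automatically positive semidefinite and reproduces the
  reported sign structure. The loadings are deliberately moderate
  (|l| ≈ 0.15–0.18 for biomarkers): observed whole-cohort correlations of
  roughly |ρ| ≈ 0.4–0.5 between the lipid and endothelial/inflammatory
  blocks arise mostly from the phenotype mixture itself, and strong
  *conditional* coupling would smear patients along the very axis that
  separates the phenotypes. An explicit correlation matrix can be supplied
  instead (validated for symmetry, unit diagonal, PSD), in which case
  severity is drawn independently.
* **SOFA components** are ordinal 0–4: the count of thresholds
  (0.3, 0.9, 1.5, 2.1) exceeded by w·g + √(1−w²)·η + δ with w = 0.6 and
  per-component, per-phenotype shifts δ calibrated to the reported
  per-cluster component medians (total ≈ 8 vs. 4 in derivation). Sharing g
  makes organ failure co-move with the biomarker block.
* **Outcomes** are drawn from per-phenotype probability triples taken from
  the published per-cluster outcome fractions (derivation hypo
  0.448/0.397/0.155, normo 0.791/0.145/0.064; replication hypo
  0.461/0.231/0.308, normo 0.550/0.317/0.133). Admission fields are then
  generated consistently with the drawn outcome (early deaths get a death
  day ≤ 14; CCI is an 80/20 mixture of long-stay-with-dysfunction and
  short-stay-to-LTAC/hospice), so re-adjudicating the records reproduces the
  drawn labels exactly. 28-day mortality is certain for early deaths and a
  top-up Bernoulli otherwise, making the per-phenotype marginal equal the
  configured probability while staying coherent with the outcome.
* **Missingness** is MCAR at 5 % per cell, applied to the laboratory
  biomarkers only (SOFA scores and vitals are charted, not assayed).

**Calibration of separation.** The log-scale SDs of the five signature
lipids (e.g. HDL-C σ = 0.53 against Δln(26/7) = 1.31) are set so the planted
between-phenotype separation is at least 2 SD per lipid — the
clearly-separated two-phenotype regime the pipeline is designed to detect.
The printed within-cluster IQRs would imply somewhat wider spreads
(HDL-C σ ≈ 0.7–0.9); those IQRs are conditional on a cluster assignment that
itself came from the clustering, so they compress the true within-phenotype
spread ambiguously, and we prefer an explicit, documented regime. Under
these defaults the k = 2 cut recovers the latent labels with ARI ≥ 0.9 at
n = 200, CH peaks at k = 2, and signature directions match the planted
biology.

**What the generator does not emulate**, and hence what passing tests do not
show about real data: informative (non-MCAR) missingness, longitudinal
trajectories, heavy-tailed assay noise and detection limits, site effects,
treatment feedback (e.g. propofol lowering lipids), and any phenotype
structure beyond two clusters. The generator also plants exactly the
separation it is asked to; recovery results certify the pipeline under those
conditions, not the clinical effect size.

The replication default mirrors the replication cohort's higher severity
(SOFA ≥ 4 entry criterion): sicker normo cluster, higher early-death
fractions, replication cluster medians for the signature lipids. Its SOFA
direction structure is shared with derivation (hypo worse on all six
components); two published replication component medians run the other way,
but cross-cohort direction-concordance experiments require a
shared-structure generative family, which we prioritize.

## Numerical conventions and degenerate inputs

* SD uses the n−1 denominator everywhere; a constant feature (σ = 0) maps to
  z = 0 with a warning, making it cluster-neutral instead of NaN-propagating.
* Percentages in outcome tables are 100·count/cluster-n rounded to one
  decimal; the underlying counts and denominators are always carried.
* Missing cells in cohort CSVs are the empty string or `NA` on read, written
  empty; floats round-trip via `repr` so write∘read is bit-stable.
* All-missing feature with no supplied median → imputation error; cluster of
  size < 2 → test error; k outside [1, n] → cut error; a patient profile
  with all features tied → distance error naming the patient.
* Problem sizes in the packaged experiments — n = 200 × 10 seeds for
  recovery, n = 86 × 5 seeds for concordance, n = 400 × 50 seeds for the
  selection study, n = 10⁴ for calibration — were chosen as the smallest
  sizes at which the corresponding binomial/multinomial error bands are
  decisively narrower than the effects being checked.
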