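# lipophen

Unsupervised **lipoprotein phenotyping of sepsis cohorts**: derivation of
*Hypolipoprotein* vs. *Normolipoprotein* patient clusters from enrollment
biomarkers, cross-cohort replication of the cluster signature, and prediction
of chronic critical illness (CCI) or early death.

## The problem

Sepsis outcomes are heterogeneous: some patients recover rapidly, others die
within two weeks, and a third group lingers in chronic critical illness.
Cholesterol metabolism collapses early in sepsis — HDL-C, ApoA-I and PON-1
activity fall while endothelial dysfunction markers (ICAM-1, E-selectin) and
inflammatory cytokines rise — and this axis appears to stratify outcomes.
`lipophen` implements the full analysis pipeline for studying that
stratification:

1. **Phenotype derivation.** Patients are compared by Spearman rank
   correlation ρ between their z-scored feature profiles, giving the
   dissimilarity d(i,j) = 1 − ρ(i,j) ∈ [0, 2]. Hierarchical agglomerative
   clustering with Ward's minimum-variance linkage (Lance–Williams recurrence
   on squared dissimilarities) yields a dendrogram; the first two clusters are
   extracted, the choice of k = 2 being checked with the elbow curve and the
   Calinski–Harabasz score CH(k) = [B/(k−1)]/[W/(n−k)]. The cluster with the
   lower median HDL-C is labelled Hypolipoprotein.
2. **Signature extraction.** Each feature is tested between clusters with a
   two-sided Welch t-test; results are tiered at p < 0.05 (\*) and
   p < 0.0001 (\*\*). The signature stores the feature list with the fitted
   means, scaling factors and medians needed for transfer.
3. **Replication.** An independent cohort is projected through the signature:
   patients missing > 20 % of the signature features are excluded, missing
   cells are median-imputed, values are z-normalized with the *derivation*
   means and scales, outliers are capped at ±3 SD, and the Spearman/Ward
   clustering is rebuilt. Per-feature replication t-tests use a Bonferroni
   threshold of 0.05/|F|.
4. **Outcome prediction.** A LASSO-penalized logistic regression over 29
   candidate predictors (λ by seeded 10-fold cross-validated deviance,
   ApoA-I log-transformed) selects variables; an unpenalized refit reports
   odds ratios with 95 % Wald intervals. ROC/AUC (Mann–Whitney estimator)
   compares cluster membership with SOFA and APACHE II.

Because patient-level study data are not public, the package ships a
**synthetic cohort generator** that plants the two-phenotype structure
(log-normal biomarkers correlated through a latent severity factor, ordinal
SOFA components thresholded from the same latent, phenotype-conditional
outcome probabilities, MCAR missingness) so every stage is testable end to
end. The generator's latent phenotype labels are the ground truth for
recovery experiments.

## Worked example

```bash
lipophen simulate --n 172 --seed 7 --out sim
# wrote 172-patient cohort to sim/cohort.csv
lipophen derive --cohort sim/cohort.csv --out deriv
# derived signature with 13 significant features; best k = 2
lipophen simulate --preset replication --n 86 --seed 8 --out rep
lipophen replicate --cohort rep/cohort.csv --signature deriv/signature.json --out repl
# projected 86 patients (0 excluded); direction concordance 93%
lipophen predict --cohort sim/cohort.csv --seed 7 --out pred
# selected: apoa1, ldl_c
```

`deriv/quality.tsv` shows the k-selection diagnostics — the
Calinski–Harabasz score peaks at the planted two clusters:

```
k   within_ss   calinski_harabasz
1   5301.0
2   4040.88     53.01
3   3857.18     31.63
4   3784.49     22.44
```

`pred/auc.tsv` compares discrimination of rapid recovery vs. CCI/early death
(here 52 events / 120 non-events): binary cluster membership reaches AUC
0.730 against 0.618 for total SOFA; `pred/odds_ratios.tsv` reports the
refit of the LASSO-selected set, e.g. log-ApoA-I OR 0.14 (95 % CI
0.026–0.74, p = 0.02) — higher ApoA-I is protective — and LDL-C OR 0.977
per mg/dL (CI crossing 1).

The same stages are available as a library:

```python
from lipophen import generate_cohort, default_derivation_config, run_derivation

cohort, latent = generate_cohort(default_derivation_config(n=200, seed=0))
result = run_derivation(cohort)
result.phenotype.value_counts()      # hypolipoprotein / normolipoprotein
result.signature.selected()          # features significant at p < 0.05
```

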