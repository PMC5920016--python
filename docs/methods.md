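# Methods

This note documents the statistical machinery of `coxenpipe`: what each
stage computes, the generative model the synthetic studies are built on, the
defaults and why they were chosen, and what the passing test suite does and
does not establish about real data.

## Pipeline stages

### Association screening

Each gene is tested against one drug's activity vector (−log10 GI50
convention; higher = more sensitive) with one of five statistics:

* **pearson / spearman** — product-moment correlation of expression (or of
  midranks) with activity; two-sided p from the exact t transform
  `t = r sqrt((n−2)/(1−r²))`.
* **welch_t** — lines with activity strictly above the panel median form the
  "sensitive" group, the rest (including median-valued lines) "resistant";
  Welch's unequal-variance t with Satterthwaite degrees of freedom. The
  strict-inequality rule is a documented convention: a median split alone
  does not say where ties go.
* **ancova / rank_ancova** — least-squares fit of
  `activity ~ intercept + histology offsets + β₁·expression`; the statistic
  is the t of β₁ (equivalently the partial correlation t with
  `df = n − levels − 1`). The rank variant midrank-transforms expression and
  activity first. With a single histology level both reduce exactly to
  simple-regression inference.

Ranking is by raw p-value with |statistic| descending and gene ID ascending
as deterministic tie-breaks. No multiplicity correction is applied because
selection is by rank (top-k), not by a significance threshold. Genes with
zero variance or more than 20% missing values are skipped with a logged
count; tolerably incomplete genes are tested on complete cases. The default
candidate size (top_k = 500) comfortably exceeds the final per-drug set
sizes (27–68) while keeping the COXEN reference set informative.

The whole-panel path is vectorized (closed-form correlation/t algebra with a
QR-based residualization for the ANCOVA family); the per-gene functions go
through scipy/statsmodels and the test suite asserts the two paths agree to
1e-9 relative tolerance, so the fast path is continuously cross-checked.

### COXEN scoring

The COXEN score of gene *g* between panels A and B is the Pearson
correlation of its two coexpression vectors — the correlations of *g* with
each gene of a reference set, computed within each panel over that panel's
samples. Scores live in [−1, 1]; identical panels give exactly 1, and the
score is symmetric in the panels and invariant to per-gene affine rescaling
and to sample reordering (Pearson invariances).

The reference set defaults to the candidate set itself minus the gene under
evaluation: genome-wide vectors are dominated by near-zero noise
correlations (sd ≈ 1/√n per entry), which dilutes the concordance signal,
while the drug-associated candidates carry the structure that matters for
the downstream model. `coexpression_vector`/`coxen_score` accept an explicit
reference list for the whole-universe variant. Selection keeps the
`n_select` highest-scoring candidates, breaking ties by candidate rank and
then gene ID; per-drug defaults (T = 33, F = 56, A = 27, C = 68) mirror the
biomarker-set sizes of the study design this pipeline operationalizes, and
any value ≥ 5 is accepted. The patient reference cohort is quarantined: the
pipeline config refuses a study in which it doubles as a validation cohort.

### Per-drug principal-component regression

Training touches cell lines only — the fitting interface does not accept
patient cohorts. The biomarker submatrix is standardized per gene (training
mean/sd), decomposed by SVD, and activity is regressed on the leading
components. The component rule defaults to the smallest k explaining ≥ 80%
of the biomarker-set variance, capped at 10 and at the matrix rank, with an
explicit-k override; with all components retained the fit coincides with
OLS on the standardized genes (a tested equivalence). Loadings are
orthonormal by construction, so the model is a fixed linear map from
standardized expression to a chemosensitivity score.

At scoring time the cohort is re-standardized within itself. Cell lines and
tumours are different systems with incomparable location and scale; applying
training means/sds across that gap would mostly encode platform offsets.
Training-parameter standardization is available (`standardization=
"training"`), cohort mode is the default. Up to 10% of model genes may be
missing from a cohort; they contribute zero after standardization (mean
imputation) with a warning, more than 10% is a scoring error.

### Percentiles and combination

Raw scores are mapped to `(rank − 1)/(n − 1)` with midranks for ties: min 0,
max 1, invariant under any strictly monotone transform. Per-drug percentiles
are fused by maximum-likelihood logistic regression of pCR on the
percentiles, main effects only — interaction terms among four drugs would
saturate the small evaluation cohorts this design targets. On complete
separation the fit falls back to the unparameterized equal-weight mean with
a warning. The combination model is fitted once on a designated fitting
cohort and applied unchanged to validation cohorts; refitting on a
validation cohort is not part of the supported flow. Higher percentile
always means "predicted more sensitive".

### Outcome evaluation

AUC is the Mann–Whitney normalization (ties count half); the rank-sum p is
exact (full enumeration) below a combined n of 20 without ties and the
continuity-corrected normal approximation otherwise, two-sided by default.
Dichotomization takes the top `ceil(fraction·n)` scores (default 30%) as
COXEN-positive with descending score / ascending sample ID as the
deterministic order, so boundary ties resolve reproducibly. Kaplan–Meier
curves and the two-group log-rank test are delegated to lifelines; the
median is the earliest time the estimated survival reaches 0.5 and is
reported as "> max follow-up" when the curve never gets there. NPV is the
fraction of predicted-negative patients with residual disease, and the joint
false-negative risk of stacking several single-drug predictors is the
product of their per-drug risks `1 − NPV_d` under an explicit independence
assumption. Patients without a pCR/RD label are excluded from response
metrics (with a logged count) but retained for survival.

## The synthetic study generator

### Expression model

Every gene is a standardized Gaussian mixture of factor signal and noise.
With k = 5 background factors and variance shares b = 0.3 (background) and
w = 0.5 (signature):

* background gene: `x_g = √b·(u_g·F) + √(1−b)·ε`, with `u_g` a random unit
  loading vector and F the panel's factor scores;
* signature gene of drug d: `x_g = √w·s_d + √(1−w)·ε`, with `s_d` the
  panel's drug factor.

Loading directions are drawn once per study but **separately for the
cell-line and patient panels**; factor scores are fresh per panel/cohort.
In patient panels, a fraction `concordant_fraction` of each drug's signature
keeps the cell-line attachment to `s_d` ("concordant"); the rest fall back
to their independently drawn patient background loadings. Cross-panel
coexpression concordance is therefore planted only in the concordant
signature genes — precisely the structure the COXEN score detects. Making
background co-regulation panel-specific is deliberate: if background
loadings were shared across systems, every housekeeping-style gene would be
perfectly concordant and concordance would carry no selection information.

### Clinical channels

Cell-line activity for drug d is
`signature_effect · Σ_g∈sig(d) x_g + offset(tissue) + ε`, ε standard normal,
with per-tissue offsets drawn as `tissue_shift`-scaled normals — the
histology confounder the ANCOVA variants adjust for. The per-patient true
score is the mean over drugs of the standardized signature projection
(z-scored sum of that drug's signature expression). Response is
`pCR ~ Bernoulli(logistic(response_intercept + response_slope·score))`;
survival is exponential with hazard
`baseline_hazard · exp(−hazard_log_ratio·score)`, censored by an independent
exponential with rate `censor_rate`; observed time is the minimum, in
months, with no administrative cutoff.

All randomness descends from `SimulationConfig.seed` through named
`SeedSequence` children (structure / cell lines / one stream per cohort), so
identical configs are bit-identical and additional cohorts can be drawn from
the same study without storing the latent structure.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| n_cell_lines | 60 | size of a classic pharmacogenomic screen |
| n_patients | 200 | a mid-sized neoadjuvant trial cohort |
| n_genes | 2000 | desk-scale stand-in for a filtered array |
| n_signature_genes_per_drug | 25 | matches the 27–68 biomarker-set range |
| signature_effect | 0.6 | strong but noisy per-gene in vitro slope |
| concordant_fraction | 0.5 | half the in vitro signature survives in tumours |
| n_tissues / tissue_shift | 4 / 0.5 | visible histology confounding, not dominant |
| response_intercept / slope | −1.2 / 4.0 | marginal pCR rate ≈ 0.3 and an oracle (true-score) AUC ≈ 0.8, typical of ER− neoadjuvant cohorts with a strong genomic signal; set by a design calculation on the generator alone |
| baseline_hazard | 0.02 /month | median DFS ≈ 35 months at score 0 |
| hazard_log_ratio | 0.8 | clear survival separation for the top-30% split |
| censor_rate | 0.01 /month | roughly a third of patients censored |

The score entering the logistic/hazard links is the mean of per-drug
standardized projections, so its sd is ≈ 1/√n_drugs (0.5 at four drugs);
`response_slope = 4.0` therefore corresponds to an effective slope ≈ 2 per
sd of score.

### What the generator does not emulate

Probe-level microarray artifacts, cross-platform batch effects, realistic
breast-cancer subtype biology, non-exponential survival, informative
censoring, and drug–drug interactions. Passing tests show the pipeline's
statistics are correct and that it recovers the planted structure under the
stated conditions; they do not certify predictive performance on real
cohorts.

## Numerical choices and degenerate inputs

* p-values from |r| = 1 (zero residual) are reported as 0; perfect ANCOVA
  fits yield an infinite t with p 0 rather than an error.
* Zero-variance genes are detectable (`ExpressionPanel.zero_variance_genes`)
  and skipped or rejected with the gene named, depending on the stage.
* All-tied score vectors: percentiles become 0.5 with a warning; the
  top-fraction split falls back to sample-ID order with a warning.
* SVD rank is cut at `S > S_max·1e-10`; requested components beyond the rank
  are reduced with a warning.
* The logistic combination treats perfect separation and non-convergence as
  a fallback to equal weights, never as a hard failure mid-pipeline.
* Tie-breaking everywhere (candidate ranking, COXEN selection,
  dichotomization) ends at the string-sorted identifier, making every stage
  deterministic under re-runs and row permutations.

## Test-suite problem sizes

Unit tests run on 300-gene/40-line studies. The calibration and recovery
checks use the default study conditions (2000 genes, 60 lines, 200 patients)
over 10–20 seeds, 2000 replicates for the type-I-error checks, and pooled
screening p-values over 20 seeds for the uniformity test; pooling across
seeds is used because genes within one simulated panel share latent factors
and are therefore not independent draws. These sizes keep the full suite
and the acceptance script each well under a minute of compute per block
while leaving the stochastic acceptance bands comfortable margins.

## Known limitations

* The COXEN reference-set choice (candidates vs whole universe) changes
  scores; only the candidate-set default is exercised by the recovery tests.
* The "sequential" component-entry variant of principal-component regression
  (stepwise inclusion by significance) is not implemented; the variance-
  target rule is the documented substitute.
* Cox proportional-hazards modelling, competing risks, time-dependent AUC,
  and confidence bands on KM curves are out of scope.
* Gene identifiers are plain strings joined by exact intersection; platform
  harmonization is a concern for the caller.
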