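# Methods

This note documents the statistical procedures implemented in
`methsubtypes`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic cohort generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Problem setting

Tumor cohorts profiled on the Illumina 450K methylation array yield a
probes × samples matrix of beta values (methylated / total intensity,
in [0, 1]) plus per-patient survival follow-up and clinical staging.
The package discovers *prognostic molecular subtypes* from such data:
it screens CpGs whose methylation predicts survival, clusters the
cohort on those CpGs, characterizes the clusters clinically, extracts
cluster-specific marker CpGs, and builds a classifier that assigns new
samples to the discovered subtypes.

The pipeline is exposed as a model object:

```python
model = MethylationSubtypeModel(methylation, clinical, manifest, config)
results = model.fit()
print(results.summary())
```

## Pipeline stages

### 1. Preprocessing

* **Probe filters.** A probe is removed when it is missing in strictly
  more than `max_missing_frac` (default 0.70) of samples, flagged
  cross-reactive, located on a sex chromosome (chromosome names are
  normalized by stripping any `chr` prefix), or flagged for SNP
  overlap.  Filtering is idempotent, and each removed probe is reported
  under the first rule it violates.  Most production 450K pipelines use
  stricter missingness cutoffs; the threshold is configurable.
* **Sample filter.** Samples need strictly more than
  `min_followup_days` (default 30) of follow-up.
* **Imputation.** Remaining holes are filled by k-nearest-neighbor
  imputation in probe space (`k = 10`): the distance between two probes
  is the Euclidean distance over their mutually observed samples,
  rescaled by the fraction of shared samples (nan-Euclidean); a missing
  value becomes the unweighted mean, in that sample, of the `k` nearest
  probes that carry a value there.  When fewer than `k` donors exist
  the probe's own mean is used (with a warning).  Observed entries pass
  through bit-exactly; imputed values are clipped to [0, 1].
* **Train/test split.** Samples are split `train_frac` (default 0.5,
  giving 153/154 for a 307-sample cohort) at random, re-randomizing
  until the two halves are balanced — chi-square p > 0.05 for stage and
  event status, two-sample Kolmogorov–Smirnov p > 0.05 for age and
  follow-up time — up to `split_attempts` (200) draws.  If no draw
  passes, the best-scoring split is returned flagged.  The balance
  procedure is this package's operationalization of "the two groups
  were similar"; the split is deterministic given the seed.

### 2. Cox screening

Per CpG *g*, the hazard model is

  h_i(t) = h0(t) · exp(β_meth · beta_{g,i} + β_T·T + β_N·N + β_M·M +
  β_grade·grade + β_stage·stage)

* **Stage 1 (univariate).** Each probe is fitted alone; probes with
  Wald p < `alpha_univariate` (0.05) proceed.
* **Stage 2 (covariate-adjusted).** Candidates are re-fitted with T, N,
  M, grade and stage as covariates.  The "TNM classification" enters as
  three separate ordinal scores (T1→1 … T4→4, N0/1, M0/1) — one degree
  of freedom per covariate, no dummy expansion.  The methylation-term
  p-values are Benjamini–Hochberg adjusted across candidates and probes
  with q < `q_cutoff` (0.05) are kept.  Samples with missing clinical
  covariates are dropped per fit and the n used is recorded.

The partial likelihood is maximized by Newton–Raphson with
step-halving, which makes the log partial likelihood non-decreasing
across iterations; Efron's correction handles tied event times
(Breslow available; the two coincide without ties).  Convergence is
declared when the largest Newton step falls below 1e-8 (at most 50
iterations); monotone-likelihood fits (perfect separation) are flagged
non-converged and excluded from selection rather than reported with
meaningless p-values.  The implementation agrees with an established
reference fitter to ~1e-5 in coefficients on random data (tested).

### 3. Consensus clustering

Run on the train half over the screened CpGs (samples × probes).  For
each k in `k_min..k_max` (2..20; the tests and worked examples sweep
2..10 to keep runs short) and each of `n_consensus_iter` (100)
iterations, 80% of the samples are drawn without replacement and
clustered by k-means (squared-Euclidean, k-means++ initialization, 10
restarts, ≤300 Lloyd iterations).  The consensus matrix entry M_k[i,j]
is the fraction of co-clustered runs among runs where both samples were
drawn; the diagonal is 1.  Features are never resampled (the resampling
unit is the tumor sample).

Model selection uses three derived quantities:

* the empirical CDF of the upper-triangle consensus values on a fixed
  101-point grid;
* its area A(k) = Σ_i (x_i − x_{i−1}) · CDF(x_i) (histogram
  formulation; for an all-ones consensus matrix the area is exactly one
  grid-bin width);
* the relative area change Δ(2) = A(2), Δ(k) = (A(k) − A(k−1)) / A(k−1).

Per-k final labels come from average-linkage hierarchical clustering of
1 − M_k cut into k clusters, relabeled 1..k by decreasing size.
*Cluster consensus* is the mean within-cluster consensus over sample
pairs (singletons score 1).  The chosen K is the largest k whose every
cluster consensus is ≥ `min_cluster_consensus` (0.90) and beyond which
Δ stays below `delta_tol` (0.05 — the stability tolerance is a free
parameter; no canonical value exists).  Two documented fallbacks: if no
eligible k has a stabilized area the largest eligible k is used; if no
k is eligible at all, the k with the best mean cluster consensus is
returned — both flagged in the decision trace.  Child RNG streams are
keyed by (k, iteration), so extending the k range never perturbs
completed runs.

### 4. Characterization

Kaplan–Meier curves per cluster, the K-sample log-rank test across
clusters (chi-square on K−1 df; a generalized inverse guards degenerate
covariance), and Pearson chi-square association (no continuity
correction) between cluster labels and each clinical attribute.  Age is
dichotomized at 60 years, with exactly 60 assigned to "old".

### 5. Cluster-specific CpG calling

For each screened CpG the K cluster means m_1..m_K are normalized to
p_c = m_c / Σ m and scored by Shannon entropy H = −Σ p_c log2 p_c
(bits).  A flat profile scores the maximum log2 K; a CpG methylated in
essentially one cluster scores low.  Because the raw orientation is
sensitive only to one-cluster *hyper*methylation, the profile is also
reflected (1 − m_c) and the calling score is min(H_raw, H_reflected).

The threshold is calibrated on a simulated null: each null probe takes
a baseline drawn from the empirical distribution of observed per-probe
grand means, perturbed per cluster by independent Normal(0, sd) noise
with sd = `entropy_sd` (0.04) and clipped to [0.01, 0.99]; the
threshold is the `null_quantile` (0.001) quantile of the null scores
(10 000 draws, seeded).  The 0.001 quantile targets ≈0.1% false calls
among non-specific probes.

A called probe's direction is read from its largest deviation from the
cross-cluster median: hyper if the maximum mean sticks out further
above the median than the minimum drops below it (ties toward hyper),
and the called cluster is then the argmax (hyper) or argmin (hypo)
mean.  Direction is deliberately *not* tied to which entropy
orientation won: for mid-range baselines the reflected orientation can
score lower on a genuinely hypermethylated probe (relative-contrast
asymmetry of the entropy), which would miscall direction; the
deviation rule is orientation-free and exact on planted signal.  The
winning orientation is still reported per call.

Gene annotation is the union of manifest gene symbols over called
probes (one probe may contribute several genes, so genes can outnumber
probes); the promoter subset uses the Illumina feature classes TSS1500,
TSS200, 5'UTR and 1stExon.

### 6. Subtype classifier

Gaussian naive Bayes over the called specific CpGs: class priors are
training frequencies; per-class/per-feature means and variances are
maximum-likelihood moments with variances floored at `var_floor` (1e-6,
guarding near-constant CpGs).  Posteriors are computed in log space
with log-sum-exp normalization; argmax ties go to the smaller class
index.  "Bayes classifier" is interpreted as naive Bayes with Gaussian
features — the simplest model consistent with continuous beta-value
features and no stated network structure.

Evaluation: stratified tenfold cross-validation (classes are dealt
round-robin across folds, so classes smaller than the fold count
degrade gracefully; training-fold classes reduced below 2 samples are
dropped from that fold's fit with a warning).  Pooled accuracy
(correct/total over held-out predictions) is the headline number;
per-fold accuracies and their mean are also reported since either
convention appears in the literature.  Multiclass AUC is the Hand–Till
macro-average: for each unordered class pair the two conditional
pairwise AUCs (Mann–Whitney with ties at 0.5) are averaged, and the
overall AUC is the mean over pairs; for K = 2 this reduces exactly to
the classic rank-sum AUC (tested).

The trained model assigns the held-out test half; the test clusters are
re-characterized (KM, log-rank, associations) and each cluster label
present in both halves gets a two-group train-vs-test log-rank — the
consistency check that samples predicted into the same subtype share
the same prognosis.

### 7. Enrichment

Generic hypergeometric over-representation of a query gene list (e.g.
the promoter-specific genes) against user-supplied GMT gene sets:
p = P(X ≥ overlap) with population = universe, successes = set size,
draws = query size; BH adjustment across sets.  The external TF
annotation database used in the original analysis is not redistributed;
any GMT collection can be supplied.

## The synthetic cohort generator

`CohortSpec`/`generate_cohort` produce cohorts with the statistical
structure the analysis assumes, so every stage is testable without
external data.  Defaults emulate a 307-sample renal-carcinoma 450K
cohort with K = 7 latent prognostic subtypes:

* **Methylation.** Each probe has a baseline mean μ_g ~ Uniform(0.35,
  0.65); a subtype-specific probe shifts its owning subtype's mean by
  ±δ (δ = 0.3, direction 50/50 hyper/hypo), clipped to [0.01, 0.99].
  Values are Beta draws parameterized by (mean, precision) with shape
  parameters mean·ϕ and (1−mean)·ϕ, ϕ = 30 — values stay in [0, 1]
  like real beta values.  The baseline range is chosen so μ ± δ stays
  inside (0, 1) (validated).  100 specific CpGs per subtype among 2000.
* **Survival.** Follow-up = min(Exponential(rate of the sample's
  subtype), Uniform(0, 5500 days)); event = 1 iff the exponential came
  first (≈40% censoring at the defaults).  The K = 7 default rates form
  two prognostic tiers — indolent subtypes 1, 2, 4, 6 (1/7000..1/4800
  events/day) and aggressive 3, 5, 7 (1/650..1/350) — so subtypes 1–2
  have the best and 3 and 7 the worst prognosis, and *every* subtype's
  log-hazard deviates clearly from the cohort mean.  The tiering is a
  deliberate realism choice: with a monotone ladder of rates the middle
  subtypes sit at the cohort-average hazard, their marker CpGs carry no
  marginal survival signal, and the Cox screen (correctly) discards
  them — no screening-based pipeline can recover such subtypes.
* **Clinical covariates.** Stage/grade/T/N/M are drawn from a mixture:
  with probability `clinical_assoc_strength` (0.45) from a
  subtype-tilted categorical (exponential tilt of the global
  distribution, tilt tracking the subtype's hazard rank), else from the
  global categorical.  Age gets a small subtype mean offset; sex is
  Bernoulli(0.5) independent of subtype by design, so the expected
  association table (everything but sex associated) is recoverable.
* **Artifacts.** Missing entries are injected completely at random
  (2%); the first probes in the layout carry cross-reactive,
  sex-chromosome and SNP flags and are never subtype-specific.
* **Determinism.** One master seed; independent child streams per
  concern (labels, methylation, survival, clinical, missingness,
  manifest), so changing e.g. the missingness rate does not shift the
  planted signal.

`null_pvalue_cohort` redraws survival at a single rate independent of
everything — the type-I-error harness for the screen.
`planted_effect_cohort` plants one maximally variable CpG
(Beta(0.25, 0.25), the bimodal shape of variable 450K probes) with a
chosen log-hazard slope; `confounded_probe_cohort` makes survival
depend on stage and plants a probe that is a near-deterministic
function of stage (tight Beta noise, precision 400, rather than an
exactly collinear copy, which would make the adjusted Wald test
ill-posed).

**What the generator does not emulate:** batch effects, probe-type
(Infinium I/II) intensity differences, genomic correlation between
neighboring CpGs, copy-number or purity artifacts, non-proportional
hazards, and informative censoring.  Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data complications.

## Known limitations and observed behavior

* The covariate-adjusted BH stage sits on a power cliff: all probes of
  one subtype share the same samples, so their adjusted p-values move
  together, and a subtype whose conditional signal is borderline
  retains either many or almost none of its markers in a given cohort
  realization.  Under the default conditions the end-to-end pipeline
  recovers the planted K = 7 with ARI 1.0 in most cohort replicates and
  otherwise merges the weakest-deviation subtype (K = 6, ARI ≈ 0.87).
  The direct consensus benchmark (clustering the 700 planted CpGs
  without screening, 150 samples, k 2–10, 100 iterations) recovers
  K = 7 with ARI 1.0 in 10/10 seeds.
* The K-selection rule's area-stability condition is vacuous at the top
  of the eligible range; recovery therefore leans on the 0.90
  cluster-consensus eligibility rule to disqualify over-split k, which
  is exactly how it behaves on planted data.
* Problem sizes in the test-suite and in `scripts/acceptance.py` (e.g.
  k swept 2–10 rather than 2–20, 5–10 benchmark seeds, 10–50 screen
  replicates) are the package's chosen benchmark sizes; every
  stage-level default matches the protocol values documented above.
* Ordinal clinical covariates enter the Cox model as integer scores
  (one df each); no dummy expansion, no proportional-hazards
  diagnostics, no penalized variants.
* `select_k`'s "coefficient of variation" language from the consensus
  literature is subsumed into the cluster-consensus rule; no separate
  CV statistic is computed.
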