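# methsubtypes

**DNA-methylation-based prognostic subtyping of tumor cohorts.**

Tumors with the same histology can behave very differently in the
clinic.  `methsubtypes` discovers *prognostic molecular subtypes* from
Illumina 450K DNA-methylation profiles paired with survival follow-up —
the workflow used to subtype renal cell carcinoma cohorts into
survival-distinct epigenetic classes.  It is aimed at computational
biologists who have a beta-value matrix (probes × samples), a clinical
table (follow-up, vital status, TNM/stage/grade/age/sex) and a probe
manifest, and want a reproducible, tested implementation of the whole
discovery chain:

1. **Preprocessing** — probe hygiene filters (missingness > 70%,
   cross-reactive, sex-chromosome, SNP-overlap probes), the > 30-day
   follow-up filter, KNN imputation in probe space, and a re-randomized
   train/test split balanced on age, stage, follow-up and mortality.
2. **Cox screening** — per CpG *g*, univariate Cox proportional-hazards
   selection (p < 0.05) then a covariate-adjusted model

   h_i(t) = h₀(t)·exp(β_meth·β-value_{g,i} + β_T·T + β_N·N + β_M·M +
   β_grade·grade + β_stage·stage)

   with Benjamini–Hochberg control of the methylation term (q < 0.05).
   The partial likelihood is maximized by Newton–Raphson with Efron tie
   handling and step-halving.
3. **Consensus clustering** — 100 iterations of k-means (squared
   Euclidean, k-means++) on 80% sample subsamples for k = 2…20; the
   consensus matrix CDF, its area A(k) and the relative area change
   Δ(k) select K (largest k with ≥ 90% cluster consensus and a
   stabilized CDF area); final labels by average-linkage clustering of
   1 − M.
4. **Characterization** — Kaplan–Meier curves per cluster, K-sample
   log-rank, chi-square association of clusters with T/N/M, stage,
   grade, age (< 60 vs ≥ 60) and sex.
5. **Specific-CpG calling** — Shannon entropy of each CpG's normalized
   cluster-mean profile, scored in both raw and reflected (1 − m)
   orientations against a simulated null (SD = 0.04, 0.1% quantile),
   yielding cluster-specific hyper-/hypomethylated markers and their
   (promoter) gene annotation.
6. **Bayes classifier** — Gaussian naive Bayes on the specific CpGs,
   stratified tenfold cross-validation, Hand–Till multiclass AUC, and
   test-set subtype assignment with train-vs-test per-cluster log-rank
   consistency checks.
7. **Enrichment** — hypergeometric gene-set enrichment of the
   promoter-specific genes against any GMT collection (e.g. TF target
   sets), BH-adjusted.

A first-class synthetic-cohort generator (`methsubtypes.synthetic`)
produces 450K-like cohorts with planted subtypes, subtype-dependent
hazards, subtype-tilted clinical covariates (sex independent by
design), missing values and flagged probes, so the whole pipeline is
testable end to end without external data.

## Worked example

```python
from methsubtypes import CohortSpec, MethylationSubtypeModel, PipelineConfig

cfg = PipelineConfig(seed=1001, k_max=10)
model, cohort = MethylationSubtypeModel.from_synthetic(
    CohortSpec(seed=1002), cfg)
results = model.fit()
print(results.summary())
```

prints

```
DNA methylation prognostic subtyping
============================================
samples (train / test):      148 / 148
probes after filtering:      1940 (removed 60)
univariate Cox hits:         560
screened prognostic CpGs:    247
chosen number of subtypes K: 7
cluster sizes:               1: 31, 2: 23, 3: 20, 4: 19, 5: 19, 6: 19, 7: 17
train log-rank:              chi2 = 111.82, df = 6, p = 8.46e-22
specific CpGs called:        219 (entropy < 2.7763 bits)
annotated genes (promoter):  199 (87)
10-fold CV accuracy:         100.0%
Hand-Till multiclass AUC:    1.0000
test-set log-rank:           chi2 = 132.84, p = 3.24e-26
```

Reading the numbers: of 2000 simulated CpGs, 60 fail the probe filters
and 247 survive the two-stage Cox screen as independent prognostic
markers.  Consensus clustering of the 148 training samples on those
CpGs selects K = 7 — the planted number of subtypes — and the clusters
differ strongly in survival (log-rank p ≈ 8e-22).  219 CpGs are called
cluster-specific by the entropy criterion; the naive Bayes classifier
built on them reassigns held-out samples into subtypes that reproduce
the survival separation on the test half (p ≈ 3e-26).
`results.save(outdir)` writes every intermediate artifact (screen
table, consensus matrices, CDF/Δ-area table, labels, KM tables,
specific calls, gene lists, classifier JSON, metrics) as plain text;
two runs with the same config are byte-identical.

A thin CLI mirrors the stages
(`methsubtypes simulate | preprocess | screen | cluster | characterize |
specific | classify | enrich | run-all`):

```bash
methsubtypes simulate --outdir sim --seed 3
methsubtypes run-all --methylation sim/methylation.tsv \
    --clinical sim/clinical.tsv --manifest sim/manifest.csv \
    --outdir run --seed 3
```

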