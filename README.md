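# sclc-subtyper

Small-cell lung cancer (SCLC) comprises four transcriptionally defined
subtypes — SCLC-A (*ASCL1*), SCLC-N (*NEUROD1*), SCLC-P (*POU2F3*) and the
inflamed SCLC-I — with distinct therapeutic vulnerabilities. Subtyping from
tissue is hard in practice (fine-needle biopsies, degraded RNA), while SCLC
sheds abundant cell-free DNA. This package implements subtype classification
from DNA methylation (RRBS beta values) and gene expression, including a
plasma (cfDNA) classifier and a methylation-based circulating-tumor-DNA
fraction estimator, for computational oncologists building or evaluating
methylation-based SCLC biomarkers.

## Methods at a glance

**Feature association.** For a feature *x* (CpG beta value in percent, gene
expression, or tile mean) and subtype *s*, the one-vs-rest association is the
empirical AUROC — equal to the normalized Mann–Whitney statistic
U/(n₁n₀) with midrank ties — plus the mean difference
Δ = mean(x | s) − mean(x | not s).

**Site selection.** A CpG is selected for a subtype when its two-sided AUC,
max(AUC, 1−AUC), and |Δ| (percentage points) pass per-subtype thresholds:
A (0.70, 25), N (0.70, 30), P (0.80, 35), I (0.70, 30); an optional second
dataset (e.g. cell lines, AUC ≥ 0.7) restricts selection to tumor-intrinsic
signals.

**Consensus ensembles.** Per subtype, *M* one-vs-rest gradient-boosted tree
models (DART regularization) are each trained on a random draw of *k*
features from the subtype's pool (methylation classifier: k = 50 CpG sites of
the selected pool, M = 500; gene-ratio classifier: k = 20 log₂ gene-ratio
features over the top-AUC gene union). A model votes for its subtype when its
predicted probability exceeds 0.5; a sample is called subtype *s* when more
than 50% of *s*-models vote positive and *s* has the highest vote fraction,
otherwise **equivocal**. The plasma classifier (cfDMC) reuses the tissue site
pools intersected with the sites detected in cfDNA and is refit on plasma
samples.

**ctDNA fraction.** Reporter CpGs whose beta value tracks an external
tumor-fraction truth near the identity (OLS of beta on truth in percent:
R² > 0.65, slope 0.9–1.1, intercept −10..10) are averaged to estimate the
tumor fraction of a plasma sample; a seven-site GRCh38 panel ships as the
default.

**Statistics.** ROC/AUC, Youden's J cutoffs, exact (Clopper–Pearson) binomial
confidence intervals, Cohen's kappa, chi-square goodness of fit, and Wilcoxon
rank-sum tests with Benjamini–Hochberg FDR correction.

Real cohorts with subtype labels are controlled-access, so the package
includes a seeded synthetic-cohort generator
(`sclc_subtyper.synthetic_cohort`) that plants the structure the classifiers
assume — subtype-specific differential CpGs, genome-wide hypo-/hyper-
methylation shifts, marker-gene programs, FFPE/cfDNA missingness, and cfDNA
as a tumor/leukocyte mixture at known fraction — and emits the planted truth
for recovery testing. See `docs/methods.md` for modeling details.

## Worked example

```python
from sclc_subtyper import (EnsembleConfig, MedianImputer,
                           associate_all_subtypes, calls_to_table,
                           select_sites, split_train_test, train_ensemble)
from sclc_subtyper.synthetic_cohort import CohortSpec, simulate_tissue

meth, expr, sheet, truth = simulate_tissue(CohortSpec(rng_seed=7))
train, test = split_train_test(sheet, train_frac=0.7, seed=7)

m_train = meth.subset_samples(train)
assoc = associate_all_subtypes(m_train.beta, sheet.labels(train))
pools = select_sites(assoc)            # per-subtype CpG pools
print({s: len(p) for s, p in pools.items()})

imputer = MedianImputer().fit(m_train)
config = EnsembleConfig(models_per_subtype=100, features_per_model=50,
                        rng_seed=7)
dmc = train_ensemble(imputer.transform(m_train).beta, sheet.labels(train),
                     pools, config, imputer=imputer)
calls = calls_to_table(dmc.predict_methylation(meth.subset_samples(test)))
truth_labels = sheet.labels(calls["sample"]).to_numpy()
acc = (calls["label"].to_numpy() == truth_labels).mean()
print(f"held-out accuracy {100 * acc:.1f}% on {len(calls)} samples")
```

Output:

```
{'SCLC-A': 60, 'SCLC-N': 60, 'SCLC-P': 60, 'SCLC-I': 60}
held-out accuracy 100.0% on 48 samples
```

The selection step recovered all 60 planted differential CpGs per subtype
(the cohort plants 60 each at a 35-point shift over 8-point noise), and the
400-model consensus classified every held-out sample correctly with no
equivocal calls.

The same workflow is available from the shell:

```
sclc-subtyper simulate --seed 7 --out cohort/
sclc-subtyper split --sheet cohort/samples.tsv --seed 7 --out split.tsv
sclc-subtyper train-dmc --methylation cohort/methylation --sheet cohort/samples.tsv \
    --split split.tsv --seed 7 --out dmc/
sclc-subtyper predict --model dmc/ --methylation cohort/methylation --out calls.tsv
sclc-subtyper evaluate --calls calls.tsv --sheet cohort/samples.tsv --out report.tsv
```

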