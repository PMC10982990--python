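# Methods

This note documents the models and procedures implemented in `sclc_subtyper`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions.

## Data model and quality filters

Beta values are percentages of methylated reads per CpG (0–100) and stay on
that scale everywhere; the calibration bounds of the tumor-fraction estimator
(intercept −10..10) only make sense in percent. Coordinates are 1-based
("chr12:27974490"); bedGraph-style 0-based inputs are converted on read via
`zero_based=True`. Strand is ignored and CpGs on opposite strands are
distinct sites — reads of both dialects carry no strand column, and merging
would require a reference genome.

Two filters precede modeling: per-sample masking of sites with read coverage
below 10 (configurable `min_coverage`), and removal of sites missing in more
than 10% of samples (`filter_missingness`, configurable). Missingness is
preserved through binning and feature association — both handle missing
values pairwise — and is imputed only at the classifier boundary, because the
association statistics are exact on pairwise-complete data while tree
learners need complete vectors. Imputation is per-site median by default,
with parameters learned on training samples only and reapplied to test
samples (`MedianImputer`); a constant-fill strategy exists. Tree-native
missing handling would be an alternative; median imputation was chosen as the
default because it keeps the feature matrix interpretable and the base
learner configuration independent of the missingness mechanism.

## Genome tiling and global methylation profiles

`make_tiling` partitions each chromosome into fixed-width tiles (100 bp for
site-level association, 100 kbp for global profiles), cutting the last tile.
Tile values are arithmetic means of the non-missing site betas in the tile
per sample; a CpG belongs to exactly one tile by its position. Global
profiles average tile means per subtype first and then smooth with a centered
rolling window (default 500 tiles = 50 Mbp at 100 kbp width), per chromosome
so windows never span a chromosome break. Centered alignment is the
convention of zoo-style `rollmean`; the choice affects only edge tiles, which
are emitted as missing by default (`shrink_at_edges=True` relaxes this).
Whether to smooth per-subtype means or per-sample profiles is genuinely open;
the per-subtype-mean-first order was chosen because tile means are computed
per sample and then averaged per subtype, making the subtype mean the natural
series to smooth.

## Feature association and site selection

Association of a feature with a subtype is the one-vs-rest empirical AUROC
with midrank tie handling, computed as the normalized Mann–Whitney U —
orientation AUC > 0.5 when in-class values tend higher — plus the effect size
Δ = mean(in-class) − mean(out-of-class). Selection applies per-subtype
thresholds to the *two-sided* AUC, max(AUC, 1−AUC), and to |Δ|: hypo- and
hypermethylated markers are both informative, and ROC tooling with automatic
direction reports associations this way. Defaults: SCLC-A (0.70, 25 points),
SCLC-N (0.70, 30), SCLC-P (0.80, 35), SCLC-I (0.70, 30). An optional
secondary association table (cell lines) with its own AUC floor (0.70)
restricts selection to signals reproducible outside tumor-stroma context.
Within a subtype, selected sites are ranked by two-sided AUC with |Δ| and
then feature id as tie-breaks; the composite ranking is deterministic.

The gene-expression path selects, per subtype, the k = 50 genes with highest
AUC (ties: larger |Δ|, then lexicographic), takes the union across subtypes,
and builds one feature per unordered gene pair: log₂((a + ε)/(b + ε)) with
pseudocount ε = 1 and the lexicographically smaller gene as numerator. Ratios
of raw abundances are available behind `log2=False`. The log transform makes
the feature antisymmetric in the pair and finite for all non-negative
abundances.

## Consensus ensembles

For each subtype, `models_per_subtype` one-vs-rest base models are trained,
each on `features_per_model` features drawn uniformly without replacement
from the subtype's pool (methylation: 50 sites of the selected pool by
default, 10/100 as alternatives; ratios: 20). Draws are seeded per
(ensemble seed, subtype index, model index), so they are reproducible and
independent of sample order, and every draw is logged (`subsets.tsv`) for
exact replay.

Base learners are gradient-boosted trees with dropout (DART): 200 rounds,
learning rate 0.1, depth 3, dropout rate 0.1, binary logistic objective,
balanced class weights (`scale_pos_weight`), and per-node feature subsampling
`colsample_bynode = 0.3`. The feature subsampling matters: on cleanly
separable training data boosting concentrates on one or two dominant split
features, and a test sample whose missing values happen to land on those
features (imputed toward out-of-class medians) is then mis-voted by every
base model simultaneously — the random subset draws do not protect against
this because the dominant features recur across subsets. Per-node sampling
decorrelates the trees within each base model and removes this failure mode.

A base model votes positive when its predicted probability exceeds 0.5. The
consensus fraction of subtype *s* is the fraction of *s*-models voting
positive; a sample is labeled argmax-*s* when that fraction exceeds the
consensus threshold (0.5), otherwise "equivocal". Votes are counted within
each subtype's own models rather than across all models, matching per-subtype
consensus fractions as a heterogeneity readout (`heterogeneity_profile`).
Ties at the argmax go to the higher mean predicted probability, then to
equivocal.

`cv_scheme` (LOOCV or repeated 5-fold × 20) names the scheme used by
`cross_validated_accuracy` for model-size evaluation — e.g. comparing 10, 50
and 100 sites per model. Running cross-validation inside each of 2000 base
models would multiply the training cost by the fold count for no change in
the fitted models (hyperparameters are fixed), so base models are fit once on
the full training set and cross-validation is a separate, explicit
evaluation.

The plasma classifier (`refit_cfdna`) reuses the tissue site pools
intersected with the sites detected in the cfDNA matrix (after the
missingness filter) and retrains on plasma samples whose labels come from the
expression classifier. If the intersection drops below
`features_per_model`, the per-model draw is capped at the smallest pool with
a warning rather than failing — plasma detection inevitably thins the
tissue panel.

## ctDNA fraction estimation

Reporter CpGs are calibrated by ordinary least squares of beta (percent, y)
on an external tumor-fraction truth (percent, x), per site on
pairwise-complete samples; a site qualifies with R² > 0.65, slope in
[0.9, 1.1] and intercept in [−10, 10] — i.e. the site reads out the fraction
near the identity. Beta is regressed on truth (not the reverse) because the
slope/intercept bounds describe beta as a near-identity function of the
fraction. Sites with fewer than 3 complete pairs or degenerate variance are
skipped with a warning. The estimate for a sample is the arithmetic mean of
its observed reporter betas (affine-equivariant; the count of contributing
sites is reported). A seven-site GRCh38 panel ships as the default so the
estimator runs without calibration data. Manual curation of a final panel is
replaced by the deterministic criteria.

## Evaluation statistics

Clopper–Pearson intervals use beta-distribution quantiles with the usual
boundary conventions (lower 0 at zero successes, upper 100 at all successes);
values are kept at full precision and formatted to one decimal in percent
only for reports. Youden's J cutoffs break ties toward higher specificity.
Cohen's kappa is computed from the confusion table with expected agreement
from marginal products. "Wilcoxon" group comparisons are two-sided rank-sum
(Mann–Whitney) tests; Benjamini–Hochberg correction is applied within the
requested family of pairs, since family boundaries (figure panels) are an
analysis choice.

## Synthetic cohorts

The generator plants the structure the classifiers assume, with defaults
chosen as the study conditions for the test suite:

* 40 samples per subtype; 2000 null CpGs with trimodal baselines
  (modes ≈ 5/50/95%, weights 0.4/0.2/0.4) mimicking CpG bimodality;
* 60 differential CpGs per subtype shifted by 35 points in-class, with the
  planted direction aligned to each subtype's global phenotype
  (hypomethylated markers for SCLC-P, hypermethylated otherwise) — marker
  direction and genome-wide drift are not independent in methylation data;
* genome-wide per-subtype offsets, default P −8, N +6, A/I 0 points,
  qualitatively reproducing the hypo-/hypermethylated phenotypes of tiled
  profiles (magnitudes are generator choices, not measured values);
* Gaussian within-class noise (sd 8 points) clipped to [0, 100] for
  transparent effect-size control; a Beta-noise option exists for realism;
* uniform random missingness (default 10%) emulating FFPE/cfDNA dropout;
* 7 ctDNA reporter CpGs near-fully methylated in tumor of every subtype with
  their own small noise scale (sd 1) — the estimator's premise is sites
  selected for invariant tumor methylation;
* expression: log-normal null genes plus 25 marker genes per subtype at
  8-fold change.

cfDNA samples are linear mixtures, `f·tissue + (1−f)·background + noise`
clipped to [0, 100], with a flat 50% background except 0 at the reporter
sites, plus optional uniform site dropout emulating reduced plasma coverage.

What the generator does **not** emulate: read-level bisulfite data and
coverage heterogeneity, copy-number effects on beta values, correlated
(regional) methylation structure, structured (non-uniform) missingness,
tumor-purity gradients in tissue, and fragmentomic properties of cfDNA.
Passing recovery tests therefore demonstrates that the pipeline's statistics
and ensembles behave as designed under the assumed generative model, not that
the published classifiers' accuracies transfer to real cohorts.

## Problem sizes and numerical conventions

The test suite and the acceptance script train 100 base models per subtype
for the tissue classifier and 50 per subtype for the plasma refits (at the
default 200 DART rounds); these sizes give stable consensus fractions on the
synthetic cohorts while keeping a full run in minutes on one CPU. The
determinism check uses a small ensemble (10 models, 40 rounds) since scale is
irrelevant to it. All randomness flows from explicit seeds: cohort
generation, train/test splits, subset draws (keyed per subtype and model
index) and the xgboost boosters (single-threaded, seeded per model), so
identical configuration and data reproduce byte-identical call tables and
subset logs. Degenerate inputs follow explicit conventions: AUC of a feature
with an absent class is 0.5; constant features get AUC 0.5 via midranks;
tiles without observed sites are missing; equivocal calls are excluded from
accuracy and reported as a separate count.
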