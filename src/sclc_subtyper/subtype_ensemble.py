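"""Random-feature consensus ensembles for SCLC subtype calling.

Three classifiers share this machinery: the gene-ratio classifier (GRC,
trained on log gene-ratio features, 20 ratios per base model), the tissue
DNA-methylation classifier (DMC, 10/50/100 CpG sites per base model, default
50), and its plasma refit (cfDMC, same site pools intersected with the sites
detectable in cfDNA).

For each subtype, ``models_per_subtype`` one-vs-rest base models are trained,
each on a feature subset drawn uniformly without replacement from that
subtype's feature pool. Base learners are gradient-boosted trees with
tree-dropout regularization (DART). A base model votes for its subtype when
its predicted probability exceeds 0.5; the per-subtype consensus fraction is
the fraction of that subtype's models voting positive. A sample is called the
subtype with the highest consensus fraction provided the fraction exceeds the
consensus threshold (0.5), otherwise it is "equivocal". Ties at the argmax
are broken toward the subtype with the higher mean predicted probability, and
to "equivocal" if still tied.

Subset draws are seeded per (subtype, model index), so they are independent
of training-sample order, and every draw is logged for exact replay.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml

from .methylome_io import SUBTYPES, MedianImputer, MethylationMatrix, SampleSheet

CV_SCHEMES = ("loocv", "repeated_kfold", "none")


@dataclass
class EnsembleConfig:
    """Hyperparameters of a consensus ensemble.

    The DART parameters (200 rounds, learning rate 0.1, depth 3, dropout
    rate 0.1) are package defaults; all are exposed. ``cv_scheme`` names the
    cross-validation used by :func:`cross_validated_accuracy` for model-size
    evaluation; base models themselves are fit with the fixed hyperparameters.
    """

    models_per_subtype: int = 500
    features_per_model: int = 50
    n_estimators: int = 200
    learning_rate: float = 0.1
    max_depth: int = 3
    rate_drop: float = 0.1
    skip_drop: float = 0.0
    colsample_bynode: float = 0.3
    consensus_threshold: float = 0.5
    vote_probability_threshold: float = 0.5
    cv_scheme: str = "loocv"
    cv_folds: int = 5
    cv_repeats: int = 20
    balanced_class_weights: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.models_per_subtype < 1:
            raise ValueError("models_per_subtype must be >= 1")
        if self.features_per_model < 1:
            raise ValueError("features_per_model must be >= 1")
        if not 0.0 < self.consensus_threshold < 1.0:
            raise ValueError("consensus_threshold must lie in (0, 1)")
        if self.cv_scheme not in CV_SCHEMES:
            raise ValueError(f"cv_scheme must be one of {CV_SCHEMES}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnsembleConfig":
        return cls(**d)


@dataclass
class SubtypeCall:
    """Consensus fractions and final label for one sample."""

    sample: str
    fractions: dict[str, float]
    mean_probs: dict[str, float]
    label: str


def _xgb_params(config: EnsembleConfig, seed: int, scale_pos_weight: float) -> dict:
    return {
        "booster": "dart",
        "eta": config.learning_rate,
        "max_depth": config.max_depth,
        "rate_drop": config.rate_drop,
        "skip_drop": config.skip_drop,
        "colsample_bynode": config.colsample_bynode,
        "objective": "binary:logistic",
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
        "verbosity": 0,
        "scale_pos_weight": scale_pos_weight,
    }


def consensus_label(fractions: pd.Series, mean_probs: pd.Series,
                    threshold: float) -> str:
    """Consensus rule: the argmax subtype when its fraction exceeds the
    threshold, else "equivocal"; argmax ties go to the higher mean predicted
    probability, and to "equivocal" if still tied."""
    if (fractions <= threshold).all():
        return "equivocal"
    best = fractions.max()
    cand = list(fractions.index[fractions == best])
    if len(cand) == 1:
        return cand[0]
    mp = mean_probs.loc[cand]
    winners = list(mp.index[mp == mp.max()])
    return winners[0] if len(winners) == 1 else "equivocal"


def _check_complete(features: pd.DataFrame, rows: Sequence[str], what: str) -> None:
    missing_rows = [r for r in rows if r not in features.index]
    if missing_rows:
        raise ValueError(f"{what}: features absent from matrix: {missing_rows[:5]}")
    block = features.loc[list(rows)]
    if block.isna().any().any():
        raise ValueError(f"{what}: missing values remain after imputation")


class ConsensusEnsemble:
    """Per-subtype collections of random-feature base models plus the
    consensus-calling rule. Subset draws are recorded for exact replay."""

    def __init__(self, config: EnsembleConfig,
                 pools: dict[str, tuple[str, ...]],
                 subsets: dict[str, list[tuple[str, ...]]],
                 boosters: dict[str, list[xgb.Booster]],
                 imputer: MedianImputer | None = None):
        for subtype, models in subsets.items():
            pool = set(pools[subtype])
            for subset in models:
                if not set(subset) <= pool:
                    raise ValueError(
                        f"{subtype}: base-model subset not within feature pool")
        self.config = config
        self.pools = pools
        self.subsets = subsets
        self.boosters = boosters
        self.imputer = imputer

    @property
    def subtypes(self) -> list[str]:
        return list(self.pools)

    # -- prediction ----------------------------------------------------------
    def predict_fractions(self, features: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Consensus fractions and mean positive-vote probabilities.

        ``features`` is features x samples, complete over every pool. Returns
        (fractions, mean_probs), both samples x subtypes.
        """
        for subtype in self.subtypes:
            _check_complete(features, self.pools[subtype], f"predict ({subtype})")
        samples = list(features.columns)
        fractions = {}
        mean_probs = {}
        thr = self.config.vote_probability_threshold
        for subtype in self.subtypes:
            votes = np.zeros(len(samples))
            probs = np.zeros(len(samples))
            for subset, booster in zip(self.subsets[subtype],
                                       self.boosters[subtype]):
                X = features.loc[list(subset)].to_numpy(dtype=float).T
                p = booster.predict(xgb.DMatrix(
                    X, feature_names=[f"f{i}" for i in range(len(subset))]))
                votes += p > thr
                probs += p
            n_models = len(self.subsets[subtype])
            fractions[subtype] = votes / n_models
            mean_probs[subtype] = probs / n_models
        return (pd.DataFrame(fractions, index=samples),
                pd.DataFrame(mean_probs, index=samples))

    def predict(self, features: pd.DataFrame) -> list[SubtypeCall]:
        fractions, mean_probs = self.predict_fractions(features)
        calls = []
        for sample in fractions.index:
            frac = fractions.loc[sample]
            mp = mean_probs.loc[sample]
            label = consensus_label(frac, mp, self.config.consensus_threshold)
            calls.append(SubtypeCall(sample=sample, fractions=dict(frac),
                                     mean_probs=dict(mp), label=label))
        return calls

    def predict_methylation(self, m: MethylationMatrix) -> list[SubtypeCall]:
        """Predict from a methylation matrix, applying the stored imputer.

        The matrix is restricted to the union of the feature pools; pool
        sites absent from the matrix, and missing cells, are filled from the
        imputer's training medians. A pool feature that cannot be filled
        raises.
        """
        pool_union = sorted({f for pool in self.pools.values() for f in pool})
        beta = m.beta.reindex(pool_union)
        if self.imputer is not None and self.imputer.medians_ is not None:
            beta = beta.T.fillna(self.imputer.medians_).T
        return self.predict(beta)

    # -- bookkeeping ---------------------------------------------------------
    def subsets_table(self) -> pd.DataFrame:
        rows = [(subtype, i, ",".join(subset))
                for subtype in self.subtypes
                for i, subset in enumerate(self.subsets[subtype])]
        return pd.DataFrame(rows, columns=["subtype", "model_index", "features"])

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        self.subsets_table().to_csv(directory / "subsets.tsv", sep="\t", index=False)
        pools_rows = [(s, f) for s in self.subtypes for f in self.pools[s]]
        pd.DataFrame(pools_rows, columns=["subtype", "feature"]).to_csv(
            directory / "pools.tsv", sep="\t", index=False)
        if self.imputer is not None and self.imputer.medians_ is not None:
            self.imputer.medians_.rename("median").to_csv(
                directory / "imputer.tsv", sep="\t", index_label="feature")
        for subtype in self.subtypes:
            mdir = directory / "models" / subtype
            mdir.mkdir(parents=True, exist_ok=True)
            for i, booster in enumerate(self.boosters[subtype]):
                booster.save_model(mdir / f"{i:04d}.json")

    @classmethod
    def load(cls, directory: str | Path) -> "ConsensusEnsemble":
        directory = Path(directory)
        with open(directory / "config.yaml") as fh:
            config = EnsembleConfig.from_dict(yaml.safe_load(fh))
        pools_df = pd.read_csv(directory / "pools.tsv", sep="\t")
        pools = {s: tuple(g["feature"]) for s, g in pools_df.groupby(
            "subtype", sort=False)}
        subs_df = pd.read_csv(directory / "subsets.tsv", sep="\t")
        subsets: dict[str, list[tuple[str, ...]]] = {s: [] for s in pools}
        boosters: dict[str, list[xgb.Booster]] = {s: [] for s in pools}
        for _, row in subs_df.iterrows():
            subsets[row["subtype"]].append(tuple(row["features"].split(",")))
        for subtype in pools:
            mdir = directory / "models" / subtype
            for i in range(len(subsets[subtype])):
                booster = xgb.Booster()
                booster.load_model(mdir / f"{i:04d}.json")
                boosters[subtype].append(booster)
        imputer = None
        ipath = directory / "imputer.tsv"
        if ipath.exists():
            med = pd.read_csv(ipath, sep="\t", index_col="feature")["median"]
            imputer = MedianImputer()
            imputer.medians_ = med
        return cls(config=config, pools=pools, subsets=subsets,
                   boosters=boosters, imputer=imputer)


def calls_to_table(calls: Sequence[SubtypeCall],
                   subtypes: Sequence[str] = SUBTYPES) -> pd.DataFrame:
    """Flat call table: sample, one consensus-fraction column per subtype, label."""
    rows = []
    for c in calls:
        rows.append([c.sample] + [c.fractions[s] for s in subtypes] + [c.label])
    cols = ["sample"] + [f"frac_{s.split('-')[1]}" for s in subtypes] + ["label"]
    return pd.DataFrame(rows, columns=cols)


def heterogeneity_profile(calls: Sequence[SubtypeCall],
                          subtypes: Sequence[str] = SUBTYPES) -> pd.DataFrame:
    """Per-sample 4-vector of raw consensus fractions, for plotting/export."""
    return pd.DataFrame({s: [c.fractions[s] for c in calls] for s in subtypes},
                        index=[c.sample for c in calls])


def split_train_test(sheet: SampleSheet, train_frac: float = 0.7,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified train/test split over labeled samples (70/30 by default).

    Deterministic under ``seed``; strata with fewer than 2 samples go to
    training with a warning. Unknown-labeled samples are excluded.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = sheet.labels()
    strata = sorted(set(labels) - {"unknown"},
                    key=lambda s: (SUBTYPES.index(s) if s in SUBTYPES else 99, s))
    train: list[str] = []
    test: list[str] = []
    for stratum in strata:
        ids = sorted(sid for sid, lab in labels.items() if lab == stratum)
        if len(ids) < 2:
            warnings.warn(f"subtype {stratum} has {len(ids)} sample(s); "
                          "assigning to training set")
            train.extend(ids)
            continue
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(test)


def train_ensemble(features: pd.DataFrame, labels: pd.Series | Mapping[str, str],
                   pools: Mapping[str, Sequence[str]],
                   config: EnsembleConfig,
                   imputer: MedianImputer | None = None) -> ConsensusEnsemble:
    """Train the per-subtype random-feature ensembles.

    ``features`` is features x samples and must be complete over every pool
    (impute first). ``labels`` maps sample id to its subtype. For each
    subtype and model index, ``features_per_model`` features are drawn
    uniformly without replacement from the subtype's pool with a dedicated
    seed stream keyed to (rng_seed, subtype index, model index), so draws do
    not depend on sample order.
    """
    if isinstance(labels, Mapping):
        labels = pd.Series(labels)
    labels = labels.loc[list(features.columns)]
    subtype_order = [s for s in SUBTYPES if s in pools] + \
                    [s for s in pools if s not in SUBTYPES]
    pools_sorted = {s: tuple(sorted(set(pools[s]))) for s in subtype_order}
    for subtype, pool in pools_sorted.items():
        if len(pool) == 0:
            raise ValueError(f"empty feature pool for {subtype}")
        if len(pool) < config.features_per_model:
            raise ValueError(
                f"pool for {subtype} has {len(pool)} features, "
                f"fewer than features_per_model={config.features_per_model}")
        _check_complete(features, pool, f"train ({subtype})")
        if not (labels == subtype).any():
            raise ValueError(f"no training samples labeled {subtype}")

    subsets: dict[str, list[tuple[str, ...]]] = {}
    boosters: dict[str, list[xgb.Booster]] = {}
    for si, subtype in enumerate(subtype_order):
        pool = pools_sorted[subtype]
        y = (labels == subtype).to_numpy(dtype=int)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        spw = (n_neg / n_pos) if (config.balanced_class_weights and n_pos) else 1.0
        subs, boos = [], []
        for mi in range(config.models_per_subtype):
            rng = np.random.default_rng([config.rng_seed, si, mi])
            subset = tuple(sorted(rng.choice(len(pool),
                                             size=config.features_per_model,
                                             replace=False)))
            feat_subset = tuple(pool[i] for i in subset)
            X = features.loc[list(feat_subset)].to_numpy(dtype=float).T
            seed = int(rng.integers(0, 2**31 - 1))
            dtrain = xgb.DMatrix(
                X, label=y,
                feature_names=[f"f{i}" for i in range(len(feat_subset))])
            booster = xgb.train(_xgb_params(config, seed, spw), dtrain,
                                num_boost_round=config.n_estimators)
            subs.append(feat_subset)
            boos.append(booster)
        subsets[subtype] = subs
        boosters[subtype] = boos
    return ConsensusEnsemble(config=config, pools=pools_sorted, subsets=subsets,
                             boosters=boosters, imputer=imputer)


def refit_cfdna(e: ConsensusEnsemble, cfdna: MethylationMatrix,
                labels: pd.Series | Mapping[str, str],
                max_missing_frac: float = 0.10,
                config: EnsembleConfig | None = None) -> ConsensusEnsemble:
    """Refit the tissue classifier for plasma samples.

    Pools are the tissue pools intersected with the sites detected in the
    cfDNA matrix after the missingness filter; training labels come from the
    caller (in the published workflow, samples with a gene-ratio
    classification). When an intersected pool drops below the configured
    subset size, the per-model draw is capped at the smallest pool with a
    warning (plasma detection inevitably thins the tissue site set).
    Imputation parameters are learned on the cfDNA training samples and
    stored on the returned ensemble.
    """
    from .methylome_io import filter_missingness

    filtered = filter_missingness(cfdna, max_missing_frac)
    present = set(filtered.site_ids)
    pools = {}
    for subtype, pool in e.pools.items():
        inter = tuple(s for s in pool if s in present)
        if not inter:
            raise ValueError(f"no tissue pool sites detected in cfDNA for {subtype}")
        pools[subtype] = inter
    config = config or dataclasses.replace(e.config, cv_scheme="loocv")
    smallest = min(len(p) for p in pools.values())
    if smallest < config.features_per_model:
        warnings.warn(
            f"cfDNA pools reduced to {smallest} sites; capping "
            f"features_per_model at {smallest} (was {config.features_per_model})")
        config = dataclasses.replace(config, features_per_model=smallest)
    if isinstance(labels, Mapping):
        labels = pd.Series(labels)
    train_ids = [s for s in filtered.samples if s in labels.index]
    train_m = filtered.subset_samples(train_ids)
    imputer = MedianImputer().fit(train_m)
    complete = imputer.transform(train_m)
    return train_ensemble(complete.beta, labels.loc[train_ids], pools, config,
                          imputer=imputer)


def cross_validated_accuracy(features: pd.DataFrame,
                             labels: pd.Series | Mapping[str, str],
                             pools: Mapping[str, Sequence[str]],
                             config: EnsembleConfig) -> dict:
    """Cross-validated consensus accuracy under the configured scheme.

    Used for model-size evaluation (e.g. choosing sites per model); expensive,
    intended for small configurations. ``loocv`` leaves one sample out per
    fold; ``repeated_kfold`` uses stratified k-fold with repeats.
    """
    from sklearn.model_selection import LeaveOneOut, RepeatedStratifiedKFold

    if isinstance(labels, Mapping):
        labels = pd.Series(labels)
    labels = labels.loc[list(features.columns)]
    y = labels.to_numpy()
    n = len(y)
    if config.cv_scheme == "loocv":
        splitter = LeaveOneOut()
        splits = splitter.split(np.zeros(n))
    elif config.cv_scheme == "repeated_kfold":
        splitter = RepeatedStratifiedKFold(n_splits=config.cv_folds,
                                           n_repeats=config.cv_repeats,
                                           random_state=config.rng_seed)
        splits = splitter.split(np.zeros(n), y)
    else:
        raise ValueError("cv_scheme 'none' has no cross-validation to run")
    correct = total = equivocal = 0
    for train_idx, test_idx in splits:
        cols = features.columns
        e = train_ensemble(features[cols[train_idx]], labels.iloc[train_idx],
                           pools, config)
        calls = e.predict(features[cols[test_idx]])
        for call, truth in zip(calls, y[test_idx]):
            if call.label == "equivocal":
                equivocal += 1
            else:
                correct += int(call.label == truth)
            total += 1
    classified = total - equivocal
    return {
        "n_predictions": total,
        "n_equivocal": equivocal,
        "accuracy": correct / classified if classified else float("nan"),
    }
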