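import warnings

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from hypothesis import given, settings
from hypothesis import strategies as st

from sclc_subtyper import (EnsembleConfig, MethylationMatrix, SampleSheet,
                           calls_to_table, consensus_label,
                           cross_validated_accuracy, heterogeneity_profile,
                           refit_cfdna, split_train_test, train_ensemble)

SUBTYPES = ("SCLC-A", "SCLC-N", "SCLC-P", "SCLC-I")


def _sheet(counts: dict[str, int]) -> SampleSheet:
    rows = []
    for s, n in counts.items():
        for i in range(n):
            rows.append((f"{s[-1]}{i:02d}", "tissue", s, "baseline"))
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "specimen_type", "subtype_label",
                       "timepoint"]))


def _training_data(n_per=6, n_feat_per=8, seed=0):
    """Tiny separable training table: one informative block per subtype."""
    rng = np.random.default_rng(seed)
    samples, labels = [], {}
    for s in SUBTYPES:
        for i in range(n_per):
            sid = f"{s[-1]}{i:02d}"
            samples.append(sid)
            labels[sid] = s
    feats, pools = [], {}
    values = []
    for k, s in enumerate(SUBTYPES):
        names = [f"{s[-1]}_site{j}" for j in range(n_feat_per)]
        pools[s] = names
        feats.extend(names)
        block = rng.normal(20, 4, size=(n_feat_per, len(samples)))
        in_cols = [i for i, sid in enumerate(samples) if labels[sid] == s]
        block[:, in_cols] += 55
        values.append(block)
    features = pd.DataFrame(np.vstack(values), index=feats, columns=samples)
    return features, pd.Series(labels), pools


class TestSplit:
    def test_seven_three_split_per_subtype(self):
        sheet = _sheet({s: 10 for s in SUBTYPES})
        train, test = split_train_test(sheet, 0.7, seed=1)
        labels = sheet.labels()
        for s in SUBTYPES:
            assert sum(labels[t] == s for t in train) == 7
            assert sum(labels[t] == s for t in test) == 3

    def test_same_seed_same_split(self):
        sheet = _sheet({s: 9 for s in SUBTYPES})
        assert split_train_test(sheet, 0.7, seed=5) == \
            split_train_test(sheet, 0.7, seed=5)

    def test_disjoint_and_exhaustive(self):
        sheet = _sheet({"SCLC-A": 13, "SCLC-N": 6, "SCLC-P": 4, "SCLC-I": 5})
        train, test = split_train_test(sheet, 0.7, seed=2)
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(sheet.labeled_ids())

    @given(seed=st.integers(0, 1000), n=st.integers(2, 25),
           frac=st.floats(0.2, 0.9))
    @settings(max_examples=40, deadline=None)
    def test_stratum_proportions_within_one_sample(self, seed, n, frac):
        sheet = _sheet({"SCLC-A": n, "SCLC-N": max(2, n // 2)})
        train, _ = split_train_test(sheet, frac, seed=seed)
        labels = sheet.labels()
        for s, total in (("SCLC-A", n), ("SCLC-N", max(2, n // 2))):
            got = sum(labels[t] == s for t in train)
            assert abs(got - frac * total) <= 1

    def test_singleton_stratum_goes_to_training_with_warning(self):
        sheet = _sheet({"SCLC-A": 5, "SCLC-P": 1})
        with pytest.warns(UserWarning, match="SCLC-P"):
            train, test = split_train_test(sheet, 0.7, seed=0)
        assert "P00" in train and "P00" not in test


@pytest.fixture(scope="module")
def tiny_ensemble():
    features, labels, pools = _training_data()
    config = EnsembleConfig(models_per_subtype=5, features_per_model=4,
                            n_estimators=20, rng_seed=3)
    e = train_ensemble(features, labels, pools, config)
    return e, features, labels, pools, config


class TestTrainPredict:
    def test_pool_equal_to_subset_size_gives_identical_models(self):
        features, labels, pools = _training_data(n_feat_per=4)
        config = EnsembleConfig(models_per_subtype=3, features_per_model=4,
                                n_estimators=10, rng_seed=0)
        e = train_ensemble(features, labels, pools, config)
        for s in SUBTYPES:
            assert len({sub for sub in e.subsets[s]}) == 1
        fr, _ = e.predict_fractions(features)
        # all models share the subset, so votes are unanimous
        assert set(np.unique(fr.to_numpy())) <= {0.0, 1.0}

    def test_same_seed_identical_subset_draws(self):
        features, labels, pools = _training_data()
        config = EnsembleConfig(models_per_subtype=4, features_per_model=3,
                                n_estimators=5, rng_seed=11)
        e1 = train_ensemble(features, labels, pools, config)
        e2 = train_ensemble(features, labels, pools, config)
        assert e1.subsets == e2.subsets

    def test_subsets_invariant_to_sample_order(self):
        features, labels, pools = _training_data()
        config = EnsembleConfig(models_per_subtype=4, features_per_model=3,
                                n_estimators=5, rng_seed=7)
        e1 = train_ensemble(features, labels, pools, config)
        perm = list(reversed(features.columns))
        e2 = train_ensemble(features[perm], labels, pools, config)
        assert e1.subsets == e2.subsets

    def test_pool_smaller_than_subset_raises(self):
        features, labels, pools = _training_data(n_feat_per=3)
        config = EnsembleConfig(models_per_subtype=2, features_per_model=4,
                                n_estimators=5)
        with pytest.raises(ValueError, match="fewer than"):
            train_ensemble(features, labels, pools, config)

    def test_missing_values_rejected(self):
        features, labels, pools = _training_data()
        features.iloc[0, 0] = np.nan
        config = EnsembleConfig(models_per_subtype=1, features_per_model=2,
                                n_estimators=5)
        with pytest.raises(ValueError, match="missing values"):
            train_ensemble(features, labels, pools, config)

    def test_fractions_equal_brute_force_vote_counts(self, tiny_ensemble):
        e, features, labels, pools, config = tiny_ensemble
        fr, mp = e.predict_fractions(features)
        for s in SUBTYPES:
            votes = np.zeros(features.shape[1])
            for subset, booster in zip(e.subsets[s], e.boosters[s]):
                X = features.loc[list(subset)].to_numpy().T
                p = booster.predict(xgb.DMatrix(
                    X, feature_names=[f"f{i}" for i in range(len(subset))]))
                votes += p > 0.5
            np.testing.assert_allclose(fr[s].to_numpy(),
                                       votes / config.models_per_subtype)

    def test_holdout_accuracy_on_separable_data(self, tiny_ensemble):
        e, features, labels, _, _ = tiny_ensemble
        calls = e.predict(features)
        tab = calls_to_table(calls)
        assert (tab["label"].to_numpy() == labels.loc[tab["sample"]].to_numpy()).all()

    def test_single_model_reduces_to_argmax_with_abstention(self):
        features, labels, pools = _training_data()
        config = EnsembleConfig(models_per_subtype=1, features_per_model=4,
                                n_estimators=20, rng_seed=5)
        e = train_ensemble(features, labels, pools, config)
        _, mean_probs = e.predict_fractions(features)
        calls = e.predict(features)
        for call in calls:
            probs = mean_probs.loc[call.sample]
            direct = probs.idxmax() if (probs > 0.5).any() else "equivocal"
            assert call.label == direct

    def test_save_load_roundtrip(self, tiny_ensemble, tmp_path):
        e, features, _, _, _ = tiny_ensemble
        e.save(tmp_path / "bundle")
        from sclc_subtyper import ConsensusEnsemble
        back = ConsensusEnsemble.load(tmp_path / "bundle")
        assert back.subsets == e.subsets
        f1, _ = e.predict_fractions(features)
        f2, _ = back.predict_fractions(features)
        pd.testing.assert_frame_equal(f1, f2)


class TestConsensusLabel:
    @given(fracs=st.lists(st.floats(0, 1), min_size=4, max_size=4),
           probs=st.lists(st.floats(0, 1), min_size=4, max_size=4),
           thr=st.floats(0.1, 0.9))
    @settings(max_examples=100, deadline=None)
    def test_equivocal_iff_no_fraction_exceeds_threshold(self, fracs, probs, thr):
        f = pd.Series(fracs, index=SUBTYPES)
        p = pd.Series(probs, index=SUBTYPES)
        label = consensus_label(f, p, thr)
        if label == "equivocal":
            assert (f <= thr).all() or \
                (f == f.max()).sum() > 1  # multi-way unresolved tie
        else:
            assert f[label] > thr
            assert f[label] == f.max()

    def test_all_fractions_at_threshold_is_equivocal(self):
        f = pd.Series([0.5, 0.5, 0.2, 0.1], index=SUBTYPES)
        p = pd.Series([0.9, 0.8, 0.1, 0.1], index=SUBTYPES)
        assert consensus_label(f, p, 0.5) == "equivocal"

    def test_tie_broken_by_mean_probability(self):
        f = pd.Series([0.8, 0.8, 0.0, 0.0], index=SUBTYPES)
        p = pd.Series([0.7, 0.9, 0.1, 0.1], index=SUBTYPES)
        assert consensus_label(f, p, 0.5) == "SCLC-N"


class TestHeterogeneityAndExport:
    def test_fractions_roundtrip_through_export(self, tiny_ensemble, tmp_path):
        e, features, _, _, _ = tiny_ensemble
        calls = e.predict(features)
        prof = heterogeneity_profile(calls)
        assert ((prof >= 0) & (prof <= 1)).all().all()
        path = tmp_path / "calls.tsv"
        calls_to_table(calls).to_csv(path, sep="\t", index=False,
                                     float_format="%.6f")
        back = pd.read_csv(path, sep="\t")
        for s in SUBTYPES:
            col = f"frac_{s.split('-')[1]}"
            np.testing.assert_allclose(back[col].to_numpy(),
                                       prof[s].to_numpy(), atol=1e-6)


class TestRefitCfdna:
    def test_full_site_overlap_keeps_pools(self, tiny_ensemble):
        e, features, labels, pools, _ = tiny_ensemble
        sites = [f"chr1:{i + 1}" for i in range(len(features))]
        renamed = features.copy()
        renamed.index = sites
        name_map = dict(zip(features.index, sites))
        e2_pools = {s: tuple(sorted(name_map[f] for f in p))
                    for s, p in e.pools.items()}
        cfdna = MethylationMatrix(renamed)
        # rebuild a site-named ensemble, then refit on an identical matrix
        config = EnsembleConfig(models_per_subtype=2, features_per_model=4,
                                n_estimators=5, rng_seed=1)
        e_sites = train_ensemble(renamed, labels,
                                 {s: list(p) for s, p in e2_pools.items()},
                                 config)
        refit = refit_cfdna(e_sites, cfdna, labels)
        assert {s: tuple(sorted(p)) for s, p in refit.pools.items()} == \
            {s: tuple(sorted(p)) for s, p in e_sites.pools.items()}

    def test_missing_subtype_pool_raises(self, tiny_ensemble):
        e, features, labels, pools, _ = tiny_ensemble
        sites = [f"chr1:{i + 1}" for i in range(len(features))]
        renamed = features.copy()
        renamed.index = sites
        name_map = dict(zip(features.index, sites))
        config = EnsembleConfig(models_per_subtype=2, features_per_model=4,
                                n_estimators=5, rng_seed=1)
        e_sites = train_ensemble(
            renamed, labels,
            {s: [name_map[f] for f in p] for s, p in pools.items()}, config)
        drop = set(e_sites.pools["SCLC-P"])
        thinned = renamed.loc[[s for s in sites if s not in drop]]
        with pytest.raises(ValueError, match="SCLC-P"):
            refit_cfdna(e_sites, MethylationMatrix(thinned), labels)


def test_cross_validated_accuracy_loocv_smoke():
    features, labels, pools = _training_data(n_per=4)
    config = EnsembleConfig(models_per_subtype=2, features_per_model=3,
                            n_estimators=10, cv_scheme="loocv", rng_seed=2)
    res = cross_validated_accuracy(features, labels, pools, config)
    assert res["n_predictions"] == 16
    assert res["accuracy"] >= 0.8
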