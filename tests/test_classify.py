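"""Split regimes, scoring, attribution and the leakage contrast."""

import numpy as np
import pandas as pd
import pytest

from sleepprint.classify import (
    ClassifierConfig,
    SplitRegime,
    attribute_features,
    confusion_matrix,
    fit_predict,
    make_splits,
    run_regime,
    score_single,
    shap_contributions,
)

FAST = ClassifierConfig(n_estimators=60, max_depth=4)


def toy_table(n_subjects=6, epochs=40, n_feats=8, informative=True, seed=0):
    """Feature table with (optionally) a subject-identifying feature."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["GSC", "MI", "MSI"]
    for s in range(n_subjects):
        for night in (1, 2):
            X = rng.standard_normal((epochs, n_feats))
            if informative:
                X[:, 0] += 5.0 * s
            frame = pd.DataFrame(
                X, columns=[f"f{i}" for i in range(n_feats)])
            frame.insert(0, "subject", f"S{s}")
            frame.insert(1, "night", night)
            frame.insert(2, "stage", "NREM")
            frame.insert(3, "isi_group", groups[s % 3])
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)


class TestSplits:
    def test_night_to_night_is_deterministic(self, rng):
        table = toy_table()
        r = SplitRegime("night_to_night", repetitions=3)
        splits = make_splits(table, r, rng)
        for train, test in splits:
            assert np.array_equal(train, splits[0][0])
            assert set(table["night"].iloc[train]) == {1}
            assert set(table["night"].iloc[test]) == {2}

    def test_subject_wise_subjects_disjoint(self, rng):
        table = toy_table()
        for train, test in make_splits(
                table, SplitRegime("subject_wise", repetitions=5), rng):
            assert not (set(table["subject"].iloc[train])
                        & set(table["subject"].iloc[test]))

    def test_intra_individual_test_fraction(self, rng):
        table = toy_table(epochs=50)
        (train, test), = make_splits(
            table, SplitRegime("intra_individual", repetitions=1), rng)
        assert len(test) == pytest.approx(0.2 * len(table), rel=0.05)
        assert len(train) + len(test) == len(table)

    def test_subject_wise_needs_five_subjects(self, rng):
        table = toy_table(n_subjects=4)
        with pytest.raises(ValueError, match="5 subjects"):
            make_splits(table, SplitRegime("subject_wise"), rng)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError):
            SplitRegime("leave_one_out").validate()


class TestFitPredict:
    def test_class_index_feature_is_perfectly_separable(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 300)
        X = np.c_[y.astype(float), rng.standard_normal((300, 3))]
        pred, proba, model = fit_predict(X[:200], y[:200], X[200:], FAST)
        assert (pred == y[200:]).mean() == 1.0
        assert proba.shape == (100, 3)

    def test_single_class_training_warns_and_predicts_constant(self):
        X = np.random.default_rng(1).standard_normal((20, 3))
        with pytest.warns(UserWarning, match="single-class"):
            pred, _, model = fit_predict(X, np.zeros(20), X, FAST)
        assert np.all(pred == 0)
        assert model is None


class TestScore:
    def test_perfect_and_coin_flip_confusions(self):
        assert score_single([0, 0, 1, 1], [0, 0, 1, 1]) == {
            "accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0}
        m = score_single([0, 1, 0, 1], [0, 0, 1, 1])
        assert m["accuracy"] == 0.5
        assert m["f1"] == 0.5

    def test_matches_bruteforce_per_class_metrics(self, rng):
        truth = rng.integers(0, 3, 200)
        pred = rng.integers(0, 3, 200)
        m = score_single(pred, truth)
        precs, recs = [], []
        for c in range(3):
            tp = np.sum((pred == c) & (truth == c))
            precs.append(tp / max(np.sum(pred == c), 1))
            recs.append(tp / np.sum(truth == c))
        assert m["precision"] == pytest.approx(np.mean(precs))
        assert m["recall"] == pytest.approx(np.mean(recs))
        conf = confusion_matrix(pred, truth, np.arange(3))
        assert conf.sum() == 200
        assert np.all(conf.sum(axis=1) == np.bincount(truth, minlength=3))

    def test_class_absent_from_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            m = score_single(np.array([0, 1, 2]), np.array([0, 1, 1]),
                             classes=np.arange(3))
        assert 0.0 <= m["f1"] <= 1.0


class TestAttribution:
    def _fit(self, X, y):
        _, _, model = fit_predict(X, y, X[:1], FAST)
        return model

    def test_additivity_contract(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((150, 5))
        y = (X[:, 0] > 0).astype(int) + (X[:, 1] > 0).astype(int)
        model = self._fit(X, y)
        contribs = shap_contributions(model, X[:20])
        import xgboost as xgb

        margins = model.get_booster().predict(
            xgb.DMatrix(X[:20]), output_margin=True)
        assert np.allclose(contribs.sum(axis=-1), margins, atol=1e-5)

    def test_constant_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 4))
        X[:, 2] = 1.0
        y = (X[:, 0] > 0).astype(int)
        model = self._fit(X, y)
        contribs = shap_contributions(model, X[:50])
        assert np.abs(contribs[..., 2]).max() == 0.0

    def test_planted_informative_feature_ranks_first(self):
        # one real feature among many noise features: top attribution
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            X = rng.standard_normal((240, 30))
            y = (X[:, 7] > 0).astype(int)
            model = self._fit(X, y)
            names = [f"ch_{i}_x" for i in range(30)]
            from sleepprint.spectra import BandScheme

            scheme = BandScheme({"x": (0.0, 1.0)})
            summ = attribute_features(model, X, names, scheme=scheme)
            if summ.mean_abs.index[0] == "ch_7_x":
                hits += 1
        assert hits >= n_rep - 1

    def test_band_shares_sum_to_one(self, small_table):
        regime = SplitRegime("intra_individual", repetitions=1)
        _, attribution = run_regime(small_table, regime, FAST, seed=0,
                                    collect_attribution=True)
        assert sum(attribution.band_shares_top10.values()) == pytest.approx(1.0)
        assert len(attribution.top10) == 10


class TestLeakageContrast:
    def test_regime_ordering_on_fingerprint_cohort(self, small_table):
        """Same-subject splits score high; held-out subjects fall to chance."""
        intra, _ = run_regime(
            small_table, SplitRegime("intra_individual", repetitions=2),
            FAST, seed=3)
        night, _ = run_regime(
            small_table, SplitRegime("night_to_night", repetitions=2),
            FAST, seed=3)
        subj, _ = run_regime(
            small_table, SplitRegime("subject_wise", repetitions=4),
            FAST, seed=3)
        assert intra.metrics["accuracy"][0] >= 90.0
        assert night.metrics["accuracy"][1] == 0.0  # deterministic split
        assert subj.metrics["accuracy"][0] <= intra.metrics["accuracy"][0]
        # chance level for 3 balanced-ish groups
        assert subj.metrics["accuracy"][0] <= 100 / 3 + 35.0

    def test_label_permutation_drops_subject_wise_to_chance(self, small_table):
        rng = np.random.default_rng(9)
        table = small_table.copy()
        # shuffle group labels over subjects (within-subject consistent)
        subjects = sorted(table["subject"].unique())
        glabels = [table.loc[table["subject"] == s, "isi_group"].iloc[0]
                   for s in subjects]
        shuffled = dict(zip(subjects, rng.permutation(glabels)))
        table["isi_group"] = table["subject"].map(shuffled)
        report, _ = run_regime(
            table, SplitRegime("subject_wise", repetitions=6), FAST, seed=1)
        acc = report.metrics["accuracy"][0] / 100
        # within a wide interval of chance at the subject-cluster level
        n_units = 6 * 2  # 6 reps x ~2 held-out subjects
        half = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n_units)
        assert abs(acc - 1 / 3) <= half + 0.05
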