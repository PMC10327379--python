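"""Balanced accuracy, univariate logistic fits, nested CV, ensembles."""

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

import olivenet as ov
from olivenet.classifier import (
    CvSummary,
    EnsembleCorrelationClassifier,
    EnsembleModel,
    SettingModel,
    balanced_accuracy,
    balanced_sample_weight,
    fit_logistic_batch,
    fit_setting_model,
    predict_consensus,
    select_ensemble,
)
from olivenet.features import FeatureMatrix
from olivenet.propagation import PropagationSettings


def _setting(i=0):
    return PropagationSettings(threshold=400, c_disease=0.1 * (i + 1), c_molecule=0.5)


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1])
        assert balanced_accuracy(y, y) == 1.0

    def test_all_negative_on_imbalanced_labels(self):
        y = np.array([1, 0, 0, 0, 0, 0])
        assert balanced_accuracy(y, np.zeros(6)) == 0.5

    def test_confusion_counts_example(self):
        # TP=3 FN=1 TN=2 FP=2 -> (3/4 + 2/4) / 2
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 1, 0, 0])
        assert balanced_accuracy(y, pred) == pytest.approx(0.625)

    def test_single_class_labels_error(self):
        with pytest.raises(ValueError, match="both classes"):
            balanced_accuracy(np.ones(4), np.ones(4))


class TestLogisticFit:
    def test_batch_fit_matches_scikit_learn(self):
        """The batched IRLS solver is cross-checked against LogisticRegression."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 4))
        y = (rng.random(120) < expit(1.5 * X[:, 0] - 0.5)).astype(int)
        w = balanced_sample_weight(y)
        b0, b1 = fit_logistic_batch(X, y, w, l2=1e-4, tol=1e-10, max_iter=200)
        for j in range(X.shape[1]):
            ref = LogisticRegression(C=1e4, class_weight="balanced", tol=1e-10)
            ref.fit(X[:, [j]], y)
            assert b0[j] == pytest.approx(float(ref.intercept_[0]), abs=1e-4)
            assert b1[j] == pytest.approx(float(ref.coef_[0, 0]), abs=1e-4)

    def test_separable_feature_reaches_perfect_training_accuracy(self):
        x = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = fit_setting_model(x, y, _setting())
        pred = (expit(m.intercept + m.slope * x) >= 0.5).astype(int)
        assert balanced_accuracy(y, pred) == 1.0

    def test_flipping_labels_flips_slope_sign(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = (x + rng.normal(scale=0.5, size=60) > 0).astype(int)
        m = fit_setting_model(x, y, _setting())
        m_flip = fit_setting_model(x, 1 - y, _setting())
        assert m.slope > 0 > m_flip.slope

    def test_label_independent_feature_cv_accuracy_near_chance(self):
        rng = np.random.default_rng(42)
        n = 200
        X = 0.5 + rng.normal(scale=0.1, size=(n, 3))
        y = np.concatenate([np.ones(40, int), np.zeros(160, int)])
        clf = EnsembleCorrelationClassifier(n_repeats=3, random_state=0).fit(X, y)
        assert 0.35 <= clf.cv_summary_.mean_balanced_accuracy <= 0.65


class TestNestedCv:
    def _planted(self, rng, n=180, k=12):
        y = np.concatenate([np.ones(30, int), np.zeros(n - 30, int)])
        X = rng.normal(scale=0.2, size=(n, k))
        X[:, 5] += 0.9 * y  # one strongly separating setting
        return X, y

    def test_planted_signal_recovered(self):
        X, y = self._planted(np.random.default_rng(3))
        clf = EnsembleCorrelationClassifier(n_repeats=3, random_state=1).fit(X, y)
        assert clf.cv_summary_.mean_balanced_accuracy > 0.9

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(4)
        X, y = self._planted(rng)
        y_perm = rng.permutation(y)
        clf = EnsembleCorrelationClassifier(n_repeats=3, random_state=1).fit(X, y_perm)
        assert 0.4 <= clf.cv_summary_.mean_balanced_accuracy <= 0.6

    def test_fixed_seed_reproduces_summary_exactly(self):
        X, y = self._planted(np.random.default_rng(5))
        a = EnsembleCorrelationClassifier(n_repeats=1, random_state=7).fit(X, y)
        b = EnsembleCorrelationClassifier(n_repeats=1, random_state=7).fit(X, y)
        assert a.cv_summary_ == b.cv_summary_
        assert np.array_equal(a.nested_cv_scores_, b.nested_cv_scores_)
        assert np.array_equal(a.member_indices_, b.member_indices_)

    def test_stratification_balances_folds(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.concatenate([np.ones(30, int), np.zeros(150, int)])
        rng = np.random.default_rng(0)
        for seed in rng.integers(2 ** 31, size=5):
            kf = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(seed))
            for _, test_idx in kf.split(np.zeros((180, 1)), y):
                ideal = len(test_idx) * 30 / 180
                assert abs(y[test_idx].sum() - ideal) <= 1

    def test_min_class_size_enforced(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1] + [0] * 7)
        with pytest.raises(ValueError, match="minimum class size"):
            EnsembleCorrelationClassifier(n_outer=5).fit(X, y)

    def test_inner_selection_never_sees_held_out_rows(self, monkeypatch):
        """Setting selection must only ever receive outer-training rows."""
        X, y = self._planted(np.random.default_rng(6))
        n = len(y)
        all_rows = {tuple(row) for row in X}
        assert len(all_rows) == n  # fingerprints are unique
        seen_by_selection = []
        orig = EnsembleCorrelationClassifier._select_setting

        def spy(self, X_train, y_train, seed):
            seen_by_selection.append({tuple(row) for row in X_train})
            return orig(self, X_train, y_train, seed)

        monkeypatch.setattr(EnsembleCorrelationClassifier, "_select_setting", spy)
        EnsembleCorrelationClassifier(n_repeats=2, random_state=1).fit(X, y)
        assert len(seen_by_selection) == 2 * 5
        for rep in range(2):
            held_out = []
            for fold in seen_by_selection[5 * rep: 5 * rep + 5]:
                assert len(fold) < n
                held_out.append(all_rows - fold)
            # the five held-out folds of one repeat partition all rows
            assert set().union(*held_out) == all_rows
            assert sum(len(h) for h in held_out) == n


class TestEnsembleSelection:
    def _models(self, accs):
        return [
            SettingModel(setting=_setting(i), intercept=0.0, slope=1.0,
                         cv_balanced_accuracy=a)
            for i, a in enumerate(accs)
        ]

    def _cv(self, mean):
        return CvSummary(mean_balanced_accuracy=mean, sd_balanced_accuracy=0.0,
                         n_repeats=25, n_outer_folds=5, n_inner_folds=5, rng_seed=1)

    def test_above_mean_models_selected(self):
        ens = select_ensemble(self._models([0.60, 0.80]), self._cv(0.70))
        assert len(ens.members) == 1
        assert ens.members[0].cv_balanced_accuracy == 0.80

    def test_fallback_to_best_when_none_qualify(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            ens = select_ensemble(self._models([0.55, 0.65]), self._cv(0.70))
        assert len(ens.members) == 1
        assert ens.members[0].cv_balanced_accuracy == 0.65
        assert "falling back" in caplog.text

    def test_exactly_equal_accuracy_excluded(self):
        ens = select_ensemble(self._models([0.70, 0.80]), self._cv(0.70))
        assert [m.cv_balanced_accuracy for m in ens.members] == [0.80]


class TestPredictConsensus:
    def _ensemble(self, probs):
        # slope 0 makes each member output a constant probability
        members = tuple(
            SettingModel(setting=_setting(i), intercept=float(np.log(p / (1 - p))),
                         slope=0.0, cv_balanced_accuracy=0.9)
            for i, p in enumerate(probs)
        )
        return EnsembleModel(members=members, selection_threshold=0.5, cv=CvSummary(
            0.8, 0.02, 25, 5, 5, 1))

    def _features(self, n_settings):
        return FeatureMatrix(
            molecules=("molA",),
            settings=tuple(_setting(i) for i in range(n_settings)),
            values=np.zeros((1, n_settings)),
        )

    def test_single_member_scales_to_percent(self):
        out = predict_consensus(self._ensemble([0.78]), self._features(1))
        assert out["molA"] == pytest.approx(78.0)

    def test_two_members_average(self):
        out = predict_consensus(self._ensemble([0.60, 0.80]), self._features(2))
        assert out["molA"] == pytest.approx(70.0)

    def test_output_bounded_in_percent(self, planted_study):
        clf = planted_study["clf"]
        probs = clf.correlation_probability(planted_study["X"])
        assert np.all(probs >= 0.0) and np.all(probs <= 100.0)

    def test_missing_setting_column_is_an_error(self):
        ens = self._ensemble([0.6, 0.7])
        fm = self._features(1)  # lacks the second member's setting
        with pytest.raises(KeyError, match="lacks the setting"):
            predict_consensus(ens, fm)

    def test_model_json_round_trip(self, tmp_path):
        ens = self._ensemble([0.6, 0.7])
        p = tmp_path / "model.json"
        ens.to_json(p)
        again = EnsembleModel.from_json(p)
        assert again == ens
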