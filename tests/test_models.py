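import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from eegasym.features import feature_columns
from eegasym.models import (
    ModelConfig,
    anova_f_select,
    binarize_labels,
    compute_metrics,
    fit_elasticnet_logistic,
    logo_cv,
    nested_grid_search,
    predict_scores,
)

from conftest import RECOVERY_EMOTION


class TestBinarize:
    def test_basic(self):
        out = binarize_labels(["happy", "sad", "happy"], "happy")
        assert list(out) == [1, 0, 1]

    def test_all_target(self):
        out = binarize_labels(["sad", "sad"], "sad")
        assert list(out) == [1, 1]

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="disgust"):
            binarize_labels(["happy", "sad"], "disgust")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="surprise"):
            binarize_labels(["happy", "surprise"], "happy")


class TestAnovaSelect:
    def test_constant_feature_excluded(self, rng):
        X = np.column_stack([np.ones(100), rng.normal(size=100)])
        y = (rng.random(100) < 0.5).astype(int)
        mask = anova_f_select(X, y)
        assert not mask[0]

    def test_informative_feature_included(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = np.column_stack([y + rng.normal(0, 0.1, size=n), rng.normal(size=n)])
        mask = anova_f_select(X, y)
        assert mask[0]

    def test_f_equals_squared_pooled_t(self, rng):
        n = 120
        y = (rng.random(n) < 0.4).astype(int)
        X = rng.normal(size=(n, 10))
        from sklearn.feature_selection import f_classif
        F, _ = f_classif(X, y)
        for j in range(10):
            t, _ = sst.ttest_ind(X[y == 1, j], X[y == 0, j], equal_var=True)
            assert np.isclose(F[j], t**2, atol=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            anova_f_select(rng.normal(size=(10, 3)), np.ones(10))


class TestElasticNetFit:
    def test_extreme_regularization_shrinks_all(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, 5)) + y[:, None]
        omega = fit_elasticnet_logistic(X, y, phi=0.5, C=1e-6)
        assert np.all(np.abs(omega) < 1e-3)

    def test_informative_feature_positive_sign(self, rng):
        n = 500
        y = (rng.random(n) < 0.5).astype(int)
        X = np.column_stack(
            [np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.3, n),
             rng.normal(size=n)]
        )
        omega = fit_elasticnet_logistic(X, y, phi=0.5, C=1.0)
        assert omega[0] > 0

    def test_deterministic_given_seed(self, rng):
        n = 150
        y = (rng.random(n) < 0.5).astype(int)
        X = rng.normal(size=(n, 8)) + 0.5 * y[:, None]
        w1 = fit_elasticnet_logistic(X, y, 0.3, 1.0, seed=11)
        w2 = fit_elasticnet_logistic(X, y, 0.3, 1.0, seed=11)
        assert np.array_equal(w1, w2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_elasticnet_logistic(rng.normal(size=(10, 2)), np.zeros(10), 0.5, 1.0)

    def test_scores_strictly_in_unit_interval(self, rng):
        X = rng.normal(size=(50, 3))
        omega = rng.normal(size=3)
        s = predict_scores(X, omega)
        assert np.all((s > 0) & (s < 1))


class TestMetrics:
    def test_perfect_separation_all_ones(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(y, s)
        for v in m.as_dict().values():
            assert np.isclose(v, 1.0)

    def test_hand_computed_contingency(self):
        # TP=3, FP=1, FN=2, TN=4
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05])
        m = compute_metrics(y, s, threshold=0.5)
        assert np.isclose(m.sensitivity, 0.6)
        assert np.isclose(m.specificity, 0.8)
        assert np.isclose(m.ppv, 0.75)
        assert np.isclose(m.npv, 2 / 3, atol=1e-4)
        assert np.isclose(m.f1, 2 / 3, atol=1e-4)
        assert np.isclose(m.g_mean, np.sqrt(0.6 * 0.8), atol=1e-4)

    def test_gmean_identity(self, rng):
        y = (rng.random(80) < 0.4).astype(int)
        s = rng.random(80)
        m = compute_metrics(y, s)
        assert np.isclose(m.g_mean, np.sqrt(m.sensitivity * m.specificity),
                          atol=1e-12)

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, np.full(4, 0.7))
        assert m.auc_roc == 0.5

    def test_single_class_auc_missing(self):
        m = compute_metrics(np.ones(5), np.linspace(0, 1, 5))
        assert m.auc_roc is None and m.auc_pr is None

    def test_no_predicted_positives_warns_and_zeroes(self):
        y = np.array([1, 0, 1, 0])
        with pytest.warns(UserWarning, match="no predicted positives"):
            m = compute_metrics(y, np.full(4, 0.1))
        assert m.ppv == 0.0 and m.f1 == 0.0


def _toy_features(rng, n_subjects=6, per_subject=40, effect=0.0):
    """Minimal canonical feature table with an optional planted column."""
    cols = feature_columns()
    rows = []
    emotions = ["neutral", "sad", "fear", "happy"]
    for s in range(n_subjects):
        for i in range(per_subject):
            emotion = emotions[i % 4]
            x = rng.normal(0, 0.3, size=len(cols))
            if emotion == "sad":
                x[2] += effect  # FP1_FP2_alpha
            rows.append({
                "subject_id": f"S{s:02d}", "session_id": 1, "trial_id": i // 4,
                "segment_index": i, "emotion": emotion,
                **dict(zip(cols, x)),
            })
    return pd.DataFrame(rows)


class TestNestedGridSearch:
    def test_grid_cardinality_is_66(self, rng):
        config = ModelConfig()
        assert len(config.phi_grid) * len(config.C_grid) == 66

    def test_degenerate_grid_returned_without_search(self, rng):
        df = _toy_features(rng, n_subjects=3, per_subject=12)
        config = ModelConfig(phi_grid=(0.5,), C_grid=(1.0,))
        phi, C = nested_grid_search(
            df[feature_columns()].to_numpy(),
            binarize_labels(df["emotion"], "sad"),
            df["subject_id"].to_numpy(),
            config,
        )
        assert (phi, C) == (0.5, 1.0)

    def test_too_few_subjects_rejected(self, rng):
        df = _toy_features(rng, n_subjects=2, per_subject=12)
        with pytest.raises(ValueError, match="subjects"):
            nested_grid_search(
                df[feature_columns()].to_numpy(),
                binarize_labels(df["emotion"], "sad"),
                df["subject_id"].to_numpy(),
                ModelConfig(),
            )

    def test_strong_signal_not_fully_shrunk(self, rng):
        df = _toy_features(rng, n_subjects=5, per_subject=48, effect=1.5)
        config = ModelConfig(phi_grid=(0.0, 0.5, 1.0), C_grid=(1e-3, 1e-1, 1e1))
        phi, C = nested_grid_search(
            df[feature_columns()].to_numpy(),
            binarize_labels(df["emotion"], "sad"),
            df["subject_id"].to_numpy(),
            config,
        )
        assert C > 1e-3


class TestLogoCV:
    def test_one_fold_per_subject_disjoint(self, rng):
        df = _toy_features(rng, n_subjects=5, per_subject=24, effect=1.0)
        config = ModelConfig(phi_grid=(0.5,), C_grid=(1.0,))
        folds = logo_cv(df, "sad", config)
        assert len(folds) == 5
        held = {f.held_out_subject for f in folds}
        assert held == set(df["subject_id"].unique())

    def test_omega_embedding_zero_iff_unselected_or_shrunk(self, rng):
        df = _toy_features(rng, n_subjects=4, per_subject=24, effect=1.0)
        folds = logo_cv(df, "sad", ModelConfig(phi_grid=(1.0,), C_grid=(0.1,)))
        for f in folds:
            assert f.omega.shape == (135,)
            assert np.all(f.omega[~f.selected_mask] == 0)

    def test_no_leakage_test_rows_do_not_affect_omega(self, rng):
        df = _toy_features(rng, n_subjects=4, per_subject=24, effect=1.0)
        config = ModelConfig(phi_grid=(0.5,), C_grid=(1.0,), seed=3)
        folds1 = logo_cv(df, "sad", config)
        # permute the feature values of one held-out subject's rows only
        df2 = df.copy()
        mask = df2["subject_id"] == folds1[0].held_out_subject
        cols = feature_columns()
        scram = df2.loc[mask, cols].to_numpy()
        df2.loc[mask, cols] = scram[::-1]
        folds2 = logo_cv(df2, "sad", config)
        assert np.array_equal(folds1[0].omega, folds2[0].omega)

    def test_planted_effect_high_auc(self, recovery_folds):
        aucs = [f.metrics_test.auc_roc for f in recovery_folds
                if f.metrics_test.auc_roc is not None]
        assert np.mean(aucs) > 0.9

    def test_null_data_auc_near_half(self, null_features):
        config = ModelConfig(phi_grid=(0.5,), C_grid=(1.0,), seed=5)
        folds = logo_cv(null_features, "sad", config)
        aucs = [f.metrics_test.auc_roc for f in folds
                if f.metrics_test.auc_roc is not None]
        assert 0.45 <= float(np.mean(aucs)) <= 0.55

    def test_chosen_hyperparameters_from_grid(self, recovery_folds):
        config_phis = {0.0, 0.5, 1.0}
        for f in recovery_folds:
            assert f.phi_star in config_phis
            assert f.C_star in {1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2}
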