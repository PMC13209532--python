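import numpy as np
import pandas as pd
import pytest

from tugait.classify import (
    ALL_FEATURES,
    GRADING_FEATURES,
    SCREENING_FEATURES,
    HierarchicalLassoClassifier,
    fit_stage,
    loocv_evaluate,
    metrics_from_confusion,
    regularization_sweep,
)
from tugait.errors import EvaluationError, SchemaError
from tugait.simulate import (
    CohortSpec,
    overlap_cohort_spec,
    separable_cohort_spec,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def separable():
    df = simulate_cohort(separable_cohort_spec(seed=0))
    return df, df["label"].to_numpy()


def test_stage_feature_sets_match_the_design():
    assert SCREENING_FEATURES == ("T_total", "V_walk", "T_turn", "N_total", "CV")
    assert GRADING_FEATURES == (
        "V_walk", "N_walk", "SL_mean", "T_total", "T_turn", "T_sts", "CV"
    )


class TestFitStage:
    def test_separable_cohort_trains_to_perfection(self, separable):
        X, y = separable
        model = fit_stage(X, y, "screening", reg_strength="select")
        Xs = X[list(SCREENING_FEATURES)].to_numpy()
        y1 = np.where(y == "N", "N", "A")
        assert (model.pipeline.predict(Xs) == y1).mean() == 1.0

    def test_strong_penalty_zeroes_coefficients(self, separable):
        X, y = separable
        model = fit_stage(X, y, "screening", reg_strength=0.01)
        assert model.n_selected < len(SCREENING_FEATURES)
        assert np.sum(model.coefficients == 0.0) >= 1

    def test_permuted_labels_score_at_chance(self, separable):
        X, y = separable
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        from tugait.classify import _cv_accuracy, _make_pipeline

        Xs = X[list(SCREENING_FEATURES)].to_numpy()
        y1 = np.where(y_perm == "N", "N", "A")
        acc, _ = _cv_accuracy(_make_pipeline(1.0, 0), Xs, y1, 3, 0)
        assert 0.3 <= acc <= 0.85  # chance band for a 2:1 binary split

    def test_single_class_training_set_rejected(self):
        X = pd.DataFrame(np.ones((4, 8)), columns=list(ALL_FEATURES))
        with pytest.raises(EvaluationError):
            fit_stage(X, np.array(["N", "N", "N", "N"]), "screening")


class TestCascade:
    def test_normal_prediction_bypasses_stage_two(self, separable):
        X, y = separable
        clf = HierarchicalLassoClassifier(random_state=0).fit(X, y)
        preds = clf.predict(X)
        # every sample screened normal stays N; the rest are M or P
        assert set(preds) <= {"N", "M", "P"}
        stage1 = clf.stage1_.pipeline
        x1 = X[list(SCREENING_FEATURES)].to_numpy()
        screened_normal = stage1.predict_proba(x1)[:, list(stage1.classes_).index("A")] < 0.5
        assert (preds[screened_normal] == "N").all()
        assert (preds[~screened_normal] != "N").all()

    def test_missing_feature_is_a_schema_error(self, separable):
        X, y = separable
        clf = HierarchicalLassoClassifier(random_state=0).fit(X, y)
        with pytest.raises(SchemaError):
            clf.predict(X.drop(columns=["CV"]))

    def test_sklearn_get_set_params_roundtrip(self):
        clf = HierarchicalLassoClassifier(stage2_C=2.0)
        params = clf.get_params()
        assert params["stage2_C"] == 2.0
        clf.set_params(stage2_C=0.5)
        assert clf.stage2_C == 0.5


class TestLoocv:
    def test_separable_cohort_is_recovered(self, separable):
        X, y = separable
        rep = loocv_evaluate(X, y, random_state=0)
        assert rep.accuracy >= 0.95
        assert rep.screening_accuracy == 1.0

    def test_overlapping_m_p_errors_stay_in_the_pathological_block(self):
        df = simulate_cohort(overlap_cohort_spec(seed=1))
        rep = loocv_evaluate(df, df["label"].to_numpy(), random_state=0)
        C = rep.confusion  # rows/cols ordered N, M, P
        assert C[0, 1] == 0 and C[0, 2] == 0  # no N predicted pathological
        assert C[1, 0] == 0 and C[2, 0] == 0  # no pathological predicted N

    def test_identical_features_score_majority_fraction(self):
        X = pd.DataFrame(np.ones((12, 8)), columns=list(ALL_FEATURES))
        y = np.array(["N"] * 4 + ["M"] * 4 + ["P"] * 4)
        rep = loocv_evaluate(X, y, random_state=0)
        # indistinguishable classes: accuracy cannot beat the class prior
        assert rep.accuracy <= 1 / 3 + 1e-9

    def test_determinism_under_fixed_seed(self, separable):
        X, y = separable
        r1 = loocv_evaluate(X, y, random_state=0)
        r2 = loocv_evaluate(X, y, random_state=0)
        assert (r1.y_pred == r2.y_pred).all()
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_no_scaler_leakage_across_folds(self, separable):
        """Fold-specific scalers must differ on heterogeneous data."""
        X, y = separable
        means = []
        for i in (0, len(y) - 1):
            tr = np.ones(len(y), dtype=bool)
            tr[i] = False
            m = HierarchicalLassoClassifier(random_state=0).fit(X[tr], y[tr])
            means.append(m.stage1_.scaler_mean.copy())
        assert not np.allclose(means[0], means[1])


class TestSweep:
    def test_feature_count_non_increasing_with_penalty(self, separable):
        X, y = separable
        table, chosen = regularization_sweep(X, y, "screening", random_state=0)
        by_penalty = table.sort_values("penalty")
        counts = by_penalty["n_selected_features"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert chosen in set(table["C"])

    def test_weakest_penalty_keeps_the_most_features(self, separable):
        """The lasso path only ever grows as the penalty relaxes; features
        that carry no class signal (N_total in this cohort) rightly stay
        out even at the weakest penalty."""
        X, y = separable
        table, _ = regularization_sweep(X, y, "screening", random_state=0)
        weakest = table.loc[table["penalty"].idxmin()]
        assert weakest["n_selected_features"] == table["n_selected_features"].max()
        assert weakest["n_selected_features"] >= 2


def test_confusion_metrics_match_hand_computation():
    C = np.array([[10, 0, 0], [1, 8, 1], [0, 2, 8]])
    precision, recall, f1 = metrics_from_confusion(C)
    assert precision["N"] == pytest.approx(10 / 11)
    assert recall["N"] == pytest.approx(1.0)
    assert precision["M"] == pytest.approx(8 / 10)
    assert recall["M"] == pytest.approx(8 / 10)
    assert f1["M"] == pytest.approx(0.8)
    assert precision["P"] == pytest.approx(8 / 9)
    assert recall["P"] == pytest.approx(0.8)
    assert f1["P"] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))
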