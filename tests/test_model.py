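"""Linear discriminant: OLS, stepwise selection, calibration, prediction."""

import numpy as np
import pytest

import statsmodels.api as sm

from skinsens import (
    PUBLISHED_MODEL,
    calibrate_intercept,
    calibrated_published_model,
    classify,
    denormalize,
    evaluate_accuracy,
    fit_full_linear,
    homo_threshold,
    predict_score,
    stepwise_fit,
)
from skinsens.descriptors import NormalizationParams, minmax_apply, minmax_fit
from skinsens.errors import (
    CalibrationError,
    LengthMismatchError,
    SingularDesignError,
    SkinsensError,
)
from skinsens.model import model_from_json, model_to_json
from skinsens.simulate import default_config, simulate_dataset


def _design_from_table(table, names):
    params = minmax_fit(table, names=list(names))
    X = np.column_stack(
        [
            minmax_apply(params, n, [getattr(r.descriptors, n) for r in table])
            for n in names
        ]
    )
    y = np.array([1.0 if r.label == "sensitizer" else 0.0 for r in table])
    return X, y, params


class TestFullLinearFit:
    def test_label_column_gives_perfect_fit(self):
        rng = np.random.default_rng(0)
        y = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        X = np.column_stack([y, rng.normal(size=6)])
        coefs, intercept = fit_full_linear(X, y)
        assert coefs[0] == pytest.approx(1.0, abs=1e-10)
        assert coefs[1] == pytest.approx(0.0, abs=1e-10)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(SkinsensError, match="labels"):
            fit_full_linear(np.arange(8.0).reshape(4, 2), np.ones(4))

    def test_singular_design_rejected(self):
        X = np.ones((6, 1))  # constant column duplicates the intercept
        with pytest.raises(SingularDesignError):
            fit_full_linear(X, np.array([0, 1, 0, 1, 1, 0.0]))

    def test_matches_oracle_on_reference_training_rows(self, table1):
        """Raw-unit univariate refit agrees with an independent OLS oracle.

        The refit slope lands near 16, not at the published 15.30 — the
        published coefficients are a fixed reference artifact, not a refit
        target.
        """
        train = table1.subset("train")
        X = np.array([[r.epsilon_homo] for r in train])
        y = np.array([1.0 if r.label == "sensitizer" else 0.0 for r in train])
        coefs, intercept = fit_full_linear(X, y)
        oracle = sm.OLS(y, sm.add_constant(X)).fit()
        assert intercept == pytest.approx(oracle.params[0], abs=1e-8)
        assert coefs[0] == pytest.approx(oracle.params[1], abs=1e-8)
        assert 14 < coefs[0] < 19
        assert coefs[0] != pytest.approx(15.30, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_problems(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 6))
        n = int(rng.integers(p + 4, 11) if p + 4 < 11 else p + 5)
        X = rng.normal(size=(n, p))
        y = rng.permutation((np.arange(n) % 2).astype(float))
        coefs, intercept = fit_full_linear(X, y)
        oracle = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(coefs, oracle.params[1:], atol=1e-8)
        assert intercept == pytest.approx(oracle.params[0], abs=1e-8)


class TestStepwise:
    def test_single_descriptor_passthrough(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0.0, 1.0], 10)
        X = (y + rng.normal(0, 0.1, 20)).reshape(-1, 1)
        report = stepwise_fit(X, y, ["epsilon_homo"])
        assert report.selected_descriptors == ("epsilon_homo",)
        coefs, intercept = fit_full_linear(X, y)
        assert report.coefficients[0] == pytest.approx(coefs[0])
        assert report.intercept == pytest.approx(intercept)

    def test_synthetic_noise_descriptors_abandoned(self):
        table = simulate_dataset(default_config(100, 100, seed=1))
        names = [
            "epsilon_homo",
            "epsilon_lumo",
            "epsilon_homo_minus1",
            "epsilon_lumo_plus1",
            "q_min",
            "q_max",
            "q_hetero",
            "q_mean_abs",
            "dipole",
        ]
        X, y, _ = _design_from_table(table, names)
        report = stepwise_fit(X, y, names)
        assert report.selected_descriptors == ("epsilon_homo",)
        assert set(report.abandoned) | set(report.selected_descriptors) == set(names)

    def test_duplicate_informative_column_first_wins(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0.0, 1.0], 15)
        x = y + rng.normal(0, 0.1, 30)
        X = np.column_stack([x, x])
        report = stepwise_fit(X, y, ["a", "b"])
        assert report.selected_descriptors == ("a",)
        assert "b" in report.abandoned

    def test_keep_rule_validated(self):
        with pytest.raises(SkinsensError):
            stepwise_fit(np.ones((4, 1)), [0, 1, 0, 1], ["x"], keep_rule=1.5)


class TestDenormalize:
    def test_recovers_published_slope_geometry(self):
        params = NormalizationParams({"epsilon_homo": (-0.343, -0.258)}, fitted=True)
        model = denormalize([15.30 * 0.085], 0.0, params, ["epsilon_homo"])
        assert model.slopes[0] == pytest.approx(15.30)

    def test_identity_normalization_is_noop(self):
        params = NormalizationParams({"x": (0.0, 1.0)}, fitted=True)
        model = denormalize([2.5], 0.7, params, ["x"])
        assert model.slopes[0] == pytest.approx(2.5)
        assert model.intercept == pytest.approx(0.7)

    def test_predictions_equivalent_before_and_after(self):
        rng = np.random.default_rng(3)
        params = NormalizationParams(
            {"epsilon_homo": (-0.343, -0.258), "dipole": (0.5, 4.2)}, fitted=True
        )
        names = ["epsilon_homo", "dipole"]
        coefs, intercept = [1.3, -0.4], 0.2
        model = denormalize(coefs, intercept, params, names)
        for _ in range(100):
            raw = {
                "epsilon_homo": rng.uniform(-0.4, -0.2),
                "dipole": rng.uniform(0, 5),
            }
            norm_p = intercept + sum(
                c * minmax_apply(params, n, raw[n]) for c, n in zip(coefs, names)
            )
            assert predict_score(model, raw) == pytest.approx(norm_p, abs=1e-10)


class TestPublishedModel:
    def test_calibrated_intercept_reproduces_printed_scores(self, table1, calibrated_model):
        for rec in table1:
            p = predict_score(calibrated_model, rec.epsilon_homo)
            assert p == pytest.approx(rec.p_published, abs=5e-5), rec.name

    def test_two_anchor_rows_agree(self):
        m1 = calibrate_intercept(PUBLISHED_MODEL, [(-0.243, 1.3601)])
        m2 = calibrate_intercept(PUBLISHED_MODEL, [(-0.371, -0.5983)])
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)

    def test_perturbed_anchor_is_inconsistent(self):
        with pytest.raises(CalibrationError):
            calibrate_intercept(
                PUBLISHED_MODEL, [(-0.243, 1.3601), (-0.371, -0.5983 + 0.01)]
            )

    @pytest.mark.parametrize(
        "eps,expected",
        [(-0.262, 1.0694), (-0.362, -0.4606)],
    )
    def test_score_examples(self, calibrated_model, eps, expected):
        assert predict_score(calibrated_model, eps) == pytest.approx(expected, abs=5e-5)

    def test_inversion_identity(self, calibrated_model):
        eps = (0.5 - calibrated_model.intercept) / calibrated_model.slopes[0]
        assert predict_score(calibrated_model, eps) == pytest.approx(0.5)

    def test_published_model_is_frozen(self):
        with pytest.raises(Exception):
            PUBLISHED_MODEL.intercept = 0.0


class TestClassification:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.7022, "sensitizer"),
            (-0.1699, "non-sensitizer"),
            (0.50, "non-sensitizer"),  # strict inequality at the threshold
        ],
    )
    def test_threshold_rule(self, p, expected):
        assert classify(p) == expected

    def test_homo_threshold_printed_arithmetic(self):
        assert homo_threshold(PUBLISHED_MODEL) == pytest.approx(-0.299, abs=5e-4)

    def test_homo_threshold_calibrated_within_tolerance(self, calibrated_model):
        assert homo_threshold(calibrated_model) == pytest.approx(-0.299, abs=1e-3)

    def test_homo_threshold_trivial_model(self):
        from skinsens.model import LinearSensitizerModel

        m = LinearSensitizerModel(("epsilon_homo",), (1.0,), 0.5)
        assert homo_threshold(m) == pytest.approx(0.0)

    def test_monotone_and_equivalent_to_homo_rule(self, calibrated_model):
        grid = np.linspace(-0.5, -0.1, 1000)
        scores = np.array([predict_score(calibrated_model, e) for e in grid])
        assert np.all(np.diff(scores) > 0)
        thr = homo_threshold(calibrated_model)
        for e, p in zip(grid, scores):
            assert (p > 0.5) == (e > thr)


class TestEvaluate:
    def test_reference_table_fully_correct(self, table1, calibrated_model):
        preds = [
            classify(predict_score(calibrated_model, r.epsilon_homo)) for r in table1
        ]
        rep = evaluate_accuracy(preds, [r.label for r in table1], [r.split for r in table1])
        assert (rep.correct, rep.total) == (30, 30)
        assert rep.percent == pytest.approx(100.0)
        assert (rep.per_split["train"].correct, rep.per_split["train"].total) == (15, 15)
        assert (rep.per_split["test"].correct, rep.per_split["test"].total) == (15, 15)

    def test_inverted_predictions_score_zero(self, table1, calibrated_model):
        flip = {"sensitizer": "non-sensitizer", "non-sensitizer": "sensitizer"}
        preds = [
            flip[classify(predict_score(calibrated_model, r.epsilon_homo))]
            for r in table1
        ]
        rep = evaluate_accuracy(preds, [r.label for r in table1])
        assert rep.correct == 0

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            evaluate_accuracy(["sensitizer"], [])


class TestSerialization:
    def test_model_json_round_trip(self, calibrated_model):
        assert model_from_json(model_to_json(calibrated_model)) == calibrated_model
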