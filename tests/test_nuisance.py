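"""Parametric nuisance fits and the stacking ensemble."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from attmatch import (
    EnsembleSpec,
    StudyData,
    fit_ensemble,
    fit_outcome_parametric,
    fit_propensity_parametric,
    generate_dataset,
    stack_weights,
)
from attmatch.nuisance import DEFAULT_PS_BOUNDS, _loss_value
from attmatch.synthetic import ScenarioSpec


def _binary_study(n=10_000, p_by_x=(0.25, 0.75), seed=0):
    """One binary covariate; P(A=1 | X=0) and P(A=1 | X=1) set by construction."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    a = (rng.uniform(size=n) < np.where(x == 1, p_by_x[1], p_by_x[0])).astype(int)
    y = rng.normal(size=n)
    return StudyData(covariates=pd.DataFrame({"X": x.astype(float)}), treatment=a, outcome=y)


class TestPropensityParametric:
    def test_null_model_recovers_treated_fraction(self):
        rng = np.random.default_rng(1)
        n = 10_000
        x = rng.normal(size=n)
        a = (rng.uniform(size=n) < 0.4).astype(int)
        data = StudyData(pd.DataFrame({"X": x}), a, rng.normal(size=n))
        fit = fit_propensity_parametric(data)
        slope, slope_se = fit.params[1], fit.bse[1]
        assert abs(slope) < 3 * slope_se
        assert np.allclose(fit.fitted_ps, a.mean(), atol=0.02)

    def test_saturated_binary_covariate_matches_cell_proportions(self):
        data = _binary_study(n=40_000, p_by_x=(0.25, 0.75), seed=2)
        fit = fit_propensity_parametric(data)
        x = data.covariates["X"].to_numpy()
        for val in (0, 1):
            cell = data.treatment[x == val].mean()
            assert fit.fitted_ps[x == val][0] == pytest.approx(cell, abs=1e-6)

    def test_misspecification_under_square_term(self, good_spec):
        """Main-terms logistic cannot capture the true W1^2 dependence."""
        data = generate_dataset(good_spec, n=50_000, seed=3)
        fit = fit_propensity_parametric(data)
        mae = np.mean(np.abs(fit.fitted_ps - data.true_propensity))
        assert mae > 0.005

    def test_truncation_bounds_respected(self, poor_spec):
        data = generate_dataset(poor_spec, n=2000, seed=4)
        fit = fit_propensity_parametric(data)
        assert fit.fitted_ps.min() >= DEFAULT_PS_BOUNDS[0]
        assert fit.fitted_ps.max() <= DEFAULT_PS_BOUNDS[1]

    def test_weight_rescale_invariance(self, good_data):
        w = np.random.default_rng(5).uniform(0.5, 2.0, size=good_data.n)
        f1 = fit_propensity_parametric(good_data, weights=w)
        f2 = fit_propensity_parametric(good_data, weights=17.3 * w)
        assert np.allclose(f1.fitted_ps, f2.fitted_ps, atol=1e-10)


class TestOutcomeParametric:
    def test_exact_linear_truth_recovered(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.normal(size=n)
        a = rng.integers(0, 2, size=n)
        a[:2] = [0, 1]
        y = 3.0 + 2.0 * a + 1.0 * x
        data = StudyData(pd.DataFrame({"X": x}), a, y)
        fit = fit_outcome_parametric(data)
        assert np.allclose(fit.predict(data.X, data.treatment), y, atol=1e-9)
        assert fit.params[1] == pytest.approx(2.0, abs=1e-9)

    def test_weight_doubling_equals_row_duplication(self):
        rng = np.random.default_rng(7)
        n = 60
        x = rng.normal(size=n)
        a = rng.integers(0, 2, size=n)
        a[:2] = [0, 1]
        y = 1 + a + x + rng.normal(size=n)
        data = StudyData(pd.DataFrame({"X": x}), a, y)
        w = np.ones(n)
        w[5] = 2.0
        fit_w = fit_outcome_parametric(data, weights=w)
        dup = StudyData(
            pd.DataFrame({"X": np.append(x, x[5])}),
            np.append(a, a[5]),
            np.append(y, y[5]),
        )
        fit_d = fit_outcome_parametric(dup)
        assert np.allclose(fit_w.params, fit_d.params, atol=1e-9)

    def test_interaction_truth_gives_constant_predicted_effect(self):
        """A main-terms fit flattens any A*X interaction in the truth."""
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.uniform(size=n)
        a = rng.integers(0, 2, size=n)
        y = x + a * (1.0 + 3.0 * x)
        data = StudyData(pd.DataFrame({"X": x}), a, y)
        fit = fit_outcome_parametric(data)
        effect = fit.predict(data.X, 1) - fit.predict(data.X, 0)
        assert np.ptp(effect) < 1e-9  # constant in X by construction

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(9)
        n = 50
        x = rng.normal(size=n)
        a = rng.integers(0, 2, size=n)
        a[:2] = [0, 1]
        data = StudyData(pd.DataFrame({"X": x, "X2": 2 * x}), a, rng.normal(size=n))
        with pytest.raises(ValueError, match="X"):
            fit_outcome_parametric(data)


class TestStackWeights:
    def test_exact_column_gets_weight_one(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=40)
        P = np.column_stack([y, rng.normal(size=40)])
        b = stack_weights(P, y)
        assert b[0] == pytest.approx(1.0, abs=1e-6)
        assert b.sum() == pytest.approx(1.0)

    def test_identical_columns_split_equally(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        col = y + rng.normal(scale=0.1, size=30)
        P = np.column_stack([col, col])
        b = stack_weights(P, y)
        assert b[0] == pytest.approx(b[1], abs=1e-12)
        assert b.sum() == pytest.approx(1.0)

    def test_beats_grid_search_oracle(self):
        """Simplex optimum verified against a 0.01-step grid over 3 columns."""
        rng = np.random.default_rng(12)
        n = 50
        y = rng.normal(size=n)
        P = rng.normal(size=(n, 3))
        w = rng.uniform(0.5, 1.5, size=n)
        b = stack_weights(P, y, weights=w, loss="squared_error")
        best = np.inf
        steps = np.arange(0, 101) / 100
        for b1 in steps:
            for b2 in np.arange(0, 101 - round(100 * b1)) / 100:
                cand = np.array([b1, b2, 1 - b1 - b2])
                best = min(best, _loss_value(P @ cand, y, w, "squared_error"))
        got = _loss_value(P @ b, y, w, "squared_error")
        assert got <= best + 1e-8

    def test_log_loss_supported(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, size=80).astype(float)
        P = np.clip(np.column_stack([y * 0.8 + 0.1, rng.uniform(size=80)]), 0.01, 0.99)
        b = stack_weights(P, y, loss="log_loss")
        assert b[0] > 0.9

    def test_non_finite_predictions_error(self):
        with pytest.raises(ValueError):
            stack_weights(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]))


class TestEnsemble:
    SPEC = EnsembleSpec(learners=("glm", "glm_interactions", "knn"), folds=5, seed=3)

    def test_single_learner_gets_weight_one(self, good_data):
        fit = fit_ensemble(good_data, "outcome", spec=EnsembleSpec(("glm",), folds=5, seed=1))
        assert fit.stack["weights"]["glm"] == pytest.approx(1.0)
        direct = fit_outcome_parametric(good_data)
        assert np.allclose(fit.fitted, direct.fitted, atol=1e-8)

    def test_true_model_learner_dominates_noise_learner(self):
        """CV risk separates the correctly specified learner from kNN noise."""
        spec = ScenarioSpec(
            name="good",
            treat_coefs=(0, 1, 0.2, 0.5, 0.0),
            out_coefs=(1, 2, 1, 0.7, 1),
            effect_coefs=(2, 1),
            noise_sd=0.3,
        )
        data = generate_dataset(spec, n=5000, seed=14)
        fit = fit_ensemble(
            data, "outcome", spec=EnsembleSpec(("glm_interactions", "knn"), folds=5, seed=2)
        )
        assert fit.stack["weights"]["glm_interactions"] > 0.9

    def test_oracle_inequality(self, good_data):
        fit = fit_ensemble(good_data, "treatment", spec=self.SPEC)
        risks = fit.stack["cv_risks"]
        assert fit.stack["ensemble_cv_risk"] <= min(risks.values()) + 1e-8

    def test_propensity_truncation(self, poor_spec):
        data = generate_dataset(poor_spec, n=600, seed=15)
        fit = fit_ensemble(data, "treatment", spec=self.SPEC)
        assert fit.fitted_ps.min() >= DEFAULT_PS_BOUNDS[0]
        assert fit.fitted_ps.max() <= DEFAULT_PS_BOUNDS[1]

    def test_seeded_determinism(self, good_data):
        f1 = fit_ensemble(good_data, "outcome", spec=self.SPEC)
        f2 = fit_ensemble(good_data, "outcome", spec=self.SPEC)
        assert np.array_equal(f1.fitted, f2.fitted)

    def test_minimum_sample_size_enforced(self, good_spec):
        data = generate_dataset(good_spec, n=20, seed=16)
        with pytest.raises(ValueError, match="n >="):
            fit_ensemble(data, "treatment", spec=EnsembleSpec(("glm",), folds=10, seed=0))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(min_value=0.01, max_value=100.0))
def test_stack_weights_scale_invariant_in_observation_weights(scale):
    rng = np.random.default_rng(17)
    y = rng.normal(size=30)
    P = rng.normal(size=(30, 2))
    w = rng.uniform(0.1, 1.0, size=30)
    b1 = stack_weights(P, y, weights=w)
    b2 = stack_weights(P, y, weights=scale * w)
    assert np.allclose(b1, b2, atol=1e-8)
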