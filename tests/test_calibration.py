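"""Error model, weighted least squares, multi-start fitting, profiles,
and phospho-degree anchoring."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from eposignal.calibration import (
    ExperimentDataset,
    anchor_scalings,
    fit_multistart,
    objective,
    parse_perturbation_id,
    perturbation_id,
    profile_likelihood,
    sigma_error_model,
)
from eposignal.network import Perturbation, simulate


class TestSigmaErrorModel:
    @pytest.mark.parametrize("y, y_max, expected", [
        (50.0, 100.0, 10.0),   # 5 relative + 5 absolute
        (0.0, 100.0, 5.0),     # absolute floor at zero signal
        (80.0, 80.0, 12.0),    # 0.15 * value at the condition maximum
    ])
    def test_formula(self, y, y_max, expected):
        assert sigma_error_model(y, y_max) == pytest.approx(expected)

    @given(st.floats(0, 1e3), st.floats(0, 1e3), st.floats(1e-6, 1e3))
    def test_monotone_in_both_arguments(self, y1, y2, extra):
        y_lo, y_hi = sorted([y1, y2])
        y_max = y_hi + extra
        assert sigma_error_model(y_lo, y_max) <= sigma_error_model(y_hi, y_max)
        assert sigma_error_model(y_lo, y_max) <= sigma_error_model(
            y_lo, y_max + extra)

    def test_silent_condition_rejected(self):
        with pytest.raises(ValueError):
            sigma_error_model(0.0, 0.0)


class TestObjective:
    def test_noiseless_self_consistency(self):
        theta0 = np.array([2.0, 0.5])
        t = np.linspace(0, 10, 12)
        predict = lambda th: th[0] * np.exp(-th[1] * t)
        y = predict(theta0)
        sigma = 0.1 * np.abs(y) + 0.05 * y.max()
        assert objective(predict, (y, sigma), theta0) < 1e-8

    def test_discriminates_perturbed_parameter(self):
        theta0 = np.array([2.0, 0.5])
        t = np.linspace(0, 10, 12)
        predict = lambda th: th[0] * np.exp(-th[1] * t)
        y = predict(theta0)
        sigma = np.full_like(y, 0.05)
        assert objective(predict, (y, sigma), theta0 * [1.1, 1.0]) > 0

    def test_known_residual_sum(self):
        # residuals of exactly 1 sigma and 2 sigma -> chi^2 = 1 + 4 = 5
        y = np.array([1.0, 2.0])
        sigma = np.array([0.5, 0.25])
        predict = lambda th: y - np.array([1 * 0.5, 2 * 0.25])
        assert objective(predict, (y, sigma), np.array([0.0])) == pytest.approx(5.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(1, 5, 20)
        sigma = rng.uniform(0.1, 0.5, 20)
        yhat = y + rng.normal(0, 0.2, 20)
        perm = rng.permutation(20)
        a = objective(lambda th: yhat, (y, sigma), np.array([1.0]))
        b = objective(lambda th: yhat[perm], (y[perm], sigma[perm]),
                      np.array([1.0]))
        assert a == pytest.approx(b)


class TestFitMultistart:
    def _toy(self):
        t = np.linspace(0, 10, 25)
        predict = lambda th: th[0] * np.exp(-th[1] * t)
        theta0 = np.array([2.0, 0.3])
        y = predict(theta0)
        sigma = np.full_like(y, 0.05)
        return predict, y, sigma, theta0

    def test_same_seed_bit_identical(self):
        predict, y, sigma, _ = self._toy()
        f1 = fit_multistart(predict, (y, sigma), 8, (-2, 1), seed=5,
                            parameter_names=["a", "k"])
        f2 = fit_multistart(predict, (y, sigma), 8, (-2, 1), seed=5,
                            parameter_names=["a", "k"])
        assert np.array_equal(f1.theta_hat, f2.theta_hat)
        assert f1.objective == f2.objective

    def test_recovers_global_optimum_vs_grid_oracle(self):
        """Dense grid search locates the optimum independently."""
        predict, y, sigma, theta0 = self._toy()
        grid_a = np.logspace(-1, 1, 120)
        grid_k = np.logspace(-2, 0.5, 120)
        best = min(
            ((objective(predict, (y, sigma), np.array([a, k])), a, k)
             for a in grid_a for k in grid_k))
        fit = fit_multistart(predict, (y, sigma), 50, (-2, 1), seed=2,
                             parameter_names=["a", "k"])
        assert fit.theta_hat[0] == pytest.approx(best[1], rel=0.02)
        assert fit.theta_hat[1] == pytest.approx(best[2], rel=0.02)
        assert fit.objective <= best[0] + 1e-9

    def test_more_starts_never_worse(self):
        predict, y, sigma, _ = self._toy()
        objs = [fit_multistart(predict, (y, sigma), n, (-2, 1), seed=7,
                               parameter_names=["a", "k"]).objective
                for n in (2, 5, 10)]
        assert objs[0] >= objs[1] >= objs[2] - 1e-12

    def test_infinite_bounds_rejected(self):
        predict, y, sigma, _ = self._toy()
        with pytest.raises(ValueError):
            fit_multistart(predict, (y, sigma), 3, (-np.inf, 1),
                           parameter_names=["a", "k"])


class TestProfileLikelihood:
    def test_profile_minimum_equals_fit_minimum(self):
        t = np.linspace(0, 10, 25)
        predict = lambda th: th[0] * np.exp(-th[1] * t)
        y = predict(np.array([2.0, 0.3]))
        sigma = np.full_like(y, 0.05)
        fit = fit_multistart(predict, (y, sigma), 10, (-2, 1), seed=1,
                             parameter_names=["a", "k"])
        for p in ("a", "k"):
            prof = profile_likelihood(fit, predict, (y, sigma), p)
            assert prof.profile.min() == pytest.approx(fit.objective,
                                                       rel=1e-6, abs=1e-9)
            assert prof.contains(fit.theta_dict[p])

    def test_exponential_decay_matches_fisher_interval(self):
        """PL interval vs the analytic curvature (Fisher) interval."""
        k_true, sigma0, n = 0.30, 0.02, 50
        t = np.linspace(0.1, 12, n)
        predict = lambda th: np.exp(-th[0] * t)
        rng = np.random.default_rng(11)
        y = predict([k_true]) + rng.normal(0, sigma0, n)
        sigma = np.full(n, sigma0)
        fit = fit_multistart(predict, (y, sigma), 8, (-2, 1), seed=3,
                             parameter_names=["k"])
        k_hat = fit.theta_hat[0]
        # Fisher: var(k) = sigma^2 / sum (t e^{-k t})^2
        se = sigma0 / np.sqrt(np.sum((t * np.exp(-k_hat * t)) ** 2))
        grid = k_hat + np.linspace(-4, 4, 81) * se
        prof = profile_likelihood(fit, predict, (y, sigma), "k",
                                  grid=grid[grid > 0])
        pl_halfwidth = (prof.ci_upper - prof.ci_lower) / 2
        assert pl_halfwidth == pytest.approx(1.959964 * se, rel=0.05)

    def test_product_degenerate_pair_has_open_profile(self):
        """Only k1*k2 is identified: flat profile, open CI both sides."""
        t = np.linspace(0, 10, 20)
        predict = lambda th: th[0] * th[1] * t
        y = predict([0.5, 0.4])
        sigma = np.full_like(y, 0.05)
        fit = fit_multistart(predict, (y, sigma), 10, (-2, 1), seed=9,
                             parameter_names=["k1", "k2"])
        prof = profile_likelihood(fit, predict, (y, sigma), "k1",
                                  span_log10=1.0, n_points=9)
        assert prof.lower_open and prof.upper_open
        spread = prof.profile.max() - prof.profile.min()
        assert spread < 1e-3


class TestAnchorScalings:
    def test_pakt_anchor_in_nanomolar(self, truth, t_grid):
        """54% of 407 nM AKT at (2.5 U/ml, 10 min) -> 219.78 nM."""
        inst = truth.instance("mCFU-E")
        grid = np.unique(np.concatenate([t_grid, [10.0]]))
        traj = simulate(inst, 2.5, grid)
        got = traj.observables["pAKT"][np.searchsorted(grid, 10.0)]
        assert got == pytest.approx(0.54 * 407.0, rel=1e-6)

    def test_pperk_anchor_in_nanomolar(self, truth):
        """Max scaled ppERK in the anchored context = 10% of 1140 nM."""
        t = np.linspace(0.0, 60.0, 121)
        traj = simulate(truth.instance("mCFU-E"), 50.0, t)
        assert traj.observables["ppERK"].max() == pytest.approx(114.0, rel=1e-6)

    def test_identity_anchoring(self, full_model, contexts):
        """fraction = 1 makes the scale equal total / raw maximum."""
        from eposignal.calibration import Anchor
        from eposignal.network import apply_cell_context
        inst = apply_cell_context(full_model, contexts["mCFU-E"])
        t = np.linspace(0.0, 60.0, 61)
        scales = anchor_scalings(
            {"mCFU-E": inst},
            anchors=(Anchor("pEpoR", "mCFU-E", 1.0, "EpoR", 50.0, None),),
            t_grid=t)
        raw_max = simulate(inst, 50.0, t).observables["pEpoR"].max()
        assert scales["pEpoR"] == pytest.approx(4.16 / raw_max)

    def test_missing_context_is_configuration_error(self, full_model):
        with pytest.raises(ValueError, match="mCFU-E"):
            anchor_scalings({})


class TestPerturbationIds:
    def test_round_trip(self):
        perts = [Perturbation("inhibitor", "U0126", 0.5),
                 Perturbation("overexpression", "PTEN", 4.0)]
        assert parse_perturbation_id(perturbation_id(perts)) == perts

    def test_none(self):
        assert perturbation_id([]) == "none"
        assert parse_perturbation_id("none") == []


class TestExperimentDataset:
    def test_sigma_assignment_per_condition_group(self):
        import pandas as pd
        df = pd.DataFrame(dict(
            context=["c"] * 4, epo_Uml=[5.0] * 4,
            perturbation_id=["none"] * 4, time_min=[0, 10, 30, 60],
            observable=["pAKT"] * 4, value_nM=[0.0, 50.0, 100.0, 25.0],
            sigma_nM=np.nan))
        out = ExperimentDataset.assign_sigmas(df)
        assert out["sigma_nM"].tolist() == [5.0, 10.0, 15.0, 7.5]

    def test_single_time_point_condition_rejected(self):
        import pandas as pd
        df = pd.DataFrame(dict(
            context=["c"], epo_Uml=[5.0], perturbation_id=["none"],
            time_min=[10.0], observable=["pAKT"], value_nM=[1.0],
            sigma_nM=[0.1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            ExperimentDataset(df)
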