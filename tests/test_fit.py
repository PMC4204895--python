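"""The SSIO loop: weight initialization, kinetics fitting, weight updates,
the effective-parameter BIC and the full iteration."""

import math

import numpy as np
import pytest

from ssio import (
    ExpressionSeries,
    FitConfig,
    GeneKinetics,
    KeyMismatchError,
    Regulation,
    RegulatoryNetwork,
    SignalSchedule,
    WeightVector,
    bic_score,
    effective_parameters,
    fit_kinetics,
    initialize_kinetics,
    initialize_weights,
    model_residual,
    run_ssio,
    simulate,
    update_weights,
)
from ssio.ode import ModelState


def _single_reg_series(sign=+1, n=12):
    """A target driven by one regulator (profile shapes correlated)."""
    t = np.linspace(0.0, 10.0, n)
    x = 50.0 + 40.0 * np.sin(t / 3.0)
    y = 30.0 + sign * 0.5 * (x - x.mean()) + 60.0
    net = RegulatoryNetwork(
        genes=["R", "T"], regulations=[Regulation("R", "T", sign)]
    )
    series = ExpressionSeries(["R", "T"], t, np.vstack([x, y]), floor=0.0)
    return series, net


class TestInitializeWeights:
    @pytest.mark.parametrize("sign", [+1, -1])
    def test_single_regulator_weight_is_unit_with_declared_sign(self, sign):
        series, net = _single_reg_series(sign)
        w = initialize_weights(series, net)
        assert w.entries[("T", "R")] == pytest.approx(float(sign))

    def test_identical_profile_gives_unit_weight_and_tiny_residual(self):
        t = np.linspace(0.0, 10.0, 15)
        x = 100.0 + 50.0 * np.sin(t)
        net = RegulatoryNetwork(
            genes=["R", "T"], regulations=[Regulation("R", "T", +1)]
        )
        series = ExpressionSeries(["R", "T"], t, np.vstack([x, x]), floor=0.0)
        w = initialize_weights(series, net)
        assert w.entries[("T", "R")] == pytest.approx(1.0)

    def test_three_regulator_ranking_recovered(self, rng):
        # target built from three TFs with weights 0.6 > 0.3 > 0.1
        t = np.linspace(0.0, 19.0, 20)
        X = 80.0 + 30.0 * rng.standard_normal((3, 20))
        y = np.array([0.6, 0.3, 0.1]) @ X
        net = RegulatoryNetwork(
            genes=["TF1", "TF2", "TF3", "T"],
            regulations=[Regulation(f"TF{i}", "T", +1) for i in (1, 2, 3)],
        )
        series = ExpressionSeries(
            ["TF1", "TF2", "TF3", "T"], t, np.vstack([X, y]), floor=0.0
        )
        w = initialize_weights(series, net)
        q = [w.entries[("T", f"TF{i}")] for i in (1, 2, 3)]
        assert q[0] > q[1] > q[2] > 0

    def test_frozen_source_weight_zero(self):
        series, net = _single_reg_series(+1)
        net.zero_weight_sources = {"R"}
        w = initialize_weights(series, net)
        assert w.entries[("T", "R")] == 0.0


class TestFitKinetics:
    def test_constitutive_decay_recovered_within_five_percent(self):
        true = GeneKinetics(k1=4.0, k2=1.0, k3=1.0, d=0.5)
        net = RegulatoryNetwork(genes=["G"], regulations=[])
        t = np.linspace(0.0, 10.0, 30)
        traj = simulate(
            ModelState(0.0, [0.2]), t, net, WeightVector({}), {"G": true}
        )
        series = ExpressionSeries(["G"], t, traj.T, floor=0.0)
        init = {"G": GeneKinetics(k1=3.0, k2=1.5, k3=1.0, d=0.25)}
        cfg = FitConfig()
        out = fit_kinetics(series, net, WeightVector({}), init, cfg)
        assert out["G"].d == pytest.approx(true.d, rel=0.05)
        # the identifiable basal rate k1/(1+k2) is matched too
        basal = out["G"].k1 / (1 + out["G"].k2)
        assert basal == pytest.approx(2.0, rel=0.05)

    def test_perfect_initialization_is_a_fixed_point(self, cascade3):
        rc = cascade3
        out = fit_kinetics(
            rc.series, rc.network, rc.weights, rc.kinetics, FitConfig()
        )
        for g in rc.network.genes:
            true = rc.kinetics[g]
            # parameters barely move and the shooting objective stays tiny
            assert out[g].d == pytest.approx(true.d, rel=0.02)
        err2, _, _ = model_residual(
            rc.series, rc.network, rc.weights, out
        )
        assert err2 < 1e-3

    def test_two_point_series_matches_grid_search_in_decay(self):
        # one gene, two timepoints: the shooting error profile over d must
        # have its least-squares minimizer where a dense grid search puts it
        net = RegulatoryNetwork(genes=["G"], regulations=[])
        t = np.array([0.0, 1.0])
        series = ExpressionSeries(["G"], t, [[3.0, 2.0]], floor=0.0)
        cfg = FitConfig()
        from ssio.fit import _OneStepProblem

        problem = _OneStepProblem(series, net, SignalSchedule.silent([]), cfg.substeps)

        def sq_err(d):
            r = problem.residuals("G", np.array([4.0, 1.0, 1.0, d]), np.zeros(0))
            return float(r @ r)

        grid = np.linspace(0.05, 4.9, 3000)
        d_grid = grid[np.argmin([sq_err(d) for d in grid])]
        from scipy.optimize import minimize_scalar

        d_opt = minimize_scalar(sq_err, bounds=(0.05, 4.9), method="bounded").x
        assert d_opt == pytest.approx(d_grid, abs=2e-3)


class TestUpdateWeights:
    def test_zero_scalar_leaves_weights_unchanged(self, cascade3):
        rc = cascade3
        w = update_weights(
            rc.series, rc.network, rc.weights, rc.kinetics,
            FitConfig(enforce_signs=False), forced_scalar=0.0,
        )
        for k, v in rc.weights.entries.items():
            assert w.entries[k] == pytest.approx(v)

    def test_single_tf_step_never_worse_than_standing_still(self):
        series, net = _single_reg_series(+1)
        cfg = FitConfig()
        w0 = initialize_weights(series, net, config=cfg)
        kin = initialize_kinetics(series, net, w0, config=cfg)
        kin = fit_kinetics(series, net, w0, kin, cfg)
        before, _, _ = model_residual(series, net, w0, kin, cfg)
        w1 = update_weights(series, net, w0, kin, cfg)
        after, _, _ = model_residual(series, net, w1, kin, cfg)
        assert after <= before + 1e-9

    def test_masked_timepoints_do_not_enter_objective(self, cascade3):
        rc = cascade3
        n_t = rc.series.times.size
        keep = np.ones(n_t, dtype=bool)
        keep[3:6] = False  # mask some interior timepoints for G2
        masks = {"G2": keep}
        cfg = FitConfig()
        _, by_gene, _ = model_residual(
            rc.series, rc.network, rc.weights, rc.kinetics, cfg, masks=masks
        )
        # perturb the masked observations: masked residuals must not change
        series2 = ExpressionSeries(
            list(rc.series.gene_ids),
            rc.series.times,
            rc.series.values.copy(),
            rc.series.floor,
        )
        g2 = series2.gene_index("G2")
        series2.values[g2, 4] *= 3.0  # an interior masked timepoint
        _, by_gene2, _ = model_residual(
            series2, rc.network, rc.weights, rc.kinetics, cfg, masks=masks
        )
        # interval 3 (predicting t[4]) is gone and t[4] only seeds interval 4,
        # which is also masked, so G2's residual is unchanged
        assert by_gene2["G2"] == pytest.approx(by_gene["G2"], rel=1e-12)


class TestScoring:
    def test_unchanged_weights_give_zero_effective_parameters(self):
        w = WeightVector({("a", "b"): 0.4, ("a", "c"): -0.1})
        assert effective_parameters(w, w.copy(), iteration=7) == 0.0

    def test_first_iteration_penalty_free(self):
        w1 = WeightVector({("a", "b"): 0.0})
        w2 = WeightVector({("a", "b"): 5.0})
        assert effective_parameters(w2, w1, iteration=1) == 0.0

    def test_single_weight_change_zero_to_one_at_iteration_three(self):
        w1 = WeightVector({("a", "b"): 0.0})
        w2 = WeightVector({("a", "b"): 1.0})
        expected = (math.pi / 4) * math.log(3)
        assert effective_parameters(w2, w1, 3) == pytest.approx(expected, rel=1e-12)
        assert effective_parameters(w2, w1, 3) == pytest.approx(0.8627, abs=5e-4)

    def test_mismatched_keys_rejected(self):
        with pytest.raises(KeyMismatchError):
            effective_parameters(
                WeightVector({("a", "b"): 0.0}), WeightVector({("a", "c"): 0.0}), 2
            )

    def test_bic_value_and_monotonicity(self):
        assert bic_score(10.0, 2.0, 10) == pytest.approx(2 * math.log(10), rel=1e-12)
        assert bic_score(5.0, 2.0, 10) < bic_score(10.0, 2.0, 10)
        assert bic_score(10.0, 3.0, 10) > bic_score(10.0, 2.0, 10)


class TestRunSSIO:
    def test_noiseless_cascade_recovery(self, cascade3):
        rc = cascade3
        res = run_ssio(rc.series, rc.network, FitConfig(max_iterations=8))
        obs = rc.series.values[:, 1:]
        total_ss = float(np.sum((obs - obs.mean()) ** 2))
        assert res.best.residual_sq < 0.01 * total_ss
        for (tgt, src), q_true in rc.weights.entries.items():
            assert np.sign(res.best.weights.entries[(tgt, src)]) == np.sign(q_true)
        # per-target ranking for the two-regulator target G3
        w = res.best.weights.entries
        assert w[("G3", "G1")] > w[("G3", "G2")]

    def test_single_iteration_history(self, cascade3):
        rc = cascade3
        res = run_ssio(rc.series, rc.network, FitConfig(max_iterations=1))
        assert len(res.history) == 1
        assert res.best is res.history[0]
        assert res.stop_reason == "max_iterations"

    def test_rerun_is_bitwise_identical(self, cascade3):
        rc = cascade3
        cfg = FitConfig(max_iterations=3, seed=5)
        a = run_ssio(rc.series, rc.network, cfg).to_json()
        b = run_ssio(rc.series, rc.network, cfg).to_json()
        assert a == b

    def test_best_bic_is_minimum_of_history(self, cascade3):
        rc = cascade3
        res = run_ssio(rc.series, rc.network, FitConfig(max_iterations=6))
        assert res.best.bic == min(h.bic for h in res.history)
        assert res.best.residual_sq <= res.history[0].residual_sq + 1e-12

    def test_constraints_can_be_disabled_for_overfitting_demo(self, cascade3):
        rc = cascade3
        cfg = FitConfig(
            max_iterations=2, enforce_signs=False, use_component_penalty=False
        )
        res = run_ssio(rc.series, rc.network, cfg)
        assert len(res.history) == 2  # runs without constraint machinery
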