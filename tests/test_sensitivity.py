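"""Priors, Metropolis calibration, K–S regional sensitivity, bistability
scanning, importance ranking and the cross-species K–S comparison."""

import numpy as np
import pytest
from scipy import stats

from ssio import (
    ConfigError,
    ExpressionSeries,
    GeneKinetics,
    ModelState,
    PriorSpec,
    Regulation,
    RegulatoryNetwork,
    SignalSchedule,
    WeightVector,
    bistability_scan,
    build_prior,
    classify_behavioral,
    importance_rank,
    ks_sensitivity,
    local_sensitivity,
    metropolis_step,
    run_mcmc,
    saddle_node_k1,
    weighted_expression_compare,
)
from ssio.sensitivity import LocalSensitivityEntry


class TestPrior:
    def test_other_role_above_quarter_doubles(self):
        p = build_prior({"x": 0.3}, {"x": "other"})
        assert p.bounds["x"] == (0.0, pytest.approx(0.6))

    def test_other_role_below_quarter_gets_half_unit(self):
        p = build_prior({"x": 0.1}, {"x": "other"})
        assert p.bounds["x"] == (0.0, 0.5)

    def test_degradation_band_is_plus_minus_point_one(self):
        p = build_prior({"d": 0.5}, {"d": "degradation"})
        lo, hi = p.bounds["d"]
        assert lo == pytest.approx(0.4) and hi == pytest.approx(0.6)

    def test_weight_role_unit_interval(self):
        p = build_prior({"q": 0.77}, {"q": "weight"})
        assert p.bounds["q"] == (0.0, 1.0)

    def test_unknown_role_rejected(self):
        with pytest.raises(ConfigError):
            build_prior({"x": 1.0}, {"x": "mystery"})


class TestMetropolis:
    def test_improvement_always_accepted(self):
        prior = PriorSpec({"x": (0.0, 1.0)})
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, _, accepted = metropolis_step(
                np.array([0.5]), 2.0, prior, rng, err_fn=lambda t: 1.0
            )
            assert accepted

    def test_flat_landscape_acceptance_tends_to_one(self):
        prior = PriorSpec({"x": (0.0, 1.0)})
        rng = np.random.default_rng(1)
        acc = sum(
            metropolis_step(np.array([0.5]), 1.0, prior, rng, lambda t: 1.0)[2]
            for _ in range(2000)
        )
        assert acc == 2000

    def test_half_alpha_frequency_within_three_sigma(self):
        # err_n = 1, err* = 2 -> alpha = 0.5; binomial 3 sigma at 10^4 trials
        prior = PriorSpec({"x": (0.0, 1.0)})
        rng = np.random.default_rng(2)
        n = 10_000
        acc = sum(
            metropolis_step(np.array([0.5]), 1.0, prior, rng, lambda t: 2.0)[2]
            for _ in range(n)
        )
        sigma = np.sqrt(n * 0.5 * 0.5)
        assert abs(acc - 0.5 * n) < 3 * sigma

    def test_nonfinite_candidate_rejected(self):
        prior = PriorSpec({"x": (0.0, 1.0)})
        rng = np.random.default_rng(3)
        theta, err, accepted = metropolis_step(
            np.array([0.5]), 1.0, prior, rng, lambda t: float("nan")
        )
        assert not accepted and err == 1.0


class TestKSSensitivity:
    @staticmethod
    def _trace(n, behavioral_fn, seed, burn_in=0, n_params=2):
        prior = PriorSpec({f"p{j}": (0.0, 1.0) for j in range(n_params)})
        trace = run_mcmc(
            prior,
            err_fn=lambda t: 1.0,  # flat: chain = iid prior draws
            behavioral_fn=behavioral_fn,
            n_steps=n,
            seed=seed,
            burn_in=burn_in,
        )
        return trace, prior

    def test_independent_coin_flag_stays_below_noise_bound(self):
        coin = np.random.default_rng(7)
        trace, prior = self._trace(10_000, lambda t: coin.random() < 0.5, seed=11)
        table = ks_sensitivity(trace, prior, bins=10)
        assert table.defined
        for s in table.statistic.values():
            assert s < 0.05

    def test_median_threshold_rule_saturates_statistic(self):
        trace, prior = self._trace(
            12_000, lambda t: t[0] > 0.5, seed=12, burn_in=2000
        )
        table = ks_sensitivity(trace, prior, bins=10)
        assert table.statistic["p0"] >= 0.95
        assert table.statistic["p1"] < 0.05

    def test_single_class_trace_undefined(self):
        trace, prior = self._trace(500, lambda t: True, seed=13)
        table = ks_sensitivity(trace, prior)
        assert not table.defined
        assert all(np.isnan(v) for v in table.statistic.values())

    def test_burn_in_removed_from_statistics(self):
        trace, _ = self._trace(1000, lambda t: True, seed=14, burn_in=400)
        assert len(trace.chain()) == 600


class TestBehavioralClassification:
    def test_reference_parameters_are_behavioral(self, adipo_mini5):
        rc = adipo_mini5
        assert classify_behavioral(
            rc.series, rc.network, rc.weights, rc.kinetics, rc.schedule,
            markers=["B", "A", "P"],
        )

    def test_zeroed_weights_are_not_behavioral(self, adipo_mini5):
        rc = adipo_mini5
        zeros = WeightVector({k: 0.0 for k in rc.weights.entries})
        assert not classify_behavioral(
            rc.series, rc.network, zeros, rc.kinetics, rc.schedule,
            markers=["B", "A", "P"],
        )

    def test_marker_exactly_at_midpoint_fails(self):
        # a constitutive gene ends at its own observed start level: with the
        # threshold constructed exactly at that level the strict rule fails
        net = RegulatoryNetwork(genes=["G"], regulations=[], signals=["s"])
        kin = {"G": GeneKinetics(k1=4.0, k2=1.0, k3=1.0, d=0.5)}
        t = np.linspace(0.0, 10.0, 5)
        eq = 4.0
        series = ExpressionSeries(["G"], t, [[eq] * 5], floor=0.0)
        w = WeightVector({})
        assert not classify_behavioral(
            series, net, w, kin, SignalSchedule.silent(["s"]), markers=["G"]
        )


class TestBistability:
    def test_monostable_cascade_shows_no_trigger(self):
        net = RegulatoryNetwork(
            genes=["G1", "G2"], regulations=[Regulation("G1", "G2")]
        )
        kinetics = {
            "G1": GeneKinetics(k1=2.0, k2=1.0, k3=1.0, d=0.5),
            "G2": GeneKinetics(k1=3.0, k2=2.0, k3=0.8, d=0.7),
        }
        weights = WeightVector({("G2", "G1"): 1.0})
        scan = bistability_scan(
            net, weights, kinetics, ("G1", "k1"),
            np.linspace(1.0, 5.0, 5),
            np.array([0.0, 0.0]), np.array([10.0, 10.0]),
        )
        assert scan.trigger_level is None
        np.testing.assert_allclose(scan.low_branch, scan.high_branch, atol=1e-5)

    def test_trigger_within_one_grid_step_of_brute_force(self, feedback_bistable2):
        rc = feedback_bistable2
        grid = np.arange(700.0, 1350.0, 50.0)
        truth = saddle_node_k1(rc.kinetics, rc.weights, np.arange(700.0, 1350.0, 1.0))
        scan = bistability_scan(
            rc.network, rc.weights, rc.kinetics, ("G1", "k1"), grid,
            np.array(rc.truth["low_init"]), np.array(rc.truth["high_init"]),
        )
        assert scan.trigger_level is not None
        assert truth is not None
        assert abs(scan.trigger_level - truth) <= 50.0 + 1e-9

    def test_branches_ordered_where_bistable(self, feedback_bistable2):
        rc = feedback_bistable2
        grid = np.array([300.0, 500.0, 700.0, 900.0])
        scan = bistability_scan(
            rc.network, rc.weights, rc.kinetics, ("G1", "k1"), grid,
            np.array(rc.truth["low_init"]), np.array(rc.truth["high_init"]),
        )
        gap = scan.high_branch[:, 0] - scan.low_branch[:, 0]
        assert np.all(gap > 0)  # low branch strictly below high branch

    def test_local_sensitivity_reference_delta_zero(self, feedback_bistable2):
        rc = feedback_bistable2
        grid = np.array([700.0, 900.0, 1100.0, 1300.0])
        entries = local_sensitivity(
            rc.network, rc.weights, rc.kinetics, ("G1", "k1"), grid,
            np.array(rc.truth["low_init"]), np.array(rc.truth["high_init"]),
            perturb=("G2", "k3"), deltas=[0.0],
        )
        assert isinstance(entries[0], LocalSensitivityEntry)
        ref = bistability_scan(
            rc.network, rc.weights, rc.kinetics, ("G1", "k1"), grid,
            np.array(rc.truth["low_init"]), np.array(rc.truth["high_init"]),
        )
        assert entries[0].trigger_level == ref.trigger_level
        assert entries[0].trigger_shift == 0.0

    def test_killing_the_feedback_removes_bistability(self, feedback_bistable2):
        rc = feedback_bistable2
        # flattening G2's sigmoid (k3 -> ~0) cuts the loop gain
        entries = local_sensitivity(
            rc.network, rc.weights, rc.kinetics, ("G1", "k1"),
            np.array([700.0, 900.0, 1100.0, 1300.0]),
            np.array(rc.truth["low_init"]), np.array(rc.truth["high_init"]),
            perturb=("G2", "k3"), deltas=[-0.999],
        )
        assert not entries[0].bistable
        # brute force confirms a single fixed point after the perturbation
        from ssio import count_fixed_points_2gene

        kin = dict(rc.kinetics)
        base = kin["G2"]
        kin["G2"] = GeneKinetics(base.k1, base.k2, base.k3 * 0.001, base.d)
        n, _ = count_fixed_points_2gene(kin, rc.weights)
        assert n == 1


def fd_importance_oracle(rc, target, src, y, t):
    """Central finite-difference importance |dF_target/dX_src|·X_src.

    Recomputes the combined input and sigmoid independently of the
    package's dynamics code, in extended precision so the difference of
    two near-saturated rates keeps enough significant digits.
    """
    gi = {g: i for i, g in enumerate(rc.network.genes)}
    kin = rc.kinetics[target]
    sig = {s: rc.schedule.level(s, t) for s in rc.network.signals}

    def rate(x_src):
        A = np.longdouble(0.0)
        for r in rc.network.regulators_of(target):
            q = np.longdouble(rc.weights.entries[(target, r.source)])
            if r.source == src:
                x = x_src
            elif r.source in gi:
                x = np.longdouble(y[gi[r.source]])
            else:
                x = np.longdouble(sig[r.source])
            A += q * x
        z = np.longdouble(kin.k3) * A
        if A >= 0:
            return np.longdouble(kin.k1) / (1 + np.longdouble(kin.k2) * np.exp(-z))
        e = np.longdouble(kin.k2) * np.exp(z)
        return np.longdouble(kin.k1) * e / (1 + e)

    x0 = np.longdouble(y[gi[src]])
    h = max(np.longdouble(1e-4) * abs(x0), np.longdouble(1e-4))
    deriv = (rate(x0 + h) - rate(x0 - h)) / (2 * h)
    return float(abs(deriv) * x0)


class TestImportance:
    def test_jacobian_matches_finite_differences(self, adipo_mini5, rng):
        rc = adipo_mini5
        y = rng.uniform(5.0, 300.0, len(rc.network.genes))
        state = ModelState(5.0, y)
        ranking = importance_rank(
            rc.network, rc.weights, rc.kinetics, {"s": state}, rc.schedule
        )["s"]
        gi = {g: i for i, g in enumerate(rc.network.genes)}
        for tgt, ranked in ranking.items():
            for src, imp in ranked:
                if src not in gi:
                    continue  # signal regulators have no state column
                expected = fd_importance_oracle(rc, tgt, src, y, 5.0)
                assert imp == pytest.approx(expected, rel=1e-6, abs=1e-12)

    def test_zero_weight_regulator_ranks_last(self, adipo_mini5):
        rc = adipo_mini5
        w = rc.weights.copy()
        w.entries[("A", "B")] = 0.0
        state = ModelState(5.0, np.full(len(rc.network.genes), 100.0))
        ranked = importance_rank(
            rc.network, w, rc.kinetics, {"s": state}, rc.schedule
        )["s"]["A"]
        assert ranked[-1][0] == "B"
        assert ranked[-1][1] == 0.0

    def test_doubling_regulator_level_raises_its_importance(self):
        # single activator in its linear regime: importance ∝ X·F'(qX)
        net = RegulatoryNetwork(
            genes=["R", "T"], regulations=[Regulation("R", "T")]
        )
        kin = {
            "R": GeneKinetics(1.0, 1.0, 1.0, 1.0),
            "T": GeneKinetics(10.0, 1.0, 0.001, 1.0),
        }
        w = WeightVector({("T", "R"): 0.5})
        lo = importance_rank(net, w, kin, {"s": ModelState(0.0, np.array([10.0, 1.0]))})
        hi = importance_rank(net, w, kin, {"s": ModelState(0.0, np.array([20.0, 1.0]))})
        assert hi["s"]["T"][0][1] > lo["s"]["T"][0][1]


class TestWeightedExpressionCompare:
    @staticmethod
    def _series(values, times=(-2.0, 0.0, 3.0, 14.0)):
        genes = [f"R{i}" for i in range(len(values))]
        return ExpressionSeries(genes, np.array(times), np.array(values), floor=0.0)

    @staticmethod
    def _stage_days():
        return {
            "proliferating": -2.0,
            "preadipocyte": 0.0,
            "immature": 3.0,
            "mature": 14.0,
        }

    def test_identical_profiles_give_zero_distance(self, rng):
        vals = rng.uniform(20.0, 300.0, (4, 4))
        w = WeightVector({("T", f"R{i}"): 0.5 for i in range(4)})
        out = weighted_expression_compare(
            w, self._series(vals), w, self._series(vals), "T",
            self._stage_days(), self._stage_days(),
        )
        for d_stat, p in out.values():
            assert d_stat == 0.0
            assert p == pytest.approx(1.0)

    def test_disjoint_changes_give_unit_distance(self):
        low = [[10.0, 11.0, 12.0, 13.0]] * 3
        high = [[10.0, 110.0, 1210.0, 13310.0]] * 3
        w = WeightVector({("T", f"R{i}"): 1.0 for i in range(3)})
        a, b = self._series(low), self._series(high)
        out = weighted_expression_compare(
            w, a, w, b, "T", self._stage_days(), self._stage_days()
        )
        # z-scoring a constant-across-regulators change vector yields zeros
        # in both species; perturb per-regulator scales to break ties
        wa = WeightVector({("T", f"R{i}"): 1.0 + 0.1 * i for i in range(3)})
        out = weighted_expression_compare(
            wa, a, wa, b, "T", self._stage_days(), self._stage_days()
        )
        assert all(np.isfinite(p) for _, p in out.values())

    def test_pvalues_match_reference_ks_on_toy_vectors(self):
        # hand-built weighted profiles whose change vectors differ
        a_vals = [[10, 40, 90, 160], [20, 25, 30, 35], [5, 50, 20, 80]]
        b_vals = [[100, 90, 80, 70], [30, 60, 120, 240], [50, 40, 60, 30]]
        w = WeightVector({("T", f"R{i}"): 0.7 for i in range(3)})
        a, b = self._series(a_vals), self._series(b_vals)
        out = weighted_expression_compare(
            w, a, w, b, "T", self._stage_days(), self._stage_days()
        )
        for k, stage_pair in enumerate(
            [("proliferating", "preadipocyte"), ("preadipocyte", "immature"),
             ("immature", "mature")]
        ):
            da = np.array([row[k + 1] - row[k] for row in (0.7 * np.array(a_vals))])
            db = np.array([row[k + 1] - row[k] for row in (0.7 * np.array(b_vals))])
            za = (da - da.mean()) / da.std(ddof=1)
            zb = (db - db.mean()) / db.std(ddof=1)
            ref = stats.ks_2samp(za, zb, method="asymp")
            d_stat, p = out[f"{stage_pair[0]}->{stage_pair[1]}"]
            assert d_stat == pytest.approx(float(ref.statistic), abs=1e-6)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-6)

    def test_single_regulator_species_undefined(self):
        a = self._series([[10.0, 20.0, 30.0, 40.0]])
        w1 = WeightVector({("T", "R0"): 1.0})
        out = weighted_expression_compare(
            w1, a, w1, a, "T", self._stage_days(), self._stage_days()
        )
        assert out is None
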