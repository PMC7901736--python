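"""Upper-level game: cost model, analytic equilibria, replicator dynamics."""

import math

import numpy as np
import pytest

from percevolve import (
    CostModel,
    PatchEnvironment,
    RatioEnvironment,
    ThresholdDistribution,
    critical_alpha,
    integrate_replicator,
    perception_cost,
    predict_continuous_environment,
    solve_equilibria_for_distribution,
    solve_lower_equilibrium,
    solve_multi_ratio,
    solve_single_ratio,
    strategy_fitness,
)


def closed_form_single_threshold(alpha):
    """Quadratic oracle for c(d) = 0.5 d with c = alpha/(1+d): d = (sqrt(1+8a)-1)/2."""
    return 0.5 * (math.sqrt(1.0 + 8.0 * alpha) - 1.0)


def staged_quadratic_thresholds(alpha, freqs):
    """Stage-by-stage quadratic oracle for the sequential threshold equations."""
    out, acc = [], 0.0
    for f in freqs:
        # alpha/(1+d) = acc + 0.5 f d  ->  0.5 f d^2 + (0.5 f + acc) d + acc - alpha = 0
        a, b, c = 0.5 * f, 0.5 * f + acc, acc - alpha
        d = (-b + math.sqrt(b * b - 4 * a * c)) / (2 * a)
        out.append(d)
        acc += 0.5 * f * d
    return out


class TestCostModel:
    @pytest.mark.parametrize(
        "tau, alpha, plateau, expected",
        [
            (0.0, 0.5, None, 0.5),
            (math.inf, 0.5, None, 0.0),
            (3.0, 0.5, 1.5, 0.2),
            (1.0, 1.0, None, 0.5),
        ],
    )
    def test_values(self, tau, alpha, plateau, expected):
        assert perception_cost(tau, CostModel(alpha, plateau)) == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            CostModel(0.5)(-0.1)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            CostModel(0.0)

    def test_strictly_decreasing(self):
        c = CostModel(0.7)
        taus = np.linspace(0, 10, 50)
        vals = c(taus)
        assert np.all(np.diff(vals) < 0)


class TestSingleRatio:
    def test_threshold_matches_quadratic_oracle(self):
        for alpha in (0.1, 0.5, 1.0, 1.4):
            sol = solve_single_ratio(5.0, CostModel(alpha))
            assert sol.thresholds[0] == pytest.approx(closed_form_single_threshold(alpha), abs=1e-9)

    def test_alpha_half_reference_value(self):
        sol = solve_single_ratio(5.0, CostModel(0.5))
        assert sol.thresholds[0] == pytest.approx((math.sqrt(5) - 1) / 2, abs=1e-9)
        assert sol.regime == "coexistence"

    def test_identical_patches_support_no_perception(self):
        for alpha in (0.1, 1.0):
            assert solve_single_ratio(1.0, CostModel(alpha)).regime == "all_uninformed"

    def test_high_cost_collapses_to_uninformed(self):
        # required dR* exceeds the even-split maximum 4/3 at alpha = 1.6
        sol = solve_single_ratio(5.0, CostModel(1.6))
        assert sol.regime == "all_uninformed"
        assert sol.occupancy_inf == 1.0

    def test_equal_fitness_of_occupied_strategies(self):
        cost = CostModel(0.5)
        sol = solve_single_ratio(5.0, cost)
        eqs = solve_equilibria_for_distribution(sol.to_distribution(), RatioEnvironment.single(5.0))
        f_informed = strategy_fitness(sol.thresholds[0], eqs, cost)
        f_inf = strategy_fitness(math.inf, eqs, cost)
        assert f_informed == pytest.approx(f_inf, abs=1e-8)

    def test_no_profitable_deviation(self):
        cost = CostModel(0.5)
        sol = solve_single_ratio(5.0, cost)
        eqs = solve_equilibria_for_distribution(sol.to_distribution(), RatioEnvironment.single(5.0))
        f_star = strategy_fitness(sol.thresholds[0], eqs, cost)
        for tau in np.concatenate([np.linspace(0, 5, 201), [math.inf]]):
            assert strategy_fitness(tau, eqs, cost) <= f_star + 1e-9

    def test_just_above_threshold_is_dominated_by_indifference(self):
        cost = CostModel(0.5)
        sol = solve_single_ratio(5.0, cost)
        eqs = solve_equilibria_for_distribution(sol.to_distribution(), RatioEnvironment.single(5.0))
        tau = sol.thresholds[0] + 0.05
        assert strategy_fitness(tau, eqs, cost) < strategy_fitness(math.inf, eqs, cost)

    def test_monotonicity_in_cost(self):
        alphas = np.linspace(0.05, 1.55, 25)
        sols = [solve_single_ratio(5.0, CostModel(a)) for a in alphas]
        infs = [s.occupancy_inf for s in sols]
        thrs = [s.thresholds[0] for s in sols if np.isfinite(s.thresholds[0])]
        assert all(b >= a - 1e-12 for a, b in zip(infs, infs[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(thrs, thrs[1:]))


class TestPlateau:
    def test_plateau_below_threshold_gives_single_strategy(self):
        sol = solve_single_ratio(5.0, CostModel(0.5, tau_plateau=0.5))
        assert sol.regime == "plateau_single"
        assert sol.thresholds[0] == pytest.approx(0.5)
        assert sol.occupancies[0] == pytest.approx(1.0)
        assert sol.occupancy_inf == 0.0

    def test_plateau_above_threshold_preserves_bifurcation(self):
        sol = solve_single_ratio(5.0, CostModel(0.5, tau_plateau=1.5))
        assert sol.regime == "coexistence"
        assert sol.occupancy_inf > 0
        # indifferent agents now pay a residual cost, so the informed
        # strategy settles below the plateau-free threshold
        assert 0 < sol.thresholds[0] < closed_form_single_threshold(0.5)


class TestMultiRatio:
    def test_reduces_to_single_ratio(self):
        env = RatioEnvironment.single(5.0)
        a = solve_multi_ratio(env, CostModel(0.5))
        b = solve_single_ratio(5.0, CostModel(0.5))
        np.testing.assert_allclose(a.thresholds, b.thresholds, atol=1e-9)
        np.testing.assert_allclose(a.occupancies, b.occupancies, atol=1e-9)
        assert a.occupancy_inf == pytest.approx(b.occupancy_inf, abs=1e-9)

    def test_two_ratio_worked_example(self):
        # alpha = 0.5, ratios {2, 10}: staged quadratics give 1 and sqrt(2)-1
        env = RatioEnvironment((10.0, 2.0), (0.5, 0.5))
        sol = solve_multi_ratio(env, CostModel(0.5))
        assert sol.thresholds[0] == pytest.approx(1.0, abs=1e-9)
        assert sol.thresholds[1] == pytest.approx(math.sqrt(2) - 1, abs=1e-9)
        oracle = staged_quadratic_thresholds(0.5, env.freqs)
        np.testing.assert_allclose(sol.thresholds, oracle, atol=1e-9)

    def test_three_subpopulations_coexist(self):
        sol = solve_multi_ratio(RatioEnvironment((10.0, 2.0), (0.5, 0.5)), CostModel(0.5))
        assert sol.regime == "coexistence"
        assert np.all(sol.occupancies > 0)
        assert sol.occupancy_inf > 0

    def test_equal_fitness_across_randomized_environments(self, rng):
        checked = 0
        while checked < 8:
            alpha = rng.uniform(0.2, 1.0)
            r2 = rng.uniform(1.5, 4.0)
            r1 = r2 + rng.uniform(1.0, 8.0)
            f1 = rng.uniform(0.3, 0.7)
            env = RatioEnvironment((r1, r2), (f1, 1 - f1))
            cost = CostModel(alpha)
            sol = solve_multi_ratio(env, cost)
            if sol.regime != "coexistence" or sol.n_dropped:
                continue
            eqs = solve_equilibria_for_distribution(sol.to_distribution(), env)
            fits = [strategy_fitness(t, eqs, cost) for t in sol.occupied_thresholds]
            fits.append(strategy_fitness(math.inf, eqs, cost))
            assert max(fits) - min(fits) < 1e-6
            checked += 1

    def test_highest_sensitivity_independent_of_larger_ratio(self):
        # the most sensitive strategy's threshold and share only depend on
        # the smallest ratio and the cost
        base = solve_multi_ratio(RatioEnvironment((5.0, 2.0), (0.5, 0.5)), CostModel(0.5))
        alt = solve_multi_ratio(RatioEnvironment((10.0, 2.0), (0.5, 0.5)), CostModel(0.5))
        assert base.thresholds[-1] == pytest.approx(alt.thresholds[-1], abs=1e-10)
        assert base.occupancies[-1] == pytest.approx(alt.occupancies[-1], abs=1e-10)

    def test_requires_decreasing_ratios(self):
        with pytest.raises(ValueError):
            RatioEnvironment((2.0, 10.0), (0.5, 0.5))


class TestContinuousEnvironment:
    def test_low_cost_clusters_near_zero(self):
        sol = predict_continuous_environment(0.01)
        occ, shares = sol.occupied_thresholds, sol.occupied_shares
        assert occ.size > 0
        weights = shares / shares.sum()
        assert float(occ @ weights) < 0.05  # informed mass clusters near tau = 0

    def test_high_cost_all_uninformed(self):
        sol = predict_continuous_environment(2.0)
        assert sol.regime == "all_uninformed"

    def test_mean_sensitivity_rises_then_band_collapses(self):
        # mean occupied threshold grows with the cost of perception,
        # until perception dies out entirely
        means = []
        for alpha in (0.01, 0.3, 0.8, 1.1):
            sol = predict_continuous_environment(alpha)
            shares = sol.occupied_shares
            means.append(float(sol.occupied_thresholds @ (shares / shares.sum())))
        assert all(b > a for a, b in zip(means, means[1:]))
        assert predict_continuous_environment(1.5).regime == "all_uninformed"


class TestCriticalAlpha:
    def test_single_ratio_closed_form(self):
        # boundary where c(d_max) = 0.5 d_max at d_max = 2(r-1)/(1+r); r=5 -> 14/9
        assert critical_alpha(RatioEnvironment.single(5.0)) == pytest.approx(14 / 9, abs=2e-3)

    def test_richer_patches_support_costlier_perception(self):
        assert critical_alpha(RatioEnvironment.single(2.0)) < critical_alpha(
            RatioEnvironment.single(5.0)
        )


class TestReplicator:
    def test_uniform_fitness_is_fixed_point(self):
        # identical patches: every strategy earns the same reward; with the
        # cost removed (alpha -> tiny) the distribution barely moves
        support = np.array([0.2, 0.7, 1.4])
        init = ThresholdDistribution(support, np.array([0.3, 0.3, 0.2]), 0.2)
        traj = integrate_replicator(
            init, RatioEnvironment.single(1.0), CostModel(1e-9), dt=0.05, n_steps=10
        )
        np.testing.assert_allclose(traj[-1].weights, init.weights, atol=1e-8)

    def test_analytic_solution_is_stationary(self):
        cost = CostModel(0.5)
        sol = solve_single_ratio(5.0, cost)
        init = sol.to_distribution()
        traj = integrate_replicator(
            init, RatioEnvironment.single(5.0), cost, dt=0.05, n_steps=1, record_every=1
        )
        assert abs(traj[-1].weight_inf - init.weight_inf) < 1e-6
        np.testing.assert_allclose(traj[-1].weights, init.weights, atol=1e-6)

    def test_dominated_strategy_decays_monotonically(self):
        # tau above the prevailing difference pays more cost for the same
        # reward as indifference: strictly dominated, must vanish
        support = np.array([0.618, 3.0])
        init = ThresholdDistribution(support, np.array([0.4, 0.2]), 0.4)
        traj = integrate_replicator(
            init, RatioEnvironment.single(5.0), CostModel(0.5),
            dt=0.05, n_steps=1000, record_every=50,
        )
        dominated = [t.weights[1] for t in traj]
        assert all(b <= a + 1e-12 for a, b in zip(dominated, dominated[1:]))
        assert dominated[-1] < 0.01

    def test_converges_to_analytic_equilibrium(self):
        cost = CostModel(0.5)
        sol = solve_single_ratio(5.0, cost)
        d_star, rho_inf = sol.thresholds[0], sol.occupancy_inf
        support = np.round(np.linspace(0.0, 3.0, 31), 6)
        init = ThresholdDistribution(support, np.full(31, 0.9 / 31), 0.1)
        traj = integrate_replicator(
            init, RatioEnvironment.single(5.0), cost, dt=0.05, n_steps=4000, record_every=1000
        )
        fin = traj[-1]
        near = np.abs(fin.support - d_star) <= 0.15
        assert fin.weights[near].sum() == pytest.approx(1 - rho_inf, abs=0.05)
        assert fin.weight_inf == pytest.approx(rho_inf, abs=0.05)

    def test_invalid_dt_rejected(self):
        init = ThresholdDistribution.point(0.5)
        with pytest.raises(ValueError):
            integrate_replicator(init, RatioEnvironment.single(2.0), CostModel(0.5), dt=0.0)
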