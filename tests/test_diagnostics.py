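"""Ergodic averages, social cost, Lyapunov exponents, periodic orbits and
sigma-family scans."""

import numpy as np
import pytest

import mwudyn as md


@pytest.fixture(scope="module")
def chaotic_traj(ex1_spec, ex1_state):
    """Example-1 orbit deep in the chaotic regime (sigma = 12.2)."""
    return md.iterate(ex1_spec.to_game(), ex1_state, 20_000, 10_000)


@pytest.fixture(scope="module")
def nash_traj():
    g = md.CongestionGame(mu=[0.5, 0.5], a=[1.0, 3.0], b=0.3)
    x0 = md.PopulationState.from_x([0.2, 0.4])  # flow = b exactly
    return g, md.iterate(g, x0, 100)


class TestTimeAverages:
    def test_constant_orbit_at_nash(self, nash_traj):
        g, traj = nash_traj
        assert md.time_average_flow(traj) == pytest.approx(0.3, abs=1e-13)
        c1, c2 = md.time_average_costs(traj, g)
        assert c1 == pytest.approx(0.21, abs=1e-12)
        assert c2 == pytest.approx(0.21, abs=1e-12)

    def test_cost_linearity_identity(self, ex1_spec, chaotic_traj):
        """mean C1 = alpha q mean(f) and mean C2 = beta q (1 - mean(f))
        exactly, because the costs are linear in the flow."""
        g = ex1_spec.to_game()
        f = md.time_average_flow(chaotic_traj)
        c1, c2 = md.time_average_costs(chaotic_traj, g)
        assert c1 == pytest.approx(g.alpha * g.q * f, abs=1e-12)
        assert c2 == pytest.approx(g.beta * g.q * (1 - f), abs=1e-12)

    def test_telescoping_identity(self, ex1_spec, ex1_state):
        """mean(f) - b = (s_N - s_0)/N exactly: summing g(s)-s = M.y(s)-b
        along the orbit telescopes."""
        g = ex1_spec.to_game()
        ctx = md.CurveContext.for_game(g, ex1_state)
        traj = md.iterate(g, ex1_state, 5_000)
        s = md.curve_coordinates(ctx, traj)
        n = traj.n_steps
        lhs = md.time_average_flow(traj) - g.b
        assert lhs == pytest.approx((s[-1] - s[0]) / n, abs=1e-10)
        # and hence the Cesàro error is bounded by range(s)/N
        assert abs(lhs) <= (s.max() - s.min()) / n + 1e-15

    def test_empty_trajectory_rejected(self, ex1_game):
        traj = md.Trajectory(
            burn_in=0,
            flows=np.array([]),
            c1=np.array([]),
            c2=np.array([]),
            social=np.array([]),
            z_final=np.array([0.0, 0.0]),
        )
        with pytest.raises(ValueError):
            md.time_average_flow(traj)
        with pytest.raises(ValueError):
            md.time_average_costs(traj, ex1_game)


class TestNormalizedSocialCost:
    def test_one_at_equilibrium(self, nash_traj):
        g, traj = nash_traj
        assert md.normalized_social_cost(traj, g) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_identity(self, ex1_spec, chaotic_traj):
        """normalized cost = 1 + mean((f-b)^2)/(b(1-b)), an exact algebraic
        rearrangement of the defining ratio."""
        g = ex1_spec.to_game()
        got = md.normalized_social_cost(chaotic_traj, g)
        f = chaotic_traj.flows
        expected = 1.0 + ((f - g.b) ** 2).mean() / (g.b * (1 - g.b))
        assert got == pytest.approx(expected, abs=1e-10)
        assert got > 1.0  # chaos is socially costly

    def test_never_below_one(self):
        for seed in range(8):
            spec = md.random_population(3, (1.0, 25.0), seed=seed)
            g = spec.to_game(sigma=1.0)
            traj = md.iterate(g, spec.initial_state(), 2_000, 500)
            assert md.normalized_social_cost(traj, g) >= 1.0 - 1e-9


class TestLyapunov:
    def test_negative_at_stable_fixed_point(self, ex1_spec, ex1_state):
        g = ex1_spec.to_game(sigma=1.0)
        ctx = md.CurveContext.for_game(g, ex1_state)
        s_star = md.equilibrium_on_curve(ctx, g)
        lam = md.lyapunov_exponent(ctx, g, 0.0, 2_000, burn_in=5_000)
        assert lam < 0
        assert lam == pytest.approx(
            np.log(abs(md.reduced_derivative(ctx, g, s_star))), abs=1e-6
        )

    def test_vanishing_rates_give_zero(self):
        g = md.CongestionGame(mu=[0.5, 0.5], a=[1e-7, 1e-7], b=0.3)
        ctx = md.CurveContext.for_game(g, md.PopulationState.from_x([0.2, 0.6]))
        assert md.lyapunov_exponent(ctx, g, 0.0, 200) == pytest.approx(
            0.0, abs=1e-5
        )

    def test_positive_in_chaotic_regime(self, ex1_spec, ex1_state):
        g = ex1_spec.to_game()  # sigma = 12.2
        ctx = md.CurveContext.for_game(g, ex1_state)
        assert md.lyapunov_exponent(ctx, g, 0.0, 20_000, burn_in=2_000) > 0

    def test_trajectory_route_agrees_with_reduced_route(
        self, ex1_spec, ex1_state, chaotic_traj
    ):
        """The state-space and reduced-map estimators follow chaotic orbits
        that decorrelate through roundoff, so they agree statistically
        (same ergodic average), not bitwise."""
        g = ex1_spec.to_game()
        ctx = md.CurveContext.for_game(g, ex1_state)
        a = md.lyapunov_from_trajectory(chaotic_traj, g)
        b = md.lyapunov_exponent(ctx, g, 0.0, 20_000, burn_in=10_000)
        assert a == pytest.approx(b, abs=0.05)


class TestPeriodicOrbits:
    def test_period_one_recovers_equilibrium(self, ex1_ctx, ex1_game):
        s_star = md.equilibrium_on_curve(ex1_ctx, ex1_game)
        orbits = md.find_periodic_orbits(ex1_ctx, ex1_game, 1, (-5, 5))
        assert len(orbits) == 1
        assert orbits[0].points[0] == pytest.approx(s_star, abs=1e-10)
        assert orbits[0].stable  # sigma = 1 is below the first bifurcation

    def test_no_higher_period_below_first_bifurcation(self, ex1_spec, ex1_state):
        g = ex1_spec.to_game(sigma=0.5)
        ctx = md.CurveContext.for_game(g, ex1_state)
        for p in (2, 3):
            assert md.find_periodic_orbits(ctx, g, p, (-10, 10)) == []

    def test_period_two_past_first_bifurcation(self, ex1_spec, ex1_state):
        sig = md.sigma_critical(ex1_spec.to_game(sigma=1.0), ex1_state)
        g = ex1_spec.to_game(sigma=1.3 * sig)
        ctx = md.CurveContext.for_game(g, ex1_state)
        orbits = md.find_periodic_orbits(ctx, g, 2, (-5, 5))
        assert len(orbits) >= 1
        s1, s2 = orbits[0].points
        g2 = md.reduced_map(ctx, g, md.reduced_map(ctx, g, s1))
        assert g2 == pytest.approx(s1, abs=1e-8)
        assert abs(s2 - s1) > 1e-4  # genuinely period 2, not a fixed point

    def test_empty_range_rejected(self, ex1_ctx, ex1_game):
        with pytest.raises(ValueError):
            md.find_periodic_orbits(ex1_ctx, ex1_game, 2, (1.0, 1.0))


class TestClassifyOrbit:
    def test_constant(self):
        assert md.classify_orbit(np.full(300, 0.3)) == "fixed_point"

    def test_alternating(self):
        s = np.tile([0.1, 0.5], 200)
        assert md.classify_orbit(s) == "periodic(2)"

    def test_minimal_period_reported(self):
        s = np.tile([0.1, 0.5, 0.9], 120)
        assert md.classify_orbit(s) == "periodic(3)"

    def test_chaotic_series(self, chaotic_traj):
        assert md.classify_orbit(chaotic_traj.flows) == "aperiodic"

    def test_first_instability_is_period_doubling(self, ex1_spec, ex1_state):
        """Just below the critical sigma the orbit settles to the fixed
        point; just above, to a 2-cycle — the canonical period-doubling
        route."""
        sig = md.sigma_critical(ex1_spec.to_game(sigma=1.0), ex1_state)
        for factor, expected in [(0.95, "fixed_point"), (1.1, "periodic(2)")]:
            g = ex1_spec.to_game(sigma=factor * sig)
            ctx = md.CurveContext.for_game(g, ex1_state)
            tail = md.iterate_reduced(ctx, g, 0.0, 300, burn_in=200_000)
            assert md.classify_orbit(tail) == expected


class TestDiagnose:
    def test_report_fields(self, ex1_spec, chaotic_traj):
        g = ex1_spec.to_game()
        rep = md.diagnose(chaotic_traj, g)
        assert rep.orbit_class == "aperiodic"
        assert rep.lyapunov > 0
        assert rep.normalized_social_cost > 1
        assert rep.horizon == 20_000 and rep.burn_in == 10_000
        d = rep.to_dict()
        assert set(d) >= {"mean_flow", "mean_c1", "mean_c2", "lyapunov"}

    def test_fixed_point_report(self, ex1_spec, ex1_state):
        g = ex1_spec.to_game(sigma=0.5)
        traj = md.iterate(g, ex1_state, 500, 2_000)
        rep = md.diagnose(traj, g)
        assert rep.orbit_class == "fixed_point"
        assert rep.lyapunov < 0
        assert rep.mean_flow == pytest.approx(0.3, abs=1e-9)
        assert rep.normalized_social_cost == pytest.approx(1.0, abs=1e-9)


class TestSigmaScan:
    def test_single_small_sigma_sits_on_fixed_point(self, ex1_game, ex1_state):
        scan = md.sigma_scan(ex1_game, ex1_state, [0.1], n_samples=200,
                             burn_in=5_000)
        x_star = scan.samples[0, -1]
        assert np.max(np.abs(scan.samples[0] - x_star)) < 1e-6
        assert scan.reports[0].orbit_class == "fixed_point"

    def test_mean_flow_pinned_across_grid(self, ex1_game, ex1_state):
        """The time-average flow stays at b for every sigma, chaotic
        windows included, while per-type averages wander."""
        grid = np.arange(0.5, 14.01, 0.5)
        scan = md.sigma_scan(ex1_game, ex1_state, grid,
                             n_samples=4_000, burn_in=10_000)
        mean_flows = np.array([r.mean_flow for r in scan.reports])
        assert np.max(np.abs(mean_flows - ex1_game.b)) < 5e-3
        # per-type time averages are NOT pinned: they vary across sigma
        mean_x1 = scan.samples[:, :, 0].mean(axis=1)
        assert mean_x1.max() - mean_x1.min() > 0.02

    def test_scan_matches_plain_iteration(self, ex1_spec, ex1_state):
        g1 = ex1_spec.to_game(sigma=1.0)
        scan = md.sigma_scan(g1, ex1_state, [12.2], n_samples=100, burn_in=50)
        traj = md.iterate(ex1_spec.to_game(sigma=12.2), ex1_state, 100, 50)
        np.testing.assert_allclose(scan.flows[0], traj.flows, atol=1e-12)

    def test_grid_validation(self, ex1_game, ex1_state):
        with pytest.raises(ValueError):
            md.sigma_scan(ex1_game, ex1_state, [])
        with pytest.raises(ValueError):
            md.sigma_scan(ex1_game, ex1_state, [2.0, 1.0])


class TestSigmaCritical:
    def test_homogeneous_closed_form(self):
        # one type: threshold at sigma * a * x*(1-x*) = 2 with x* = b
        a0, b = 4.0, 0.3
        g = md.CongestionGame(mu=[1.0], a=[a0], b=b)
        x0 = md.PopulationState.from_x([0.5])
        got = md.sigma_critical(g, x0)
        assert got == pytest.approx(2.0 / (a0 * b * (1 - b)), abs=1e-6)

    def test_scale_invariance(self, ex1_spec, ex1_state):
        g = ex1_spec.to_game(sigma=1.0)
        s1 = md.sigma_critical(g, ex1_state)
        s2 = md.sigma_critical(g.scaled(2.0), ex1_state)
        assert s2 == pytest.approx(s1 / 2.0, abs=1e-6)

    def test_bracket_failure_is_structured(self, ex1_game, ex1_state):
        with pytest.raises(md.BracketError):
            md.sigma_critical(ex1_game, ex1_state, bracket=(1e-4, 1e-3))

    def test_iteration_confirms_threshold(self, ex1_spec, ex1_state):
        sig = md.sigma_critical(ex1_spec.to_game(sigma=1.0), ex1_state)
        for factor, stable in [(0.9, True), (1.1, False)]:
            g = ex1_spec.to_game(sigma=factor * sig)
            ctx = md.CurveContext.for_game(g, ex1_state)
            tail = md.iterate_reduced(ctx, g, 0.0, 100, burn_in=100_000)
            assert (np.max(np.abs(np.diff(tail))) < 1e-9) == stable
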