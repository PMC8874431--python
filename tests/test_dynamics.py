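"""Tests for the five-state model: derivative identities, closed forms,
oracle equivalence and the simulation invariants."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

from parvodyn import (
    SCENARIOS,
    SystemState,
    derivatives,
    initial_state,
    optimum_temperature,
    run_temperature_grid,
    simulate,
    summarize,
)
from parvodyn.params import DEFAULT_K


class TestDerivatives:
    def test_host_at_carrying_capacity_has_zero_growth(self, table1):
        p = table1[0]
        d = derivatives(SystemState(H1=p.K, H2=0, I1=0, I2=0, P=0), p)
        assert d.H1 == pytest.approx(0.0, abs=1e-12)

    def test_parasite_free_submodel_is_pure_logistic_competition(self, table1):
        p = table1[2]
        s = SystemState(H1=5000, H2=8000, I1=0, I2=0, P=0)
        d = derivatives(s, p)
        crowd = (p.K - s.H1 - s.H2) / p.K
        assert d.H1 == pytest.approx(p.r1 * s.H1 * crowd, rel=1e-12)
        assert d.H2 == pytest.approx(p.r2 * s.H2 * crowd, rel=1e-12)
        assert d.P == d.I1 == d.I2 == 0.0

    def test_host_free_zoospores_decay_at_mortality_rate(self, table1):
        p = table1[1]
        d = derivatives(SystemState(H1=0, H2=0, I1=0, I2=0, P=3000), p)
        assert d.P == pytest.approx(-p.m * 3000, rel=1e-12)
        assert d.H1 == d.H2 == d.I1 == d.I2 == 0.0

    def test_infection_moves_hosts_to_infected_pool(self, table1):
        p = table1[2]
        s = SystemState(H1=10000, H2=0, I1=0, I2=0, P=1000)
        d = derivatives(s, p)
        f1 = p.a1 * s.H1 / (1 + p.a1 * p.h1 * s.H1)
        assert d.I1 == pytest.approx(f1 * s.P, rel=1e-12)
        assert d.H1 == pytest.approx(
            p.r1 * s.H1 * (p.K - s.H1) / p.K - f1 * s.P, rel=1e-12
        )


class TestSimulate:
    def test_single_host_logistic_asymptote_is_K(self, table1):
        traj = simulate(initial_state(True, False, False), table1[0], horizon=200)
        assert traj.H1[-1] == pytest.approx(DEFAULT_K, rel=1e-3)

    def test_zoospore_decay_matches_closed_form_without_attack(self, table1):
        p0 = table1[2]
        p = type(p0)(**{**p0.__dict__, "a1": 0.0, "a2": 0.0})
        traj = simulate(SystemState(H1=1000, H2=1000, I1=0, I2=0, P=2000), p, 10)
        np.testing.assert_allclose(
            traj.P, 2000 * np.exp(-p.m * traj.times), rtol=1e-6, atol=1e-5
        )

    def test_host_free_decay_is_exactly_exponential(self, table1):
        p = table1[0]
        traj = simulate(SystemState(H1=0, H2=0, I1=0, I2=0, P=5000), p, 5)
        np.testing.assert_allclose(
            traj.P, 5000 * np.exp(-p.m * traj.times), rtol=1e-6, atol=1e-6
        )

    def test_self_convergence_under_tolerance_halving(self, table1):
        p = table1[2]
        init = initial_state(True, True, True)
        a = simulate(init, p, 30, rtol=1e-8, atol=1e-6)
        b = simulate(init, p, 30, rtol=5e-9, atol=5e-7)
        scale = max(a.states.max(), 1.0)
        assert np.max(np.abs(a.states[-1] - b.states[-1])) / scale < 1e-4

    def test_parasite_free_matches_independent_competition_integrator(self, table1):
        """Oracle: a separately coded two-species logistic-competition RHS."""
        for p in table1:
            def lv(t, y):
                H1, H2 = y
                crowd = (p.K - H1 - H2) / p.K
                return [p.r1 * H1 * crowd, p.r2 * H2 * crowd]

            oracle = solve_ivp(lv, (0, 14), [1000.0, 1000.0], rtol=1e-10,
                               atol=1e-8, t_eval=np.arange(0, 14.05, 0.05),
                               method="LSODA")
            traj = simulate(initial_state(True, True, False), p, 14,
                            rtol=1e-10, atol=1e-8)
            np.testing.assert_allclose(traj.H1, oracle.y[0], rtol=1e-6)
            np.testing.assert_allclose(traj.H2, oracle.y[1], rtol=1e-6)

    def test_zero_yield_means_zoospores_eventually_vanish(self, table1):
        p0 = table1[2]
        p = type(p0)(**{**p0.__dict__, "eps1": 0.0, "eps2": 0.0})
        traj = simulate(initial_state(True, True, True), p, 30)
        # no spontaneous zoospore generation: P decays monotonically to ~0
        assert np.all(np.diff(traj.P) <= 1e-9)
        assert traj.P[-1] < 1e-6 * traj.P[0]

    def test_invalid_horizon_rejected(self, table1):
        with pytest.raises(ValueError):
            simulate(initial_state(True, True, True), table1[0], horizon=0)


class TestInvariants:
    def test_non_negativity_and_boundedness_for_all_parameterizations(self, table1):
        for p in table1:
            for scen in SCENARIOS.values():
                traj = simulate(
                    initial_state(scen.host1, scen.host2, scen.parasitoid),
                    p, scen.horizon,
                )
                assert traj.states.min() >= 0.0  # outputs are clipped
                # uninfected hosts are bounded by the shared carrying capacity
                assert np.max(traj.H1 + traj.H2) <= p.K * (1 + 1e-6)

    def test_parasitism_only_removes_hosts_in_single_host_scenarios(self, table1):
        for p in table1:
            for host1 in (True, False):
                base = simulate(initial_state(host1, not host1, False), p, 30)
                wp = simulate(initial_state(host1, not host1, True), p, 30)
                series = "H1" if host1 else "H2"
                assert getattr(wp, series).max() <= getattr(base, series).max() * (
                    1 + 1e-9
                )


class TestGridAndSummaries:
    def test_grid_covers_every_scenario_temperature_pair(self, table1):
        res = run_temperature_grid(table1, ["host1_alone", "both_parasitoid"])
        keys = {(t.scenario, t.parameters.temperature) for t, _ in res}
        assert len(keys) == 10
        for traj, s in res:
            assert s.temperature == traj.parameters.temperature

    def test_unknown_scenario_rejected(self, table1):
        with pytest.raises(ValueError, match="unknown scenario"):
            run_temperature_grid(table1, ["no_such_scenario"])

    def test_empty_parameter_table_rejected(self):
        with pytest.raises(ValueError):
            run_temperature_grid([], ["both"])

    def test_identical_trajectories_have_unit_impact_ratio(self, table1):
        traj = simulate(initial_state(True, True, False), table1[0], 14)
        s = summarize(traj, traj)
        assert s.impact_ratio_H1 == pytest.approx(1.0)
        assert s.impact_ratio_H2 == pytest.approx(1.0)

    def test_extinct_host_has_zero_impact_ratio(self, table1):
        p = table1[0]
        dead = simulate(SystemState(H1=0, H2=1000, I1=0, I2=0, P=0), p, 14)
        alive = simulate(initial_state(True, True, False), p, 14)
        s = summarize(dead, alive)
        assert s.impact_ratio_H1 == 0.0

    def test_temperature_mismatch_rejected(self, table1):
        a = simulate(initial_state(True, True, False), table1[0], 14)
        b = simulate(initial_state(True, True, False), table1[1], 14)
        with pytest.raises(ValueError):
            summarize(a, b)

    def test_optimum_temperature_reports_tie_set_and_lowest(self):
        ties, single = optimum_temperature({13: 1.0, 15: 1.0, 18: 0.5})
        assert ties == [13, 15]
        assert single == 13

    def test_dominance_ratio_is_h2_over_h1_peaks(self, table1):
        traj = simulate(initial_state(True, True, False), table1[2], 14)
        s = summarize(traj, traj)
        assert s.dominance_ratio == pytest.approx(traj.H2.max() / traj.H1.max())
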