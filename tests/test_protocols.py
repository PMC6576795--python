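"""Private-resource schedules, arrival gating, and propagule placement."""

import numpy as np
import pytest

from defensim import (GridState, InvasionProtocol, ResourceSchedule,
                      ScheduleMode, SimulationParams, arrivals_enabled,
                      attempt_invasion, place_propagule, run_simulation,
                      schedule_factors)
from defensim.engine import Setup
from defensim.lattice import is_edge_connected
from defensim.params import B, EMPTY, P, InvasionTest


class TestScheduleFactors:
    def test_all_boosts_lapse_at_tau(self):
        for mode in ScheduleMode:
            sch = ResourceSchedule(mode=mode, tau=100, r_plus=2.0, rho_plus=3.0)
            assert schedule_factors(sch, 100) == (1.0, 1.0)
            assert schedule_factors(sch, 5000) == (1.0, 1.0)

    def test_enhanced_production_multiplies_rho(self):
        sch = ResourceSchedule(mode=ScheduleMode.ENHANCED_PRODUCTION,
                               tau=100, rho_plus=2.0)
        assert schedule_factors(sch, 50) == (1.0, 2.0)

    def test_enhanced_growth_multiplies_r(self):
        sch = ResourceSchedule(mode=ScheduleMode.ENHANCED_GROWTH,
                               tau=100, r_plus=1.5)
        assert schedule_factors(sch, 99) == (1.5, 1.0)

    def test_none_and_protected_leave_rates_alone(self):
        for mode in (ScheduleMode.NONE, ScheduleMode.PROTECTED_GROWTH):
            sch = ResourceSchedule(mode=mode, tau=100, r_plus=9.0, rho_plus=9.0)
            assert schedule_factors(sch, 1) == (1.0, 1.0)
        assert schedule_factors(None, 1) == (1.0, 1.0)


class TestArrivalsEnabled:
    def test_size_trigger_threshold_crossing(self):
        p = SimulationParams(M=100, CSI=0.1, f=0.01)
        proto = InvasionProtocol.from_params(p, InvasionTest.TEST2)
        assert not arrivals_enabled(10, 999, p, proto)
        assert arrivals_enabled(10, 1000, p, proto)

    def test_size_trigger_respects_kappa(self):
        p = SimulationParams(M=10, CSI=0.0, kappa=300, f=0.01)
        proto = InvasionProtocol.from_params(p, InvasionTest.TEST2)
        assert not arrivals_enabled(299, 50, p, proto)
        assert arrivals_enabled(300, 50, p, proto)

    def test_time_trigger_from_kappa(self):
        p = SimulationParams(M=10, kappa=1, f=0.01)
        proto = InvasionProtocol.from_params(p, InvasionTest.TEST1)
        assert arrivals_enabled(1, 0, p, proto)

    def test_full_protection_blocks_until_tau(self):
        p = SimulationParams(M=10, s_plus=1.0, tau=200, f=0.01)
        sch = ResourceSchedule.from_params(p, ScheduleMode.PROTECTED_GROWTH)
        proto = InvasionProtocol.from_params(p, InvasionTest.TEST1)
        assert not arrivals_enabled(100, 0, p, proto, sch)
        assert arrivals_enabled(200, 0, p, proto, sch)

    def test_partial_protection_does_not_block_globally(self):
        p = SimulationParams(M=10, s_plus=0.25, tau=200, f=0.01)
        sch = ResourceSchedule.from_params(p, ScheduleMode.PROTECTED_GROWTH)
        proto = InvasionProtocol.from_params(p, InvasionTest.TEST1)
        assert arrivals_enabled(100, 0, p, proto, sch)


class TestPlacement:
    def test_cluster_on_empty_grid(self, rng):
        state = GridState.empty(10)
        ev = place_propagule(state, 10, (4, 4), rng, t=1)
        assert ev.n_placed_on_empty == 10 and ev.n_placed_by_overwrite == 0
        assert (state.occupancy == P).sum() == 10
        assert (4, 4) in ev.sites
        assert is_edge_connected(set(ev.sites), 10)

    def test_cluster_overwrites_full_grid(self, rng):
        state = GridState.empty(10)
        state.occupancy[:] = B
        state.a_int[:] = 0.5
        ev = place_propagule(state, 10, (4, 4), rng, t=1)
        assert ev.n_placed_by_overwrite == 10 and ev.n_overwritten_B == 10
        assert is_edge_connected(set(ev.sites), 10)
        for site in ev.sites:  # displaced producers void their antibiotic
            assert state.a_int[site] == 0.0

    def test_empty_only_mode_dies_on_occupied_focal(self, rng):
        state = GridState.empty(10)
        state.occupancy[:] = B
        ev = place_propagule(state, 10, (4, 4), rng, t=1, empty_only=True)
        assert ev.n_placed == 0
        assert not (state.occupancy == P).any()

    def test_empty_only_mode_stops_at_enclosed_pocket(self, rng):
        state = GridState.empty(9)
        state.occupancy[:] = B
        state.occupancy[3:5, 3:5] = EMPTY  # 4-site pocket
        ev = place_propagule(state, 10, (3, 3), rng, t=1, empty_only=True)
        assert ev.n_placed == 4
        assert ev.n_placed_by_overwrite == 0

    def test_blocked_focal_kills_propagule(self, rng):
        state = GridState.empty(10)
        blocked = np.zeros((10, 10), dtype=bool)
        blocked[4, 4] = True
        ev = place_propagule(state, 10, (4, 4), rng, t=1, blocked=blocked)
        assert ev.n_placed == 0

    def test_protected_region_is_never_entered(self, rng):
        state = GridState.empty(12)
        blocked = np.zeros((12, 12), dtype=bool)
        blocked[:, 6:] = True
        ev = place_propagule(state, 30, (5, 5), rng, t=1, blocked=blocked)
        assert ev.n_placed == 30
        assert not (state.occupancy[:, 6:] == P).any()

    def test_zero_propagule_size(self, rng):
        state = GridState.empty(6)
        assert place_propagule(state, 0, (1, 1), rng, t=1).n_placed == 0


class TestArrivalProcess:
    def _count_events(self, params, n_steps, seed=5):
        proto = InvasionProtocol.from_params(params, InvasionTest.TEST1)
        rng = np.random.default_rng(seed)
        total = 0
        for t in range(n_steps):
            state = GridState.empty(params.M)  # fresh: placements always land
            total += len(attempt_invasion(state, params, proto, None, t, rng,
                                          enabled=True))
        return total

    def test_generation_clock_count_is_binomial(self):
        # one Bernoulli(f) trial per generation: Binomial(window, f)
        p = SimulationParams(M=12, f=0.1, n_Pt=3, arrival_clock="generation")
        n = 10_000
        total = self._count_events(p, n)
        se = np.sqrt(n * 0.1 * 0.9)
        assert abs(total - n * 0.1) < 3 * se

    def test_substep_clock_count_is_binomial_in_substeps(self):
        # Bernoulli(f) per antibiotic update step: Binomial(window*u, f)
        p = SimulationParams(M=12, f=0.01, u=100, n_Pt=3,
                             arrival_clock="substep")
        n = 2000
        total = self._count_events(p, n)
        mean, var = n * 100 * 0.01, n * 100 * 0.01 * 0.99
        assert abs(total - mean) < 3 * np.sqrt(var)

    def test_f_zero_never_arrives(self):
        p = SimulationParams(M=12, f=0.0)
        assert self._count_events(p, 500) == 0

    def test_fully_protected_habitat_sees_no_parasites_before_tau(self):
        # integration: full protection (s+ = 1) with heavy pressure
        p = SimulationParams(M=15, n_B0=10, s_plus=1.0, tau=120, f=0.2,
                             max_generations=100, seed=3)
        setup = Setup.build(p, ScheduleMode.PROTECTED_GROWTH, InvasionTest.TEST1)
        result = run_simulation(setup.params, setup.schedule, setup.protocol)
        assert (result.trajectory["n_P"] == 0).all()
        assert not result.events
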