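"""Antibiotic field dynamics: stencil, reaction terms, stability, oracles."""

import math

import numpy as np
import pytest

from defensim import (GridState, SimulationParams, antibiotic_substep,
                      clear_intracellular, diffusion_term, reaction_term,
                      run_substeps)
from defensim._kernels import diffusion_substeps_needed


def literal_substep(occ, a_ext, a_int, p, rho_eff):
    """Loop-based transcription of the discretised field update.

    Independent oracle: five-point diffusion (subcycled identically), then
    the per-site reaction terms evaluated on the start-of-substep fields.
    """
    M = occ.shape[0]
    n_sub = diffusion_substeps_needed(p.D, p.Dt)
    ext0 = a_ext.copy()
    ext = a_ext.copy()
    for _ in range(n_sub):
        new = np.empty_like(ext)
        for i in range(M):
            for j in range(M):
                lap = (ext[(i - 1) % M, j] + ext[(i + 1) % M, j]
                       + ext[i, (j - 1) % M] + ext[i, (j + 1) % M]
                       - 4.0 * ext[i, j])
                new[i, j] = ext[i, j] + p.D * (p.Dt / n_sub) * lap
        ext = new
    new_int = a_int.copy()
    for i in range(M):
        for j in range(M):
            e0, i0 = ext0[i, j], a_int[i, j]
            if occ[i, j] == 1:
                d_ext = rho_eff + p.beta_B * i0 - p.alpha_B * e0 - p.phi * e0
                d_int = p.alpha_B * e0 - p.beta_B * i0 - p.gamma_B * i0
            elif occ[i, j] == 2:
                d_ext = p.beta_P * i0 - p.alpha_P * e0 - p.phi * e0
                d_int = p.alpha_P * e0 - p.beta_P * i0 - p.gamma_P * i0
            else:
                d_ext, d_int = -p.phi * e0, 0.0
            ext[i, j] = max(ext[i, j] + d_ext * p.Dt, 0.0)
            new_int[i, j] = max(i0 + d_int * p.Dt, 0.0)
    return ext, new_int


class TestDiffusionTerm:
    def test_uniform_field_has_zero_increment(self):
        inc = diffusion_term(np.full((8, 8), 3.7), D=2.0, dt=0.1)
        assert np.allclose(inc, 0.0, atol=1e-14)

    def test_unit_spike_five_point_stencil(self):
        field = np.zeros((7, 7))
        field[3, 3] = 1.0
        inc = diffusion_term(field, D=1.0, dt=0.1)  # D*dt = 0.1
        assert inc[3, 3] == pytest.approx(-0.4)
        for nb in ((2, 3), (4, 3), (3, 2), (3, 4)):
            assert inc[nb] == pytest.approx(0.1)
        assert np.count_nonzero(inc) == 5

    def test_increment_conserves_mass(self, rng):
        field = rng.random((12, 12)) * 5
        assert abs(diffusion_term(field, 3.0, 0.1).sum()) < 1e-12


class TestReactionTerm:
    def test_decay_everywhere_on_empty_grid(self):
        p = SimulationParams(M=6, phi=0.3, n_B0=0)
        state = GridState.empty(6)
        d_ext, d_int = reaction_term(np.ones((6, 6)), state.a_int,
                                     state.occupancy, p)
        assert np.allclose(d_ext, -0.3)  # times dt=0.1 -> -0.03
        assert np.allclose(d_int, 0.0)

    def test_decay_occupied_only_variant(self):
        p = SimulationParams(M=6, phi=0.3, n_B0=0, decay_occupied_only=True)
        state = GridState.empty(6)
        d_ext, _ = reaction_term(np.ones((6, 6)), state.a_int,
                                 state.occupancy, p)
        assert np.allclose(d_ext, 0.0)

    def test_lone_producer_sources_antibiotic(self):
        p = SimulationParams(M=6, rho_B0=1.0, n_B0=0)
        occ = np.zeros((6, 6), dtype=np.int8)
        occ[2, 2] = 1
        d_ext, d_int = reaction_term(np.zeros((6, 6)), np.zeros((6, 6)), occ, p)
        assert d_ext[2, 2] == pytest.approx(1.0)  # only the production term
        assert d_ext.sum() == pytest.approx(1.0)
        assert np.allclose(d_int, 0.0)

    def test_nonproducer_never_produces(self, rng):
        p = SimulationParams(M=6, rho_B0=1.0, phi=0.0, beta_P=0.0, n_B0=0)
        occ = np.zeros((6, 6), dtype=np.int8)
        occ[1, 4] = 2
        a_ext = rng.random((6, 6))
        a_int = np.zeros((6, 6))
        a_int[1, 4] = rng.random()
        d_ext, _ = reaction_term(a_ext, a_int, occ, p)
        # the parasite only removes antibiotic (uptake), never adds
        assert d_ext[1, 4] == pytest.approx(-p.alpha_P * a_ext[1, 4])


class TestSubstep:
    def test_pure_diffusion_conserves_mass(self, rng):
        p = SimulationParams(M=20, phi=0.0, D=5.0, n_B0=0, f=0.0)
        state = GridState.empty(20)
        state.a_ext[:] = rng.random((20, 20)) * 4
        total0 = state.a_ext.sum()
        report = run_substeps(state, p, n_substeps=10_000)
        assert report.clamped_sites == 0
        assert abs(state.a_ext.sum() - total0) / total0 < 1e-8

    def test_high_diffusion_is_subcycled_and_stable(self):
        p = SimulationParams(M=15, D=50.0, Dt=0.1, phi=0.0, n_B0=0)
        assert diffusion_substeps_needed(50.0, 0.1) == math.ceil(4 * 50 * 0.1) == 20
        state = GridState.empty(15)
        state.a_ext[7, 7] = 100.0
        state, report = antibiotic_substep(state, p)
        assert report.substeps_taken == 20
        assert report.clamped_sites == 0
        assert (state.a_ext >= 0).all()

    def test_matches_literal_loop_transcription(self, rng):
        # 5x5 oracle equivalence over 10 substeps, mixed occupancy, D high
        # enough to trigger subcycling
        p = SimulationParams(M=5, D=5.0, Dt=0.1, beta_B=0.6, n_B0=0)
        occ = rng.integers(0, 3, size=(5, 5)).astype(np.int8)
        state = GridState(occ.copy(), rng.random((5, 5)) * 2,
                          np.where(occ > 0, rng.random((5, 5)), 0.0))
        ext, aint = state.a_ext.copy(), state.a_int.copy()
        for _ in range(10):
            ext, aint = literal_substep(occ, ext, aint, p, p.rho_B0)
        run_substeps(state, p, n_substeps=10)
        np.testing.assert_allclose(state.a_ext, ext, rtol=0, atol=1e-12)
        np.testing.assert_allclose(state.a_int, aint, rtol=0, atol=1e-12)

    def test_point_source_field_is_fourfold_symmetric(self):
        p = SimulationParams(M=11, D=2.0, Dt=0.1, phi=0.1, n_B0=0)
        state = GridState.empty(11)
        state.a_ext[5, 5] = 50.0
        run_substeps(state, p, n_substeps=60)
        f = state.a_ext
        np.testing.assert_allclose(f, np.rot90(f), atol=1e-10)
        np.testing.assert_allclose(f, f.T, atol=1e-10)

    def test_intracellular_fixed_point_under_held_field(self):
        # with A_ext pinned, A_int -> alpha * A_ext / (beta + gamma)
        p = SimulationParams(M=5, D=0.0, phi=0.0, rho_B0=0.0, alpha_B=0.5,
                             beta_B=0.6, gamma_B=0.3, n_B0=0)
        occ = np.zeros((5, 5), dtype=np.int8)
        occ[2, 2] = 1
        state = GridState(occ, np.zeros((5, 5)), np.zeros((5, 5)))
        held = 2.0
        for _ in range(2000):
            state.a_ext[2, 2] = held
            antibiotic_substep(state, p)
        expected = p.alpha_B * held / (p.beta_B + p.gamma_B)
        assert state.a_int[2, 2] == pytest.approx(expected, rel=1e-6)

    def test_nonnegativity_across_preset_rate_sets(self):
        # the published rate sets must never drive a concentration negative
        from defensim import load_config, preset_names

        seen = set()
        for name in preset_names():
            s = load_config(name)
            key = (s.params.D, s.params.phi, s.params.beta_B, s.params.Dt,
                   s.params.alpha_B, s.params.gamma_B, s.params.rho_B0)
            if key in seen:
                continue
            seen.add(key)
            p = s.params.replace(M=24, n_B0=60)
            state = GridState.empty(24)
            state.occupancy[5:15, 5:15] = 1
            state.occupancy[16:20, 3:20] = 2
            report = run_substeps(state, p, n_substeps=2000)
            assert report.clamped_sites == 0, name
            assert (state.a_ext >= 0).all() and (state.a_int >= 0).all()

    def test_nonfinite_field_raises_with_location(self):
        p = SimulationParams(M=5, n_B0=0)
        state = GridState.empty(5)
        state.a_ext[1, 3] = np.inf
        with pytest.raises(FloatingPointError, match=r"site"):
            run_substeps(state, p, n_substeps=1)


class TestClearIntracellular:
    def test_vacated_site_keeps_extracellular_field(self):
        state = GridState.empty(5)
        state.occupancy[2, 2] = 1
        state.a_int[2, 2] = 0.8
        state.a_ext[2, 2] = 1.5
        state.occupancy[2, 2] = 0  # the occupant dies
        clear_intracellular(state, (2, 2))
        assert state.a_int[2, 2] == 0.0
        assert state.a_ext[2, 2] == 1.5
        state.check()
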