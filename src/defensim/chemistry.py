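"""Antibiotic field dynamics: diffusion, production, uptake, efflux, decay.

One antibiotic *substep* advances both concentration fields by ``Dt``:

* extracellular ``A_ext`` diffuses between von Neumann neighbours with rate
  ``D`` (five-point stencil on the torus) and decays at rate ``phi``;
* each occupied site exchanges antibiotic with its cell: production
  ``rho`` (producers only), efflux ``beta * A_int`` outward, uptake
  ``alpha * A_ext`` inward, intracellular decomposition ``gamma * A_int``.

The explicit diffusion stencil is stable only for ``D * Dt / Dx^2 <= 1/4``;
for larger ``D * Dt`` the diffusion operator is transparently subcycled
(operator splitting: several diffusion micro-steps, then one reaction step
per substep).  Within a substep, diffusion is applied first and the reaction
terms are evaluated on the start-of-substep fields, so results do not depend
on any site visitation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import chemistry_kernel, diffusion_substeps_needed
from .params import B, EMPTY, P, GridState, ResourceSchedule, SimulationParams

__all__ = ["ChemistryStepReport", "diffusion_term", "reaction_term",
           "antibiotic_substep", "run_substeps", "clear_intracellular"]


@dataclass
class ChemistryStepReport:
    """Audit record for a chemistry update (artifact plumbing, not model)."""

    substeps_taken: int          # diffusion micro-steps per substep
    total_mass_before: float     # sum of A_ext + A_int before the update
    total_mass_after: float
    clamped_sites: int           # sites clamped to zero concentration


def diffusion_term(a_ext: np.ndarray, D: float, dt: float) -> np.ndarray:
    """Five-point-stencil diffusion increment over one step of length ``dt``.

    ``increment(i) = D*dt/Dx^2 * (sum of the 4 von Neumann neighbours - 4*A(i))``
    with ``Dx = 1``.  The increment sums to zero over the torus (discrete
    conservation).  Pure function; no stability subcycling here.
    """
    lap = (np.roll(a_ext, 1, axis=0) + np.roll(a_ext, -1, axis=0)
           + np.roll(a_ext, 1, axis=1) + np.roll(a_ext, -1, axis=1)
           - 4.0 * a_ext)
    return D * dt * lap


def reaction_term(a_ext: np.ndarray, a_int: np.ndarray, occupancy: np.ndarray,
                  params: SimulationParams,
                  schedule: ResourceSchedule | None = None,
                  t: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit-time reaction rates for the two fields (not yet scaled by dt).

    At a site occupied by strain ``xi``, the extracellular field gains
    ``rho_xi(t) + beta_xi*A_int - alpha_xi*A_ext`` and loses ``phi*A_ext``;
    the intracellular field gains ``alpha_xi*A_ext - beta_xi*A_int -
    gamma_xi*A_int``.  The non-producer's production rate is always zero.
    Extracellular decay also acts at empty sites (environmental decay does
    not depend on occupancy) unless ``params.decay_occupied_only`` restores
    the strictly site-gated variant.

    ``rho_B(t)`` honours an ENHANCED_PRODUCTION schedule:
    ``rho_B0 * rho_plus`` while ``t < tau``, ``rho_B0`` afterwards.
    """
    from .protocols import schedule_factors

    _, pm = schedule_factors(schedule, t)
    rho_B_eff = params.rho_B0 * pm

    is_b = occupancy == B
    is_p = occupancy == P
    occupied = is_b | is_p

    d_ext = np.zeros_like(a_ext)
    d_int = np.zeros_like(a_int)

    d_ext[is_b] = (rho_B_eff + params.beta_B * a_int[is_b]
                   - params.alpha_B * a_ext[is_b])
    d_ext[is_p] = params.beta_P * a_int[is_p] - params.alpha_P * a_ext[is_p]
    if params.decay_occupied_only:
        d_ext[occupied] -= params.phi * a_ext[occupied]
    else:
        d_ext -= params.phi * a_ext

    d_int[is_b] = (params.alpha_B * a_ext[is_b]
                   - (params.beta_B + params.gamma_B) * a_int[is_b])
    d_int[is_p] = (params.alpha_P * a_ext[is_p]
                   - (params.beta_P + params.gamma_P) * a_int[is_p])
    return d_ext, d_int


def _scratch(state: GridState) -> tuple[np.ndarray, np.ndarray]:
    return np.empty_like(state.a_ext), np.empty_like(state.a_ext)


def run_substeps(state: GridState, params: SimulationParams,
                 schedule: ResourceSchedule | None = None,
                 t: int = 0, n_substeps: int | None = None,
                 scratch: tuple[np.ndarray, np.ndarray] | None = None,
                 ) -> ChemistryStepReport:
    """Advance the fields in place by ``n_substeps`` substeps (default: ``u``).

    This is the engine's batched entry point; :func:`antibiotic_substep` is
    the single-substep convenience wrapper over the same compiled kernel.
    """
    from .protocols import schedule_factors

    if n_substeps is None:
        n_substeps = params.u
    if scratch is None:
        scratch = _scratch(state)
    buf, ext0 = scratch
    _, pm = schedule_factors(schedule, t)
    n_sub = diffusion_substeps_needed(params.D, params.Dt)
    mass_before = float(state.a_ext.sum() + state.a_int.sum())
    clamped = chemistry_kernel(
        state.occupancy, state.a_ext, state.a_int, buf, ext0,
        n_substeps, params.D, params.Dt, n_sub,
        params.rho_B0 * pm, params.alpha_B, params.alpha_P,
        params.beta_B, params.beta_P, params.gamma_B, params.gamma_P,
        params.phi, params.decay_occupied_only,
    )
    state.t_substep += n_substeps
    mass_after = float(state.a_ext.sum() + state.a_int.sum())
    if not np.isfinite(mass_after):
        bad = np.argwhere(~np.isfinite(state.a_ext))
        site = tuple(bad[0]) if len(bad) else tuple(np.argwhere(~np.isfinite(state.a_int))[0])
        raise FloatingPointError(
            f"non-finite antibiotic concentration at site {site} "
            f"(substep {state.t_substep})"
        )
    return ChemistryStepReport(n_sub, mass_before, mass_after, int(clamped))


def antibiotic_substep(state: GridState, params: SimulationParams,
                       schedule: ResourceSchedule | None = None,
                       t: int = 0) -> tuple[GridState, ChemistryStepReport]:
    """Apply exactly one antibiotic substep of length ``Dt`` in place."""
    report = run_substeps(state, params, schedule, t, n_substeps=1)
    return state, report


def clear_intracellular(state: GridState, site: tuple[int, int]) -> GridState:
    """Void the intracellular antibiotic at a vacated or overwritten site.

    Called when an occupant dies or is displaced; a newborn or newly placed
    cell starts with ``A_int = 0``.  The extracellular field is untouched.
    """
    state.a_int[site] = 0.0
    return state
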