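"""Reproduction rates and the stochastic death-birth update.

Reproduction rates:

* producer:      ``r_B = r_B0 * g(t) - c``   (g = private growth boost)
* non-producer:  ``r_P = r_P0 - lambda(a, T, k, A_int)``

where ``lambda`` is a sigmoid dose-response in the cell's intracellular
antibiotic concentration.  Rates are clamped at zero before entering the
selection lottery: a poisoned cell (rate driven negative) can still die but
never reproduces.

Each cellular generation, ``round(eps * N)`` focal sites are drawn uniformly
(with replacement by default).  In draw order: the focal occupant dies, then
the eight Moore neighbours compete to refill the site with probability
proportional to their rates; if none has positive rate, the site stays
empty.  Updates within a generation are sequential (asynchronous), so later
draws see the outcomes of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._kernels import death_birth_kernel
from .params import B, EMPTY, P, GridState, ResourceSchedule, SimulationParams

__all__ = ["POISONED_RATE_THRESHOLD", "RateField", "dosage_effect",
           "reproduction_rate", "effective_b_rate", "selection_probabilities",
           "death_birth_update", "compute_rate_field"]

#: display threshold below which a non-producer counts as "poisoned"
POISONED_RATE_THRESHOLD = 0.05


@dataclass
class RateField:
    """Per-site reproduction rates at one instant (zero at empty sites)."""

    r: np.ndarray
    poisoned_mask: np.ndarray  # P cells with rate below the display threshold


def dosage_effect(a: float, T: float, k: float, A_int) -> np.ndarray | float:
    """Sigmoid growth inhibition ``a / (1 + exp(-k (A_int - T)))``.

    Monotone nondecreasing in ``A_int``; equals ``a/2`` exactly at the
    threshold ``A_int = T``; saturates (never NaN) for large ``|k(A-T)|``.
    Accepts scalars or arrays.
    """
    return a * expit(k * (np.asarray(A_int, dtype=float) - T)) if np.ndim(A_int) \
        else float(a * expit(k * (float(A_int) - T)))


def effective_b_rate(params: SimulationParams,
                     schedule: ResourceSchedule | None = None,
                     t: int = 0) -> float:
    """Producer reproduction rate ``max(r_B0 * g(t) - c, 0)``."""
    from .protocols import schedule_factors

    gm, _ = schedule_factors(schedule, t)
    return max(params.r_B0 * gm - params.c, 0.0)


def reproduction_rate(cell_type: int, A_int: float, params: SimulationParams,
                      schedule: ResourceSchedule | None = None,
                      t: int = 0) -> float:
    """Reproduction rate of a single cell, clamped below at zero."""
    if cell_type == B:
        return effective_b_rate(params, schedule, t)
    if cell_type == P:
        return max(params.r_P0 - dosage_effect(params.a, params.T, params.k, A_int), 0.0)
    return 0.0


def selection_probabilities(neighbour_rates) -> np.ndarray | None:
    """Normalise nonnegative neighbour rates into a probability vector.

    Returns ``None`` when every rate is zero (the no-birth outcome: the
    focal site stays, or becomes, empty).  Negative inputs are a contract
    violation -- clamping happens upstream.
    """
    rates = np.asarray(neighbour_rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("neighbour rates must be nonnegative (clamp upstream)")
    total = rates.sum()
    if total <= 0:
        return None
    return rates / total


def compute_rate_field(state: GridState, params: SimulationParams,
                       schedule: ResourceSchedule | None = None,
                       t: int = 0) -> RateField:
    """Vectorised snapshot of all current reproduction rates."""
    r = np.zeros_like(state.a_ext)
    is_b = state.occupancy == B
    is_p = state.occupancy == P
    r[is_b] = effective_b_rate(params, schedule, t)
    lam = dosage_effect(params.a, params.T, params.k, state.a_int[is_p])
    r[is_p] = np.maximum(params.r_P0 - lam, 0.0)
    poisoned = is_p & (r < POISONED_RATE_THRESHOLD)
    return RateField(r=r, poisoned_mask=poisoned)


def death_birth_update(state: GridState, params: SimulationParams,
                       rng: np.random.Generator,
                       schedule: ResourceSchedule | None = None,
                       t: int = 0, n_generations: int = 1) -> tuple[int, int]:
    """One death-birth generation, in place.  Returns ``(B births, P births)``.

    Focal sites are drawn uniformly from *all* sites (occupied or empty):
    an occupied focal dies and is contested, an empty focal is simply
    contested -- colonisation of empty space happens through the same
    lottery.  Rates are evaluated against the occupancy as updated by
    earlier draws of the same generation; producer rates are constant within
    a generation while non-producer rates follow each cell's current
    ``A_int`` (which chemistry only changes between generations).

    The RNG stream is consumed in a fixed order -- ``n_draws`` focal indices,
    then ``n_draws`` selection uniforms -- for reproducibility.

    ``n_generations > 1`` batches several consecutive generations into one
    compiled call.  This is exact only when nothing outside the death-birth
    process changes between generations (no chemistry, constant schedule);
    it is intended for chemistry-free studies such as drift or pure
    cost-selection experiments.
    """
    n_draws = int(round(params.eps * params.N)) * max(1, int(n_generations))
    if params.draws_with_replacement or n_generations > 1:
        focal = rng.integers(0, params.N, size=n_draws)
    else:
        focal = rng.choice(params.N, size=min(n_draws, params.N), replace=False)
    unif = rng.random(n_draws)
    b_births, p_births = death_birth_kernel(
        state.occupancy, state.a_int,
        focal.astype(np.int64), unif,
        effective_b_rate(params, schedule, t),
        params.r_P0, params.a, params.T, params.k,
    )
    state.generation += max(1, int(n_generations))
    return int(b_births), int(p_births)
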