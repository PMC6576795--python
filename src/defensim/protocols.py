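"""Host-side experimental manipulations: private resources and invasions.

Two invasion experiments probe whether the beneficial strain, once helped,
can hold the habitat on its own:

* **Test 1** (time-limited help): the host supplies a private resource --
  protected space, a growth boost, or a production boost -- until generation
  ``tau``; parasite propagules arrive from generation ``kappa`` on.
* **Test 2** (size-triggered): arrivals are withheld until the beneficial
  colony occupies a ``CSI`` fraction of the habitat; the trigger latches
  once crossed.

An arrival event places ``n_Pt`` parasites as an edge-connected cluster
grown outward from a uniformly chosen focal site, filling empty sites in
preference to overwriting occupied ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import VON_NEUMANN, neighbours
from .params import (B, EMPTY, P, GridState, InvasionProtocol, InvasionTest,
                     ResourceSchedule, ScheduleMode, SimulationParams)

__all__ = ["ArrivalEvent", "schedule_factors", "arrivals_enabled",
           "attempt_invasion", "place_propagule"]


@dataclass
class ArrivalEvent:
    """Record of one parasite propagule placement."""

    time_step: int
    focal_site: tuple[int, int]
    n_placed_on_empty: int = 0
    n_placed_by_overwrite: int = 0
    n_overwritten_B: int = 0
    sites: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return self.n_placed_on_empty + self.n_placed_by_overwrite


def schedule_factors(schedule: ResourceSchedule | None, t: int
                     ) -> tuple[float, float]:
    """(growth multiplier, production multiplier) at generation ``t``.

    ENHANCED_GROWTH multiplies the producer's baseline reproduction rate by
    ``r_plus`` while ``t < tau``; ENHANCED_PRODUCTION multiplies its
    antibiotic production rate by ``rho_plus``.  PROTECTED_GROWTH and NONE
    leave both at 1, and every boost lapses at ``tau``.
    """
    if schedule is None or not schedule.active(t):
        return 1.0, 1.0
    if schedule.mode is ScheduleMode.ENHANCED_GROWTH:
        return schedule.r_plus, 1.0
    if schedule.mode is ScheduleMode.ENHANCED_PRODUCTION:
        return 1.0, schedule.rho_plus
    return 1.0, 1.0


def arrivals_enabled(t: int, n_B: int, params: SimulationParams,
                     protocol: InvasionProtocol,
                     schedule: ResourceSchedule | None = None) -> bool:
    """Whether a parasite propagule may arrive at generation ``t``.

    TEST1: from generation ``kappa``; under full protection
    (PROTECTED_GROWTH with ``s_plus = 1``) effectively from ``tau``, since
    every landing site would be blocked before then.  TEST2: once the
    beneficial colony holds ``round(csi * N)`` sites (and ``t >= kappa``).
    The TEST2 trigger is evaluated against the instantaneous count here;
    the engine latches it permanently on first crossing.
    """
    if protocol.test_id is InvasionTest.TEST2:
        need = int(round((protocol.csi or 0.0) * params.N))
        return t >= protocol.kappa and n_B >= need
    enabled = t >= protocol.kappa
    if (enabled and schedule is not None
            and schedule.mode is ScheduleMode.PROTECTED_GROWTH
            and schedule.active(t) and schedule.s_plus >= 1.0):
        return False  # the whole surface is protected until tau
    return enabled


def place_propagule(state: GridState, n_Pt: int, focal: tuple[int, int],
                    rng: np.random.Generator, t: int,
                    blocked: np.ndarray | None = None,
                    empty_only: bool = False) -> ArrivalEvent:
    """Place up to ``n_Pt`` parasites as a connected cluster around ``focal``.

    The cluster grows greedily from the focal site: at each step one
    edge-neighbour of the already-placed set is colonised, empty frontier
    sites taking strict precedence over occupied ones (which are overwritten
    -- a displaced cell's intracellular antibiotic is voided).  Ties are
    broken uniformly at random, so the cluster is isotropic but fully
    determined by the RNG stream.  Sites in ``blocked`` (a protected host
    region) are skipped; a blocked focal site kills the whole propagule.
    Placed parasites start with ``A_int = 0``.

    With ``empty_only`` (the size-triggered experiment, where parasites
    invade *empty places*) no site is ever overwritten: the propagule dies
    on an occupied focal site, and placement stops early when the connected
    empty region around the focal is exhausted.
    """
    M = state.M
    event = ArrivalEvent(time_step=t, focal_site=focal)
    if n_Pt <= 0:
        return event
    if blocked is not None and blocked[focal]:
        return event  # propagule lands on protected ground and is killed off
    if empty_only and state.occupancy[focal] != EMPTY:
        return event  # no empty place at the landing point

    def occupy(site: tuple[int, int]) -> None:
        prev = state.occupancy[site]
        if prev == EMPTY:
            event.n_placed_on_empty += 1
        else:
            event.n_placed_by_overwrite += 1
            if prev == B:
                event.n_overwritten_B += 1
        state.occupancy[site] = P
        state.a_int[site] = 0.0
        event.sites.append(site)

    occupy(focal)
    placed = {focal}
    frontier_empty: list[tuple[int, int]] = []
    frontier_occ: list[tuple[int, int]] = []
    in_frontier = {focal}

    def extend_frontier(site: tuple[int, int]) -> None:
        for nb in neighbours(site, VON_NEUMANN, M):
            if nb in in_frontier:
                continue
            if blocked is not None and blocked[nb]:
                continue
            in_frontier.add(nb)
            if state.occupancy[nb] == EMPTY:
                frontier_empty.append(nb)
            else:
                frontier_occ.append(nb)

    extend_frontier(focal)
    while event.n_placed < n_Pt:
        if frontier_empty:
            pool = frontier_empty
        elif frontier_occ and not empty_only:
            pool = frontier_occ
        else:
            break  # no colonisable site left adjacent to the cluster
        idx = int(rng.integers(len(pool)))
        site = pool.pop(idx)
        if site in placed:
            continue
        occupy(site)
        placed.add(site)
        extend_frontier(site)
    return event


def attempt_invasion(state: GridState, params: SimulationParams,
                     protocol: InvasionProtocol,
                     schedule: ResourceSchedule | None,
                     t: int, rng: np.random.Generator,
                     enabled: bool | None = None) -> list[ArrivalEvent]:
    """All arrival attempts of one generation.

    The arrival lottery ticks on ``params.arrival_clock``: one Bernoulli(f)
    trial per antibiotic update step (``Binomial(u, f)`` propagules per
    generation; the default) or a single trial per generation.  Each
    successful trial places a propagule of ``n_Pt`` parasites around a
    uniformly chosen focal site; see :func:`place_propagule`.  In the
    size-triggered experiment (TEST2) parasites settle on empty places
    only; in TEST1 crowded rings may be overwritten.  Before ``tau`` in
    PROTECTED_GROWTH mode the protected region is excluded.  Returns the
    events that placed at least one parasite.
    """
    if enabled is None:
        n_B = int(np.count_nonzero(state.occupancy == B))
        enabled = arrivals_enabled(t, n_B, params, protocol, schedule)
    if not enabled:
        return []
    if params.arrival_clock == "substep":
        n_trials = int(rng.binomial(params.u, protocol.f))
    else:
        n_trials = int(rng.random() < protocol.f)
    if n_trials == 0:
        return []
    blocked = None
    if (schedule is not None
            and schedule.mode is ScheduleMode.PROTECTED_GROWTH
            and schedule.active(t)):
        blocked = schedule.protected_mask
    empty_only = protocol.test_id is InvasionTest.TEST2
    events = []
    for _ in range(n_trials):
        focal_flat = int(rng.integers(params.N))
        focal = (focal_flat // params.M, focal_flat % params.M)
        event = place_propagule(state, protocol.n_Pt, focal, rng, t,
                                blocked=blocked, empty_only=empty_only)
        if event.n_placed:
            events.append(event)
    return events
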