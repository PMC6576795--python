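"""Simulation orchestration: the generation loop, termination, outcomes.

One cellular generation comprises, in order:

1. the generation's parasite-arrival attempts (if an invasion protocol is
   active),
2. ``u`` antibiotic substeps advancing the chemical fields,
3. a death-birth sweep over ``round(eps * N)`` focal sites.

Runs terminate when the population is homogeneous, when the beneficial
strain has proven itself invasion-proof (see below), or at
``max_generations``.

Because parasite propagules keep arriving forever when ``f > 0``, a strict
"last parasite gone" criterion would never fire for a colony that repels
every propagule on contact: freshly landed, instantly poisoned cells linger
until they die off.  A win for the producer against ongoing pressure is
therefore declared when, with arrivals enabled and at least one propagule
landed, *no parasite has managed to reproduce* for a full holdout window
(default 500 generations), the private resource has lapsed, and the
producer holds the majority of cells.  A parasite that cannot reproduce
cannot change the verdict -- its cells only dwindle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import run_substeps
from .demography import death_birth_update
from .lattice import place_inoculum
from .params import (B, EMPTY, P, GridState, InvasionProtocol, InvasionTest,
                     Outcome, ResourceSchedule, ScheduleMode, SimulationParams)
from .protocols import ArrivalEvent, arrivals_enabled, attempt_invasion

__all__ = ["SimulationResult", "Setup", "initial_state", "run_simulation",
           "classify_outcome", "TRAJECTORY_COLUMNS"]

#: fixed census column order of the trajectory table
TRAJECTORY_COLUMNS = ("generation", "n_B", "n_P", "n_empty",
                      "mean_A_ext", "mean_A_int_B", "mean_A_int_P")


@dataclass
class Setup:
    """A consistent (params, schedule, protocol) bundle.

    ``protocol`` may be ``None`` for invasion-free runs (pure colony
    growth).  Overriding a parameter rebuilds the schedule and protocol so
    the three stay in sync.
    """

    params: SimulationParams
    schedule: ResourceSchedule | None = None
    protocol: InvasionProtocol | None = None

    @classmethod
    def build(cls, params: SimulationParams,
              mode: ScheduleMode | str = ScheduleMode.NONE,
              test: InvasionTest | str | None = InvasionTest.TEST1) -> "Setup":
        schedule = ResourceSchedule.from_params(params, mode)
        protocol = InvasionProtocol.from_params(params, test) if test is not None else None
        return cls(params, schedule, protocol)

    @property
    def mode(self) -> ScheduleMode:
        return self.schedule.mode if self.schedule is not None else ScheduleMode.NONE

    @property
    def test(self) -> InvasionTest | None:
        return self.protocol.test_id if self.protocol is not None else None

    def with_overrides(self, **changes) -> "Setup":
        """Copy with parameter/mode/test overrides applied consistently."""
        mode = changes.pop("mode", self.mode)
        test = changes.pop("test", self.test)
        params = self.params.replace(**changes) if changes else self.params
        return Setup.build(params, mode, test)


@dataclass
class SimulationResult:
    outcome: Outcome
    trajectory: pd.DataFrame
    state: GridState
    events: list[ArrivalEvent] = field(default_factory=list)

    def __iter__(self):  # allow ``outcome, trajectory = run_simulation(...)``
        return iter((self.outcome, self.trajectory))


def initial_state(params: SimulationParams,
                  rng: np.random.Generator | None = None) -> GridState:
    """Fresh habitat with the ``n_B0`` founder cells and zero antibiotic."""
    state = GridState.empty(params.M)
    place_inoculum(state, params.n_B0, rng=rng,
                   random_placement=params.random_inoculum)
    return state


def classify_outcome(n_B: int, n_P: int, N: int, t: int, *,
                     pressure_ongoing: bool,
                     invasion_proof: bool,
                     at_max_time: bool) -> Outcome | None:
    """Outcome of the run, or ``None`` if it should continue.

    A run ends when the habitat is fully colonised by one strain or the
    verdict can no longer change:

    * producer extinct, parasite present -> parasite wins (the producer
      never re-arrives, so no holdout is needed);
    * parasite absent, no further arrivals possible, habitat fully
      colonised -> producer wins (an uncontested colony keeps growing
      until it has filled the habitat);
    * ``invasion_proof`` (holdout survived under ongoing pressure) ->
      producer wins;
    * at the time bound the winner is the sole surviving strain, or
      UNRESOLVED if both persist.
    """
    fb, fp = n_B / N, n_P / N
    if n_B == 0 and n_P == 0:
        return Outcome("UNRESOLVED", 0.0, 0.0, t, "HOMOGENEOUS")
    if n_B == 0:
        return Outcome("P", fb, fp, t, "HOMOGENEOUS")
    if n_P == 0 and not pressure_ongoing and n_B == N:
        return Outcome("B", fb, fp, t, "HOMOGENEOUS")
    if invasion_proof:
        return Outcome("B", fb, fp, t, "HOMOGENEOUS")
    if at_max_time:
        if n_P == 0:
            return Outcome("B", fb, fp, t, "MAX_TIME")
        return Outcome("UNRESOLVED", fb, fp, t, "MAX_TIME")
    return None


def run_simulation(params: SimulationParams,
                   schedule: ResourceSchedule | None = None,
                   protocol: InvasionProtocol | None = None,
                   rng: np.random.Generator | int | None = None,
                   census_interval: int = 1,
                   ) -> SimulationResult:
    """Run one full simulation.  Deterministic given the seed.

    ``rng`` may be a NumPy generator, an integer seed, or ``None`` (then
    ``params.seed`` is used).  The trajectory table records the census every
    ``census_interval`` generations plus the final generation.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    state = initial_state(params, rng)
    N = params.N
    scratch = (np.empty_like(state.a_ext), np.empty_like(state.a_ext))
    W = params.holdout_window

    rows: list[tuple] = []
    events: list[ArrivalEvent] = []
    n_B, n_P, _ = state.counts()

    enabled_gen: int | None = None   # first generation with arrivals enabled
    last_p_birth = -1                # last generation a parasite reproduced
    any_arrival = False
    outcome: Outcome | None = None

    def census(g: int) -> None:
        occ = state.occupancy
        is_b = occ == B
        is_p = occ == P
        rows.append((
            g, n_B, n_P, N - n_B - n_P,
            float(state.a_ext.mean()),
            float(state.a_int[is_b].mean()) if n_B else 0.0,
            float(state.a_int[is_p].mean()) if n_P else 0.0,
        ))

    census(0)
    pressure = protocol is not None and protocol.f > 0
    for g in range(1, params.max_generations + 1):
        # (1) arrival attempts
        if protocol is not None:
            if enabled_gen is None and arrivals_enabled(g, n_B, params,
                                                        protocol, schedule):
                enabled_gen = g  # latches (TEST2 never re-arms)
            if enabled_gen is not None:
                new_events = attempt_invasion(state, params, protocol,
                                              schedule, g, rng, enabled=True)
                if new_events:
                    events.extend(new_events)
                    any_arrival = True
                    n_B, n_P, _ = state.counts()

        # (2) antibiotic substeps
        run_substeps(state, params, schedule, t=g, scratch=scratch)

        # (3) death-birth sweep
        _, p_births = death_birth_update(state, params, rng, schedule, t=g)
        if p_births:
            last_p_birth = g
        n_B, n_P, _ = state.counts()

        if g % census_interval == 0:
            census(g)

        # termination
        schedule_done = schedule is None or not schedule.active(g)
        invasion_proof = (
            pressure and enabled_gen is not None and any_arrival
            and schedule_done
            and g - enabled_gen >= W
            and g - max(last_p_birth, enabled_gen) >= W
            and n_B > n_P
        )
        # in the size-triggered experiment parasites settle on empty places
        # only, so a fully colonised habitat can never be invaded again
        arrivals_can_land = not (
            protocol is not None
            and protocol.test_id is InvasionTest.TEST2
            and n_B + n_P == N
        )
        outcome = classify_outcome(
            n_B, n_P, N, g,
            pressure_ongoing=pressure and arrivals_can_land,
            invasion_proof=invasion_proof,
            at_max_time=(g == params.max_generations),
        )
        if outcome is not None:
            if rows[-1][0] != g:
                census(g)
            break

    assert outcome is not None
    trajectory = pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS))
    return SimulationResult(outcome, trajectory, state, events)
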