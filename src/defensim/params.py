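"""Core domain types: parameters, lattice state, schedules, protocols, outcomes.

The model describes two bacterial strains competing for space on the surface
of a host, discretised as an ``M x M`` toroidal lattice:

* ``B`` -- the *beneficial* strain: produces an antibiotic (at a growth cost
  ``c``) and is resistant to it.
* ``P`` -- the *parasitic* strain: grows faster (pays no cost) but is
  sensitive to the antibiotic.

The antibiotic lives in two scalar fields, an extracellular concentration
``A_ext`` that diffuses over the lattice and an intracellular concentration
``A_int`` carried by each occupied site.  All model constants are collected
in :class:`SimulationParams`; host-side interventions (private resources,
invasion protocols) are described by :class:`ResourceSchedule` and
:class:`InvasionProtocol`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace
from enum import Enum

import numpy as np

__all__ = [
    "EMPTY",
    "B",
    "P",
    "ScheduleMode",
    "InvasionTest",
    "ConfigurationError",
    "SimulationParams",
    "GridState",
    "ResourceSchedule",
    "InvasionProtocol",
    "Outcome",
]

# occupancy codes (int8 lattice values)
EMPTY: int = 0
B: int = 1
P: int = 2


class ConfigurationError(ValueError):
    """Raised when a parameter set or configuration file is invalid."""


class ScheduleMode(str, Enum):
    """How the host privileges the beneficial strain before time ``tau``."""

    NONE = "NONE"
    PROTECTED_GROWTH = "PROTECTED_GROWTH"
    ENHANCED_GROWTH = "ENHANCED_GROWTH"
    ENHANCED_PRODUCTION = "ENHANCED_PRODUCTION"


class InvasionTest(str, Enum):
    """Which signal ends the private-resource phase / gates parasite arrival.

    TEST1 uses elapsed time (arrivals start at ``kappa``; private resource
    lapses at ``tau``).  TEST2 uses the size of the beneficial colony
    (arrivals start once occupancy reaches the CSI fraction).
    """

    TEST1 = "TEST1"
    TEST2 = "TEST2"


@dataclass
class SimulationParams:
    """Complete parameterisation of the lattice model.

    Rates are per unit model time; one antibiotic substep advances the
    chemistry by ``Dt`` and one cellular generation comprises ``u`` substeps,
    so ``Dt * u`` model time elapses per generation.  The spatial resolution
    is fixed at one lattice cell (``Dx = 1``) and is not tunable.

    Attributes
    ----------
    M:
        lattice side length; the habitat has ``N = M * M`` sites.
    Dt:
        time resolution of one antibiotic substep.
    u:
        antibiotic substeps per cellular generation.
    eps:
        fraction of sites (``eps * N`` draws) updated per generation in the
        death-birth process.
    D:
        antibiotic diffusion rate (lattice-cell^2 per unit time).
    rho_B0:
        baseline antibiotic production (export) rate of B.
    rho_plus:
        production amplification while the resource is private
        (ENHANCED_PRODUCTION mode): effective production is
        ``rho_plus * rho_B0`` for ``t < tau``.  1 means no boost.
    alpha_B, alpha_P:
        antibiotic uptake rates.
    beta_B, beta_P:
        antibiotic efflux rates (efflux resistance re-exports internalised
        antibiotic back into the environment).
    gamma_B, gamma_P:
        intracellular decomposition rates.
    phi:
        extracellular decay rate.
    r_B0, r_P0:
        baseline reproduction rates.
    c:
        reproduction-rate cost of antibiotic production and resistance,
        subtracted from B's rate.
    r_plus:
        growth amplification while private (ENHANCED_GROWTH mode): B's
        baseline becomes ``r_plus * r_B0`` for ``t < tau``.  1 = no boost.
    a, T, k:
        dosage-effect parameters: maximum effect, intracellular threshold,
        and steepness of the sigmoid growth inhibition of P.
    n_B0:
        initial beneficial-colony size (founder cells).
    n_Pt:
        parasite propagule size (individuals placed per arrival event).
    f:
        arrival probability per generation.
    kappa:
        first generation at which arrivals may occur.
    tau:
        generation at which the private resource expires.
    s_plus:
        protected fraction of the habitat (PROTECTED_GROWTH mode),
        ``s_plus = ss / N`` with ``ss`` protected sites.
    CSI:
        colony-size-at-invasion fraction ``q / N`` gating arrivals in TEST2.
    max_generations:
        hard bound on the number of cellular generations.
    seed:
        RNG seed used when no generator is supplied explicitly.
    holdout_window:
        generations of sustained invasion pressure that the beneficial
        strain must survive, after its last observed competitive setback,
        before a win against an ongoing arrival process is declared.
    decay_occupied_only:
        if True, extracellular decay ``-phi * A_ext`` acts only at occupied
        sites (the strictly site-gated reading of the discretised reaction
        term); by default decay acts everywhere, since environmental decay
        cannot plausibly depend on occupancy.
    draws_with_replacement:
        whether the ``eps * N`` focal sites of a generation are drawn with
        replacement (default) or without.
    random_inoculum:
        place the ``n_B0`` founders uniformly at random instead of as a
        compact patch at the grid centre.
    kappa_in_substeps:
        interpret ``kappa`` (and ``tau``) on the antibiotic-substep clock
        instead of the generation clock.  Off by default; all times are
        measured in cellular generations.
    arrival_clock:
        clock on which the per-``f`` arrival lottery ticks.  ``"substep"``
        (default): one Bernoulli(f) trial per antibiotic update step, i.e.
        Binomial(u, f) propagules per generation -- the literal reading of
        an arrival probability per update step when ``u`` update steps
        elapse per generation.  ``"generation"``: a single Bernoulli(f)
        trial per generation (much sparser invasion pressure).
    """

    M: int = 100
    Dt: float = 0.1
    u: int = 100
    eps: float = 0.01
    D: float = 5.0

    rho_B0: float = 1.0
    rho_plus: float = 1.0
    alpha_B: float = 0.5
    alpha_P: float = 0.5
    beta_B: float = 0.0
    beta_P: float = 0.0
    gamma_B: float = 0.4
    gamma_P: float = 0.4
    phi: float = 0.3

    r_B0: float = 0.8
    r_P0: float = 0.8
    c: float = 0.1
    r_plus: float = 1.0

    a: float = 1.0
    T: float = 1.0
    k: float = 25.0

    n_B0: int = 100
    n_Pt: int = 10
    f: float = 0.01
    kappa: int = 1
    tau: int = 0
    s_plus: float = 0.0
    CSI: float = 0.0

    max_generations: int = 100_000
    seed: int = 0

    # numerical / bookkeeping switches (documented model decisions)
    holdout_window: int = 500
    decay_occupied_only: bool = False
    draws_with_replacement: bool = True
    random_inoculum: bool = False
    kappa_in_substeps: bool = False
    arrival_clock: str = "substep"

    #: spatial resolution -- one lattice cell; fixed, not a tunable.
    Dx: float = field(default=1.0, init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def N(self) -> int:
        """Number of lattice sites."""
        return self.M * self.M

    @property
    def time_per_generation(self) -> float:
        """Model time elapsed per cellular generation (``Dt * u``)."""
        return self.Dt * self.u

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check ranges; raise :class:`ConfigurationError` on violation.

        Biologically *expected* orderings (``alpha_B <= alpha_P``,
        ``gamma_B <= gamma_P``, ``beta_B >= beta_P``) are not enforced --
        violating them only triggers a warning, since exploring them is a
        legitimate use of the model.
        """
        if not isinstance(self.M, (int, np.integer)) or self.M < 3:
            raise ConfigurationError(f"M must be an integer >= 3, got {self.M!r}")
        if not self.Dt > 0:
            raise ConfigurationError(f"Dt must be > 0, got {self.Dt!r}")
        if not isinstance(self.u, (int, np.integer)) or self.u < 1:
            raise ConfigurationError(f"u must be an integer >= 1, got {self.u!r}")
        if not 0 < self.eps <= 1:
            raise ConfigurationError(f"eps must lie in (0, 1], got {self.eps!r}")
        for name in (
            "D", "rho_B0", "alpha_B", "alpha_P", "beta_B", "beta_P",
            "gamma_B", "gamma_P", "phi", "r_B0", "r_P0", "c", "a", "k",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be a finite rate >= 0, got {v!r}")
        for name in ("s_plus", "CSI", "f"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("n_B0", "n_Pt", "kappa", "tau", "max_generations", "holdout_window"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")
        if self.n_B0 > self.N:
            raise ConfigurationError(
                f"n_B0 = {self.n_B0} exceeds the number of sites N = {self.N}"
            )
        if self.alpha_B > self.alpha_P:
            warnings.warn("alpha_B > alpha_P: producer takes up antibiotic faster "
                          "than the sensitive strain (unusual)", stacklevel=2)
        if self.gamma_B > self.gamma_P:
            warnings.warn("gamma_B > gamma_P is the decomposition-resistance regime; "
                          "the default expectation is gamma_B <= gamma_P", stacklevel=2)
        if self.beta_B < self.beta_P:
            warnings.warn("beta_B < beta_P: the non-producer has the higher efflux "
                          "rate (unusual)", stacklevel=2)
        for name in ("r_plus", "rho_plus"):
            v = getattr(self, name)
            if v < 1:
                warnings.warn(f"{name} = {v} < 1: the private resource is a handicap, "
                              "not an advantage", stacklevel=2)
        if self.arrival_clock not in ("substep", "generation"):
            raise ConfigurationError(
                f"arrival_clock must be 'substep' or 'generation', "
                f"got {self.arrival_clock!r}")

    def replace(self, **changes) -> "SimulationParams":
        """Return a validated copy with ``changes`` applied."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls) if f.init)


@dataclass
class GridState:
    """Snapshot of the lattice at one instant.

    ``occupancy`` holds {EMPTY, B, P} codes; ``a_ext``/``a_int`` are the
    extracellular and intracellular antibiotic concentration fields.
    ``a_int`` is pinned to zero at empty sites; ``a_ext`` is defined
    everywhere (antibiotic persists and diffuses over vacant surface).
    """

    occupancy: np.ndarray
    a_ext: np.ndarray
    a_int: np.ndarray
    t_substep: int = 0
    generation: int = 0

    @classmethod
    def empty(cls, M: int) -> "GridState":
        return cls(
            occupancy=np.zeros((M, M), dtype=np.int8),
            a_ext=np.zeros((M, M), dtype=np.float64),
            a_int=np.zeros((M, M), dtype=np.float64),
        )

    @property
    def M(self) -> int:
        return self.occupancy.shape[0]

    def counts(self) -> tuple[int, int, int]:
        """Return ``(n_B, n_P, n_empty)``."""
        n_b = int(np.count_nonzero(self.occupancy == B))
        n_p = int(np.count_nonzero(self.occupancy == P))
        return n_b, n_p, self.occupancy.size - n_b - n_p

    def copy(self) -> "GridState":
        return GridState(
            self.occupancy.copy(), self.a_ext.copy(), self.a_int.copy(),
            self.t_substep, self.generation,
        )

    def check(self) -> None:
        """Assert the state invariants (nonnegative fields, A_int gating)."""
        if self.occupancy.shape != self.a_ext.shape or self.a_ext.shape != self.a_int.shape:
            raise ValueError("field shapes disagree")
        if not np.isfinite(self.a_ext).all() or not np.isfinite(self.a_int).all():
            raise ValueError("non-finite concentration values")
        if (self.a_ext < 0).any() or (self.a_int < 0).any():
            raise ValueError("negative concentration values")
        if (self.a_int[self.occupancy == EMPTY] != 0).any():
            raise ValueError("A_int nonzero at an empty site")


@dataclass
class ResourceSchedule:
    """The host's private-resource policy.

    One of four modes, active until generation ``tau``:

    * ``PROTECTED_GROWTH`` -- parasites cannot settle inside a cohesive
      region of ``round(s_plus * N)`` sites (``protected_mask``).
    * ``ENHANCED_GROWTH`` -- B's baseline reproduction rate is multiplied
      by ``r_plus``.
    * ``ENHANCED_PRODUCTION`` -- B's antibiotic production rate is
      multiplied by ``rho_plus``.
    * ``NONE`` -- no intervention.

    After ``tau`` the resource is public: all boosts drop to 1 and the mask
    is inert.
    """

    mode: ScheduleMode = ScheduleMode.NONE
    tau: int = 0
    s_plus: float = 0.0
    r_plus: float = 1.0
    rho_plus: float = 1.0
    protected_mask: np.ndarray | None = None

    @classmethod
    def from_params(cls, params: SimulationParams,
                    mode: ScheduleMode | str = ScheduleMode.NONE,
                    anchor: tuple[int, int] | None = None) -> "ResourceSchedule":
        """Build a schedule consistent with ``params``.

        The protected region (PROTECTED_GROWTH only) is a deterministic
        quasi-disc grown around ``anchor`` (default: the grid centre, where
        the founder colony is placed).
        """
        from .lattice import build_protected_mask

        mode = ScheduleMode(mode)
        mask = None
        if mode is ScheduleMode.PROTECTED_GROWTH:
            if anchor is None:
                anchor = (params.M // 2, params.M // 2)
            mask = build_protected_mask(params.s_plus, params.M, anchor)
        return cls(mode=mode, tau=params.tau, s_plus=params.s_plus,
                   r_plus=params.r_plus, rho_plus=params.rho_plus,
                   protected_mask=mask)

    def active(self, t: int) -> bool:
        """Whether the private resource is still being supplied at time ``t``."""
        return self.mode is not ScheduleMode.NONE and t < self.tau


@dataclass
class InvasionProtocol:
    """Parasite arrival process and its gating.

    Propagules of ``n_Pt`` individuals arrive with probability ``f`` per
    generation.  In TEST1 arrivals start at generation ``kappa``; in TEST2
    they start once the beneficial colony holds ``csi * N`` sites (and
    ``t >= kappa``), and the trigger latches permanently once crossed.
    """

    test_id: InvasionTest = InvasionTest.TEST1
    f: float = 0.0
    n_Pt: int = 10
    kappa: int = 1
    csi: float | None = None

    @classmethod
    def from_params(cls, params: SimulationParams,
                    test_id: InvasionTest | str = InvasionTest.TEST1) -> "InvasionProtocol":
        test_id = InvasionTest(test_id)
        return cls(test_id=test_id, f=params.f, n_Pt=params.n_Pt,
                   kappa=params.kappa,
                   csi=params.CSI if test_id is InvasionTest.TEST2 else None)


@dataclass
class Outcome:
    """Verdict of one simulation run.

    ``winner`` is ``"B"`` or ``"P"`` when one strain holds the habitat at
    termination and the other is extinct (or, for B under an ongoing arrival
    process, reduced to moribund transients that have not reproduced for a
    full holdout window), else ``"UNRESOLVED"``.
    """

    winner: str
    final_B_fraction: float
    final_P_fraction: float
    generations_elapsed: int
    reason: str  # "HOMOGENEOUS" | "MAX_TIME"

    @property
    def b_wins(self) -> bool:
        return self.winner == "B"
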