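"""Experiment layer: replicate batches, 2-D parameter sweeps, MSC estimation.

Phase diagrams are built by sweeping two named parameters over a full
factorial grid and recording, per cell, the frequency of producer wins over
replicate runs.  "Mixed" colours in such diagrams are replicate-frequency
mixtures, not within-run coexistence; unresolved runs are tallied
separately.

The Minimal Sustainable Colony size (MSC) at a given diffusion rate is the
smallest colony-size-at-invasion (CSI) fraction at which the producer wins
the majority of replicates of the size-triggered invasion experiment.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Setup, run_simulation
from .params import Outcome

__all__ = ["SweepResult", "MSCEstimate", "replicate_seed", "run_replicates",
           "sweep", "estimate_msc", "SENTINEL_NONE"]

#: returned as ``msc`` when no CSI up to 1 lets the producer win
SENTINEL_NONE: float = float("nan")


def replicate_seed(master_seed: int, *indices: int) -> np.random.Generator:
    """Independent generator for one (cell, replicate) of an experiment.

    Counter-based: the master seed and the index tuple feed a
    ``SeedSequence`` spawn key, so any cell of any sweep can be re-run in
    isolation and no RNG state is shared between runs.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=tuple(int(i) for i in indices))
    return np.random.default_rng(ss)


@dataclass
class SweepResult:
    """Outcome frequencies over a 2-D parameter grid."""

    axis1_name: str
    axis1_values: tuple
    axis2_name: str
    axis2_values: tuple
    win_fraction: np.ndarray          # producer-win frequency, shape (len1, len2)
    unresolved_fraction: np.ndarray   # same shape
    n_replicates: int
    outcomes: pd.DataFrame            # per-replicate records
    preset: str = ""

    def to_table(self) -> pd.DataFrame:
        """Long-format table (one row per replicate run)."""
        return self.outcomes.copy()


@dataclass
class MSCEstimate:
    """Bracketed estimate of the minimal sustainable colony size."""

    D: float
    msc: float                        # CSI fraction, or SENTINEL_NONE (nan)
    bracket: tuple[float | None, float | None]  # (largest failing, smallest passing)
    n_replicates: int
    win_frequency: dict[float, float] = field(default_factory=dict)

    @property
    def found(self) -> bool:
        return not np.isnan(self.msc)


def run_replicates(setup: Setup, n_replicates: int, master_seed: int,
                   cell_index: tuple[int, ...] = (),
                   census_interval: int = 50,
                   majority_early_stop: bool = False,
                   ) -> list[Outcome]:
    """Run independent replicates of one configuration.

    With ``majority_early_stop`` the batch stops as soon as either verdict
    (producer win / not) already holds a strict majority of
    ``n_replicates`` -- the remaining runs cannot change a majority-vote
    summary.
    """
    outcomes: list[Outcome] = []
    wins = 0
    need = n_replicates // 2 + 1
    for rep in range(n_replicates):
        rng = replicate_seed(master_seed, *cell_index, rep)
        result = run_simulation(setup.params, setup.schedule, setup.protocol,
                                rng=rng, census_interval=census_interval)
        outcomes.append(result.outcome)
        wins += result.outcome.b_wins
        if majority_early_stop:
            losses = len(outcomes) - wins
            if wins >= need or losses >= need:
                break
    return outcomes


def _config_key(setup: Setup, extra: dict) -> str:
    payload = {"params": {k: getattr(setup.params, k)
                          for k in setup.params.field_names()},
               "mode": setup.mode.value,
               "test": setup.test.value if setup.test else None,
               **extra}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def sweep(setup: Setup,
          axis1: tuple[str, "np.typing.ArrayLike"],
          axis2: tuple[str, "np.typing.ArrayLike"],
          n_replicates: int = 3,
          master_seed: int = 0,
          census_interval: int = 200,
          cache_dir: str | Path | None = None,
          preset: str = "") -> SweepResult:
    """Full-factorial 2-D sweep with independent per-(cell, replicate) seeds.

    Axis names must be overridable fields of the setup (any
    ``SimulationParams`` field, or ``mode`` / ``test``).  With ``cache_dir``
    each grid cell's outcomes are cached on disk keyed by a configuration
    hash, making interrupted sweeps resumable.
    """
    name1, values1 = axis1
    name2, values2 = axis2
    values1 = tuple(np.asarray(values1).tolist())
    values2 = tuple(np.asarray(values2).tolist())
    for name in (name1, name2):
        if name not in setup.params.field_names() and name not in ("mode", "test"):
            raise KeyError(f"unknown sweep axis: {name!r}")

    win = np.zeros((len(values1), len(values2)))
    unres = np.zeros_like(win)
    records = []
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)

    for i, v1 in enumerate(values1):
        for j, v2 in enumerate(values2):
            cell = setup.with_overrides(**{name1: v1, name2: v2})
            cell_outcomes: list[Outcome] | None = None
            cache_file = None
            if cache is not None:
                key = _config_key(cell, {"seed": master_seed, "reps": n_replicates,
                                         "cell": (i, j)})
                cache_file = cache / f"{key}.json"
                if cache_file.exists():
                    raw = json.loads(cache_file.read_text())
                    cell_outcomes = [Outcome(**o) for o in raw]
            if cell_outcomes is None:
                cell_outcomes = run_replicates(cell, n_replicates, master_seed,
                                               cell_index=(i, j),
                                               census_interval=census_interval)
                if cache_file is not None:
                    cache_file.write_text(json.dumps([vars(o) for o in cell_outcomes]))
            n = len(cell_outcomes)
            win[i, j] = sum(o.b_wins for o in cell_outcomes) / n
            unres[i, j] = sum(o.winner == "UNRESOLVED" for o in cell_outcomes) / n
            for rep, o in enumerate(cell_outcomes):
                records.append((v1, v2, rep, o.winner, o.generations_elapsed,
                                o.final_B_fraction, o.final_P_fraction, o.reason))

    outcomes = pd.DataFrame(records, columns=[name1, name2, "replicate", "winner",
                                              "generations", "final_B_fraction",
                                              "final_P_fraction", "reason"])
    return SweepResult(name1, values1, name2, values2, win, unres,
                       n_replicates, outcomes, preset)


def estimate_msc(setup: Setup, D: float, csi_values,
                 n_replicates: int = 3, master_seed: int = 0,
                 threshold: float = 0.5, refine_steps: int = 0,
                 early_stop: bool = True) -> MSCEstimate:
    """Estimate the MSC at diffusion rate ``D``.

    Runs the size-triggered invasion experiment (TEST2) at each CSI in
    ascending order and returns the smallest CSI whose producer-win
    frequency is at least ``threshold`` (majority by default).  Assuming
    the win frequency is monotone in CSI (the community-bistability
    property), the scan stops at the first passing value and, with
    ``refine_steps > 0``, bisects between the bracket endpoints.  If the win
    frequencies observed along the way decrease beyond what replicate noise
    allows, a warning is emitted and the full ascending scan is used
    instead.
    """
    import warnings

    csi_values = sorted(float(x) for x in csi_values)
    if list(csi_values) != sorted(csi_values):
        raise ValueError("csi_values must be sorted ascending")
    base = setup.with_overrides(D=float(D), test="TEST2")

    freq: dict[float, float] = {}
    last_fail: float | None = None
    first_pass: float | None = None

    def win_freq(csi: float, idx: int) -> float:
        cell = base.with_overrides(CSI=csi)
        outs = run_replicates(cell, n_replicates, master_seed,
                              cell_index=(idx,), majority_early_stop=early_stop)
        return sum(o.b_wins for o in outs) / len(outs)

    for idx, csi in enumerate(csi_values):
        w = freq[csi] = win_freq(csi, idx)
        if w >= threshold:
            first_pass = csi
            break
        last_fail = csi

    # monotonicity sanity: a pass followed (in the precomputed list) by a fail
    # cannot be detected with early stopping; with early_stop=False, rescan.
    if not early_stop and first_pass is not None:
        later = [c for c in csi_values if c > first_pass]
        for idx, csi in enumerate(later, start=len(freq)):
            freq[csi] = win_freq(csi, idx)
        drops = [c for c in later if freq[c] < threshold]
        if drops:
            warnings.warn("win frequency is non-monotone in CSI beyond noise; "
                          "falling back to exhaustive scan", stacklevel=2)
            passing = [c for c in csi_values if freq[c] >= threshold]
            first_pass = passing[0] if passing else None
            below = [c for c in csi_values if c < (first_pass or 2.0)]
            last_fail = below[-1] if below else None

    for step in range(refine_steps):
        if first_pass is None or last_fail is None:
            break
        mid = 0.5 * (last_fail + first_pass)
        w = freq[mid] = win_freq(mid, 1000 + step)
        if w >= threshold:
            first_pass = mid
        else:
            last_fail = mid

    msc = first_pass if first_pass is not None else SENTINEL_NONE
    return MSCEstimate(D=float(D), msc=msc, bracket=(last_fail, first_pass),
                       n_replicates=n_replicates, win_frequency=freq)
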