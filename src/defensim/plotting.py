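"""Rendering of lattice snapshots, trajectories, and phase diagrams.

Colour semantics of spatial snapshots: producers yellow, parasites black,
poisoned parasites (reproduction rate below 0.05) dark grey, empty surface
white; the
extracellular antibiotic field runs white (zero) through orange-red
(intermediate) to brown-black (maximal).
"""

from __future__ import annotations

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, ListedColormap

from .demography import POISONED_RATE_THRESHOLD, compute_rate_field
from .params import B, EMPTY, P, GridState, ResourceSchedule, SimulationParams

__all__ = ["render_snapshot", "plot_trajectory", "plot_phase_diagram",
           "save_field_text", "load_field_text"]

#: occupancy panel colours: empty, producer, parasite, poisoned parasite
_OCC_COLORS = ["#ffffff", "#f5c400", "#000000", "#555555"]
_FIELD_CMAP = LinearSegmentedColormap.from_list(
    "antibiotic", ["#ffffff", "#ff8c1a", "#d43500", "#5c1a00", "#140500"])


def render_snapshot(state: GridState, params: SimulationParams,
                    schedule: ResourceSchedule | None = None,
                    t: int = 0, vmax: float | None = None):
    """Two-panel figure: occupancy (with poisoned parasites) and ``A_ext``.

    Returns the matplotlib figure; the caller saves or displays it.
    """
    rate_field = compute_rate_field(state, params, schedule, t)
    display = np.zeros_like(state.occupancy, dtype=np.int8)
    display[state.occupancy == B] = 1
    display[state.occupancy == P] = 2
    display[rate_field.poisoned_mask] = 3

    fig, (ax_occ, ax_field) = plt.subplots(1, 2, figsize=(9, 4.4))
    ax_occ.imshow(display, cmap=ListedColormap(_OCC_COLORS), vmin=0, vmax=3,
                  interpolation="nearest")
    ax_occ.set_title(f"occupancy (gen {state.generation})")
    im = ax_field.imshow(state.a_ext, cmap=_FIELD_CMAP, vmin=0.0, vmax=vmax,
                         interpolation="nearest")
    ax_field.set_title("extracellular antibiotic")
    fig.colorbar(im, ax=ax_field, shrink=0.8)
    for ax in (ax_occ, ax_field):
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    return fig


def plot_trajectory(trajectory, params: SimulationParams | None = None):
    """Census time series: strain counts and mean antibiotic levels."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5.5), sharex=True)
    ax1.plot(trajectory["generation"], trajectory["n_B"],
             color="#f5c400", label="producer (B)")
    ax1.plot(trajectory["generation"], trajectory["n_P"],
             color="black", label="parasite (P)")
    ax1.set_ylabel("cells")
    ax1.legend(frameon=False)
    ax2.plot(trajectory["generation"], trajectory["mean_A_ext"],
             color="#d43500", label="mean $A^{ext}$")
    ax2.plot(trajectory["generation"], trajectory["mean_A_int_P"],
             color="#555555", label="mean $A^{int}$ (P)")
    ax2.set_xlabel("generation")
    ax2.set_ylabel("concentration")
    ax2.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_phase_diagram(result, threshold: float = 0.5):
    """Producer-win-frequency heatmap of a 2-D sweep.

    Yellow marks cells where the producer wins the majority of replicates,
    black where the parasite does, intermediate oranges mixed outcomes.
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = LinearSegmentedColormap.from_list(
        "winfreq", ["#000000", "#d43500", "#ff8c1a", "#f5c400"])
    im = ax.imshow(result.win_fraction.T, origin="lower", cmap=cmap,
                   vmin=0.0, vmax=1.0, aspect="auto",
                   extent=(-0.5, len(result.axis1_values) - 0.5,
                           -0.5, len(result.axis2_values) - 0.5))
    ax.set_xticks(range(len(result.axis1_values)),
                  [f"{v:g}" for v in result.axis1_values])
    ax.set_yticks(range(len(result.axis2_values)),
                  [f"{v:g}" for v in result.axis2_values])
    ax.set_xlabel(result.axis1_name)
    ax.set_ylabel(result.axis2_name)
    fig.colorbar(im, ax=ax, label="producer win frequency")
    fig.tight_layout()
    return fig


def save_field_text(field: np.ndarray, path) -> None:
    """Write a field as delimited text, one row per lattice row.

    Uses full round-trip precision so ``load_field_text`` restores the
    array bit-exactly.
    """
    np.savetxt(path, field, fmt="%.17g", delimiter="\t")


def load_field_text(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
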