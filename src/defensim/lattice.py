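"""Toroidal lattice geometry: neighbourhoods, compact regions, inoculation.

The habitat is an ``M x M`` grid with periodic (toroidal) boundaries in both
axes.  Sites are addressed 0-based, row-major, as ``(row, col)`` coordinates
or as flat indices ``row * M + col``.
"""

from __future__ import annotations

import numpy as np

from .params import B, GridState, ConfigurationError

__all__ = ["VON_NEUMANN", "MOORE", "neighbours", "build_protected_mask",
           "quasi_disc", "place_inoculum", "is_edge_connected"]

VON_NEUMANN = "VON_NEUMANN"
MOORE = "MOORE"

_VN_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
_MOORE_OFFSETS = ((-1, -1), (-1, 0), (-1, 1),
                  (0, -1), (0, 1),
                  (1, -1), (1, 0), (1, 1))


def neighbours(i: int | tuple[int, int], kind: str, M: int) -> list[tuple[int, int]]:
    """Neighbours of site ``i`` under toroidal wrap-around.

    ``kind`` selects the von Neumann neighbourhood (4 sites: N/S/E/W, used by
    the diffusion stencil) or the Moore neighbourhood (8 sites, used by the
    death-birth reproduction competition).  ``i`` may be a flat index or a
    ``(row, col)`` pair.
    """
    if M < 3:
        raise ConfigurationError(f"M must be >= 3, got {M}")
    if kind == VON_NEUMANN:
        offsets = _VN_OFFSETS
    elif kind == MOORE:
        offsets = _MOORE_OFFSETS
    else:
        raise ConfigurationError(f"unknown neighbourhood kind: {kind!r}")
    if isinstance(i, (int, np.integer)):
        if not 0 <= i < M * M:
            raise ConfigurationError(f"site index {i} out of range for M={M}")
        r, c = divmod(int(i), M)
    else:
        r, c = int(i[0]) % M, int(i[1]) % M
    return [((r + dr) % M, (c + dc) % M) for dr, dc in offsets]


def quasi_disc(n_sites: int, M: int, anchor: tuple[int, int]) -> np.ndarray:
    """Deterministic compact patch of ``n_sites`` sites around ``anchor``.

    Sites are added in rings of increasing Chebyshev radius; within a ring,
    in order of increasing Euclidean (torus) distance from the anchor, ties
    broken by (row, col) offset.  Any prefix of this ordering is
    edge-connected, so the patch approximates a disc and is usable both for
    the protected host region and for founder-colony placement.

    Returns a boolean ``M x M`` mask.
    """
    mask = np.zeros((M, M), dtype=bool)
    if n_sites <= 0:
        return mask
    n_sites = min(n_sites, M * M)
    ar, ac = int(anchor[0]) % M, int(anchor[1]) % M
    placed = 0
    radius = 0
    max_radius = (M + 1) // 2
    while placed < n_sites and radius <= max_radius:
        ring = []
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if max(abs(dr), abs(dc)) != radius:
                    continue
                # torus distance components
                tr = min(abs(dr), M - abs(dr))
                tc = min(abs(dc), M - abs(dc))
                ring.append((tr * tr + tc * tc, dr, dc))
        ring.sort()
        for _, dr, dc in ring:
            r, c = (ar + dr) % M, (ac + dc) % M
            if not mask[r, c]:
                mask[r, c] = True
                placed += 1
                if placed == n_sites:
                    break
        radius += 1
    return mask


def build_protected_mask(s_plus: float, M: int, anchor: tuple[int, int]) -> np.ndarray:
    """Cohesive protected region of ``round(s_plus * M * M)`` sites.

    Deterministic given ``(s_plus, M, anchor)``.  ``s_plus = 0`` yields an
    empty mask, ``s_plus = 1`` the full grid.
    """
    if not 0 <= s_plus <= 1:
        raise ConfigurationError(f"s_plus must lie in [0, 1], got {s_plus}")
    n_sites = int(round(s_plus * M * M))
    return quasi_disc(n_sites, M, anchor)


def place_inoculum(state: GridState, n_B0: int,
                   rng: np.random.Generator | None = None,
                   random_placement: bool = False,
                   anchor: tuple[int, int] | None = None) -> GridState:
    """Seed ``n_B0`` beneficial founder cells.

    By default the founders form a compact quasi-disc at the grid centre
    (a single founding colony).  With ``random_placement`` they are strewn
    uniformly without replacement, for sensitivity checks.
    """
    M = state.M
    if random_placement:
        if rng is None:
            raise ValueError("random placement requires an rng")
        flat = rng.choice(M * M, size=n_B0, replace=False)
        state.occupancy.flat[flat] = B
    else:
        if anchor is None:
            anchor = (M // 2, M // 2)
        state.occupancy[quasi_disc(n_B0, M, anchor)] = B
    return state


def is_edge_connected(sites: set[tuple[int, int]] | np.ndarray, M: int) -> bool:
    """Whether a site set is connected under von Neumann (edge) adjacency."""
    if isinstance(sites, np.ndarray):
        sites = {(int(r), int(c)) for r, c in zip(*np.nonzero(sites))}
    if not sites:
        return True
    stack = [next(iter(sites))]
    seen = {stack[0]}
    while stack:
        site = stack.pop()
        for nb in neighbours(site, VON_NEUMANN, M):
            if nb in sites and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(sites)
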