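"""Numba-compiled inner loops for the chemistry and death-birth updates.

These kernels are the performance core; every numerical decision they embody
(update order, subcycling, clamping) is mirrored one-to-one by the plain
NumPy/Python reference implementations in :mod:`defensim.chemistry` and
:mod:`defensim.demography`, which the test suite holds them against.

All randomness is injected from outside as pre-drawn arrays so that the
kernels are pure functions of their inputs and the single NumPy generator
owned by the engine defines the reproducible random stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["diffusion_substeps_needed", "chemistry_kernel", "death_birth_kernel"]


def diffusion_substeps_needed(D: float, dt: float) -> int:
    """Number of diffusion micro-steps per substep for explicit stability.

    The forward-Euler five-point stencil on a unit lattice is stable for
    ``D * dt <= 1/4``; above that bound the diffusion operator is subcycled
    into ``ceil(4 * D * dt)`` equal fractional steps.
    """
    if D * dt <= 0.25:
        return 1
    return int(np.ceil(4.0 * D * dt))


@njit(cache=True)
def chemistry_kernel(occ, a_ext, a_int, buf, ext0,
                     n_substeps, D, dt, n_sub,
                     rho_B_eff, alpha_B, alpha_P, beta_B, beta_P,
                     gamma_B, gamma_P, phi, decay_occupied_only):
    """Advance the antibiotic fields by ``n_substeps`` substeps of length dt.

    Per substep: (1) the diffusion operator is applied to the extracellular
    field, subcycled into ``n_sub`` Jacobi micro-steps of length
    ``dt / n_sub``; (2) the reaction terms (production, efflux, uptake,
    decomposition, extracellular decay) are evaluated on the
    start-of-substep fields and applied once with weight ``dt``.  Both
    stages read from frozen copies, so the result is independent of site
    visitation order.  Negative concentrations produced by an over-large
    reaction step are clamped to zero and counted.

    ``buf`` and ``ext0`` are caller-provided scratch arrays (same shape as
    ``a_ext``).  ``occ``, ``a_ext`` and ``a_int`` are updated in place.
    Returns the number of clamped sites.
    """
    M = occ.shape[0]
    coef = D * (dt / n_sub)
    clamped = 0
    for _step in range(n_substeps):
        # freeze start-of-substep extracellular field for the reaction stage
        for i in range(M):
            for j in range(M):
                ext0[i, j] = a_ext[i, j]
        # diffusion: n_sub Jacobi micro-steps
        for _s in range(n_sub):
            for i in range(M):
                im = M - 1 if i == 0 else i - 1
                ip = 0 if i == M - 1 else i + 1
                for j in range(M):
                    jm = M - 1 if j == 0 else j - 1
                    jp = 0 if j == M - 1 else j + 1
                    lap = (a_ext[im, j] + a_ext[ip, j]
                           + a_ext[i, jm] + a_ext[i, jp]
                           - 4.0 * a_ext[i, j])
                    buf[i, j] = a_ext[i, j] + coef * lap
            for i in range(M):
                for j in range(M):
                    a_ext[i, j] = buf[i, j]
        # reaction: evaluated on the frozen start-of-substep fields
        for i in range(M):
            for j in range(M):
                o = occ[i, j]
                e0 = ext0[i, j]
                if o == 1:  # producer B
                    i0 = a_int[i, j]
                    d_ext = rho_B_eff + beta_B * i0 - alpha_B * e0 - phi * e0
                    d_int = alpha_B * e0 - beta_B * i0 - gamma_B * i0
                elif o == 2:  # non-producer P
                    i0 = a_int[i, j]
                    d_ext = beta_P * i0 - alpha_P * e0 - phi * e0
                    d_int = alpha_P * e0 - beta_P * i0 - gamma_P * i0
                else:
                    d_int = 0.0
                    d_ext = 0.0 if decay_occupied_only else -phi * e0
                ne = a_ext[i, j] + d_ext * dt
                ni = a_int[i, j] + d_int * dt
                if ne < 0.0:
                    ne = 0.0
                    clamped += 1
                if ni < 0.0:
                    ni = 0.0
                    clamped += 1
                a_ext[i, j] = ne
                a_int[i, j] = ni
    return clamped


@njit(cache=True)
def death_birth_kernel(occ, a_int, focal_idx, unif,
                       r_B_eff, r_P0, a, T, k):
    """One death-birth generation over pre-drawn focal sites.

    For each flat index in ``focal_idx``, in sequence: the occupant (if any)
    dies and its intracellular antibiotic is voided; then the eight Moore
    neighbours compete to refill the site with probability proportional to
    their current reproduction rates (clamped at zero), evaluated against
    the occupancy as already updated earlier this generation.  If no
    neighbour has positive rate the site stays empty.  Newborns inherit type
    only and start with ``A_int = 0``.

    ``unif`` supplies one uniform variate per focal draw for the roulette
    selection.  Returns ``(b_births, p_births)``.
    """
    M = occ.shape[0]
    b_births = 0
    p_births = 0
    rates = np.empty(8, dtype=np.float64)
    types = np.empty(8, dtype=np.int8)
    for n in range(focal_idx.shape[0]):
        fi = focal_idx[n]
        i = fi // M
        j = fi % M
        # death of the focal occupant
        occ[i, j] = 0
        a_int[i, j] = 0.0
        # gather Moore-neighbour reproduction rates
        total = 0.0
        q = 0
        for di in range(-1, 2):
            ii = (i + di) % M
            for dj in range(-1, 2):
                if di == 0 and dj == 0:
                    continue
                jj = (j + dj) % M
                o = occ[ii, jj]
                if o == 1:
                    rr = r_B_eff
                elif o == 2:
                    z = k * (a_int[ii, jj] - T)
                    if z > 60.0:
                        lam = a
                    elif z < -60.0:
                        lam = 0.0
                    else:
                        lam = a / (1.0 + np.exp(-z))
                    rr = r_P0 - lam
                    if rr < 0.0:
                        rr = 0.0
                else:
                    rr = 0.0
                rates[q] = rr
                types[q] = o
                total += rr
                q += 1
        if total <= 0.0:
            continue  # no birth: the site stays empty
        x = unif[n] * total
        acc = 0.0
        chosen = -1
        for q in range(8):
            if rates[q] <= 0.0:
                continue
            acc += rates[q]
            chosen = q
            if x < acc:
                break
        occ[i, j] = types[chosen]
        # a_int[i, j] is already 0 -- newborns carry no antibiotic
        if types[chosen] == 1:
            b_births += 1
        else:
            p_births += 1
    return b_births, p_births
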