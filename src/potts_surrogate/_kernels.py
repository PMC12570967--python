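"""Numba kernels for the Metropolis pixel-copy dynamics.

The incremental energy change of a copy attempt and the per-MCS sweep are
compiled with numba; randomness is pre-drawn outside the kernels from a
seeded numpy generator so that trajectories are pure functions of the seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Neighbour offsets. The first four entries are the von Neumann
# neighbourhood, so OFFSETS_8[:4] is the 4-neighbourhood.
OFFSETS_8 = np.array(
    [(-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1)],
    dtype=np.int64,
)


def offsets_for(neighborhood: int) -> np.ndarray:
    if neighborhood == 4:
        return OFFSETS_8[:4]
    if neighborhood == 8:
        return OFFSETS_8
    raise ValueError("neighborhood must be 4 or 8")


@njit(cache=False)
def delta_h_core(
    cell_id, volumes, surfaces,
    sx, sy, dx, dy,
    j_cm, j_cc, lam_v, v_t, lam_s, s_t,
    contact_offsets,
):
    """Incremental ΔH (contact + volume + surface) if the destination voxel
    (dx, dy) adopts the id of the source voxel (sx, sy)."""
    n = cell_id.shape[0]
    s_id = cell_id[sx, sy]
    d_id = cell_id[dx, dy]

    dh = 0.0
    same_s = 0  # contact-neighbourhood sites of dest already holding s_id
    same_d = 0  # ... holding d_id
    n_off = contact_offsets.shape[0]
    for k in range(n_off):
        nx = (dx + contact_offsets[k, 0]) % n
        ny = (dy + contact_offsets[k, 1]) % n
        nid = cell_id[nx, ny]
        # contact term: J(tau_a, tau_b) * (1 - delta_ab)
        if nid != d_id:
            dh -= j_cm if (nid == 0 or d_id == 0) else j_cc
        if nid != s_id:
            dh += j_cm if (nid == 0 or s_id == 0) else j_cc
        if nid == s_id:
            same_s += 1
        if nid == d_id:
            same_d += 1

    if s_id != 0:
        v = volumes[s_id]
        dh += lam_v * ((v + 1 - v_t) ** 2 - (v - v_t) ** 2)
        s = surfaces[s_id]
        ds = (n_off - same_s) - same_s
        dh += lam_s * ((s + ds - s_t) ** 2 - (s - s_t) ** 2)
    if d_id != 0:
        v = volumes[d_id]
        dh += lam_v * ((v - 1 - v_t) ** 2 - (v - v_t) ** 2)
        s = surfaces[d_id]
        ds = same_d - (n_off - same_d)
        dh += lam_s * ((s + ds - s_t) ** 2 - (s - s_t) ** 2)
    return dh


@njit(cache=False)
def chemotaxis_delta(conc, sx, sy, dx, dy, lam_chem, sat):
    """Saturating chemotaxis contribution to ΔH for a copy attempt:
    -λ_chem [ c(dest)/(s c(dest)+1) - c(src)/(s c(src)+1) ]."""
    cd = conc[dx, dy]
    cs = conc[sx, sy]
    return -lam_chem * (cd / (sat * cd + 1.0) - cs / (sat * cs + 1.0))


@njit(cache=False)
def sweep(
    cell_id, volumes, surfaces, conc,
    rx, ry, nk, ru,
    j_cm, j_cc, lam_v, v_t, lam_s, s_t, lam_chem, sat, temp,
    contact_offsets, copy_offsets,
):
    """One Monte-Carlo step: ``len(rx)`` copy attempts with pre-drawn
    randomness. Updates lattice and bookkeeping in place; returns the
    number of accepted copies."""
    n = cell_id.shape[0]
    n_off = contact_offsets.shape[0]
    accepted = 0
    for a in range(rx.shape[0]):
        sx = rx[a]
        sy = ry[a]
        off = copy_offsets[nk[a]]
        dx = (sx + off[0]) % n
        dy = (sy + off[1]) % n
        s_id = cell_id[sx, sy]
        d_id = cell_id[dx, dy]
        if s_id == d_id:
            continue
        dh = delta_h_core(
            cell_id, volumes, surfaces, sx, sy, dx, dy,
            j_cm, j_cc, lam_v, v_t, lam_s, s_t, contact_offsets,
        )
        dh += chemotaxis_delta(conc, sx, sy, dx, dy, lam_chem, sat)
        if dh > 0.0 and ru[a] >= np.exp(-dh / temp):
            continue
        # accepted: flip the destination voxel and patch the bookkeeping
        same_s = 0
        same_d = 0
        for k in range(n_off):
            nid = cell_id[(dx + contact_offsets[k, 0]) % n,
                          (dy + contact_offsets[k, 1]) % n]
            if nid == s_id:
                same_s += 1
            if nid == d_id:
                same_d += 1
        cell_id[dx, dy] = s_id
        volumes[s_id] += 1  # index 0 tracks the medium voxel count
        volumes[d_id] -= 1
        if s_id != 0:
            surfaces[s_id] += (n_off - same_s) - same_s
        if d_id != 0:
            surfaces[d_id] += same_d - (n_off - same_d)
        accepted += 1
    return accepted
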