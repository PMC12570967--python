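"""Effective energy of the Cellular-Potts model.

The Hamiltonian has contact, volume-constraint and surface-constraint
terms evaluated on the whole configuration, plus a per-attempt saturating
chemotaxis bias that exists only as an energy *change* of a pixel copy
(it is not a state function and is therefore excluded from
:func:`total_energy`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._kernels import offsets_for
from .diffusion import DiffusionField
from .lattice import LatticeState
from .params import CPMParams

__all__ = ["CopyAttempt", "total_energy", "delta_h", "acceptance_probability"]


@dataclass(frozen=True)
class CopyAttempt:
    """A pixel-copy attempt: the destination voxel adopts the source id."""

    source: tuple[int, int]
    destination: tuple[int, int]

    def validate(self, params: CPMParams) -> None:
        L = params.lattice_size
        sx, sy = self.source
        dx, dy = self.destination
        if (sx % L, sy % L) == (dx % L, dy % L):
            raise ValueError("source and destination must differ")
        offs = {tuple(o) for o in offsets_for(params.copy_neighborhood)}
        d = ((dx - sx + L // 2) % L - L // 2, (dy - sy + L // 2) % L - L // 2)
        if d not in offs:
            raise ValueError(
                f"destination is not a copy-neighbourhood neighbour of source: {d}"
            )


def total_energy(state: LatticeState, field: DiffusionField | None,
                 params: CPMParams) -> float:
    """Contact + volume + surface energy of the configuration, evaluated
    from scratch (chemotaxis is per-attempt and excluded)."""
    cid = state.cell_id
    offs = offsets_for(params.contact_neighborhood)
    contact = 0.0
    for k in range(len(offs) // 2):
        di, dj = offs[2 * k + 1]
        b = np.roll(cid, shift=(-di, -dj), axis=(0, 1))
        diff = cid != b
        cm = diff & ((cid == 0) | (b == 0))
        contact += params.j_cell_medium * np.count_nonzero(cm)
        contact += params.j_cell_cell * np.count_nonzero(diff & ~cm)

    from .lattice import recount_surfaces, recount_volumes

    vols = recount_volumes(cid)
    surfs = recount_surfaces(cid, params.contact_neighborhood)
    live = np.flatnonzero(vols[1:] > 0) + 1
    vol_term = params.lambda_volume * np.sum((vols[live] - params.v_target) ** 2)
    surf_term = params.lambda_surface * np.sum((surfs[live] - params.s_target) ** 2)
    return float(contact + vol_term + surf_term)


def delta_h(state: LatticeState, field: DiffusionField,
            attempt: CopyAttempt, params: CPMParams,
            include_chemotaxis: bool = True) -> float:
    """Incremental energy change if the attempt is applied.

    Requires source and destination ids to differ (same-id attempts are
    no-ops and must be skipped upstream).
    """
    attempt.validate(params)
    L = params.lattice_size
    sx, sy = (attempt.source[0] % L, attempt.source[1] % L)
    dx, dy = (attempt.destination[0] % L, attempt.destination[1] % L)
    if state.cell_id[sx, sy] == state.cell_id[dx, dy]:
        raise ValueError("source and destination hold the same id (no-op attempt)")
    dh = float(_kernels.delta_h_core(
        state.cell_id, state.volumes, state.surfaces,
        sx, sy, dx, dy,
        params.j_cell_medium, params.j_cell_cell,
        params.lambda_volume, params.v_target,
        params.lambda_surface, params.s_target,
        offsets_for(params.contact_neighborhood),
    ))
    if include_chemotaxis:
        dh += float(_kernels.chemotaxis_delta(
            field.conc, sx, sy, dx, dy,
            params.lambda_chemotaxis, params.saturation,
        ))
    return dh


def acceptance_probability(dh: float, temperature: float) -> float:
    """Boltzmann acceptance Pr = exp(-max(0, ΔH / H'))."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return float(np.exp(-max(0.0, dh / temperature)))
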