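"""Diffusive cytokine field: ∂c/∂t = D ∇²c − k c + secretion.

Forward-Euler with a 5-point periodic Laplacian, operator-split per
sub-step as diffuse → decay → secrete. The multiplicative decay keeps the
field non-negative whenever the diffusion CFL condition holds and makes
uniform-field decay exactly (1 − k·dt)^n. Secretion adds
``secretion_rate·dt`` at every voxel occupied by a cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CPMParams

__all__ = ["DiffusionField", "diffusion_step", "laplacian_periodic"]


@dataclass
class DiffusionField:
    """Non-negative 2-D concentration array, same shape as the lattice."""

    conc: np.ndarray

    @classmethod
    def zeros(cls, lattice_size: int) -> "DiffusionField":
        return cls(conc=np.zeros((lattice_size, lattice_size), dtype=np.float64))

    def total(self) -> float:
        return float(self.conc.sum())

    def copy(self) -> "DiffusionField":
        return DiffusionField(conc=self.conc.copy())


def laplacian_periodic(c: np.ndarray) -> np.ndarray:
    return (np.roll(c, 1, axis=0) + np.roll(c, -1, axis=0)
            + np.roll(c, 1, axis=1) + np.roll(c, -1, axis=1) - 4.0 * c)


def diffusion_step(field: DiffusionField, state, params: CPMParams,
                   n_substeps: int | None = None) -> DiffusionField:
    """Advance the field by one MCS of model time (``pde_steps_per_mcs``
    Euler sub-steps; stability is enforced at parameter construction)."""
    dt = params.dt
    steps = params.pde_steps_per_mcs if n_substeps is None else n_substeps
    c = field.conc
    occupied = None
    if params.secretion_rate > 0.0:
        occupied = (state.cell_id != 0).astype(np.float64)
    for _ in range(steps):
        c = c + params.diffusion_d * dt * laplacian_periodic(c)
        if params.decay_k > 0.0:
            c = c * (1.0 - params.decay_k * dt)
        if occupied is not None:
            c = c + params.secretion_rate * dt * occupied
    field.conc = c
    return field
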