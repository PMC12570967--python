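"""Model parameters for the Cellular-Potts vasculogenesis simulator.

A single :class:`CPMParams` instance holds every coupling of the effective
energy (contact, volume, surface, chemotaxis), the Potts temperature, and
the reaction--diffusion constants of the cytokine field, for one point of
the parameter space (one "class" of the surrogate).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["CPMParams"]


@dataclass(frozen=True)
class CPMParams:
    """Parameters of the vasculogenesis Cellular-Potts model.

    Defaults are the baseline (t0) parameterisation of the model: a stiff
    volume constraint around 50-voxel cells, weak surface constraint,
    adhesive cell-cell contacts, and strong saturating chemotaxis toward a
    self-secreted diffusive cytokine.

    Parameters
    ----------
    lambda_volume : float
        Stiffness of the quadratic volume constraint (energy / voxel^2).
    v_target : float
        Target volume per cell, in voxels.
    lambda_surface : float
        Stiffness of the quadratic surface (circumference) constraint.
    s_target : float
        Target boundary length per cell, in lattice faces.
    j_cell_medium : float
        Contact energy per face at cell-medium interfaces.
    j_cell_cell : float
        Contact energy per face at cell-cell interfaces.
    lambda_chemotaxis : float
        Strength of the saturating chemotaxis bias.
    saturation : float
        Saturation constant ``s``; the chemotaxis potential at
        concentration ``c`` is ``c / (s*c + 1)``.
    decay_k : float
        First-order decay constant of the cytokine field (1 / MCS).
    diffusion_d : float
        Diffusion constant of the cytokine field (voxel^2 / MCS).
    secretion_rate : float
        Concentration added per MCS at every cell-occupied voxel.
    temperature : float
        Boltzmann temperature H' of the Metropolis acceptance rule.
    lattice_size : int
        Side length of the square periodic lattice, in voxels.
    pde_steps_per_mcs : int
        Forward-Euler sub-steps of the diffusion solver per MCS
        (``dt = 1 / pde_steps_per_mcs``).
    contact_neighborhood : int
        4 (von Neumann) or 8 (Moore); used for both the contact-energy sum
        and the surface (boundary-face) count.
    copy_neighborhood : int
        4 or 8; candidate neighbours for pixel-copy attempts.
    """

    lambda_volume: float = 5.0
    v_target: float = 50.0
    lambda_surface: float = 1.0
    s_target: float = 16.8
    j_cell_medium: float = 8.2
    j_cell_cell: float = 6.0
    lambda_chemotaxis: float = 2000.0
    saturation: float = 0.5
    decay_k: float = 0.6
    diffusion_d: float = 1.0
    secretion_rate: float = 0.1
    temperature: float = 8.0
    lattice_size: int = 256
    pde_steps_per_mcs: int = 4
    contact_neighborhood: int = 4
    copy_neighborhood: int = 8

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lattice_size < 8:
            raise ValueError("lattice_size must be >= 8")
        for name in ("lambda_volume", "lambda_surface", "lambda_chemotaxis",
                     "saturation", "decay_k", "diffusion_d", "secretion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pde_steps_per_mcs < 1:
            raise ValueError("pde_steps_per_mcs must be >= 1")
        if self.contact_neighborhood not in (4, 8):
            raise ValueError("contact_neighborhood must be 4 or 8")
        if self.copy_neighborhood not in (4, 8):
            raise ValueError("copy_neighborhood must be 4 or 8")
        # explicit forward-Euler stability on the unit lattice (dx = 1)
        dt = 1.0 / self.pde_steps_per_mcs
        if self.diffusion_d * dt > 0.25:
            raise ValueError(
                f"diffusion unstable: D*dt = {self.diffusion_d * dt:.3g} > 0.25; "
                "increase pde_steps_per_mcs"
            )
        if self.decay_k * dt > 1.0:
            raise ValueError("decay unstable: k*dt > 1; increase pde_steps_per_mcs")

    @property
    def dt(self) -> float:
        """Diffusion sub-step in MCS units."""
        return 1.0 / self.pde_steps_per_mcs

    def replace(self, **changes: Any) -> "CPMParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CPMParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CPM parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "CPMParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
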