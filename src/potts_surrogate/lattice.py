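"""Lattice state and initialisation for the Cellular-Potts model.

The lattice is a square periodic array of cell ids (0 = medium). Volumes
and surfaces are kept incrementally during simulation; :func:`recount_volumes`
and :func:`recount_surfaces` recompute them from scratch and are the
bookkeeping oracle used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import offsets_for
from .params import CPMParams

__all__ = [
    "LatticeState",
    "init_lattice",
    "recount_volumes",
    "recount_surfaces",
]


@dataclass
class LatticeState:
    """Cell-id lattice plus incremental per-cell bookkeeping.

    ``volumes[i]`` / ``surfaces[i]`` are indexed by cell id (entry 0, the
    medium, is unused). Ids whose volume has dropped to zero are dead and
    are omitted from :meth:`volume_map`.
    """

    cell_id: np.ndarray
    volumes: np.ndarray
    surfaces: np.ndarray
    rng: np.random.Generator
    mcs: int = 0
    params: CPMParams = field(default_factory=CPMParams)

    def volume_map(self) -> dict[int, int]:
        """Mapping cell id -> voxel count for live cells."""
        return {int(i): int(v) for i, v in enumerate(self.volumes)
                if i > 0 and v > 0}

    def surface_map(self) -> dict[int, int]:
        return {int(i): int(self.surfaces[i]) for i in self.volume_map()}

    def n_cells(self) -> int:
        return int(np.count_nonzero(self.volumes[1:] > 0))

    def binary_image(self) -> np.ndarray:
        """Foreground mask of the cell layer (True where any cell sits)."""
        return self.cell_id != 0

    def copy(self) -> "LatticeState":
        import copy as _copy
        return LatticeState(
            cell_id=self.cell_id.copy(),
            volumes=self.volumes.copy(),
            surfaces=self.surfaces.copy(),
            rng=_copy.deepcopy(self.rng),
            mcs=self.mcs,
            params=self.params,
        )


def recount_volumes(cell_id: np.ndarray, max_id: int | None = None) -> np.ndarray:
    if max_id is None:
        max_id = int(cell_id.max(initial=0))
    return np.bincount(cell_id.ravel(), minlength=max_id + 1).astype(np.int64)


def recount_surfaces(cell_id: np.ndarray, neighborhood: int = 4,
                     max_id: int | None = None) -> np.ndarray:
    """Boundary faces per cell: neighbour pairs (under the configured
    neighbourhood, periodic) whose two sides hold different ids. A face
    between two distinct cells counts toward both."""
    if max_id is None:
        max_id = int(cell_id.max(initial=0))
    counts = np.zeros(max_id + 1, dtype=np.int64)
    offs = offsets_for(neighborhood)
    # each unordered pair once: half of the symmetric offset set
    for k in range(len(offs) // 2):
        di, dj = offs[2 * k + 1]  # (1,0), (0,1), and for Moore (-1,1),(1,1)
        b = np.roll(cell_id, shift=(-di, -dj), axis=(0, 1))
        mask = cell_id != b
        counts += np.bincount(cell_id[mask], minlength=max_id + 1)
        counts += np.bincount(b[mask], minlength=max_id + 1)
    counts[0] = 0
    return counts


def init_lattice(params: CPMParams, n_cells: int, seed: int) -> LatticeState:
    """Seed ``n_cells`` square blobs of ~``v_target`` voxels at random
    non-overlapping positions on the periodic lattice.

    Blob side is ``round(sqrt(v_target))``; anchors are drawn as a random
    subset of a blob-spaced grid (with a random global offset), which keeps
    placement collision-free at any admissible density. Burn-in erases the
    seed geometry.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    L = params.lattice_size
    if n_cells * params.v_target > L * L:
        raise ValueError("over-dense initialization: n_cells * v_target exceeds lattice area")
    side = max(1, round(float(np.sqrt(params.v_target))))
    per_axis = L // side
    if n_cells > per_axis * per_axis:
        # anchor grid too coarse for this packing: tighten the spacing and
        # shrink the seed blobs; the volume constraint re-grows them toward
        # v_target during burn-in
        spacing = L // int(np.ceil(np.sqrt(n_cells)))
        side = min(side, spacing)
        per_axis = L // side if side > 0 else 0
    if side < 1 or n_cells > per_axis * per_axis:
        raise ValueError(
            f"over-dense initialization: cannot place {n_cells} blobs "
            f"on a {L}x{L} lattice"
        )
    rng = np.random.default_rng(seed)
    anchors = rng.choice(per_axis * per_axis, size=n_cells, replace=False)
    ox, oy = rng.integers(0, L, size=2)
    cell_id = np.zeros((L, L), dtype=np.int64)
    for cid, a in enumerate(anchors, start=1):
        ax = (int(a) // per_axis) * side + int(ox)
        ay = (int(a) % per_axis) * side + int(oy)
        ix = (np.arange(ax, ax + side) % L)[:, None]
        iy = (np.arange(ay, ay + side) % L)[None, :]
        cell_id[ix, iy] = cid
    volumes = recount_volumes(cell_id, max_id=n_cells)
    surfaces = recount_surfaces(cell_id, params.contact_neighborhood, max_id=n_cells)
    return LatticeState(cell_id=cell_id, volumes=volumes, surfaces=surfaces,
                        rng=rng, mcs=0, params=params)
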