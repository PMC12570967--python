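"""Training-data protocol for the surrogate.

A shared burn-in configuration (t0) is fanned out across a grid of
(J_cell,medium, k) parameter pairs — the 25 "classes" of the surrogate —
and binary snapshots of the cell layer are saved on a fixed MCS schedule
for every replicate. At full scale this yields 25 classes x 100
replicates x 51 snapshots = 127 500 labelled images (5100 per class).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .params import CPMParams

__all__ = [
    "GRID_J_VALUES",
    "GRID_K_VALUES",
    "ParameterGrid",
    "build_param_grid",
    "snapshot_schedule",
    "SnapshotDataset",
    "generate_t0",
    "generate_dataset",
    "plan_dataset",
    "full_protocol",
    "toy_protocol",
]

GRID_J_VALUES = (0.0, 5.0, 10.0, 15.0, 20.0)
GRID_K_VALUES = (0.05, 0.1875, 0.325, 0.465, 0.6)

MANIFEST_COLUMNS = ["path", "class_index", "j_value", "k_value", "replicate", "mcs"]


@dataclass(frozen=True)
class ParameterGrid:
    """Cartesian grid over (J_cell,medium, decay k); class indexing is
    row-major over (j, k)."""

    base: CPMParams
    j_values: tuple[float, ...] = GRID_J_VALUES
    k_values: tuple[float, ...] = GRID_K_VALUES

    @property
    def n_classes(self) -> int:
        return len(self.j_values) * len(self.k_values)

    def class_to_jk(self, class_index: int) -> tuple[float, float]:
        nk = len(self.k_values)
        if not 0 <= class_index < self.n_classes:
            raise IndexError(f"class_index {class_index} out of range")
        return self.j_values[class_index // nk], self.k_values[class_index % nk]

    def jk_to_class(self, j: float, k: float) -> int:
        return self.j_values.index(j) * len(self.k_values) + self.k_values.index(k)

    def params_for(self, class_index: int) -> CPMParams:
        j, k = self.class_to_jk(class_index)
        return self.base.replace(j_cell_medium=j, decay_k=k)

    @property
    def param_sets(self) -> list[CPMParams]:
        return [self.params_for(i) for i in range(self.n_classes)]


def build_param_grid(base: CPMParams,
                     j_values: tuple[float, ...] = GRID_J_VALUES,
                     k_values: tuple[float, ...] = GRID_K_VALUES) -> ParameterGrid:
    """Parameter sets differing from ``base`` only in J_cell,medium and k."""
    return ParameterGrid(base=base, j_values=tuple(j_values), k_values=tuple(k_values))


def snapshot_schedule(start_mcs: int, end_mcs: int, interval: int) -> list[int]:
    """Stamps ``start, start+interval, ...`` up to and including the largest
    value <= ``end_mcs``; empty when start > end."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if start_mcs > end_mcs:
        return []
    return list(range(start_mcs, end_mcs + 1, interval))


@dataclass
class SnapshotDataset:
    """Labelled binary snapshots with class / replicate / MCS bookkeeping."""

    images: list = dc_field(default_factory=list)
    labels: list = dc_field(default_factory=list)
    replicates: list = dc_field(default_factory=list)
    mcs_stamps: list = dc_field(default_factory=list)
    paths: list = dc_field(default_factory=list)
    jk: list = dc_field(default_factory=list)
    final_state: object = None
    final_field: object = None

    def __len__(self) -> int:
        return len(self.images)

    def append(self, image: np.ndarray, label: int, replicate: int, mcs: int,
               path: str = "", jk: tuple[float, float] = (np.nan, np.nan)) -> None:
        img = np.asarray(image)
        if not np.isin(img, (0, 1)).all():
            raise ValueError("snapshot images must be binary (0/1)")
        self.images.append(img.astype(np.uint8))
        self.labels.append(int(label))
        self.replicates.append(int(replicate))
        self.mcs_stamps.append(int(mcs))
        self.paths.append(path)
        self.jk.append(jk)

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "path": self.paths,
            "class_index": self.labels,
            "j_value": [j for j, _ in self.jk],
            "k_value": [k for _, k in self.jk],
            "replicate": self.replicates,
            "mcs": self.mcs_stamps,
        }, columns=MANIFEST_COLUMNS)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, H, W) uint8 image stack and (N,) int label vector."""
        return np.stack(self.images), np.asarray(self.labels, dtype=np.int64)


def _snapshot_path(class_index: int, replicate: int, mcs: int) -> str:
    return f"class_{class_index:02d}/rep_{replicate:03d}/mcs_{mcs:06d}.png"


def save_png(image: np.ndarray, path: str | Path) -> None:
    """8-bit grayscale PNG, foreground (cell) = 255, medium = 0."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(image) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= 128).astype(np.uint8)


def generate_t0(base: CPMParams, n_cells: int, burn_in_mcs: int, seed: int,
                out_path: str | Path | None = None):
    """Burn the base-parameter model in for ``burn_in_mcs`` MCS and return
    (state, field); optionally persist the reusable t0 checkpoint."""
    from .lattice import init_lattice
    from .diffusion import DiffusionField
    from .simulate import continue_simulation, save_checkpoint

    if burn_in_mcs < 0:
        raise ValueError("burn_in_mcs must be >= 0")
    state = init_lattice(base, n_cells, seed)
    field = DiffusionField.zeros(base.lattice_size)
    continue_simulation(state, field, burn_in_mcs, None, base)
    if out_path is not None:
        save_checkpoint(out_path, state, field)
    return state, field


def replicate_seed(base_seed: int, class_index: int, replicate: int) -> int:
    """Collision-free replicate seeding: base + class*10^6 + replicate."""
    return int(base_seed) + class_index * 10**6 + replicate


def plan_dataset(grid: ParameterGrid, n_replicates: int,
                 schedule: list[int], out_dir: str = "dataset") -> pd.DataFrame:
    """Dry-run manifest: identical rows to :func:`generate_dataset`'s,
    without running any simulation."""
    rows = []
    for c in range(grid.n_classes):
        j, k = grid.class_to_jk(c)
        for r in range(n_replicates):
            for mcs in schedule:
                rows.append((str(Path(out_dir) / _snapshot_path(c, r, mcs)),
                             c, j, k, r, mcs))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def generate_dataset(grid: ParameterGrid, t0, n_replicates: int,
                     schedule: list[int], base_seed: int,
                     out_dir: str | Path | None = None,
                     shared_t0: bool = True) -> SnapshotDataset:
    """Fan the shared t0 state out across the grid.

    For every (class, replicate) pair the t0 configuration is resumed under
    the class parameters with a distinct seed and run to ``max(schedule)``,
    saving binary snapshots at each scheduled MCS. ``t0`` is either a
    checkpoint path or a ``(state, field)`` pair.
    """
    from .simulate import continue_simulation, load_checkpoint

    if not schedule:
        raise ValueError("schedule must be non-empty")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if not out_dir.is_dir():
            raise OSError(f"cannot write to {out_dir}")

    if isinstance(t0, (str, Path)):
        t0_state, t0_field = load_checkpoint(t0)
    else:
        t0_state, t0_field = t0

    ds = SnapshotDataset()
    end = max(schedule)
    for c in range(grid.n_classes):
        cparams = grid.params_for(c)
        j, k = grid.class_to_jk(c)
        for r in range(n_replicates):
            seed = replicate_seed(base_seed, c, r)
            if shared_t0:
                state = t0_state.copy()
                field = t0_field.copy()
            else:
                from .lattice import init_lattice
                from .diffusion import DiffusionField
                state = init_lattice(cparams, t0_state.n_cells(), seed)
                field = DiffusionField.zeros(cparams.lattice_size)
            state.params = cparams
            state.rng = np.random.default_rng(seed)
            snaps = continue_simulation(state, field, end, schedule, cparams)
            for mcs, img in snaps:
                rel = _snapshot_path(c, r, mcs)
                if out_dir is not None:
                    save_png(img, out_dir / rel)
                    rel = str(out_dir / rel)
                ds.append(img, label=c, replicate=r, mcs=mcs, path=rel, jk=(j, k))
    return ds


def full_protocol() -> dict:
    """Full-scale protocol: 256^2 lattice, ~1000 cells, 10 000-MCS burn-in,
    5x5 grid, snapshots every 100 MCS in [15 000, 20 001], 100 replicates."""
    base = CPMParams()
    return {
        "base": base,
        "n_cells": 1000,
        "burn_in_mcs": 10_000,
        "grid": build_param_grid(base),
        "n_replicates": 100,
        "schedule": snapshot_schedule(15_000, 20_001, 100),
    }


def toy_protocol() -> dict:
    """Desk-scale preset: 64^2 lattice, 60 cells, 2x2 grid (J in {0, 20},
    k in {0.05, 0.6}), burn-in 1000, snapshots every 100 MCS in
    [1500, 2001], 5 replicates. Same code paths, minutes on one CPU."""
    base = CPMParams(lattice_size=64)
    return {
        "base": base,
        "n_cells": 60,
        "burn_in_mcs": 1000,
        "grid": build_param_grid(base, j_values=(0.0, 20.0), k_values=(0.05, 0.6)),
        "n_replicates": 5,
        "schedule": snapshot_schedule(1500, 2001, 100),
    }
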