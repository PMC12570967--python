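"""Monte-Carlo driver: interleaved Potts sweeps and PDE updates, plus a
deterministic single-file checkpoint format."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import _kernels
from ._kernels import offsets_for
from .diffusion import DiffusionField, diffusion_step
from .lattice import LatticeState, init_lattice
from .params import CPMParams

__all__ = [
    "monte_carlo_step",
    "run_simulation",
    "continue_simulation",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_MAGIC = b"POTTS-CKPT v1\n"


def monte_carlo_step(state: LatticeState, field: DiffusionField,
                     params: CPMParams | None = None) -> LatticeState:
    """One MCS: ``lattice_size**2`` pixel-copy attempts (one per site on
    average), Metropolis-accepted at temperature H'. Bookkeeping is updated
    incrementally; ids that reach volume 0 simply drop out of the live set.
    """
    if params is None:
        params = state.params
    L = params.lattice_size
    n_attempts = L * L
    copy_offs = offsets_for(params.copy_neighborhood)
    rng = state.rng
    rx = rng.integers(0, L, size=n_attempts)
    ry = rng.integers(0, L, size=n_attempts)
    nk = rng.integers(0, len(copy_offs), size=n_attempts)
    ru = rng.random(n_attempts)
    _kernels.sweep(
        state.cell_id, state.volumes, state.surfaces, field.conc,
        rx, ry, nk, ru,
        params.j_cell_medium, params.j_cell_cell,
        params.lambda_volume, params.v_target,
        params.lambda_surface, params.s_target,
        params.lambda_chemotaxis, params.saturation, params.temperature,
        offsets_for(params.contact_neighborhood), copy_offs,
    )
    state.mcs += 1
    return state


def continue_simulation(state: LatticeState, field: DiffusionField,
                        until_mcs: int, snapshot_mcs: list[int] | None = None,
                        params: CPMParams | None = None):
    """Run MCS/PDE pairs until ``state.mcs == until_mcs``; collect binary
    snapshots (uint8 0/1) at the requested absolute MCS stamps."""
    if params is None:
        params = state.params
    wanted = set(snapshot_mcs or [])
    out: list[tuple[int, np.ndarray]] = []
    if state.mcs in wanted:
        out.append((state.mcs, state.binary_image().astype(np.uint8)))
    while state.mcs < until_mcs:
        monte_carlo_step(state, field, params)
        diffusion_step(field, state, params)
        if state.mcs in wanted:
            out.append((state.mcs, state.binary_image().astype(np.uint8)))
    return out


def run_simulation(params: CPMParams, n_cells: int, total_mcs: int,
                   seed: int, snapshot_mcs: list[int] | None = None):
    """Initialise, then interleave one Potts sweep and one diffusion update
    per MCS. Returns a :class:`~potts_surrogate.datasets.SnapshotDataset`
    holding the requested binary snapshots (all labelled class 0)."""
    from .datasets import SnapshotDataset

    snapshot_mcs = sorted(set(snapshot_mcs or []))
    if snapshot_mcs and snapshot_mcs[-1] > total_mcs:
        raise ValueError("snapshot_mcs entries must be <= total_mcs")
    state = init_lattice(params, n_cells, seed)
    field = DiffusionField.zeros(params.lattice_size)
    snaps = continue_simulation(state, field, total_mcs, snapshot_mcs, params)
    ds = SnapshotDataset()
    for mcs, img in snaps:
        ds.append(img, label=0, replicate=0, mcs=mcs)
    ds.final_state = state
    ds.final_field = field
    return ds


def save_checkpoint(path: str | Path, state: LatticeState,
                    field: DiffusionField) -> None:
    """Single-file checkpoint: magic line, JSON header (version, mcs,
    params, RNG state, array shapes/dtypes), then raw C-order array bytes.
    Byte-for-byte reproducible for identical state."""
    header = {
        "version": 1,
        "mcs": int(state.mcs),
        "params": state.params.to_dict(),
        "rng_state": state.rng.bit_generator.state,
        "n_ids": int(len(state.volumes)),
        "shape": list(state.cell_id.shape),
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(CHECKPOINT_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        fh.write(np.ascontiguousarray(state.cell_id, dtype=np.int64).tobytes())
        fh.write(np.ascontiguousarray(field.conc, dtype=np.float64).tobytes())


def load_checkpoint(path: str | Path) -> tuple[LatticeState, DiffusionField]:
    from .lattice import recount_surfaces, recount_volumes

    with open(path, "rb") as fh:
        magic = fh.read(len(CHECKPOINT_MAGIC))
        if magic != CHECKPOINT_MAGIC:
            raise ValueError(f"not a checkpoint file: {path}")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        shape = tuple(header["shape"])
        count = shape[0] * shape[1]
        cell_id = np.frombuffer(fh.read(count * 8), dtype=np.int64).reshape(shape).copy()
        conc = np.frombuffer(fh.read(count * 8), dtype=np.float64).reshape(shape).copy()
    params = CPMParams.from_dict(header["params"])
    rng = np.random.default_rng(0)
    rng.bit_generator.state = header["rng_state"]
    max_id = header["n_ids"] - 1
    state = LatticeState(
        cell_id=cell_id,
        volumes=recount_volumes(cell_id, max_id=max_id),
        surfaces=recount_surfaces(cell_id, params.contact_neighborhood, max_id=max_id),
        rng=rng,
        mcs=header["mcs"],
        params=params,
    )
    return state, DiffusionField(conc=conc)
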