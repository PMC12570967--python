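"""Effective-energy correctness: brute-force Hamiltonian oracle,
incremental ΔH vs full recomputation, and the Boltzmann acceptance rule."""

import numpy as np
import pytest

from potts_surrogate import (
    CPMParams,
    CopyAttempt,
    DiffusionField,
    acceptance_probability,
    delta_h,
    total_energy,
)
from potts_surrogate.lattice import LatticeState, recount_surfaces, recount_volumes

from conftest import random_field, random_state


def brute_force_energy(cell_id: np.ndarray, params: CPMParams) -> float:
    """Independent O(L^2 * n_offsets) double loop over neighbour pairs plus
    per-cell constraint terms; no shared code with the implementation."""
    L = cell_id.shape[0]
    if params.contact_neighborhood == 4:
        offsets = [(1, 0), (0, 1)]
    else:
        offsets = [(1, 0), (0, 1), (1, 1), (1, -1)]
    contact = 0.0
    for i in range(L):
        for j in range(L):
            a = cell_id[i, j]
            for di, dj in offsets:  # each unordered pair exactly once
                b = cell_id[(i + di) % L, (j + dj) % L]
                if a != b:
                    contact += (params.j_cell_medium
                                if (a == 0 or b == 0) else params.j_cell_cell)
    energy = contact
    for cid in np.unique(cell_id):
        if cid == 0:
            continue
        vol = np.count_nonzero(cell_id == cid)
        surf = 0
        mask = cell_id == cid
        for di, dj in offsets:
            rolled = np.roll(cell_id, (-di, -dj), axis=(0, 1))
            surf += np.count_nonzero(mask & (rolled != cid))
            surf += np.count_nonzero((rolled == cid) & (cell_id != cid))
        energy += params.lambda_volume * (vol - params.v_target) ** 2
        energy += params.lambda_surface * (surf - params.s_target) ** 2
    return energy


def make_state(cell_id: np.ndarray, params: CPMParams) -> LatticeState:
    mx = int(cell_id.max())
    return LatticeState(
        cell_id=cell_id.astype(np.int64),
        volumes=recount_volumes(cell_id, max_id=mx),
        surfaces=recount_surfaces(cell_id, params.contact_neighborhood, max_id=mx),
        rng=np.random.default_rng(0),
        params=params,
    )


class TestTotalEnergy:
    def test_empty_lattice_is_zero(self):
        p = CPMParams(lattice_size=8)
        state = make_state(np.zeros((8, 8), dtype=int), p)
        assert total_energy(state, None, p) == 0.0

    def test_relaxed_isolated_cell_is_zero(self):
        # V = V_target, S = S_target, J_cell,medium = 0: every term vanishes
        p = CPMParams(lattice_size=8, v_target=4.0, s_target=8.0,
                      j_cell_medium=0.0)
        cell_id = np.zeros((8, 8), dtype=int)
        cell_id[3:5, 3:5] = 1
        state = make_state(cell_id, p)
        assert total_energy(state, None, p) == pytest.approx(0.0, abs=1e-12)

    def test_block_matches_brute_force(self):
        p = CPMParams(lattice_size=8, j_cell_medium=8.2, lambda_volume=5.0,
                      v_target=50.0, lambda_surface=1.0, s_target=16.8)
        cell_id = np.zeros((8, 8), dtype=int)
        cell_id[2:4, 2:4] = 1  # 2x2 block
        state = make_state(cell_id, p)
        assert total_energy(state, None, p) == pytest.approx(
            brute_force_energy(cell_id, p), abs=1e-9)

    @pytest.mark.parametrize("neighborhood", [4, 8])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_lattices_match_brute_force(self, neighborhood, seed):
        rng = np.random.default_rng(seed)
        p = CPMParams(lattice_size=12, contact_neighborhood=neighborhood,
                      v_target=6.0, s_target=10.0)
        cell_id = rng.integers(0, 4, size=(12, 12))
        state = make_state(cell_id, p)
        assert total_energy(state, None, p) == pytest.approx(
            brute_force_energy(cell_id, p), abs=1e-9)


class TestDeltaH:
    def test_chemotaxis_closed_form(self):
        # -λ [ c_d/(s c_d + 1) - c_s/(s c_s + 1) ] at λ=2000, s=0.5,
        # c(dest)=2, c(src)=1: -2000 (2/2 - 1/1.5) = -2000/3
        p = CPMParams(lattice_size=8, lambda_chemotaxis=2000.0, saturation=0.5,
                      j_cell_medium=0.0, j_cell_cell=0.0,
                      lambda_volume=0.0, lambda_surface=0.0)
        cell_id = np.zeros((8, 8), dtype=int)
        cell_id[2, 2] = 1
        state = make_state(cell_id, p)
        conc = np.zeros((8, 8))
        conc[2, 2] = 1.0   # source
        conc[2, 3] = 2.0   # destination
        dh = delta_h(state, DiffusionField(conc=conc),
                     CopyAttempt((2, 2), (2, 3)), p)
        assert dh == pytest.approx(-2000.0 / 3.0, rel=1e-12)

    def test_volume_growth_contribution(self):
        # a cell at V = V_target growing by one voxel: λ_v (1² - 0²) = +5
        p = CPMParams(lattice_size=16, lambda_volume=5.0, v_target=50.0,
                      lambda_surface=0.0, j_cell_medium=0.0, j_cell_cell=0.0,
                      lambda_chemotaxis=0.0)
        cell_id = np.zeros((16, 16), dtype=int)
        cell_id[4:9, 4:14] = 1  # exactly 50 voxels
        state = make_state(cell_id, p)
        field = DiffusionField.zeros(16)
        dh = delta_h(state, field, CopyAttempt((8, 10), (9, 10)), p)
        assert dh == pytest.approx(5.0, abs=1e-12)

    def test_same_id_attempt_rejected(self, small_params):
        rng = np.random.default_rng(0)
        state = random_state(rng, 16, 2, small_params)
        state.cell_id[0, 0] = state.cell_id[0, 1] = 1
        with pytest.raises(ValueError):
            delta_h(state, random_field(rng, 16),
                    CopyAttempt((0, 0), (0, 1)), small_params)

    @pytest.mark.parametrize("neighborhood", [4, 8])
    def test_matches_full_energy_recompute(self, neighborhood):
        """Core correctness: incremental ΔH (minus chemotaxis) equals the
        difference of two from-scratch Hamiltonian evaluations."""
        rng = np.random.default_rng(42)
        p = CPMParams(lattice_size=16, v_target=6.0, s_target=9.0,
                      contact_neighborhood=neighborhood)
        checked = 0
        while checked < 500:
            state = random_state(rng, 16, 3, p)
            field = random_field(rng, 16)
            for _ in range(20):
                sx, sy = rng.integers(0, 16, 2)
                off = rng.choice([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                                  (0, 1), (1, -1), (1, 0), (1, 1)])
                dx, dy = (sx + off[0]) % 16, (sy + off[1]) % 16
                if state.cell_id[sx, sy] == state.cell_id[dx, dy]:
                    continue
                attempt = CopyAttempt((int(sx), int(sy)), (int(dx), int(dy)))
                dh = delta_h(state, field, attempt, p, include_chemotaxis=False)
                before = total_energy(state, field, p)
                after_state = state.copy()
                after_state.cell_id[dx, dy] = state.cell_id[sx, sy]
                after = total_energy(after_state, field, p)
                assert dh == pytest.approx(after - before, abs=1e-9)
                checked += 1
        assert checked >= 500


class TestAcceptance:
    @pytest.mark.parametrize("dh,expected", [
        (0.0, 1.0),
        (-3.2, 1.0),
        (8.0, np.exp(-1.0)),
    ])
    def test_closed_forms(self, dh, expected):
        assert acceptance_probability(dh, 8.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_for_positive_dh(self):
        probs = [acceptance_probability(dh, 8.0) for dh in np.linspace(0.1, 40, 50)]
        assert all(0 < p < 1 for p in probs)
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.0, 0.0)

    def test_monte_carlo_frequency_at_dh_equal_temperature(self):
        # empirical acceptance of ΔH = H' over 1e5 trials vs exp(-1)
        rng = np.random.default_rng(7)
        n = 100_000
        p = acceptance_probability(8.0, 8.0)
        freq = np.mean(rng.random(n) < p)
        se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / n)
        assert abs(freq - np.exp(-1)) < 3 * se
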