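"""Morphology metrics: lacunae flood-fill oracle, branch-width sanity on
analytic shapes, and Wasserstein-1 properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from potts_surrogate import branch_widths, emd_1d, feature_report, lacunae_areas
from potts_surrogate.datasets import SnapshotDataset


def flood_fill_areas(image: np.ndarray, periodic: bool) -> list[int]:
    """Brute-force BFS over background with 4-connectivity; independent of
    the scipy-based implementation."""
    h, w = image.shape
    seen = np.zeros_like(image, dtype=bool)
    areas = []
    for si in range(h):
        for sj in range(w):
            if image[si, sj] or seen[si, sj]:
                continue
            stack = [(si, sj)]
            seen[si, sj] = True
            size = 0
            touches_border = False
            while stack:
                i, j = stack.pop()
                size += 1
                if not periodic and (i in (0, h - 1) or j in (0, w - 1)):
                    touches_border = True
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if periodic:
                        ni, nj = ni % h, nj % w
                    elif not (0 <= ni < h and 0 <= nj < w):
                        continue
                    if not image[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        stack.append((ni, nj))
            if periodic or not touches_border:
                areas.append(size)
    return sorted(areas)


class TestLacunae:
    def test_all_background_is_absent(self):
        assert lacunae_areas(np.zeros((8, 8), dtype=np.uint8)) is None

    def test_all_foreground_has_no_lacunae(self):
        assert lacunae_areas(np.ones((8, 8), dtype=np.uint8)) == []

    def test_ring_with_hole_nonperiodic(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[2:7, 2:7] = 1
        img[3:6, 3:6] = 0  # 3x3 hole
        # non-periodic: the frame-touching background is exterior
        assert lacunae_areas(img, periodic=False) == [9]

    def test_ring_with_hole_periodic_includes_outer(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[2:7, 2:7] = 1
        img[3:6, 3:6] = 0
        # periodic: no exterior; outer background is one big lacuna
        # (foreground = 25 - 9 = 16 voxels, so outer bg = 81 - 16 - 9 = 56)
        assert lacunae_areas(img, periodic=True) == [9, 56]

    def test_wrap_stitching_merges_components(self):
        # a background strip crossing the seam must count as one lacuna
        img = np.ones((8, 8), dtype=np.uint8)
        img[:, 0] = 0
        img[:, 7] = 0
        assert lacunae_areas(img, periodic=True) == [16]
        assert lacunae_areas(img, periodic=False) == []

    def test_min_area_threshold(self):
        img = np.ones((8, 8), dtype=np.uint8)
        img[1, 1] = 0          # single-voxel hole: suppressed by default
        img[4:6, 4:6] = 0      # 4-voxel hole: kept
        assert lacunae_areas(img) == [4]
        assert lacunae_areas(img, min_area=1) == [1, 4]

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            lacunae_areas(np.full((4, 4), 2))

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("periodic", [True, False])
    def test_random_images_match_flood_fill_oracle(self, seed, periodic):
        rng = np.random.default_rng(seed)
        img = (rng.random((32, 32)) > 0.4).astype(np.uint8)
        got = lacunae_areas(img, periodic=periodic, min_area=1)
        assert got == flood_fill_areas(img, periodic)

    def test_area_closure(self):
        # lacunae + foreground fill the periodic lattice
        rng = np.random.default_rng(10)
        img = (rng.random((24, 24)) > 0.4).astype(np.uint8)
        areas = lacunae_areas(img, periodic=True, min_area=1)
        assert sum(areas) + int(img.sum()) == 24 * 24


class TestBranchWidths:
    def test_all_background_is_absent(self):
        assert branch_widths(np.zeros((8, 8), dtype=np.uint8)) is None

    def test_periodic_bar_width(self):
        # full-width bar of thickness 5: widths concentrated at 5 ± 1
        img = np.zeros((32, 32), dtype=np.uint8)
        img[10:15, :] = 1
        widths = branch_widths(img, periodic=True)
        assert widths
        assert all(abs(w - 5) <= 1 for w in widths)

    def test_single_voxel_degenerate(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[3, 3] = 1
        widths = branch_widths(img)
        assert widths and max(widths) <= 2.0

    def test_thicker_bar_wider(self):
        def bar(t):
            img = np.zeros((32, 32), dtype=np.uint8)
            img[8:8 + t, :] = 1
            return img
        w3 = np.median(branch_widths(bar(3)))
        w7 = np.median(branch_widths(bar(7)))
        assert w7 > w3


class TestEMD:
    @pytest.mark.parametrize("a,b,expected", [
        ([3.0, 1.0, 2.0], [3.0, 1.0, 2.0], 0.0),
        ([0.0], [1.0], 1.0),
        ([0.0, 1.0], [1.0, 2.0], 1.0),
    ])
    def test_closed_forms(self, a, b, expected):
        assert emd_1d(a, b) == pytest.approx(expected, abs=1e-12)

    def test_equal_size_samples_match_quantile_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=17)
            b = rng.normal(size=17)
            oracle = np.abs(np.sort(a) - np.sort(b)).mean()
            assert emd_1d(a, b) == pytest.approx(oracle, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            emd_1d([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        b=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        c=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        shift=st.floats(-20, 20),
    )
    def test_metric_properties(self, a, b, c, shift):
        dab = emd_1d(a, b)
        assert dab >= 0
        assert dab == pytest.approx(emd_1d(b, a), rel=1e-9, abs=1e-12)
        # triangle inequality and translation equivariance
        assert dab <= emd_1d(a, c) + emd_1d(c, b) + 1e-9
        shifted = [x + shift for x in a]
        assert emd_1d(a, shifted) == pytest.approx(abs(shift), rel=1e-9, abs=1e-9)


class TestFeatureReport:
    @staticmethod
    def _dataset(images, labels):
        ds = SnapshotDataset()
        for img, lab in zip(images, labels):
            ds.append(img, label=lab, replicate=0, mcs=0)
        return ds

    @staticmethod
    def _ring(hole: int, size: int = 24):
        img = np.zeros((size, size), dtype=np.uint8)
        img[4:4 + hole + 4, 4:4 + hole + 4] = 1
        img[6:6 + hole, 6:6 + hole] = 0
        return img

    def test_identical_datasets_give_zero(self):
        imgs = [self._ring(4), self._ring(6)]
        ds = self._dataset(imgs, [0, 0])
        rep = feature_report(ds, ds)
        assert (rep["emd"] == 0).all()
        assert set(rep["feature"]) == {"lacunae_area", "branch_width"}

    def test_all_background_class_is_absent(self):
        gen = self._dataset([np.zeros((24, 24), dtype=np.uint8)], [0])
        ref = self._dataset([self._ring(4)], [0])
        rep = feature_report(gen, ref)
        assert rep["emd"].isna().all()
        assert (rep["n_generated"] == 0).all()
        assert (rep["n_reference"] == 1).all()

    def test_thickness_shift_moves_branch_width_emd(self):
        def bar(t):
            img = np.zeros((32, 32), dtype=np.uint8)
            img[8:8 + t, :] = 1
            return img
        gen = self._dataset([bar(7)], [0])
        ref = self._dataset([bar(5)], [0])
        rep = feature_report(gen, ref)
        bw = rep[rep["feature"] == "branch_width"]["emd"].iloc[0]
        # uniform-width periodic bars: widths shift by exactly 2
        assert bw == pytest.approx(2.0, abs=0.5)
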