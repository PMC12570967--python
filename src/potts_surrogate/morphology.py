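"""Vascular morphology metrics on binary configurations.

Two phenotype features are extracted from each snapshot: the areas of
lacunae (connected background regions enclosed by the vessel network) and
the local widths of vascular branches (twice the Euclidean distance
transform sampled on the foreground skeleton). Feature distributions of
generated versus reference snapshots are compared per class with the 1-D
Earth Mover's (Wasserstein-1) distance.

Conventions: background connectivity 4 and foreground connectivity 8 (the
standard complementary pair), periodic stitching on by default to match
the simulation domain, and a minimum lacuna area of 4 voxels to suppress
single-voxel noise. On periodic domains there is no exterior, so every
background component is a lacuna; in non-periodic analysis components
touching the frame are treated as exterior and excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import wasserstein_distance
from skimage.morphology import skeletonize

__all__ = [
    "lacunae_areas",
    "branch_widths",
    "emd_1d",
    "feature_report",
    "extract_features",
    "MorphologyFeatures",
]

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def _check_binary(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if img.dtype == bool:
        return img
    if not np.isin(img, (0, 1)).all():
        raise ValueError("image must be strictly binary (0/1 or bool)")
    return img.astype(bool)


def _merge_periodic(labels: np.ndarray) -> np.ndarray:
    """Union labels across the wrap seams (top/bottom rows, left/right
    columns) and relabel to a canonical representative."""
    n = int(labels.max())
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    for a, b in zip(labels[0, :], labels[-1, :]):
        union(int(a), int(b))
    for a, b in zip(labels[:, 0], labels[:, -1]):
        union(int(a), int(b))
    out = np.array([find(i) for i in range(n + 1)])
    return out[labels]


def lacunae_areas(image: np.ndarray, periodic: bool = True,
                  min_area: int = 4, connectivity: int = 4):
    """Areas of connected background components (lacunae).

    Returns ``None`` ("absent") when the image has no foreground — such a
    configuration has no vessel network to enclose anything.
    """
    img = _check_binary(image)
    if not img.any():
        return None
    bg = ~img
    if not bg.any():
        return []
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, _ = ndimage.label(bg, structure=struct)
    if periodic:
        labels = _merge_periodic(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if not periodic:
        # components touching the frame are exterior, not lacunae
        border = np.unique(np.concatenate([
            labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
        keep = ~np.isin(ids, border[border > 0])
        counts = counts[keep]
    return sorted(int(c) for c in counts if c >= min_area)


def branch_widths(image: np.ndarray, periodic: bool = True):
    """Branch widths: 2 x Euclidean distance transform at skeleton voxels.

    For periodic domains the image is wrap-padded before skeletonisation
    and distance transform, then cropped back, so branches crossing the
    seam are measured correctly. Returns ``None`` when there is no
    foreground.
    """
    img = _check_binary(image)
    if not img.any():
        return None
    if periodic:
        pad = max(4, min(img.shape) // 2)
        work = np.pad(img, pad, mode="wrap")
    else:
        pad = 0
        work = img
    skel = skeletonize(work)
    edt = ndimage.distance_transform_edt(work)
    if pad:
        sl = (slice(pad, pad + img.shape[0]), slice(pad, pad + img.shape[1]))
        skel = skel[sl]
        edt = edt[sl]
    widths = 2.0 * edt[skel]
    return sorted(float(w) for w in widths)


def emd_1d(sample_a, sample_b) -> float:
    """1-D Wasserstein-1 distance between two empirical distributions."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("emd_1d requires non-empty samples")
    return float(wasserstein_distance(a, b))


class MorphologyFeatures:
    """Feature bundle of one snapshot; ``valid`` is False when the image
    could not be quantified (no foreground)."""

    def __init__(self, lacunae, widths):
        self.valid = lacunae is not None and widths is not None
        self.lacunae_areas = list(lacunae) if self.valid else []
        self.branch_widths = list(widths) if self.valid else []


def extract_features(image: np.ndarray, periodic: bool = True,
                     min_area: int = 4) -> MorphologyFeatures:
    return MorphologyFeatures(
        lacunae_areas(image, periodic=periodic, min_area=min_area),
        branch_widths(image, periodic=periodic),
    )


def _pooled(dataset, label: int, feature: str, periodic: bool, min_area: int):
    pool: list[float] = []
    n = 0
    images, labels = dataset.stacked()
    for img in images[labels == label]:
        if feature == "lacunae_area":
            vals = lacunae_areas(img, periodic=periodic, min_area=min_area)
        else:
            vals = branch_widths(img, periodic=periodic)
        if vals is not None:
            pool.extend(vals)
            n += 1
    return pool, n


def feature_report(generated, reference, periodic: bool = True,
                   min_area: int = 4) -> pd.DataFrame:
    """Per-class EMD between pooled generated and reference feature
    distributions.

    Rows: (class_index, feature) with columns ``emd`` (NaN when either
    side has no quantifiable sample), ``n_generated``, ``n_reference``
    (quantifiable snapshot counts).
    """
    classes = sorted(set(generated.labels) | set(reference.labels))
    rows = []
    for c in classes:
        for feature in ("lacunae_area", "branch_width"):
            g, ng = _pooled(generated, c, feature, periodic, min_area)
            r, nr = _pooled(reference, c, feature, periodic, min_area)
            emd = emd_1d(g, r) if g and r else np.nan
            rows.append((c, feature, emd, ng, nr))
    return pd.DataFrame(
        rows, columns=["class_index", "feature", "emd", "n_generated", "n_reference"]
    )
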