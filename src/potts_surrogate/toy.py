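"""Procedural two-class toy image dataset for end-to-end checks.

Class 0: horizontal stripes with a random phase and slight period jitter.
Class 1: thresholded Gaussian blobs. Both binary, single-channel, 32x32 by
default — small enough that the desk-scale diffusion surrogate and the
verification classifier train in minutes on one CPU, while still giving
two visually and statistically distinct phenotypes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["make_stripes", "make_blobs", "toy_dataset"]


def make_stripes(rng: np.random.Generator, size: int = 32,
                 period: int = 8) -> np.ndarray:
    phase = rng.integers(0, period)
    rows = (np.arange(size) + phase) % period < period // 2
    img = np.repeat(rows[:, None], size, axis=1)
    # sparse salt noise so the class has within-class variability
    flip = rng.random((size, size)) < 0.01
    return (img ^ flip).astype(np.uint8)


def make_blobs(rng: np.random.Generator, size: int = 32,
               smooth: float = 3.0, density: float = 0.5) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), smooth,
                                    mode="wrap")
    thresh = np.quantile(field, 1.0 - density)
    return (field > thresh).astype(np.uint8)


def toy_dataset(n_per_class: int = 500, size: int = 32, seed: int = 0):
    """Balanced (images, labels) stack: class 0 stripes, class 1 blobs."""
    rng = np.random.default_rng(seed)
    imgs = [make_stripes(rng, size) for _ in range(n_per_class)]
    imgs += [make_blobs(rng, size) for _ in range(n_per_class)]
    labels = np.repeat([0, 1], n_per_class)
    return np.stack(imgs), labels
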