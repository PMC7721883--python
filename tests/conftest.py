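"""Shared fixtures: random valid label maps, small mosaics, classifiers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi

from cryptscape.core_io import STRUCT_8, CryptLabelMap
from cryptscape.segmentation import (
    LABEL_COLLAGEN,
    LABEL_CRYPT,
    train_pixel_classifier,
)
from cryptscape.synthetic import MosaicSpec, generate_mosaic


def place_random_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int] = (64, 64),
    n_max: int = 6,
    radius_range: tuple[float, float] = (2.0, 7.0),
    pixel_size_um: float = 1.0,
) -> CryptLabelMap:
    """A valid random label map: disjoint, non-adjacent elliptical blobs.

    Candidates whose 1-px dilation touches an existing object are
    rejected, so every label is its own 8-connected component.
    """
    n = int(rng.integers(1, n_max + 1))
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    placed = 0
    for _ in range(200):
        if placed == n:
            break
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        a = rng.uniform(*radius_range)
        b = rng.uniform(*radius_range)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        cand = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
        if not cand.any():
            continue
        grown = ndi.binary_dilation(cand, structure=STRUCT_8)
        if (grown & occupied).any():
            continue
        placed += 1
        labels[cand] = placed
        occupied |= cand
    assert placed >= 1
    return CryptLabelMap(labels=labels, pixel_size_um=pixel_size_um)


def sparse_training_labels(
    true_labels: np.ndarray, rng: np.random.Generator, n_per_class: int = 400
) -> np.ndarray:
    """Sparse scribble mask from ground truth: crypt vs everything else."""
    out = np.zeros(true_labels.shape, dtype=int)
    lumen = true_labels > 0
    for mask, code in [(lumen, LABEL_CRYPT), (~lumen, LABEL_COLLAGEN)]:
        coords = np.column_stack(np.nonzero(mask))
        take = min(n_per_class, len(coords))
        sel = coords[rng.choice(len(coords), take, replace=False)]
        out[sel[:, 0], sel[:, 1]] = code
    return out


SMALL_MOSAIC_SPEC = MosaicSpec(
    image_shape=(300, 300),
    pixel_size_um=1.0,
    n_crypts=16,
    crypt_radius_mean_um=13.0,
    crypt_radius_sd_um=1.5,
    min_gap_um=12.0,
    fiber_texture_amplitude=20.0,
    noise_sd=8.0,
    seed=5,
)


@pytest.fixture(scope="session")
def small_mosaic():
    """One textured, noisy mosaic with ground truth (session-wide)."""
    return generate_mosaic(SMALL_MOSAIC_SPEC)


@pytest.fixture(scope="session")
def trained_classifier(small_mosaic):
    img, truth = small_mosaic
    rng = np.random.default_rng(11)
    masks = sparse_training_labels(truth.label_map.labels, rng)
    return train_pixel_classifier([img], [masks], n_stages=2, seed=0)
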