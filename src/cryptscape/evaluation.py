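"""Synthetic benchmark experiments for the full pipeline.

These functions exercise the package end to end on generated mosaics
with known ground truth: train the pixel classifier from sparse
scribbles, segment, measure, and compare against the exhaustive
brute-force oracle.  They back both the test suite and the
reproduction script, so the numbers they return are always recomputed
from scratch.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cryptscape.cohort import flag_outliers, welch_t
from cryptscape.core_io import CryptLabelMap
from cryptscape.segmentation import (
    LABEL_COLLAGEN,
    LABEL_CRYPT,
    hysteresis_segment,
    postprocess_labels,
    predict_probability,
    train_pixel_classifier,
)
from cryptscape.spatial import compute_crypt_table, summarize_image
from cryptscape.synthetic import MosaicSpec, fibrosis_transform, generate_mosaic

#: mosaic used by the recovery experiments: a 300 µm field at 1 µm/px
#: holding ~16 crypts of 13 µm lumen radius (≈530 µm² area, comfortably
#: above the 300 µm² filter), textured walls, moderate noise
RECOVERY_SPEC = MosaicSpec(
    image_shape=(300, 300),
    pixel_size_um=1.0,
    n_crypts=16,
    crypt_radius_mean_um=13.0,
    crypt_radius_sd_um=1.5,
    min_gap_um=12.0,
    fiber_texture_amplitude=20.0,
    noise_sd=8.0,
    seed=0,
)

#: cohort-scale mosaic for the fibrosis-direction experiment: a field
#: comparable to the imaged colon mosaics (400 µm across) with enough
#: crypts for stable spatial summaries
PHENOTYPE_SPEC = MosaicSpec(
    image_shape=(400, 400),
    pixel_size_um=1.0,
    n_crypts=35,
    crypt_radius_mean_um=12.0,
    crypt_radius_sd_um=1.5,
    min_gap_um=8.0,
    fiber_texture_amplitude=20.0,
    noise_sd=8.0,
    seed=0,
)


def scribble_labels(
    true_labels: np.ndarray, rng: np.random.Generator, n_per_class: int = 400
) -> np.ndarray:
    """Sparse training scribbles sampled from ground truth."""
    out = np.zeros(true_labels.shape, dtype=int)
    lumen = true_labels > 0
    for mask, code in [(lumen, LABEL_CRYPT), (~lumen, LABEL_COLLAGEN)]:
        coords = np.column_stack(np.nonzero(mask))
        sel = coords[
            rng.choice(len(coords), min(n_per_class, len(coords)), replace=False)
        ]
        out[sel[:, 0], sel[:, 1]] = code
    return out


def segment_mosaic(
    spec: MosaicSpec, train_seed: int = 0
) -> tuple[CryptLabelMap, CryptLabelMap]:
    """Generate a mosaic, train a classifier on it, segment it.

    Returns (found label map, ground-truth label map).
    """
    img, truth = generate_mosaic(spec)
    rng = np.random.default_rng(train_seed)
    masks = scribble_labels(truth.label_map.labels, rng)
    clf = train_pixel_classifier([img], [masks], n_stages=2, seed=train_seed)
    pmap = predict_probability(clf, img)
    mask = hysteresis_segment(pmap, 0.5, 0.8)
    found = postprocess_labels(mask, spec.pixel_size_um)
    return found, truth.label_map


def interior_iou(
    found: CryptLabelMap, truth: CryptLabelMap
) -> tuple[list[float], int, int]:
    """Per-interior-crypt IoU against best-overlap match, plus counts.

    Returns (IoU of every interior ground-truth crypt, ground-truth
    interior count, found interior count).
    """
    ious = []
    for lab in truth.label_ids():
        if truth.border_flags[lab]:
            continue
        t_mask = truth.labels == lab
        overlap = np.bincount(
            found.labels[t_mask], minlength=found.n_labels + 1
        )
        best = int(overlap[1:].argmax()) + 1 if found.n_labels else 0
        if best == 0 or overlap[best] == 0:
            ious.append(0.0)
            continue
        f_mask = found.labels == best
        ious.append(float((t_mask & f_mask).sum() / (t_mask | f_mask).sum()))
    truth_interior = sum(
        1 for lab in truth.label_ids() if not truth.border_flags[lab]
    )
    found_interior = sum(
        1 for lab in found.label_ids() if not found.border_flags[lab]
    )
    return ious, truth_interior, found_interior


def recovery_experiment(min_gap_um: float, seed: int = 0) -> dict:
    """Segment a mosaic of known spacing; compare mean nearest distance.

    The headline number is the absolute error (µm) between the mean
    nearest-crypt distance computed from the recovered segmentation and
    from the ground truth, both restricted to interior crypts within
    the 40 µm search radius.
    """
    spec = dataclasses.replace(RECOVERY_SPEC, min_gap_um=min_gap_um, seed=seed)
    found, truth = segment_mosaic(spec, train_seed=seed + 1)
    s_found = summarize_image(compute_crypt_table(found))
    s_truth = summarize_image(compute_crypt_table(truth))
    return {
        "min_gap_um": min_gap_um,
        "mean_nn_found_um": s_found.mean_nn_distance_um,
        "mean_nn_truth_um": s_truth.mean_nn_distance_um,
        "abs_error_um": abs(
            s_found.mean_nn_distance_um - s_truth.mean_nn_distance_um
        ),
        "interior_found": s_found.interior_count,
        "interior_truth": s_truth.interior_count,
    }


def noise_free_iou_experiment(seed: int = 0) -> dict:
    """Noise-free segmentation fidelity: per-crypt IoU and exact count."""
    spec = dataclasses.replace(
        RECOVERY_SPEC, noise_sd=0.0, fiber_texture_amplitude=0.0, seed=seed
    )
    found, truth = segment_mosaic(spec, train_seed=seed + 1)
    ious, n_truth, n_found = interior_iou(found, truth)
    return {
        "min_iou": min(ious) if ious else float("nan"),
        "mean_iou": float(np.mean(ious)) if ious else float("nan"),
        "interior_truth": n_truth,
        "interior_found": n_found,
    }


def phenotype_experiment(
    severity: float, seeds: tuple[int, ...] = (0, 1, 2)
) -> dict:
    """Mean spatial summaries of fibrosis-transformed mosaics.

    Uses the ground-truth label maps (the direction of the phenotype is
    a property of the generated tissue, not of segmentation fidelity).
    """
    spec0 = fibrosis_transform(PHENOTYPE_SPEC, severity)
    sums = []
    for seed in seeds:
        _, truth = generate_mosaic(dataclasses.replace(spec0, seed=seed))
        sums.append(summarize_image(compute_crypt_table(truth.label_map)))
    return {
        "severity": severity,
        "interior_count": float(np.mean([s.interior_count for s in sums])),
        "mean_area_um2": float(np.mean([s.mean_area_um2 for s in sums])),
        "mean_nn_distance_um": float(
            np.mean([s.mean_nn_distance_um for s in sums])
        ),
        "mean_neighbor_count": float(
            np.mean([s.mean_neighbor_count for s in sums])
        ),
    }


def welch_type1_error(
    n_sim: int = 2000, n_per_group: int = 8, seed: int = 0
) -> float:
    """Empirical type-I error of Welch's t at nominal 0.05.

    Null draws share a mean but not a variance (sd 1 vs 2) — the
    unequal-variance setting Welch's correction exists for.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        x = rng.normal(0, 1, n_per_group)
        y = rng.normal(0, 2, n_per_group)
        if welch_t(x, y).p_value < 0.05:
            hits += 1
    return hits / n_sim


def grubbs_null_flag_rate(
    n_sim: int = 1000, n: int = 20, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of clean normal samples with any outlier flag."""
    rng = np.random.default_rng(seed)
    hits = sum(
        bool(flag_outliers(rng.standard_normal(n), alpha=alpha))
        for _ in range(n_sim)
    )
    return hits / n_sim
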