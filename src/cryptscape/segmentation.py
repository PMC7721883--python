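"""From SHG stack to crypt label map.

The pipeline is: max projection over z, per-pixel crypt probability,
hysteresis thresholding (high-probability seeds grown through
low-probability pixels, 8-connectivity), hole filling, and a physical
size filter (objects under 300 µm² discarded).

The probability step is a two-stage linear-logistic pixel classifier
over a multi-scale feature bank (Gaussian smoothing, gradient
magnitude, local variance).  Stage 2 re-fits with smoothed stage-1
probabilities appended to the features, so spatial context sharpens
the decision — the autocontext idea.  Users with their own classifier
can instead load an externally produced probability map TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from sklearn.linear_model import LogisticRegression

from cryptscape.core_io import STRUCT_8, CryptLabelMap, Image2D, SHGImageStack

DEFAULT_SCALES = (1.0, 2.0, 4.0, 8.0)

#: label codes of training scribbles
LABEL_UNANNOTATED = 0
LABEL_CRYPT = 1
LABEL_COLLAGEN = 2


@dataclass
class ProbabilityMap:
    """Per-pixel crypt-class probability in [0, 1]."""

    probs: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probability map must be 2D")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class _Stage:
    weights: np.ndarray
    bias: float
    feat_mean: np.ndarray
    feat_std: np.ndarray


@dataclass
class PixelClassifier:
    """Linear-logistic pixel classifier with an optional context stage."""

    scales: tuple[float, ...]
    stages: list[_Stage] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": "cryptscape-classifier",
            "scales": list(self.scales),
            "stages": [
                {
                    "weights": s.weights.tolist(),
                    "bias": s.bias,
                    "feat_mean": s.feat_mean.tolist(),
                    "feat_std": s.feat_std.tolist(),
                }
                for s in self.stages
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelClassifier":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "cryptscape-classifier":
            raise ValueError(f"{path} is not a cryptscape classifier file")
        clf = cls(scales=tuple(doc["scales"]))
        for s in doc["stages"]:
            clf.stages.append(
                _Stage(
                    weights=np.asarray(s["weights"]),
                    bias=float(s["bias"]),
                    feat_mean=np.asarray(s["feat_mean"]),
                    feat_std=np.asarray(s["feat_std"]),
                )
            )
        return clf


# ---------------------------------------------------------------------------
# projection and features
# ---------------------------------------------------------------------------


def max_project(stack: SHGImageStack) -> Image2D:
    """Per-pixel maximum over z; pixel size is preserved."""
    return Image2D(
        pixels=stack.voxels.max(axis=0), pixel_size_um=stack.pixel_size_um
    )


def compute_features(
    img: Image2D | np.ndarray, scales: tuple[float, ...] = DEFAULT_SCALES
) -> np.ndarray:
    """Multi-scale feature bank, shape (rows, cols, 3 * len(scales)).

    Per scale sigma (px): Gaussian-smoothed intensity, Gaussian
    gradient magnitude, and local variance
    ``E[x^2] - E[x]^2`` under the same Gaussian window.  Boundaries are
    reflective; everything is deterministic.
    """
    if not scales:
        raise ValueError("need at least one scale")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    pixels = img.pixels if isinstance(img, Image2D) else np.asarray(img)
    pixels = pixels.astype(float)
    feats = []
    for sigma in scales:
        smooth = ndi.gaussian_filter(pixels, sigma, mode="reflect")
        grad = ndi.gaussian_gradient_magnitude(pixels, sigma, mode="reflect")
        sq = ndi.gaussian_filter(pixels**2, sigma, mode="reflect")
        var = np.clip(sq - smooth**2, 0, None)
        feats.extend([smooth, grad, var])
    return np.stack(feats, axis=-1)


def _context_features(
    probs: np.ndarray, scales: tuple[float, ...]
) -> np.ndarray:
    """Smoothed stage-1 probabilities: the autocontext extra features."""
    return np.stack(
        [ndi.gaussian_filter(probs, s, mode="reflect") for s in scales],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


def _fit_stage(feats: np.ndarray, target: np.ndarray, seed: int) -> _Stage:
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std[std == 0] = 1.0
    z = (feats - mean) / std
    model = LogisticRegression(
        C=1.0, max_iter=2000, tol=1e-8, random_state=seed
    )
    model.fit(z, target)
    # sklearn orders classes ascending; make "1" the crypt class
    w = model.coef_[0]
    b = float(model.intercept_[0])
    if model.classes_[1] != 1:
        w, b = -w, -b
    return _Stage(weights=w, bias=b, feat_mean=mean, feat_std=std)


def _stage_probs(stage: _Stage, feats: np.ndarray) -> np.ndarray:
    if feats.shape[-1] != stage.weights.shape[0]:
        raise ValueError(
            f"feature dimension {feats.shape[-1]} does not match "
            f"classifier ({stage.weights.shape[0]})"
        )
    z = (feats - stage.feat_mean) / stage.feat_std
    logit = z @ stage.weights + stage.bias
    return 1.0 / (1.0 + np.exp(-logit))


def train_pixel_classifier(
    images: list[Image2D],
    label_masks: list[np.ndarray],
    n_stages: int = 2,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the crypt-vs-collagen pixel classifier on sparse scribbles.

    ``label_masks`` use 0 = unannotated, 1 = crypt, 2 = collagen /
    background.  Stage 2 (when requested) appends Gaussian-smoothed
    stage-1 probabilities to the feature bank and refits.  Training is
    deterministic given inputs and seed.
    """
    if n_stages not in (1, 2):
        raise ValueError("n_stages must be 1 or 2")
    if len(images) != len(label_masks) or not images:
        raise ValueError("need >= 1 image with a matching label mask")
    feat_maps = [compute_features(img, scales) for img in images]
    sel = [m != LABEL_UNANNOTATED for m in label_masks]
    if not any(s.any() for s in sel):
        raise ValueError("all label masks are empty")
    target = np.concatenate(
        [(m[s] == LABEL_CRYPT).astype(int) for m, s in zip(label_masks, sel)]
    )
    if len(np.unique(target)) < 2:
        raise ValueError("training labels contain only one class")
    feats = np.concatenate(
        [fm[s] for fm, s in zip(feat_maps, sel)], axis=0
    )
    clf = PixelClassifier(scales=tuple(scales))
    clf.stages.append(_fit_stage(feats, target, seed))
    if n_stages == 2:
        feats2 = []
        for fm, s in zip(feat_maps, sel):
            p1 = _stage_probs(clf.stages[0], fm)
            ctx = _context_features(p1, scales)
            feats2.append(np.concatenate([fm, ctx], axis=-1)[s])
        clf.stages.append(
            _fit_stage(np.concatenate(feats2, axis=0), target, seed)
        )
    return clf


def predict_probability(
    classifier: PixelClassifier, img: Image2D
) -> ProbabilityMap:
    """Apply the trained classifier to one image."""
    if classifier.n_stages == 0:
        raise ValueError("classifier has no trained stages")
    feats = compute_features(img, classifier.scales)
    probs = _stage_probs(classifier.stages[0], feats)
    if classifier.n_stages == 2:
        ctx = _context_features(probs, classifier.scales)
        probs = _stage_probs(
            classifier.stages[1], np.concatenate([feats, ctx], axis=-1)
        )
    return ProbabilityMap(probs=probs, pixel_size_um=img.pixel_size_um)


# ---------------------------------------------------------------------------
# hysteresis segmentation and post-processing
# ---------------------------------------------------------------------------


def hysteresis_segment(
    prob_map: ProbabilityMap | np.ndarray,
    low: float,
    high: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Two-threshold segmentation with strict inequalities.

    A pixel is selected iff its probability exceeds ``low`` and it is
    connected, through pixels exceeding ``low``, to some pixel
    exceeding ``high``.
    """
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError("need 0 <= low <= high <= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    probs = (
        prob_map.probs if isinstance(prob_map, ProbabilityMap) else prob_map
    )
    mask_low = probs > low
    mask_high = probs > high
    structure = STRUCT_8 if connectivity == 8 else None
    comp, n_comp = ndi.label(mask_low, structure=structure)
    if n_comp == 0:
        return np.zeros_like(mask_low)
    seeded = np.unique(comp[mask_high])
    keep = np.zeros(n_comp + 1, dtype=bool)
    keep[seeded[seeded > 0]] = True
    return keep[comp]


def fill_single_object_holes(labels: np.ndarray) -> np.ndarray:
    """Fill background holes fully enclosed by exactly one object.

    A hole is a 4-connected background component that does not touch
    the image border; it is filled into the enclosing object only when
    every object pixel 8-adjacent to it carries one single label —
    holes jointly bounded by several objects are left open.
    """
    out = labels.copy()
    bg_comp, n_bg = ndi.label(labels == 0, structure=None)  # 4-connectivity
    if n_bg == 0:
        return out
    touches_border = np.unique(
        np.concatenate(
            [bg_comp[0], bg_comp[-1], bg_comp[:, 0], bg_comp[:, -1]]
        )
    )
    border_set = set(int(b) for b in touches_border if b > 0)
    slices = ndi.find_objects(bg_comp)
    for hole_id in range(1, n_bg + 1):
        if hole_id in border_set:
            continue
        sl = slices[hole_id - 1]
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, labels.shape)
        )
        hole = bg_comp[grown] == hole_id
        ring = ndi.binary_dilation(hole, structure=STRUCT_8) & ~hole
        owners = np.unique(out[grown][ring])
        owners = owners[owners > 0]
        if owners.size == 1:
            out[grown][hole] = owners[0]
    return out


def postprocess_labels(
    mask: np.ndarray, pixel_size_um: float, min_area_um2: float = 300.0
) -> CryptLabelMap:
    """Label, fill holes, apply the physical size filter, renumber.

    Objects are 8-connected; holes are filled first so the filled area
    counts toward the size test; objects with area < ``min_area_um2``
    are then discarded; surviving labels are renumbered contiguously by
    descending area (ties by original order) and border flags mark
    objects touching any image edge.
    """
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be > 0")
    labels, _ = ndi.label(np.asarray(mask, dtype=bool), structure=STRUCT_8)
    labels = _fill_to_fixpoint(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    min_px = min_area_um2 / (pixel_size_um**2)
    drop = ids[counts < min_px]
    if drop.size:
        labels[np.isin(labels, drop)] = 0
        # removals can leave cavities enclosed by a single survivor
        labels = _fill_to_fixpoint(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    for new, idx in enumerate(order, start=1):
        remap[ids[idx]] = new
    return CryptLabelMap(labels=remap[labels], pixel_size_um=pixel_size_um)


def _fill_to_fixpoint(labels: np.ndarray) -> np.ndarray:
    while True:
        filled = fill_single_object_holes(labels)
        if np.array_equal(filled, labels):
            return filled
        labels = filled
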