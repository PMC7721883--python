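"""Crypt spatial morphometrics from a label map.

Fibrosis reads out as fewer, larger, more widely spaced crypts, so the
quantities of interest are: per-crypt area, the minimum border-to-border
distance to every other crypt, the nearest-crypt distance (defined only
within a 40 µm search radius), and the number of neighboring crypts
within 20 µm of the crypt border.  Distances are Euclidean between
boundary-pixel centers, in µm.

Crypts touching the image edge are excluded from per-image statistics
but still serve as distance and neighbor partners for interior crypts.

The fast implementation computes one exact Euclidean distance transform
per label and reads off minima at the other labels' boundary pixels; it
is tested for exact equality against the exhaustive all-pairs oracle in
:mod:`cryptscape.synthetic`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps, colors
from scipy import ndimage as ndi

from cryptscape.config import AnalysisConfig
from cryptscape.core_io import (
    STRUCT_8,
    ContourSet,
    CryptLabelMap,
    load_contours,
)
from cryptscape.synthetic import CRYPT_TABLE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PairwiseDistances:
    """Symmetric border-to-border distances between labeled crypts."""

    distances: dict[tuple[int, int], float]
    radius_um: float
    labels: list[int]

    def get(self, i: int, j: int) -> float | None:
        """Distance in µm, or None when beyond the stored radius."""
        if i == j:
            raise ValueError("no self-distance")
        return self.distances.get((min(i, j), max(i, j)))

    def partners(self, label: int) -> dict[int, float]:
        out = {}
        for (i, j), d in self.distances.items():
            if i == label:
                out[j] = d
            elif j == label:
                out[i] = d
        return out


@dataclass
class ImageSummary:
    """Per-image aggregates over interior (non-border) crypts."""

    interior_count: int
    mean_area_um2: float  # NaN when no interior crypts
    mean_nn_distance_um: float  # NaN when no interior crypt has a nn
    mean_neighbor_count: float
    n_border_crypts: int
    n_nn_defined: int

    def to_dict(self) -> dict:
        return {
            "interior_count": self.interior_count,
            "mean_area_um2": self.mean_area_um2,
            "mean_nn_distance_um": self.mean_nn_distance_um,
            "mean_neighbor_count": self.mean_neighbor_count,
            "n_border_crypts": self.n_border_crypts,
            "n_nn_defined": self.n_nn_defined,
        }


# ---------------------------------------------------------------------------
# boundaries and distances
# ---------------------------------------------------------------------------


def boundary_pixels(label_map: CryptLabelMap, label: int) -> np.ndarray:
    """(row, col) object pixels with at least one background 8-neighbor.

    The image edge counts as background, so objects truncated by the
    field of view expose a boundary there too.
    """
    mask = label_map.labels == label
    if label < 1 or not mask.any():
        raise ValueError(f"label {label} not present")
    eroded = ndi.binary_erosion(mask, structure=STRUCT_8, border_value=0)
    return np.column_stack(np.nonzero(mask & ~eroded))


def pairwise_border_distances(
    label_map: CryptLabelMap, radius_um: float | None = None
) -> PairwiseDistances:
    """Minimum boundary-to-boundary distance for every crypt pair.

    One exact Euclidean distance transform is computed per label (from
    its boundary pixels); the pair minimum is then the smallest value
    of that transform over the other label's boundary pixels — equal to
    the exhaustive all-pairs minimum, at O(K·N) instead of O(B²).

    All pair minima are stored; ``radius_um`` records the radius the
    caller cares about and must cover both the nearest-crypt and the
    neighbor radii.
    """
    ids = label_map.label_ids()
    px = label_map.pixel_size_um
    if radius_um is None:
        radius_um = float("inf")
    boundaries = {lab: boundary_pixels(label_map, lab) for lab in ids}
    distances: dict[tuple[int, int], float] = {}
    for pos, i in enumerate(ids[:-1]):
        not_boundary = np.ones(label_map.labels.shape, dtype=bool)
        bi = boundaries[i]
        not_boundary[bi[:, 0], bi[:, 1]] = False
        edt = ndi.distance_transform_edt(not_boundary)
        for j in ids[pos + 1 :]:
            bj = boundaries[j]
            d = float(edt[bj[:, 0], bj[:, 1]].min()) * px
            distances[(i, j)] = d
    return PairwiseDistances(
        distances=distances, radius_um=float(radius_um), labels=ids
    )


def nearest_crypt_distance(
    distances: PairwiseDistances, label: int, nn_radius_um: float = 40.0
) -> tuple[float, int] | None:
    """Distance and partner of the nearest crypt within the search radius.

    Border crypts are valid partners.  Returns None when no other crypt
    lies within ``nn_radius_um`` (the value is then excluded from image
    means rather than truncated).  Ties break toward the smaller label.
    """
    if nn_radius_um > distances.radius_um:
        raise ValueError("distances were not computed out to nn_radius_um")
    partners = distances.partners(label)
    if not partners:
        return None
    j = min(partners, key=lambda k: (partners[k], k))
    if partners[j] > nn_radius_um:
        return None
    return partners[j], j


def neighbor_count(
    distances: PairwiseDistances, label: int, neighbor_radius_um: float = 20.0
) -> int:
    """Number of other crypts within the (inclusive) neighbor radius."""
    if neighbor_radius_um > distances.radius_um:
        raise ValueError("distances were not computed out to neighbor radius")
    return sum(
        1 for d in distances.partners(label).values() if d <= neighbor_radius_um
    )


def compute_crypt_table(
    label_map: CryptLabelMap,
    nn_radius_um: float = 40.0,
    neighbor_radius_um: float = 20.0,
) -> pd.DataFrame:
    """Per-crypt metrics table (fast path; oracle-identical)."""
    labels = label_map.labels
    px = label_map.pixel_size_um
    distances = pairwise_border_distances(
        label_map, radius_um=max(nn_radius_um, neighbor_radius_um)
    )
    rows = []
    for lab in label_map.label_ids():
        mask = labels == lab
        rr, cc = np.nonzero(mask)
        nn = nearest_crypt_distance(distances, lab, nn_radius_um)
        rows.append(
            {
                "label": lab,
                "area_um2": float(mask.sum()) * px * px,
                "centroid_row": float(rr.mean()),
                "centroid_col": float(cc.mean()),
                "is_border": label_map.border_flags[lab],
                "nn_distance_um": nn[0] if nn else np.nan,
                "nn_label": nn[1] if nn else None,
                "neighbor_count": neighbor_count(
                    distances, lab, neighbor_radius_um
                ),
            }
        )
    return pd.DataFrame(rows, columns=CRYPT_TABLE_COLUMNS)


def summarize_image(crypt_table: pd.DataFrame) -> ImageSummary:
    """Aggregate a crypt table over interior crypts only.

    Border crypts contribute to the table as partners but never to the
    per-image means; the nearest-crypt mean runs over interior crypts
    whose nearest distance is defined (within the search radius).
    """
    interior = crypt_table[~crypt_table["is_border"].astype(bool)]
    nn = interior["nn_distance_um"].dropna()
    return ImageSummary(
        interior_count=len(interior),
        mean_area_um2=(
            float(interior["area_um2"].mean()) if len(interior) else np.nan
        ),
        mean_nn_distance_um=float(nn.mean()) if len(nn) else np.nan,
        mean_neighbor_count=(
            float(interior["neighbor_count"].mean())
            if len(interior)
            else np.nan
        ),
        n_border_crypts=int(crypt_table["is_border"].astype(bool).sum()),
        n_nn_defined=int(len(nn)),
    )


# ---------------------------------------------------------------------------
# heatmaps and the contour update mode
# ---------------------------------------------------------------------------

HEATMAP_COLORMAP = "viridis"
COLOR_BACKGROUND = (0.0, 0.0, 0.0)
COLOR_ABSENT = (0.85, 0.85, 0.85)
COLOR_BORDER_CRYPT = (0.55, 0.55, 0.55)


def render_heatmap(
    label_map: CryptLabelMap,
    values: dict[int, float] | pd.Series,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Color every crypt by a per-crypt value (e.g. nearest distance).

    Values are mapped through a perceptually uniform monotone colormap
    (viridis) normalized to the [min, max] of the defined values;
    crypts with no defined value are light gray, border crypts mid
    gray, background black.  Returns the RGB image (floats in [0, 1])
    and a table of label → value → hex color.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    cmap = colormaps[HEATMAP_COLORMAP]
    defined = {
        k: float(v)
        for k, v in values.items()
        if v is not None and np.isfinite(v)
    }
    if defined:
        vmin, vmax = min(defined.values()), max(defined.values())
        norm = colors.Normalize(vmin=vmin, vmax=vmax)
    rgb = np.zeros(label_map.labels.shape + (3,))
    rgb[:] = COLOR_BACKGROUND
    rows = []
    for lab in label_map.label_ids():
        if label_map.border_flags[lab]:
            color = COLOR_BORDER_CRYPT
        elif lab in defined:
            if vmax > vmin:
                color = cmap(norm(defined[lab]))[:3]
            else:
                color = cmap(0.5)[:3]
        else:
            color = COLOR_ABSENT
        rgb[label_map.labels == lab] = color
        rows.append(
            {
                "label": lab,
                "value": defined.get(lab, np.nan),
                "color": colors.to_hex(color),
                "is_border": label_map.border_flags[lab],
            }
        )
    return rgb, pd.DataFrame(rows)


def update_from_contours(
    source: str | ContourSet, config: AnalysisConfig | None = None
) -> tuple[CryptLabelMap, pd.DataFrame, ImageSummary]:
    """Recompute every metric from a (possibly hand-edited) contour file.

    Mirrors the macro's manual-correction workflow: contours saved from
    an automatic segmentation are edited (merged, split, deleted,
    vertices moved) and all measurements are recalculated from the
    edited segments.  Objects that fall below the minimum area after
    editing are dropped with a warning, consistent with the size
    filter; an unedited file reproduces the original outputs exactly.
    """
    config = config or AnalysisConfig()
    label_map = load_contours(source)
    label_map.validate()
    px = label_map.pixel_size_um
    areas = {
        lab: float((label_map.labels == lab).sum()) * px * px
        for lab in label_map.label_ids()
    }
    small = [lab for lab, a in areas.items() if a < config.min_area_um2]
    if small:
        logger.warning(
            "dropping %d contour object(s) below %.0f um^2 after edit: %s",
            len(small),
            config.min_area_um2,
            small,
        )
        labels = label_map.labels.copy()
        remap = np.zeros(label_map.n_labels + 1, dtype=np.int32)
        new = 0
        for lab in label_map.label_ids():
            if lab not in small:
                new += 1
                remap[lab] = new
        labels = remap[labels]
        label_map = CryptLabelMap(labels=labels, pixel_size_um=px)
    table = compute_crypt_table(
        label_map,
        nn_radius_um=config.nn_radius_um,
        neighbor_radius_um=config.neighbor_radius_um,
    )
    return label_map, table, summarize_image(table)
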