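"""Image, label-map, contour and configuration I/O.

All physical thresholds downstream are in µm, so pixel size is treated
as first-class metadata: it is read from TIFF resolution tags when
present, may be overridden explicitly, and its absence is an error.

Contours are stored as JSON polygons whose vertices sit on pixel
*corners* (integer coordinates, ``(row, col)`` order).  A pixel belongs
to an object iff its center ``(row + 0.5, col + 0.5)`` lies inside the
object's outer ring(s) and outside its holes; because centers are at
half-integers and ring edges run along integer grid lines, this
rasterization rule reproduces the originating label map exactly, and a
hand-edited file (labels merged, split, deleted, vertices moved) loads
back into a valid, contiguously relabeled map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import shapely.affinity
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.geometry.polygon import orient

logger = logging.getLogger(__name__)

CONTOUR_FORMAT = "cryptscape-contours"
CONTOUR_VERSION = 1

#: 8-connectivity structuring element shared across the package.
STRUCT_8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SHGImageStack:
    """A z-stack of SHG intensities with physical pixel size.

    A 2D image is represented as a stack with ``z = 1``.
    """

    voxels: np.ndarray  # (z, row, col)
    pixel_size_um: float
    z_step_um: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("voxels must be a (z, row, col) array with z >= 1")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("intensities must be finite and >= 0")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class Image2D:
    """A single 2D intensity image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and >= 0")


@dataclass
class CryptLabelMap:
    """Integer-labeled crypt segmentation.

    ``labels`` holds 0 for background and 1..K for crypts with no gaps;
    each positive label is a single 8-connected component.
    ``border_flags[k]`` is True iff label ``k`` touches the image edge.
    """

    labels: np.ndarray
    pixel_size_um: float
    border_flags: dict[int, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be > 0")
        if not self.border_flags:
            self.border_flags = compute_border_flags(self.labels)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def label_ids(self) -> list[int]:
        return list(range(1, self.n_labels + 1))

    def validate(self) -> None:
        """Check the label-set, connectivity and border-flag invariants."""
        present = np.unique(self.labels)
        present = present[present > 0]
        k = self.n_labels
        if not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError(f"labels must be gap-free 1..K, found {present}")
        objects = ndi.find_objects(self.labels)
        for lab in range(1, k + 1):
            sl = objects[lab - 1]
            if sl is None:
                raise ValueError(f"label {lab} missing")
            _, n_comp = ndi.label(self.labels[sl] == lab, structure=STRUCT_8)
            if n_comp != 1:
                raise ValueError(
                    f"label {lab} has {n_comp} 8-connected components"
                )
        expected = compute_border_flags(self.labels)
        if self.border_flags != expected:
            raise ValueError("border_flags inconsistent with label map")


def compute_border_flags(labels: np.ndarray) -> dict[int, bool]:
    """True per label iff the object has a pixel on the image edge."""
    k = int(labels.max(initial=0))
    flags = {lab: False for lab in range(1, k + 1)}
    if k == 0:
        return flags
    edge = np.concatenate(
        [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
    )
    for lab in np.unique(edge):
        if lab > 0:
            flags[int(lab)] = True
    return flags


@dataclass
class ContourSet:
    """Closed per-label polygons on pixel-corner coordinates.

    ``objects`` maps each label to a list of polygons; a polygon is a
    dict with an ``exterior`` ring and optional ``holes`` rings, each a
    list of ``[row, col]`` vertices (integers on the pixel grid).
    """

    image_shape: tuple[int, int]
    pixel_size_um: float
    objects: dict[int, list[dict]]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": CONTOUR_FORMAT,
            "version": CONTOUR_VERSION,
            "image_shape": list(self.image_shape),
            "pixel_size_um": self.pixel_size_um,
            "objects": [
                {"label": lab, "polygons": polys}
                for lab, polys in sorted(self.objects.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "ContourSet":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != CONTOUR_FORMAT:
            raise ValueError(f"{path} is not a {CONTOUR_FORMAT} file")
        objects = {
            int(entry["label"]): entry["polygons"] for entry in doc["objects"]
        }
        return cls(
            image_shape=tuple(doc["image_shape"]),
            pixel_size_um=float(doc["pixel_size_um"]),
            objects=objects,
        )


# ---------------------------------------------------------------------------
# TIFF image I/O
# ---------------------------------------------------------------------------


def _pixel_size_from_tags(page: tifffile.TiffPage) -> float | None:
    """Extract the XY pixel size (µm) from TIFF resolution tags."""
    tags = page.tags
    res = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if res is None or unit is None:
        return None
    num, den = res.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_value = getattr(unit.value, "value", unit.value)
    if unit_value == 2:  # inch
        unit_um = 25400.0
    elif unit_value == 3:  # centimeter
        unit_um = 10000.0
    else:
        return None
    return unit_um / pixels_per_unit


def _resolution_kwargs(pixel_size_um: float) -> dict:
    pixels_per_cm = 1e4 / pixel_size_um
    return {
        "resolution": (pixels_per_cm, pixels_per_cm),
        "resolutionunit": "CENTIMETER",
    }


def read_image(
    path: str | Path, pixel_size_override: float | None = None
) -> SHGImageStack:
    """Read a single- or multi-page grayscale TIFF as an image stack.

    Pixel-size precedence is explicit override > TIFF resolution
    metadata; if neither is available the call fails rather than
    guessing, because every downstream threshold is physical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        meta_px = _pixel_size_from_tags(tf.pages[0])
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D grayscale TIFF")
    pixel_size = (
        pixel_size_override if pixel_size_override is not None else meta_px
    )
    if pixel_size is None:
        raise ValueError(
            f"{path}: no pixel size in TIFF metadata and no override given"
        )
    return SHGImageStack(
        voxels=voxels, pixel_size_um=float(pixel_size), name=path.stem
    )


def write_image(stack: SHGImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF with resolution metadata."""
    tifffile.imwrite(
        path, stack.voxels, **_resolution_kwargs(stack.pixel_size_um)
    )


def write_label_map(label_map: CryptLabelMap, path: str | Path) -> None:
    """Write a label map as a 16-bit TIFF (bit-exact round trip)."""
    if label_map.n_labels > 65535:
        raise ValueError("label map has more than 65535 labels")
    tifffile.imwrite(
        path,
        label_map.labels.astype(np.uint16),
        **_resolution_kwargs(label_map.pixel_size_um),
    )


def read_label_map(
    path: str | Path, pixel_size_override: float | None = None
) -> CryptLabelMap:
    """Read a label-map TIFF; border flags are recomputed from pixels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray()
        meta_px = _pixel_size_from_tags(tf.pages[0])
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{path}: label maps must hold integer pixels")
    pixel_size = (
        pixel_size_override if pixel_size_override is not None else meta_px
    )
    if pixel_size is None:
        raise ValueError(
            f"{path}: no pixel size in TIFF metadata and no override given"
        )
    return CryptLabelMap(
        labels=labels.astype(np.int32), pixel_size_um=float(pixel_size)
    )


# ---------------------------------------------------------------------------
# contour save / load (the macro's "update mode" persistence)
# ---------------------------------------------------------------------------


def _label_geometry(mask: np.ndarray) -> MultiPolygon:
    """Union of unit pixel squares of a binary mask, as shapely geometry.

    Uses x = col, y = row; the square of pixel (r, c) spans
    [c, c+1] x [r, r+1], so its center is (c + 0.5, r + 0.5).
    """
    boxes = []
    for r in range(mask.shape[0]):
        cols = np.flatnonzero(mask[r])
        if cols.size == 0:
            continue
        # merge horizontal runs into single boxes
        breaks = np.flatnonzero(np.diff(cols) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [cols.size - 1]))
        for s, e in zip(starts, ends):
            boxes.append(box(cols[s], r, cols[e] + 1, r + 1))
    geom = shapely.union_all(boxes)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def _ring_coords(ring) -> list[list[int]]:
    # shapely works in (x, y) = (col, row); files store [row, col]
    return [[int(round(y)), int(round(x))] for x, y in ring.coords]


def save_contours(
    label_map: CryptLabelMap, path: str | Path | None = None
) -> ContourSet:
    """Extract per-label boundary polygons; optionally write JSON.

    Outer rings are oriented counter-clockwise and holes clockwise (in
    the row-down image coordinate frame of the stored arrays).
    """
    objects: dict[int, list[dict]] = {}
    slices = ndi.find_objects(label_map.labels)
    for lab in label_map.label_ids():
        sl = slices[lab - 1]
        r0, c0 = sl[0].start, sl[1].start
        geom = _label_geometry(label_map.labels[sl] == lab)
        geom = shapely.affinity.translate(geom, xoff=c0, yoff=r0)
        polys = []
        for poly in geom.geoms:
            poly = orient(poly, sign=1.0)  # exterior CCW, holes CW
            entry: dict = {"exterior": _ring_coords(poly.exterior)}
            if poly.interiors:
                entry["holes"] = [_ring_coords(h) for h in poly.interiors]
            polys.append(entry)
        objects[lab] = polys
    contour_set = ContourSet(
        image_shape=label_map.labels.shape,
        pixel_size_um=label_map.pixel_size_um,
        objects=objects,
    )
    if path is not None:
        contour_set.to_json(path)
    return contour_set


def _polygon_from_entry(entry: dict, shape: tuple[int, int]) -> Polygon:
    def to_xy(ring: list) -> list[tuple[float, float]]:
        return [(float(c), float(r)) for r, c in ring]

    poly = Polygon(to_xy(entry["exterior"]), [to_xy(h) for h in entry.get("holes", [])])
    if not poly.is_valid:
        raise ValueError(
            "invalid polygon (self-intersecting outer boundary?): "
            f"{shapely.is_valid_reason(poly)}"
        )
    minx, miny, maxx, maxy = poly.bounds
    rows, cols = shape
    if minx < 0 or miny < 0 or maxx > cols or maxy > rows:
        raise ValueError(
            f"polygon bounds {poly.bounds} extend outside image {shape}"
        )
    return poly


def _rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers fall inside the polygon."""
    minx, miny, maxx, maxy = poly.bounds
    c_lo, c_hi = int(np.floor(minx)), int(np.ceil(maxx))
    r_lo, r_hi = int(np.floor(miny)), int(np.ceil(maxy))
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    inside = shapely.contains_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
    mask = np.zeros(shape, dtype=bool)
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def load_contours(source: str | Path | ContourSet) -> CryptLabelMap:
    """Rasterize a contour file back to a valid, gap-free label map.

    Objects are relabeled contiguously in file-label order; an object
    whose polygons rasterize to several 8-connected components (a
    hand-edited split) becomes several labels; empty objects are
    dropped with a warning.  Overlapping objects are rejected.
    """
    contour_set = (
        source if isinstance(source, ContourSet) else ContourSet.from_json(source)
    )
    shape = tuple(contour_set.image_shape)
    labels = np.zeros(shape, dtype=np.int32)
    next_label = 1
    for lab in sorted(contour_set.objects):
        mask = np.zeros(shape, dtype=bool)
        for entry in contour_set.objects[lab]:
            poly = _polygon_from_entry(entry, shape)
            mask |= _rasterize(poly, shape)
        if not mask.any():
            logger.warning("contour object %d rasterized to no pixels; dropped", lab)
            continue
        if np.any(labels[mask] > 0):
            raise ValueError(f"contour object {lab} overlaps a previous object")
        comp, n_comp = ndi.label(mask, structure=STRUCT_8)
        for i in range(1, n_comp + 1):
            labels[comp == i] = next_label
            next_label += 1
    return CryptLabelMap(labels=labels, pixel_size_um=contour_set.pixel_size_um)
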