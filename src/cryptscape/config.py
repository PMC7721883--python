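"""Analysis configuration: one flat, YAML-serializable parameter set.

Every threshold in the pipeline is physical (µm) or a probability, so a
single configuration object travels from the command line (or a YAML
file) down to every module.  CLI flags override file values; a missing
pixel size is always an explicit error, never a silent default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Parameters of the crypt segmentation and morphometry pipeline.

    Attributes
    ----------
    low_threshold, high_threshold:
        Hysteresis probabilities; pixels above ``high_threshold`` seed
        regions grown through pixels above ``low_threshold``.
    min_area_um2:
        Objects smaller than this are discarded after hole filling
        (300 µm² by default).
    nn_radius_um:
        Search radius for the nearest-crypt distance; crypts whose
        nearest neighbor is farther are treated as having no defined
        nearest distance (40 µm by default).
    neighbor_radius_um:
        Radius of the neighboring-crypt count (20 µm by default).
    collagen_threshold:
        Fixed manual intensity threshold of the collagen-covered-area
        recipe; ``None`` until the user sets it.
    white_detail_size:
        Disk radius (px) of the white top-hat used to enhance small
        bright structures before collagen thresholding.
    median_size:
        Radius (px) of the median denoising window, window side
        ``2 * median_size + 1``.
    pixel_size_um:
        Optional override of the physical XY pixel size.
    seed:
        Seed for every stochastic step (classifier training order,
        synthetic mosaics).
    """

    low_threshold: float = 0.5
    high_threshold: float = 0.8
    min_area_um2: float = 300.0
    nn_radius_um: float = 40.0
    neighbor_radius_um: float = 20.0
    collagen_threshold: float | None = None
    white_detail_size: int = 2
    median_size: int = 1
    pixel_size_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_threshold <= self.high_threshold <= 1.0):
            raise ValueError(
                "need 0 <= low_threshold <= high_threshold <= 1, got "
                f"{self.low_threshold}, {self.high_threshold}"
            )
        for name in ("min_area_um2", "nn_radius_um", "neighbor_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.white_detail_size < 1 or self.median_size < 1:
            raise ValueError("filter sizes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config from YAML; keyword arguments override file keys."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
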