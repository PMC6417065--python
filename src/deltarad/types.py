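"""Core data containers shared across the pipeline.

Axis convention (stated once, used everywhere): arrays are ordered
``(z, y, x)`` and axial slices index ``z``. Spacings are millimetres in the
same ``(z, y, x)`` order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ImageVolume",
    "ROISet",
    "NormalizedVolume",
    "QuantizedROI",
    "FeatureVector",
    "DeltaFeatureVector",
]


@dataclass
class ImageVolume:
    """A 3D intensity grid with physical voxel spacing in mm (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROISet:
    """Tumor and bladder-urine masks aligned to an :class:`ImageVolume` grid."""

    tumor: np.ndarray
    bladder: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.bladder = np.asarray(self.bladder, dtype=bool)
        if self.tumor.shape != self.bladder.shape:
            raise ValueError("tumor and bladder masks must share a grid")


@dataclass
class NormalizedVolume(ImageVolume):
    """Intensity grid after normalization, with provenance flags.

    After urine normalization the mean intensity inside the bladder mask is
    exactly 1; intensities are unitless (urine-referenced).
    """

    collewet_applied: bool = False
    urine_applied: bool = False

    def with_data(self, data: np.ndarray, **flags) -> "NormalizedVolume":
        return replace(self, data=data, **flags)


@dataclass
class QuantizedROI:
    """Gray levels 1..n_levels inside ``mask`` (0 outside), plus the
    continuous urine-normalized intensities the levels were derived from.

    ``dimensionality`` is "3D" for full volumes (3D arrays) or "2D" for a
    single axial slice (2D arrays); spacing is isotropic after resampling.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing: tuple[float, ...]
    dimensionality: str
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.dimensionality not in ("2D", "3D"):
            raise ValueError(f"dimensionality must be '2D' or '3D', got {self.dimensionality!r}")
        expected_ndim = 3 if self.dimensionality == "3D" else 2
        if self.levels.ndim != expected_ndim:
            raise ValueError(
                f"{self.dimensionality} ROI requires a {expected_ndim}D array, "
                f"got ndim={self.levels.ndim}"
            )
        if self.levels.shape != self.mask.shape:
            raise ValueError("levels and mask must share a grid")
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, n_levels]")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FeatureVector:
    """The 55 named feature values for one ROI at one timepoint."""

    values: dict[str, float]
    dimensionality: str
    timepoint: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = {str(k): float(v) for k, v in self.values.items()}

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names=None) -> np.ndarray:
        names = list(self.values) if names is None else names
        return np.array([self.values[n] for n in names], dtype=float)


@dataclass
class DeltaFeatureVector:
    """Elementwise after-minus-before feature values for one patient."""

    values: dict[str, float]
    dimensionality: str
    patient_id: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names=None) -> np.ndarray:
        names = list(self.values) if names is None else names
        return np.array([self.values[n] for n in names], dtype=float)
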