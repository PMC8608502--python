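"""Core in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* voxel index order is ``(k, i, j)`` = (slice, row, column), 0-based;
* physical coordinates are millimetres, with
  ``world(k, i, j) = origin + (k, i, j) * spacing`` applied per axis, so the
  world tuple is ordered ``(z, y, x)`` to match the index order;
* intensities are Hounsfield units (HU), clamped to the 12-bit CT range
  ``[-1024, 3071]`` at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

HU_MIN = -1024.0
HU_MAX = 3071.0


def clamp_hu(values: np.ndarray) -> np.ndarray:
    """Clamp an HU array to the 12-bit CT range ``[-1024, 3071]``."""
    return np.clip(values, HU_MIN, HU_MAX)


@dataclass
class CTVolume:
    """A 3D CT scalar grid in Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels
        3D array indexed ``(slice, row, column)``, in HU.
    spacing
        Millimetres per voxel along each axis ``(slice, row, column)``.
    origin
        World coordinate (mm, ``(z, y, x)`` order) of voxel ``(0, 0, 0)``.
    source_id
        Free-text provenance tag (file path, series UID, phantom seed ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"CTVolume requires a 3D array, got ndim={self.voxels.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("CTVolume voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_mm(self, index) -> np.ndarray:
        """World (z, y, x) mm coordinate of a (possibly fractional) index."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def mm_to_index(self, position_mm) -> np.ndarray:
        """Fractional (k, i, j) index of a world (z, y, x) mm position."""
        return (np.asarray(position_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.spacing
        )


@dataclass
class BinaryMask:
    """Indicator array on the grid of a parent :class:`CTVolume`."""

    values: np.ndarray
    parent_shape: tuple[int, int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"BinaryMask requires a 3D array, got ndim={self.values.ndim}")
        if self.parent_shape is None:
            self.parent_shape = self.values.shape
        self.parent_shape = tuple(int(n) for n in self.parent_shape)
        if tuple(self.values.shape) != self.parent_shape:
            raise ValidationError(
                f"mask shape {self.values.shape} != parent shape {self.parent_shape}"
            )
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError("BinaryMask values must be 0/1")
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def count(self) -> int:
        return int(self.values.sum())


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    av = a.values.astype(bool) if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)
    bv = b.values.astype(bool) if isinstance(b, BinaryMask) else np.asarray(b, dtype=bool)
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


@dataclass
class NoduleFeatures:
    """Shape and intensity descriptors of one candidate region.

    ``circularity`` is 4π·area/perimeter² measured on the candidate's peak
    slice (the slice holding most region voxels); ``elongation`` is the ratio
    of the extreme principal axes of the 3D second-moment tensor in mm, so a
    sphere scores ~1 and an in-lung vessel segment scores well above 2.
    ``contrast_hu`` compares the region mean to a surrounding shell;
    ``boundary_gradient_hu_per_mm`` averages the HU gradient magnitude over
    the region's border voxels.
    """

    volume_mm3: float
    equivalent_diameter_mm: float
    circularity: float
    elongation: float
    mean_hu: float
    max_hu: float
    contrast_hu: float
    boundary_gradient_hu_per_mm: float

    FIELD_ORDER = (
        "volume_mm3",
        "equivalent_diameter_mm",
        "circularity",
        "elongation",
        "mean_hu",
        "max_hu",
        "contrast_hu",
        "boundary_gradient_hu_per_mm",
    )

    def __post_init__(self) -> None:
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise ValidationError("NoduleFeatures fields must all be finite")
        if self.volume_mm3 <= 0:
            raise ValidationError("volume_mm3 must be positive")
        if not (0 < self.circularity <= 1.1):
            raise ValidationError(f"circularity {self.circularity} outside (0, 1.1]")
        if self.elongation < 1:
            raise ValidationError(f"elongation {self.elongation} < 1")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELD_ORDER], dtype=float)


@dataclass
class Candidate:
    """One suspected shadow emitted by the detector.

    ``centroid_index`` is the integer voxel nearest the response-weighted
    centroid (snapped to the peak voxel if rounding leaves the lung mask);
    ``centroid_mm`` keeps the sub-voxel world position. ``radius_mm`` is the
    filter scale of maximal response and ``response`` its HU-contrast value.
    """

    centroid_index: tuple[int, int, int]
    centroid_mm: tuple[float, float, float]
    radius_mm: float
    response: float
    features: Optional[NoduleFeatures] = None
    label: Optional[str] = None
    score: Optional[float] = None
    feature_error: Optional[str] = None

    def __post_init__(self) -> None:
        self.centroid_index = tuple(int(v) for v in self.centroid_index)
        self.centroid_mm = tuple(float(v) for v in self.centroid_mm)
        if not np.isfinite(self.response) or self.response <= 0:
            raise ValidationError(f"candidate response must be finite and > 0, got {self.response}")
        if not np.isfinite(self.radius_mm) or self.radius_mm <= 0:
            raise ValidationError(f"candidate radius_mm must be finite and > 0, got {self.radius_mm}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score {self.score} outside [0, 1]")
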