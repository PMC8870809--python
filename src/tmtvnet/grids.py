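"""Core spatial containers for the TMTV pipeline.

A :class:`VolumeGrid` is a 3D scalar field (PET in SUV units or CT in
Hounsfield units) on a regular axis-aligned grid.  Arrays are indexed
``[x, y, z]`` with ``z`` the axial (cranio-caudal) direction; a voxel's
value sits at its center coordinate ``origin_mm + index * spacing_mm``.

Binary masks are plain boolean ``numpy`` arrays aligned to a grid; a
:class:`RoiSet` collects several (possibly overlapping) regions of
interest, each identified by a positive integer id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["VolumeGrid", "RoiSet", "volume_ml", "PET_SUV", "CT_HU"]

PET_SUV = "PET_SUV"
CT_HU = "CT_HU"

#: out-of-field fill value per modality (PET: no uptake, CT: air)
BACKGROUND_VALUE = {PET_SUV: 0.0, CT_HU: -1000.0}


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing and origin metadata.

    Parameters
    ----------
    values
        3D array indexed ``[x, y, z]``.
    spacing_mm
        Voxel edge lengths in mm, strictly positive.
    origin_mm
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    modality
        ``"PET_SUV"`` or ``"CT_HU"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = PET_SUV

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got shape {self.values.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.modality not in (PET_SUV, CT_HU):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def background_value(self) -> float:
        return BACKGROUND_VALUE[self.modality]

    def physical_center_mm(self) -> np.ndarray:
        """World coordinate of the geometric center of the field of view."""
        shape = np.asarray(self.shape, dtype=float)
        return np.asarray(self.origin_mm) + (shape - 1) / 2.0 * np.asarray(self.spacing_mm)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm coordinates."""
        return np.asarray(self.origin_mm) + np.asarray(idx, dtype=float) * np.asarray(self.spacing_mm)

    def world_to_index(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to (fractional) voxel indices."""
        return (np.asarray(xyz_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "VolumeGrid":
        """A new grid with identical geometry but different voxel data."""
        return VolumeGrid(
            values=values,
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
            modality=modality or self.modality,
        )


def volume_ml(mask: np.ndarray, grid: VolumeGrid) -> float:
    """Volume in mL of a boolean mask on ``grid``."""
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {grid.shape}")
    return float(np.count_nonzero(mask)) * grid.voxel_volume_ml


@dataclass
class RoiSet:
    """Labeled regions of interest over a grid.

    ROIs may overlap (loose manual-style boxes often do), so each ROI is
    stored as its own boolean mask keyed by a positive integer id.
    """

    shape: tuple[int, int, int]
    rois: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        for rid, mask in self.rois.items():
            self._check(rid, mask)

    def _check(self, rid: int, mask: np.ndarray) -> None:
        if rid <= 0:
            raise ValueError(f"ROI id must be positive, got {rid}")
        if mask.shape != self.shape or mask.dtype != bool:
            raise ValueError(f"ROI {rid}: expected bool mask of shape {self.shape}")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "RoiSet":
        """Build from an integer label volume (0 = background)."""
        labels = np.asarray(labels)
        ids = [int(v) for v in np.unique(labels) if v > 0]
        return cls(shape=labels.shape, rois={i: labels == i for i in ids})

    def to_labels(self, dtype=np.int16) -> np.ndarray:
        """Paint ids into one label volume (higher id wins on overlap)."""
        out = np.zeros(self.shape, dtype=dtype)
        for rid in sorted(self.rois):
            out[self.rois[rid]] = rid
        return out

    def add(self, rid: int, mask: np.ndarray) -> None:
        self._check(rid, mask)
        self.rois[rid] = mask

    def ids(self) -> list[int]:
        return sorted(self.rois)

    def union(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for mask in self.rois.values():
            out |= mask
        return out

    def items(self) -> Iterator[tuple[int, np.ndarray]]:
        for rid in sorted(self.rois):
            yield rid, self.rois[rid]

    def __len__(self) -> int:
        return len(self.rois)

    def __contains__(self, rid: int) -> bool:
        return rid in self.rois
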