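"""Reading, SUV conversion, fixed-grid resampling and 0-1 intensity scaling.

The CNN consumes a fixed physical field of view: a 128 x 128 x 256 grid at
4 mm isotropic spacing (a 51.2 x 51.2 x 102.4 cm box, enough for a
whole-body acquisition), with CT Hounsfield units mapped affinely from
[-1000, 1000] to [0, 1] and PET SUV from [0, 25] to [0, 1], clipping
outside those ranges.  PET and CT are center-aligned on the same origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import VolumeGrid, RoiSet, PET_SUV, CT_HU, BACKGROUND_VALUE

__all__ = [
    "QualityCheckError",
    "load_volume",
    "save_volume",
    "resample_to_grid",
    "resample_mask",
    "scale_intensities",
    "ScaledInput",
    "suv_scale_factor",
    "FIXED_GRID_SHAPE",
    "FIXED_GRID_SPACING",
    "CT_RANGE",
    "PET_RANGE",
]

FIXED_GRID_SHAPE = (128, 128, 256)
FIXED_GRID_SPACING = (4.0, 4.0, 4.0)
CT_RANGE = (-1000.0, 1000.0)
PET_RANGE = (0.0, 25.0)


class QualityCheckError(ValueError):
    """Raised when an input volume fails geometry quality control."""


def check_slice_positions(z_positions_mm: Sequence[float], rtol: float = 1e-3) -> float:
    """Verify axial slice completeness and interval regularity.

    Returns the common slice interval; raises :class:`QualityCheckError`
    naming the defect (missing slice / irregular interval) otherwise.
    """
    z = np.sort(np.asarray(z_positions_mm, dtype=float))
    if z.size < 2:
        raise QualityCheckError("fewer than 2 axial slices")
    gaps = np.diff(z)
    ref = np.median(gaps)
    if ref <= 0:
        raise QualityCheckError("duplicate axial slice positions")
    bad = np.abs(gaps - ref) > rtol * ref + 1e-9
    if bad.any():
        k = int(np.argmax(bad))
        if gaps[k] > 1.5 * ref:
            raise QualityCheckError(
                f"missing axial slice: gap of {gaps[k]:.3f} mm after slice {k} "
                f"(expected interval {ref:.3f} mm)"
            )
        raise QualityCheckError(
            f"irregular slice interval: {gaps[k]:.3f} mm after slice {k} "
            f"(expected {ref:.3f} mm)"
        )
    return float(ref)


def load_volume(path: str | Path, modality: str) -> VolumeGrid:
    """Load a NIfTI volume into the package's (x, y, z-axial) convention.

    The affine must be axis-aligned (diagonal up to sign); sheared or
    rotated geometries fail quality control, as do non-positive spacings.
    PET volumes are expected in SUV already (negative values are clipped
    to zero, as SUV is non-negative by definition).
    """
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0):
        raise QualityCheckError(f"non-positive voxel spacing {tuple(spacing)}")
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-3 * spacing.max():
        raise QualityCheckError(
            "non-axis-aligned affine (sheared or rotated grid); "
            "slice geometry cannot be verified as regular"
        )
    values = np.asanyarray(img.dataobj).astype(np.float32)
    if values.ndim != 3:
        raise QualityCheckError(f"expected a 3D volume, got shape {values.shape}")
    # normalize to positive-stepping axes
    origin = affine[:3, 3].astype(float)
    for ax in range(3):
        if rot[ax, ax] < 0:
            values = np.flip(values, axis=ax)
            origin[ax] = origin[ax] + rot[ax, ax] * (values.shape[ax] - 1)
    if modality == PET_SUV:
        values = np.clip(values, 0.0, None)
    return VolumeGrid(values, tuple(spacing), tuple(origin), modality)


def save_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing/origin in the affine."""
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# DICOM PET: body-weight SUV conversion (optional ingestion path)

def suv_scale_factor(
    *,
    weight_kg: float,
    injected_dose_bq: float,
    half_life_s: float,
    injection_to_scan_s: float,
) -> float:
    """Multiplicative factor turning activity concentration (Bq/mL) into
    body-weight SUV.

    SUV_bw = concentration / (decay-corrected dose / body weight), with the
    dose decayed from injection time to series start:
    ``dose * 2**(-dt / half_life)``.  Weight in kg is converted to grams so
    SUV is the usual dimensionless g/mL ratio.
    """
    if min(weight_kg, injected_dose_bq, half_life_s) <= 0:
        raise ValueError("weight, dose and half-life must be positive")
    decayed_dose = injected_dose_bq * 2.0 ** (-injection_to_scan_s / half_life_s)
    return weight_kg * 1000.0 / decayed_dose


def suv_factor_from_dicom(ds) -> float:
    """Extract the body-weight SUV factor from a PET DICOM dataset.

    Uses PatientWeight, RadionuclideTotalDose, RadionuclideHalfLife and the
    interval between RadiopharmaceuticalStartTime and SeriesTime.  Voxels
    must additionally be rescaled with RescaleSlope/Intercept to Bq/mL
    before applying this factor.
    """
    info = ds.RadiopharmaceuticalInformationSequence[0]
    t0 = _dicom_time_s(str(info.RadiopharmaceuticalStartTime))
    t1 = _dicom_time_s(str(ds.SeriesTime))
    return suv_scale_factor(
        weight_kg=float(ds.PatientWeight),
        injected_dose_bq=float(info.RadionuclideTotalDose),
        half_life_s=float(info.RadionuclideHalfLife),
        injection_to_scan_s=t1 - t0,
    )


def _dicom_time_s(tm: str) -> float:
    """DICOM TM (HHMMSS.frac) to seconds since midnight."""
    tm = tm.strip()
    h, m = int(tm[0:2]), int(tm[2:4])
    s = float(tm[4:]) if len(tm) > 4 else 0.0
    return h * 3600.0 + m * 60.0 + s


def load_dicom_pet_series(directory: str | Path) -> VolumeGrid:
    """Minimal DICOM PET series reader: sort by slice position, check
    interval regularity, stack, rescale to Bq/mL and convert to SUV."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = [float(s.ImagePositionPatient[2]) for s in slices]
    dz = check_slice_positions(zs)
    factor = suv_factor_from_dicom(slices[0])
    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float32)
        arr = arr * float(getattr(s, "RescaleSlope", 1.0)) + float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr.T)  # DICOM rows/cols -> (x, y)
    values = np.clip(np.stack(planes, axis=-1) * factor, 0.0, None)
    ps = [float(v) for v in slices[0].PixelSpacing]
    origin = tuple(float(v) for v in slices[0].ImagePositionPatient)
    return VolumeGrid(values, (ps[1], ps[0], dz), origin, PET_SUV)


# ---------------------------------------------------------------------------
# Resampling

def resample_to_grid(
    v: VolumeGrid,
    shape: tuple[int, int, int] = FIXED_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = FIXED_GRID_SPACING,
) -> VolumeGrid:
    """Trilinear resampling onto the fixed CNN grid.

    The output physical field is centered on the input field's center;
    voxels that fall outside the input field are filled with the
    modality's background (0 SUV for PET, -1000 HU for CT).
    """
    return _resample(v, shape, spacing_mm, order=1, cval=v.background_value)


def resample_mask(
    mask: np.ndarray,
    source: VolumeGrid,
    shape: tuple[int, int, int] = FIXED_GRID_SHAPE,
    spacing_mm: tuple[float, float, float] = FIXED_GRID_SPACING,
) -> tuple[np.ndarray, VolumeGrid]:
    """Nearest-neighbor resampling for label/binary volumes.

    Labels are carried, never interpolated, so the output label set is a
    subset of the input's.  Returns the resampled array and its grid.
    """
    src = source.with_values(np.asarray(mask))
    out = _resample(src, shape, spacing_mm, order=0, cval=0)
    values = out.values
    if np.asarray(mask).dtype == bool:
        values = values.astype(bool)
    else:
        values = np.rint(values).astype(np.asarray(mask).dtype)
    return values, out.with_values(values)


def _resample(v: VolumeGrid, shape, spacing_mm, order: int, cval: float) -> VolumeGrid:
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing_mm, dtype=float)
    center = v.physical_center_mm()
    origin = center - (np.asarray(shape) - 1) / 2.0 * spacing

    idx = np.indices(shape, dtype=float)
    world = origin[:, None, None, None] + idx * spacing[:, None, None, None]
    src_idx = (world - np.asarray(v.origin_mm)[:, None, None, None]) / np.asarray(
        v.spacing_mm
    )[:, None, None, None]
    values = ndimage.map_coordinates(
        np.asarray(v.values, dtype=float), src_idx, order=order,
        mode="grid-constant", cval=cval, prefilter=False,
    )
    return VolumeGrid(values.astype(np.float32) if order else values,
                      tuple(spacing), tuple(origin), v.modality)


# ---------------------------------------------------------------------------
# Intensity scaling

@dataclass
class ScaledInput:
    """The two aligned, 0-1 scaled channels the network consumes."""

    ct: np.ndarray
    pet: np.ndarray
    grid: VolumeGrid  # geometry shared by both channels

    def stack(self) -> np.ndarray:
        """(2, nx, ny, nz) array, CT first then PET."""
        return np.stack([self.ct, self.pet], axis=0)


def _affine01(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((np.asarray(values, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)


def scale_intensities(ct: VolumeGrid, pet: VolumeGrid) -> ScaledInput:
    """Affine 0-1 scaling: CT from [-1000, 1000] HU, PET from [0, 25] SUV,
    clipping values outside the range (the map stays fixed across cases)."""
    if ct.modality != CT_HU or pet.modality != PET_SUV:
        raise ValueError("expected (CT_HU, PET_SUV) volumes")
    if not ct.same_geometry(pet, atol=1e-3):
        raise ValueError("CT and PET must share the same grid geometry")
    return ScaledInput(
        ct=_affine01(ct.values, *CT_RANGE),
        pet=_affine01(pet.values, *PET_RANGE),
        grid=pet.with_values(pet.values),
    )


def unscale_pet(scaled: np.ndarray) -> np.ndarray:
    """Inverse of the PET channel scaling on the in-range interval."""
    lo, hi = PET_RANGE
    return np.asarray(scaled, dtype=float) * (hi - lo) + lo
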