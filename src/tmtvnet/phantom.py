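"""Synthetic whole-body PET/CT phantoms with exact analytic ground truth.

Clinical lymphoma PET/CT cohorts are restricted data, so this module
generates seed-controlled stand-ins: an elliptical "body" on CT, hot
ellipsoidal lesions (optionally coalescent double-peak masses and
Gaussian-heterogeneous uptake), physiological uptakes such as brain and
bladder, an optional injection-site artifact at an arm edge, and additive
Gaussian noise on the PET signal.

Each lesion's analytic ellipsoid volume (4/3*pi*r1*r2*r3) is recorded as
truth alongside a voxelized truth mask, so segmentation accuracy can be
checked against exact geometry rather than against another segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .grids import VolumeGrid, RoiSet, PET_SUV, CT_HU

__all__ = [
    "LesionSpec",
    "OrganSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "manual_roi_boxes",
]


@dataclass
class LesionSpec:
    """One FDG-avid lesion: an ellipsoid with flat or Gaussian uptake.

    ``partner_offset_mm`` adds a second identical lobe displaced by the
    given offset, producing the coalescent double-peak masses that make
    per-lesion thresholding hard in lymphoma.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float
    profile: str = "flat"  # "flat" | "gaussian"
    partner_offset_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.center_mm = tuple(float(c) for c in self.center_mm)
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"lesion radii must be positive, got {self.radii_mm}")
        if self.peak_suv <= 0:
            raise ValueError(f"peak_suv must be positive, got {self.peak_suv}")
        if self.profile not in ("flat", "gaussian"):
            raise ValueError(f"profile must be 'flat' or 'gaussian', got {self.profile!r}")

    @property
    def analytic_volume_ml(self) -> float:
        """Exact ellipsoid volume in mL; doubled for coalescent pairs."""
        v = 4.0 / 3.0 * np.pi * float(np.prod(self.radii_mm)) / 1000.0
        return 2.0 * v if self.partner_offset_mm is not None else v

    def lobe_centers(self) -> list[np.ndarray]:
        centers = [np.asarray(self.center_mm)]
        if self.partner_offset_mm is not None:
            centers.append(np.asarray(self.center_mm) + np.asarray(self.partner_offset_mm))
        return centers


@dataclass
class OrganSpec:
    """A physiological uptake (brain, bladder, ...): sphere of given SUV."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float


@dataclass
class ArtifactSpec:
    """Injection-site tracer extravasation: a small very hot blob at an
    arm-edge location, deliberately excluded from the truth masks (it is
    the classic false-positive of automated TMTV segmentation)."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 8.0
    suv: float = 15.0


@dataclass
class PhantomSpec:
    """Full description of one synthetic PET/CT case."""

    grid_shape: tuple[int, int, int] = (64, 64, 128)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    lesions: list[LesionSpec] = field(default_factory=list)
    organs: list[OrganSpec] = field(default_factory=list)
    background_suv: float = 0.7
    noise_sd: float = 0.1
    artifact: ArtifactSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(s <= 0 for s in self.grid_shape) or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("grid_shape and voxel_spacing_mm must be positive")
        if self.background_suv <= 0:
            raise ValueError("background_suv must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_spacing_mm)
        for i, les in enumerate(self.lesions):
            if les.peak_suv <= self.background_suv:
                raise ValueError(
                    f"lesion {i}: peak_suv {les.peak_suv} must exceed background_suv "
                    f"{self.background_suv} (lesions are FDG-avid)"
                )
            for c in les.lobe_centers():
                if np.any(c < 0) or np.any(c >= extent):
                    raise ValueError(
                        f"lesion {i}: center {tuple(c)} lies outside the grid "
                        f"(physical extent {tuple(extent)} mm)"
                    )
        for j, org in enumerate(self.organs):
            c = np.asarray(org.center_mm)
            if np.any(c < 0) or np.any(c >= extent):
                raise ValueError(f"organ {j}: center {org.center_mm} lies outside the grid")


@dataclass
class PhantomCase:
    """Everything :func:`generate_phantom` produces for one case."""

    pet: VolumeGrid
    ct: VolumeGrid
    truth_masks: RoiSet
    truth_volumes_ml: dict[int, float]
    spec: PhantomSpec


def _world_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis world coordinates of voxel centers (broadcastable)."""
    sp = spec.voxel_spacing_mm
    xs = np.arange(spec.grid_shape[0]) * sp[0]
    ys = np.arange(spec.grid_shape[1]) * sp[1]
    zs = np.arange(spec.grid_shape[2]) * sp[2]
    return (
        xs[:, None, None],
        ys[None, :, None],
        zs[None, None, :],
    )


def _lesion_field(les: LesionSpec, coords) -> np.ndarray:
    """Noise-free SUV contribution of a lesion (max over its lobes).

    Flat: peak_suv inside the ellipsoid.  Gaussian: anisotropic Gaussian
    attaining peak_suv at the center with sigma = radius / 2 per axis, so
    uptake at the nominal boundary falls to ~13.5% of the peak.
    """
    x, y, z = coords
    out = None
    for c in les.lobe_centers():
        rx, ry, rz = les.radii_mm
        q = ((x - c[0]) / rx) ** 2 + ((y - c[1]) / ry) ** 2 + ((z - c[2]) / rz) ** 2
        if les.profile == "flat":
            f = np.where(q <= 1.0, les.peak_suv, 0.0)
        else:
            f = les.peak_suv * np.exp(-2.0 * q)  # sigma_i = r_i / 2
        out = f if out is None else np.maximum(out, f)
    return out


def _sphere_field(center, radius, value, coords) -> np.ndarray:
    x, y, z = coords
    c = np.asarray(center, dtype=float)
    q = ((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / radius**2
    return np.where(q <= 1.0, value, 0.0)


def _schematic_ct(spec: PhantomSpec) -> np.ndarray:
    """Schematic CT: air at -1000 HU, an elliptical soft-tissue body near
    0 HU, and two bone-like rods at +700 HU along the axial direction."""
    x, y, z = _world_coords(spec)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_spacing_mm)
    cx, cy = extent[0] / 2, extent[1] / 2
    body = ((x - cx) / (0.42 * extent[0])) ** 2 + ((y - cy) / (0.38 * extent[1])) ** 2
    ct = np.full(spec.grid_shape, -1000.0)
    ct = np.where(body <= 1.0, 30.0, ct)  # soft tissue
    for dx in (-0.12, 0.12):  # paired paravertebral bone rods
        rod = (x - (cx + dx * extent[0])) ** 2 + (y - (cy - 0.15 * extent[1])) ** 2
        ct = np.where(rod <= (0.04 * min(extent[0], extent[1])) ** 2, 700.0, ct)
    return ct + 0.0 * z  # broadcast to 3D


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one synthetic PET/CT case with exact ground truth.

    The noise-free PET is the voxel-wise maximum of the background, every
    lesion/organ/artifact contribution (so a lesion's peak SUV is attained
    exactly); seeded Gaussian noise is then added and clipped at zero.
    The truth mask of lesion ``i`` contains the voxels whose *noise-free
    lesion contribution* exceeds ``background_suv`` — an analytic,
    noise-independent definition.
    """
    coords = _world_coords(spec)
    rng = np.random.default_rng(spec.seed)

    pet = np.full(spec.grid_shape, spec.background_suv, dtype=float)
    truth = RoiSet(shape=spec.grid_shape)
    truth_volumes: dict[int, float] = {}

    for i, les in enumerate(spec.lesions):
        f = _lesion_field(les, coords)
        pet = np.maximum(pet, f)
        truth.add(i + 1, f > spec.background_suv)
        truth_volumes[i + 1] = les.analytic_volume_ml

    for org in spec.organs:
        pet = np.maximum(pet, _sphere_field(org.center_mm, org.radius_mm, org.suv, coords))
    if spec.artifact is not None:
        a = spec.artifact
        pet = np.maximum(pet, _sphere_field(a.center_mm, a.radius_mm, a.suv, coords))

    if spec.noise_sd > 0:
        pet = pet + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    pet = np.clip(pet, 0.0, None)

    ct = _schematic_ct(spec)

    pet_grid = VolumeGrid(pet.astype(np.float32), spec.voxel_spacing_mm, modality=PET_SUV)
    ct_grid = VolumeGrid(ct.astype(np.float32), spec.voxel_spacing_mm, modality=CT_HU)
    return PhantomCase(pet=pet_grid, ct=ct_grid, truth_masks=truth,
                       truth_volumes_ml=truth_volumes, spec=spec)


def manual_roi_boxes(truth_masks: RoiSet, margin_mm: float,
                     spacing_mm: Sequence[float]) -> RoiSet:
    """Loose manual-style ROIs: each lesion's bounding box dilated by a
    physician-like margin and clipped to the grid.

    Emulates how readers circle uptakes generously rather than tracing
    them; overlapping boxes keep their distinct ids.  ROIs that would
    contain no lesion voxel (empty truth mask) are never emitted.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    margins = [int(np.ceil(margin_mm / s)) for s in spacing_mm]
    out = RoiSet(shape=truth_masks.shape)
    for rid, mask in truth_masks.items():
        if not mask.any():
            continue
        idx = np.nonzero(mask)
        box = np.zeros(truth_masks.shape, dtype=bool)
        lo = [max(0, int(idx[a].min()) - margins[a]) for a in range(3)]
        hi = [min(truth_masks.shape[a], int(idx[a].max()) + margins[a] + 1) for a in range(3)]
        box[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        out.add(rid, box)
    return out


# ---------------------------------------------------------------------------
# Serialization (NIfTI volumes + JSON sidecar with the analytic truth)

def save_phantom(case: PhantomCase, out_dir: str | Path) -> dict[str, Path]:
    """Write PET/CT/truth-label NIfTIs plus a JSON truth sidecar."""
    from .io_preprocess import save_volume  # local import: avoid cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pet": out / "pet.nii.gz",
        "ct": out / "ct.nii.gz",
        "truth": out / "truth_labels.nii.gz",
        "sidecar": out / "truth.json",
    }
    save_volume(case.pet, paths["pet"])
    save_volume(case.ct, paths["ct"])
    labels = case.truth_masks.to_labels()
    save_volume(case.pet.with_values(labels), paths["truth"])
    sidecar = []
    for i, les in enumerate(case.spec.lesions):
        sidecar.append({
            "lesion_id": i + 1,
            "center_mm": list(les.center_mm),
            "radii_mm": list(les.radii_mm),
            "peak_suv": les.peak_suv,
            "profile": les.profile,
            "analytic_volume_ml": les.analytic_volume_ml,
        })
    paths["sidecar"].write_text(json.dumps(sidecar, indent=2))
    return paths


def spec_from_json(path: str | Path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a JSON file (CLI entry point)."""
    raw = json.loads(Path(path).read_text())
    lesions = [LesionSpec(**d) for d in raw.pop("lesions", [])]
    organs = [OrganSpec(**d) for d in raw.pop("organs", [])]
    artifact = raw.pop("artifact", None)
    return PhantomSpec(
        lesions=lesions,
        organs=organs,
        artifact=ArtifactSpec(**artifact) if artifact else None,
        **raw,
    )


def spec_to_json(spec: PhantomSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(spec), indent=2))
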