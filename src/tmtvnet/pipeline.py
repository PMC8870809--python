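"""End-to-end composition helpers: phantom -> preprocessed training case.

These glue the pipeline stages together for simulation studies: a seeded
random phantom population, and the conversion of one phantom into the
(scaled CT+PET channels, TMTVprob target) pair the network trains on.
"""

from __future__ import annotations

import numpy as np

from .grids import RoiSet
from .io_preprocess import scale_intensities
from .phantom import PhantomCase, PhantomSpec, LesionSpec, OrganSpec, ArtifactSpec, \
    generate_phantom, manual_roi_boxes
from .thresholds import ground_truth_for_case
from .vnet.train import TrainingCase

__all__ = ["random_phantom_spec", "training_case_from_phantom", "make_cohort"]

#: loose manual-style ROI margin around each lesion (mm)
DEFAULT_ROI_MARGIN_MM = 8.0


def random_phantom_spec(
    seed: int,
    grid_shape: tuple[int, int, int] = (64, 64, 128),
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
    n_lesions: tuple[int, int] = (1, 4),
    peak_suv: tuple[float, float] = (6.0, 15.0),
    radii_mm: tuple[float, float] = (8.0, 16.0),
    background_suv: float = 0.7,
    noise_sd: float = 0.15,
    gaussian_fraction: float = 0.3,
    coalescent_fraction: float = 0.2,
    with_organs: bool = False,
    with_artifact: bool = False,
) -> PhantomSpec:
    """A seeded random case emulating an FDG-avid lymphoma presentation.

    Lesion count, positions (central 50% of the field, where the body
    lies), radii and peak SUVs are drawn uniformly from the given ranges;
    a fraction of lesions get heterogeneous (Gaussian) uptake or a
    coalescent partner lobe.  Optional physiological uptakes (brain-like
    sphere at the cranial end, bladder-like at the caudal third) and an
    arm-edge injection artifact exercise the false-positive pitfalls.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(grid_shape) * np.asarray(voxel_spacing_mm)
    lesions = []
    for _ in range(int(rng.integers(n_lesions[0], n_lesions[1] + 1))):
        center = tuple(rng.uniform(0.25, 0.75, 3) * extent)
        radii = tuple(rng.uniform(*radii_mm, 3))
        profile = "gaussian" if rng.random() < gaussian_fraction else "flat"
        partner = None
        if rng.random() < coalescent_fraction:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            partner = tuple(direction * 1.2 * np.mean(radii))
        lesions.append(
            LesionSpec(center, radii, peak_suv=float(rng.uniform(*peak_suv)),
                       profile=profile, partner_offset_mm=partner)
        )
    organs = []
    if with_organs:
        organs = [
            OrganSpec((extent[0] / 2, extent[1] / 2, 0.92 * extent[2]), 0.1 * extent[2], 7.0),
            OrganSpec((extent[0] / 2, extent[1] / 2, 0.12 * extent[2]), 0.05 * extent[2], 9.0),
        ]
    artifact = None
    if with_artifact:
        artifact = ArtifactSpec((0.06 * extent[0], extent[1] / 2, 0.7 * extent[2]))
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_spacing_mm=voxel_spacing_mm,
        lesions=lesions,
        organs=organs,
        background_suv=background_suv,
        noise_sd=noise_sd,
        artifact=artifact,
        seed=int(seed),
    )


def training_case_from_phantom(
    case: PhantomCase, roi_margin_mm: float = DEFAULT_ROI_MARGIN_MM
) -> tuple[TrainingCase, np.ndarray, RoiSet]:
    """Phantom -> (network training case, TMTVprob, manual-style ROIs).

    Loose ROI boxes stand in for the physician delineation, the four
    threshold operators build the TMTVprob target, and the CT/PET pair is
    0-1 scaled.  The phantom must already be on the network grid.
    """
    rois = manual_roi_boxes(case.truth_masks, roi_margin_mm, case.spec.voxel_spacing_mm)
    prob = ground_truth_for_case(case.pet, rois)
    scaled = scale_intensities(case.ct, case.pet)
    tc = TrainingCase(
        case_id=f"phantom-{case.spec.seed}", inputs=scaled.stack(), target=prob
    )
    return tc, prob, rois


def make_cohort(
    n_cases: int, seed: int, **spec_kwargs
) -> list[tuple[PhantomCase, TrainingCase]]:
    """Generate ``n_cases`` seeded random phantoms with training cases."""
    rng = np.random.default_rng(seed)
    out = []
    for case_seed in rng.integers(0, 2**31 - 1, size=n_cases):
        case = generate_phantom(random_phantom_spec(int(case_seed), **spec_kwargs))
        tc, _, _ = training_case_from_phantom(case)
        out.append((case, tc))
    return out
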