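"""Shared phantom fixtures for the test suite (all generated at run time)."""

import numpy as np
import pytest

from tmtvnet import (
    ArtifactSpec,
    LesionSpec,
    PhantomSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def sphere_case():
    """Flat 10 mm-radius sphere (analytic volume 4.19 mL) on a 2 mm grid."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        voxel_spacing_mm=(2.0, 2.0, 2.0),
        lesions=[LesionSpec(center_mm=(40, 40, 40), radii_mm=(10, 10, 10), peak_suv=10.0)],
        background_suv=0.5,
        noise_sd=0.05,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def two_lesion_case():
    """Two well-separated flat lesions with SUVmax 10 and 4 (noise-free),
    so the 41% methodology must apply two distinct per-lesion thresholds."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 64),
        voxel_spacing_mm=(4.0, 4.0, 4.0),
        lesions=[
            LesionSpec(center_mm=(64, 64, 64), radii_mm=(12, 12, 12), peak_suv=10.0),
            LesionSpec(center_mm=(64, 64, 192), radii_mm=(12, 12, 12), peak_suv=4.0),
        ],
        background_suv=0.7,
        noise_sd=0.0,
        seed=3,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def coalescent_case():
    """One >30 mL double-peak Gaussian mass (coalescent nodal conglomerate)."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        voxel_spacing_mm=(4.0, 4.0, 4.0),
        lesions=[
            LesionSpec(
                center_mm=(52, 64, 54),
                radii_mm=(16, 16, 16),
                peak_suv=12.0,
                profile="gaussian",
                partner_offset_mm=(16.0, 0.0, 20.0),
            )
        ],
        background_suv=0.7,
        noise_sd=0.0,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def artifact_case():
    """Lesion plus an arm-edge injection artifact excluded from the truth."""
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        voxel_spacing_mm=(4.0, 4.0, 4.0),
        lesions=[LesionSpec(center_mm=(64, 64, 64), radii_mm=(12, 12, 12), peak_suv=8.0)],
        background_suv=0.7,
        noise_sd=0.1,
        artifact=ArtifactSpec(center_mm=(8, 64, 96), radius_mm=8.0, suv=15.0),
        seed=17,
    )
    return generate_phantom(spec)
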