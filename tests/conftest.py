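"""Shared fixtures: analytic phantoms and the (expensive) trained segmenter.

All fixtures are generated programmatically; session scope keeps the
30-phantom training run and the simulated imaging cohort to one execution
for the whole suite.
"""

import numpy as np
import pytest

import enterometry as em
from enterometry.pipeline import simulate_imaging_study, train_segmentation_model
from enterometry.segmentation import SemiAutoConfig


def axial_tube_spec(
    wall_thickness=6.0,
    lumen_radius=5.0,
    length_mm=100.0,
    spacing=(1.3, 1.3, 5.0),
    n_inplane=48,
    noise_sigma=0.0,
    **kwargs,
):
    """A straight tube along the slice-normal axis, ends on slice boundaries.

    Coronal slices cut the tube transversely, so slice-wise thickness and
    in-plane annulus voxelization behave as for a clean 2D annulus.
    """
    c = n_inplane * spacing[0] / 2.0
    z0 = 3 * spacing[2]
    nz = int(np.ceil((z0 * 2 + length_mm) / spacing[2]))
    ctrl = np.array([[c, c, z0], [c, c, z0 + length_mm / 2], [c, c, z0 + length_mm]])
    return em.PhantomSpec(
        grid_shape=(n_inplane, n_inplane, nz),
        spacing=spacing,
        curve_control_points=ctrl,
        lumen_radius_mm=lumen_radius,
        wall_thickness_mm=wall_thickness,
        noise_sigma=noise_sigma,
        **kwargs,
    )


@pytest.fixture(scope="session")
def wall6_phantom():
    """Noise-free constant 6 mm wall tube at study spacing."""
    return em.make_phantom(axial_tube_spec(wall_thickness=6.0))


@pytest.fixture(scope="session")
def ramp_phantom():
    """Noise-free variable-thickness tube, cosine ramp 3 -> 8 mm."""
    spec = axial_tube_spec(wall_thickness=em.cosine_ramp_thickness(3.0, 8.0))
    return em.make_phantom(spec)


@pytest.fixture(scope="session")
def semiauto_config():
    return SemiAutoConfig()


@pytest.fixture(scope="session")
def trained_model(semiauto_config):
    """Partition scorer trained on 30 randomized tube phantoms."""
    return train_segmentation_model(n_phantoms=30, config=semiauto_config, rng_seed=202)


@pytest.fixture(scope="session")
def imaging_study_table(trained_model, semiauto_config):
    """Simulated 20-subject x 3-timepoint imaging cohort, fully measured
    (perturbed-truth manual masks and semi-automated segmentation), with
    the reference study's missing-data pattern."""
    return simulate_imaging_study(
        n_subjects=20,
        model=trained_model,
        config=semiauto_config,
        rng_seed=303,
        n_missing_month6=2,
        n_missing_all_followup=1,
    )
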