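"""Shared fixtures: a small desk-scale scanner, phantoms and acquisitions.

Everything is generated programmatically at test time; session scope keeps
the expensive simulations (SSS, acquisitions) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from scatterscale.acquisition import simulate_acquisition
from scatterscale.geometry import build_geometry
from scatterscale.input_function import make_input_function
from scatterscale.motion import RigidShift
from scatterscale.phantoms import default_phantom_spec, make_head_phantom, tracer_profile
from scatterscale.schedules import FrameSchedule


SMALL_GEOMETRY = dict(
    n_rings=4,
    ring_pitch_mm=6.0,
    n_angles=48,
    n_radial=96,
    radial_pitch_mm=1.22,
    max_ring_difference=2,
    fov_radius_mm=45.0,
)


@pytest.fixture(scope="session")
def geometry():
    return build_geometry(SMALL_GEOMETRY)


@pytest.fixture(scope="session")
def head_phantom(geometry):
    """Verapamil-style head: 30 mm radius, 4 mm skin, two interior regions."""
    spec = default_phantom_spec(
        head_radius_mm=30.0,
        skin_thickness_mm=4.0,
        axial_extent_mm=geometry.n_rings * geometry.ring_pitch_mm,
    )
    return make_head_phantom(spec, geometry, nxy=48)


@pytest.fixture(scope="session")
def fine_phantom(geometry):
    """Same head on a finer grid (less edge smear for tail-fit checks)."""
    spec = default_phantom_spec(
        head_radius_mm=30.0,
        skin_thickness_mm=4.0,
        axial_extent_mm=geometry.n_rings * geometry.ring_pitch_mm,
    )
    return make_head_phantom(spec, geometry, nxy=64)


@pytest.fixture(scope="session")
def gradient_phantom(geometry):
    spec = default_phantom_spec(
        head_radius_mm=30.0,
        skin_thickness_mm=4.0,
        axial_extent_mm=geometry.n_rings * geometry.ring_pitch_mm,
        axial_gradient=0.6,
    )
    return make_head_phantom(spec, geometry, nxy=48)


@pytest.fixture(scope="session")
def input_fn():
    return make_input_function()


@pytest.fixture(scope="session")
def late_frame_schedule():
    """A single late 10-min frame (quasi-static scan)."""
    return FrameSchedule.from_durations([600.0], start_s=3000.0)


@pytest.fixture(scope="session")
def verapamil():
    return tracer_profile("verapamil_like")


@pytest.fixture(scope="session")
def aligned_acquisition(fine_phantom, verapamil, late_frame_schedule, input_fn,
                        geometry):
    """No transmission/emission mismatch, 2e6 counts, 35 % scatter."""
    return simulate_acquisition(
        fine_phantom,
        verapamil,
        late_frame_schedule,
        input_fn,
        geometry,
        mismatch=RigidShift(),
        scatter_fraction=0.35,
        counts_per_frame=2e6,
        seed=11,
    )


@pytest.fixture(scope="session")
def mismatch_acquisition(fine_phantom, verapamil, late_frame_schedule, input_fn,
                         geometry):
    """5 mm radial mu-map shift (patient moved between the scans)."""
    return simulate_acquisition(
        fine_phantom,
        verapamil,
        late_frame_schedule,
        input_fn,
        geometry,
        mismatch=RigidShift(5.0, 0.0, 0.0),
        scatter_fraction=0.35,
        counts_per_frame=2e6,
        seed=11,
    )


@pytest.fixture(scope="session")
def mismatch_expectation(fine_phantom, verapamil, late_frame_schedule, input_fn,
                         geometry):
    """Same mismatch acquisition without Poisson noise (expectation data)."""
    return simulate_acquisition(
        fine_phantom,
        verapamil,
        late_frame_schedule,
        input_fn,
        geometry,
        mismatch=RigidShift(5.0, 0.0, 0.0),
        scatter_fraction=0.35,
        counts_per_frame=2e6,
        seed=11,
        noise=False,
    )


@pytest.fixture(scope="session")
def true_scatter_model(aligned_acquisition, fine_phantom, geometry):
    """SSS estimator evaluated on the true (unshifted) configuration."""
    from scatterscale.scatter import sss_estimate

    truth = aligned_acquisition.truth_frames[0]
    act = fine_phantom[0].with_values(truth.values)
    return sss_estimate(act, fine_phantom[1], geometry, mode="sss3d")
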