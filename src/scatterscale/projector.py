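"""Line-integral forward/back projection and ACF sinograms.

The projector samples each LOR at a fixed step (half the smallest voxel
pitch) with trilinear interpolation; ``back_project`` is the exact matrix
transpose of ``forward_project``, which OSEM relies on.
"""

from __future__ import annotations

import numpy as np

from ._ray import back_line_integrals, line_integrals
from .geometry import ScannerGeometry
from .sinogram import Sinogram
from .volume import VolumeImage

__all__ = ["forward_project", "back_project", "compute_acf"]


def _check(volume: VolumeImage, geometry: ScannerGeometry) -> None:
    ext_x = volume.shape[0] * volume.voxel_pitch_mm[0]
    if ext_x < 2 * geometry.fov_radius_mm - volume.voxel_pitch_mm[0]:
        raise ValueError("volume grid does not cover the transverse FOV")


def _step(volume: VolumeImage) -> float:
    return min(volume.voxel_pitch_mm) / 2.0


def forward_project(volume: VolumeImage, geometry: ScannerGeometry) -> Sinogram:
    """Line integral of the volume along every LOR (input units x mm)."""
    _check(volume, geometry)
    a, b = geometry.endpoints()
    px, py, pz = volume.voxel_pitch_mm
    vals = line_integrals(
        np.ascontiguousarray(volume.values, dtype=np.float64),
        px, py, pz, a, b, _step(volume),
    )
    return Sinogram(values=vals, kind="emission", geometry=geometry)


def back_project(
    sinogram_values: np.ndarray | Sinogram,
    geometry: ScannerGeometry,
    template: VolumeImage,
    bin_mask: np.ndarray | None = None,
) -> VolumeImage:
    """Adjoint of :func:`forward_project` onto the template's grid.

    ``bin_mask`` restricts the smear to a subset of bins (used for OSEM
    subsets); masked-out bins contribute nothing.
    """
    if isinstance(sinogram_values, Sinogram):
        y = sinogram_values.values
    else:
        y = np.asarray(sinogram_values, dtype=np.float64).reshape(-1)
    if y.size != geometry.n_bins:
        raise ValueError("sinogram length does not match geometry")
    if bin_mask is not None:
        y = np.where(bin_mask, y, 0.0)
    a, b = geometry.endpoints()
    px, py, pz = template.voxel_pitch_mm
    out = np.zeros(template.shape, dtype=np.float64)
    back_line_integrals(out, px, py, pz, a, b, _step(template), y)
    return template.with_values(out, quantity="activity_kBq_per_ml")


def compute_acf(mu_map: VolumeImage, geometry: ScannerGeometry) -> Sinogram:
    """Attenuation correction factors exp(line integral of mu) per LOR.

    Bins whose LOR misses the object have an integral of exactly zero and an
    ACF of exactly one.
    """
    if mu_map.quantity != "mu_per_mm":
        raise ValueError("compute_acf requires a mu_per_mm volume")
    if np.any(mu_map.values < 0):
        raise ValueError("mu map must be non-negative")
    proj = forward_project(mu_map.with_values(mu_map.values), geometry)
    return Sinogram(values=np.exp(proj.values), kind="acf", geometry=geometry)
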