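"""Voxel images: activity maps, attenuation (mu) maps and label maps.

Values live on an (x, y, z) grid with the physical origin at the volume
centre; NIfTI round-trips carry the voxel pitch in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "default_volume_grid", "load_nifti", "MU_SOFT_TISSUE"]

#: linear attenuation coefficient of soft tissue / water at 511 keV, 1/mm
MU_SOFT_TISSUE = 0.0096

QUANTITIES = ("activity_kBq_per_ml", "mu_per_mm", "label")


@dataclass
class VolumeImage:
    """Scalar field on a voxel grid.

    ``voxel_pitch_mm`` is an (x, y, z) triple; the grid is centred on the
    physical origin.  ``quantity`` declares the physical meaning and drives
    validation: mu maps must lie in [0, 0.02] /mm, activity must be
    non-negative, labels must be integer-valued.
    """

    values: np.ndarray
    voxel_pitch_mm: tuple[float, float, float]
    quantity: str = "activity_kBq_per_ml"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D (x, y, z) array")
        if np.isscalar(self.voxel_pitch_mm):
            p = float(self.voxel_pitch_mm)  # type: ignore[arg-type]
            self.voxel_pitch_mm = (p, p, p)
        self.voxel_pitch_mm = tuple(float(p) for p in self.voxel_pitch_mm)
        if any(p <= 0 for p in self.voxel_pitch_mm):
            raise ValueError("voxel pitch must be positive")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}")
        self.validate()

    def validate(self) -> None:
        v = self.values
        if self.quantity == "mu_per_mm":
            if np.any(v < 0) or np.any(v > 0.02):
                raise ValueError("mu values must lie in [0, 0.02] per mm")
        elif self.quantity == "activity_kBq_per_ml":
            if np.any(v < 0):
                raise ValueError("activity values must be non-negative")
        elif self.quantity == "label":
            if not np.issubdtype(v.dtype, np.integer) and not np.allclose(
                v, np.round(v)
            ):
                raise ValueError("label values must be integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        px, py, pz = self.voxel_pitch_mm
        return px * py * pz / 1000.0

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along each axis."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * p
            for n, p in zip(self.shape, self.voxel_pitch_mm)
        )  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, quantity: str | None = None):
        return replace(self, values=values, quantity=quantity or self.quantity)

    def congruent_with(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_pitch_mm, other.voxel_pitch_mm
        )

    # ---- NIfTI round trip -------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.voxel_pitch_mm) + [1.0])
        # keep origin at volume centre
        for i in range(3):
            affine[i, 3] = -(self.shape[i] - 1) / 2.0 * self.voxel_pitch_mm[i]
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float64), affine)
        img.header["descrip"] = self.quantity.encode()[:79]
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, quantity: str | None = None) -> "VolumeImage":
        img = nib.load(path)
        pitch = tuple(float(z) for z in img.header.get_zooms()[:3])
        if quantity is None:
            quantity = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
            if quantity not in QUANTITIES:
                quantity = "activity_kBq_per_ml"
        values = np.asarray(img.dataobj, dtype=np.float64)
        if quantity == "label":
            values = np.round(values).astype(np.int32)
        return cls(values=values, voxel_pitch_mm=pitch, quantity=quantity)


def load_nifti(path: str, quantity: str | None = None) -> VolumeImage:
    return VolumeImage.from_nifti(path, quantity=quantity)


def default_volume_grid(
    geometry, nxy: int = 64, quantity: str = "activity_kBq_per_ml"
) -> VolumeImage:
    """Empty volume matched to a scanner geometry.

    Transverse pitch spans the FOV diameter with ``nxy`` voxels; axially the
    grid has ``2 * n_rings - 1`` slices at half the ring pitch, covering the
    axial extent of the detector rings exactly.
    """
    pitch_xy = 2.0 * geometry.fov_radius_mm / nxy
    nz = 2 * geometry.n_rings - 1
    pitch_z = geometry.ring_pitch_mm / 2.0
    values = np.zeros((nxy, nxy, nz))
    if quantity == "label":
        values = values.astype(np.int32)
    return VolumeImage(
        values=values, voxel_pitch_mm=(pitch_xy, pitch_xy, pitch_z), quantity=quantity
    )
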