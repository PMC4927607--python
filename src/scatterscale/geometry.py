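"""Cylindrical scanner geometry and LOR bookkeeping.

The sinogram is parameterised parallel-beam style: each bin is identified by
(segment, plane, angle, radial).  A segment collects LORs with a fixed ring
difference ``d`` (segment 0 holds the direct, in-plane LORs); a plane within
segment ``d`` is an ordered ring pair ``(ring_a, ring_b)`` with
``ring_b - ring_a = d``.  The LOR tilts axially between the two ring planes.

Coordinates: physical origin at the centre of the field of view, radial bin 0
at the negative FOV edge, voxel indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["ScannerGeometry", "build_geometry", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised for inconsistent scanner geometry parameters."""


@dataclass(frozen=True)
class ScannerGeometry:
    """Miniature cylindrical PET scanner.

    Parameters
    ----------
    n_rings : int
        Number of detector rings along the axial direction.
    ring_pitch_mm : float
        Axial spacing between adjacent rings.
    n_angles : int
        Number of projection angles over 180 degrees.
    n_radial : int
        Number of radial bins per projection.
    radial_pitch_mm : float
        Radial sampling pitch.
    max_ring_difference : int
        Largest |ring_b - ring_a| accepted; segments run from
        ``-max_ring_difference`` to ``+max_ring_difference``.
    fov_radius_mm : float
        Transverse field-of-view radius; the radial extent must cover it.
    """

    n_rings: int = 8
    ring_pitch_mm: float = 9.76
    n_angles: int = 96
    n_radial: int = 128
    radial_pitch_mm: float = 1.525
    max_ring_difference: int = 3
    fov_radius_mm: float = 90.0

    def __post_init__(self) -> None:
        for name in ("n_rings", "n_angles", "n_radial"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("ring_pitch_mm", "radial_pitch_mm", "fov_radius_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.max_ring_difference < 0:
            raise ConfigurationError("max_ring_difference must be >= 0")
        if self.max_ring_difference >= self.n_rings:
            raise ConfigurationError(
                "max_ring_difference must be smaller than n_rings "
                f"({self.max_ring_difference} >= {self.n_rings})"
            )
        if self.n_radial * self.radial_pitch_mm < 2 * self.fov_radius_mm:
            raise ConfigurationError(
                "radial extent does not cover the FOV: "
                f"{self.n_radial} x {self.radial_pitch_mm} mm < "
                f"2 x {self.fov_radius_mm} mm"
            )

    # ---- segment / plane layout -------------------------------------------------

    @property
    def segments(self) -> np.ndarray:
        """Ring differences, ordered -mrd .. +mrd."""
        m = self.max_ring_difference
        return np.arange(-m, m + 1)

    @property
    def n_segments(self) -> int:
        return 2 * self.max_ring_difference + 1

    def n_planes(self, ring_difference: int) -> int:
        return self.n_rings - abs(ring_difference)

    def ring_pair(self, ring_difference: int, plane: int) -> tuple[int, int]:
        """Ordered (ring_a, ring_b) for a plane within a segment."""
        d = ring_difference
        ring_a = plane + max(0, -d)
        ring_b = plane + max(0, d)
        return ring_a, ring_b

    @property
    def segment_shapes(self) -> list[tuple[int, int, int]]:
        return [
            (self.n_planes(d), self.n_angles, self.n_radial) for d in self.segments
        ]

    @property
    def n_bins(self) -> int:
        return sum(int(np.prod(s)) for s in self.segment_shapes)

    @property
    def segment_offsets(self) -> np.ndarray:
        sizes = [int(np.prod(s)) for s in self.segment_shapes]
        return np.concatenate([[0], np.cumsum(sizes)])

    # ---- physical coordinates ---------------------------------------------------

    @property
    def ring_z_mm(self) -> np.ndarray:
        return (np.arange(self.n_rings) - (self.n_rings - 1) / 2.0) * self.ring_pitch_mm

    @property
    def radial_mm(self) -> np.ndarray:
        """Signed radial offset of each radial bin centre."""
        return (
            np.arange(self.n_radial) - (self.n_radial - 1) / 2.0
        ) * self.radial_pitch_mm

    @property
    def angles_rad(self) -> np.ndarray:
        return np.pi * np.arange(self.n_angles) / self.n_angles

    @property
    def detector_radius_mm(self) -> float:
        """Radius of the detector circle the LOR endpoints sit on."""
        return self.n_radial * self.radial_pitch_mm / 2.0 + self.radial_pitch_mm

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, B) endpoint coordinates in mm, each of shape (n_bins, 3)."""
        return _endpoints(self)

    # ---- flat <-> per-segment views --------------------------------------------

    def split(self, flat: np.ndarray) -> dict[int, np.ndarray]:
        """View a flat bin array as {ring_difference: (plane, angle, radial)}."""
        if flat.shape[-1] != self.n_bins:
            raise ValueError("array length does not match geometry bin count")
        off = self.segment_offsets
        out: dict[int, np.ndarray] = {}
        for i, d in enumerate(self.segments):
            out[int(d)] = flat[..., off[i] : off[i + 1]].reshape(
                flat.shape[:-1] + self.segment_shapes[i]
            )
        return out

    def concat(self, per_segment: dict[int, np.ndarray]) -> np.ndarray:
        """Inverse of :meth:`split`."""
        parts = [np.asarray(per_segment[int(d)]).reshape(-1) for d in self.segments]
        return np.concatenate(parts)


@lru_cache(maxsize=8)
def _endpoints(geom: ScannerGeometry) -> tuple[np.ndarray, np.ndarray]:
    r_det = geom.detector_radius_mm
    ring_z = geom.ring_z_mm
    phi = geom.angles_rad
    s = geom.radial_mm
    # transverse geometry shared by all segments/planes
    n_vec = np.stack([np.cos(phi), np.sin(phi)], axis=1)  # (n_angles, 2)
    u_vec = np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    t_half = np.sqrt(np.maximum(r_det**2 - s**2, 0.0))  # (n_radial,)
    # (n_angles, n_radial, 2)
    centre = n_vec[:, None, :] * s[None, :, None]
    a_xy = centre - u_vec[:, None, :] * t_half[None, :, None]
    b_xy = centre + u_vec[:, None, :] * t_half[None, :, None]

    a_list, b_list = [], []
    for d in geom.segments:
        n_pl = geom.n_planes(d)
        za = np.empty(n_pl)
        zb = np.empty(n_pl)
        for p in range(n_pl):
            ra, rb = geom.ring_pair(int(d), p)
            za[p] = ring_z[ra]
            zb[p] = ring_z[rb]
        shape = (n_pl, geom.n_angles, geom.n_radial)
        a = np.empty(shape + (3,))
        b = np.empty(shape + (3,))
        a[..., :2] = a_xy[None, :, :, :]
        b[..., :2] = b_xy[None, :, :, :]
        a[..., 2] = za[:, None, None]
        b[..., 2] = zb[:, None, None]
        a_list.append(a.reshape(-1, 3))
        b_list.append(b.reshape(-1, 3))
    A = np.ascontiguousarray(np.concatenate(a_list))
    B = np.ascontiguousarray(np.concatenate(b_list))
    A.setflags(write=False)
    B.setflags(write=False)
    return A, B


@lru_cache(maxsize=8)
def segplane_table(geom: ScannerGeometry) -> tuple:
    """Flat list over (segment, plane): (d, p, ring_a, ring_b, z_a, z_b)."""
    ring_z = geom.ring_z_mm
    rows = []
    for d in geom.segments:
        for p in range(geom.n_planes(int(d))):
            ra, rb = geom.ring_pair(int(d), p)
            rows.append((int(d), p, ra, rb, float(ring_z[ra]), float(ring_z[rb])))
    return tuple(rows)


@lru_cache(maxsize=8)
def segplane_index(geom: ScannerGeometry) -> np.ndarray:
    """Per-bin index into :func:`segplane_table`."""
    idx = np.empty(geom.n_bins, dtype=np.int64)
    pos = 0
    row = 0
    per_plane = geom.n_angles * geom.n_radial
    for d in geom.segments:
        for _p in range(geom.n_planes(int(d))):
            idx[pos : pos + per_plane] = row
            pos += per_plane
            row += 1
    idx.setflags(write=False)
    return idx


def build_geometry(config: dict | None = None, **kwargs) -> ScannerGeometry:
    """Build and validate a :class:`ScannerGeometry` from a config mapping.

    Unknown keys raise; missing keys take the desk-scale defaults.
    """
    params = dict(config or {})
    params.update(kwargs)
    valid = set(ScannerGeometry.__dataclass_fields__)
    unknown = set(params) - valid
    if unknown:
        raise ConfigurationError(f"unknown geometry keys: {sorted(unknown)}")
    return ScannerGeometry(**params)
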