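"""Sinogram container and its on-disk format.

Values are stored flat over (segment, plane, angle, radial); the geometry
object owns the layout.  On disk a sinogram is a raw float64 payload next to
a JSON sidecar carrying the geometry, kind and shape — the round trip is
bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import ScannerGeometry

__all__ = ["Sinogram", "add_poisson_noise", "save_sinogram", "load_sinogram"]

KINDS = ("emission", "acf", "scatter", "trues")


@dataclass
class Sinogram:
    """Projection data on the (segment, plane, angle, radial) grid."""

    values: np.ndarray
    kind: str
    geometry: ScannerGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.values.size != self.geometry.n_bins:
            raise ValueError(
                f"value count {self.values.size} does not match geometry "
                f"({self.geometry.n_bins} bins)"
            )
        self.validate()

    def validate(self) -> None:
        if self.kind == "acf":
            if np.any(self.values < 1.0 - 1e-12):
                raise ValueError("ACF sinogram must have all values >= 1")
        else:
            if np.any(self.values < 0):
                raise ValueError(f"{self.kind} sinogram must be non-negative")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def split(self) -> dict[int, np.ndarray]:
        """Per-segment views shaped (plane, angle, radial)."""
        return self.geometry.split(self.values)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Sinogram":
        return Sinogram(
            values=np.asarray(values), kind=kind or self.kind, geometry=self.geometry
        )

    def copy(self) -> "Sinogram":
        return self.with_values(self.values.copy())


def add_poisson_noise(sinogram: Sinogram, total_counts: int, seed: int) -> Sinogram:
    """Poisson realisation rescaled so the *expected* total equals total_counts.

    The returned bins are the integer draws themselves (count space); the
    deterministic input acts as the mean shape.
    """
    if sinogram.kind not in ("emission", "trues"):
        raise ValueError("Poisson noise applies to emission-like sinograms")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    v = sinogram.values
    if np.any(v < 0):
        raise ValueError("input sinogram must be non-negative")
    s = v.sum()
    if s == 0:
        return sinogram.with_values(np.zeros_like(v), kind="emission")
    lam = v * (total_counts / s)
    rng = np.random.default_rng(seed)
    draws = rng.poisson(lam).astype(np.float64)
    return sinogram.with_values(draws, kind="emission")


# ---- I/O ---------------------------------------------------------------------


def save_sinogram(sino: Sinogram, path: str | Path) -> None:
    """Write ``<path>.f64`` (raw float64 payload) + ``<path>.json`` sidecar."""
    path = Path(path)
    payload = path.with_suffix(".f64")
    sidecar = path.with_suffix(".json")
    sino.values.astype("<f8").tofile(payload)
    meta = {
        "kind": sino.kind,
        "n_bins": int(sino.values.size),
        "dtype": "<f8",
        "geometry": dataclasses.asdict(sino.geometry),
    }
    sidecar.write_text(json.dumps(meta, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    geom = ScannerGeometry(**sidecar["geometry"])
    values = np.fromfile(path.with_suffix(".f64"), dtype=sidecar["dtype"])
    return Sinogram(values=values, kind=sidecar["kind"], geometry=geom)
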