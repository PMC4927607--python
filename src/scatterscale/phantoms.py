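"""Synthetic head phantoms and tracer uptake profiles.

The head is a soft-tissue cylinder spanning the axial FOV, wrapped in a thin
skin shell, with spherical interior regions (a centrally placed region and a
"lower brain" region near the bottom of the axial FOV, where the clinically
observed scatter-scaling artefact lives).  Attenuation is uniform soft
tissue inside the head and zero outside.

Tracer profiles assign per-region kinetic parameters.  The verapamil-like
profile is the interesting one: low brain uptake with prominent skin (rim)
uptake, the configuration that makes scatter tail fitting fragile when the
transmission and emission data are misaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScannerGeometry
from .kinetics import KineticParams
from .volume import MU_SOFT_TISSUE, VolumeImage, default_volume_grid

__all__ = [
    "Region",
    "PhantomSpec",
    "TracerProfile",
    "make_head_phantom",
    "default_phantom_spec",
    "tracer_profile",
    "LABELS",
]

#: canonical label values
LABELS = {"background": 0, "brain": 1, "skin": 2, "lower_brain": 3, "central": 4}


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Region:
    label: int
    name: str
    centre_mm: tuple[float, float, float]
    radius_mm: float
    tissue_class: str = "grey"


@dataclass(frozen=True)
class PhantomSpec:
    head_radius_mm: float = 30.0
    skin_thickness_mm: float = 4.0
    regions: tuple[Region, ...] = ()
    mu_tissue_per_mm: float = MU_SOFT_TISSUE
    mu_bone_per_mm: float = MU_SOFT_TISSUE  # no bone shell by default
    axial_gradient: float = 0.0  # relative activity slope across the axial FOV

    def __post_init__(self) -> None:
        if self.head_radius_mm <= 0 or self.skin_thickness_mm < 0:
            raise PhantomSpecError("head radius must be > 0, skin thickness >= 0")
        if self.skin_thickness_mm >= self.head_radius_mm:
            raise PhantomSpecError("skin shell thicker than the head")
        inner = self.head_radius_mm - self.skin_thickness_mm
        for r in self.regions:
            rho = float(np.hypot(r.centre_mm[0], r.centre_mm[1]))
            if rho + r.radius_mm > inner + 1e-9:
                raise PhantomSpecError(
                    f"region {r.name!r} extends outside the head interior"
                )


def default_phantom_spec(
    head_radius_mm: float = 30.0,
    skin_thickness_mm: float = 4.0,
    axial_extent_mm: float | None = None,
    axial_gradient: float = 0.0,
) -> PhantomSpec:
    """Two-region head: a central sphere and a lower-brain sphere.

    The lower-brain region sits near the bottom of the axial FOV, mimicking
    the cerebellum/parahippocampal placement of the clinical artefact.
    """
    z_low = -(axial_extent_mm or 4 * head_radius_mm / 3.0) * 0.3
    r_reg = head_radius_mm * 0.25
    regions = (
        Region(LABELS["lower_brain"], "lower_brain", (0.0, -0.3 * head_radius_mm, z_low), r_reg),
        Region(LABELS["central"], "central", (0.0, 0.2 * head_radius_mm, 0.0), r_reg),
    )
    return PhantomSpec(
        head_radius_mm=head_radius_mm,
        skin_thickness_mm=skin_thickness_mm,
        regions=regions,
        axial_gradient=axial_gradient,
    )


def make_head_phantom(
    spec: PhantomSpec, geometry: ScannerGeometry, nxy: int = 48
) -> tuple[VolumeImage, VolumeImage, VolumeImage]:
    """Build (activity template, mu map, label map) on the default grid.

    The activity template is 1 inside the head (times the optional axial
    gradient) and 0 outside; frame-wise activity is painted onto the label
    map from kinetic model curves by the acquisition simulator.
    """
    if spec.head_radius_mm > geometry.fov_radius_mm:
        raise PhantomSpecError("head does not fit in the FOV")
    template = default_volume_grid(geometry, nxy=nxy)
    x, y, z = template.grid_mm()
    X, Y = np.meshgrid(x, y, indexing="ij")
    rho = np.sqrt(X**2 + Y**2)

    head2d = rho <= spec.head_radius_mm
    skin2d = head2d & (rho > spec.head_radius_mm - spec.skin_thickness_mm)

    labels = np.zeros(template.shape, dtype=np.int32)
    labels[head2d, :] = LABELS["brain"]
    labels[skin2d, :] = LABELS["skin"]

    Z = np.broadcast_to(z[None, None, :], template.shape)
    X3 = np.broadcast_to(X[:, :, None], template.shape)
    Y3 = np.broadcast_to(Y[:, :, None], template.shape)
    for r in spec.regions:
        d2 = (
            (X3 - r.centre_mm[0]) ** 2
            + (Y3 - r.centre_mm[1]) ** 2
            + (Z - r.centre_mm[2]) ** 2
        )
        inside = d2 <= r.radius_mm**2
        if not inside.any():
            raise PhantomSpecError(
                f"region {r.name!r} covers no voxels at this grid resolution"
            )
        labels[inside] = r.label

    mu = np.where(labels > 0, spec.mu_tissue_per_mm, 0.0)

    activity = (labels > 0).astype(float)
    if spec.axial_gradient != 0.0:
        half = max(abs(z[0]), abs(z[-1])) or 1.0
        slope = 1.0 + spec.axial_gradient * (Z / half)
        activity *= np.clip(slope, 0.0, None)

    return (
        template.with_values(activity, quantity="activity_kBq_per_ml"),
        template.with_values(mu, quantity="mu_per_mm"),
        template.with_values(labels, quantity="label"),
    )


@dataclass(frozen=True)
class TracerProfile:
    """Per-region kinetics for one synthetic tracer."""

    name: str
    model: str  # '1t' or '2t'
    region_params: dict[str, KineticParams] = field(hash=False)
    skin_activity_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("1t", "2t"):
            raise ValueError("model must be '1t' or '2t'")
        if self.skin_activity_ratio > 1.0 and self.name != "verapamil_like":
            raise ValueError(
                "skin_activity_ratio > 1 is reserved for verapamil_like"
            )

    def params_for(self, region_name: str) -> KineticParams:
        return self.region_params.get(region_name, self.region_params["brain"])


def tracer_profile(name: str) -> TracerProfile:
    """Built-in tracer profiles.

    Rates are plausible desk-scale choices, not values claimed from any
    clinical dataset: the verapamil-like tracer is 1T with V_T ~ 1 in brain
    and a hot skin rim; the flumazenil-like tracer is 1T with high K1; the
    raclopride-like tracer is reversible 2T with an elevated k3/k4 in the
    central (striatum-like) region.
    """
    if name == "verapamil_like":
        brain = KineticParams(K1=0.05, k2=0.05, Vb=0.05)
        return TracerProfile(
            name=name,
            model="1t",
            region_params={
                "brain": brain,
                "lower_brain": brain,
                "central": brain,
                "skin": KineticParams(K1=0.15, k2=0.05, Vb=0.05),
            },
            skin_activity_ratio=3.0,
        )
    if name == "flumazenil_like":
        brain = KineticParams(K1=0.35, k2=0.07, Vb=0.05)
        return TracerProfile(
            name=name,
            model="1t",
            region_params={
                "brain": brain,
                "lower_brain": brain,
                "central": KineticParams(K1=0.40, k2=0.07, Vb=0.05),
                "skin": KineticParams(K1=0.02, k2=0.10, Vb=0.05),
            },
        )
    if name == "raclopride_like":
        brain = KineticParams(K1=0.10, k2=0.25, k3=0.017, k4=0.05, Vb=0.05)
        return TracerProfile(
            name=name,
            model="2t",
            region_params={
                "brain": brain,
                "lower_brain": brain,
                "central": KineticParams(K1=0.10, k2=0.25, k3=0.15, k4=0.05, Vb=0.05),
                "skin": KineticParams(K1=0.02, k2=0.25, k3=0.017, k4=0.05, Vb=0.05),
            },
        )
    raise ValueError(f"unknown tracer profile {name!r}")
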