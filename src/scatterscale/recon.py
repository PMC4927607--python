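"""Ordinary-Poisson OSEM with attenuation and an additive scatter term.

Forward model per bin: ybar = (1/ACF) * P(x) + s, with P the line-integral
projector and s the already-scaled scatter estimate in count space (the
additive term is applied after attenuation, i.e. scatter is modelled in the
prompt data as measured; it is never negative).  The multiplicative EM
update runs over angle subsets in bit-reversed order:

    x <- x / S_k * P_k^T[(1/ACF) y / ybar],   S_k = P_k^T(1/ACF)

Initialisation is uniform inside the FOV cylinder; voxels with zero subset
sensitivity are masked out and logged.  With 1 subset this is MLEM and, with
no additive term, conserves total modelled counts at every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._ray import back_line_integrals, line_integrals
from .geometry import ScannerGeometry
from .scatter import (
    ScatterModel,
    fit_tail_scale,
    scatter_correct,
    sss_estimate,
    tail_mask,
)
from .sinogram import Sinogram
from .volume import VolumeImage, default_volume_grid

__all__ = [
    "ReconSettings",
    "sensitivity_image",
    "osem_reconstruct",
    "reconstruct_dynamic",
    "dynamic_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconSettings:
    iterations: int = 12
    subsets: int = 16
    psf_fwhm_mm: float | None = None
    stop_epsilon: float = 0.0
    nxy: int = 48  # transverse voxels of the reconstruction grid
    preliminary_iterations: int = 2  # no-scatter pass feeding the SSS estimate

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.subsets < 1:
            raise ValueError("subsets must be >= 1")

    def validate_for(self, geometry: ScannerGeometry) -> None:
        if geometry.n_angles % self.subsets != 0:
            raise ValueError(
                f"subsets ({self.subsets}) must divide n_angles "
                f"({geometry.n_angles})"
            )


def _bit_reversed(n: int) -> list[int]:
    bits = max(1, (n - 1).bit_length())
    order = sorted(range(n), key=lambda i: int(f"{i:0{bits}b}"[::-1], 2))
    return order


@lru_cache(maxsize=16)
def _angle_index(geom: ScannerGeometry) -> np.ndarray:
    idx = np.empty(geom.n_bins, dtype=np.int64)
    pos = 0
    for d in geom.segments:
        n_pl = geom.n_planes(int(d))
        block = np.repeat(np.arange(geom.n_angles), geom.n_radial)
        for _ in range(n_pl):
            idx[pos : pos + block.size] = block
            pos += block.size
    idx.setflags(write=False)
    return idx


@lru_cache(maxsize=16)
def _subset_bins(geom: ScannerGeometry, subsets: int):
    """Per-subset bin indices and contiguous endpoint arrays."""
    a, b = geom.endpoints()
    angle = _angle_index(geom)
    out = []
    for k in range(subsets):
        sel = np.flatnonzero(angle % subsets == k)
        out.append(
            (sel, np.ascontiguousarray(a[sel]), np.ascontiguousarray(b[sel]))
        )
    return out


def _fov_mask(template: VolumeImage, geometry: ScannerGeometry) -> np.ndarray:
    x, y, _ = template.grid_mm()
    X, Y = np.meshgrid(x, y, indexing="ij")
    return ((X**2 + Y**2) <= geometry.fov_radius_mm**2)[:, :, None] * np.ones(
        template.shape, dtype=bool
    )


def _gaussian_psf(values: np.ndarray, fwhm_mm: float, pitch) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    sigma = [fwhm_mm / 2.35482 / p for p in pitch]
    return gaussian_filter(values, sigma=sigma, mode="constant")


def sensitivity_image(
    geometry: ScannerGeometry,
    acf: Sinogram,
    subset: int | None = None,
    subsets: int = 1,
    template: VolumeImage | None = None,
) -> VolumeImage:
    """Back projection of 1/ACF over one subset's angles (or all angles)."""
    if template is None:
        template = default_volume_grid(geometry)
    inv_acf = 1.0 / acf.values
    out = np.zeros(template.shape)
    px, py, pz = template.voxel_pitch_mm
    step = min(template.voxel_pitch_mm) / 2.0
    if subset is None:
        a, b = geometry.endpoints()
        back_line_integrals(out, px, py, pz, a, b, step, inv_acf)
    else:
        sel, a, b = _subset_bins(geometry, subsets)[subset]
        back_line_integrals(out, px, py, pz, a, b, step,
                            np.ascontiguousarray(inv_acf[sel]))
    return template.with_values(out)


def osem_reconstruct(
    emission: Sinogram,
    acf: Sinogram,
    scatter: Sinogram | None,
    geometry: ScannerGeometry,
    settings: ReconSettings,
    template: VolumeImage | None = None,
) -> VolumeImage:
    """OP-OSEM reconstruction; deterministic given its inputs."""
    settings.validate_for(geometry)
    if template is None:
        template = default_volume_grid(geometry, nxy=settings.nxy)
    y = emission.values
    if y.sum() == 0:
        log.warning("zero-count frame: returning a uniform zero image")
        return template.with_values(np.zeros(template.shape))
    inv_acf = 1.0 / acf.values
    b_add = scatter.values if scatter is not None else np.zeros_like(y)
    if np.any(b_add < 0):
        raise ValueError("additive scatter term must be non-negative")

    fov = _fov_mask(template, geometry)
    x = np.where(fov, 1.0, 0.0)
    px, py, pz = template.voxel_pitch_mm
    step = min(template.voxel_pitch_mm) / 2.0
    subset_data = _subset_bins(geometry, settings.subsets)
    psf = settings.psf_fwhm_mm

    # subset sensitivities (PSF-matched when resolution modelling is on)
    sens = []
    for sel, a, b in subset_data:
        s_img = np.zeros(template.shape)
        back_line_integrals(s_img, px, py, pz, a, b, step,
                            np.ascontiguousarray(inv_acf[sel]))
        if psf:
            s_img = _gaussian_psf(s_img, psf, template.voxel_pitch_mm)
        sens.append(s_img)
    dead = [s <= 0 for s in sens]
    if any(d[fov].any() for d in dead):
        log.warning("zero-sensitivity voxels inside the FOV were masked")

    order = _bit_reversed(settings.subsets)
    for _it in range(settings.iterations):
        x_prev = x
        for k in order:
            sel, a, b = subset_data[k]
            xs = _gaussian_psf(x, psf, template.voxel_pitch_mm) if psf else x
            fp = line_integrals(np.ascontiguousarray(xs), px, py, pz, a, b, step)
            ybar = inv_acf[sel] * fp + b_add[sel]
            ratio = np.where(ybar > 0, y[sel] / np.maximum(ybar, 1e-300), 0.0)
            corr = np.zeros(template.shape)
            back_line_integrals(corr, px, py, pz, a, b, step,
                                np.ascontiguousarray(inv_acf[sel] * ratio))
            if psf:
                corr = _gaussian_psf(corr, psf, template.voxel_pitch_mm)
            with np.errstate(invalid="ignore", divide="ignore"):
                upd = np.where(sens[k] > 0, corr / sens[k], 0.0)
            x = np.where(fov & ~dead[k], x * upd, 0.0)
        if settings.stop_epsilon > 0:
            rel = np.abs(x - x_prev).sum() / max(x_prev.sum(), 1e-30)
            if rel < settings.stop_epsilon:
                break
    return template.with_values(np.maximum(x, 0.0))


@dataclass
class PipelineResult:
    """Frames (calibrated to kBq/ml), per-frame fits and the scatter model."""

    frames: list[VolumeImage]
    fits: list
    scatter_models: list[ScatterModel]
    margin: int
    mode: str


def dynamic_pipeline(
    acquisition,
    settings: ReconSettings,
    margins: list[int],
    mode: str = "sss3d",
    per_plane: bool = True,
    acf_threshold: float = 1.03,
    sss_kwargs: dict | None = None,
    outer_loops: int = 1,
) -> dict[int, PipelineResult]:
    """Scatter-corrected dynamic reconstruction for several ACF-margins.

    The preliminary no-scatter reconstruction and the SSS estimate are shared
    across margins — the margin only changes the tail-scaling fit, exactly as
    the ACF-margin is defined.  With ``outer_loops`` = 2 the scatter model is
    re-estimated once from a scatter-corrected intermediate reconstruction
    (using the first margin in ``margins``), which reduces the shape bias the
    uncorrected preliminary image leaves in the model.
    """
    geom = acquisition.geometry
    acf = acquisition.acf
    sss_kwargs = dict(sss_kwargs or {})
    prelim_settings = ReconSettings(
        iterations=settings.preliminary_iterations,
        subsets=settings.subsets,
        nxy=settings.nxy,
    )

    def model_from(img) -> ScatterModel:
        act = img.with_values(
            np.maximum(img.values, 0.0), quantity="activity_kBq_per_ml"
        )
        return sss_estimate(act, acquisition.mu_map_shifted, geom, mode=mode,
                            **sss_kwargs)

    models: list[ScatterModel] = []
    for f, em in enumerate(acquisition.emission):
        prelim = osem_reconstruct(em, acf, None, geom, prelim_settings)
        models.append(model_from(prelim))
    for _loop in range(1, outer_loops):
        mask0 = tail_mask(acf, threshold=acf_threshold,
                          margin_voxels=int(margins[0]))
        refreshed: list[ScatterModel] = []
        for f, em in enumerate(acquisition.emission):
            fit = fit_tail_scale(em, models[f], mask0, per_plane=per_plane)
            scat = scatter_correct(em, models[f], fit)
            inter = osem_reconstruct(em, acf, scat, geom, settings)
            refreshed.append(model_from(inter))
        models = refreshed

    results: dict[int, PipelineResult] = {}
    for margin in margins:
        mask = tail_mask(acf, threshold=acf_threshold, margin_voxels=margin)
        frames, fits = [], []
        for f, em in enumerate(acquisition.emission):
            fit = fit_tail_scale(em, models[f], mask, per_plane=per_plane)
            scat = scatter_correct(em, models[f], fit)
            img = osem_reconstruct(em, acf, scat, geom, settings)
            alpha = acquisition.count_scale[f]
            cal = img.with_values(img.values / alpha if alpha > 0 else img.values)
            frames.append(cal)
            fits.append(fit)
        results[margin] = PipelineResult(
            frames=frames, fits=fits, scatter_models=models,
            margin=margin, mode=mode,
        )
    return results


def reconstruct_dynamic(
    acquisition,
    scatter_strategy: dict | None = None,
    settings: ReconSettings | None = None,
) -> list[VolumeImage]:
    """Reconstruct every frame with one scatter strategy.

    ``scatter_strategy`` keys: mode ('sss2d'|'sss3d'), margin (radial bins),
    per_plane (bool).  Frames are returned calibrated to kBq/ml.
    """
    strategy = {"mode": "sss3d", "margin": 0, "per_plane": True}
    strategy.update(scatter_strategy or {})
    settings = settings or ReconSettings()
    res = dynamic_pipeline(
        acquisition,
        settings,
        margins=[int(strategy["margin"])],
        mode=strategy["mode"],
        per_plane=bool(strategy["per_plane"]),
    )
    return res[int(strategy["margin"])].frames
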