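"""Single scatter simulation, ACF-margin tail masks and tail fitting.

The single scatter estimate follows the standard model: for a detector pair
(A, B) and a scatter point S inside the attenuating object, an annihilation
photon pair emitted along one leg reaches the scatter point, Compton-scatters
through angle theta into the other detector, and survives attenuation at
511 keV on the unscattered leg and at the Compton-shifted energy on the
scattered leg.  Summing the Klein-Nishina-weighted contributions of a coarse
scatter-point grid over both leg assignments gives an unscaled, spatially
smooth scatter sinogram; tail fitting against measured counts in bins the
ACF declares object-free sets the absolute scale.

The ACF-margin widens the object band of the ACF sinogram radially before
the tail is extracted, so that a transmission/emission mismatch (patient
motion between the scans) cannot leak true emission counts into the scatter
tail and inflate the scale factors.  The margin affects only the scaling
fit, never the attenuation correction itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import binary_dilation, gaussian_filter
from scipy.special import erf

from ._ray import line_integrals
from .geometry import ScannerGeometry, segplane_index, segplane_table
from .sinogram import Sinogram
from .volume import VolumeImage

__all__ = [
    "klein_nishina",
    "scattered_energy",
    "kn_total_cross_section",
    "ScatterModel",
    "TailMask",
    "TailFitResult",
    "sss_estimate",
    "tail_mask",
    "fit_tail_scale",
    "scatter_correct",
    "oracle_scale",
    "broaden",
    "margin_to_mm",
    "DegenerateInputError",
    "FitDegenerateError",
]

#: mu cutoff defining the scatter-point support, 1/mm
MU_CUTOFF = 0.002
E0_KEV = 511.0


class DegenerateInputError(ValueError):
    pass


class FitDegenerateError(ValueError):
    pass


# ---- Compton physics ---------------------------------------------------------


def klein_nishina(theta):
    """Unpolarised Klein-Nishina differential cross-section at 511 keV.

    Returned in units of r_e^2 (classical electron radius squared):
    (1/2) P^2 (P + 1/P - sin^2 theta) with P = E'/E = 1/(2 - cos theta).
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("scattering angle must lie in [0, pi]")
    cos_t = np.cos(theta)
    p = 1.0 / (2.0 - cos_t)
    val = 0.5 * p**2 * (p + 1.0 / p - (1.0 - cos_t**2))
    return val if val.ndim else float(val)


def scattered_energy(theta):
    """Compton-shifted photon energy in keV for a 511 keV primary."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < -1e-12) or np.any(theta > np.pi + 1e-12):
        raise ValueError("scattering angle must lie in [0, pi]")
    val = E0_KEV / (2.0 - np.cos(theta))
    return val if val.ndim else float(val)


def kn_total_cross_section(energy_keV):
    """Total Klein-Nishina cross-section (relative units).

    Used to scale attenuation coefficients to the scattered photon energy:
    in water at a few hundred keV Compton scattering dominates, so
    mu(E) ~ mu(511) * sigma(E) / sigma(511).
    """
    eps = np.asarray(energy_keV, dtype=float) / E0_KEV
    t = 1.0 + 2.0 * eps
    val = (1.0 + eps) / eps**2 * (2.0 * (1.0 + eps) / t - np.log(t) / eps)
    val += np.log(t) / (2.0 * eps) - (1.0 + 3.0 * eps) / t**2
    return val if val.ndim else float(val)


# ---- domain types ------------------------------------------------------------


@dataclass
class ScatterModel:
    """Unscaled single-scatter sinogram plus provenance."""

    sinogram: Sinogram
    scatter_grid_mm: float
    mode: str  # 'sss2d' | 'sss3d'


@dataclass
class TailMask:
    mask: np.ndarray  # flat bool over bins
    acf_threshold: float
    margin_voxels: int
    geometry: ScannerGeometry

    @property
    def n_tail_bins(self) -> int:
        return int(self.mask.sum())


@dataclass
class TailFitResult:
    """Per-(segment, plane) scatter scale factors and diagnostics."""

    plane_scales: np.ndarray  # one per segplane row
    flagged: np.ndarray  # bool: too few tail bins / degenerate model
    tail_bin_counts: np.ndarray
    global_scale: float
    residual_norm: float
    per_plane: bool
    geometry: ScannerGeometry

    def bin_scales(self) -> np.ndarray:
        """Scale factor per sinogram bin."""
        if not self.per_plane:
            return np.full(self.geometry.n_bins, self.global_scale)
        return self.plane_scales[segplane_index(self.geometry)]


# ---- tail mask ---------------------------------------------------------------


def tail_mask(
    acf: Sinogram, threshold: float = 1.03, margin_voxels: int = 0
) -> TailMask:
    """Bins outside the (radially dilated) object band of the ACF sinogram.

    Object band O = {ACF > threshold}; O is dilated by ``margin_voxels``
    along the radial axis only, and the tail is its complement.  With margin
    0 the tail is exactly {ACF <= threshold}.
    """
    if acf.kind != "acf":
        raise ValueError("tail_mask requires an ACF sinogram")
    if margin_voxels < 0:
        raise ValueError("margin must be non-negative")
    geom = acf.geometry
    if margin_voxels >= geom.n_radial / 2:
        raise ValueError("margin of half the radial extent or more is degenerate")
    rows = acf.values.reshape(-1, geom.n_radial)
    obj = rows > threshold
    if margin_voxels > 0:
        structure = np.ones((1, 2 * margin_voxels + 1), dtype=bool)
        obj = binary_dilation(obj, structure=structure)
    mask = ~obj.reshape(-1)
    return TailMask(
        mask=mask,
        acf_threshold=threshold,
        margin_voxels=margin_voxels,
        geometry=geom,
    )


# ---- tail fitting ------------------------------------------------------------

MIN_TAIL_BINS = 20


def fit_tail_scale(
    measured: Sinogram,
    model: ScatterModel,
    mask: TailMask,
    per_plane: bool = True,
    min_tail_bins: int = MIN_TAIL_BINS,
) -> TailFitResult:
    """Least-squares scale of the scatter model to measured tail counts.

    Per plane: s_p = sum(y m) / sum(m^2) over that plane's tail bins,
    clamped at zero; planes with fewer than ``min_tail_bins`` tail bins (or
    an identically zero model there) are flagged and take the nearest fitted
    plane's scale.  Global mode pools every tail bin.
    """
    geom = measured.geometry
    if model.sinogram.geometry != geom or mask.geometry != geom:
        raise ValueError("measured, model and mask must share a geometry")
    y = measured.values
    m = model.sinogram.values
    t = mask.mask

    mm_all = float((m[t] ** 2).sum())
    if mm_all == 0.0:
        raise FitDegenerateError("scatter model is zero on every tail bin")
    global_scale = max(float((y[t] * m[t]).sum()) / mm_all, 0.0)

    table = segplane_table(geom)
    idx = segplane_index(geom)
    n_rows = len(table)
    scales = np.zeros(n_rows)
    flagged = np.zeros(n_rows, dtype=bool)
    counts = np.zeros(n_rows, dtype=np.int64)
    for r in range(n_rows):
        sel = t & (idx == r)
        counts[r] = int(sel.sum())
        mm = float((m[sel] ** 2).sum())
        if counts[r] < min_tail_bins or mm == 0.0:
            flagged[r] = True
            continue
        scales[r] = max(float((y[sel] * m[sel]).sum()) / mm, 0.0)

    if flagged.all():
        scales[:] = global_scale
    elif flagged.any():
        fitted = np.flatnonzero(~flagged)
        for r in np.flatnonzero(flagged):
            nearest = fitted[np.argmin(np.abs(fitted - r))]
            scales[r] = scales[nearest]

    s_bin = scales[idx] if per_plane else global_scale
    residual = float(np.sqrt(((y[t] - s_bin[t] * m[t]) ** 2).sum())) if per_plane \
        else float(np.sqrt(((y[t] - global_scale * m[t]) ** 2).sum()))
    return TailFitResult(
        plane_scales=scales,
        flagged=flagged,
        tail_bin_counts=counts,
        global_scale=global_scale,
        residual_norm=residual,
        per_plane=per_plane,
        geometry=geom,
    )


def scatter_correct(
    measured: Sinogram, model: ScatterModel, fit: TailFitResult
) -> Sinogram:
    """Scaled scatter estimate, the additive term for reconstruction."""
    geom = measured.geometry
    if model.sinogram.geometry != geom or fit.geometry != geom:
        raise ValueError("inputs must share a geometry")
    return Sinogram(
        values=fit.bin_scales() * model.sinogram.values,
        kind="scatter",
        geometry=geom,
    )


def oracle_scale(
    truth_scatter: Sinogram, model: ScatterModel, per_plane: bool = False
):
    """Best-fit scale of the model to a known scatter sinogram over ALL bins.

    The reference s* for scale-recovery experiments: what a least-squares fit
    would return with the full noiseless scatter signal available.
    """
    m = model.sinogram.values
    y = truth_scatter.values
    if per_plane:
        idx = segplane_index(truth_scatter.geometry)
        n_rows = idx.max() + 1
        out = np.zeros(n_rows)
        for r in range(n_rows):
            sel = idx == r
            mm = float((m[sel] ** 2).sum())
            out[r] = float((y[sel] * m[sel]).sum()) / mm if mm > 0 else 0.0
        return out
    mm = float((m**2).sum())
    if mm == 0:
        raise FitDegenerateError("model is identically zero")
    return float((y * m).sum()) / mm


def margin_to_mm(margin_voxels: int, radial_pitch_mm: float = 1.22) -> float:
    """ACF-margin in mm for a margin in radial bins."""
    return margin_voxels * radial_pitch_mm


def broaden(sino: Sinogram, sigma_bins: float = 2.0) -> Sinogram:
    """Smooth angular broadening per plane.

    Used by the acquisition simulator to decorrelate the scatter ground
    truth from the estimator's exact kernel.  The smoothing acts along the
    angle axis only: angular scatter profiles are gentle everywhere, so the
    perturbation decorrelates spatial structure without multiplicatively
    distorting the steep radial shoulder of the scatter tail (which is
    where the margin fit samples; a radial Gaussian would inflate an
    exponentially decaying tail by tens of percent there).
    """
    parts = sino.split()
    out = {}
    for d, arr in parts.items():
        out[d] = gaussian_filter(arr, sigma=(0, sigma_bins, 0), mode="nearest")
    return sino.with_values(sino.geometry.concat(out))


# ---- single scatter simulation ----------------------------------------------


def _scatter_points(mu_map: VolumeImage, grid_mm: float):
    """Coarse grid of scatter points where mu exceeds the cutoff."""
    stride = [max(1, int(round(grid_mm / p))) for p in mu_map.voxel_pitch_mm]
    xs, ys, zs = mu_map.grid_mm()
    sub = mu_map.values[:: stride[0], :: stride[1], :: stride[2]]
    X, Y, Z = np.meshgrid(
        xs[:: stride[0]], ys[:: stride[1]], zs[:: stride[2]], indexing="ij"
    )
    keep = sub > MU_CUTOFF
    if not keep.any():
        raise DegenerateInputError("no scatter points: mu everywhere below cutoff")
    pos = np.stack([X[keep], Y[keep], Z[keep]], axis=1)
    mu_s = sub[keep]
    d_vol = float(np.prod([s * p for s, p in zip(stride, mu_map.voxel_pitch_mm)]))
    return np.ascontiguousarray(pos), mu_s, d_vol


def _coarse_samples(n: int, k: int) -> np.ndarray:
    return np.unique(np.round(np.linspace(0, n - 1, min(k, n))).astype(int))


def sss_estimate(
    activity_estimate: VolumeImage,
    mu_map: VolumeImage,
    geometry: ScannerGeometry,
    mode: str = "sss3d",
    scatter_grid_mm: float = 8.0,
    lld_keV: float = 400.0,
    energy_fwhm_frac: float = 0.17,
    n_angle_samples: int = 12,
    n_radial_samples: int = 17,
) -> ScatterModel:
    """Unscaled single-scatter sinogram for the current activity/mu estimate.

    ``sss3d`` evaluates every segment's true oblique geometry; ``sss2d``
    evaluates direct (segment 0) planes only and fills oblique bins by
    axial-midpoint interpolation between direct planes.  The estimate is
    computed on a coarse (angle, radial) grid and bilinearly interpolated to
    the full sinogram — single scatter is spatially smooth.

    The energy window is a step at ``lld_keV`` smoothed by a Gaussian with
    FWHM ``energy_fwhm_frac`` x 511 keV.
    """
    if mode not in ("sss2d", "sss3d"):
        raise ValueError("mode must be 'sss2d' or 'sss3d'")
    if not activity_estimate.congruent_with(mu_map):
        raise ValueError("activity and mu must share a voxel grid")

    s_pos, mu_s, d_vol = _scatter_points(mu_map, scatter_grid_mm)
    n_s = s_pos.shape[0]

    ai = _coarse_samples(geometry.n_angles, n_angle_samples)
    ri = _coarse_samples(geometry.n_radial, n_radial_samples)
    phi = geometry.angles_rad[ai]
    s_rad = geometry.radial_mm[ri]
    r_det = geometry.detector_radius_mm
    n_vec = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    u_vec = np.stack([-np.sin(phi), np.cos(phi)], axis=1)
    t_half = np.sqrt(np.maximum(r_det**2 - s_rad**2, 0.0))
    centre = n_vec[:, None, :] * s_rad[None, :, None]  # (na, nr, 2)
    end_xy = np.stack(
        [
            centre - u_vec[:, None, :] * t_half[None, :, None],  # side A
            centre + u_vec[:, None, :] * t_half[None, :, None],  # side B
        ],
        axis=2,
    )  # (na, nr, 2, 2)

    ring_z = geometry.ring_z_mm
    na, nr = len(ai), len(ri)
    n_rings = geometry.n_rings
    # endpoint table: (na, nr, side, ring, 3)
    ends = np.empty((na, nr, 2, n_rings, 3))
    ends[..., :2] = end_xy[:, :, :, None, :]
    ends[..., 2] = ring_z[None, None, None, :]
    ends_flat = np.ascontiguousarray(ends.reshape(-1, 3))
    n_e = ends_flat.shape[0]

    # ray integrals from every scatter point to every endpoint
    a_rays = np.repeat(s_pos, n_e, axis=0)
    b_rays = np.tile(ends_flat, (n_s, 1))
    px, py, pz = mu_map.voxel_pitch_mm
    step = min(mu_map.voxel_pitch_mm)
    i_act = line_integrals(
        np.ascontiguousarray(activity_estimate.values, dtype=np.float64),
        px, py, pz, a_rays, b_rays, step,
    ).reshape(n_s, na, nr, 2, n_rings)
    i_mu = line_integrals(
        np.ascontiguousarray(mu_map.values, dtype=np.float64),
        px, py, pz, a_rays, b_rays, step,
    ).reshape(n_s, na, nr, 2, n_rings)

    sigma_e = energy_fwhm_frac * E0_KEV / 2.35482
    sigma_ref = kn_total_cross_section(E0_KEV)
    table = segplane_table(geometry)

    def eval_rows(rows):
        """Coarse (na, nr) scatter values for the given segplane rows."""
        out = np.empty((len(rows), na, nr))
        end3 = ends_flat.reshape(na, nr, 2, n_rings, 3)
        for j, (d, p, ra, rb, za, zb) in enumerate(rows):
            a_pos = end3[:, :, 0, ra, :].reshape(-1, 3)
            b_pos = end3[:, :, 1, rb, :].reshape(-1, 3)
            ia_act = i_act[:, :, :, 0, ra].reshape(n_s, -1)
            ib_act = i_act[:, :, :, 1, rb].reshape(n_s, -1)
            ia_mu = i_mu[:, :, :, 0, ra].reshape(n_s, -1)
            ib_mu = i_mu[:, :, :, 1, rb].reshape(n_s, -1)

            vec_as = s_pos[:, None, :] - a_pos[None, :, :]  # A -> S
            vec_sb = b_pos[None, :, :] - s_pos[:, None, :]  # S -> B
            r_as = np.sqrt((vec_as**2).sum(-1))
            r_sb = np.sqrt((vec_sb**2).sum(-1))
            cos_t = (vec_as * vec_sb).sum(-1) / (r_as * r_sb)
            cos_t = np.clip(cos_t, -1.0, 1.0)
            pfac = 1.0 / (2.0 - cos_t)
            kn = 0.5 * pfac**2 * (pfac + 1.0 / pfac - (1.0 - cos_t**2))
            e_sc = E0_KEV * pfac
            ratio = kn_total_cross_section(e_sc) / sigma_ref
            accept = 0.5 * (1.0 + erf((e_sc - lld_keV) / (np.sqrt(2) * sigma_e)))

            att_a_511 = np.exp(-ia_mu)
            att_b_511 = np.exp(-ib_mu)
            att_a_sc = np.exp(-ia_mu * ratio)
            att_b_sc = np.exp(-ib_mu * ratio)
            emit = ia_act * att_a_511 * att_b_sc + ib_act * att_b_511 * att_a_sc
            contrib = (
                mu_s[:, None] * d_vol * kn / (r_as**2 * r_sb**2) * accept * emit
            )
            out[j] = contrib.sum(axis=0).reshape(na, nr)
        return out

    full = np.empty(geometry.n_bins)
    angle_grid = np.arange(geometry.n_angles)
    radial_grid = np.arange(geometry.n_radial)
    AG, RG = np.meshgrid(angle_grid, radial_grid, indexing="ij")
    query = np.stack([AG.ravel(), RG.ravel()], axis=1)

    def upsample(coarse_plane):
        interp = RegularGridInterpolator(
            (ai.astype(float), ri.astype(float)),
            coarse_plane,
            method="linear",
            bounds_error=False,
            fill_value=None,
        )
        return interp(query).reshape(geometry.n_angles, geometry.n_radial)

    if mode == "sss3d":
        coarse = eval_rows(table)
        offset = 0
        per_plane = geometry.n_angles * geometry.n_radial
        for j in range(len(table)):
            full[offset : offset + per_plane] = np.maximum(
                upsample(coarse[j]), 0.0
            ).ravel()
            offset += per_plane
    else:
        direct_rows = [row for row in table if row[0] == 0]
        coarse = eval_rows(direct_rows)
        direct_maps = np.stack([upsample(c) for c in coarse])  # (n_rings, na*, nr*)
        direct_z = np.array([row[4] for row in direct_rows])
        offset = 0
        per_plane = geometry.n_angles * geometry.n_radial
        for d, p, ra, rb, za, zb in table:
            z_mid = (za + zb) / 2.0
            q = np.interp(z_mid, direct_z, np.arange(len(direct_rows)))
            lo = int(np.floor(q))
            hi = min(lo + 1, len(direct_rows) - 1)
            w = q - lo
            plane = (1.0 - w) * direct_maps[lo] + w * direct_maps[hi]
            full[offset : offset + per_plane] = np.maximum(plane, 0.0).ravel()
            offset += per_plane

    return ScatterModel(
        sinogram=Sinogram(values=full, kind="scatter", geometry=geometry),
        scatter_grid_mm=scatter_grid_mm,
        mode=mode,
    )
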