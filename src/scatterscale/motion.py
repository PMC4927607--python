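"""Rigid-displacement metric, translation-only registration, and motion QC.

Motion is summarised as the Euclidean displacement sqrt(dx^2 + dy^2 + dz^2).
Registration is translation-only: the argmax of normalised cross-correlation
over the voxel-step translation grid (evaluated exactly via FFT
cross-correlation), refined per axis by parabolic interpolation to sub-voxel
precision.  Rotations are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schedules import FrameSchedule
from .volume import VolumeImage

__all__ = [
    "RigidShift",
    "MotionReport",
    "displacement_magnitude",
    "estimate_rigid_shift",
    "motion_qc_frames",
]

#: frames with fewer counts than this are skipped in QC
QC_MIN_COUNTS = 1e3


@dataclass(frozen=True)
class RigidShift:
    dx_mm: float = 0.0
    dy_mm: float = 0.0
    dz_mm: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.dx_mm, self.dy_mm, self.dz_mm])):
            raise ValueError("shift components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx_mm, self.dy_mm, self.dz_mm])

    @property
    def magnitude_mm(self) -> float:
        return displacement_magnitude(self)


def displacement_magnitude(shift: RigidShift) -> float:
    """sqrt(dx^2 + dy^2 + dz^2) in mm."""
    return float(np.sqrt(np.sum(shift.as_array() ** 2)))


@dataclass
class MotionReport:
    frame_shifts: list[RigidShift | None]  # None: reference window or skipped
    frame_magnitudes_mm: list[float | None]
    average_mm: float
    maximum_mm: float
    trans_emission_shift: RigidShift | None = None

    @property
    def trans_emission_mm(self) -> float | None:
        if self.trans_emission_shift is None:
            return None
        return self.trans_emission_shift.magnitude_mm


def _parabolic_offset(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -0.5, 0.5))


def estimate_rigid_shift(
    reference: VolumeImage,
    moving: VolumeImage,
    search_mm: float = 10.0,
    step_mm: float | None = None,
) -> RigidShift:
    """Translation that best aligns ``moving`` onto ``reference``.

    The effective grid step is the voxel pitch per axis (the FFT correlation
    evaluates every voxel-step translation); parabolic refinement recovers
    sub-voxel shifts.  ``step_mm`` below the voxel pitch is not honoured.
    """
    if not reference.congruent_with(moving):
        raise ValueError("images must share a voxel grid")
    ref = np.asarray(reference.values, dtype=float)
    mov = np.asarray(moving.values, dtype=float)
    ref0 = ref - ref.mean()
    mov0 = mov - mov.mean()
    if np.allclose(ref0, 0) or np.allclose(mov0, 0):
        warnings.warn("flat image(s): registration degenerate, returning zero shift")
        return RigidShift(0.0, 0.0, 0.0)

    shape = ref.shape
    # corr[l] = sum_i mov0[i] ref0[i - l]: the peak lag is the translation
    # that carries the reference onto the moving image, i.e. the shift of mov
    corr = np.real(
        np.fft.ifftn(np.fft.fftn(mov0) * np.conj(np.fft.fftn(ref0)))
    )
    lags = [np.fft.fftfreq(n, 1.0 / n).astype(int) for n in shape]
    pitch = reference.voxel_pitch_mm
    within = np.ones(shape, dtype=bool)
    for ax, (lag, p) in enumerate(zip(lags, pitch)):
        sel = np.abs(lag * p) <= max(search_mm, p)
        bshape = [1] * len(shape)
        bshape[ax] = shape[ax]
        within &= sel.reshape(bshape)
    corr_masked = np.where(within, corr, -np.inf)
    peak = np.unravel_index(np.argmax(corr_masked), shape)

    shift_vox = []
    for ax, n in enumerate(shape):
        idx = peak[ax]
        im = list(peak)
        ip = list(peak)
        im[ax] = (idx - 1) % n
        ip[ax] = (idx + 1) % n
        off = _parabolic_offset(corr[tuple(im)], corr[peak], corr[tuple(ip)])
        shift_vox.append(lags[ax][idx] + off)
    dx, dy, dz = (s * p for s, p in zip(shift_vox, pitch))
    return RigidShift(dx, dy, dz)


def motion_qc_frames(
    frames: list[VolumeImage],
    schedule: FrameSchedule,
    reference_window_s: float = 60.0,
    search_mm: float = 10.0,
) -> MotionReport:
    """Per-frame motion vs a summed early-scan reference image.

    The reference is the duration-weighted sum of all frames starting within
    the first ``reference_window_s`` of the scan (motion inside that window
    is undetectable by construction); low-count frames are skipped.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    if len(frames) != schedule.n_frames:
        raise ValueError("frame count does not match schedule")
    if schedule.end_s <= reference_window_s:
        raise ValueError("schedule shorter than the reference window")

    in_window = schedule.starts_s < reference_window_s
    if not in_window.any():
        raise ValueError("no frames start inside the reference window")
    ref_vals = np.zeros(frames[0].shape)
    for f, w, d in zip(frames, in_window, schedule.durations_s):
        if w:
            ref_vals += f.values * d
    reference = frames[0].with_values(ref_vals)

    shifts: list[RigidShift | None] = []
    mags: list[float | None] = []
    for i, frame in enumerate(frames):
        if in_window[i]:
            shifts.append(None)
            mags.append(None)
            continue
        if float(frame.values.sum()) < QC_MIN_COUNTS:
            warnings.warn(f"frame {i}: too few counts for motion QC, skipped")
            shifts.append(None)
            mags.append(None)
            continue
        sh = estimate_rigid_shift(reference, frame, search_mm=search_mm)
        shifts.append(sh)
        mags.append(sh.magnitude_mm)

    valid = [m for m in mags if m is not None]
    if not valid:
        raise ValueError("no frames eligible for motion QC")
    return MotionReport(
        frame_shifts=shifts,
        frame_magnitudes_mm=mags,
        average_mm=float(np.mean(valid)),
        maximum_mm=float(np.max(valid)),
    )
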