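"""Plasma-input compartment models, TAC fitting and V_T.

Implements the single-tissue (1T) and reversible two-tissue (2T) plasma-input
models with a blood volume fraction term:

    C_model(t) = (1 - Vb) * C_tissue(t) + Vb * C_b(t)

1T:  C_tissue = K1 * exp(-k2 t) (*) C_p
2T:  C_tissue = K1/(a2-a1) * [(k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t}] (*) C_p
     a_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2

The volume of distribution is V_T = K1/k2 for 1T and K1/k2 * (1 + k3/k4) for
the reversible 2T model.  Rate constants are per minute (K1 in
ml cm^-3 min^-1); time grids are in seconds and converted internally.

Convolution uses recursive exponential quadrature on the input's sampling
grid (exact trapezoid for each exponential kernel), avoiding FFT edge
artefacts at these short grid lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .input_function import InputFunction
from .schedules import FrameSchedule
from .volume import VolumeImage

__all__ = [
    "KineticParams",
    "TAC",
    "KineticFit",
    "model_tissue_curve",
    "model_tac",
    "fit_tac",
    "voi_tacs",
    "tac_to_csv",
    "tac_from_csv",
    "fit_to_json",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants; k3/k4 are None for the 1T model."""

    K1: float  # ml cm^-3 min^-1
    k2: float  # 1/min
    k3: float | None = None
    k4: float | None = None
    Vb: float = 0.05

    def __post_init__(self) -> None:
        if self.K1 < 0 or self.k2 <= 0:
            raise ValueError("K1 must be >= 0 and k2 > 0")
        if (self.k3 is None) != (self.k4 is None):
            raise ValueError("k3 and k4 must be given together")
        if self.k3 is not None and (self.k3 < 0 or self.k4 <= 0):
            raise ValueError("k3 must be >= 0 and k4 > 0")
        if not 0 <= self.Vb <= 0.2:
            raise ValueError("Vb must lie in [0, 0.2]")

    @property
    def is_2t(self) -> bool:
        return self.k3 is not None

    @property
    def V_T(self) -> float:
        if self.k2 == 0:
            return np.inf
        vt = self.K1 / self.k2
        if self.is_2t:
            vt *= 1.0 + self.k3 / self.k4
        return vt


@dataclass
class TAC:
    """Regional time-activity curve on a frame schedule."""

    mid_times_min: np.ndarray
    durations_min: np.ndarray
    activity: np.ndarray  # kBq/ml
    label: int | str = 0

    def __post_init__(self) -> None:
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.durations_min = np.asarray(self.durations_min, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if np.any(np.diff(self.mid_times_min) <= 0):
            raise ValueError("frame mid-times must be strictly increasing")
        if np.any(self.activity < -1e-9):
            raise ValueError("activity must be non-negative")


@dataclass
class KineticFit:
    params: KineticParams
    model: str
    V_T: float
    wrss: float
    covariance: np.ndarray | None
    converged: bool
    n_starts: int = 3


def _exp_conv(cp: np.ndarray, rate_per_min: float, dt_min: float) -> np.ndarray:
    """(exp(-rate t) (*) cp)(t_n) by recursive trapezoid quadrature.

    The recursion y_n = e y_{n-1} + h (cp_n + e cp_{n-1}) is the trapezoid
    rule applied per step to the exponential kernel; ``lfilter`` runs it in C.
    """
    from scipy.signal import lfilter

    e = float(np.exp(-min(rate_per_min * dt_min, 700.0)))
    h = dt_min / 2.0
    drive = np.empty_like(cp)
    drive[0] = 0.0
    drive[1:] = h * (cp[1:] + cp[:-1] * e)
    return lfilter([1.0], [1.0, -e], drive)


def model_tissue_curve(
    params: KineticParams, model: str, input_fn: InputFunction
) -> np.ndarray:
    """C_model on the input function's sampling grid (kBq/ml)."""
    t_min = input_fn.t_s / 60.0
    dt_min = float(t_min[1] - t_min[0])
    cp = input_fn.cp
    if model == "1t":
        ct = params.K1 * _exp_conv(cp, params.k2, dt_min)
    elif model == "2t":
        k2 = params.k2
        k3 = params.k3 if params.k3 is not None else 0.0
        k4 = params.k4 if params.k4 is not None else 1.0
        ssum = k2 + k3 + k4
        disc = max(ssum**2 - 4.0 * k2 * k4, 0.0)
        root = np.sqrt(disc)
        a1 = (ssum - root) / 2.0
        a2 = (ssum + root) / 2.0
        if a2 - a1 < 1e-9:  # degenerate repeated root
            a2 = a1 + 1e-9
        c1 = (k3 + k4 - a1) / (a2 - a1)
        c2 = (a2 - k3 - k4) / (a2 - a1)
        ct = params.K1 * (
            c1 * _exp_conv(cp, a1, dt_min) + c2 * _exp_conv(cp, a2, dt_min)
        )
    else:
        raise ValueError("model must be '1t' or '2t'")
    return (1.0 - params.Vb) * ct + params.Vb * input_fn.cb


def model_tac(
    params: KineticParams,
    model: str,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    label: int | str = 0,
) -> TAC:
    """Frame-averaged model TAC over the schedule."""
    if schedule.end_s > input_fn.t_s[-1] + 1e-9:
        raise ValueError("frame schedule exceeds the input function's range")
    curve = model_tissue_curve(params, model, input_fn)
    activity = frame_average(curve, input_fn.t_s, schedule)
    return TAC(
        mid_times_min=schedule.mid_times_s / 60.0,
        durations_min=schedule.durations_s / 60.0,
        activity=activity,
        label=label,
    )


def frame_average(
    curve: np.ndarray, t_s: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Mean of a sampled curve within each frame (trapezoid on the fine grid)."""
    out = np.empty(schedule.n_frames)
    for i, (start, dur) in enumerate(schedule.frames_s):
        sel = (t_s >= start - 1e-9) & (t_s <= start + dur + 1e-9)
        tt = t_s[sel]
        if tt.size < 2:
            out[i] = float(np.interp(start + dur / 2.0, t_s, curve))
        else:
            out[i] = float(np.trapezoid(curve[sel], tt) / (tt[-1] - tt[0]))
    return out


_STARTS_1T = [
    (0.1, 0.1, 0.05),
    (0.5, 0.05, 0.02),
    (0.02, 0.5, 0.1),
]
_STARTS_2T = [
    (0.1, 0.2, 0.05, 0.05, 0.05),
    (0.5, 0.5, 0.1, 0.02, 0.02),
    (0.05, 0.1, 0.3, 0.1, 0.1),
]


def fit_tac(
    tac: TAC,
    model: str,
    input_fn: InputFunction,
    weights: str = "frame-duration",
    init: tuple | None = None,
    bounds: tuple | None = None,
) -> KineticFit:
    """Weighted NLLS fit with fixed multi-start; non-convergence is flagged.

    Parameter vector: (K1, k2, Vb) for 1T, (K1, k2, k3, k4, Vb) for 2T.
    Default bounds: K1, k2, k3, k4 in (0, 2]; Vb in [0, 0.2].
    """
    if tac.activity.size < 6:
        raise ValueError("need at least 6 frames to fit")
    if weights == "frame-duration":
        w = np.sqrt(tac.durations_min / tac.durations_min.sum())
    elif weights == "uniform":
        w = np.ones_like(tac.activity)
    else:
        raise ValueError("weights must be 'frame-duration' or 'uniform'")

    schedule = FrameSchedule.from_mid_times(tac.mid_times_min * 60.0,
                                            tac.durations_min * 60.0)
    n_par = 3 if model == "1t" else 5
    if bounds is None:
        lo = np.full(n_par, 1e-6)
        hi = np.full(n_par, 2.0)
        lo[-1], hi[-1] = 0.0, 0.2
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    def unpack(x) -> KineticParams:
        if model == "1t":
            return KineticParams(K1=x[0], k2=x[1], Vb=x[2])
        return KineticParams(K1=x[0], k2=x[1], k3=x[2], k4=x[3], Vb=x[4])

    def resid(x):
        curve = model_tissue_curve(unpack(x), model, input_fn)
        pred = frame_average(curve, input_fn.t_s, schedule)
        return w * (pred - tac.activity)

    starts = [init] if init is not None else (
        _STARTS_1T if model == "1t" else _STARTS_2T
    )
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-9, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimiser starts failed")

    params = unpack(best.x)
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(tac.activity.size - n_par, 1)
        cov = np.linalg.pinv(jtj) * 2.0 * best.cost / dof
    except Exception:
        pass
    converged = bool(best.status > 0)
    return KineticFit(
        params=params,
        model=model,
        V_T=params.V_T,
        wrss=float(2.0 * best.cost),
        covariance=cov,
        converged=converged,
        n_starts=len(starts),
    )


def tac_to_csv(tac: TAC, path) -> None:
    """Write a TAC as CSV with units in the header row."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", tac.label])
        w.writerow(["mid_time_min", "duration_min", "activity_kBq_per_ml"])
        for t, d, a in zip(tac.mid_times_min, tac.durations_min, tac.activity):
            w.writerow([f"{t:.6g}", f"{d:.6g}", f"{a:.9g}"])


def tac_from_csv(path) -> TAC:
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    label = rows[0][1]
    data = np.array(rows[2:], dtype=float)
    try:
        label = int(label)
    except ValueError:
        pass
    return TAC(mid_times_min=data[:, 0], durations_min=data[:, 1],
               activity=data[:, 2], label=label)


def fit_to_json(fit: KineticFit, path) -> None:
    """Serialise a fit (params in ml/cm^3/min and 1/min; V_T in ml/cm^3)."""
    import dataclasses
    import json

    blob = {
        "model": fit.model,
        "params": dataclasses.asdict(fit.params),
        "V_T_ml_per_cm3": fit.V_T,
        "wrss": fit.wrss,
        "converged": fit.converged,
        "n_starts": fit.n_starts,
        "covariance": None if fit.covariance is None
        else np.asarray(fit.covariance).tolist(),
    }
    from pathlib import Path

    Path(path).write_text(json.dumps(blob, indent=2))


def voi_tacs(
    frames: list[VolumeImage],
    labels: VolumeImage,
    schedule: FrameSchedule,
    names: dict[int, str] | None = None,
) -> dict[int, TAC]:
    """Mean activity per label per frame; label 0 (background) is skipped."""
    if len(frames) != schedule.n_frames:
        raise ValueError("frame count does not match schedule")
    lab = np.asarray(labels.values)
    out: dict[int, TAC] = {}
    for value in np.unique(lab):
        if value == 0:
            continue
        m = lab == value
        if not m.any():
            raise ValueError(f"label {value} is empty")
        series = np.array([float(f.values[m].mean()) for f in frames])
        out[int(value)] = TAC(
            mid_times_min=schedule.mid_times_s / 60.0,
            durations_min=schedule.durations_s / 60.0,
            activity=np.maximum(series, 0.0),
            label=names.get(int(value), int(value)) if names else int(value),
        )
    return out
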