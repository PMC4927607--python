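"""Synthetic arterial input functions.

A Feng-type shape: linear rise from zero to the peak, then a sum of three
decaying exponentials, continuous at the peak.  The whole-blood curve is the
plasma curve scaled by a constant blood-to-plasma ratio (no metabolite
modelling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InputFunction", "make_input_function", "DEFAULT_DECAY"]

#: (fraction, lambda per second) of the three post-peak exponentials
DEFAULT_DECAY = ((0.70, 8.0e-3), (0.25, 8.0e-4), (0.05, 8.0e-5))


@dataclass
class InputFunction:
    """Sampled plasma (Cp) and whole-blood (Cb) curves, kBq/ml vs seconds."""

    t_s: np.ndarray
    cp: np.ndarray
    cb: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if np.any(self.cp < 0) or np.any(self.cb < 0):
            raise ValueError("input curves must be non-negative")
        if abs(self.cp[0]) > 1e-12:
            raise ValueError("Cp(0) must be zero")

    def sample_cp(self, t_s) -> np.ndarray:
        return np.interp(t_s, self.t_s, self.cp)

    def sample_cb(self, t_s) -> np.ndarray:
        return np.interp(t_s, self.t_s, self.cb)


def make_input_function(
    peak_time_s: float = 30.0,
    peak_value: float = 50.0,
    decay_constants=DEFAULT_DECAY,
    seed: int | None = None,
    duration_s: float = 3600.0,
    dt_s: float = 1.0,
    blood_to_plasma: float = 0.8,
    jitter_fraction: float = 0.0,
) -> InputFunction:
    """Linear-rise / tri-exponential-decay plasma curve.

    Deterministic given its parameters; ``seed`` only matters when
    ``jitter_fraction`` > 0, which perturbs the decay constants by up to that
    relative amount (used to individualise synthetic subjects).
    """
    if peak_time_s <= 0 or dt_s <= 0 or duration_s <= peak_time_s:
        raise ValueError("times must be positive with duration > peak time")
    if peak_value < 0:
        raise ValueError("peak_value must be non-negative")
    fracs = np.array([f for f, _ in decay_constants], dtype=float)
    lams = np.array([l for _, l in decay_constants], dtype=float)
    if np.any(fracs <= 0) or np.any(lams <= 0):
        raise ValueError("decay fractions and constants must be positive")
    fracs = fracs / fracs.sum()
    if jitter_fraction > 0:
        rng = np.random.default_rng(seed)
        lams = lams * (1.0 + jitter_fraction * rng.uniform(-1, 1, size=lams.size))

    t = np.arange(0.0, duration_s + dt_s / 2.0, dt_s)
    cp = np.empty_like(t)
    rise = t <= peak_time_s
    cp[rise] = peak_value * t[rise] / peak_time_s
    tau = t[~rise] - peak_time_s
    cp[~rise] = peak_value * (fracs[None, :] * np.exp(-np.outer(tau, lams))).sum(
        axis=1
    )
    return InputFunction(t_s=t, cp=cp, cb=blood_to_plasma * cp)
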