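"""Dynamic PET acquisition simulator with known ground truth.

Per frame the simulator paints kinetic-model activity onto the phantom's
label map, forward-projects it through the TRUE attenuation to get the
trues, adds a single-scatter component generated by the SSS estimator on the
true (unshifted) configuration — extra-broadened so estimator-vs-truth
comparisons are not circular — scaled to a stated scatter fraction, and
draws Poisson counts.  The delivered ACF, however, is computed from the
mu-map rigidly SHIFTED by the transmission/emission mismatch, which is
exactly how patient motion between the two scans corrupts scatter scaling.

Both the trues and the scatter component are linear in the activity
distribution, so per-label projections and per-label SSS shapes are computed
once and combined with the regional TACs frame by frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import shift as ndi_shift

from .geometry import ScannerGeometry
from .input_function import InputFunction
from .kinetics import TAC, model_tac
from .motion import RigidShift
from .phantoms import LABELS, TracerProfile
from .projector import compute_acf, forward_project
from .scatter import broaden, sss_estimate
from .sinogram import Sinogram, add_poisson_noise, save_sinogram
from .schedules import FrameSchedule
from .volume import VolumeImage

__all__ = ["DynamicAcquisition", "simulate_acquisition", "save_acquisition"]

LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class DynamicAcquisition:
    """Everything the pipeline sees plus full ground truth."""

    geometry: ScannerGeometry
    schedule: FrameSchedule
    tracer: TracerProfile
    emission: list[Sinogram]  # Poisson prompts, count space
    prompts_mean: list[Sinogram]  # noiseless expectation of the prompts
    trues: list[Sinogram]  # noiseless trues component, count space
    scatter_truth: list[Sinogram]  # noiseless scatter component, count space
    acf: Sinogram  # delivered ACF (from the shifted mu-map)
    acf_true: Sinogram  # ground-truth ACF (unshifted mu-map)
    mu_map: VolumeImage  # unshifted
    mu_map_shifted: VolumeImage
    labels: VolumeImage
    truth_frames: list[VolumeImage]  # activity in kBq/ml
    region_tacs: dict[int, TAC]
    count_scale: np.ndarray  # counts per (kBq/ml x mm) per frame
    mismatch: RigidShift
    scatter_fraction: float
    seed: int
    input_fn: InputFunction


def _shift_volume(vol: VolumeImage, shift: RigidShift) -> VolumeImage:
    """Rigidly shift a volume: vacuum fill transversely, nearest fill axially.

    The phantom continues beyond the axial FOV (a head continues into the
    neck), so an axial shift must not drag vacuum into the edge planes —
    that would fake object-free tails on whole planes, which no radial
    ACF-margin could ever exclude.
    """
    vox = [m / p for m, p in zip(shift.as_array(), vol.voxel_pitch_mm)]
    shifted = ndi_shift(vol.values, (0.0, 0.0, vox[2]), order=1, mode="nearest")
    shifted = ndi_shift(shifted, (vox[0], vox[1], 0.0), order=1,
                        mode="constant", cval=0.0)
    if vol.quantity == "mu_per_mm":
        shifted = np.clip(shifted, 0.0, 0.02)
    return vol.with_values(shifted)


def simulate_acquisition(
    phantom: tuple[VolumeImage, VolumeImage, VolumeImage],
    tracer: TracerProfile,
    schedule: FrameSchedule,
    input_fn: InputFunction,
    geometry: ScannerGeometry,
    mismatch: RigidShift = RigidShift(),
    scatter_fraction: float = 0.35,
    counts_per_frame: float | np.ndarray = 2e5,
    seed: int = 0,
    noise: bool = True,
    truth_broaden_sigma: float = 2.0,
    sss_kwargs: dict | None = None,
) -> DynamicAcquisition:
    """Simulate a dynamic scan; see the module docstring for the model."""
    if not 0.0 <= scatter_fraction <= 0.7:
        raise ValueError("scatter_fraction must lie in [0, 0.7]")
    if schedule.end_s > input_fn.t_s[-1] + 1e-9:
        raise ValueError("schedule exceeds the input function's time range")
    template, mu_map, labels = phantom
    counts = np.broadcast_to(
        np.asarray(counts_per_frame, dtype=float), (schedule.n_frames,)
    ).copy()

    # regional ground-truth TACs
    lab_values = [int(v) for v in np.unique(labels.values) if v != 0]
    region_tacs: dict[int, TAC] = {}
    for lab in lab_values:
        name = LABEL_NAMES.get(lab, "brain")
        params = tracer.params_for(name)
        region_tacs[lab] = model_tac(
            params, tracer.model, input_fn, schedule, label=name
        )

    # per-label unit-activity shapes (linear building blocks)
    acf_true = compute_acf(mu_map, geometry)
    mu_shifted = _shift_volume(mu_map, mismatch)
    acf = compute_acf(mu_shifted, geometry)
    att_true = 1.0 / acf_true.values

    sss_kwargs = dict(sss_kwargs or {})
    label_proj: dict[int, np.ndarray] = {}
    label_scatter: dict[int, np.ndarray] = {}
    for lab in lab_values:
        mask_act = template.with_values(
            template.values * (labels.values == lab),
            quantity="activity_kBq_per_ml",
        )
        label_proj[lab] = forward_project(mask_act, geometry).values * att_true
        if scatter_fraction > 0:
            model = sss_estimate(mask_act, mu_map, geometry, mode="sss3d",
                                 **sss_kwargs)
            label_scatter[lab] = broaden(
                model.sinogram, sigma_bins=truth_broaden_sigma
            ).values

    rng_seed = np.random.default_rng(seed)
    emission, prompts_mean, trues_list, scatter_list = [], [], [], []
    truth_frames: list[VolumeImage] = []
    count_scale = np.empty(schedule.n_frames)
    for f in range(schedule.n_frames):
        act_img = np.zeros(template.shape)
        trues_raw = np.zeros(geometry.n_bins)
        scatter_raw = np.zeros(geometry.n_bins)
        for lab in lab_values:
            a = region_tacs[lab].activity[f]
            act_img += a * template.values * (labels.values == lab)
            trues_raw += a * label_proj[lab]
            if scatter_fraction > 0:
                scatter_raw += a * label_scatter[lab]
        truth_frames.append(template.with_values(act_img))

        if scatter_fraction > 0 and scatter_raw.sum() > 0:
            # scale scatter so scatter / (trues + scatter) == scatter_fraction
            target = scatter_fraction / (1.0 - scatter_fraction)
            scatter_raw *= target * trues_raw.sum() / scatter_raw.sum()
        total_raw = trues_raw.sum() + scatter_raw.sum()
        alpha = counts[f] / total_raw if total_raw > 0 else 0.0
        count_scale[f] = alpha
        trues_c = trues_raw * alpha
        scatter_c = scatter_raw * alpha
        mean_c = trues_c + scatter_c

        trues_list.append(Sinogram(trues_c, "trues", geometry))
        scatter_list.append(Sinogram(scatter_c, "scatter", geometry))
        mean_sino = Sinogram(mean_c, "emission", geometry)
        prompts_mean.append(mean_sino)
        if noise and counts[f] > 0 and total_raw > 0:
            sub_seed = int(rng_seed.integers(0, 2**31 - 1))
            emission.append(
                add_poisson_noise(mean_sino, int(counts[f]), sub_seed)
            )
        else:
            emission.append(mean_sino.copy())

    return DynamicAcquisition(
        geometry=geometry,
        schedule=schedule,
        tracer=tracer,
        emission=emission,
        prompts_mean=prompts_mean,
        trues=trues_list,
        scatter_truth=scatter_list,
        acf=acf,
        acf_true=acf_true,
        mu_map=mu_map,
        mu_map_shifted=mu_shifted,
        labels=labels,
        truth_frames=truth_frames,
        region_tacs=region_tacs,
        count_scale=count_scale,
        mismatch=mismatch,
        scatter_fraction=scatter_fraction,
        seed=seed,
        input_fn=input_fn,
    )


def save_acquisition(acq: DynamicAcquisition, out_dir: str | Path) -> Path:
    """Write per-frame sinogram containers, NIfTI truth and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for f, (em, tr, scat, truth) in enumerate(
        zip(acq.emission, acq.trues, acq.scatter_truth, acq.truth_frames)
    ):
        save_sinogram(em, out / f"frame{f:02d}_emission")
        save_sinogram(tr, out / f"frame{f:02d}_trues")
        save_sinogram(scat, out / f"frame{f:02d}_scatter")
        truth.to_nifti(str(out / f"frame{f:02d}_truth.nii.gz"))
        entries.append({"frame": f, "count_scale": float(acq.count_scale[f])})
    save_sinogram(acq.acf, out / "acf")
    save_sinogram(acq.acf_true, out / "acf_true")
    acq.mu_map.to_nifti(str(out / "mu.nii.gz"))
    acq.labels.to_nifti(str(out / "labels.nii.gz"))
    manifest = {
        "seed": acq.seed,
        "tracer": acq.tracer.name,
        "scatter_fraction": acq.scatter_fraction,
        "mismatch_mm": list(acq.mismatch.as_array()),
        "n_frames": acq.schedule.n_frames,
        "frames": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
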