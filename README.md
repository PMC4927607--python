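# scatterscale

A desk-scale laboratory for scatter scaling in quantitative brain PET.

High-resolution brain PET relies on model-based scatter correction: a
single scatter simulation (SSS) predicts the *shape* of the scatter
background, and its absolute *scale* is fitted against measured counts in
sinogram "tails" — bins the attenuation-correction-factor (ACF) sinogram
declares free of the object. That fit has a failure mode: if the patient
moves between the transmission scan (which produces the ACF) and the
emission scan, true emission counts — especially from tracers with hot
uptake at the skin, near the patient contour — land in bins the stale ACF
still calls "tail", and the scatter scale is overestimated. The
reconstruction then subtracts too much scatter, depressing activity and the
volume of distribution (V_T) in regions near the artefact. Widening the
ACF's object band radially by a *margin* before extracting the tail
protects the fit; the margin is used only for scatter scaling, never for
attenuation correction.

`scatterscale` rebuilds this entire chain at desk scale on synthetic head
phantoms with known ground truth, so every link can be checked against an
oracle: a cylindrical scanner model with an adjoint-exact line-integral
projector, 2D and 3D SSS with Klein–Nishina physics, ACF-margin tail
fitting, ordinary-Poisson OSEM with additive scatter, plasma-input 1T/2T
compartment modelling with blood volume fraction (V_T = K1/k2 or
K1/k2·(1 + k3/k4)), and translation-only motion QC
(displacement √(Δx² + Δy² + Δz²)).

It is aimed at people who work on PET reconstruction or quantification and
want a transparent, fully synthetic sandbox in which scatter-scaling
pathologies can be produced, measured and cured on demand.

## Worked example

The central mechanism in a dozen lines — fit the scatter scale with and
without a 5 mm transmission/emission mismatch:

```python
from scatterscale import *
from scatterscale.acquisition import simulate_acquisition
from scatterscale.phantoms import default_phantom_spec
from scatterscale.scatter import oracle_scale
from scatterscale.schedules import FrameSchedule

geom = build_geometry(n_rings=4, ring_pitch_mm=6.0, n_angles=48,
                      n_radial=96, radial_pitch_mm=1.22,
                      max_ring_difference=2, fov_radius_mm=45.0)
phantom = make_head_phantom(default_phantom_spec(30.0, 4.0,
                                                 axial_extent_mm=24.0),
                            geom, nxy=64)
acq = simulate_acquisition(
    phantom, tracer_profile("verapamil_like"),
    FrameSchedule.from_durations([600.0], start_s=3000.0),
    make_input_function(), geom,
    mismatch=RigidShift(5.0, 0.0, 0.0),   # patient moved 5 mm
    scatter_fraction=0.35, counts_per_frame=2e6, seed=1,
)
model = sss_estimate(phantom[0].with_values(acq.truth_frames[0].values),
                     phantom[1], geom, mode="sss3d")
s_star = oracle_scale(acq.scatter_truth[0], model)
for margin in (0, 2, 4, 8, 14):
    mask = tail_mask(acq.acf, threshold=1.03, margin_voxels=margin)
    fit = fit_tail_scale(acq.emission[0], model, mask, per_plane=False)
    print(f"margin {margin:2d}: fitted/oracle scale = "
          f"{fit.global_scale / s_star:.3f}")
```

Output (seed 1):

```
margin  0: fitted/oracle scale = 2.149
margin  2: fitted/oracle scale = 1.422
margin  4: fitted/oracle scale = 1.003
margin  8: fitted/oracle scale = 0.995
margin 14: fitted/oracle scale = 0.979
```

At margin 0 the fit overestimates the true scatter scale by 115 % — the hot
skin rim has leaked into the stale tail. An 8-bin margin (≈10 mm at the
1.22 mm radial pitch) restores the scale to within half a percent. On an
aligned acquisition the same curve is flat near 1.0 at every margin.

## Analysis scripts

Numbered drivers under `analysis/` run the study end to end and write
tables under `results/`:

1. `01_phantom_and_acquisition.py` — phantom + paired aligned/shifted
   dynamic acquisitions;
2. `02_tail_scale_recovery.py` — fitted/oracle scatter scale vs ACF-margin
   (the table behind the example above, both cases, all margins);
3. `03_margin_sweep.py` — full pipeline (OSEM + kinetics): V_T vs margin,
   flat without mismatch, artefact-and-plateau with it;
4. `04_sss_mode_comparison.py` — 2D vs 3D SSS at an 8-bin margin on an
   axial-gradient phantom (central-VOI 3D/2D V_T ratio ≈ 1.03);
5. `05_motion_qc.py` — frame-to-reference motion report with injected
   shifts.

A `scatterscale` CLI wraps the same functionality
(`simulate | scatter-estimate | recon | sweep | compare-sss | motion-qc`).

## Acceptance script

`scripts/acceptance.py` re-runs the package's central computation from
scratch — the tail-fitted scatter-scale-versus-margin curves for an aligned
and a 5 mm-mismatched acquisition — prints the curves, and writes its
report to the path given by `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model, every tunable parameter with its
default and rationale, what the synthetic world does and does not emulate,
and the numerical choices (interpolation, tolerances, tie-breaks,
degenerate inputs).
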