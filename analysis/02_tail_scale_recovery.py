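"""Tail-fitted scatter scale vs ACF-margin, with and without mismatch.

The central mechanism: with the mu-map shifted 5 mm against the emission
data, true emission counts from the hot skin rim leak into the bins the ACF
declares object-free, and the scatter scale fitted on those bins
overestimates badly at margin 0.  Widening the object band (the ACF-margin)
pushes the tail away from the leaked counts; by an 8-bin (~10 mm) margin the
fitted scale is back at the oracle value.  Aligned data stay near the oracle
at every margin.

Writes results/02_tail_scale_recovery.csv.
Run from the repository root:  python analysis/02_tail_scale_recovery.py
"""

from pathlib import Path

import pandas as pd

from scatterscale.acquisition import simulate_acquisition
from scatterscale.geometry import build_geometry
from scatterscale.input_function import make_input_function
from scatterscale.motion import RigidShift
from scatterscale.phantoms import default_phantom_spec, make_head_phantom, tracer_profile
from scatterscale.scatter import fit_tail_scale, oracle_scale, sss_estimate, tail_mask
from scatterscale.schedules import FrameSchedule

RESULTS = Path("results")
MARGINS = (0, 2, 4, 6, 8, 10, 12, 14)


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    geom = build_geometry(
        n_rings=4, ring_pitch_mm=6.0, n_angles=48, n_radial=96,
        radial_pitch_mm=1.22, max_ring_difference=2, fov_radius_mm=45.0,
    )
    spec = default_phantom_spec(30.0, 4.0, axial_extent_mm=24.0)
    phantom = make_head_phantom(spec, geom, nxy=64)
    tracer = tracer_profile("verapamil_like")
    schedule = FrameSchedule.from_durations([600.0], start_s=3000.0)
    input_fn = make_input_function()

    rows = []
    for name, shift in (("aligned", RigidShift()),
                        ("shifted_5mm", RigidShift(5.0, 0.0, 0.0))):
        acq = simulate_acquisition(
            phantom, tracer, schedule, input_fn, geom, mismatch=shift,
            scatter_fraction=0.35, counts_per_frame=2e6, seed=seed,
        )
        model = sss_estimate(
            phantom[0].with_values(acq.truth_frames[0].values), phantom[1],
            geom, mode="sss3d",
        )
        s_star = oracle_scale(acq.scatter_truth[0], model)
        for margin in MARGINS:
            mask = tail_mask(acq.acf, threshold=1.03, margin_voxels=margin)
            fit = fit_tail_scale(acq.emission[0], model, mask, per_plane=False)
            rows.append(
                {
                    "case": name,
                    "margin_voxels": margin,
                    "margin_mm": margin * geom.radial_pitch_mm,
                    "tail_bins": mask.n_tail_bins,
                    "shat_over_sstar": fit.global_scale / s_star,
                }
            )

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "02_tail_scale_recovery.csv", index=False,
              float_format="%.6g")
    print(df.pivot(index="margin_voxels", columns="case",
                   values="shat_over_sstar").round(3).to_string())
    shifted0 = df[(df.case == "shifted_5mm") & (df.margin_voxels == 0)]
    shifted8 = df[(df.case == "shifted_5mm") & (df.margin_voxels == 8)]
    print(
        f"\nmargin 0 overestimates the scatter scale by "
        f"{100 * (shifted0.shat_over_sstar.iloc[0] - 1):.0f} % under a 5 mm "
        f"mismatch; an 8-bin (~10 mm) margin brings it to within "
        f"{100 * abs(shifted8.shat_over_sstar.iloc[0] - 1):.1f} % of the oracle."
    )


if __name__ == "__main__":
    main()
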