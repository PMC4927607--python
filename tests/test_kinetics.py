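import copy

import numpy as np
import pytest

from scatterscale.input_function import InputFunction, make_input_function
from scatterscale.kinetics import (
    KineticParams,
    fit_tac,
    model_tac,
    model_tissue_curve,
    voi_tacs,
)
from scatterscale.schedules import FrameSchedule, make_frame_schedule
from scatterscale.volume import VolumeImage


@pytest.fixture(scope="module")
def schedule():
    return make_frame_schedule("verapamil_raclopride")


class TestModelTac:
    def test_zero_k1_leaves_only_blood_signal(self, input_fn, schedule):
        p = KineticParams(K1=0.0, k2=0.1, Vb=0.1)
        curve = model_tissue_curve(p, "1t", input_fn)
        assert np.allclose(curve, 0.1 * input_fn.cb)

    def test_constant_input_closed_form(self, schedule):
        """For Cp = c (t>0), the 1T response is K1 c (1 - e^{-k2 t}) / k2."""
        t = np.arange(0.0, 3601.0)
        c = 10.0
        cp = np.full_like(t, c)
        cp[0] = 0.0
        inp = InputFunction(t_s=t, cp=cp, cb=np.zeros_like(t))
        p = KineticParams(K1=0.1, k2=0.2, Vb=0.0)
        curve = model_tissue_curve(p, "1t", inp)
        t_min = t / 60.0
        expected = p.K1 * c / p.k2 * (1.0 - np.exp(-p.k2 * t_min))
        # the first samples carry the trapezoid startup error of the
        # discontinuous ramp; beyond a few minutes the curves agree closely
        assert np.allclose(curve[300:], expected[300:], rtol=2e-3)

    def test_2t_with_k3_zero_collapses_to_1t(self, input_fn, schedule):
        p1 = KineticParams(K1=0.1, k2=0.2, Vb=0.05)
        p2 = KineticParams(K1=0.1, k2=0.2, k3=0.0, k4=0.1, Vb=0.05)
        a = model_tac(p1, "1t", input_fn, schedule).activity
        b = model_tac(p2, "2t", input_fn, schedule).activity
        assert np.allclose(a, b, rtol=1e-9)

    def test_schedule_beyond_input_rejected(self, input_fn):
        sched = FrameSchedule.from_durations([4000.0])
        with pytest.raises(ValueError):
            model_tac(KineticParams(K1=0.1, k2=0.1), "1t", input_fn, sched)


class TestVtIdentities:
    def test_1t_vt_is_k1_over_k2(self):
        assert KineticParams(K1=0.05, k2=0.05).V_T == pytest.approx(1.0)

    def test_2t_vt_formula(self):
        p = KineticParams(K1=0.1, k2=0.2, k3=0.05, k4=0.025)
        assert p.V_T == pytest.approx(0.5 * 3.0)


class TestFitTac:
    def test_noiseless_1t_recovery(self, input_fn, schedule):
        p = KineticParams(K1=0.05, k2=0.05, Vb=0.05)
        tac = model_tac(p, "1t", input_fn, schedule)
        fit = fit_tac(tac, "1t", input_fn)
        assert fit.converged
        assert fit.V_T == pytest.approx(1.0, rel=0.01)

    def test_noiseless_2t_recovery(self, input_fn, schedule):
        p = KineticParams(K1=0.1, k2=0.2, k3=0.05, k4=0.025, Vb=0.05)
        tac = model_tac(p, "2t", input_fn, schedule)
        fit = fit_tac(tac, "2t", input_fn)
        assert fit.V_T == pytest.approx(1.5, rel=0.02)

    def test_2t_fit_on_1t_data_nests(self, input_fn, schedule):
        p = KineticParams(K1=0.05, k2=0.05, Vb=0.05)
        tac = model_tac(p, "1t", input_fn, schedule)
        fit = fit_tac(tac, "2t", input_fn)
        assert fit.V_T == pytest.approx(1.0, rel=0.03)

    def test_rmse_degrades_gracefully_with_noise(self, input_fn, schedule):
        p = KineticParams(K1=0.05, k2=0.05, Vb=0.05)
        tac = model_tac(p, "1t", input_fn, schedule)
        rng = np.random.default_rng(0)
        rmses = []
        for level in (0.02, 0.05, 0.10):
            errs = []
            for _ in range(15):
                noisy = copy.deepcopy(tac)
                noisy.activity = np.maximum(
                    tac.activity * (1 + level * rng.standard_normal(20)), 0.0
                )
                errs.append(fit_tac(noisy, "1t", input_fn).V_T - 1.0)
            rmses.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmses[0] < rmses[1] < rmses[2]

    def test_too_few_frames_rejected(self, input_fn):
        sched = FrameSchedule.from_durations([60.0] * 5)
        p = KineticParams(K1=0.05, k2=0.05)
        tac = model_tac(p, "1t", input_fn, sched)
        with pytest.raises(ValueError):
            fit_tac(tac, "1t", input_fn)


class TestVoiTacs:
    def _label_volume(self):
        lab = np.zeros((6, 6, 2), dtype=np.int32)
        lab[1:3, 1:3, :] = 1
        lab[4, 4, 0] = 2
        return VolumeImage(lab, (2.0, 2.0, 2.0), "label")

    def test_uniform_frames_give_flat_tacs(self):
        labels = self._label_volume()
        sched = FrameSchedule.from_durations([60.0] * 8)
        frames = [
            VolumeImage(np.full((6, 6, 2), 3.5), (2.0, 2.0, 2.0))
            for _ in range(8)
        ]
        tacs = voi_tacs(frames, labels, sched)
        assert set(tacs) == {1, 2}
        for tac in tacs.values():
            assert np.allclose(tac.activity, 3.5)

    def test_single_voxel_label_is_that_voxels_series(self):
        labels = self._label_volume()
        sched = FrameSchedule.from_durations([60.0] * 8)
        rng = np.random.default_rng(2)
        frames = [
            VolumeImage(rng.random((6, 6, 2)), (2.0, 2.0, 2.0)) for _ in range(8)
        ]
        tacs = voi_tacs(frames, labels, sched)
        series = np.array([f.values[4, 4, 0] for f in frames])
        assert np.allclose(tacs[2].activity, series)

    def test_label_means_reassemble_global_mean(self):
        labels = self._label_volume()
        lab = labels.values
        sched = FrameSchedule.from_durations([60.0] * 8)
        rng = np.random.default_rng(3)
        frames = [
            VolumeImage(rng.random((6, 6, 2)), (2.0, 2.0, 2.0)) for _ in range(8)
        ]
        tacs = voi_tacs(frames, labels, sched)
        for f_idx, frame in enumerate(frames):
            total = sum(
                tacs[v].activity[f_idx] * (lab == v).sum() for v in (1, 2)
            )
            expected = frame.values[lab > 0].sum()
            assert total == pytest.approx(expected, abs=1e-9)


class TestRoundTrip:
    def test_tac_csv_roundtrip(self, input_fn, tmp_path):
        from scatterscale.kinetics import tac_from_csv, tac_to_csv
        from scatterscale.schedules import make_frame_schedule

        sched = make_frame_schedule("flumazenil")
        p = KineticParams(K1=0.35, k2=0.07, Vb=0.05)
        tac = model_tac(p, "1t", input_fn, sched, label="brain")
        path = tmp_path / "tac.csv"
        tac_to_csv(tac, path)
        back = tac_from_csv(path)
        assert back.label == "brain"
        assert np.allclose(back.activity, tac.activity)
        assert np.allclose(back.mid_times_min, tac.mid_times_min)

    def test_fit_json(self, input_fn, tmp_path):
        import json

        from scatterscale.kinetics import fit_to_json
        from scatterscale.schedules import make_frame_schedule

        sched = make_frame_schedule("verapamil_raclopride")
        p = KineticParams(K1=0.05, k2=0.05, Vb=0.05)
        fit = fit_tac(model_tac(p, "1t", input_fn, sched), "1t", input_fn)
        path = tmp_path / "fit.json"
        fit_to_json(fit, path)
        blob = json.loads(path.read_text())
        assert blob["model"] == "1t"
        assert blob["V_T_ml_per_cm3"] == pytest.approx(1.0, rel=0.01)
        assert blob["converged"] is True
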