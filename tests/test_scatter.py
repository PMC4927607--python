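import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scatterscale.geometry import build_geometry
from scatterscale.scatter import (
    DegenerateInputError,
    FitDegenerateError,
    fit_tail_scale,
    klein_nishina,
    kn_total_cross_section,
    margin_to_mm,
    oracle_scale,
    scatter_correct,
    scattered_energy,
    sss_estimate,
    tail_mask,
)
from scatterscale.sinogram import Sinogram
from scatterscale.volume import default_volume_grid


class TestComptonPhysics:
    def test_forward_scatter_limit(self):
        assert klein_nishina(0.0) == pytest.approx(1.0)

    def test_backscatter_value(self):
        # P = 1/3 at theta = pi: 0.5 * (1/9) * (1/3 + 3) = 5/27
        assert klein_nishina(np.pi) == pytest.approx(5.0 / 27.0)

    def test_monotone_decreasing_up_to_ninety_degrees(self):
        theta = np.linspace(0.0, np.pi / 2, 200)
        vals = klein_nishina(theta)
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 511.0), (np.pi / 2, 255.5), (np.pi, 511.0 / 3.0)],
    )
    def test_scattered_energy(self, theta, expected):
        assert scattered_energy(theta) == pytest.approx(expected)

    def test_angle_range_enforced(self):
        with pytest.raises(ValueError):
            klein_nishina(-0.1)
        with pytest.raises(ValueError):
            scattered_energy(3.5)

    def test_total_cross_section_decreases_with_energy(self):
        e = np.array([170.0, 255.5, 511.0])
        sig = kn_total_cross_section(e)
        assert np.all(np.diff(sig) < 0)


@pytest.fixture(scope="module")
def row_geometry():
    """One plane, one angle, seven radial bins - for hand-derived masks."""
    return build_geometry(
        n_rings=1, ring_pitch_mm=2.0, n_angles=1, n_radial=7,
        radial_pitch_mm=2.0, max_ring_difference=0, fov_radius_mm=7.0,
    )


class TestTailMask:
    def _acf(self, row_geometry, row):
        return Sinogram(np.asarray(row, dtype=float), "acf", row_geometry)

    def test_hand_derived_margin_zero(self, row_geometry):
        acf = self._acf(row_geometry, [1.0, 1.0, 1.5, 2.0, 1.5, 1.0, 1.0])
        mask = tail_mask(acf, threshold=1.03, margin_voxels=0)
        assert set(np.flatnonzero(mask.mask)) == {0, 1, 5, 6}

    def test_hand_derived_margin_one(self, row_geometry):
        # object {2,3,4} dilated by 1 -> {1..5}; tail = {0,6}
        acf = self._acf(row_geometry, [1.0, 1.0, 1.5, 2.0, 1.5, 1.0, 1.0])
        mask = tail_mask(acf, threshold=1.03, margin_voxels=1)
        assert set(np.flatnonzero(mask.mask)) == {0, 6}

    def test_unit_acf_everything_is_tail(self, row_geometry):
        acf = self._acf(row_geometry, np.ones(7))
        for margin in (0, 1, 2):
            assert tail_mask(acf, 1.03, margin).n_tail_bins == 7

    def test_excessive_margin_rejected(self, row_geometry):
        acf = self._acf(row_geometry, np.ones(7))
        with pytest.raises(ValueError):
            tail_mask(acf, 1.03, 4)

    def test_requires_acf_kind(self, row_geometry):
        em = Sinogram(np.ones(7), "emission", row_geometry)
        with pytest.raises(ValueError):
            tail_mask(em, 1.03, 0)

    @settings(deadline=None, max_examples=40)
    @given(
        data=st.lists(st.floats(1.0, 3.0), min_size=7, max_size=7),
        margin=st.integers(0, 3),
    )
    def test_mask_respects_threshold_and_distance(self, row_geometry, data, margin):
        acf = self._acf(row_geometry, data)
        mask = tail_mask(acf, threshold=1.03, margin_voxels=margin)
        above = np.flatnonzero(np.asarray(data) > 1.03)
        for i in np.flatnonzero(mask.mask):
            assert data[i] <= 1.03
            if above.size:
                assert np.abs(above - i).min() > margin


class TestTailFit:
    def test_exact_scale_of_two(self, aligned_acquisition, true_scatter_model):
        mask = tail_mask(aligned_acquisition.acf, 1.03, 0)
        measured = true_scatter_model.sinogram.with_values(
            2.0 * true_scatter_model.sinogram.values, kind="emission"
        )
        fit = fit_tail_scale(measured, true_scatter_model, mask)
        assert fit.global_scale == pytest.approx(2.0, rel=1e-12)
        fitted = fit.plane_scales[~fit.flagged]
        assert np.allclose(fitted, 2.0)

    def test_matches_brute_force_scan(self, aligned_acquisition,
                                      true_scatter_model):
        """The closed-form scale minimises SSE over a brute-force grid."""
        mask = tail_mask(aligned_acquisition.acf, 1.03, 2)
        y = aligned_acquisition.emission[0].values[mask.mask]
        m = true_scatter_model.sinogram.values[mask.mask]
        fit = fit_tail_scale(
            aligned_acquisition.emission[0], true_scatter_model, mask,
            per_plane=False,
        )
        scales = np.linspace(0.0, 3.0 * fit.global_scale, 3001)
        sse = ((y[None, :] - scales[:, None] * m[None, :]) ** 2).sum(axis=1)
        best = scales[np.argmin(sse)]
        assert fit.global_scale == pytest.approx(best, rel=2e-3)

    def test_noisy_recovery_within_two_percent(self, geometry,
                                               true_scatter_model):
        rng = np.random.default_rng(4)
        m = true_scatter_model.sinogram.values
        mask = tail_mask(
            Sinogram(np.ones(geometry.n_bins), "acf", geometry), 1.03, 0
        )
        # SNR >= 10 on tail bins: scale counts so mean tail bin ~ 100
        scale = 100.0 / m[m > 0].mean()
        y = rng.poisson(scale * m).astype(float)
        fit = fit_tail_scale(
            Sinogram(y, "emission", geometry), true_scatter_model, mask,
            per_plane=False,
        )
        assert fit.global_scale == pytest.approx(scale, rel=0.02)

    def test_mismatch_inflates_scale(self, aligned_acquisition,
                                     mismatch_acquisition, true_scatter_model):
        """Emission leaking into the tail of a shifted-mu acquisition makes
        the fitted scale strictly larger than the aligned fit."""
        fits = {}
        for name, acq in (("aligned", aligned_acquisition),
                          ("shifted", mismatch_acquisition)):
            mask = tail_mask(acq.acf, 1.03, 0)
            fits[name] = fit_tail_scale(
                acq.emission[0], true_scatter_model, mask, per_plane=False
            ).global_scale
        assert fits["shifted"] > 1.5 * fits["aligned"]

    def test_zero_model_degenerate(self, geometry):
        zero = Sinogram(np.zeros(geometry.n_bins), "scatter", geometry)
        from scatterscale.scatter import ScatterModel

        model = ScatterModel(zero, 8.0, "sss3d")
        acf = Sinogram(np.ones(geometry.n_bins), "acf", geometry)
        mask = tail_mask(acf, 1.03, 0)
        with pytest.raises(FitDegenerateError):
            fit_tail_scale(
                Sinogram(np.ones(geometry.n_bins), "emission", geometry),
                model, mask,
            )


class TestScatterCorrect:
    def test_zero_scale_gives_zero_correction(self, aligned_acquisition,
                                              true_scatter_model):
        mask = tail_mask(aligned_acquisition.acf, 1.03, 0)
        zero = aligned_acquisition.emission[0].with_values(
            np.zeros_like(aligned_acquisition.emission[0].values)
        )
        fit = fit_tail_scale(zero, true_scatter_model, mask)
        out = scatter_correct(zero, true_scatter_model, fit)
        assert out.values.sum() == 0.0

    def test_scale_invariance(self, aligned_acquisition, true_scatter_model):
        """Doubling the model halves the fit; the product is unchanged."""
        from scatterscale.scatter import ScatterModel

        em = aligned_acquisition.emission[0]
        mask = tail_mask(aligned_acquisition.acf, 1.03, 4)
        fit1 = fit_tail_scale(em, true_scatter_model, mask)
        out1 = scatter_correct(em, true_scatter_model, fit1)
        doubled = ScatterModel(
            true_scatter_model.sinogram.with_values(
                2.0 * true_scatter_model.sinogram.values
            ),
            true_scatter_model.scatter_grid_mm,
            true_scatter_model.mode,
        )
        fit2 = fit_tail_scale(em, doubled, mask)
        out2 = scatter_correct(em, doubled, fit2)
        assert np.allclose(fit2.plane_scales, fit1.plane_scales / 2.0)
        assert np.allclose(out1.values, out2.values, rtol=1e-12)

    def test_corrected_total_not_above_measured(self, aligned_acquisition,
                                                true_scatter_model):
        em = aligned_acquisition.emission[0]
        mask = tail_mask(aligned_acquisition.acf, 1.03, 4)
        fit = fit_tail_scale(em, true_scatter_model, mask, per_plane=False)
        out = scatter_correct(em, true_scatter_model, fit)
        assert out.values.sum() <= em.values.sum()


class TestSssEstimate:
    def test_zero_activity_gives_zero_scatter(self, head_phantom, geometry):
        act, mu, _ = head_phantom
        zero = act.with_values(np.zeros(act.shape))
        model = sss_estimate(zero, mu, geometry, mode="sss3d")
        assert model.sinogram.values.sum() == 0.0

    def test_empty_scatter_grid_degenerate(self, head_phantom, geometry):
        act, mu, _ = head_phantom
        air = mu.with_values(np.zeros(mu.shape))
        with pytest.raises(DegenerateInputError):
            sss_estimate(act, air, geometry)

    def test_model_is_smooth(self, true_scatter_model, geometry):
        """No bin exceeds 4x the mean of its 8 in-plane neighbours."""
        for arr in true_scatter_model.sinogram.split().values():
            for plane in arr:
                nb = (
                    plane[:-2, :-2] + plane[:-2, 1:-1] + plane[:-2, 2:]
                    + plane[1:-1, :-2] + plane[1:-1, 2:]
                    + plane[2:, :-2] + plane[2:, 1:-1] + plane[2:, 2:]
                ) / 8.0
                centre = plane[1:-1, 1:-1]
                assert np.all(centre <= 4.0 * nb + 1e-15)

    def test_scatter_peaks_under_object_with_tails_outside(
        self, true_scatter_model, aligned_acquisition, geometry
    ):
        """Broad hump peaking under the object, nonzero beyond its ACF band."""
        m = true_scatter_model.sinogram.split()[0][1]  # one direct plane
        acf = aligned_acquisition.acf_true.split()[0][1]
        obj = acf > 1.03
        assert np.unravel_index(np.argmax(m), m.shape)[1] not in (0, m.shape[1] - 1)
        assert m[obj].max() > 5.0 * m[:, :4].max()  # far radial tail is small
        assert m[~obj].min() > 0.0  # but never zero

    def test_convergence_in_scatter_grid(self, head_phantom, geometry):
        """Halving the scatter-point grid changes the estimate by < 3 % RMS."""
        act, mu, _ = head_phantom
        coarse = sss_estimate(act, mu, geometry, scatter_grid_mm=8.0)
        fine = sss_estimate(act, mu, geometry, scatter_grid_mm=4.0)
        c = coarse.sinogram.values / coarse.sinogram.values.sum()
        f = fine.sinogram.values / fine.sinogram.values.sum()
        assert np.linalg.norm(c - f) / np.linalg.norm(f) < 0.03


class TestModeCollapse:
    def test_2d_3d_agree_for_axially_uniform_object(self, head_phantom,
                                                    geometry):
        act, mu, _ = head_phantom
        m3 = sss_estimate(act, mu, geometry, mode="sss3d").sinogram.values
        m2 = sss_estimate(act, mu, geometry, mode="sss2d").sinogram.values
        assert np.linalg.norm(m3 - m2) / np.linalg.norm(m3) < 0.05

    def test_axial_gradient_separates_modes(self, head_phantom,
                                            gradient_phantom, geometry):
        def oblique_rms(phantom):
            act, mu, _ = phantom
            s3 = sss_estimate(act, mu, geometry, mode="sss3d").sinogram.split()
            s2 = sss_estimate(act, mu, geometry, mode="sss2d").sinogram.split()
            num = sum(((s3[d] - s2[d]) ** 2).sum() for d in s3 if d != 0)
            den = sum((s3[d] ** 2).sum() for d in s3 if d != 0)
            return np.sqrt(num / den)

        assert oblique_rms(gradient_phantom) > oblique_rms(head_phantom)


def test_margin_unit_conversion():
    assert margin_to_mm(8) == pytest.approx(9.76)
    assert round(margin_to_mm(8)) == 10
    assert round(margin_to_mm(14)) == 17


def test_oracle_scale_recovers_known_scaling(true_scatter_model,
                                             aligned_acquisition):
    truth = aligned_acquisition.scatter_truth[0]
    s = oracle_scale(truth, true_scatter_model)
    assert s > 0
    # truth is the (broadened) model at scale s: residual well below signal
    resid = truth.values - s * true_scatter_model.sinogram.values
    assert np.linalg.norm(resid) < 0.1 * np.linalg.norm(truth.values)


def test_flagged_planes_take_nearest_fitted_scale():
    """A plane whose tail is entirely masked out is flagged and inherits the
    nearest fitted plane's scale."""
    from scatterscale.scatter import ScatterModel

    g = build_geometry(
        n_rings=2, ring_pitch_mm=4.0, n_angles=4, n_radial=40,
        radial_pitch_mm=2.0, max_ring_difference=0, fov_radius_mm=40.0,
    )
    rng = np.random.default_rng(0)
    m = rng.uniform(0.5, 1.5, g.n_bins)
    model = ScatterModel(Sinogram(m, "scatter", g), 8.0, "sss3d")
    # plane 0: ACF everywhere above threshold -> zero tail bins -> flagged;
    # plane 1: ACF of 1 everywhere -> all bins are tail
    acf_vals = np.ones(g.n_bins)
    per_plane_bins = g.n_angles * g.n_radial
    acf_vals[:per_plane_bins] = 2.0
    mask = tail_mask(Sinogram(acf_vals, "acf", g), 1.03, 0)
    measured = Sinogram(3.0 * m, "emission", g)
    fit = fit_tail_scale(measured, model, mask)
    assert fit.flagged[0] and not fit.flagged[1]
    assert fit.tail_bin_counts[0] == 0
    assert fit.plane_scales[1] == pytest.approx(3.0)
    assert fit.plane_scales[0] == fit.plane_scales[1]
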