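"""Tests of the synthetic-data generator: dynamics, rendering, drift,
titrations, and their ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tirfquant.binding import fit_kd
from tirfquant.images import ImagingParams, NoiseModel
from tirfquant.ptm import extend_polyline, linescan_profile, subtract_background
from tirfquant.synthetic import (
    DynamicsParams,
    FOVLayout,
    MicrotubuleSpec,
    TitrationDesign,
    apply_drift,
    density_for_linescan_mean,
    expected_linescan_mean,
    make_fov_layout,
    render_fov_image,
    render_kymograph,
    scale_for_median,
    simulate_dynamics,
    simulate_titration,
)


class TestSimulateDynamics:
    def test_deterministic_given_seed(self):
        p = DynamicsParams()
        a = simulate_dynamics(p, 10, 600.0, rng_seed=7)
        b = simulate_dynamics(p, 10, 600.0, rng_seed=7)
        pd.testing.assert_frame_equal(a.events, b.events)
        c = simulate_dynamics(p, 10, 600.0, rng_seed=8)
        assert not a.events.equals(c.events)

    def test_vanishing_variance_limit(self):
        """Shape -> infinity at fixed mean 200 s: every lifetime is ~200 s
        and a microtubule grows v * 200 / 60 um before each catastrophe."""
        p = DynamicsParams(
            lifetime_shape=1e6, lifetime_scale_s=200.0 / 1e6, speed_cv=0.0,
            regrow_delay_s=0.0,
        )
        t = simulate_dynamics(p, 5, 1000.0, rng_seed=1)
        unc = t.events[~t.events.censored]
        lifetimes = unc.catastrophe_time_s - unc.onset_time_s
        assert np.allclose(lifetimes, 200.0, rtol=0.01)
        lengths = unc.speed_um_min * lifetimes / 60.0
        expected = unc.speed_um_min * 200.0 / 60.0
        assert np.allclose(lengths, expected, rtol=0.01)

    def test_no_catastrophe_within_duration_all_censored(self):
        p = DynamicsParams(lifetime_shape=3.0, lifetime_scale_s=1e6)
        t = simulate_dynamics(p, 8, 600.0, rng_seed=0)
        assert t.events.censored.all()
        assert len(t.events) == 16  # one growing event per seed and end

    def test_gamma_law_moments_against_independent_generator(self):
        """>= 10^4 simulated lifetimes match an independent Monte-Carlo of
        the same gamma law in mean and variance within 3 standard errors."""
        k, theta = 3.0, 67.5
        p = DynamicsParams(
            lifetime_shape=k, lifetime_scale_s=theta, regrow_delay_s=0.0
        )
        t = simulate_dynamics(p, 60, 45_000.0, rng_seed=3)
        unc = t.events[(~t.events.censored) & (t.events.end == "plus")]
        x = (unc.catastrophe_time_s - unc.onset_time_s).to_numpy()
        assert x.size >= 10_000
        oracle = stats.gamma.rvs(a=k, scale=theta, size=200_000,
                                 random_state=np.random.RandomState(99))
        se_mean = oracle.std() / np.sqrt(x.size)
        assert abs(x.mean() - k * theta) < 3 * se_mean
        var_se = np.sqrt(np.var((oracle - oracle.mean()) ** 2) / x.size)
        assert abs(x.var() - k * theta**2) < 3 * var_se

    def test_censoring_bookkeeping(self):
        t = simulate_dynamics(DynamicsParams(), 20, 900.0, rng_seed=5)
        for (_, _), grp in t.events.groupby(["mt_id", "end"]):
            # at most one censored episode per end, and it is the last one
            assert grp.censored.sum() <= 1
            if grp.censored.any():
                assert grp.censored.iloc[-1]
            # uncensored + censored episodes account for every nucleation
            assert grp.censored.sum() + (~grp.censored).sum() == len(grp)

    def test_invalid_inputs_name_the_field(self):
        with pytest.raises(ValueError, match="duration_s"):
            simulate_dynamics(DynamicsParams(), 5, -1.0, rng_seed=0)
        with pytest.raises(ValueError, match="lifetime_shape"):
            DynamicsParams(lifetime_shape=0.0)
        with pytest.raises(ValueError, match="v_plus_um_min"):
            DynamicsParams(v_plus_um_min=-1.0)

    def test_scale_for_median(self):
        theta = scale_for_median(202.61, 3.0)
        assert stats.gamma.ppf(0.5, a=3.0, scale=theta) == pytest.approx(202.61)


class TestRenderKymograph:
    def test_tip_column_noiseless_no_psf(self):
        """With no PSF and no noise, the farthest occupied column at frame
        t is the pixel containing the tip: round(tip_position / pixel_size)
        under the pixel-center convention."""
        p = DynamicsParams(speed_cv=0.0, lifetime_scale_s=1e6)
        ev = simulate_dynamics(p, 1, 300.0, rng_seed=0)
        im = ImagingParams(psf_sigma_px=0.0, noise=NoiseModel(kind="none"))
        k = render_kymograph(ev, im, 0, rng_seed=0)
        img = k.channels["tubulin"]
        for t in (10, 80, 140):
            tip_px = k.truth["plus_tip_um"][t] / im.pixel_size_um
            last = np.nonzero(img[t] > im.background + 1e-9)[0][-1]
            assert last == int(np.floor(tip_px + 0.5))

    def test_zero_gain_channel_is_pure_background(self):
        p = DynamicsParams(speed_cv=0.0)
        ev = simulate_dynamics(p, 1, 200.0, rng_seed=0)
        im = ImagingParams(
            noise=NoiseModel(kind="none"),
            channel_gains={"seed": 80.0, "tubulin": 0.0},
        )
        k = render_kymograph(ev, im, 0, rng_seed=0)
        assert np.allclose(k.channels["tubulin"], im.background)

    def test_rendering_affine_in_gain_and_background(self):
        p = DynamicsParams(speed_cv=0.0)
        ev = simulate_dynamics(p, 1, 200.0, rng_seed=2)
        im1 = ImagingParams(noise=NoiseModel(kind="none"), background=100.0,
                            channel_gains={"seed": 80.0, "tubulin": 50.0})
        im2 = ImagingParams(noise=NoiseModel(kind="none"), background=40.0,
                            channel_gains={"seed": 160.0, "tubulin": 100.0})
        k1 = render_kymograph(ev, im1, 0, rng_seed=0)
        k2 = render_kymograph(ev, im2, 0, rng_seed=0)
        net1 = k1.channels["tubulin"] - 100.0
        net2 = k2.channels["tubulin"] - 40.0
        assert np.allclose(net2, 2.0 * net1)

    def test_missing_mt_id_raises(self):
        ev = simulate_dynamics(DynamicsParams(), 2, 100.0, rng_seed=0)
        with pytest.raises(KeyError, match="99"):
            render_kymograph(ev, ImagingParams(), 99)


class TestRenderFov:
    def _isolated_layout(self, angle_deg=0.0, density=150.0):
        mt = MicrotubuleSpec(
            anchor_px=(100.0, 60.0),
            angle_rad=np.deg2rad(angle_deg),
            seed_length_um=3.0,
            plus_length_um=5.0,
            minus_length_um=2.0,
            antibody_density=density,
            seed_density=70.0,
        )
        return FOVLayout(shape=(120, 200), mts=[mt])

    def test_zero_antibody_density_background_only(self, imaging_noiseless):
        layout = self._isolated_layout(density=0.0)
        fov = render_fov_image(layout, imaging_noiseless, rng_seed=0)
        assert np.allclose(fov.channels["antibody"], imaging_noiseless.background)

    def test_pixel_sum_matches_analytic_integral(self, imaging_noiseless):
        """Total counts of an isolated microtubule equal
        density x length x gain (the PSF preserves the integral)."""
        layout = self._isolated_layout(angle_deg=20.0)
        fov = render_fov_image(layout, imaging_noiseless, rng_seed=0)
        net = fov.channels["antibody"] - imaging_noiseless.background
        mt = layout.mts[0]
        length_um = mt.seed_length_um + mt.plus_length_um + mt.minus_length_um
        expected = (
            mt.antibody_density * length_um
            * imaging_noiseless.channel_gains["antibody"]
        )
        assert net.sum() == pytest.approx(expected, rel=1e-3)

    def test_doubling_density_doubles_linescan_mean(self, imaging_noiseless):
        vals = []
        for dens in (120.0, 240.0):
            layout = self._isolated_layout(density=dens)
            fov = render_fov_image(layout, imaging_noiseless, rng_seed=0)
            trace = extend_polyline(fov.truth["mt_polylines"][0], 10.0)
            prof = linescan_profile(fov, trace)
            n = prof.samples["antibody"].size
            m = subtract_background(prof, "antibody", span=(26, n - 26))
            vals.append(m.value)
        assert vals[1] == pytest.approx(2.0 * vals[0], rel=1e-6)

    def test_expected_linescan_calibration(self, imaging_noiseless):
        """The analytic linescan expectation matches the rendered value."""
        dens = density_for_linescan_mean(175.0, imaging_noiseless, "seed")
        mt = MicrotubuleSpec(
            anchor_px=(100.0, 60.0), angle_rad=0.0, seed_length_um=4.0,
            plus_length_um=4.0, minus_length_um=2.0,
            antibody_density=0.0, seed_density=dens,
        )
        fov = render_fov_image(FOVLayout(shape=(120, 200), mts=[mt]),
                               imaging_noiseless, rng_seed=0)
        trace = extend_polyline(fov.truth["seed_polylines"][0], 10.0)
        prof = linescan_profile(fov, trace)
        n = prof.samples["seed"].size
        m = subtract_background(prof, "seed", span=(26, n - 26))
        assert m.value == pytest.approx(175.0, rel=0.01)

    def test_layout_rejects_out_of_bounds_anchor(self):
        mt = MicrotubuleSpec(
            anchor_px=(500.0, 60.0), angle_rad=0.0, seed_length_um=3.0,
            plus_length_um=3.0, minus_length_um=1.0,
            antibody_density=1.0, seed_density=1.0,
        )
        with pytest.raises(ValueError, match="outside"):
            FOVLayout(shape=(120, 200), mts=[mt])

    def test_overlap_flagging(self, imaging_noiseless):
        mts = [
            MicrotubuleSpec((100.0, 60.0), 0.0, 3.0, 5.0, 2.0, 10.0, 10.0),
            MicrotubuleSpec((100.0, 62.0), 0.0, 3.0, 5.0, 2.0, 10.0, 10.0),
            MicrotubuleSpec((100.0, 110.0), 0.0, 3.0, 5.0, 2.0, 10.0, 10.0),
        ]
        fov = render_fov_image(FOVLayout(shape=(140, 200), mts=mts),
                               imaging_noiseless, rng_seed=0)
        assert fov.truth["overlapping"][:2] == [True, True]
        assert fov.truth["overlapping"][2] is False

    def test_grid_layout_is_overlap_free(self, imaging_default, rng):
        layout = make_fov_layout(
            70, imaging_default, rng, antibody_density_mean=100.0, seed_density=70.0
        )
        fov = render_fov_image(layout, imaging_default, rng_seed=1)
        assert not any(fov.truth["overlapping"])


class TestApplyDrift:
    def test_zero_track_is_identity(self, rng):
        movie = rng.normal(100, 5, (5, 32, 32))
        out = apply_drift(movie, np.zeros((5, 2)))
        assert np.array_equal(out, movie)

    def test_integer_track_exact(self, rng):
        movie = rng.normal(100, 5, (4, 40, 40))
        track = np.array([[3 * n, -2 * n] for n in range(4)], dtype=float)
        out = apply_drift(movie, track, fill=0.0)
        for n in range(4):
            rolled = np.roll(np.roll(movie[n], -2 * n, axis=0), 3 * n, axis=1)
            interior = np.s_[: -2 * n or None, 3 * n:]
            assert np.allclose(out[n][interior], rolled[interior])

    def test_oversized_drift_rejected(self, rng):
        movie = rng.normal(0, 1, (2, 16, 16))
        with pytest.raises(ValueError, match="exceeds"):
            apply_drift(movie, np.array([[0.0, 0.0], [20.0, 0.0]]))


class TestSimulateTitration:
    def test_endpoint_limits_noiseless(self):
        d = TitrationDesign(kd=1e-8, top_concentration=1e-4, n_points=24,
                            noise_sd=0.0)
        tit = simulate_titration(d, rng_seed=0)
        # lowest concentration ~ 6 pM: essentially free
        assert tit.response[-1] == pytest.approx(d.signal_free, abs=1e-3)
        # top >> Kd and >> labeled total: saturated
        assert tit.response[0] == pytest.approx(d.signal_bound, rel=1e-3)

    def test_deterministic_given_seed(self):
        d = TitrationDesign(kd=15.5e-9, top_concentration=2e-6, noise_sd=0.05)
        a = simulate_titration(d, rng_seed=4)
        b = simulate_titration(d, rng_seed=4)
        assert np.array_equal(a.response, b.response)

    def test_round_trip_self_consistency(self):
        """A noiseless curve refit by the Kd fitter returns the generating
        Kd to < 1e-6 relative error."""
        d = TitrationDesign(kd=15.5e-9, top_concentration=2e-6, noise_sd=0.0)
        fit = fit_kd(simulate_titration(d, rng_seed=0))
        assert fit.kd == pytest.approx(15.5e-9, rel=1e-6)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="n_points"):
            TitrationDesign(kd=1e-9, top_concentration=1e-6, n_points=4)
        d = TitrationDesign(kd=1e-9, top_concentration=1e-6)
        conc = d.concentrations()
        assert np.allclose(conc[:-1] / conc[1:], 2.0)


def test_expected_linescan_mean_formula(imaging_default):
    """The width-2 expectation equals the Gaussian ridge amplitude averaged
    at perpendicular offsets of +/- 0.5 px."""
    sigma = imaging_default.psf_sigma_px
    lam = 10.0 * imaging_default.pixel_size_um * imaging_default.channel_gains["seed"]
    manual = lam / (np.sqrt(2 * np.pi) * sigma) * np.exp(-0.125 / sigma**2)
    assert expected_linescan_mean(10.0, imaging_default, "seed") == pytest.approx(manual)
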