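"""Filopodial straightening, kymographs, velocity windows and mixture fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filotrack as ft
from filotrack.kinetics import (FilopodiumPath, straighten, straighten_frame,
                                build_kymograph, measure_kymo_velocity,
                                instantaneous_velocities, windowed_slopes,
                                fit_two_gaussians, compare_velocities)
from filotrack.render import render_stack
from filotrack.tracking import Spot, Track


class TestFilopodiumPath:
    def test_arc_length_of_semicircle(self):
        """Spline through a semicircle of radius 2: arc length ~ pi r."""
        theta = np.linspace(0, np.pi, 20)
        pts = np.column_stack([2 * np.cos(theta) + 3, 2 * np.sin(theta) + 1])
        path = FilopodiumPath(pts)
        assert path.length_um == pytest.approx(np.pi * 2, abs=0.1)

    def test_projection_and_reversal_negate_velocities(self):
        pts = np.array([[1.0, 1.0], [5.0, 1.0]])
        path = FilopodiumPath(pts)
        track_pts = np.column_stack([np.linspace(1.5, 4.5, 20), np.full(20, 1.0)])
        s, dist = path.project(track_pts)
        t = np.arange(20) * 0.05
        v_fwd = windowed_slopes(t, s, 10)
        s_rev, _ = path.reversed().project(track_pts)
        v_rev = windowed_slopes(t, s_rev, 10)
        np.testing.assert_allclose(v_fwd, -v_rev, atol=1e-6)


class TestStraighten:
    def test_straight_path_equals_axis_crop(self, filo_config):
        """A straight horizontal filopodium straightens to the aligned crop."""
        rng = np.random.default_rng(0)
        frame = rng.uniform(100, 200, size=(24, 80))
        path = FilopodiumPath(np.array([[1.05, 1.15], [6.05, 1.15]]))
        strip = straighten_frame(frame, path, filo_config, stripe_px=5,
                                 reduce=False)
        # row 11 is the path row (y = 1.15 um); crop columns 10..60
        crop = frame[9:14, 10:10 + strip.shape[0]].T
        assert strip.shape[1] == 5
        np.testing.assert_allclose(strip, crop, atol=1e-6)

    def test_even_stripe_rejected(self, filo_config):
        path = FilopodiumPath(np.array([[1.0, 1.2], [6.0, 1.2]]))
        with pytest.raises(ValueError):
            straighten_frame(np.zeros((24, 80)), path, filo_config, stripe_px=4)

    def test_kymograph_intensity_bookkeeping(self, filo_config, filopodium):
        """Kymograph columns hold exactly the straightened frame profiles."""
        rng = np.random.default_rng(1)
        tr = ft.directed_filopodial_run(filopodium, 1.4, 12, filo_config, rng,
                                        s0_um=0.5)
        stack = render_stack([tr], filo_config, seed=2)
        profiles = straighten(stack, FilopodiumPath(filopodium.axis_um))
        kymo = build_kymograph(profiles, filo_config)
        np.testing.assert_allclose(kymo.data.sum(axis=0),
                                   profiles.sum(axis=1), rtol=1e-12)


class TestKymoVelocity:
    def test_immobile_punctum_horizontal_band(self, filo_config, filopodium):
        tr = ft.directed_filopodial_run(filopodium, 0.0, 30, filo_config,
                                        np.random.default_rng(3), s0_um=2.5)
        stack = render_stack([tr], filo_config, seed=4)
        kymo = build_kymograph(straighten(stack, FilopodiumPath(filopodium.axis_um)),
                               filo_config)
        v = measure_kymo_velocity(kymo)
        assert abs(v) < 0.05

    def test_directed_run_slope_recovered(self, filo_config, filopodium):
        """Directed run at 1.4 um/s appears as a diagonal streak of that slope."""
        tr = ft.directed_filopodial_run(filopodium, 1.4, 50, filo_config,
                                        np.random.default_rng(5), s0_um=0.2)
        stack = render_stack([tr], filo_config, seed=6)
        kymo = build_kymograph(straighten(stack, FilopodiumPath(filopodium.axis_um)),
                               filo_config)
        v = measure_kymo_velocity(kymo, 0, 45)
        assert v == pytest.approx(1.4, abs=0.05)

    def test_stalled_then_directed_segments(self, filo_config, filopodium):
        """Segment-wise analysis separates stalled (0) from directed (v)."""
        cfg = filo_config
        n = 60
        t = np.arange(n) * cfg.frame_interval_s
        s = np.where(t < 1.5, 1.0, 1.0 + 1.4 * (t - 1.5))
        xy = np.array([FilopodiumPath(filopodium.axis_um).point_at(si) for si in s])
        from filotrack.simulate import GroundTruthTrajectory, FILO_DIRECTED
        tr = GroundTruthTrajectory(0, t, np.column_stack([xy, np.zeros(n)]),
                                   np.full(n, FILO_DIRECTED, dtype=object))
        stack = render_stack([tr], cfg, seed=7)
        kymo = build_kymograph(straighten(stack, FilopodiumPath(filopodium.axis_um)),
                               cfg)
        v_stall = measure_kymo_velocity(kymo, 0, 28)
        v_run = measure_kymo_velocity(kymo, 32, 58)
        assert abs(v_stall) < 0.08
        assert v_run == pytest.approx(1.4, abs=0.12)

    def test_blank_segment_rejected(self, filo_config, filopodium):
        stack = render_stack([], filo_config, n_frames=20, seed=8)
        kymo = build_kymograph(straighten(stack, FilopodiumPath(filopodium.axis_um)),
                               filo_config)
        with pytest.raises(ValueError):
            measure_kymo_velocity(kymo)

    def test_short_segment_rejected(self, filo_config, filopodium):
        stack = render_stack([], filo_config, n_frames=20, seed=9)
        kymo = build_kymograph(straighten(stack, FilopodiumPath(filopodium.axis_um)),
                               filo_config)
        with pytest.raises(ValueError, match="5 time columns"):
            measure_kymo_velocity(kymo, 0, 4)


def _track_from_positions(pos, frame0=0):
    spots = [Spot(frame0 + k, float(x), float(y), 100.0, 150.0)
             for k, (x, y) in enumerate(pos)]
    return Track(track_id=0, spots=spots)


class TestInstantaneousVelocities:
    def test_constant_velocity_all_windows(self, filo_config):
        path = FilopodiumPath(np.array([[1.0, 1.2], [6.0, 1.2]]))
        t = np.arange(40) * filo_config.frame_interval_s
        pos = np.column_stack([1.5 + 0.8 * t, np.full(40, 1.2)])
        vs = instantaneous_velocities(_track_from_positions(pos), path,
                                      filo_config)
        np.testing.assert_allclose(vs.velocities, 0.8, atol=0.02)

    def test_pure_diffusion_mean_zero(self, filo_config):
        path = FilopodiumPath(np.array([[0.5, 1.2], [7.5, 1.2]]))
        rng = np.random.default_rng(10)
        vs = []
        for _ in range(40):
            s = 4.0 + np.cumsum(rng.normal(0, np.sqrt(2 * 0.2 * 0.05), 100))
            pos = np.column_stack([np.clip(s, 0.6, 7.4), np.full(100, 1.2)])
            vs.extend(instantaneous_velocities(_track_from_positions(pos), path,
                                               filo_config).velocities)
        vs = np.array(vs)
        se = vs.std(ddof=1) / np.sqrt(len(vs))
        # windows overlap, so successive slopes are correlated: inflate the
        # naive SE by ~sqrt(window)
        assert abs(vs.mean()) < 3 * se * np.sqrt(10)

    def test_alternating_phases_bimodal(self, filo_config):
        """Alternating 500-ms stalled/directed phases give a bimodal
        window-velocity histogram at ~0 and ~1.4 um/s."""
        path = FilopodiumPath(np.array([[0.2, 1.2], [7.8, 1.2]]))
        dt = filo_config.frame_interval_s
        t = np.arange(140) * dt
        phase = (t // 0.5).astype(int) % 2
        v_true = 1.4 * phase
        s = 0.5 + np.cumsum(v_true * dt)
        pos = np.column_stack([s, np.full(len(t), 1.2)])
        vs = instantaneous_velocities(_track_from_positions(pos), path,
                                      filo_config).velocities
        frac_slow = np.mean(np.abs(vs) < 0.35)
        frac_fast = np.mean(np.abs(vs - 1.4) < 0.35)
        assert frac_slow > 0.2 and frac_fast > 0.2

    def test_off_axis_samples_dropped(self, filo_config):
        path = FilopodiumPath(np.array([[1.0, 1.2], [6.0, 1.2]]))
        pos = np.column_stack([np.linspace(1.5, 4.0, 20), np.full(20, 2.2)])
        vs = instantaneous_velocities(_track_from_positions(pos), path,
                                      filo_config)
        assert vs.n == 0

    def test_track_shorter_than_window_rejected(self, filo_config):
        path = FilopodiumPath(np.array([[1.0, 1.2], [6.0, 1.2]]))
        pos = np.column_stack([np.linspace(1.5, 2.0, 5), np.full(5, 1.2)])
        with pytest.raises(ValueError):
            instantaneous_velocities(_track_from_positions(pos), path,
                                     filo_config)


def _draw_mixture(rng, n, frac2, m1, s1, m2, s2):
    comp = rng.random(n) < frac2
    return np.where(comp, rng.normal(m2, s2, n), rng.normal(m1, s1, n))


class TestTwoGaussianFit:
    def test_needs_hundred_samples(self):
        with pytest.raises(ValueError):
            fit_two_gaussians(np.zeros(50))

    def test_well_separated_mixture_weights(self):
        """50/50 mixture of N(0, 0.1) and N(1, 0.1): weights 0.5 +/- 0.02."""
        rng = np.random.default_rng(11)
        v = _draw_mixture(rng, 10000, 0.5, 0.0, 0.1, 1.0, 0.1)
        fit = fit_two_gaussians(v)
        assert fit.V1 == pytest.approx(0.0, abs=0.02)
        assert fit.V2 == pytest.approx(1.0, abs=0.02)
        assert fit.pct_V2 == pytest.approx(0.5, abs=0.02)

    def test_table_parameters_recovered_over_seeds(self):
        """Median over 50 draws at the directed-fraction mixture of the
        full-length construct (n=425): V2 within 0.05, %V2 within 7 points."""
        v2s, pcts, n_unresolved = [], [], 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            v = _draw_mixture(rng, 425, 0.35, -0.06, 0.21, 0.28, 0.69)
            fit = fit_two_gaussians(v, bin_width=0.1)
            if fit.V2 is None:
                # overlapping components: a rare draw may not resolve two
                n_unresolved += 1
                continue
            v2s.append(fit.V2)
            pcts.append(100 * fit.pct_V2)
        assert n_unresolved <= 3
        assert np.median(v2s) == pytest.approx(0.28, abs=0.05)
        assert np.median(pcts) == pytest.approx(35.0, abs=7.0)

    def test_single_population_falls_back(self):
        """Narrow single-Gaussian input (free fluorophore): V2 undefined."""
        rng = np.random.default_rng(12)
        v = rng.normal(-0.06, 0.01, 378)
        fit = fit_two_gaussians(v, bin_width=0.005)
        assert fit.single_component and fit.V2 is None
        assert fit.pct_V2 == 0.0
        assert fit.V1 == pytest.approx(-0.06, abs=0.005)

    @pytest.mark.parametrize("bin_width", [0.05, 0.1, 0.2])
    def test_fitted_means_stable_across_bin_widths(self, bin_width):
        rng = np.random.default_rng(13)
        v = _draw_mixture(rng, 5000, 0.35, -0.06, 0.21, 0.28, 0.69)
        fit = fit_two_gaussians(v, bin_width=bin_width)
        assert fit.V2 == pytest.approx(0.28, abs=0.06)


class TestCompareVelocities:
    def test_reported_constructs_significance(self):
        """Full-length vs the SAH/CC deletion is significant (p < 0.05);
        the two deletions against each other are not (p > 0.05)."""
        fl = (0.28, 0.69, 149)
        d1 = (0.15, 0.60, 124)
        d2 = (0.23, 0.78, 43)
        assert compare_velocities(fl, d1) < 0.05
        assert compare_velocities(d2, d1) > 0.05

    def test_identical_fits_give_half(self):
        assert compare_velocities((0.3, 0.5, 100), (0.3, 0.5, 100)) == pytest.approx(0.5)

    def test_small_effective_n_refused(self):
        with pytest.raises(ValueError):
            compare_velocities((0.3, 0.5, 2), (0.3, 0.5, 100))

    def test_mixturefit_effective_n(self):
        from filotrack.kinetics import MixtureFit
        fit_a = MixtureFit(V1=-0.06, sigma1=0.21, A1=1.0, V2=0.28, sigma2=0.69,
                           A2=0.4, n_total=425, n_V2=149, pct_V2=149 / 425)
        fit_b = MixtureFit(V1=-0.04, sigma1=0.18, A1=1.0, V2=0.15, sigma2=0.60,
                           A2=0.5, n_total=275, n_V2=124, pct_V2=124 / 275)
        assert compare_velocities(fit_a, fit_b) < 0.05
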