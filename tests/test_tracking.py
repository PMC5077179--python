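"""Spot detection, nearest-neighbour linking and intensity traces."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import filotrack as ft
from filotrack.render import render_stack
from filotrack.simulate import GroundTruthTrajectory, MEM2D
from filotrack.tracking import (Spot, link_tracks, assert_spot_partition,
                                extract_intensity_trace)


def _immobile(config, x, y, n_frames, mol_id=0):
    t = np.arange(n_frames) * config.frame_interval_s
    xyz = np.tile([x, y, 0.0], (n_frames, 1))
    return GroundTruthTrajectory(mol_id, t, xyz,
                                 np.full(n_frames, MEM2D, dtype=object))


class TestDetectSpots:
    def test_blank_frames_yield_no_spots(self, config):
        """False-positive rate < 1e-3 per frame on rendered noise."""
        cfg = ft.SimConfig(field_w_px=128, field_h_px=128)
        blank = render_stack([], cfg, n_frames=100, seed=21)
        n_fp = sum(len(ft.detect_spots(f, cfg, 4.0)) for f in blank.data)
        assert n_fp == 0

    def test_localization_precision_about_30nm(self, config):
        """Single-fluorophore spot at study SNR localizes to ~30 nm SD."""
        tr = _immobile(config, 2.45, 2.45, 100)
        stack = render_stack([tr], config, seed=22)
        spots = [s for fr in ft.detect_stack(stack) for s in fr]
        assert len(spots) > 60
        sd = np.hypot(np.std([s.x_um for s in spots]),
                      np.std([s.y_um for s in spots])) / np.sqrt(2)
        assert 0.015 < sd < 0.045

    def test_pixel_center_spot_unbiased(self, config):
        """Noise-free spot on a pixel centre: centroid bias < 5 nm."""
        cfg = ft.SimConfig(field_w_px=48, field_h_px=48,
                           background_photons_per_px=0.0)
        tr = _immobile(cfg, 2.45, 2.45, 1)  # centre of pixel (24, 24)
        stack = render_stack([tr], cfg, seed=0, noise=False)
        spots = ft.detect_spots(stack.data[0], cfg, 4.0)
        assert len(spots) == 1
        assert abs(spots[0].x_um - 2.45) * 1000 < 5
        assert abs(spots[0].y_um - 2.45) * 1000 < 5

    def test_localization_unbiased_off_center(self, config):
        """Mean localization offset < 10 nm for a sub-pixel-offset emitter."""
        tr = _immobile(config, 2.473, 2.408, 80)
        stack = render_stack([tr], config, seed=23)
        spots = [s for fr in ft.detect_stack(stack) for s in fr]
        dx = np.mean([s.x_um for s in spots]) - 2.473
        dy = np.mean([s.y_um for s in spots]) - 2.408
        assert np.hypot(dx, dy) * 1000 < 10

    def test_saturated_spot_excluded(self, config):
        frame = np.full((48, 48), config.camera_offset)
        frame[20:23, 20:23] = config.saturation_level
        assert ft.detect_spots(frame, config, 4.0) == []

    def test_duplicates_within_fwhm_merged(self, config):
        spots = [Spot(0, 1.00, 1.00, 500.0, 150.0),
                 Spot(0, 1.10, 1.00, 900.0, 150.0),
                 Spot(0, 2.50, 2.50, 400.0, 150.0)]
        from filotrack.tracking import _merge_duplicates
        kept = _merge_duplicates(spots, fwhm_um=0.35)
        assert len(kept) == 2
        assert max(s.intensity for s in kept) == 900.0


def _brute_force_linking(frame_a, frame_b, max_disp):
    """Oracle: minimum-total-distance assignment by exhaustive enumeration."""
    best, best_cost = [], np.inf
    na, nb = len(frame_a), len(frame_b)
    for k in range(min(na, nb), -1, -1):
        for ia in itertools.combinations(range(na), k):
            for ib in itertools.permutations(range(nb), k):
                pairs = list(zip(ia, ib))
                ds = [np.hypot(frame_a[i].x_um - frame_b[j].x_um,
                               frame_a[i].y_um - frame_b[j].y_um)
                      for i, j in pairs]
                if any(d > max_disp for d in ds):
                    continue
                cost = sum(ds)
                if len(pairs) > len(best) or (len(pairs) == len(best)
                                              and cost < best_cost):
                    best, best_cost = pairs, cost
        if best:
            break
    return set(best)


class TestLinkTracks:
    def test_single_spot_single_track(self):
        frames = [[Spot(k, 1.0, 1.0, 100.0, 150.0)] for k in range(10)]
        tracks = link_tracks(frames, 0.5)
        assert len(tracks) == 1 and tracks[0].n_spots == 10

    def test_well_separated_spots_no_switches(self):
        """Two spots 3 gating radii apart stay two clean tracks."""
        frames = [[Spot(k, 1.0, 1.0, 100.0, 150.0),
                   Spot(k, 2.5, 1.0, 100.0, 150.0)] for k in range(10)]
        tracks = link_tracks(frames, 0.5)
        assert len(tracks) == 2
        for tr in tracks:
            assert len({round(s.x_um, 6) for s in tr.spots}) == 1

    def test_matches_brute_force_assignment(self):
        """Greedy mutual-NN agrees with the exhaustive min-cost oracle on
        unambiguous configurations of up to 4 spots per frame."""
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = rng.integers(1, 5)
            a = [Spot(0, *rng.uniform(1, 9, 2), 100.0, 150.0) for _ in range(n)]
            # well-separated spots, small displacements
            a = [s for i, s in enumerate(a)
                 if all(np.hypot(s.x_um - t.x_um, s.y_um - t.y_um) > 1.5
                        for t in a[:i])]
            b = [Spot(1, s.x_um + rng.normal(0, 0.1),
                      s.y_um + rng.normal(0, 0.1), 100.0, 150.0) for s in a]
            tracks = link_tracks([a, b], 0.5)
            got = {(a.index(t.spots[0]), b.index(t.spots[1]))
                   for t in tracks if t.n_spots == 2}
            assert got == _brute_force_linking(a, b, 0.5)

    def test_link_recovery_on_rendered_diffusion(self, config):
        """D=0.2 um^2/s at 20 frames/s: RMS step 0.2 um << 0.5 um gate, so
        essentially all detected adjacent-frame pairs are linked correctly."""
        rng = np.random.default_rng(31)
        trajs = []
        origins = [(1.2, 1.2), (3.6, 1.2), (1.2, 3.6), (3.6, 3.6)]
        for i, orig in enumerate(origins):
            p = ft.brownian_track_2d(0.2, 40, config.frame_interval_s, rng,
                                     origin=orig)
            xyz = np.column_stack([p, np.zeros(40)])
            trajs.append(GroundTruthTrajectory(
                i, np.arange(40) * config.frame_interval_s, xyz,
                np.full(40, MEM2D, dtype=object)))
        stack = render_stack(trajs, config, seed=32)
        spots_by_frame = ft.detect_stack(stack)
        tracks = link_tracks(spots_by_frame, 0.5)
        truth = {i: tr.xyz[:, :2] for i, tr in enumerate(trajs)}
        good = bad = 0
        for tr in tracks:
            for s0, s1 in zip(tr.spots, tr.spots[1:]):
                if s1.frame_index != s0.frame_index + 1:
                    continue
                m0 = _closest_truth(truth, s0)
                m1 = _closest_truth(truth, s1)
                if m0 == m1:
                    good += 1
                else:
                    bad += 1
        assert good > 50
        assert good / (good + bad) > 0.99

    def test_partition_invariant_random_frames(self):
        rng = np.random.default_rng(8)
        frames = [[Spot(k, *rng.uniform(0, 5, 2), 100.0, 150.0)
                   for _ in range(rng.integers(0, 6))] for k in range(15)]
        tracks = link_tracks(frames, 0.6)
        assert_spot_partition(tracks)  # raises on violation
        assert sum(t.n_spots for t in tracks) == sum(len(f) for f in frames)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_track_count_monotone_in_gate(self, seed):
        """Widening the gating radius never increases the track count."""
        rng = np.random.default_rng(seed)
        frames = [[Spot(k, *rng.uniform(0, 4, 2), 100.0, 150.0)
                   for _ in range(rng.integers(0, 4))] for k in range(8)]
        counts = [len(link_tracks(frames, r)) for r in (0.2, 0.5, 1.0, 3.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def _closest_truth(truth, spot):
    best, best_d = None, np.inf
    for mid, pos in truth.items():
        d = np.hypot(pos[spot.frame_index, 0] - spot.x_um,
                     pos[spot.frame_index, 1] - spot.y_um)
        if d < best_d:
            best, best_d = mid, d
    return best


class TestIntensityTrace:
    def test_constant_emitter_flat_no_step(self, config):
        cfg = ft.SimConfig(field_w_px=48, field_h_px=48,
                           background_photons_per_px=0.0)
        tr = _immobile(cfg, 2.4, 2.4, 20)
        stack = render_stack([tr], cfg, seed=0, noise=False)
        spots = ft.detect_stack(stack)
        track = link_tracks(spots, 0.5)[0]
        trace = extract_intensity_trace(track, stack)
        assert trace.terminal_step_frame is None
        assert np.allclose(trace.intensity, trace.intensity[0], rtol=1e-6)

    def test_bleach_step_detected_at_truth_frame(self, config):
        """Simulated single-step bleach is located within +/-1 frame in >=95%
        of traces."""
        cfg = ft.SimConfig(field_w_px=48, field_h_px=48,
                           photons_per_frame_at_z0=500.0)
        hits = total = 0
        for rep in range(40):
            tr = _immobile(cfg, 2.45, 2.45, 30)
            k_bleach = 18
            tr.state[k_bleach:] = "BLEACHED"
            stack = render_stack([tr], cfg, seed=100 + rep)
            tracks = link_tracks(ft.detect_stack(stack), 0.5)
            if not tracks:
                continue
            track = max(tracks, key=lambda t: t.n_spots)
            trace = extract_intensity_trace(track, stack)
            if trace.terminal_step_frame is None:
                continue
            total += 1
            if abs(trace.terminal_step_frame - k_bleach) <= 1:
                hits += 1
        assert total >= 30
        assert hits / total >= 0.95

    def test_multimer_intensity_scales_with_copies(self, config):
        """n co-localized fluorophores give ~n-fold integrated intensity, the
        signature separating single-fluorophore spots from aggregates."""
        cfg = ft.SimConfig(field_w_px=48, field_h_px=48)
        mono = render_stack([_immobile(cfg, 2.45, 2.45, 15)], cfg, seed=1)
        tet = render_stack([_immobile(cfg, 2.45, 2.45, 15, mol_id=i)
                            for i in range(4)], cfg, seed=2)
        i_mono = np.median([s.intensity for fr in ft.detect_stack(mono) for s in fr])
        i_tet = np.median([s.intensity for fr in ft.detect_stack(tet) for s in fr])
        assert i_tet / i_mono == pytest.approx(4.0, rel=0.2)
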