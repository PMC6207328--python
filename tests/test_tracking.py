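"""Detection, linking, survival filtering, velocity and kymographs against
ground truth and independently written brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from rodmotion.geometry import Spherocylinder
from rodmotion.synthetic import (CellSpec, EmitterSpec, ImagingConfig,
                                 apply_noise, render_frame, simulate_movie)
from rodmotion.tracking import (SpotDetection, Track, TrackFilterConfig,
                                assign_to_cell, build_kymograph, detect_movie,
                                detect_spots, filter_tracks, kymograph_slope,
                                link_tracks, track_velocity, tracks_per_area)


def det(frame, x, y):
    return SpotDetection(frame=frame, x_nm=x, y_nm=y, amplitude=1.0,
                         sigma_nm=80.0)


def make_track(n_frames, displacement):
    """A straight track with the requested frame count and net
    displacement."""
    xs = np.linspace(0.0, displacement, n_frames)
    return Track(frames=np.arange(n_frames),
                 xy_nm=np.column_stack([xs, np.zeros(n_frames)]))


def brute_force_link(frame_detections, gate):
    """Oracle: an independent O(n^2) mutual-nearest-neighbour linker built
    on dictionaries, no shared code with the implementation."""
    tracks = []
    active = {}  # detection index in previous frame -> track list
    prev = []
    for dets in frame_detections:
        pairs = {}
        if prev and dets:
            best_fwd, best_bwd = {}, {}
            for i, a in enumerate(prev):
                dists = {j: math.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm)
                         for j, b in enumerate(dets)}
                best_fwd[i] = min(dists, key=dists.get)
            for j, b in enumerate(dets):
                dists = {i: math.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm)
                         for i, a in enumerate(prev)}
                best_bwd[j] = min(dists, key=dists.get)
            for i, j in best_fwd.items():
                d = math.hypot(prev[i].x_nm - dets[j].x_nm,
                               prev[i].y_nm - dets[j].y_nm)
                if best_bwd[j] == i and d <= gate:
                    pairs[j] = i
        new_active = {}
        for j, b in enumerate(dets):
            if j in pairs:
                tr = active[pairs[j]]
            else:
                tr = []
                tracks.append(tr)
            tr.append(b)
            new_active[j] = tr
        active, prev = new_active, list(dets)
    return tracks


class TestDetection:
    def test_blank_frames_rare_false_positives(self, rng):
        cfg = ImagingConfig(seed=0)
        n_fp = 0
        for _ in range(100):
            frame = apply_noise(np.full((96, 96), cfg.background_level),
                                cfg, rng)
            n_fp += len(detect_spots(frame, cfg.pixel_size, snr_min=5.0))
        assert n_fp / 100 < 0.1

    def test_single_focus_subpixel_accuracy(self, rng):
        cfg = ImagingConfig()
        cell = CellSpec(center=(2000.0, 2000.0), orientation=0.2,
                        length=3000.0, width=1000.0)
        cell.emitters.append(EmitterSpec("focus", 250.0, 0.0))
        truth_xy = None
        errs = []
        for _ in range(20):
            frame = render_frame([cell], 0.0, cfg, "tirf", (62, 62))
            noisy = apply_noise(frame, cfg, rng)
            spots = detect_spots(noisy, cfg.pixel_size, snr_min=5.0)
            assert len(spots) == 1
            from rodmotion.synthetic import membrane_position
            x, y, _ = membrane_position(cell, 250.0, 0.0)
            errs.append(math.hypot(spots[0].x_nm - x, spots[0].y_nm - y))
        assert np.mean(errs) < 0.25 * cfg.pixel_size

    def test_two_well_separated_foci(self, rng):
        cfg = ImagingConfig()
        cell = CellSpec(center=(3000.0, 3000.0), orientation=0.0,
                        length=5000.0, width=1000.0)
        cell.emitters.append(EmitterSpec("focus", -1200.0, 0.0))
        cell.emitters.append(EmitterSpec("focus", 1200.0, 0.0))  # 30 psf sd
        frame = apply_noise(render_frame([cell], 0.0, cfg, "tirf", (92, 92)),
                            cfg, rng)
        assert len(detect_spots(frame, cfg.pixel_size, snr_min=5.0)) == 2


class TestLinking:
    def test_single_detection_chain(self):
        dets = [[det(f, 1000.0 + 20 * f, 1000.0)] for f in range(10)]
        tracks = link_tracks(dets, TrackFilterConfig())
        assert len(tracks) == 1 and tracks[0].n_frames == 10

    def test_gate_splits_tracks(self):
        dets = [[det(0, 1000.0, 1000.0)], [det(1, 1400.0, 1000.0)]]
        tracks = link_tracks(dets, TrackFilterConfig(max_link_distance=250.0))
        assert len(tracks) == 2

    def test_every_detection_in_exactly_one_track(self, small_movie):
        _, _, movie, _ = small_movie
        dets = detect_movie(movie)
        tracks = link_tracks(dets, TrackFilterConfig())
        assert sum(t.n_frames for t in tracks) == sum(len(d) for d in dets)

    def test_parallel_emitters_no_identity_swaps(self):
        # two emitters 1000 nm apart moving in parallel at 25 nm/frame
        dets = []
        for f in range(20):
            dets.append([det(f, 1000.0 + 25 * f, 1000.0),
                         det(f, 1000.0 + 25 * f, 2000.0)])
        tracks = link_tracks(dets, TrackFilterConfig())
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.xy_nm[:, 1]) < 1e-9  # y constant: no swap

    def test_matches_brute_force_oracle(self, small_movie):
        _, _, movie, _ = small_movie
        cfg = TrackFilterConfig()
        dets = detect_movie(movie)
        mine = link_tracks(dets, cfg)
        oracle = brute_force_link(dets, cfg.max_link_distance)
        mine_sets = sorted(
            tuple((d[0], round(d[1], 3)) for d in
                  zip(tr.frames, tr.xy_nm[:, 0])) for tr in mine)
        oracle_sets = sorted(
            tuple((d.frame, round(d.x_nm, 3)) for d in tr) for tr in oracle)
        assert mine_sets == oracle_sets

    def test_survivor_count_matches_oracle_pipeline(self, small_movie):
        """Linking + survival filtering agrees with the independent
        brute-force chain."""
        _, _, movie, _ = small_movie
        cfg = TrackFilterConfig()
        dets = detect_movie(movie)
        survivors, _ = filter_tracks(link_tracks(dets, cfg), cfg)
        n_oracle = 0
        for tr in brute_force_link(dets, cfg.max_link_distance):
            disp = math.hypot(tr[-1].x_nm - tr[0].x_nm,
                              tr[-1].y_nm - tr[0].y_nm)
            if len(tr) >= cfg.min_frames and disp >= cfg.min_displacement:
                n_oracle += 1
        assert n_oracle > 0
        assert abs(len(survivors) - n_oracle) <= 0.05 * n_oracle


class TestFilter:
    @pytest.fixture()
    def fixture_tracks(self):
        """20 tracks spanning all four (frames >=/< 5) x (displacement
        >=/< 70 nm) cells."""
        combos = [(nf, disp)
                  for nf in (2, 3, 4, 5, 8)
                  for disp in (0.0, 30.0, 69.9, 70.0)]
        return [make_track(nf, disp) for nf, disp in combos]

    def test_survivors_match_brute_force_predicates(self, fixture_tracks):
        cfg = TrackFilterConfig()
        survivors, report = filter_tracks(fixture_tracks, cfg)
        expected = [t for t in fixture_tracks
                    if t.n_frames >= 5 and t.net_displacement_nm >= 70.0]
        assert len(survivors) == len(expected) == report["kept"]
        assert all(s is e for s, e in zip(survivors, expected))
        assert sum(report.values()) - report["kept"] == 20 - len(expected)

    def test_short_but_mobile_discarded(self):
        tr = make_track(4, 200.0)
        survivors, report = filter_tracks([tr], TrackFilterConfig())
        assert survivors == [] and report["too_short"] == 1

    def test_long_but_static_discarded(self):
        tr = make_track(10, 50.0)
        survivors, report = filter_tracks([tr], TrackFilterConfig())
        assert survivors == [] and report["too_static"] == 1

    def test_idempotent(self, fixture_tracks):
        cfg = TrackFilterConfig()
        once, _ = filter_tracks(fixture_tracks, cfg)
        twice, _ = filter_tracks(once, cfg)
        assert twice == once

    def test_literal_both_fail_rule(self, fixture_tracks):
        cfg = TrackFilterConfig()
        survivors, _ = filter_tracks(fixture_tracks, cfg,
                                     rule="discard_both_fail")
        expected = [t for t in fixture_tracks
                    if t.n_frames >= 5 or t.net_displacement_nm >= 70.0]
        assert len(survivors) == len(expected)


class TestVelocity:
    def test_stationary_track(self):
        tr = Track(frames=np.arange(6), xy_nm=np.full((6, 2), 500.0))
        assert track_velocity(tr, 1.0) == pytest.approx(0.0)

    def test_constant_speed_line(self):
        tr = make_track(10, 9 * 20.0)  # 20 nm per 1-s frame
        assert track_velocity(tr, 1.0) == pytest.approx(20.0)

    def test_mean_step_estimator(self):
        tr = make_track(10, 9 * 20.0)
        assert track_velocity(tr, 1.0, method="mean_step") == \
            pytest.approx(20.0)

    def test_arc_estimator_removes_projection_compression(self):
        # circumferential motion: lateral position r*sin(v t / r)
        r, v = 500.0, 25.0
        t = np.arange(20.0)
        theta = -0.9 + v * t / r
        xy = np.column_stack([np.full(20, 3000.0), 3000.0 + r * np.sin(theta)])
        tr = Track(frames=np.arange(20), xy_nm=xy)
        fit = track_velocity(tr, 1.0)
        arc = track_velocity(tr, 1.0, method="arc",
                             cell_axis_point=np.array([3000.0, 3000.0]),
                             cell_axis_dir=np.array([1.0, 0.0]),
                             cell_width=2 * r)
        assert fit < v  # straight-line fit sees only the chord
        assert arc == pytest.approx(v, rel=0.02)

    def test_single_point_rejected(self):
        tr = Track(frames=np.array([0]), xy_nm=np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            track_velocity(tr, 1.0)

    def test_population_recovery_within_ten_percent(self, small_movie):
        cells, cfg, movie, truth = small_movie
        filt = TrackFilterConfig()
        survivors, _ = filter_tracks(
            link_tracks(detect_movie(movie), filt), filt)
        vels = []
        for tr in survivors:
            c = cells[assign_to_cell(tr, cells)]
            u = np.array([math.cos(c.orientation), math.sin(c.orientation)])
            vels.append(track_velocity(
                tr, cfg.frame_interval, method="arc",
                cell_axis_point=np.asarray(c.center), cell_axis_dir=u,
                cell_width=c.width))
        true_mean = truth.drop_duplicates("emitter_id").speed_nm_s.mean()
        assert len(vels) >= 30
        assert abs(np.mean(vels) - true_mean) / true_mean < 0.10


class TestDensity:
    def test_simple_division(self):
        tracks = [make_track(6, 100.0)] * 6
        assert tracks_per_area(tracks, 2.0) == 3.0

    def test_zero_tracks(self):
        assert tracks_per_area([], Spherocylinder(3.0, 1.0)) == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            tracks_per_area([], 0.0)


class TestKymograph:
    @pytest.fixture(scope="class")
    def moving_spot_movie(self):
        cfg = ImagingConfig(seed=21, n_frames=40)
        cell = CellSpec(center=(4000.0, 4000.0), orientation=0.4,
                        length=3570.0, width=1000.0)
        cell.emitters.append(EmitterSpec("focus", 0.0, -0.5, speed_nm_s=25.0))
        movie, truth = simulate_movie([cell], cfg, shape=(124, 124))
        filt = TrackFilterConfig()
        tracks, _ = filter_tracks(
            link_tracks(detect_movie(movie), filt), filt)
        return movie, max(tracks, key=lambda t: t.n_frames)

    def test_moving_spot_slope_near_truth(self, moving_spot_movie):
        movie, track = moving_spot_movie
        kymo = build_kymograph(movie, track)
        assert kymograph_slope(kymo) == pytest.approx(25.0, rel=0.10)

    def test_agrees_with_track_velocity(self, moving_spot_movie):
        movie, track = moving_spot_movie
        kymo = build_kymograph(movie, track)
        v_fit = track_velocity(track, movie.config.frame_interval)
        assert kymograph_slope(kymo) == pytest.approx(v_fit, rel=0.15)

    def test_static_spot_vertical_ridge(self):
        cfg = ImagingConfig(seed=3, n_frames=30)
        cell = CellSpec(center=(2000.0, 2000.0), orientation=0.0,
                        length=3570.0, width=1000.0)
        cell.emitters.append(EmitterSpec("focus", 0.0, 0.3, speed_nm_s=0.0))
        movie, _ = simulate_movie([cell], cfg, shape=(62, 62))
        tracks = link_tracks(detect_movie(movie), TrackFilterConfig())
        tr = max(tracks, key=lambda t: t.n_frames)
        slope = kymograph_slope(build_kymograph(movie, tr))
        assert slope < 2.0  # nm/s, localisation noise floor

    def test_blank_movie_rejected(self):
        cfg = ImagingConfig(seed=1, n_frames=10)
        frames = np.random.default_rng(0).poisson(100.0, (10, 40, 40)) * 1.0
        from rodmotion.synthetic import MovieStack
        movie = MovieStack(frames=frames, mode="tirf", channel="green",
                           config=cfg)
        tr = make_track(10, 300.0)
        tr.xy_nm += 1200.0
        with pytest.raises(ValueError):
            kymograph_slope(build_kymograph(movie, tr))
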