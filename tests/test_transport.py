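"""Transport analytics: segmentation, summaries, spatial stats, ROI, tilt, exact test."""

import math

import numpy as np
import pytest
from scipy import stats

from idrkit.synthetic import gen_roi_image, gen_tracks
from idrkit.transport import (
    Direction,
    Track,
    axon_spatial_stats,
    fisher_exact_2x2,
    roi_integrated_intensity,
    rose_bins,
    segment_track,
    spindle_tilt_angle,
    summarize_transport,
)


def make_track(displacements, dt=0.2, tid=0, start=0.0):
    return Track(tid, dt, start + np.concatenate([[0.0], np.cumsum(displacements)]))


class TestSegmentTrack:
    def test_monotone_run_is_one_anterograde_segment(self):
        track = make_track([0.2] * 20)
        (seg,) = segment_track(track)
        assert seg.direction is Direction.ANTEROGRADE
        assert seg.velocity == pytest.approx(1.0)
        assert seg.run_length == pytest.approx(4.0)

    def test_constant_position_is_one_pause(self):
        (seg,) = segment_track(make_track([0.0] * 20))
        assert seg.direction is Direction.PAUSE
        assert seg.duration == pytest.approx(4.0)

    def test_reversal_boundary_within_smoothing_half_width(self):
        track = make_track([0.2] * 10 + [-0.2] * 10)
        segs = segment_track(track)
        assert [s.direction for s in segs] == [Direction.ANTEROGRADE, Direction.RETROGRADE]
        assert abs(segs[0].end_frame - 10) <= 1  # (smooth_window-1)/2
        assert segs[0].velocity == pytest.approx(1.0)
        assert segs[1].velocity == pytest.approx(-1.0)

    def test_run_pause_run_with_long_pause(self):
        track = make_track([0.2] * 15 + [0.0] * 10 + [0.2] * 15)
        segs = segment_track(track)
        assert [s.direction for s in segs] == [
            Direction.ANTEROGRADE, Direction.PAUSE, Direction.ANTEROGRADE]
        assert segs[1].duration == pytest.approx(2.0)

    def test_short_pause_absorbed(self):
        track = make_track([0.2] * 15 + [0.0] + [0.2] * 15)
        (seg,) = segment_track(track, min_pause_frames=2)
        assert seg.direction is Direction.ANTEROGRADE

    def test_offset_invariance_and_reflection(self):
        disp = [0.2] * 10 + [0.0] * 8 + [-0.3] * 10
        a = segment_track(make_track(disp, start=0.0))
        b = segment_track(make_track(disp, start=57.3))
        assert [(s.direction, s.start_frame, s.end_frame) for s in a] == \
               [(s.direction, s.start_frame, s.end_frame) for s in b]
        flipped = segment_track(make_track([-d for d in disp]))
        swap = {Direction.ANTEROGRADE: Direction.RETROGRADE,
                Direction.RETROGRADE: Direction.ANTEROGRADE,
                Direction.PAUSE: Direction.PAUSE}
        assert [swap[s.direction] for s in flipped] == [s.direction for s in a]

    def test_oracle_exhaustive_per_frame_states(self):
        """Noiseless piecewise-constant tracks: recovered segments equal the
        exact per-interval state runs (the independent frame-wise oracle)."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            states = rng.choice([1.0, -1.2, 0.0], size=60, p=[0.4, 0.3, 0.3])
            # enforce dwells >= 3 by repeating each draw 3x
            states = np.repeat(states[:20], 3)
            track = make_track(states * 0.2)
            segs = segment_track(track, min_pause_frames=1)
            # oracle: run-length encode the true interval states
            runs, cur = [], [0, states[0]]
            for i, s in enumerate(states[1:], start=1):
                if s != cur[1]:
                    runs.append((cur[0], i, cur[1]))
                    cur = [i, s]
            runs.append((cur[0], len(states), cur[1]))
            assert len(segs) == len(runs)
            for seg, (a, b, v) in zip(segs, runs):
                assert (seg.start_frame, seg.end_frame) == (a, b)
                assert seg.velocity == pytest.approx(v, abs=1e-12)


class TestSummarize:
    def test_all_constant_tracks_are_stationary(self):
        tracks = [make_track([0.0] * 10, tid=i) for i in range(5)]
        s = summarize_transport(tracks)
        assert s.direction_fractions[Direction.STATIONARY] == 1.0

    def test_net_displacement_sign_convention(self):
        toward_body = make_track([-0.3] * 20, start=10.0)  # 10 um -> 4 um
        s = summarize_transport([toward_body])
        assert s.direction_fractions[Direction.RETROGRADE] == 1.0

    def test_fractions_sum_to_one(self):
        tracks, _ = gen_tracks(n_tracks=50, duration=20.0, seed=12)
        s = summarize_transport(tracks)
        assert sum(s.direction_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(s.time_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_retrograde_bias_recovered_within_binomial_ci(self):
        p_retro = 0.6
        transitions = ((0.9, 0.0, 0.1), (0.0, 0.9, 0.1),
                       (0.2 * (1 - p_retro), 0.2 * p_retro, 0.8))
        tracks, truth = gen_tracks(n_tracks=100, duration=40.0,
                                   transitions=transitions, seed=31)
        # truth: net-displacement direction of each generated track
        net = np.array([t.positions[-1] - t.positions[0] for t in tracks])
        true_frac = np.mean(net < -0.3)
        s = summarize_transport(tracks)
        rec = s.direction_fractions[Direction.RETROGRADE]
        lo, hi = stats.binom.interval(0.99, 100, true_frac)
        assert lo / 100 <= rec <= hi / 100


class TestSpatial:
    def test_density_and_relative_positions(self):
        amap = axon_spatial_stats(np.linspace(0.0, 300.0, 30), 300.0)
        assert amap.density_per_100um == pytest.approx(10.0)
        assert amap.relative_positions[-1] == pytest.approx(100.0)
        assert amap.relative_positions[0] == 0.0

    def test_position_beyond_tip_rejected(self):
        with pytest.raises(ValueError):
            axon_spatial_stats(np.array([301.0]), 300.0)

    def test_uniform_positions_fill_bins_within_multinomial_ci(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0.0, 500.0, size=1000)
        amap = axon_spatial_stats(pos, 500.0, n_bins=10)
        lo, hi = stats.binom.interval(0.999, 1000, 0.1)
        assert all(lo <= c <= hi for c in amap.bin_counts)


class TestRoi:
    def test_uniform_image_gives_zero(self):
        img = np.full((40, 40), 7.3)
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        assert roi_integrated_intensity(img, mask).integrated_signal == pytest.approx(0.0, abs=1e-9)

    def test_embedded_punctum_recovered(self):
        img, masks, _ = gen_roi_image(shape=(81, 81), background_level=2.0,
                                      puncta=[(40.0, 40.0, 500.0, 1.5)])
        big = np.zeros_like(masks[0])
        big[25:56, 25:56] = True  # punctum is >=10 sigma inside this mask
        q = roi_integrated_intensity(img, big)
        assert q.integrated_signal == pytest.approx(500.0, rel=1e-6)

    def test_empty_mask_and_clipped_dilation_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError):
            roi_integrated_intensity(img, np.zeros((10, 10), bool))
        full = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            roi_integrated_intensity(img, full)

    def test_pure_noise_expectation_zero(self):
        finals = []
        for seed in range(30):
            img, _, _ = gen_roi_image(shape=(48, 48), background_level=5.0,
                                      noise_sd=1.0, seed=seed)
            mask = np.zeros((48, 48), bool)
            mask[20:28, 20:28] = True
            finals.append(roi_integrated_intensity(img, mask).integrated_signal)
        finals = np.array(finals)
        sem = finals.std(ddof=1) / math.sqrt(finals.size)
        assert abs(finals.mean()) < 3 * sem + 1e-9


class TestTilt:
    @pytest.mark.parametrize(
        "c2, expected",
        [((1.0, 0.0), 0.0), ((1.0, 1.0), 45.0), ((1.0, 3.0), 71.57), ((-2.0, 0.0), 0.0)],
    )
    def test_axis_angles(self, c2, expected):
        a = spindle_tilt_angle((0, 0), c2, (0, 0), (1, 0))
        assert a == pytest.approx(expected, abs=0.01)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            spindle_tilt_angle((1, 1), (1, 1), (0, 0), (1, 0))

    def test_rose_binning(self):
        counts, edges = rose_bins([5.0, 10.0, 50.0, 89.0], bin_width=15.0)
        assert counts.sum() == 4 and counts[0] == 2
        assert edges[-1] == 90.0


class TestFisherExact:
    def test_published_tilt_table(self):
        p = fisher_exact_2x2(((7, 14), (0, 13)))
        assert round(p, 3) == 0.029
        assert p == pytest.approx(0.0286, abs=5e-4)

    def test_degenerate_column(self):
        assert fisher_exact_2x2(((0, 5), (0, 8))) == 1.0

    def test_hand_enumerated_table(self):
        assert fisher_exact_2x2(((3, 1), (1, 3))) == pytest.approx(34 / 70, rel=1e-12)

    def test_one_sided_tail(self):
        p_one = fisher_exact_2x2(((7, 14), (0, 13)), sided="one")
        p_scipy = stats.fisher_exact([[7, 14], [0, 13]], alternative="greater")[1]
        assert p_one == pytest.approx(p_scipy, rel=1e-9)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = fisher_exact_2x2(((a, b), (c, d)))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(((1, -2), (3, 4)))
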