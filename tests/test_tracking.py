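"""Peak detection, linking and intensity-fraction sizing."""

import numpy as np
import pytest

from parbkymo import (Kymograph, PeakObservation, SimConfig, detect_peaks,
                      detect_peaks_kymo, link_tracks, measure_fraction,
                      measure_fractions, render_kymograph, simulate_tracks,
                      summarize_tracks, Track)

MAX_DIST = 7.0
MAX_GAP = 5


# ---------------------------------------------------------------- oracles

def closure_partition(peaks_by_frame, max_dist=MAX_DIST, max_gap=MAX_GAP):
    """Transitive closure of the pairwise compatibility relation
    (|dx| <= max_dist and 0 < dframe <= max_gap), via union-find."""
    items = [(f, p.position_px) for f, peaks in enumerate(peaks_by_frame)
             for p in peaks]
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i, (fi, xi) in enumerate(items):
        for j, (fj, xj) in enumerate(items):
            if 0 < fj - fi <= max_gap and abs(xj - xi) <= max_dist:
                union(i, j)
    groups = {}
    for i, item in enumerate(items):
        groups.setdefault(find(i), set()).add(item)
    return {frozenset(g) for g in groups.values()}


def tracks_partition(tracks):
    return {frozenset((o.frame, o.position_px) for o in t.observations)
            for t in tracks}


def separated_instance(rng, n_frames=25, n_tracks_max=5):
    """Random peaks from well-separated wandering tracks (steps <= 4 px,
    gaps <= MAX_GAP, inter-track spacing > 2*MAX_DIST at all times), so the
    closure partition is exactly the ground-truth track partition."""
    n_tracks = int(rng.integers(1, n_tracks_max + 1))
    lanes = np.arange(n_tracks) * 40 + rng.integers(0, 10)
    peaks_by_frame = [[] for _ in range(n_frames)]
    for lane in lanes:
        pos = float(lane + rng.integers(0, 6))
        f = int(rng.integers(0, 4))
        while f < n_frames:
            peaks_by_frame[f].append(
                PeakObservation(frame=f, position_px=int(pos), peak_value=1.0))
            pos += float(rng.integers(-4, 5))
            pos = min(max(pos, lane - 8), lane + 8)
            f += int(rng.integers(1, MAX_GAP + 1))
    return peaks_by_frame


# ---------------------------------------------------------------- detection

class TestDetectPeaks:
    def test_flat_frame_has_no_peaks(self):
        assert detect_peaks(np.zeros(50)) == []
        assert detect_peaks(np.full(50, 3.0)) == []

    def test_single_gaussian_bump_peaks_at_argmax(self):
        x = np.arange(100.0)
        bump = 10 * np.exp(-0.5 * ((x - 40) / 3) ** 2)
        peaks = detect_peaks(bump)
        assert [p.position_px for p in peaks] == [int(np.argmax(bump))] == [40]

    def test_plateau_resolves_to_leftmost_pixel(self):
        x = np.zeros(30)
        x[10:14] = 5.0
        peaks = detect_peaks(x, prominence=1.0)
        assert [p.position_px for p in peaks] == [10]

    def test_two_bumps_reported_only_with_sufficient_prominence(self):
        x = np.arange(60.0)
        close = (8 * np.exp(-0.5 * ((x - 30) / 1.0) ** 2)
                 + 6 * np.exp(-0.5 * ((x - 33) / 1.0) ** 2))
        # shallow saddle: with a high prominence requirement only one peak
        strict = detect_peaks(close, prominence=3.0)
        loose = detect_peaks(close, prominence=0.5)
        assert len(strict) == 1
        assert len(loose) == 2
        # exhaustive scan oracle for the loose threshold
        argrelmax = [i for i in range(1, 59)
                     if close[i] > close[i - 1] and close[i] > close[i + 1]]
        assert [p.position_px for p in loose] == argrelmax


# ---------------------------------------------------------------- linking

class TestLinkTracks:
    def test_empty_input_empty_output(self):
        assert link_tracks([]) == []
        assert link_tracks([[], [], []]) == []

    def test_persistent_peak_yields_single_track(self):
        peaks = [[PeakObservation(f, 10, 1.0)] for f in range(40)]
        tracks = link_tracks(peaks)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 40

    def test_alternating_eight_pixel_jumps_yield_two_interleaved_tracks(self):
        # 8-px jumps exceed the 7-px radius frame-to-frame, but each parity
        # class reconnects through the 5-frame gap allowance
        peaks = []
        for f in range(20):
            pos = 10 if f % 2 == 0 else 18
            peaks.append([PeakObservation(f, pos, 1.0)])
        tracks = link_tracks(peaks)
        assert len(tracks) == 2
        assert tracks_partition(tracks) == closure_partition(peaks)

    def test_matches_transitive_closure_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            peaks = separated_instance(rng)
            assert tracks_partition(link_tracks(peaks)) == closure_partition(peaks)

    def test_nearer_candidate_wins_ties(self):
        peaks = [
            [PeakObservation(0, 10, 1.0), PeakObservation(0, 20, 1.0)],
            [PeakObservation(1, 13, 1.0)],
        ]
        tracks = link_tracks(peaks)
        by_first = {t.observations[0].position_px: t for t in tracks}
        assert by_first[10].n_frames == 2  # joined the nearer track
        assert by_first[20].n_frames == 1


# ---------------------------------------------------------------- sizing

def flat_kymo(n_frames=4, n_px=100, value=10.0):
    return Kymograph(np.full((n_frames, n_px), value), 0.1, 0.38, (0, n_px - 1))


class TestMeasureFraction:
    def test_uniform_intensity_five_pixel_window(self):
        kymo = flat_kymo()
        track = Track(id=0, observations=[PeakObservation(f, 50, 10.0)
                                          for f in range(4)])
        measure_fraction(kymo, track, 38.0, background=0.0, baseline_correct=False)
        for o in track.observations:
            assert o.fraction == pytest.approx(0.05)
            assert o.size_kb == pytest.approx(1.9)

    def test_all_intensity_inside_window_gives_fraction_one(self):
        arr = np.zeros((2, 50))
        arr[:, 24:27] = 7.0
        kymo = Kymograph(arr, 0.1, 0.38, (0, 49))
        track = Track(id=0, observations=[PeakObservation(0, 25, 7.0),
                                          PeakObservation(1, 25, 7.0)])
        measure_fraction(kymo, track, 38.0, background=0.0)
        assert track.observations[0].fraction == pytest.approx(1.0)

    def test_track_outside_span_rejected(self):
        kymo = Kymograph(np.ones((2, 50)), 0.1, 0.38, (5, 44))
        track = Track(id=0, observations=[PeakObservation(0, 2, 1.0)])
        with pytest.raises(ValueError):
            measure_fraction(kymo, track, 38.0, background=0.0)

    def test_overlapping_windows_do_not_double_count(self):
        arr = np.zeros((1, 60))
        arr[0, 28:34] = 10.0
        kymo = Kymograph(arr, 0.1, 0.38, (0, 59))
        tracks = [Track(id=0, observations=[PeakObservation(0, 29, 10.0)]),
                  Track(id=1, observations=[PeakObservation(0, 32, 10.0)])]
        measure_fractions(kymo, tracks, 38.0, background=0.0,
                          baseline_correct=False)
        total = tracks[0].observations[0].fraction + tracks[1].observations[0].fraction
        assert total <= 1.0 + 1e-12
        assert total == pytest.approx(1.0)

    def test_disjoint_window_fractions_sum_below_one(self, rng):
        arr = rng.poisson(50, size=(3, 120)).astype(float)
        kymo = Kymograph(arr, 0.1, 0.38, (0, 119))
        tracks = [Track(id=i, observations=[PeakObservation(f, 20 + 30 * i, 1.0)
                                            for f in range(3)])
                  for i in range(4)]
        measure_fractions(kymo, tracks, 38.0, background=0.0,
                          baseline_correct=False)
        for f in range(3):
            s = sum(t.observations[f].fraction for t in tracks)
            assert s <= 1.0 + 1e-12

    def test_simulated_plectoneme_size_recovered_within_15_percent(self):
        # one 6-kb plectoneme among 12 kb plectonemic DNA, noise-free render
        from parbkymo.synthetic import GroundTruthTrack
        cfg = SimConfig(shot_noise=False, read_noise_sd=0.0, n_frames=20,
                        parb_load_rate_per_s=0.0)
        gt = [GroundTruthTrack("plectoneme", 0, 20, np.full(20, 10.0), np.full(20, 6.0)),
              GroundTruthTrack("plectoneme", 0, 20, np.full(20, 28.0), np.full(20, 6.0))]
        rng = np.random.default_rng(0)
        dna, _ = render_kymograph(gt, cfg, rng)
        peaks = detect_peaks_kymo(dna)
        tracks = link_tracks(peaks)
        measure_fractions(dna, tracks, cfg.dna_length_kb)
        sized = sorted((t for t in tracks if t.n_frames == 20),
                       key=lambda t: t.observations[0].position_px)
        assert len(sized) == 2
        for t in sized:
            mean_size = np.mean([o.size_kb for o in t.observations])
            assert mean_size == pytest.approx(6.0, rel=0.15)


class TestSummaries:
    def test_single_persistent_track_counts(self):
        obs = [PeakObservation(f, 30, 5.0, fraction=12 / 38, size_kb=12.0)
               for f in range(10)]
        per_frame, per_track = summarize_tracks([Track(id=0, observations=obs)], 10)
        assert (per_frame.n_features == 1).all()
        np.testing.assert_allclose(per_frame.total_kb, 12.0)
        assert per_track.mean_size_kb.iloc[0] == pytest.approx(12.0)

    def test_totals_are_additive_over_disjoint_tracks(self):
        t1 = Track(id=0, observations=[PeakObservation(0, 10, 1.0, 0.1, 3.8)])
        t2 = Track(id=1, observations=[PeakObservation(0, 50, 1.0, 0.2, 7.6)])
        per_frame, _ = summarize_tracks([t1, t2], 1)
        assert per_frame.total_kb.iloc[0] == pytest.approx(11.4)
        assert per_frame.n_features.iloc[0] == 2

    def test_simulator_default_total_recovered(self):
        cfg = SimConfig(shot_noise=False, read_noise_sd=0.0, n_frames=400,
                        parb_load_rate_per_s=0.0, rng_seed=3)
        rng = np.random.default_rng(3)
        gt = simulate_tracks(cfg, rng)
        dna, _ = render_kymograph(gt, cfg, rng)
        tracks = link_tracks(detect_peaks_kymo(dna))
        measure_fractions(dna, tracks, cfg.dna_length_kb)
        per_frame, _ = summarize_tracks(tracks, cfg.n_frames)
        assert per_frame.total_kb.mean() == pytest.approx(
            cfg.plectonemic_dna_kb, rel=0.05)


class TestDetectionFidelity:
    def test_noise_free_recall_and_precision_above_95_percent(self):
        cfg = SimConfig(shot_noise=False, read_noise_sd=0.0, n_frames=300,
                        parb_load_rate_per_s=0.0, rng_seed=8)
        rng = np.random.default_rng(8)
        gt = simulate_tracks(cfg, rng)
        dna, _ = render_kymograph(gt, cfg, rng)
        peaks = detect_peaks_kymo(dna)
        detected = {(f, p.position_px) for f, obs in enumerate(peaks) for p in obs}
        margin = cfg.margin_px
        hits = misses = 0
        truth_px = {}
        for t in gt:
            for k, f in enumerate(range(t.birth_frame, t.death_frame)):
                truth_px.setdefault(f, []).append(
                    t.positions_kb[k] / cfg.kb_per_pixel + margin)
        for f, positions in truth_px.items():
            det = [p for (ff, p) in detected if ff == f]
            for x in positions:
                if det and min(abs(np.array(det) - x)) <= 3:
                    hits += 1
                else:
                    # a merged pair appears as one peak; count as hit if a
                    # *sibling* true plectoneme is within the merge radius
                    near_sibling = any(abs(y - x) <= 5 for y in positions if y is not x)
                    if near_sibling:
                        hits += 1
                    else:
                        misses += 1
        recall = hits / (hits + misses)
        false = 0
        for (f, p) in detected:
            if not any(abs(np.array(truth_px.get(f, [np.inf])) - p) <= 3):
                false += 1
        precision = 1 - false / len(detected)
        assert recall >= 0.95
        assert precision >= 0.95
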