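"""Synchrosqueezing, ridge tracking and beat segmentation."""

import numpy as np
import pytest
from scipy.signal import chirp

from eitbp.core import DataError, EitFrameSeries, N_CHANNELS
from eitbp.beatseg import (
    BeatInterval,
    BeatRejected,
    HeartRateRidge,
    detect_beats,
    exclude_premature,
    extract_segment,
    fsst,
    global_signal,
    match_beats,
    segment_beats,
    track_ridge,
)

FS = 47.68


def tone(freq: float, duration: float = 120.0, fs: float = FS) -> np.ndarray:
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def frames_from_signal(sig: np.ndarray, n_active: int = N_CHANNELS) -> EitFrameSeries:
    values = np.zeros((len(sig), N_CHANNELS))
    values[:, :n_active] = sig[:, None]
    return EitFrameSeries(values=values)


class TestGlobalSignal:
    def test_constant_channels_give_zero(self):
        eit = EitFrameSeries(values=np.full((200, N_CHANNELS), 3.7))
        assert np.allclose(global_signal(eit), 0.0, atol=1e-9)

    def test_common_sinusoid_amplitude_preserved(self):
        sig = tone(1.5, duration=30.0)
        out = global_signal(frames_from_signal(sig))
        # sliding-mean DC removal barely touches a 1.5 Hz tone (judge away
        # from the filter's edge region)
        assert np.max(out[500:-500]) == pytest.approx(1.0, abs=0.02)

    def test_sparse_channels_scale_amplitude(self):
        sig = tone(1.5, duration=30.0)
        out = global_signal(frames_from_signal(sig, n_active=64))
        assert np.max(out[500:-500]) == pytest.approx(64 / 1024, rel=0.05)

    def test_single_frame_rejected(self):
        with pytest.raises(DataError):
            global_signal(EitFrameSeries(values=np.zeros((1, N_CHANNELS))))


class TestFsst:
    def test_pure_tone_energy_concentrated_within_one_bin(self):
        sst = fsst(tone(1.5), FS)
        df = sst.freqs[1] - sst.freqs[0]
        k = int(round(1.5 / df))
        interior = slice(300, -300)
        cols = sst.magnitude[interior]
        conc = cols[:, k - 1 : k + 2].sum(axis=1) / cols.sum(axis=1)
        assert np.all(conc >= 0.90)

    def test_two_tones_give_two_ridges(self):
        sst = fsst(tone(0.3) + tone(1.5), FS)
        mean_spec = sst.magnitude[300:-300].mean(axis=0)
        # peak-finding oracle: local maxima above a fifth of the global max
        peaks = [
            i
            for i in range(1, len(mean_spec) - 1)
            if mean_spec[i] > mean_spec[i - 1]
            and mean_spec[i] >= mean_spec[i + 1]
            and mean_spec[i] > mean_spec.max() / 5
        ]
        freqs = sorted(sst.freqs[i] for i in peaks)
        assert len(freqs) == 2
        assert freqs[0] == pytest.approx(0.3, abs=0.1)
        assert freqs[1] == pytest.approx(1.5, abs=0.1)

    def test_chirp_ridge_tracks_instantaneous_frequency(self):
        duration = 120.0
        t = np.arange(int(duration * FS)) / FS
        sig = chirp(t, 1.0, t[-1], 2.0)
        sst = fsst(sig, FS)
        ridge = track_ridge(sst, band=(0.5, 3.0), max_jump_hz=0.05)
        f_true = 1.0 + (2.0 - 1.0) * ridge.times / t[-1]
        n = len(t)
        central = slice(int(0.1 * n), int(0.9 * n))
        assert np.max(np.abs(ridge.hr - f_true)[central]) < 0.05

    def test_energy_conserved_per_column(self):
        sst = fsst(tone(1.5) + 0.3 * tone(0.4), FS)
        reassigned = sst.magnitude.sum(axis=1)
        assert np.allclose(reassigned, sst.stft_column_energy, rtol=0.01)

    def test_zero_signal_flagged(self):
        sst = fsst(np.zeros(1000), FS)
        assert sst.zero_energy
        assert np.all(sst.magnitude == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(DataError):
            fsst(np.zeros(100), FS, window_len=256)


class TestTrackRidge:
    def test_stationary_tone_constant_ridge(self):
        sst = fsst(tone(1.5), FS)
        ridge = track_ridge(sst, band=(1.0, 4.0))
        df = sst.freqs[1] - sst.freqs[0]
        e = ridge.edge_cols
        assert np.all(np.abs(ridge.hr[e:-e] - 1.5) <= df)

    def test_step_tone_converges_within_slew(self):
        sig = np.concatenate([tone(1.5, 60.0), tone(1.8, 60.0)])
        sst = fsst(sig, FS)
        ridge = track_ridge(sst, band=(1.0, 4.0))
        late = ridge.hr[int(75 * FS) :]
        assert np.all(np.abs(late[: int(30 * FS)] - 1.8) < 0.2)

    def test_out_of_band_signal_flagged_unreliable(self):
        sst = fsst(tone(0.3), FS)
        ridge = track_ridge(sst, band=(1.0, 4.0))
        assert ridge.unreliable_fraction > 0.5

    def test_harmonic_robustness_ridge_stays_at_fundamental(self):
        rng = np.random.default_rng(1)
        sig = tone(1.4) + 0.8 * tone(2.8) + 0.05 * rng.normal(size=len(tone(1.4)))
        sst = fsst(sig, FS)
        ridge = track_ridge(sst, band=(1.0, 4.0))
        assert np.median(ridge.hr) == pytest.approx(1.4, abs=0.1)
        assert np.mean(np.abs(ridge.hr - 1.4) < 0.2) > 0.9

    def test_empty_band_rejected(self):
        sst = fsst(tone(1.5), FS)
        with pytest.raises(DataError):
            track_ridge(sst, band=(30.0, 40.0))


class TestSegmentBeats:
    def test_constant_90_bpm_closed_form(self):
        sst = fsst(tone(1.5), FS)
        ridge = track_ridge(sst)
        intervals = segment_beats(ridge, len(tone(1.5)), FS)
        lengths = np.array([iv.length for iv in intervals])
        assert set(np.unique(lengths)) <= {31, 32}
        assert lengths.mean() == pytest.approx(47.68 * 60 / 90, abs=0.2)

    def test_constant_86_bpm_average_33_frames(self):
        f = 86.0 / 60.0
        sig = tone(f)
        sst = fsst(sig, FS)
        ridge = track_ridge(sst)
        intervals = segment_beats(ridge, len(sig), FS)
        lengths = np.array([iv.length for iv in intervals])
        assert lengths.mean() == pytest.approx(33.0, abs=0.5)

    def test_zero_length_record_empty(self):
        ridge = HeartRateRidge(
            times=np.array([0.0, 1.0]),
            hr=np.array([1.5, 1.5]),
            quality=np.ones(2),
            reliable=np.ones(2, bool),
        )
        assert segment_beats(ridge, 0, FS) == []

    def test_mostly_unreliable_ridge_rejected(self):
        n = 1000
        ridge = HeartRateRidge(
            times=np.arange(n) / FS,
            hr=np.full(n, 1.5),
            quality=np.zeros(n),
            reliable=np.zeros(n, bool),
        )
        with pytest.raises(DataError, match="unreliable"):
            segment_beats(ridge, n, FS)

    def test_tiling_no_overlaps_no_gaps(self):
        sst = fsst(tone(1.5), FS)
        ridge = track_ridge(sst)
        intervals = segment_beats(ridge, len(tone(1.5)), FS)
        for a, b in zip(intervals[:-1], intervals[1:]):
            assert a.end == b.start


class TestExcludePremature:
    def test_uniform_lengths_nothing_excluded(self):
        ivs = [BeatInterval(i * 32, (i + 1) * 32) for i in range(20)]
        kept, log = exclude_premature(ivs)
        assert kept == ivs
        assert log == []

    def test_half_length_beat_drops_itself_and_flanks(self):
        bounds = [0]
        for ln in [32] * 8 + [16] + [32] * 8:
            bounds.append(bounds[-1] + ln)
        ivs = [BeatInterval(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        kept, log = exclude_premature(ivs)
        assert len(kept) == len(ivs) - 3
        removed = {e["beat_index"] for e in log}
        assert removed == {7, 8, 9}
        reasons = {e["beat_index"]: e["reason"] for e in log}
        assert reasons[8] == "premature"

    def test_gradual_jitter_nothing_excluded(self):
        rng = np.random.default_rng(0)
        lengths = np.round(32 * (1 + 0.05 * rng.uniform(-1, 1, 30))).astype(int)
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        ivs = [BeatInterval(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]
        kept, log = exclude_premature(ivs)
        assert kept == ivs

    def test_short_list_passes_through(self):
        ivs = [BeatInterval(0, 32), BeatInterval(32, 64)]
        kept, log = exclude_premature(ivs)
        assert kept == ivs and log == []


class TestExtractSegment:
    @pytest.mark.parametrize("length,ok", [(33, True), (64, True), (65, False)])
    def test_length_limit(self, length, ok):
        eit = EitFrameSeries(values=np.arange(100 * N_CHANNELS, dtype=float).reshape(100, -1))
        iv = BeatInterval(0, length)
        if ok:
            block = extract_segment(eit, iv)
            assert block.shape == (length, N_CHANNELS)
            assert np.array_equal(block, eit.values[:length])
        else:
            with pytest.raises(BeatRejected, match="overlong"):
                extract_segment(eit, iv)

    def test_out_of_range_rejected(self):
        eit = EitFrameSeries(values=np.zeros((50, N_CHANNELS)))
        with pytest.raises(DataError):
            extract_segment(eit, BeatInterval(40, 60))


class TestBeatRecovery:
    def test_noisy_subject_beats_recovered(self, noisy_cohort):
        """Seeded study conditions: nearly all true beats found within
        two frames on both boundaries."""
        for rec in noisy_cohort:
            intervals, ridge = detect_beats(rec.eit)
            truth_frames = rec.truth.eit_bounds * rec.eit.frame_rate
            assert match_beats(truth_frames, intervals, tol_frames=2.0) >= 0.95
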