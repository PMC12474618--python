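"""Simulator contracts: exact labels, coupling, determinism, unbalance."""

import numpy as np
import pytest

from eitbp.core import DataError, N_CHANNELS
from eitbp.synthdata import (
    Episode,
    EventSchedule,
    SimulationConfig,
    apply_millar_drift,
    generate_cohort,
    pulse_arrival_delay,
    simulate_eit_frames,
    simulate_pressure_trace,
    simulate_sync_channel,
)
from conftest import SEED, make_profile


class TestPressureTrace:
    def test_fixed_template_extrema_equal_labels_exactly(self, empty_schedule):
        profile = make_profile()
        trace, truth = simulate_pressure_trace(profile, empty_schedule, 30.0, seed=1)
        assert np.all(truth.sap == 120.0)
        assert np.all(truth.dap == 70.0)
        # the template's mean is steered to the MAP target
        assert np.all(np.abs(truth.map - 90.0) < 0.3)
        # recorded extrema of the waveform equal the labels
        for b0, b1, sap, dap in zip(
            (truth.beat_bounds[:-1] * 1000).astype(int),
            (truth.beat_bounds[1:] * 1000).astype(int),
            truth.sap,
            truth.dap,
        ):
            seg = trace.samples[b0:b1]
            assert seg.max() == sap
            assert seg.min() == dap

    def test_per_beat_ordering_and_range(self, noisy_cohort):
        for rec in noisy_cohort:
            t = rec.truth
            assert np.all(t.dap < t.map)
            assert np.all(t.map < t.sap)
            assert np.all((t.dap > 0) & (t.sap < 300))

    def test_beat_rate_follows_baseline_hr(self, empty_schedule):
        profile = make_profile(baseline_hr=120.0)
        _, truth = simulate_pressure_trace(profile, empty_schedule, 30.0, seed=1)
        lengths = np.diff(truth.beat_bounds)
        assert np.allclose(lengths, 60.0 / 120.0, atol=1e-3)

    def test_nonpositive_duration_rejected(self, empty_schedule):
        with pytest.raises(DataError):
            simulate_pressure_trace(make_profile(), empty_schedule, 5.0, seed=1)

    def test_schedule_outside_duration_rejected(self):
        sched = EventSchedule([Episode(10.0, 50.0, 10, 8, 6, -4)])
        with pytest.raises(DataError):
            simulate_pressure_trace(make_profile(), sched, 30.0, seed=1)

    def test_schedule_moves_pressures(self):
        sched = EventSchedule([Episode(20.0, 40.0, 37.5, 30.0, 24.0, -13.5)])
        _, truth = simulate_pressure_trace(make_profile(), sched, 60.0, seed=1)
        mid = (truth.beat_bounds[:-1] > 30) & (truth.beat_bounds[:-1] < 38)
        early = truth.beat_bounds[:-1] < 15
        assert truth.map[mid].mean() > truth.map[early].mean() + 25


class TestEitFrames:
    def test_zero_gains_zero_noise_yields_pure_dc(self, empty_schedule):
        profile = make_profile(channel_dc=np.linspace(-1, 1, N_CHANNELS))
        trace, _ = simulate_pressure_trace(profile, empty_schedule, 12.0, seed=1)
        eit = simulate_eit_frames(profile, trace, seed=2)
        expected = profile.channel_dc.astype(np.float32)
        assert np.all(eit.values == expected[None, :])
        assert eit.frame_rate == 47.68

    def test_respiration_completes_2p5_cycles_in_8p4_s(self, empty_schedule):
        profile = make_profile(
            resp_rate=0.3, channel_resp_gain=np.ones(N_CHANNELS)
        )
        trace, _ = simulate_pressure_trace(profile, empty_schedule, 12.0, seed=1)
        eit = simulate_eit_frames(profile, trace, seed=2)
        n = int(8.4 * eit.frame_rate)
        sig = eit.values[:n, 0].astype(float)
        nfft = 8192  # zero-pad for fine frequency resolution
        freqs = np.fft.rfftfreq(nfft, 1 / eit.frame_rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(sig - sig.mean(), n=nfft)))]
        assert peak * 8.4 == pytest.approx(2.5, abs=0.15)

    def test_cardiac_band_power_elevated_exactly_on_gained_channels(
        self, empty_schedule
    ):
        gain = np.zeros(N_CHANNELS)
        active = np.arange(0, N_CHANNELS, 16)[:64]
        gain[active] = 2e-4
        profile = make_profile(channel_cardiac_gain=gain)
        trace, _ = simulate_pressure_trace(profile, empty_schedule, 30.0, seed=1)
        eit = simulate_eit_frames(profile, trace, seed=2)
        # direct FFT oracle: per-channel power in the cardiac band
        x = eit.values - eit.values.mean(axis=0)
        spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / eit.frame_rate)
        band = (freqs >= 1.0) & (freqs <= 2.5)
        power = spec[band].sum(axis=0)
        top = np.argsort(power)[::-1][: len(active)]
        assert set(top) == set(active)

    def test_mismatched_duration_rejected(self, empty_schedule):
        profile = make_profile()
        from eitbp.core import PressureTrace

        with pytest.raises(DataError):
            simulate_eit_frames(profile, PressureTrace(samples=np.zeros(10)), seed=1)

    def test_delay_decreases_with_map(self):
        profile = make_profile()
        assert pulse_arrival_delay(profile, 110.0) < pulse_arrival_delay(
            profile, 90.0
        )
        # a 20 mmHg MAP step strictly decreases the delay
        d = pulse_arrival_delay(profile, np.array([80.0, 100.0]))
        assert d[1] < d[0]


class TestSyncChannel:
    def test_edges_on_grid_within_1ms(self):
        track = simulate_sync_channel(np.array([0.0, 0.021, 0.042]))
        from eitbp.ingest import detect_edges

        edges = detect_edges(track)
        times = track.t0 + edges / track.rate
        assert len(times) == 3
        assert np.all(np.abs(times - [0.0, 0.021, 0.042]) <= 1e-3 + 1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            simulate_sync_channel(np.array([]))


class TestMillarDrift:
    def test_zero_drift_is_identity(self, quiet_cohort):
        trace = quiet_cohort.subjects[0].pressure_millar
        out = apply_millar_drift(trace, 0.0)
        assert np.array_equal(out.samples, trace.samples)

    def test_linear_ramp(self):
        from eitbp.core import PressureTrace

        trace = PressureTrace(samples=np.full(60_000, 80.0))
        out = apply_millar_drift(trace, 5.0)
        assert out.samples[0] == 80.0
        assert out.samples[-1] == pytest.approx(85.0, abs=1e-3)

    def test_pulse_pressure_preserved(self, quiet_cohort):
        rec = quiet_cohort.subjects[0]
        truth = rec.truth
        drifted = apply_millar_drift(rec.pressure_millar, 12.0)
        for b0, b1 in zip(
            (truth.beat_bounds[:-1] * 1000).astype(int),
            (truth.beat_bounds[1:] * 1000).astype(int),
        ):
            pp0 = np.ptp(rec.pressure_millar.samples[b0:b1])
            pp1 = np.ptp(drifted.samples[b0:b1])
            assert abs(pp0 - pp1) < 0.1


class TestCohort:
    def test_determinism_bit_identical(self):
        cfg = SimulationConfig(n_subjects=2, base_duration_s=30.0)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=5)
        for ra, rb in zip(a, b):
            assert ra.subject_id == rb.subject_id
            assert np.array_equal(ra.eit.values, rb.eit.values)
            assert np.array_equal(
                ra.pressure_millar.samples, rb.pressure_millar.samples
            )
            assert np.array_equal(ra.truth.sap, rb.truth.sap)
            assert np.array_equal(ra.sync.samples, rb.sync.samples)

    def test_distinct_subject_ids(self, noisy_cohort):
        ids = noisy_cohort.subject_ids()
        assert len(set(ids)) == len(ids) == 2

    def test_single_subject_rejected(self):
        with pytest.raises(DataError):
            generate_cohort(SimulationConfig(n_subjects=1), seed=1)

    def test_unbalanced_beat_counts(self):
        cfg = SimulationConfig(
            n_subjects=3, base_duration_s=40.0, unbalance_factor=1.6
        )
        cohort = generate_cohort(cfg, seed=3)
        counts = np.array([rec.truth.n_beats for rec in cohort])
        assert counts.std() / counts.mean() > 0

    def test_eventful_cohort_spans_wide_sap_range(self):
        cfg = SimulationConfig(n_subjects=9, base_duration_s=80.0)
        cohort = generate_cohort(cfg, seed=SEED)
        sap = np.concatenate([rec.truth.sap for rec in cohort])
        assert sap.min() < 80.0
        assert sap.max() > 150.0
        assert sap.max() - sap.min() > 80.0
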