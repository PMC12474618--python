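"""Synthetic paired EIT / aortic-pressure / sync-channel simulator.

Real paired recordings of raw EIT voltage frames and invasive aortic
pressure are not publicly deposited, so every downstream stage of the
pipeline is exercised on fully synthetic cohorts with known per-beat ground
truth.  The simulator emulates the salient features of such recordings:

- a 1 kHz aortic pressure waveform built beat-by-beat from a template with
  a raised-cosine systolic upstroke and an exponential-like diastolic decay,
  whose per-beat extrema *are* the ground-truth SAP/DAP and whose per-beat
  arithmetic mean is steered to the ground-truth MAP;
- 47.68 Hz EIT frames of 1024 voltages: per-channel DC offsets, a sinusoidal
  respiration component (~0.3 Hz), a cardiac component coupled to the
  pressure waveform in both amplitude (channel gain x pulse pressure) and
  timing (pulse-arrival delay decreasing with MAP, emulating
  pressure-dependent pulse-wave propagation), plus white sensor noise;
- a drifting high-fidelity ("Millar-like") pressure channel and a
  beat-sparse stable fluid-filled reference used for recalibration;
- a 1 kHz timing-reference pulse channel with one rising edge per frame;
- hemodynamic event schedules (vasoconstrictor-, hypoxia- and
  hemorrhage-like episodes) that move pressures and, via a baroreflex-like
  coupling, heart rate;
- unbalanced per-subject recording durations, hence unbalanced beat counts.

All randomness derives from a single master seed; per-subject streams are
split off by stable hashing of the subject id, so cohorts are
bit-reproducible across processes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

from eitbp.core import (
    EIT_FRAME_RATE,
    N_CHANNELS,
    PHYSIO_RATE,
    DataError,
    EitFrameSeries,
    GroundTruth,
    PressureTrace,
    ReferenceBeats,
    StudyBundle,
    SubjectRecording,
    SyncTrack,
)

__all__ = [
    "SubjectProfile",
    "Episode",
    "EventSchedule",
    "SimulationConfig",
    "simulate_pressure_trace",
    "simulate_eit_frames",
    "simulate_sync_channel",
    "apply_millar_drift",
    "generate_cohort",
    "pulse_arrival_delay",
]

#: MAP reference for the pulse-arrival-delay coupling, mmHg.  Fixed
#: cohort-wide so that the delay is a consistent function of absolute MAP.
DELAY_MAP_REF = 90.0


@dataclass
class SubjectProfile:
    """Physiological and sensor parameters of one simulated subject."""

    subject_id: str
    baseline_hr: float  # beats/min
    hr_jitter: float  # fractional SD of beat-to-beat HR
    resp_rate: float  # Hz
    baseline_sap: float  # mmHg
    baseline_map: float  # mmHg
    baseline_dap: float  # mmHg
    channel_dc: np.ndarray  # (1024,) arbitrary voltage units
    channel_cardiac_gain: np.ndarray  # (1024,) voltage per mmHg
    channel_resp_gain: np.ndarray  # (1024,) voltage
    pressure_to_delay: float = 4e-4  # s per mmHg of MAP above reference
    delay_base: float = 0.03  # pulse-arrival delay at reference MAP, s
    noise_sd: float = 2e-3  # voltage units per channel per frame
    millar_drift_rate: float = 0.0  # mmHg/min
    resp_phase: float = 0.0  # rad
    beat_var_sd: float = 1.5  # beat-level AR(1) pressure variability, mmHg

    def __post_init__(self) -> None:
        for name in ("channel_dc", "channel_cardiac_gain", "channel_resp_gain"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_CHANNELS,):
                raise DataError(f"{name} must have shape ({N_CHANNELS},)")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if not self.baseline_dap < self.baseline_map < self.baseline_sap:
            raise DataError("baselines must satisfy DAP < MAP < SAP")
        if not 0.1 < self.resp_rate < 1.0:
            raise DataError("resp_rate must lie in (0.1, 1.0) Hz")
        if not 50 < self.baseline_hr < 240:
            raise DataError("baseline_hr must lie in (50, 240) beats/min")


@dataclass(frozen=True)
class Episode:
    """One hemodynamic episode: pressure and heart-rate offsets."""

    start_s: float
    end_s: float
    sap_delta: float
    map_delta: float
    dap_delta: float
    hr_delta: float


@dataclass
class EventSchedule:
    """Piecewise episodes with smooth onset/offset ramps.

    ``delta_at(t)`` returns the summed (sap, map, dap, hr) offsets at time
    ``t``; each episode contributes its deltas scaled by a trapezoidal
    envelope that ramps up over ``ramp_s`` seconds after ``start_s`` and
    back down after ``end_s``.
    """

    episodes: list[Episode] = field(default_factory=list)
    ramp_s: float = 8.0

    def validate(self, duration: float, profile: SubjectProfile) -> None:
        for ep in self.episodes:
            if not 0 <= ep.start_s < ep.end_s <= duration:
                raise DataError(
                    f"episode [{ep.start_s}, {ep.end_s}] outside recording "
                    f"duration {duration}"
                )
            if profile.baseline_dap + ep.dap_delta <= 5:
                raise DataError("episode would drive DAP non-positive")

    def delta_at(self, t: np.ndarray | float) -> np.ndarray:
        """Summed (sap, map, dap, hr) deltas at times ``t``; shape (4,) or (4, n)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros((4,) + t.shape)
        for ep in self.episodes:
            up = np.clip((t - ep.start_s) / self.ramp_s, 0.0, 1.0)
            down = 1.0 - np.clip((t - ep.end_s) / self.ramp_s, 0.0, 1.0)
            env = up * down
            out += np.multiply.outer(
                np.array([ep.sap_delta, ep.map_delta, ep.dap_delta, ep.hr_delta]),
                env,
            )
        return out


def pulse_arrival_delay(profile: SubjectProfile, map_mmHg: np.ndarray | float) -> np.ndarray:
    """Pulse-arrival delay of the cardiac EIT signature, seconds.

    Higher pressures propagate the pulse wave faster, so the delay decreases
    linearly with MAP (floored at 5 ms).
    """
    d = profile.delay_base - profile.pressure_to_delay * (
        np.asarray(map_mmHg, dtype=float) - DELAY_MAP_REF
    )
    return np.maximum(d, 0.005)


def _decay_shape(u: np.ndarray, k: float) -> np.ndarray:
    """Normalized exponential decay: 1 at u=0, exactly 0 at u=1."""
    return (np.exp(-k * u) - np.exp(-k)) / (1.0 - np.exp(-k))


def _beat_template(n: int, sap: float, dap: float, k: float) -> np.ndarray:
    """One beat of ``n`` samples: raised-cosine upstroke (30% of the beat)
    from DAP to SAP, then exponential-like decay back to DAP.

    Sample 0 equals DAP exactly; the peak sample equals SAP exactly; the
    (excluded) sample ``n`` of the next beat returns to DAP.
    """
    i_peak = max(1, int(round(0.3 * n)))
    pp = sap - dap
    out = np.empty(n)
    i = np.arange(i_peak + 1)
    out[: i_peak + 1] = dap + pp * 0.5 * (1.0 - np.cos(np.pi * i / i_peak))
    u = (np.arange(i_peak + 1, n) - i_peak) / (n - i_peak)
    out[i_peak + 1 :] = dap + pp * _decay_shape(u, k)
    return out


def _solve_decay_rate(n: int, sap: float, dap: float, map_target: float) -> float:
    """Choose the decay constant so the beat's sample mean hits MAP."""

    def mean_err(k: float) -> float:
        tpl = _beat_template(n, sap, dap, k)
        # inclusive of the next beat's onset sample (= dap), matching the
        # label-extraction convention of a mean between bounding minima
        return (tpl.sum() + dap) / (n + 1) - map_target

    k_lo, k_hi = 0.05, 30.0
    lo, hi = mean_err(k_lo), mean_err(k_hi)
    if lo <= 0:  # MAP target at/above achievable maximum
        return k_lo
    if hi >= 0:
        return k_hi
    return brentq(mean_err, k_lo, k_hi, xtol=1e-4)


def simulate_pressure_trace(
    profile: SubjectProfile,
    schedule: EventSchedule,
    duration: float,
    seed: int,
) -> tuple[PressureTrace, GroundTruth]:
    """Generate a beat-templated 1 kHz aortic pressure trace.

    Per-beat targets are the subject baselines plus the schedule's deltas at
    the beat onset plus a slow AR(1) beat-to-beat variability; the recorded
    ground truth is read back from the generated waveform itself (exact
    extrema, exact sample mean), so DAP < MAP < SAP holds by construction.
    """
    if duration <= 10:
        raise DataError("duration must exceed 10 s")
    schedule.validate(duration, profile)
    rng = np.random.default_rng(seed)
    fs = PHYSIO_RATE
    n_total = int(round(duration * fs))
    samples = np.empty(n_total)

    bounds: list[int] = []
    saps: list[float] = []
    maps: list[float] = []
    daps: list[float] = []

    pos = 0
    ar = 0.0  # AR(1) beat-level variability, mmHg (on the MAP scale)
    rho = 0.9
    peaks: list[int] = []  # upstroke peak-slope offsets, samples
    while True:
        t = pos / fs
        d_sap, d_map, d_dap, d_hr = schedule.delta_at(t)
        if profile.beat_var_sd > 0:
            ar = rho * ar + profile.beat_var_sd * np.sqrt(1 - rho**2) * rng.normal()
        hr = (profile.baseline_hr + d_hr) * (
            1.0 + profile.hr_jitter * rng.normal()
        )
        hr = float(np.clip(hr, 40.0, 260.0))
        n = int(round(fs * 60.0 / hr))
        if pos + n + 1 > n_total:
            break
        sap = profile.baseline_sap + d_sap + 1.25 * ar
        dap = profile.baseline_dap + d_dap + 0.8 * ar
        map_t = profile.baseline_map + d_map + ar
        pp = sap - dap
        if pp < 10:  # keep the beat well-formed under extreme schedules
            sap = dap + 10
            pp = 10.0
        # clamp MAP into the template's achievable range
        frac = np.clip((map_t - dap) / pp, 0.17, 0.48)
        map_t = dap + frac * pp
        k = _solve_decay_rate(n, sap, dap, map_t)
        tpl = _beat_template(n, sap, dap, k)
        samples[pos : pos + n] = tpl
        bounds.append(pos)
        peaks.append(max(1, int(round(0.3 * n))) // 2)
        saps.append(sap)
        daps.append(dap)
        maps.append((tpl.sum() + dap) / (n + 1))
        pos += n
    if not bounds:
        raise DataError("duration too short for a single beat")
    bounds.append(pos)
    # the recording cuts off mid-beat: fill the tail with the start of one
    # more beat at the final conditions (truncated at the record end)
    if pos < n_total:
        n_last = int(round(bounds[-1] - bounds[-2])) or 2
        tail = _beat_template(n_last, saps[-1], daps[-1], k)
        n_tail = n_total - pos
        reps = -(-n_tail // n_last)
        samples[pos:] = np.tile(tail, reps)[:n_tail]

    bounds_s = np.asarray(bounds, dtype=float) / fs
    map_arr = np.asarray(maps)
    # EIT-timebase boundaries use the mid-upstroke landmark (the steepest
    # point of the systolic upstroke) shifted by the pulse-arrival delay —
    # the same within-cycle anchor the beat detector locks onto
    landmark = (np.asarray(bounds) + np.r_[peaks, peaks[-1]]) / fs
    truth = GroundTruth(
        beat_bounds=bounds_s,
        eit_bounds=landmark
        + pulse_arrival_delay(profile, np.r_[map_arr, map_arr[-1]]),
        sap=np.asarray(saps),
        map=map_arr,
        dap=np.asarray(daps),
    )
    return PressureTrace(samples=samples), truth


def simulate_eit_frames(
    profile: SubjectProfile,
    pressure: PressureTrace,
    seed: int,
    frame_rate: float = EIT_FRAME_RATE,
) -> EitFrameSeries:
    """Render 47.68 Hz EIT voltage frames coupled to a pressure trace.

    Each frame is ``dc + resp_gain * sin(2 pi f_r t) + cardiac_gain * w(t -
    delay(MAP)) + noise`` where ``w`` is the mean-removed pressure waveform
    (1 s moving-average baseline) in mmHg and the pulse-arrival delay
    decreases with the smoothed MAP.
    """
    n_frames = int(np.floor(pressure.duration * frame_rate))
    if n_frames < 1:
        raise DataError("pressure trace too short for a single EIT frame")
    t = np.arange(n_frames) / frame_rate
    p = pressure.samples
    p_sm = uniform_filter1d(p, size=PHYSIO_RATE, mode="nearest")
    w = p - p_sm
    map_at_t = np.interp(t, pressure.times, p_sm)
    delay = pulse_arrival_delay(profile, map_at_t)
    cardiac = np.interp(t - delay, pressure.times, w)
    resp = np.sin(2 * np.pi * profile.resp_rate * t + profile.resp_phase)

    rng = np.random.default_rng(seed)
    values = np.empty((n_frames, N_CHANNELS), dtype=np.float32)
    values[:] = profile.channel_dc[None, :]
    values += np.outer(resp, profile.channel_resp_gain)
    values += np.outer(cardiac, profile.channel_cardiac_gain)
    if profile.noise_sd > 0:
        values += rng.normal(0.0, profile.noise_sd, size=values.shape).astype(
            np.float32
        )
    return EitFrameSeries(values=values, frame_rate=frame_rate)


def simulate_sync_channel(
    frame_times: np.ndarray, rate: int = PHYSIO_RATE, pulse_width: int = 8
) -> SyncTrack:
    """Render the timing-reference pulse train: one rising edge per frame.

    Each edge lands on the 1 kHz grid point nearest the true frame time, so
    the alignment error is bounded by half a sample (< 1 ms).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise DataError("frame_times is empty")
    if frame_times.size > 1 and np.any(np.diff(frame_times) <= 0):
        raise DataError("frame_times must be strictly increasing")
    pre_roll = 10  # samples of silence before the first frame's pulse
    edges = np.rint(frame_times * rate).astype(np.int64) + pre_roll
    n = int(edges[-1]) + pulse_width + 5
    samples = np.zeros(n)
    for e in edges:
        samples[e : e + pulse_width] = 1.0
    return SyncTrack(samples=samples, t0=-pre_roll / rate)


def apply_millar_drift(pressure: PressureTrace, drift_rate: float) -> PressureTrace:
    """Add a linear calibration drift of ``drift_rate`` mmHg/min.

    The drift is additive and slow, so within-beat waveform shape (and hence
    pulse pressure) is essentially unchanged.
    """
    t = np.arange(len(pressure.samples)) / pressure.rate
    return PressureTrace(
        samples=pressure.samples + drift_rate * t / 60.0, t0=pressure.t0
    )


@dataclass
class SimulationConfig:
    """Cohort-level study conditions for :func:`generate_cohort`.

    Defaults describe the reference study: nine subjects, anesthetized-pig
    hemodynamics (HR near 88 /min, pressures near 118/92/72 mmHg), three
    hemodynamic episodes per subject (vasoconstrictor-, hemorrhage- and
    hypoxia-like), strong amplitude+delay coupling of the cardiac EIT
    component and moderate sensor noise.
    """

    n_subjects: int = 9
    base_duration_s: float = 250.0
    unbalance_factor: float = 1.6
    baseline_hr_range: tuple[float, float] = (86.0, 96.0)
    hr_jitter: float = 0.02
    resp_rate_range: tuple[float, float] = (0.28, 0.34)
    baseline_dap_mean: float = 72.0
    baseline_dap_sd: float = 3.0
    baseline_pp_mean: float = 46.0
    baseline_pp_sd: float = 4.0
    events_enabled: bool = True
    event_map_deltas: tuple[float, ...] = (30.0, -35.0, 15.0)
    event_delta_sd: float = 5.0
    baroreflex_slope: float = -0.45  # beats/min per mmHg of MAP (blunted under anesthesia)
    sap_delta_ratio: float = 1.25
    dap_delta_ratio: float = 0.8
    beat_var_sd: float = 1.5
    n_cardiac_channels: int = 64
    cardiac_gain_scale: float = 2e-4  # V per mmHg on cardiac-active channels
    cardiac_gain_subject_sd: float = 0.08  # fractional subject-to-subject scale
    resp_gain_scale: float = 5e-3  # V
    dc_scale: float = 0.5  # V
    noise_sd: float = 2e-3  # V
    pressure_to_delay: float = 4e-4  # s/mmHg
    delay_base: float = 0.03  # s
    millar_drift_range: tuple[float, float] = (-3.0, 3.0)  # mmHg/min
    millar_noise_sd: float = 0.3  # mmHg
    reference_jitter_sd: float = 1.0  # mmHg on fluid-filled DAP values
    n_measuring_segments: int = 3

    def quiet(self) -> "SimulationConfig":
        """A noise-free, event-free, jitter-free copy (for exact tests)."""
        return replace(
            self,
            hr_jitter=0.0,
            events_enabled=False,
            beat_var_sd=0.0,
            noise_sd=0.0,
            millar_drift_range=(0.0, 0.0),
            millar_noise_sd=0.0,
            reference_jitter_sd=0.0,
        )


def _subject_rng(master_seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject stream derived by stable hashing of the subject id."""
    key = zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    )


def _draw_profile(
    config: SimulationConfig, subject_id: str, rng: np.random.Generator
) -> SubjectProfile:
    dap = config.baseline_dap_mean + config.baseline_dap_sd * rng.normal()
    pp = max(25.0, config.baseline_pp_mean + config.baseline_pp_sd * rng.normal())
    sap = dap + pp
    frac = float(np.clip(0.42 + 0.02 * rng.normal(), 0.25, 0.47))
    map_ = dap + frac * pp

    dc = config.dc_scale * rng.normal(size=N_CHANNELS) + 0.1
    # cardiac activity visible on a subset of channels only; the active set
    # and its gain pattern are shared cohort-wide up to a subject scale so
    # that a model can generalize across subjects
    gain_pattern = np.zeros(N_CHANNELS)
    active = np.arange(config.n_cardiac_channels) * (
        N_CHANNELS // max(config.n_cardiac_channels, 1)
    )
    pattern_rng = np.random.default_rng(12345)  # cohort-wide fixed pattern
    gain_pattern[active] = 1.0 + 0.2 * pattern_rng.normal(size=len(active))
    subject_scale = 1.0 + config.cardiac_gain_subject_sd * rng.normal()
    cardiac_gain = config.cardiac_gain_scale * subject_scale * gain_pattern
    resp_gain = config.resp_gain_scale * (
        0.8 + 0.3 * rng.normal(size=N_CHANNELS)
    )
    return SubjectProfile(
        subject_id=subject_id,
        baseline_hr=float(rng.uniform(*config.baseline_hr_range)),
        hr_jitter=config.hr_jitter,
        resp_rate=float(rng.uniform(*config.resp_rate_range)),
        baseline_sap=sap,
        baseline_map=map_,
        baseline_dap=dap,
        channel_dc=dc,
        channel_cardiac_gain=cardiac_gain,
        channel_resp_gain=resp_gain,
        pressure_to_delay=config.pressure_to_delay,
        delay_base=config.delay_base,
        noise_sd=config.noise_sd,
        millar_drift_rate=float(rng.uniform(*config.millar_drift_range)),
        resp_phase=float(rng.uniform(0, 2 * np.pi)),
        beat_var_sd=config.beat_var_sd,
    )


def _draw_schedule(
    config: SimulationConfig, duration: float, rng: np.random.Generator
) -> EventSchedule:
    if not config.events_enabled:
        return EventSchedule()
    windows = [(0.12, 0.32), (0.42, 0.62), (0.72, 0.92)]
    deltas = list(config.event_map_deltas)
    order = rng.permutation(len(deltas))
    episodes = []
    for (w0, w1), j in zip(windows, order):
        d_map = deltas[j] + config.event_delta_sd * rng.normal()
        episodes.append(
            Episode(
                start_s=w0 * duration,
                end_s=w1 * duration,
                sap_delta=config.sap_delta_ratio * d_map,
                map_delta=d_map,
                dap_delta=config.dap_delta_ratio * d_map,
                hr_delta=config.baroreflex_slope * d_map,
            )
        )
    return EventSchedule(episodes=episodes)


def generate_cohort(config: SimulationConfig, seed: int) -> StudyBundle:
    """Generate a full study cohort with unbalanced per-subject durations."""
    if config.n_subjects < 2:
        raise DataError(
            "at least 2 subjects are required (leave-one-subject-out needs >= 2)"
        )
    subjects = []
    for i in range(config.n_subjects):
        sid = f"pig{i + 1:02d}"
        rng = _subject_rng(seed, sid)
        duration = config.base_duration_s * config.unbalance_factor ** rng.uniform(
            -1.0, 1.0
        )
        profile = _draw_profile(config, sid, rng)
        schedule = _draw_schedule(config, duration, rng)
        p_true, truth = simulate_pressure_trace(
            profile, schedule, duration, seed=int(rng.integers(2**31))
        )
        millar = apply_millar_drift(p_true, profile.millar_drift_rate)
        if config.millar_noise_sd > 0:
            noise = rng.normal(
                0.0, config.millar_noise_sd * np.sqrt(15), len(millar.samples)
            )
            millar = PressureTrace(
                samples=millar.samples + uniform_filter1d(noise, 15),
                t0=millar.t0,
            )
        onset_times = truth.beat_bounds[:-1]
        reference = ReferenceBeats(
            times=onset_times,
            dap=truth.dap
            + config.reference_jitter_sd * rng.normal(size=truth.n_beats),
        )
        eit = simulate_eit_frames(
            profile, p_true, seed=int(rng.integers(2**31))
        )
        frame_times = np.arange(eit.n_frames) / eit.frame_rate
        sync = simulate_sync_channel(frame_times)
        subjects.append(
            SubjectRecording(
                subject_id=sid,
                eit=eit,
                sync=sync,
                pressure_millar=millar,
                reference=reference,
                truth=truth,
                segment_bounds=np.linspace(
                    0.0, duration, config.n_measuring_segments + 1
                ),
            )
        )
    return StudyBundle(subjects=subjects, seed=seed)
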