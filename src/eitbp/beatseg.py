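"""Heartbeat segmentation from the EIT signal alone.

The heart rate is detected exclusively from the EIT voltage stream — the
pressure channel only ever supplies labels.  The chain is:

1. :func:`global_signal` — per-channel sliding DC removal, then the mean
   across all 1024 channels;
2. :func:`fsst` — a Fourier synchrosqueezing transform: the short-time
   Fourier spectrogram is sharpened by reassigning each bin's energy to its
   instantaneous-frequency estimate, yielding strongly localized cardiac
   and respiratory components;
3. :func:`track_ridge` — greedy, continuity-constrained tracking of the
   cardiac-band ridge = instantaneous heart rate;
4. :func:`segment_beats` — beat boundaries at 2*pi crossings of the
   integrated cardiac phase, optionally anchored to the diastolic feet of
   the signal;
5. :func:`exclude_premature` / :func:`extract_segment` — premature-beat
   exclusion and 64-frame-max block extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal.windows import hann

from eitbp.core import DataError, EitFrameSeries

__all__ = [
    "SynchrosqueezedSpectrogram",
    "HeartRateRidge",
    "BeatInterval",
    "BeatRejected",
    "global_signal",
    "fsst",
    "track_ridge",
    "segment_beats",
    "exclude_premature",
    "extract_segment",
    "match_beats",
    "CARDIAC_BAND",
    "MAX_BEAT_FRAMES",
]

#: Default cardiac band, Hz (60-240 beats/min, covers anesthetized pigs).
CARDIAC_BAND = (1.0, 4.0)
#: Beats longer than this many EIT frames are excluded.
MAX_BEAT_FRAMES = 64


class BeatRejected(DataError):
    """A beat segment was rejected (e.g. overlong)."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class SynchrosqueezedSpectrogram:
    """Reassigned magnitude spectrogram (time x frequency).

    ``omega_mean`` holds, per reassigned bin, the magnitude-weighted mean of
    the contributing instantaneous-frequency estimates — a sub-bin-accurate
    frequency for any concentrated component.
    """

    magnitude: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    window: str
    window_len: int
    hop: int
    sample_rate: float
    omega_mean: np.ndarray | None = None
    #: per-column total STFT magnitude before reassignment (for energy
    #: bookkeeping: reassignment conserves it up to floored bins)
    stft_column_energy: np.ndarray | None = None
    zero_energy: bool = False


@dataclass
class HeartRateRidge:
    """Instantaneous heart-rate track with per-time quality scores.

    ``quality`` is the ridge magnitude divided by the in-band column
    magnitude; ``reliable`` flags columns whose score (and in-band energy
    share) clears the configured floors.  ``edge_cols`` counts the columns
    at each end that lie within half an analysis window of the record
    edge, where the estimate leans on padded data.
    """

    times: np.ndarray
    hr: np.ndarray  # Hz
    quality: np.ndarray
    reliable: np.ndarray
    edge_cols: int = 0

    @property
    def unreliable_fraction(self) -> float:
        return 1.0 - float(np.mean(self.reliable))


@dataclass(frozen=True)
class BeatInterval:
    """Half-open frame interval [start, end) of one heartbeat."""

    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise DataError("beat interval must have end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


def remove_channel_dc(
    eit: EitFrameSeries, dc_window_s: float = 10.0
) -> EitFrameSeries:
    """Per-channel sliding DC (baseline) removal.

    Subtracts each channel's mean over a sliding ``dc_window_s`` window.
    Removes the large static electrode-voltage offsets — a per-recording
    fingerprint that otherwise dominates the dynamic (ventilation and
    cardiac) components of interest.
    """
    if eit.n_frames < 2:
        raise DataError("need at least 2 frames")
    x = eit.values.astype(np.float32, copy=False)
    size = max(2, int(round(dc_window_s * eit.frame_rate)))
    baseline = uniform_filter1d(x, size=size, axis=0, mode="nearest")
    return EitFrameSeries(
        values=x - baseline,
        frame_rate=eit.frame_rate,
        frame_times=eit.frame_times,
    )


def global_signal(
    eit: EitFrameSeries, dc_window_s: float = 10.0
) -> np.ndarray:
    """Channel-mean EIT signal after sliding DC removal.

    Each channel's mean over a sliding ``dc_window_s`` window is subtracted
    (baseline/DC removal), then the 1024 channels are averaged.
    """
    return (
        remove_channel_dc(eit, dc_window_s=dc_window_s)
        .values.astype(np.float64)
        .mean(axis=1)
    )


def fsst(
    signal: np.ndarray,
    sample_rate: float,
    window_len: int = 256,
    hop: int = 1,
    magnitude_floor: float = 1e-8,
) -> SynchrosqueezedSpectrogram:
    """Fourier synchrosqueezing transform of a 1-D signal.

    Computes the STFT with a Hann window ``g`` and with its derivative
    window ``g'``; the per-bin instantaneous frequency estimate is
    ``omega = f - Im(V_g' / V_g) / (2 pi)`` and each STFT bin's magnitude
    is reassigned to the frequency bin nearest ``omega``.  Total per-column
    magnitude is conserved up to bins below ``magnitude_floor`` (relative
    to the column maximum) and bins whose estimate leaves the frequency
    range.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if window_len > n:
        raise DataError("window longer than signal")
    g = hann(window_len, sym=False)
    dg = np.gradient(g) * sample_rate  # dg/dt in 1/s

    half = window_len // 2
    padded = np.pad(signal, (half, window_len - half), mode="reflect")
    frames = np.lib.stride_tricks.sliding_window_view(padded, window_len)[
        : n : hop
    ]
    V = np.fft.rfft(frames * g, axis=1)
    Vd = np.fft.rfft(frames * dg, axis=1)
    freqs = np.fft.rfftfreq(window_len, d=1.0 / sample_rate)
    times = np.arange(0, n, hop) / sample_rate
    mag = np.abs(V)

    if not np.any(mag > 0):
        return SynchrosqueezedSpectrogram(
            magnitude=np.zeros_like(mag),
            times=times,
            freqs=freqs,
            window="hann",
            window_len=window_len,
            hop=hop,
            sample_rate=sample_rate,
            zero_energy=True,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        omega = freqs[None, :] - np.imag(Vd / V) / (2 * np.pi)
    df = freqs[1] - freqs[0]
    target = np.rint(omega / df)

    col_max = mag.max(axis=1, keepdims=True)
    valid = (
        np.isfinite(target)
        & (target >= 0)
        & (target < len(freqs))
        & (mag > magnitude_floor * col_max)
    )
    n_cols = mag.shape[0]
    out = np.zeros_like(mag)
    wsum = np.zeros_like(mag)
    rows = np.broadcast_to(np.arange(n_cols)[:, None], mag.shape)[valid]
    cols = target[valid].astype(np.intp)
    np.add.at(out, (rows, cols), mag[valid])
    np.add.at(wsum, (rows, cols), (mag * np.where(valid, omega, 0.0))[valid])
    with np.errstate(invalid="ignore", divide="ignore"):
        omega_mean = np.where(out > 0, wsum / np.where(out > 0, out, 1.0), 0.0)
    return SynchrosqueezedSpectrogram(
        magnitude=out,
        times=times,
        freqs=freqs,
        window="hann",
        window_len=window_len,
        hop=hop,
        sample_rate=sample_rate,
        omega_mean=omega_mean,
        stft_column_energy=mag.sum(axis=1),
    )


def track_ridge(
    sst: SynchrosqueezedSpectrogram,
    band: tuple[float, float] = CARDIAC_BAND,
    max_jump_hz: float = 0.1,
    init_block: int = 47,
    quality_floor: float = 0.05,
    band_energy_floor: float = 0.01,
    refine: bool = True,
) -> HeartRateRidge:
    """Greedy constrained ridge tracking within a frequency band.

    A forward pass picks, at each time step, the frequency of maximal
    reassigned magnitude within ``band`` intersected with ``prev +/-
    max_jump_hz``.  Initialization sums ``init_block`` columns (starting
    past the edge-biased region) and maximizes a harmonic-aware score —
    each band frequency gains credit from its own first harmonic, so the
    cardiac fundamental beats its harmonics even when both lie in band.
    With ``refine`` the discrete ridge bin is replaced by the reassigned
    bin's mean instantaneous-frequency estimate, giving sub-bin
    resolution.

    Quality is the ridge magnitude over the total in-band magnitude; a
    column is reliable when quality clears ``quality_floor`` *and* the
    in-band magnitude is at least ``band_energy_floor`` of the whole
    column (so a record with no cardiac-band energy — e.g. respiration
    only — is flagged).
    """
    f_lo, f_hi = band
    in_band = (sst.freqs >= f_lo) & (sst.freqs <= f_hi)
    if not np.any(in_band):
        raise DataError("empty cardiac band for this spectrogram")
    band_idx = np.flatnonzero(in_band)
    mag = sst.magnitude
    n_cols = mag.shape[0]

    edge = window_edge = sst.window_len // 2 // max(sst.hop, 1)
    i0 = min(edge, max(0, n_cols - init_block))
    first = mag[i0 : max(i0 + 1, min(i0 + init_block, n_cols))].sum(axis=0)
    # harmonic-aware init: credit each candidate with its first harmonic
    score = first[band_idx].astype(float)
    harm = 2 * band_idx
    ok = harm < mag.shape[1]
    score[ok] += 0.7 * first[harm[ok]]
    prev = band_idx[np.argmax(score)]

    df = sst.freqs[1] - sst.freqs[0]
    jump_bins = max(1, int(round(max_jump_hz / df)))
    ridge = np.empty(n_cols, dtype=np.intp)
    for i in range(n_cols):
        lo = max(band_idx[0], prev - jump_bins)
        hi = min(band_idx[-1], prev + jump_bins)
        window = mag[i, lo : hi + 1]
        prev = lo + int(np.argmax(window))
        ridge[i] = prev

    idx = np.arange(n_cols)
    ridge_mag = mag[idx, ridge]
    total = mag.sum(axis=1)
    in_band_total = mag[:, band_idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(in_band_total > 0, ridge_mag / in_band_total, 0.0)
        band_share = np.where(total > 0, in_band_total / total, 0.0)
    reliable = (quality >= quality_floor) & (band_share >= band_energy_floor)

    hr = sst.freqs[ridge].astype(float)
    if refine and sst.omega_mean is not None:
        refined = sst.omega_mean[idx, ridge]
        ok = refined > 0
        hr[ok] = refined[ok]
    hr = np.clip(hr, f_lo, f_hi)
    return HeartRateRidge(
        times=sst.times,
        hr=hr,
        quality=quality,
        reliable=reliable,
        edge_cols=sst.window_len // 2 // max(sst.hop, 1),
    )


def segment_beats(
    ridge: HeartRateRidge,
    n_frames: int,
    frame_rate: float,
    anchor_signal: np.ndarray | None = None,
    max_unreliable: float = 0.5,
    n_anchor_offsets: int = 48,
    snap_radius_frac: float = 0.25,
) -> list[BeatInterval]:
    """Cut the record into beats at 2*pi crossings of the cardiac phase.

    The cumulative phase is ``phi(t) = 2 pi * integral(hr dt)`` (trapezoid
    rule on the ridge; the HR estimate within half an analysis window of
    the record edges is held at the nearest interior value).  Boundaries
    are placed where ``phi`` crosses successive multiples of 2*pi, snapped
    to the nearest frame (ties to the earlier frame).

    When ``anchor_signal`` is given (conventionally the *negated* upstroke
    feature of :func:`upstroke_feature`, so that minima mark the systolic
    upstroke), a constant phase offset is first chosen that minimizes the
    mean anchor value at the boundaries, then each boundary is snapped to
    the local anchor minimum within ``snap_radius_frac`` of the median beat
    length — absorbing the slow phase drift that beat-to-beat heart-rate
    jitter induces in the integrated ridge.
    """
    if n_frames <= 0:
        return []
    if ridge.unreliable_fraction > max_unreliable:
        raise DataError(
            f"ridge unreliable over {ridge.unreliable_fraction:.0%} of the record"
        )
    hr = ridge.hr.copy()
    e = ridge.edge_cols
    if e and len(hr) > 2 * e:
        hr[:e] = hr[e]
        hr[-e:] = hr[-e - 1]
    hr_at_frame = np.interp(np.arange(n_frames) / frame_rate, ridge.times, hr)
    # phase in cycles at each frame
    phase = np.concatenate(
        [[0.0], np.cumsum((hr_at_frame[1:] + hr_at_frame[:-1]) / 2.0)]
    ) / frame_rate

    def boundaries_for(offset: float) -> np.ndarray:
        ph = phase + offset
        first = int(np.ceil(ph[0]))
        last = int(np.floor(ph[-1]))
        if last < first:
            return np.zeros(0, dtype=np.intp)
        targets = np.arange(first, last + 1, dtype=float)
        # phase is nondecreasing: invert by interpolation, snap to frame
        idx = np.interp(targets, ph, np.arange(n_frames))
        # nearest frame, ties to the earlier frame
        snapped = np.floor(idx + 0.5 - 1e-12).astype(np.intp)
        return np.unique(np.clip(snapped, 0, n_frames - 1))

    offset = 0.0
    if anchor_signal is not None:
        anchor_signal = np.asarray(anchor_signal, dtype=float)
        best_score = np.inf
        for cand in np.linspace(0.0, 1.0, n_anchor_offsets, endpoint=False):
            b = boundaries_for(cand)
            if len(b) < 2:
                continue
            score = float(np.mean(anchor_signal[b]))
            if score < best_score:
                best_score = score
                offset = float(cand)

    bounds = boundaries_for(offset)
    if anchor_signal is not None and len(bounds) > 2:
        radius = max(
            1, int(round(snap_radius_frac * float(np.median(np.diff(bounds)))))
        )
        snapped = []
        for b in bounds:
            lo = max(0, b - radius)
            hi = min(n_frames, b + radius + 1)
            snapped.append(lo + int(np.argmin(anchor_signal[lo:hi])))
        bounds = np.unique(snapped)
    return [
        BeatInterval(int(b0), int(b1))
        for b0, b1 in zip(bounds[:-1], bounds[1:])
        if b1 > b0
    ]


def upstroke_feature(
    signal: np.ndarray,
    frame_rate: float,
    highpass_s: float = 0.45,
    kernel_len: int = 13,
    smooth: int = 3,
) -> np.ndarray:
    """Matched-filter response to the systolic upstroke.

    The global signal is high-passed by subtracting a short moving average
    (suppressing respiration), then correlated with a rising-edge kernel
    (a half-period sine ramp).  The response peaks at the steepest point of
    each beat's upstroke — the most sharply localizable landmark of the
    cardiac waveform, used as the within-cycle beat anchor.
    """
    signal = np.asarray(signal, dtype=float)
    size = max(2, int(round(highpass_s * frame_rate)))
    hp = signal - uniform_filter1d(signal, size=size, mode="nearest")
    kernel = np.sin(np.linspace(-np.pi / 2, np.pi / 2, kernel_len))
    feat = np.correlate(hp, kernel, mode="same")
    if smooth > 1:
        feat = uniform_filter1d(feat, size=smooth, mode="nearest")
    return feat


def detect_beats(
    eit: EitFrameSeries,
    band: tuple[float, float] = CARDIAC_BAND,
    window_len: int = 256,
    hop: int = 1,
    **ridge_kwargs,
) -> tuple[list[BeatInterval], HeartRateRidge]:
    """Full EIT-only beat detection chain for one recording.

    Composes :func:`global_signal`, :func:`fsst`, :func:`track_ridge` and
    :func:`segment_beats` anchored on the upstroke feature.  Returns the
    beat intervals and the heart-rate ridge.
    """
    gs = global_signal(eit)
    sst = fsst(gs, eit.frame_rate, window_len=window_len, hop=hop)
    ridge = track_ridge(sst, band=band, **ridge_kwargs)
    feat = upstroke_feature(gs, eit.frame_rate)
    intervals = segment_beats(
        ridge, eit.n_frames, eit.frame_rate, anchor_signal=-feat
    )
    return intervals, ridge


def exclude_premature(
    intervals: list[BeatInterval],
    ratio: float = 0.75,
    n_neighbors: int = 10,
) -> tuple[list[BeatInterval], list[dict]]:
    """Drop premature beats and their two flanking beats.

    A beat is premature when its length falls below ``ratio`` times the
    median length of its ``n_neighbors`` nearest neighbors.  The log lists
    each removed beat with its reason.
    """
    n = len(intervals)
    if n < 3:
        return list(intervals), []
    lengths = np.array([iv.length for iv in intervals], dtype=float)
    half = n_neighbors // 2
    premature = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = np.concatenate([lengths[lo:i], lengths[i + 1 : hi]])
        if len(neigh) and lengths[i] < ratio * np.median(neigh):
            premature[i] = True
    drop = premature.copy()
    drop[:-1] |= premature[1:]
    drop[1:] |= premature[:-1]
    log = []
    for i in np.flatnonzero(drop):
        reason = (
            "premature"
            if premature[i]
            else "flanking a premature beat"
        )
        log.append({"beat_index": int(i), "length": int(lengths[i]), "reason": reason})
    return [iv for i, iv in enumerate(intervals) if not drop[i]], log


def extract_segment(
    eit: EitFrameSeries, interval: BeatInterval, max_frames: int = MAX_BEAT_FRAMES
) -> np.ndarray:
    """Slice one beat's raw (length x 1024) frame block.

    Beats longer than ``max_frames`` frames are rejected as overlong.
    """
    if interval.start < 0 or interval.end > eit.n_frames:
        raise DataError(
            f"interval [{interval.start}, {interval.end}) outside record "
            f"of {eit.n_frames} frames"
        )
    if interval.length > max_frames:
        raise BeatRejected("overlong")
    return eit.values[interval.start : interval.end]


def match_beats(
    truth_bounds_frames: np.ndarray,
    intervals: list[BeatInterval],
    tol_frames: float = 2.0,
) -> float:
    """Fraction of ground-truth beats recovered within a boundary tolerance.

    A truth beat (a pair of consecutive truth boundaries, in frames) counts
    as recovered when some detected interval has both its start and end
    within ``tol_frames`` of the truth pair.
    """
    truth_bounds_frames = np.asarray(truth_bounds_frames, dtype=float)
    n_truth = len(truth_bounds_frames) - 1
    if n_truth < 1 or not intervals:
        return 0.0
    starts = np.array([iv.start for iv in intervals], dtype=float)
    ends = np.array([iv.end for iv in intervals], dtype=float)
    recovered = 0
    for b0, b1 in zip(truth_bounds_frames[:-1], truth_bounds_frames[1:]):
        err = np.maximum(np.abs(starts - b0), np.abs(ends - b1))
        if np.min(err) <= tol_frames:
            recovered += 1
    return recovered / n_truth
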