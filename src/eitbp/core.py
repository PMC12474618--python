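"""Core data containers shared across the pipeline.

All traces live on one of two timebases: the physiological 1 kHz clock
(authoritative) and the EIT frame clock at 47.68 Hz.  EIT frames are mapped
onto the 1 kHz clock by :func:`eitbp.ingest.synchronize` using the timing
reference channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: EIT frame rate of the acquisition device, Hz.
EIT_FRAME_RATE = 47.68
#: Number of raw voltage values per EIT frame (32-electrode belt).
N_CHANNELS = 1024
#: Sampling rate of the physiological (pressure / sync) channels, Hz.
PHYSIO_RATE = 1000


class DataError(ValueError):
    """Malformed or inconsistent recording data."""


class SynchronizationError(DataError):
    """EIT frames and sync pulses cannot be aligned."""


@dataclass
class EitFrameSeries:
    """Time-ordered raw EIT voltage frames.

    Parameters
    ----------
    values : ndarray, shape (n_frames, 1024)
        Real part of the measured voltages, arbitrary units.
    frame_rate : float
        Nominal frame rate in Hz.
    frame_times : ndarray or None
        Frame times on the physiological 1 kHz timebase, seconds.  ``None``
        until the series has been synchronized.
    """

    values: np.ndarray
    frame_rate: float = EIT_FRAME_RATE
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != N_CHANNELS:
            raise DataError(
                f"EIT frames must have {N_CHANNELS} values per frame, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("EIT frames contain non-finite values")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != len(self.values):
                raise DataError("frame_times length does not match frame count")
            if len(self.frame_times) > 1 and np.any(np.diff(self.frame_times) <= 0):
                raise DataError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class PressureTrace:
    """A 1 kHz pressure trace in mmHg starting at time ``t0`` (seconds)."""

    samples: np.ndarray
    t0: float = 0.0
    rate: int = PHYSIO_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate != PHYSIO_RATE:
            raise DataError(f"pressure traces are fixed at {PHYSIO_RATE} Hz")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("pressure trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the trace at arbitrary times."""
        return np.interp(t, self.times, self.samples)


@dataclass
class SyncTrack:
    """Timing-reference pulse channel sampled at 1 kHz.

    One rising edge is emitted per EIT frame; ``detected_edges`` holds the
    sample indices of detected rising edges (filled by edge detection).
    """

    samples: np.ndarray
    t0: float = 0.0
    rate: int = PHYSIO_RATE
    detected_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.detected_edges is not None:
            self.detected_edges = np.asarray(self.detected_edges, dtype=np.int64)
            if np.any(np.diff(self.detected_edges) <= 0):
                raise DataError("detected_edges must be strictly increasing")


@dataclass
class ReferenceBeats:
    """Beat-sparse fluid-filled catheter reference.

    The fluid-filled catheter is stable over time (no drift) but only
    per-beat values are retained: the beat onset time and the diastolic
    pressure at that onset, which anchors the drift recalibration of the
    high-fidelity trace.
    """

    times: np.ndarray  # beat onset times, s
    dap: np.ndarray  # mmHg

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dap = np.asarray(self.dap, dtype=float)
        if len(self.times) != len(self.dap):
            raise DataError("reference beat times/values length mismatch")


@dataclass
class GroundTruth:
    """Simulator ground truth for one subject.

    Beat boundaries are stored on both timebases: ``beat_bounds`` are the
    diastolic-foot onsets in the pressure timebase (seconds) and
    ``eit_bounds`` are the corresponding arrival times of the cardiac
    signature in the EIT signal (seconds; shifted by the pressure-dependent
    pulse-arrival delay).  ``sap``/``map``/``dap`` are per-beat labels for
    the beats starting at ``beat_bounds[:-1]``.
    """

    beat_bounds: np.ndarray
    eit_bounds: np.ndarray
    sap: np.ndarray
    map: np.ndarray
    dap: np.ndarray

    def __post_init__(self) -> None:
        for name in ("beat_bounds", "eit_bounds", "sap", "map", "dap"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.n_beats < 1:
            raise DataError("ground truth must contain at least one beat")
        if np.any(np.diff(self.beat_bounds) <= 0):
            raise DataError("beat boundaries must be strictly increasing")
        if not (
            np.all(self.dap < self.map) and np.all(self.map < self.sap)
        ):
            raise DataError("ground truth labels must satisfy DAP < MAP < SAP")

    @property
    def n_beats(self) -> int:
        return len(self.sap)


@dataclass
class SubjectRecording:
    """All synchronized streams of a single subject plus ground truth."""

    subject_id: str
    eit: EitFrameSeries
    sync: SyncTrack
    pressure_millar: PressureTrace
    reference: ReferenceBeats
    truth: GroundTruth | None = None
    #: Start/end times of measuring sequences (manual trigger marks), s.
    segment_bounds: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.segment_bounds = np.asarray(self.segment_bounds, dtype=float)


@dataclass
class StudyBundle:
    """A cohort of subject recordings with provenance metadata."""

    subjects: list[SubjectRecording]
    seed: int | None = None
    config_hash: str | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DataError("no subjects in bundle")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject ids in bundle")

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]
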