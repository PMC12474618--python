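"""Beat-block assembly: labels, normalization, padding, dataset building.

Turns raw per-beat EIT frame blocks and the recalibrated pressure trace
into fixed-size model inputs.  Per-beat processing order (important — the
zero padding must stay exactly zero):

1. label the beat from the pressure trace (SAP = beat maximum, DAP = onset
   minimum, MAP = arithmetic mean between the bounding minima);
2. block-wise z-score of the *unpadded* length x 1024 block (one scalar
   mean and SD over all entries);
3. pad (or resample) to 64 x 1024;
4. normalize labels to [0, 1] with training-split min/max bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from eitbp.core import DataError, PressureTrace
from eitbp.beatseg import (
    BeatInterval,
    BeatRejected,
    MAX_BEAT_FRAMES,
    exclude_premature,
    extract_segment,
)

__all__ = [
    "BeatRecord",
    "BeatDataset",
    "beat_labels",
    "blockwise_znorm",
    "pad_to_64",
    "normalize_labels",
    "denormalize_labels",
    "assemble_dataset",
]

log = logging.getLogger(__name__)

BLOCK_FRAMES = MAX_BEAT_FRAMES  # 64


class DegenerateBlockError(DataError):
    """Block has zero variance and cannot be z-scored."""


@dataclass
class BeatRecord:
    """One heartbeat: normalized 64x1024 block plus labels."""

    block: np.ndarray
    raw_length: int
    subject_id: str
    t_start: float
    labels_mmHg: np.ndarray  # (SAP, MAP, DAP)

    def __post_init__(self) -> None:
        if self.block.shape != (BLOCK_FRAMES, 1024):
            raise DataError(f"block must be {BLOCK_FRAMES}x1024, got {self.block.shape}")
        sap, map_, dap = self.labels_mmHg
        if not dap <= map_ <= sap:
            raise DataError("labels must satisfy DAP <= MAP <= SAP")


@dataclass
class BeatDataset:
    """A stack of beat records with per-subject bookkeeping.

    ``blocks`` is (n, 64, 1024) float32; ``labels_mmHg`` is (n, 3) in the
    order (SAP, MAP, DAP).  Label normalization bounds are *not* stored
    here — they are recomputed per cross-validation fold from that fold's
    training split (see :func:`label_bounds`) to avoid test-subject
    leakage.
    """

    blocks: np.ndarray
    labels_mmHg: np.ndarray
    subject_ids: np.ndarray
    t_start: np.ndarray
    raw_lengths: np.ndarray
    exclusion_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.blocks)
        if not (
            len(self.labels_mmHg) == len(self.subject_ids)
            == len(self.t_start) == len(self.raw_lengths) == n
        ):
            raise DataError("dataset field lengths disagree")

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(str(s) for s in self.subject_ids))

    def subject_mask(self, subject_id: str) -> np.ndarray:
        return np.asarray(self.subject_ids) == subject_id

    def counts_per_subject(self) -> dict[str, int]:
        return {s: int(self.subject_mask(s).sum()) for s in self.subjects}


def beat_labels(
    pressure: PressureTrace,
    interval_time: tuple[float, float],
    search_window_s: float = 0.2,
) -> tuple[float, float, float]:
    """Extract (SAP, MAP, DAP) for one beat from a pressure trace.

    The beat onset and end minima are located as the trace minima within
    ``search_window_s`` of the interval's endpoints; SAP is the maximum
    between the bounding minima, DAP the value at the onset minimum, and
    MAP the arithmetic mean of all 1 kHz samples between the two minima
    (inclusive).
    """
    t0, t1 = interval_time
    if t1 - t0 < 0.2:
        raise DataError(f"beat interval [{t0:.3f}, {t1:.3f}) shorter than 200 ms")
    n = len(pressure.samples)
    w = int(round(search_window_s * pressure.rate))

    def local_min(t: float) -> int:
        i = int(round((t - pressure.t0) * pressure.rate))
        lo, hi = max(0, i - w), min(n, i + w + 1)
        if hi <= lo:
            raise DataError("beat interval outside pressure trace")
        return lo + int(np.argmin(pressure.samples[lo:hi]))

    m0 = local_min(t0)
    m1 = local_min(t1)
    if m1 <= m0:
        raise DataError("degenerate beat: bounding minima collapse")
    seg = pressure.samples[m0 : m1 + 1]
    sap = float(np.max(seg))
    dap = float(pressure.samples[m0])
    if sap <= max(dap, float(seg[-1])) + 1e-12:
        raise DataError("no interior maximum in beat interval")
    map_ = float(np.mean(seg))
    return sap, map_, dap


def blockwise_znorm(block: np.ndarray) -> np.ndarray:
    """Z-score a whole block with one scalar mean and one scalar SD.

    The output has mean 0 and population SD 1 over all entries.  A block
    with zero variance cannot carry information and is rejected.
    """
    block = np.asarray(block, dtype=np.float64)
    mean = block.mean()
    sd = block.std()
    if sd <= 0 or not np.isfinite(sd):
        raise DegenerateBlockError("block has zero standard deviation")
    return (block - mean) / sd


def pad_to_64(block: np.ndarray, mode: str = "zeropad") -> np.ndarray:
    """Bring a length x 1024 block to exactly 64 x 1024.

    ``zeropad`` appends all-zero frames (rows [length, 64) exactly zero);
    ``resample`` linearly interpolates each channel from ``length`` to 64
    samples.
    """
    block = np.asarray(block)
    length = block.shape[0]
    if length == BLOCK_FRAMES:
        return block.copy()
    if mode == "zeropad":
        if length > BLOCK_FRAMES:
            raise DataError(f"block of {length} frames exceeds {BLOCK_FRAMES} (zeropad)")
        out = np.zeros((BLOCK_FRAMES, block.shape[1]), dtype=block.dtype)
        out[:length] = block
        return out
    if mode == "resample":
        x_old = np.linspace(0.0, 1.0, length)
        x_new = np.linspace(0.0, 1.0, BLOCK_FRAMES)
        out = np.empty((BLOCK_FRAMES, block.shape[1]), dtype=np.float64)
        for c in range(block.shape[1]):
            out[:, c] = np.interp(x_new, x_old, block[:, c])
        return out
    raise DataError(f"unknown pad mode {mode!r}")


def label_bounds(labels_mmHg: np.ndarray) -> np.ndarray:
    """Per-target (min, max) over a set of labels; shape (3, 2)."""
    labels_mmHg = np.asarray(labels_mmHg, dtype=float)
    bounds = np.stack([labels_mmHg.min(axis=0), labels_mmHg.max(axis=0)], axis=1)
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise DataError("degenerate label bounds (max <= min)")
    return bounds


def normalize_labels(labels_mmHg: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Map labels to [0, 1] per target: y = (x - min) / (max - min).

    Bounds must come from the training split only.  Out-of-bounds labels
    (possible on held-out subjects) map outside [0, 1] and are *not*
    clipped — the inverse stays exact.
    """
    bounds = np.asarray(bounds, dtype=float)
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise DataError("degenerate label bounds")
    lo, hi = bounds[:, 0], bounds[:, 1]
    return (np.asarray(labels_mmHg, dtype=float) - lo) / (hi - lo)


def denormalize_labels(labels_norm: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_labels`."""
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    return np.asarray(labels_norm, dtype=float) * (hi - lo) + lo


def assemble_dataset(
    subjects,
    intervals_per_subject: dict[str, list[BeatInterval]],
    pressure_per_subject: dict[str, PressureTrace] | None = None,
    pad_mode: str = "zeropad",
    premature_ratio: float = 0.75,
) -> BeatDataset:
    """Build a :class:`BeatDataset` from segmented recordings.

    ``subjects`` is an iterable of :class:`~eitbp.core.SubjectRecording`
    whose EIT series have synchronized ``frame_times``;
    ``pressure_per_subject`` supplies the (recalibrated) label source,
    defaulting to each recording's Millar trace.  Per-beat failures
    (overlong, degenerate, unlabelable) are logged and skipped.
    """
    blocks, labels, sids, tstarts, lengths = [], [], [], [], []
    exclusions: list[dict] = []
    for rec in subjects:
        if rec.eit.frame_times is None:
            raise DataError(f"subject {rec.subject_id!r}: EIT not synchronized")
        pressure = (
            pressure_per_subject[rec.subject_id]
            if pressure_per_subject is not None
            else rec.pressure_millar
        )
        intervals = intervals_per_subject[rec.subject_id]
        kept, log_rows = exclude_premature(intervals, ratio=premature_ratio)
        for row in log_rows:
            row["subject_id"] = rec.subject_id
        exclusions.extend(log_rows)
        n_ok = 0
        for iv in kept:
            t0 = float(rec.eit.frame_times[iv.start])
            t1 = float(
                rec.eit.frame_times[iv.end]
                if iv.end < rec.eit.n_frames
                else rec.eit.frame_times[-1] + 1.0 / rec.eit.frame_rate
            )
            try:
                raw = extract_segment(rec.eit, iv)
                sap, map_, dap = beat_labels(pressure, (t0, t1))
                normed = blockwise_znorm(raw)
            except (BeatRejected, DataError) as exc:
                exclusions.append(
                    {
                        "subject_id": rec.subject_id,
                        "beat_index": iv.start,
                        "length": iv.length,
                        "reason": str(getattr(exc, "reason", exc)),
                    }
                )
                continue
            blocks.append(pad_to_64(normed, mode=pad_mode).astype(np.float32))
            labels.append((sap, map_, dap))
            sids.append(rec.subject_id)
            tstarts.append(t0)
            lengths.append(iv.length)
            n_ok += 1
        if n_ok == 0:
            log.warning("subject %s contributed zero beats", rec.subject_id)
    if not blocks:
        raise DataError("assembled dataset is empty")
    return BeatDataset(
        blocks=np.stack(blocks),
        labels_mmHg=np.asarray(labels, dtype=float),
        subject_ids=np.asarray(sids),
        t_start=np.asarray(tstarts, dtype=float),
        raw_lengths=np.asarray(lengths, dtype=np.int64),
        exclusion_log=exclusions,
    )
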