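"""Bundle I/O, EIT/physiology synchronization and drift recalibration.

The physiological 1 kHz clock is authoritative.  EIT frames carry no usable
absolute clock, so the acquisition device emits one pulse per frame on a
dedicated timing-reference channel; :func:`synchronize` maps each frame onto
the 1 kHz timebase via the rising edges of that channel.

The high-fidelity intravascular ("Millar-like") pressure trace drifts over
time, so :func:`recalibrate_millar` re-anchors it, segment by segment, to
the diastolic values of the stable fluid-filled reference catheter.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from eitbp.core import (
    N_CHANNELS,
    DataError,
    EitFrameSeries,
    GroundTruth,
    PressureTrace,
    ReferenceBeats,
    StudyBundle,
    SubjectRecording,
    SyncTrack,
    SynchronizationError,
)

__all__ = [
    "write_bundle",
    "read_bundle",
    "detect_edges",
    "synchronize",
    "recalibrate_millar",
]


def write_bundle(bundle: StudyBundle, path) -> None:
    """Write a study bundle to an HDF5 container.

    Layout: ``/subjects/<id>/{eit, sync, pressure_millar, reference/*,
    truth/*, segment_bounds}`` plus root attributes for seed and provenance.
    """
    with h5py.File(path, "w") as f:
        if bundle.seed is not None:
            f.attrs["seed"] = int(bundle.seed)
        if bundle.config_hash is not None:
            f.attrs["config_hash"] = bundle.config_hash
        grp = f.create_group("subjects")
        for rec in bundle:
            g = grp.create_group(rec.subject_id)
            g.create_dataset("eit", data=rec.eit.values)
            g.attrs["frame_rate"] = rec.eit.frame_rate
            if rec.eit.frame_times is not None:
                g.create_dataset("frame_times", data=rec.eit.frame_times)
            g.create_dataset("sync", data=rec.sync.samples)
            g.create_dataset("pressure_millar", data=rec.pressure_millar.samples)
            g.attrs["pressure_t0"] = rec.pressure_millar.t0
            ref = g.create_group("reference")
            ref.create_dataset("times", data=rec.reference.times)
            ref.create_dataset("dap", data=rec.reference.dap)
            g.create_dataset("segment_bounds", data=rec.segment_bounds)
            if rec.truth is not None:
                tr = g.create_group("truth")
                for name in ("beat_bounds", "eit_bounds", "sap", "map", "dap"):
                    tr.create_dataset(name, data=getattr(rec.truth, name))


def read_bundle(path) -> StudyBundle:
    """Read a study bundle written by :func:`write_bundle` (lossless)."""
    subjects = []
    with h5py.File(path, "r") as f:
        if "subjects" not in f:
            raise DataError("no subjects group in bundle")
        grp = f["subjects"]
        if len(grp) == 0:
            raise DataError("no subjects in bundle")
        for sid in grp:
            g = grp[sid]
            eit_values = g["eit"][()]
            if eit_values.ndim != 2 or eit_values.shape[1] != N_CHANNELS:
                raise DataError(
                    f"subject {sid!r}: EIT matrix must have {N_CHANNELS} "
                    f"columns, got shape {eit_values.shape}"
                )
            eit = EitFrameSeries(
                values=eit_values,
                frame_rate=float(g.attrs["frame_rate"]),
                frame_times=g["frame_times"][()] if "frame_times" in g else None,
            )
            truth = None
            if "truth" in g:
                tr = g["truth"]
                truth = GroundTruth(
                    **{
                        name: tr[name][()]
                        for name in ("beat_bounds", "eit_bounds", "sap", "map", "dap")
                    }
                )
            subjects.append(
                SubjectRecording(
                    subject_id=sid,
                    eit=eit,
                    sync=SyncTrack(samples=g["sync"][()]),
                    pressure_millar=PressureTrace(
                        samples=g["pressure_millar"][()],
                        t0=float(g.attrs["pressure_t0"]),
                    ),
                    reference=ReferenceBeats(
                        times=g["reference/times"][()],
                        dap=g["reference/dap"][()],
                    ),
                    truth=truth,
                    segment_bounds=g["segment_bounds"][()],
                )
            )
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        config_hash = f.attrs.get("config_hash", None)
    return StudyBundle(subjects=subjects, seed=seed, config_hash=config_hash)


def detect_edges(sync: SyncTrack) -> np.ndarray:
    """Detect rising edges at 50% of the channel's (max - min) range."""
    x = sync.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo <= 0:
        raise SynchronizationError("no edges detected: sync channel is constant")
    thresh = lo + 0.5 * (hi - lo)
    above = x >= thresh
    edges = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if edges.size == 0:
        raise SynchronizationError("no edges detected")
    return edges


def synchronize(eit: EitFrameSeries, sync: SyncTrack) -> EitFrameSeries:
    """Assign frame times from the sync channel's rising edges.

    One rising edge is expected per frame; a count mismatch aborts rather
    than guessing an alignment.  Idempotent: re-running on an already
    synchronized series yields identical frame times.
    """
    edges = detect_edges(sync)
    if len(edges) != eit.n_frames:
        raise SynchronizationError(
            f"edge count mismatch: {eit.n_frames} frames vs {len(edges)} "
            "rising edges"
        )
    sync.detected_edges = edges
    frame_times = sync.t0 + edges / sync.rate
    return EitFrameSeries(
        values=eit.values, frame_rate=eit.frame_rate, frame_times=frame_times
    )


def recalibrate_millar(
    millar: PressureTrace,
    reference: ReferenceBeats,
    segment_bounds: np.ndarray | None = None,
    search_window_s: float = 0.15,
) -> tuple[PressureTrace, pd.DataFrame]:
    """Re-anchor a drifting trace to the fluid-filled DAP reference.

    For each measuring segment a constant offset is estimated as the mean,
    over the segment's reference beats, of (reference DAP - trace DAP at
    that beat); the trace DAP is the local minimum within
    ``search_window_s`` of the reference beat onset.  The offset is added to
    the whole segment, so within-segment pulse pressure is untouched and the
    mean per-segment DAP discrepancy vanishes by construction.

    Returns the corrected trace and a per-beat offset table
    (columns: time, segment, millar_dap, reference_dap, offset).
    """
    t_end = millar.t0 + millar.duration
    if segment_bounds is None or len(segment_bounds) < 2:
        segment_bounds = np.array([millar.t0, t_end])
    segment_bounds = np.asarray(segment_bounds, dtype=float)

    in_span = (reference.times >= millar.t0) & (reference.times < t_end)
    if not np.any(in_span):
        raise DataError("no reference beats overlap the trace")

    w = int(round(search_window_s * millar.rate))
    n = len(millar.samples)
    corrected = millar.samples.copy()
    rows = []
    for si in range(len(segment_bounds) - 1):
        s0, s1 = segment_bounds[si], segment_bounds[si + 1]
        last = si == len(segment_bounds) - 2
        sel = in_span & (reference.times >= s0) & (
            (reference.times <= s1) if last else (reference.times < s1)
        )
        if not np.any(sel):
            continue
        offsets = []
        for t_b, dap_ref in zip(reference.times[sel], reference.dap[sel]):
            i = int(round((t_b - millar.t0) * millar.rate))
            lo, hi = max(0, i - w), min(n, i + w + 1)
            dap_m = float(np.min(millar.samples[lo:hi]))
            offsets.append(dap_ref - dap_m)
            rows.append(
                {
                    "time": t_b,
                    "segment": si,
                    "millar_dap": dap_m,
                    "reference_dap": dap_ref,
                    "offset": dap_ref - dap_m,
                }
            )
        offset = float(np.mean(offsets))
        i0 = int(round((s0 - millar.t0) * millar.rate))
        i1 = n if last else int(round((s1 - millar.t0) * millar.rate))
        corrected[max(0, i0) : i1] += offset
    return (
        PressureTrace(samples=corrected, t0=millar.t0),
        pd.DataFrame(rows),
    )
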