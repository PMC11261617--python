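"""Binding-event detection and per-event apparent FRET efficiency.

A binding event is a contiguous run of frames during which the summed
donor+acceptor intensity sits above the dark baseline.  Each event is scored
by the mean of the per-frame apparent efficiency I_A/(I_A+I_D) over its
frames ("averaged FRET value per event").  No gamma, leakage, or
direct-excitation corrections are applied: the apparent efficiency is the
modeled quantity throughout the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .sim_kinetics import IntensityTrace

EVENT_COLUMNS = ["molecule_id", "start_frame", "end_frame", "n_frames", "mean_I_D", "mean_I_A", "E_app", "E_sd"]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding parameters for event calling.

    Baseline and noise SD are estimated by iterative sigma-clipping of the
    total-intensity distribution (bound frames are clipped away, leaving an
    unbiased estimate of the dark level); if clipping removes almost all
    frames, the lowest ``baseline_quantile`` of frames is used instead.
    Frames with total intensity above baseline + threshold_k * SD are "on".
    Runs shorter than min_frames are discarded; on-runs separated by fewer
    than gap_frames off-frames are merged.
    """

    threshold_k: float = 3.0
    baseline_quantile: float = 0.20
    min_frames: int = 3
    gap_frames: int = 1
    clip_iterations: int = 10

    def __post_init__(self):
        if not 0 < self.baseline_quantile < 1:
            raise ValueError("baseline_quantile must be in (0, 1)")
        if self.min_frames < 1 or self.gap_frames < 0:
            raise ValueError("min_frames >= 1 and gap_frames >= 0 required")


@dataclass(frozen=True)
class BindingEvent:
    """One contiguous binding event; frames are 0-based, both ends inclusive."""

    molecule_id: str
    start_frame: int
    end_frame: int
    mean_I_D: float
    mean_I_A: float
    e_app: float
    n_frames: int
    e_sd: float = 0.0

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if self.n_frames != self.end_frame - self.start_frame + 1:
            raise ValueError("n_frames inconsistent with frame interval")
        if not 0.0 <= self.e_app <= 1.0:
            raise ValueError("E_app must lie in [0, 1]")


@dataclass
class EventTable:
    events: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.events)

    def e_values(self) -> np.ndarray:
        return np.array([ev.e_app for ev in self.events])

    def molecule_ids(self) -> np.ndarray:
        return np.array([ev.molecule_id for ev in self.events])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (ev.molecule_id, ev.start_frame, ev.end_frame, ev.n_frames, ev.mean_I_D,
             ev.mean_I_A, ev.e_app, ev.e_sd)
            for ev in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    def e_sds(self) -> np.ndarray:
        return np.array([ev.e_sd for ev in self.events])

    def filter_pure(self, max_e_sd: float | None = None, sd_factor: float = 2.5) -> "EventTable":
        """Keep events whose intra-event per-frame E scatter is at the noise
        floor.  Events spanning a binding-state change (e.g. acceptor
        exchange mid-event) mix two FRET levels and show inflated scatter;
        with no explicit threshold, ``sd_factor`` times the median scatter of
        all events is used (most events are pure).
        """
        sds = self.e_sds()
        if len(sds) == 0:
            return EventTable(events=[], provenance=dict(self.provenance))
        if max_e_sd is None:
            max_e_sd = sd_factor * float(np.median(sds))
        kept = [ev for ev in self.events if ev.e_sd <= max_e_sd]
        prov = dict(self.provenance)
        prov["purity_filter"] = {"max_e_sd": float(max_e_sd), "n_before": len(self.events),
                                 "n_after": len(kept)}
        return EventTable(events=kept, provenance=prov)

    def extend(self, other: "EventTable") -> None:
        self.events.extend(other.events)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_tsv(cls, path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        events = [
            BindingEvent(
                str(r.molecule_id), int(r.start_frame), int(r.end_frame),
                float(r.mean_I_D), float(r.mean_I_A), float(r.E_app), int(r.n_frames),
                float(getattr(r, "E_sd", 0.0)),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, provenance={"source": str(path)})


def event_fret(i_d: np.ndarray, i_a: np.ndarray, with_sd: bool = False):
    """Averaged per-frame apparent efficiency over one event.

    Frames with non-positive total intensity are excluded; returns None when
    no frame is usable.  The per-frame mean (not ratio of channel means) is
    used, so noisy low-intensity frames weight equally with bright ones.
    With ``with_sd`` the per-frame scatter is also returned (a purity
    diagnostic: pure single-pair events scatter at the noise floor).
    """
    i_d = np.asarray(i_d, dtype=float)
    i_a = np.asarray(i_a, dtype=float)
    total = i_d + i_a
    valid = total > 0
    if not valid.any():
        return (None, None) if with_sd else None
    e = i_a[valid] / total[valid]
    e_mean = float(np.clip(np.mean(e), 0.0, 1.0))
    if with_sd:
        return e_mean, float(np.std(e))
    return e_mean


def _estimate_baseline(total: np.ndarray, params: DetectionParams):
    """Dark-level mean and SD by robust sigma-clipping of the total
    intensity: bound frames are clipped away using the median and the
    MAD-based SD (insensitive to the bound population), then the dark level
    is the mean/SD of the surviving frames."""
    keep = np.ones(len(total), dtype=bool)
    for _ in range(params.clip_iterations):
        vals = total[keep]
        med = float(np.median(vals))
        sd = 1.4826 * float(np.median(np.abs(vals - med)))
        new_keep = total <= med + params.threshold_k * sd
        if new_keep.mean() < params.baseline_quantile:
            # clipping collapsed (e.g. mostly-bound trace): fall back to the
            # lowest-quantile frames
            cutoff = np.quantile(total, params.baseline_quantile)
            new_keep = total <= cutoff
            keep = new_keep
            break
        if (new_keep == keep).all():
            keep = new_keep
            break
        keep = new_keep
    vals = total[keep]
    return float(vals.mean()), float(vals.std())


def _runs(mask: np.ndarray) -> list:
    """Contiguous True runs as (start, end) inclusive pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def detect_events(trace: IntensityTrace, params: DetectionParams | None = None) -> EventTable:
    """Call binding events on one trace by total-intensity thresholding."""
    params = params or DetectionParams()
    if trace.n_frames < 2:
        raise ValueError("trace must have at least 2 frames")
    total = trace.total()
    baseline, sd = _estimate_baseline(total, params)
    threshold = baseline + params.threshold_k * sd
    runs = _runs(total > threshold)
    merged = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < params.gap_frames:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    events = []
    for start, end in merged:
        if end - start + 1 < params.min_frames:
            continue
        sl = slice(start, end + 1)
        e, e_sd = event_fret(trace.I_D[sl], trace.I_A[sl], with_sd=True)
        if e is None:
            warnings.warn(
                f"event {trace.molecule_id}:{start}-{end} dropped: no frame with positive total intensity"
            )
            continue
        events.append(
            BindingEvent(
                molecule_id=trace.molecule_id,
                start_frame=int(start),
                end_frame=int(end),
                mean_I_D=float(trace.I_D[sl].mean()),
                mean_I_A=float(trace.I_A[sl].mean()),
                e_app=e,
                n_frames=int(end - start + 1),
                e_sd=e_sd,
            )
        )
    prov = {"molecule_id": trace.molecule_id, "params": asdict(params), "n_frames": trace.n_frames}
    return EventTable(events=events, provenance={"traces": [prov]})


def detect_events_all(traces, params: DetectionParams | None = None) -> EventTable:
    """Call events on every trace and pool them into one table."""
    table = EventTable(provenance={"traces": [], "params": asdict(params or DetectionParams())})
    for tr in traces:
        sub = detect_events(tr, params)
        table.events.extend(sub.events)
        table.provenance["traces"].extend(t["molecule_id"] for t in sub.provenance["traces"])
    return table
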