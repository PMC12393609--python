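"""Tail-swing event detection, merging, and classification.

All thresholds are expressed in units of the recording's noise floor (NF),
the RMS of the baseline-corrected tail angle. An event must contain a peak
with |angle| > 3xNF and prominence > NF; events closer than 2 s are merged;
a struggle swings both ways past 10xNF, a flip is one-sided by a 20x ratio
of supra-3xNF angle sums, and everything else is a swim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .tail_kinematics import TailTrace

EVENT_TYPES = ("swim", "left_flip", "right_flip", "struggle")


@dataclass
class NoiseFloor:
    """RMS of the baseline-corrected tail angle, degrees."""

    value_deg: float


@dataclass
class TailEvent:
    onset_s: float
    offset_s: float
    onset_idx: int
    offset_idx: int  # exclusive
    peak_deg: float  # signed value of the largest-|angle| sample
    prominence_deg: float
    peak_pos_deg: float
    peak_neg_deg: float
    angle_sum_pos_deg: float  # sum of samples > +3xNF
    angle_sum_neg_deg: float  # |sum| of samples < -3xNF
    type: str | None = None


@dataclass
class EventSummary:
    counts: dict[str, int]
    durations_s: dict[str, float]
    cumulative_angle_by_type_deg: dict[str, float]
    cumulative_angle_deg: float = 0.0
    n_events: int = 0

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "durations_s": dict(self.durations_s),
            "cumulative_angle_by_type_deg": dict(
                self.cumulative_angle_by_type_deg
            ),
            "cumulative_angle_deg": self.cumulative_angle_deg,
            "n_events": self.n_events,
        }


def noise_floor(trace: TailTrace | np.ndarray) -> NoiseFloor:
    """sqrt(mean(angle^2)) over the whole baseline-corrected trace."""
    x = trace.angle_deg if isinstance(trace, TailTrace) else np.asarray(trace)
    return NoiseFloor(float(np.sqrt(np.mean(np.square(np.abs(x))))))


def _nf_value(nf: NoiseFloor | float) -> float:
    return nf.value_deg if isinstance(nf, NoiseFloor) else float(nf)


def _event_stats(
    x: np.ndarray, fs: float, lo: int, hi: int, nf: float, flip_floor_k: float
) -> TailEvent:
    seg = x[lo:hi]
    i = int(np.argmax(np.abs(seg)))
    pos = seg[seg > flip_floor_k * nf]
    neg = seg[seg < -flip_floor_k * nf]
    return TailEvent(
        onset_s=lo / fs,
        offset_s=hi / fs,
        onset_idx=lo,
        offset_idx=hi,
        peak_deg=float(seg[i]),
        prominence_deg=float(np.abs(seg[i])),
        peak_pos_deg=float(seg.max()),
        peak_neg_deg=float(seg.min()),
        angle_sum_pos_deg=float(pos.sum()),
        angle_sum_neg_deg=float(abs(neg.sum())),
    )


def detect_events(
    trace: TailTrace,
    nf: NoiseFloor | float | None = None,
    peak_k: float = 3.0,
    prominence_k: float = 1.0,
    flip_floor_k: float = 3.0,
) -> list[TailEvent]:
    """Find raw (unmerged, unclassified) tail-swing events.

    A peak qualifies when |angle| > peak_k x NF with prominence above
    prominence_k x NF (computed on |angle|). Each event extends from the last
    pre-peak crossing of 1xNF to the first post-peak crossing of 1xNF;
    overlapping extents are truncated at the midpoint between adjacent peaks
    so events never overlap. Peaks sharing an extent collapse into one event.
    """
    x = np.asarray(trace.angle_deg, dtype=float)
    fs = trace.frame_rate_hz
    nfv = _nf_value(nf) if nf is not None else noise_floor(trace).value_deg
    if nfv <= 0:
        raise ValueError("noise floor is zero: degenerate trace")
    a = np.abs(x)
    peaks, props = find_peaks(a, height=peak_k * nfv, prominence=prominence_k * nfv)
    if peaks.size == 0:
        return []
    below = a <= nfv
    events: list[tuple[int, int, int, float]] = []  # lo, hi, peak_idx, prom
    for p, prom in zip(peaks, props["prominences"]):
        pre = np.flatnonzero(below[:p])
        lo = int(pre[-1]) + 1 if pre.size else 0
        post = np.flatnonzero(below[p + 1 :])
        hi = p + 1 + int(post[0]) if post.size else x.size
        if events and lo <= events[-1][1]:
            # same sub-NF envelope (or overlap): truncate at the peak midpoint
            plo, phi, pp, pprom = events[-1]
            if hi <= phi and lo >= plo:
                events[-1] = (plo, phi, pp, max(pprom, prom))
                continue
            mid = (pp + p) // 2 + 1
            events[-1] = (plo, min(phi, mid), pp, pprom)
            lo = max(lo, mid)
        events.append((lo, hi, p, float(prom)))
    out = []
    for lo, hi, p, prom in events:
        ev = _event_stats(x, fs, lo, hi, nfv, flip_floor_k)
        ev.prominence_deg = prom
        out.append(ev)
    return out


def merge_events(
    events: list[TailEvent],
    gap_s: float = 2.0,
    trace: TailTrace | None = None,
    nf: NoiseFloor | float | None = None,
    flip_floor_k: float = 3.0,
) -> list[TailEvent]:
    """Merge events whose inter-event gap is below ``gap_s`` (strict <).

    Merging is transitive: a chain of sub-gap events collapses into one.
    When ``trace`` is given the merged event's sample statistics (peaks,
    angle sums) are recomputed over the merged extent; otherwise they are
    combined conservatively from the parts.
    """
    if not events:
        return []
    evs = sorted(events, key=lambda e: e.onset_s)
    merged: list[list[TailEvent]] = [[evs[0]]]
    for ev in evs[1:]:
        if ev.onset_s - merged[-1][-1].offset_s < gap_s:
            merged[-1].append(ev)
        else:
            merged.append([ev])
    out = []
    for group in merged:
        if len(group) == 1:
            out.append(group[0])
            continue
        lo, hi = group[0].onset_idx, group[-1].offset_idx
        if trace is not None:
            nfv = (
                _nf_value(nf)
                if nf is not None
                else noise_floor(trace).value_deg
            )
            ev = _event_stats(
                np.asarray(trace.angle_deg, float),
                trace.frame_rate_hz,
                lo,
                hi,
                nfv,
                flip_floor_k,
            )
            ev.prominence_deg = max(g.prominence_deg for g in group)
        else:
            best = max(group, key=lambda g: abs(g.peak_deg))
            ev = TailEvent(
                onset_s=group[0].onset_s,
                offset_s=group[-1].offset_s,
                onset_idx=lo,
                offset_idx=hi,
                peak_deg=best.peak_deg,
                prominence_deg=max(g.prominence_deg for g in group),
                peak_pos_deg=max(g.peak_pos_deg for g in group),
                peak_neg_deg=min(g.peak_neg_deg for g in group),
                angle_sum_pos_deg=sum(g.angle_sum_pos_deg for g in group),
                angle_sum_neg_deg=sum(g.angle_sum_neg_deg for g in group),
            )
        out.append(ev)
    return out


def classify_event(
    ev: TailEvent,
    nf: NoiseFloor | float,
    struggle_k: float = 10.0,
    flip_ratio: float = 20.0,
) -> str:
    """Assign one of {struggle, left_flip, right_flip, swim} to an event.

    struggle: bidirectional, both extreme excursions beyond struggle_k x NF
    (about 45 deg for a typical ~4.5 deg noise floor). Otherwise a flip when
    the supra-3xNF angle sum on one side exceeds flip_ratio times the other
    side's (a purely one-sided event has an infinite ratio and is a flip).
    Everything else is a swim. Exhaustive and mutually exclusive.
    """
    nfv = _nf_value(nf)
    if ev.peak_pos_deg > struggle_k * nfv and -ev.peak_neg_deg > struggle_k * nfv:
        return "struggle"
    pos, neg = ev.angle_sum_pos_deg, ev.angle_sum_neg_deg
    if pos > flip_ratio * neg and pos > 0:
        return "right_flip"
    if neg > flip_ratio * pos and neg > 0:
        return "left_flip"
    return "swim"


def extract_events(
    trace: TailTrace,
    gap_s: float = 2.0,
    peak_k: float = 3.0,
    prominence_k: float = 1.0,
    struggle_k: float = 10.0,
    flip_ratio: float = 20.0,
    flip_floor_k: float = 3.0,
) -> tuple[list[TailEvent], NoiseFloor]:
    """Detect, merge, and classify all tail-swing events of one recording."""
    nf = noise_floor(trace)
    raw = detect_events(trace, nf, peak_k, prominence_k, flip_floor_k)
    evs = merge_events(raw, gap_s, trace=trace, nf=nf, flip_floor_k=flip_floor_k)
    for ev in evs:
        ev.type = classify_event(ev, nf, struggle_k, flip_ratio)
    return evs, nf


def summarize(events: list[TailEvent], trace: TailTrace) -> EventSummary:
    """Per-type counts, durations, and cumulative |angle| statistics."""
    x = np.abs(np.asarray(trace.angle_deg, dtype=float))
    counts = {t: 0 for t in EVENT_TYPES}
    durs = {t: 0.0 for t in EVENT_TYPES}
    cum = {t: 0.0 for t in EVENT_TYPES}
    for ev in events:
        t = ev.type or "swim"
        counts[t] += 1
        durs[t] += ev.offset_s - ev.onset_s
        cum[t] += float(x[ev.onset_idx : ev.offset_idx].sum())
    return EventSummary(
        counts=counts,
        durations_s=durs,
        cumulative_angle_by_type_deg=cum,
        cumulative_angle_deg=float(x.sum()),
        n_events=len(events),
    )


def events_to_frame(events: list[TailEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "type": e.type,
                "peak_deg": e.peak_deg,
                "prominence_deg": e.prominence_deg,
            }
            for e in events
        ],
        columns=["onset_s", "offset_s", "type", "peak_deg", "prominence_deg"],
    )
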