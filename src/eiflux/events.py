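"""Rain-event detection, pulse decomposition, wet/dry labeling, and the
per-hour rainfall descriptors used as canopy-water-storage predictors.

Event rules
-----------
1. An event opens at the first unconsumed hour with P >= 0.5 mm.
2. After each qualifying rain hour a tail of 6 h (12 h if that hour is at
   night) is kept inside the event, because wet-foliage evaporation lags the
   rain; a qualifying hour inside the tail extends the event and restarts the
   tail from itself.
3. Events longer than 60 h (tail included) are re-segmented into sub-events
   that start with P >= 1 mm and are spaced more than 6 h apart, each
   re-receiving its own tail.  A long span with no hour >= 1 mm is discarded
   with a warning.

Within an event, maximal runs of consecutive rainy hours (P > 0) are rain
pulses; non-rain intervals may separate pulses without closing the event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SiteSeries

START_THRESHOLD = 0.5     # mm, rule-1 event start / tail extension
SPLIT_THRESHOLD = 1.0     # mm, rule-3 sub-event start
SPLIT_SPACING = 6         # h, rule-3 spacing
TAIL_DAY, TAIL_NIGHT = 6, 12
MAX_EVENT_HOURS = 60

__all__ = [
    "RainEvent", "HourDescriptors", "detect_events", "split_long_event",
    "label_hours", "compute_descriptors", "descriptor_frame",
]


@dataclass
class RainEvent:
    """A contiguous wet-hour span (inclusive indices) with its rain pulses."""

    start_idx: int
    end_idx: int
    pulses: list[tuple[int, int]] = field(default_factory=list)
    total_p: float = 0.0
    site_id: str = ""
    sub_event_of: int | None = None

    @property
    def duration(self) -> int:
        return self.end_idx - self.start_idx + 1

    def hours(self) -> np.ndarray:
        return np.arange(self.start_idx, self.end_idx + 1)


def _find_pulses(P: np.ndarray, start: int, end: int) -> list[tuple[int, int]]:
    """Maximal runs of P > 0 within [start, end], as inclusive index pairs."""
    pulses = []
    i = start
    while i <= end:
        if P[i] > 0:
            j = i
            while j + 1 <= end and P[j + 1] > 0:
                j += 1
            pulses.append((i, j))
            i = j + 1
        else:
            i += 1
    return pulses


def _close_event(P, night, start, threshold, n, hard_end=None):
    """Scan forward from an opening rain hour, applying the rolling tail.

    Only hours with P >= threshold extend; the tail length is re-read from the
    night mask of each extending hour.  ``hard_end`` caps how far extension
    may look (used when re-segmenting within a long span)."""
    last_rain = start
    tail = TAIL_NIGHT if night[start] else TAIL_DAY
    limit = n - 1 if hard_end is None else min(hard_end, n - 1)
    j = start + 1
    while j <= min(last_rain + tail, limit):
        if P[j] >= threshold:
            last_rain = j
            tail = TAIL_NIGHT if night[j] else TAIL_DAY
        j += 1
    end = min(last_rain + tail, limit)
    return last_rain, end


def detect_events(P, night, site_id: str = "") -> list[RainEvent]:
    """Detect rain events by the greedy left-to-right scan of rules 1-3."""
    P = np.asarray(P, dtype=float)
    night = np.asarray(night, dtype=bool)
    if np.any(P < 0):
        raise ValueError("precipitation must be non-negative")
    if len(night) != len(P):
        raise ValueError("night mask misaligned with P")
    n = len(P)
    events: list[RainEvent] = []
    i = 0
    while i < n:
        if P[i] >= START_THRESHOLD:
            _, end = _close_event(P, night, i, START_THRESHOLD, n)
            ev = RainEvent(start_idx=i, end_idx=end, site_id=site_id)
            ev.pulses = _find_pulses(P, i, end)
            ev.total_p = float(P[i:end + 1].sum())
            events.extend(split_long_event(ev, P, night))
            i = end + 1
        else:
            i += 1
    return events


def split_long_event(event: RainEvent, P, night) -> list[RainEvent]:
    """Re-segment an over-long event; return it unchanged if <= 60 h.

    Sub-events start at hours with P >= 1 mm whose gap from the previous
    qualifying hour exceeds 6 h; each gets the rolling tail anew (extension at
    the 1 mm threshold inside the re-segmentation, never crossing the next
    sub-event's start).  The split is applied once, not recursively.
    """
    P = np.asarray(P, dtype=float)
    night = np.asarray(night, dtype=bool)
    if event.duration <= MAX_EVENT_HOURS:
        return [event]
    n = len(P)
    span = np.arange(event.start_idx, event.end_idx + 1)
    heavy = span[P[span] >= SPLIT_THRESHOLD]
    if len(heavy) == 0:
        warnings.warn(
            f"event [{event.start_idx}, {event.end_idx}] exceeds {MAX_EVENT_HOURS} h "
            f"with no hour >= {SPLIT_THRESHOLD} mm; discarded", stacklevel=2)
        return []
    # group qualifying hours: new sub-event when spaced > 6 h apart
    starts = [int(heavy[0])]
    prev = heavy[0]
    for h in heavy[1:]:
        if h - prev > SPLIT_SPACING:
            starts.append(int(h))
        prev = h
    subs: list[RainEvent] = []
    parent = event.start_idx
    for idx, s in enumerate(starts):
        hard_end = starts[idx + 1] - 1 if idx + 1 < len(starts) else None
        _, end = _close_event(P, night, s, SPLIT_THRESHOLD, n, hard_end=hard_end)
        sub = RainEvent(start_idx=s, end_idx=end, site_id=event.site_id,
                        sub_event_of=parent)
        sub.pulses = _find_pulses(P, s, end)
        sub.total_p = float(P[s:end + 1].sum())
        subs.append(sub)
    return subs


def label_hours(series: SiteSeries, events: list[RainEvent]) -> pd.Series:
    """Label every hour wet (in-event), excluded (failed QC) or dry.

    QC exclusion takes precedence over event membership; labels partition
    the series exactly.
    """
    n = len(series)
    labels = np.full(n, "dry", dtype=object)
    covered = np.zeros(n, dtype=bool)
    for ev in events:
        hrs = ev.hours()
        if covered[hrs].any():
            raise ValueError("overlapping rain events")
        covered[hrs] = True
        labels[hrs] = "wet"
    if "excluded" in series.data.columns:
        labels[series.data["excluded"].to_numpy(dtype=bool)] = "excluded"
    return pd.Series(labels, index=series.data.index, name="label")


@dataclass
class HourDescriptors:
    """The eight per-hour rainfall descriptors (all causal in the event)."""

    cum_p_event: float          # mm since event start
    mean_p_event: float         # mm h-1 since event start
    max_p_event: float          # mm h-1 since event start
    p_now: float                # mm h-1
    cum_p_last_pulse: float     # mm
    max_p_last_pulse: float     # mm h-1
    dry_hours_since_pulse: int  # h; 0 during a pulse
    last_pulse_end_time: float  # local solar hour-of-day in [0, 24)


def compute_descriptors(event: RainEvent, hour_idx: int, P,
                        index: pd.DatetimeIndex) -> HourDescriptors:
    """Descriptors for one in-event hour, using only hours <= hour_idx."""
    if not (event.start_idx <= hour_idx <= event.end_idx):
        raise ValueError("hour outside event")
    P = np.asarray(P, dtype=float)
    seen = P[event.start_idx:hour_idx + 1]
    cum = float(seen.sum())
    nh = hour_idx - event.start_idx + 1
    # last pulse among hours <= hour_idx (ongoing pulse if currently raining)
    pulses = _find_pulses(P, event.start_idx, hour_idx)
    ps, pe = pulses[-1]
    pulse_vals = P[ps:pe + 1]
    dry_since = hour_idx - pe if P[hour_idx] == 0 else 0
    end_ts = index[pe]
    end_time = end_ts.hour + end_ts.minute / 60.0
    return HourDescriptors(
        cum_p_event=cum,
        mean_p_event=cum / nh,
        max_p_event=float(seen.max()),
        p_now=float(P[hour_idx]),
        cum_p_last_pulse=float(pulse_vals.sum()),
        max_p_last_pulse=float(pulse_vals.max()),
        dry_hours_since_pulse=int(dry_since),
        last_pulse_end_time=float(end_time),
    )


def descriptor_frame(events: list[RainEvent], P, index: pd.DatetimeIndex) -> pd.DataFrame:
    """Vectorized-enough table of descriptors for every wet hour of ``events``.

    One row per in-event hour, indexed by timestamp, with an ``event_id``
    column (the event's start index) for later aggregation.
    """
    P = np.asarray(P, dtype=float)
    rows, idx = [], []
    for ev in events:
        cum = 0.0
        mx = 0.0
        last_pulse = None  # (start, end) of last pulse seen so far
        for h in range(ev.start_idx, ev.end_idx + 1):
            cum += P[h]
            mx = max(mx, P[h])
            if P[h] > 0:
                if last_pulse is None or last_pulse[1] < h - 1:
                    last_pulse = (h, h)
                else:
                    last_pulse = (last_pulse[0], h)
            if last_pulse is None:
                # cannot happen for rule-1 events (start is rainy); guard for
                # hand-built events
                raise ValueError("event does not start with rain")
            ps, pe = last_pulse
            pv = P[ps:pe + 1]
            ts = index[pe]
            rows.append((
                cum, cum / (h - ev.start_idx + 1), mx, P[h],
                float(pv.sum()), float(pv.max()),
                (h - pe) if P[h] == 0 else 0,
                ts.hour + ts.minute / 60.0,
                ev.start_idx,
            ))
            idx.append(index[h])
    cols = ["cum_p_event", "mean_p_event", "max_p_event", "p_now",
            "cum_p_last_pulse", "max_p_last_pulse", "dry_hours_since_pulse",
            "last_pulse_end_time", "event_id"]
    return pd.DataFrame(rows, columns=cols, index=pd.DatetimeIndex(idx))
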