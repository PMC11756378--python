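"""Kymograph-derived microtubule dynamic-instability metrics.

Manually traced kymograph segments (pixel displacement over a number of
frames) become classified events — growth, pause, shrinkage — via the
imaging calibration.  A segment is a pause only if it is both slow
(|rate| at or below the detection floor, 0.05 um/min by default) and long
(>= 15 s); shorter near-zero segments are merged into the neighbouring
growth.  Catastrophe frequency is the number of transitions into
shrinkage divided by the total time spent in growth plus pause.  Also
here: end-state categories (no pauses / occasional pauses / fully
blocked), time-weighted growth-rate distributions, and FRAP recovery-curve
normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Calibration",
    "KymoSegment",
    "DynamicEvent",
    "EndHistory",
    "FrapSeries",
    "segments_to_events",
    "classify_pauses",
    "catastrophe_frequency",
    "end_category",
    "time_weighted_rate_distribution",
    "frap_normalize",
    "frap_mean_sd",
]

EventClass = Literal["growth", "pause", "shrinkage"]
Category = Literal["no_pauses", "occasional_pauses", "fully_blocked"]

#: Minimum pause duration (s): pauses of 15 s (5 frames) or longer count.
MIN_PAUSE_S = 15.0
#: Detection floor for growth rates (um/min); slower segments look paused.
MAX_PAUSE_RATE = 0.05


@dataclass(frozen=True)
class Calibration:
    pixel_size: float = 0.064     # um / pixel
    frame_interval: float = 3.0   # s / frame

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration values must be positive")


@dataclass
class KymoSegment:
    """One traced line segment on a kymograph."""

    mt_id: str
    dx: float                 # signed displacement, pixels (+ = growth)
    dt: float                 # duration, frames
    tip_marker_present: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("segment duration must be positive")


@dataclass
class DynamicEvent:
    cls: EventClass
    rate: float               # um/min, signed
    duration: float           # min
    tip_marker_present: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("event duration must be positive")


@dataclass
class EndHistory:
    mt_id: str
    events: list[DynamicEvent]
    observation_span: float   # min

    def __post_init__(self) -> None:
        total = sum(e.duration for e in self.events)
        if total > self.observation_span + 1e-9:
            raise ValueError("event durations exceed the observation span")


@dataclass
class FrapSeries:
    """A FRAP intensity trace normalised to its pre-bleach mean."""

    times: np.ndarray         # s
    intensities: np.ndarray   # raw, a.u.
    bleach_index: int
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.times) != len(self.intensities):
            raise ValueError("times and intensities differ in length")
        if not (2 <= self.bleach_index < len(self.times)):
            raise ValueError("need at least 2 pre-bleach points")
        pre = self.intensities[:self.bleach_index].mean()
        if pre <= 0:
            raise ValueError("non-positive pre-bleach mean")
        self.normalized = self.intensities / pre

    def recovery_fraction(self, index: int) -> float:
        """Recovered fraction of the bleached signal at a post-bleach index."""
        post0 = self.normalized[self.bleach_index]
        depth = 1.0 - post0
        if depth <= 0:
            return float("nan")
        return float((self.normalized[index] - post0) / depth)


# ---------------------------------------------------------------------------


def segments_to_events(segments: Iterable[KymoSegment], calib: Calibration,
                       min_pause_s: float = MIN_PAUSE_S,
                       max_pause_rate: float = MAX_PAUSE_RATE) -> list[DynamicEvent]:
    """Convert traced segments into provisionally classified events.

    rate = dx * pixel_size / (dt * frame_interval), in um/min; duration in
    minutes.  Classification: pause iff |rate| <= max_pause_rate and
    duration >= min_pause_s (inclusive); otherwise growth (rate >= 0) or
    shrinkage (rate < 0).  Sub-threshold near-zero segments keep their
    sign class here and are merged by :func:`classify_pauses`.
    """
    events = []
    for seg in segments:
        duration_s = seg.dt * calib.frame_interval
        rate = (seg.dx * calib.pixel_size / duration_s) * 60.0
        duration_min = duration_s / 60.0
        if abs(rate) <= max_pause_rate and duration_s >= min_pause_s:
            cls: EventClass = "pause"
        elif rate < 0:
            cls = "shrinkage"
        else:
            cls = "growth"
        events.append(DynamicEvent(cls=cls, rate=rate, duration=duration_min,
                                   tip_marker_present=seg.tip_marker_present))
    return events


def classify_pauses(events: Sequence[DynamicEvent],
                    min_pause_s: float = MIN_PAUSE_S,
                    max_pause_rate: float = MAX_PAUSE_RATE) -> list[DynamicEvent]:
    """Apply the pause rule and merge sub-threshold stalls into growth.

    A pause requires |rate| <= *max_pause_rate* AND duration >=
    *min_pause_s* (inclusive at the boundary).  Near-zero segments shorter
    than the minimum are merged into the longer adjacent growth event
    (displacement and duration combined, rate recomputed), so total time
    is conserved.
    """
    def _label(ev: DynamicEvent) -> str:
        near_zero = abs(ev.rate) <= max_pause_rate
        long_enough = ev.duration * 60.0 >= min_pause_s - 1e-9
        if near_zero and long_enough:
            return "pause"
        if near_zero:
            return "stall"  # too short to call a pause
        return "shrinkage" if ev.rate < 0 else "growth"

    def _absorb(host: DynamicEvent, stall: DynamicEvent) -> DynamicEvent:
        dur = host.duration + stall.duration
        disp = host.rate * host.duration + stall.rate * stall.duration
        return DynamicEvent(cls=host.cls, rate=disp / dur, duration=dur,
                            tip_marker_present=host.tip_marker_present)

    labelled = [(DynamicEvent(_label(e) if _label(e) != "stall" else "pause",
                              e.rate, e.duration, e.tip_marker_present), _label(e))
                for e in events]
    out: list[DynamicEvent] = []
    i = 0
    n = len(labelled)
    while i < n:
        ev, lab = labelled[i]
        if lab != "stall":
            out.append(DynamicEvent(lab, ev.rate, ev.duration, ev.tip_marker_present))
            i += 1
            continue
        prev = out[-1] if out else None
        nxt, nxt_lab = labelled[i + 1] if i + 1 < n else (None, None)
        # prefer a growth neighbour; between two growths take the longer one
        prev_ok = prev is not None and prev.cls == "growth"
        nxt_ok = nxt_lab == "growth"
        if prev_ok and (not nxt_ok or prev.duration >= nxt.duration):
            out[-1] = _absorb(prev, ev)
        elif nxt_ok:
            labelled[i + 1] = (_absorb(DynamicEvent("growth", nxt.rate, nxt.duration,
                                                    nxt.tip_marker_present), ev),
                               "growth")
        elif prev is not None:
            out[-1] = _absorb(prev, ev)  # no growth neighbour: fold backwards
        else:
            # isolated stall: too short to call a pause, so it stays a
            # near-zero growth segment and no observation time is lost
            out.append(DynamicEvent("growth", ev.rate, ev.duration,
                                    ev.tip_marker_present))
        i += 1
    return out


def catastrophe_frequency(histories: Iterable[EndHistory]) -> float:
    """Catastrophes per minute of growth + pause time.

    A catastrophe is any transition into shrinkage — from growth or from a
    pause (transient pauses end in depolymerisation).  Returns NaN when no
    growth or pause time was observed.
    """
    n_cat = 0
    productive_min = 0.0
    any_history = False
    for h in histories:
        any_history = True
        prev: DynamicEvent | None = None
        for ev in h.events:
            if ev.cls in ("growth", "pause"):
                productive_min += ev.duration
            if prev is not None and ev.cls == "shrinkage" and prev.cls in ("growth", "pause"):
                n_cat += 1
            prev = ev
    if not any_history:
        raise ValueError("no histories given")
    if productive_min <= 0:
        return float("nan")
    return n_cat / productive_min


def end_category(history: EndHistory, min_pauses: int = 1) -> Category:
    """Sort an MT end into no_pauses / occasional_pauses / fully_blocked.

    fully_blocked: no growth event over the whole observation span;
    occasional_pauses: at least *min_pauses* pauses plus some growth;
    otherwise no_pauses.
    """
    if not history.events:
        raise ValueError("empty history")
    n_growth = sum(1 for e in history.events if e.cls == "growth")
    n_pause = sum(1 for e in history.events if e.cls == "pause")
    if n_growth == 0:
        return "fully_blocked"
    if n_pause >= min_pauses:
        return "occasional_pauses"
    return "no_pauses"


def time_weighted_rate_distribution(events: Sequence[DynamicEvent]
                                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-weighted distribution of event rates.

    Each event's weight is its duration divided by the summed duration of
    all events, so the cumulative curve reads as "% of total time spent at
    or below a given rate".  Returns (sorted rates, weights, cumulative
    weights); weights sum to 1.
    """
    if not events:
        raise ValueError("no events given")
    rates = np.array([e.rate for e in events], dtype=float)
    durations = np.array([e.duration for e in events], dtype=float)
    order = np.argsort(rates, kind="stable")
    rates = rates[order]
    weights = durations[order] / durations.sum()
    return rates, weights, np.cumsum(weights)


def frap_normalize(times: Sequence[float], intensities: Sequence[float],
                   bleach_index: int) -> FrapSeries:
    """Normalise a raw FRAP trace by its mean pre-bleach intensity."""
    return FrapSeries(times=np.asarray(times, dtype=float),
                      intensities=np.asarray(intensities, dtype=float),
                      bleach_index=bleach_index)


def frap_mean_sd(series: Sequence[FrapSeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean + SD of normalised intensity across MTs, per time point.

    All series must share a common time base.
    """
    if not series:
        raise ValueError("no series given")
    t0 = series[0].times
    for s in series[1:]:
        if len(s.times) != len(t0) or np.max(np.abs(s.times - t0)) > 1e-9:
            raise ValueError("series do not share a common time base")
    stack = np.vstack([s.normalized for s in series])
    return t0, stack.mean(axis=0), stack.std(axis=0, ddof=1 if len(series) > 1 else 0)
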