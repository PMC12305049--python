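"""Sleep-deprivation stimulus schedules and trace annotation.

Two nighttime stimulus protocols are supported:

* light deprivation: lights on 5 min, then 25 min off (10 stimulated min/hour);
* mechanical deprivation: water jets on 1 min, then 4 min off (12 min/hour),
  with the infrared camera lights gated off during each water pulse, so those
  frames are unanalyzable.

"Every N minutes" is read as an OFF gap of N minutes between pulses, i.e. a
cycle of ``on_min + off_min`` — the only reading consistent with both printed
per-hour totals above.

Schedules are expressed in seconds from a recording that starts at ZT0 under a
12:12 light cycle; ZT conversion is a pure offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import IntensityTrace
from .errors import RejectedInputError


@dataclass
class StimulusSchedule:
    kind: str  # 'light' or 'mechanical'
    on_min: float
    off_min: float
    active_window: tuple  # (zt_start, zt_end) hours within each day
    on_intervals: list = field(default_factory=list)  # [(start_s, end_s), ...]
    camera_gated: bool = False

    def __post_init__(self):
        if self.on_min <= 0:
            raise RejectedInputError("on_min must be > 0")
        if self.off_min < 0:
            raise RejectedInputError("off_min must be >= 0")
        if self.camera_gated and self.kind != "mechanical":
            raise RejectedInputError("camera gating applies to mechanical schedules only")
        ivs = sorted(tuple(map(float, iv)) for iv in self.on_intervals)
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise RejectedInputError("ON intervals must not overlap")
        self.on_intervals = ivs

    @property
    def cycle_min(self) -> float:
        return self.on_min + self.off_min


def build_schedule(
    kind: str,
    on_min: float,
    off_min: float,
    active_window: tuple = (12.0, 24.0),
    total_nights: int = 1,
    camera_gated: bool | None = None,
) -> StimulusSchedule:
    """Tile ON pulses of ``on_min`` every ``on_min + off_min`` across each night.

    The first pulse of each night starts at the active-window start; pulses are
    clipped at the window end. ``camera_gated`` defaults to True for mechanical
    schedules (IR lights switch off while the water runs).
    """
    if kind not in ("light", "mechanical"):
        raise RejectedInputError(f"unknown schedule kind {kind!r}")
    if on_min + off_min <= 0:
        raise RejectedInputError("on_min + off_min must be > 0")
    if camera_gated is None:
        camera_gated = kind == "mechanical"
    zt0, zt1 = active_window
    window_min = (zt1 - zt0) * 60.0
    intervals = []
    if window_min < on_min:
        warnings.warn("active window shorter than one stimulus pulse; empty schedule")
    else:
        cycle = on_min + off_min
        for night in range(total_nights):
            base_s = (night * 24.0 + zt0) * 3600.0
            end_s = (night * 24.0 + zt1) * 3600.0
            if off_min == 0:  # continuous ON across the window
                intervals.append((base_s, end_s))
                continue
            start = base_s
            while start < end_s:
                stop = min(start + on_min * 60.0, end_s)
                intervals.append((start, stop))
                start += cycle * 60.0
    return StimulusSchedule(
        kind=kind,
        on_min=on_min,
        off_min=off_min,
        active_window=tuple(map(float, active_window)),
        on_intervals=intervals,
        camera_gated=bool(camera_gated),
    )


def minutes_per_hour(s: StimulusSchedule) -> float:
    """Stimulated minutes in a full steady-state hour: ``60 * on / (on + off)``."""
    if not s.on_intervals:
        return 0.0
    return 60.0 * s.on_min / (s.on_min + s.off_min)


def in_on_interval(times_s: np.ndarray, s: StimulusSchedule) -> np.ndarray:
    """Boolean mask: which times fall inside an ON interval (half-open)."""
    times_s = np.asarray(times_s, dtype=float)
    mask = np.zeros(times_s.shape, dtype=bool)
    for a, b in s.on_intervals:
        mask |= (times_s >= a) & (times_s < b)
    return mask


def zt_of(times_s: np.ndarray, zt_start: float = 0.0) -> np.ndarray:
    """Zeitgeber hour (mod 24) of each time."""
    return (zt_start + np.asarray(times_s, dtype=float) / 3600.0) % 24.0


def annotate_trace(trace: IntensityTrace, s: StimulusSchedule | None, zt_start: float = 0.0) -> IntensityTrace:
    """Fill ``light_state`` (day/night/stimulus) and mark camera-gated gaps missing.

    Idempotent: annotating an annotated trace yields the same annotation.
    """
    zt = zt_of(trace.time_s, zt_start)
    state = np.where(zt < 12.0, "day", "night").astype(object)
    missing = np.zeros(trace.n_frames, dtype=bool)
    if s is not None and s.on_intervals:
        # schedules are laid out in ZT-referenced seconds (recording at ZT0)
        on = in_on_interval(zt_start * 3600.0 + trace.time_s, s)
        state[on] = "stimulus"
        if s.camera_gated:
            missing = on.copy()
    if trace.missing is not None:
        missing |= trace.missing
    return IntensityTrace(
        time_s=trace.time_s,
        intensity=trace.intensity,
        fps=trace.fps,
        light_state=np.asarray(state),
        missing=missing,
        roi=trace.roi,
        quality=trace.quality,
    )
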