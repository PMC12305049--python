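"""In-memory containers shared across the analysis stack.

All time is in seconds from the start of the recording window unless a field
name says otherwise (``_ms`` for milliseconds, ``_zt`` for zeitgeber hours).
Frames are 0-based; windows are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError

#: relative tolerance on frame spacing uniformity
_SPACING_RTOL = 1e-6


@dataclass
class IntensityTrace:
    """Per-frame mean ROI intensity time series.

    Parameters
    ----------
    time_s : array of float
        Frame times in seconds, strictly increasing, uniformly spaced at 1/fps.
    intensity : array of float
        Mean pixel intensity per frame (arbitrary units).
    fps : float
        Frame rate in frames/second.
    light_state : array of str, optional
        Per-frame annotation: ``day``, ``night`` or ``stimulus``.
    missing : array of bool, optional
        Frames excluded from analysis (e.g. camera gated off during water pulses).
    roi : tuple, optional
        ``(x0, y0, x1, y1)`` pixel rectangle provenance.
    quality : str
        ``ok`` or ``low_quality``.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    fps: float
    light_state: Optional[np.ndarray] = None
    missing: Optional[np.ndarray] = None
    roi: Optional[tuple] = None
    quality: str = "ok"

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise FormatError("time_s and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensity contains non-finite values")
        if self.time_s.size >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise FormatError("time_s must be strictly increasing")
            expected = 1.0 / self.fps
            if np.any(np.abs(dt - expected) > _SPACING_RTOL * max(1.0, expected)):
                raise FormatError("time_s spacing must equal 1/fps")
        if self.light_state is not None:
            self.light_state = np.asarray(self.light_state)
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.time_s.size)

    @property
    def duration_s(self) -> float:
        if self.time_s.size == 0:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0])


@dataclass
class PulseSeries:
    """Detected bell-contraction times and the inter-pulse intervals between them."""

    pulse_times: np.ndarray
    ipis: np.ndarray = None  # type: ignore[assignment]
    threshold_used: float = np.nan
    quality: str = "ok"
    source_window: Optional[tuple] = None

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.ipis is None:
            self.ipis = np.diff(self.pulse_times)
        else:
            self.ipis = np.asarray(self.ipis, dtype=float)
        if self.pulse_times.size >= 2 and np.any(np.diff(self.pulse_times) <= 0):
            raise FormatError("pulse_times must be strictly increasing")
        if self.ipis.size != max(0, self.pulse_times.size - 1):
            raise FormatError("len(ipis) must equal max(0, n_pulses - 1)")
        if np.any(self.ipis <= 0):
            raise FormatError("every IPI must be > 0")

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)


@dataclass
class Hypnogram:
    """Per-bin sleep fractions for one animal.

    ``bin_start_zt`` is cumulative zeitgeber hours from recording start at ZT0
    (values beyond 24 index later days; day/night phase is the value mod 24).
    ``threshold`` holds the per-24-h-block normalized-median IPI threshold(s).
    """

    animal_id: str
    condition: str
    bin_start_zt: np.ndarray
    bin_len_min: float
    sleep_fraction: np.ndarray
    threshold: np.ndarray
    missing: np.ndarray
    analyzable_s: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.bin_start_zt = np.asarray(self.bin_start_zt, dtype=float)
        self.sleep_fraction = np.asarray(self.sleep_fraction, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.threshold = np.atleast_1d(np.asarray(self.threshold, dtype=float))
        if self.analyzable_s is None:
            self.analyzable_s = np.where(self.missing, 0.0, self.bin_len_min * 60.0)
        self.analyzable_s = np.asarray(self.analyzable_s, dtype=float)
        ok = ~self.missing
        frac = self.sleep_fraction[ok]
        if np.any((frac < -1e-9) | (frac > 1 + 1e-9)):
            raise FormatError("sleep_fraction must lie in [0, 1] where not missing")
        if np.any(self.threshold <= 0):
            raise FormatError("threshold must be > 0")


@dataclass
class DayNightSummary:
    """Time-weighted mean sleep over the ZT day ([0,12)) and night ([12,24))."""

    day_sleep_pct: float
    night_sleep_pct: float
    zt_day: tuple = (0.0, 12.0)
    zt_night: tuple = (12.0, 24.0)

    def __post_init__(self):
        for v in (self.day_sleep_pct, self.night_sleep_pct):
            if np.isfinite(v) and not (-1e-9 <= v <= 100 + 1e-9):
                raise FormatError("sleep percentages must lie in [0, 100]")


@dataclass
class VoltageTrace:
    """Extracellular voltage recording sampled at a uniform interval."""

    time_ms: np.ndarray
    voltage_mV: np.ndarray
    sampling_interval_ms: float = 0.08
    treatment: str = "ASW-control"

    def __post_init__(self):
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if self.time_ms.shape != self.voltage_mV.shape:
            raise FormatError("time_ms and voltage_mV must have equal length")
        if not np.all(np.isfinite(self.voltage_mV)):
            raise FormatError("voltage contains non-finite values")
        if self.time_ms.size >= 2:
            dt = np.diff(self.time_ms)
            if np.any(np.abs(dt - self.sampling_interval_ms) > 1e-6 * self.sampling_interval_ms + 1e-12):
                raise FormatError("sampling must be uniform at sampling_interval_ms")


@dataclass
class SpikeTrain:
    """Accepted action-potential events and the interspike intervals between them.

    ISIs follow the resting-potential convention: the gap from one spike's
    offset to the next spike's onset.
    """

    onsets_ms: np.ndarray
    offsets_ms: np.ndarray
    peak_amp_mV: np.ndarray
    isis_ms: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=float)
        self.offsets_ms = np.asarray(self.offsets_ms, dtype=float)
        self.peak_amp_mV = np.asarray(self.peak_amp_mV, dtype=float)
        if self.isis_ms is None:
            self.isis_ms = (
                self.onsets_ms[1:] - self.offsets_ms[:-1]
                if self.onsets_ms.size >= 2
                else np.empty(0)
            )
        self.isis_ms = np.asarray(self.isis_ms, dtype=float)
        if self.onsets_ms.size >= 2 and np.any(np.diff(self.onsets_ms) <= 0):
            raise FormatError("spike onsets must be strictly increasing")
        if self.isis_ms.size != max(0, self.onsets_ms.size - 1):
            raise FormatError("len(isis) must equal max(0, n_spikes - 1)")

    @property
    def n_spikes(self) -> int:
        return int(self.onsets_ms.size)

    @property
    def durations_ms(self) -> np.ndarray:
        return self.offsets_ms - self.onsets_ms


@dataclass
class StainQuant:
    """Purple-pixel signal ratio for one rhopalium image."""

    image_id: str
    condition: str
    rhopalium_px: int
    purple_px: int

    def __post_init__(self):
        if self.purple_px > self.rhopalium_px:
            raise FormatError("purple_px cannot exceed rhopalium_px")

    @property
    def signal(self) -> float:
        return self.purple_px / self.rhopalium_px


@dataclass
class DropTrial:
    """One drop-test trial: predrop pulsing baseline and post-drop arousal latency."""

    animal_id: str
    light: str  # 'day' or 'night'
    acclimation_min: float  # 5 (initial) or 2 (redrop)
    predrop_ipis: np.ndarray
    drop_time_s: float
    first_pulse_time_s: float = np.nan
    censored: bool = False
    observation_window_s: float = 60.0
    predrop_mean: float = np.nan
    normalized_predrop: float = np.nan
    speed_class: Optional[str] = None  # 'fast' or 'slow'

    def __post_init__(self):
        self.predrop_ipis = np.asarray(self.predrop_ipis, dtype=float)

    @property
    def latency_s(self) -> float:
        if self.censored or not np.isfinite(self.first_pulse_time_s):
            return np.nan
        return self.first_pulse_time_s - self.drop_time_s


@dataclass
class GroundTruth:
    """Generator-side labels for synthetic inputs."""

    true_pulse_times: Optional[np.ndarray] = None
    true_state_per_ipi: Optional[np.ndarray] = None  # 'wake' / 'sleep'
    true_spike_windows: Optional[list] = None  # [(onset_ms, offset_ms), ...]
    true_spike_valid: Optional[np.ndarray] = None
    true_purple_fraction: Optional[float] = None

    def __post_init__(self):
        if self.true_pulse_times is not None:
            self.true_pulse_times = np.asarray(self.true_pulse_times, dtype=float)
            if self.true_pulse_times.size >= 2 and np.any(np.diff(self.true_pulse_times) <= 0):
                raise FormatError("true pulse times must be strictly increasing")
        if self.true_state_per_ipi is not None:
            self.true_state_per_ipi = np.asarray(self.true_state_per_ipi)
        if self.true_spike_valid is not None:
            self.true_spike_valid = np.asarray(self.true_spike_valid, dtype=bool)


def as_float_array(values: Sequence, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FormatError(f"{name} contains non-finite values")
    return arr
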