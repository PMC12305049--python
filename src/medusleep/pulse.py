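"""Pulse tracking: ROI intensity extraction, normalization and dip detection.

A bell contraction shows up as a dip in the mean ROI pixel intensity. The
stack converts frames to a per-frame mean trace, removes slow lighting drift
with a rolling median, rescales by a robust noise estimate, and demarcates a
pulse at every strict local minimum deeper than a (negative) threshold, with
minima closer than a refractory interval merged to the deepest. Inter-pulse
intervals (IPIs) are successive differences of pulse times.

The detector is invariant under positive affine transforms of the raw
intensity: the rolling median absorbs offsets, the robust scale absorbs gain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import IntensityTrace, PulseSeries
from .errors import FormatError, RejectedInputError

#: consistency factor making the median absolute deviation estimate sigma
MAD_TO_SD = 1.4826

#: default detection threshold in robust noise units (dips are negative)
DEFAULT_THRESHOLD = -3.0

#: default refractory interval (physiological minimum contraction spacing)
DEFAULT_REFRACTORY_S = 0.5


def frames_in_window(window_min: float, fps: float) -> int:
    """Number of frames in an analysis window of ``window_min`` minutes."""
    if window_min <= 0 or fps <= 0:
        raise RejectedInputError("window_min and fps must be > 0")
    return int(round(window_min * 60.0 * fps))


def extract_intensity(frames, roi: tuple | None = None, fps: float = 15.0) -> IntensityTrace:
    """Mean pixel intensity of each frame over a rectangular ROI.

    ``frames`` is an ``(n, h, w)`` or ``(n, h, w, 3)`` stack (or a sequence of
    equally shaped frames); color frames are converted to grayscale by channel
    mean. ``roi`` is ``(x0, y0, x1, y1)``, half-open, defaulting to the full
    frame.
    """
    if not isinstance(frames, np.ndarray):
        shapes = {np.asarray(f).shape for f in frames}
        if len(shapes) > 1:
            raise FormatError("ragged frame stack: frames differ in shape")
        frames = np.asarray([np.asarray(f, dtype=float) for f in frames])
    frames = np.asarray(frames, dtype=float)
    if frames.ndim not in (3, 4):
        raise FormatError("expected an (n, h, w[, 3]) frame stack")
    n, h, w = frames.shape[:3]
    if n < 2:
        raise RejectedInputError("need at least 2 frames")
    if frames.ndim == 4:
        frames = frames.mean(axis=3)
    if roi is None:
        roi = (0, 0, w, h)
    x0, y0, x1, y1 = map(int, roi)
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise RejectedInputError(f"ROI {roi} empty or outside frame bounds {(w, h)}")
    mean = frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
    t = np.arange(n) / fps
    return IntensityTrace(time_s=t, intensity=mean, fps=fps, roi=(x0, y0, x1, y1))


def normalize_trace(trace: IntensityTrace, baseline_window_s: float = 10.0) -> IntensityTrace:
    """Detrend with a centered rolling median and rescale to robust noise units.

    Output = (intensity - rolling median over ``baseline_window_s``) divided by
    a robust noise scale, so a drift-free trace maps to approximately zero
    mean and unit noise. The scale is estimated from the POSITIVE deviations
    only (a one-sided MAD): contraction dips only darken the ROI, so the upper
    half of the deviation distribution is uncontaminated noise even at high
    dip duty cycles. A constant trace has zero scale and is returned as all
    zeros flagged ``low_quality``.
    """
    if baseline_window_s < 2.0 / trace.fps:
        raise RejectedInputError("baseline_window_s must be at least 2 frame intervals")
    x = trace.intensity
    win = max(3, int(round(baseline_window_s * trace.fps)) | 1)  # odd window
    med = (
        pd.Series(x).rolling(window=win, center=True, min_periods=1).median().to_numpy()
    )
    detrended = x - med
    dev = detrended - np.median(detrended)
    pos = dev[dev > 0]
    scale = MAD_TO_SD * np.median(pos) if pos.size else 0.0
    if scale == 0.0 and np.any(dev != 0):
        # degenerate noise-free case (e.g. rendered dips without sensor
        # noise): fall back to the nonzero |deviation| median so the dips
        # survive normalization
        nz = np.abs(dev[dev != 0])
        scale = MAD_TO_SD * np.median(nz)
    if scale == 0.0:
        return IntensityTrace(
            time_s=trace.time_s, intensity=np.zeros_like(x), fps=trace.fps,
            light_state=trace.light_state, missing=trace.missing, roi=trace.roi,
            quality="low_quality",
        )
    return IntensityTrace(
        time_s=trace.time_s, intensity=detrended / scale, fps=trace.fps,
        light_state=trace.light_state, missing=trace.missing, roi=trace.roi,
        quality=trace.quality,
    )


def _strict_local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (both neighbors strictly higher)."""
    if x.size < 3:
        return np.empty(0, dtype=int)
    core = (x[1:-1] < x[:-2]) & (x[1:-1] < x[2:])
    return np.flatnonzero(core) + 1


def _merge_refractory(idx: np.ndarray, depths: np.ndarray, min_gap: int) -> np.ndarray:
    """Greedy suppression: keep the deepest minimum, drop others within min_gap.

    Candidates further than min_gap apart cannot interact, so the greedy pass
    runs independently within each chain of near neighbors.
    """
    if idx.size == 0:
        return idx
    chain_breaks = np.flatnonzero(np.diff(idx) >= min_gap) + 1
    kept = []
    for lo, hi in zip(np.r_[0, chain_breaks], np.r_[chain_breaks, idx.size]):
        sub_idx, sub_depth = idx[lo:hi], depths[lo:hi]
        suppressed = np.zeros(sub_idx.size, dtype=bool)
        for k in np.argsort(sub_depth, kind="stable"):  # deepest first
            if suppressed[k]:
                continue
            kept.append(sub_idx[k])
            suppressed |= np.abs(sub_idx - sub_idx[k]) < min_gap
    return np.asarray(sorted(kept), dtype=int)


def detect_pulses(
    trace: IntensityTrace,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> PulseSeries:
    """Demarcate a pulse at every strict local minimum below ``threshold``.

    ``threshold`` is in normalized intensity units and must be negative (pulses
    are dips). Minima closer than ``refractory_s`` are merged to the deepest.
    An empty result is allowed. Frames marked missing never host a pulse.
    """
    if threshold >= 0:
        raise RejectedInputError("threshold must be negative (pulses are intensity dips)")
    if refractory_s < 1.0 / trace.fps:
        raise RejectedInputError("refractory_s must be at least one frame interval")
    x = trace.intensity
    idx = _strict_local_minima(x)
    idx = idx[x[idx] < threshold]
    if trace.missing is not None:
        idx = idx[~trace.missing[idx]]
    min_gap = max(1, int(round(refractory_s * trace.fps)))
    idx = np.sort(_merge_refractory(idx, x[idx], min_gap))
    times = trace.time_s[idx]
    window = (float(trace.time_s[0]), float(trace.time_s[-1])) if trace.n_frames else (0.0, 0.0)
    return PulseSeries(
        pulse_times=times,
        threshold_used=threshold,
        quality=trace.quality,
        source_window=window,
    )


#: dips must clear the nominal SNR floor by this factor to count as "clear":
#: detections whose depth barely exceeds the threshold are indistinguishable
#: from the extreme minima of pure noise
QUALITY_CLEARANCE = 1.5


def assess_quality(trace: IntensityTrace, pulses: PulseSeries, min_dip_snr: float = 3.0) -> str:
    """Flag windows where pulses cannot be read out cleanly.

    ``low_quality`` when no pulses were found in a nonempty window, or when
    the median dip depth (in robust noise units, measured on the normalized
    trace) fails to clear ``min_dip_snr`` by :data:`QUALITY_CLEARANCE` —
    near-threshold exceedances look exactly like noise extremes, so clear
    pulse readout requires depth well beyond the detection floor.
    """
    if trace.quality == "low_quality":
        return "low_quality"
    if pulses.n_pulses == 0:
        return "low_quality" if trace.n_frames > 0 else "ok"
    frame_idx = np.clip(np.round((pulses.pulse_times - trace.time_s[0]) * trace.fps).astype(int),
                        0, trace.n_frames - 1)
    median_snr = float(np.median(np.abs(trace.intensity[frame_idx])))
    return "ok" if median_snr >= QUALITY_CLEARANCE * min_dip_snr else "low_quality"


def track_pulses(
    trace: IntensityTrace,
    baseline_window_s: float = 10.0,
    threshold: float = DEFAULT_THRESHOLD,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    min_dip_snr: float = 3.0,
) -> PulseSeries:
    """Normalize, detect, and quality-flag in one call."""
    norm = normalize_trace(trace, baseline_window_s=baseline_window_s)
    pulses = detect_pulses(norm, threshold=threshold, refractory_s=refractory_s)
    pulses.quality = assess_quality(norm, pulses, min_dip_snr=min_dip_snr)
    return pulses
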