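"""Sleep scoring from inter-pulse intervals.

Each animal's 24-h recording defines its own sleep-wake threshold: IPIs are
divided by their mean and the threshold is the median of the normalized
values. An IPI is sleep when its normalized value is strictly greater than
the threshold (ties score wake). Sleep per bin is time-weighted: the time
covered by above-threshold IPIs divided by the analyzable time in the bin,
with IPIs spanning a bin boundary apportioned pro rata.

ZT convention: lights-on is ZT0; day = [0, 12), night = [12, 24), 12:12 cycle.
"""

from __future__ import annotations

import numpy as np

from .containers import DayNightSummary, Hypnogram, PulseSeries
from .errors import InsufficientDataError

MIN_IPIS_FOR_THRESHOLD = 10


def normalized_ipis(ipis: np.ndarray) -> np.ndarray:
    """IPIs divided by their mean (mean-normalized, unitless)."""
    ipis = np.asarray(ipis, dtype=float)
    return ipis / ipis.mean()


def sleep_threshold(ipis) -> float:
    """Per-animal sleep-wake threshold: median of mean-normalized IPIs.

    Requires at least 10 IPIs from one 24-h recording. Classification with
    this threshold is equivalent to comparing raw IPIs to their raw median
    (mean-normalization is a common positive rescaling).
    """
    ipis = np.asarray(ipis, dtype=float)
    if ipis.size < MIN_IPIS_FOR_THRESHOLD:
        raise InsufficientDataError(
            f"need >= {MIN_IPIS_FOR_THRESHOLD} IPIs for a threshold, got {ipis.size}"
        )
    return float(np.median(normalized_ipis(ipis)))


def _interval_overlap(starts, ends, bin_edges):
    """Total overlap of each [start, end) interval with each bin; returns the
    per-bin summed overlap in seconds."""
    n_bins = bin_edges.size - 1
    out = np.zeros(n_bins)
    if len(starts) == 0:
        return out
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    for b in range(n_bins):
        lo, hi = bin_edges[b], bin_edges[b + 1]
        out[b] = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None).sum()
    return out


def score_bins(
    pulses,
    threshold: float,
    bin_len_min: float = 30.0,
    zt_start: float = 0.0,
    animal_id: str = "",
    condition: str = "control",
    total_duration_s: float | None = None,
) -> Hypnogram:
    """Bin sleep fractions from one or more pulse series of the same recording.

    ``pulses`` is a :class:`PulseSeries` or a list of them (e.g. one 20-min
    window per hour); series flagged ``low_quality`` are excluded, and bins
    with no analyzable time are missing. The normalization factor is the mean
    IPI pooled over the supplied series — pass the series belonging to the same
    24-h recording that produced ``threshold``.
    """
    if isinstance(pulses, PulseSeries):
        pulses = [pulses]
    usable = [p for p in pulses if p.quality == "ok" and p.n_pulses >= 2]
    all_ipis = np.concatenate([p.ipis for p in usable]) if usable else np.empty(0)
    if total_duration_s is None:
        total_duration_s = max((p.source_window[1] if p.source_window else p.pulse_times[-1])
                               for p in pulses) if pulses else 0.0
    bin_len_s = bin_len_min * 60.0
    n_bins = int(np.ceil(total_duration_s / bin_len_s)) if total_duration_s > 0 else 0
    edges = np.arange(n_bins + 1) * bin_len_s
    sleep_s = np.zeros(n_bins)
    analyzable_s = np.zeros(n_bins)
    if all_ipis.size:
        factor = all_ipis.mean()
        for p in usable:
            starts, ends = p.pulse_times[:-1], p.pulse_times[1:]
            analyzable_s += _interval_overlap(starts, ends, edges)
            is_sleep = (p.ipis / factor) > threshold
            sleep_s += _interval_overlap(starts[is_sleep], ends[is_sleep], edges)
    missing = analyzable_s <= 0
    frac = np.divide(sleep_s, analyzable_s, out=np.zeros(n_bins), where=~missing)
    return Hypnogram(
        animal_id=animal_id,
        condition=condition,
        bin_start_zt=zt_start + edges[:-1] / 3600.0,
        bin_len_min=bin_len_min,
        sleep_fraction=frac,
        threshold=np.array([threshold]),
        missing=missing,
        analyzable_s=analyzable_s,
    )


def score_recording(
    pulses: PulseSeries,
    bin_len_min: float = 30.0,
    zt_start: float = 0.0,
    animal_id: str = "",
    condition: str = "control",
    block_len_h: float = 24.0,
) -> Hypnogram:
    """Score a multi-day recording with a threshold recomputed per 24-h block.

    The recording is split into consecutive ``block_len_h`` blocks (IPIs are
    assigned to the block containing their start); each block gets its own
    mean-normalization and median threshold, and the per-block hypnograms are
    concatenated. Concatenating two identical days therefore yields identical
    per-day hypnograms.
    """
    block_s = block_len_h * 3600.0
    end = pulses.source_window[1] if pulses.source_window else pulses.pulse_times[-1]
    n_blocks = max(1, int(np.ceil(end / block_s)))
    parts = []
    for b in range(n_blocks):
        lo, hi = b * block_s, min((b + 1) * block_s, end)
        # half-open blocks; the final block keeps its right endpoint
        if b < n_blocks - 1:
            sel = (pulses.pulse_times >= lo) & (pulses.pulse_times < hi)
        else:
            sel = (pulses.pulse_times >= lo) & (pulses.pulse_times <= hi + 1e-9)
        times = pulses.pulse_times[sel]
        sub = PulseSeries(pulse_times=times - lo, quality=pulses.quality,
                          source_window=(0.0, hi - lo))
        thr = sleep_threshold(sub.ipis)
        h = score_bins(sub, thr, bin_len_min=bin_len_min,
                       zt_start=zt_start + lo / 3600.0, animal_id=animal_id,
                       condition=condition, total_duration_s=hi - lo)
        parts.append(h)
    return Hypnogram(
        animal_id=animal_id,
        condition=condition,
        bin_start_zt=np.concatenate([h.bin_start_zt for h in parts]),
        bin_len_min=bin_len_min,
        sleep_fraction=np.concatenate([h.sleep_fraction for h in parts]),
        threshold=np.concatenate([h.threshold for h in parts]),
        missing=np.concatenate([h.missing for h in parts]),
        analyzable_s=np.concatenate([h.analyzable_s for h in parts]),
    )


def day_night_summary(h: Hypnogram) -> DayNightSummary:
    """Analyzable-time-weighted mean sleep over ZT [0,12) and [12,24), in percent."""
    zt = h.bin_start_zt % 24.0
    is_day = zt < 12.0
    out = []
    for sel in (is_day, ~is_day):
        ok = sel & ~h.missing
        if not np.any(ok):
            raise InsufficientDataError("no non-missing bins in one ZT period")
        w = h.analyzable_s[ok]
        if w.sum() <= 0:
            raise InsufficientDataError("no analyzable time in one ZT period")
        out.append(100.0 * float(np.average(h.sleep_fraction[ok], weights=w)))
    return DayNightSummary(day_sleep_pct=out[0], night_sleep_pct=out[1])


def rebound_index(sd_day: DayNightSummary, control_day: DayNightSummary) -> float:
    """Daytime rebound: deprived minus control day-sleep percentage (points)."""
    return sd_day.day_sleep_pct - control_day.day_sleep_pct
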