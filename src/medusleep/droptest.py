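"""Drop-test analysis: predrop baseline, fast/slow split, latency-to-arousal.

The drop-test releases an animal into the water column; it briefly freezes,
then resumes pulsing. The state before the drop is summarized by the mean of
the 3 IPIs immediately preceding it; all trials of an experiment (light and
dark pooled) share one normalization factor (the mean of the predrop means),
and the pooled median of the normalized baselines splits trials into
fast- (wake-like) and slow- (sleep-like) pulsing. Arousal is quantified as
the time from the drop to the first detected pulse; trials with no pulse
inside the observation window are censored, reported and excluded from the
ANOVA. Ties at the median classify as fast.
"""

from __future__ import annotations

from collections import namedtuple
from typing import Sequence

import numpy as np

from .containers import DropTrial, PulseSeries
from .errors import InsufficientDataError, RejectedInputError
from .stats import GroupComparison, anova_tukey

Latency = namedtuple("Latency", ["seconds", "censored"])


def predrop_baseline(ipis_before_drop) -> float:
    """Arithmetic mean of the 3 IPIs immediately preceding the drop."""
    ipis = np.asarray(ipis_before_drop, dtype=float)
    if ipis.size < 3:
        raise InsufficientDataError("need at least 3 predrop IPIs")
    return float(ipis[-3:].mean())


def normalize_baselines(trials: Sequence[DropTrial]) -> list[DropTrial]:
    """Fill ``predrop_mean`` and ``normalized_predrop`` on every trial.

    The normalization factor is the mean of all trials' predrop means, pooled
    over light and dark, so the normalized values are unit-free.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError("need at least 2 trials to normalize")
    for t in trials:
        t.predrop_mean = predrop_baseline(t.predrop_ipis)
    factor = float(np.mean([t.predrop_mean for t in trials]))
    if factor == 0.0:
        raise RejectedInputError("zero normalization factor")
    for t in trials:
        t.normalized_predrop = t.predrop_mean / factor
    return trials


def classify_fast_slow(trials: Sequence[DropTrial]) -> list[DropTrial]:
    """Median split of normalized predrop baselines: slow iff strictly above."""
    trials = list(trials)
    vals = np.array([t.normalized_predrop for t in trials], dtype=float)
    if np.any(~np.isfinite(vals)):
        raise RejectedInputError("normalized_predrop missing; call normalize_baselines first")
    med = float(np.median(vals))
    for t, v in zip(trials, vals):
        t.speed_class = "slow" if v > med else "fast"
    return trials


def latency_to_arousal(postdrop: PulseSeries, drop_time_s: float, window_s: float = 60.0) -> Latency:
    """Time from the drop to the first pulse strictly after it.

    Returns ``Latency(seconds, censored=False)``, or ``Latency(window_s, True)``
    when no pulse occurs within the observation window.
    """
    after = postdrop.pulse_times[postdrop.pulse_times > drop_time_s]
    after = after[after <= drop_time_s + window_s]
    if after.size == 0:
        return Latency(float(window_s), True)
    return Latency(float(after[0] - drop_time_s), False)


def _group_key(trial: DropTrial, grouping: str) -> str:
    if grouping == "light":
        return trial.light
    if grouping == "speed_acclimation":
        if trial.speed_class is None:
            raise RejectedInputError("speed_class missing; call classify_fast_slow first")
        return f"{trial.speed_class}-{trial.acclimation_min:g}min"
    raise RejectedInputError(f"unknown grouping {grouping!r}")


def compare_latencies(trials: Sequence[DropTrial], grouping: str = "light") -> GroupComparison:
    """One-way ANOVA with all-pairs Tukey HSD on non-censored latencies.

    ``grouping='light'`` compares day vs night; ``'speed_acclimation'``
    compares fast/slow crossed with 5-min vs 2-min acclimation. Each group
    must contribute at least 2 non-censored latencies.
    """
    groups: dict[str, list[float]] = {}
    for t in trials:
        if t.censored or not np.isfinite(t.latency_s):
            continue
        groups.setdefault(_group_key(t, grouping), []).append(t.latency_s)
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise InsufficientDataError("need >= 2 groups with >= 2 non-censored latencies each")
    return anova_tukey(groups)
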