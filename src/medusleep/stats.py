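"""Shared inferential procedures: one-way ANOVA + Tukey HSD, two-sample KS,
and per-bin cohort mean +/- SEM.

The contracts are fixed here (two-sided tests, equal-variance ANOVA); the
numerics are delegated to scipy. The Tukey HSD adjusted p-values are
cross-checked against an independent implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, RejectedInputError


@dataclass
class GroupComparison:
    method: str  # 'anova_tukey' or 'ks'
    groups: list
    statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # (label_a, label_b, adjusted_p)
    group_means: dict = field(default_factory=dict)  # label -> (mean, sem)

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise RejectedInputError("p_value must lie in [0, 1]")


def _mean_sem(values: np.ndarray):
    mean = float(np.mean(values))
    sem = float(sps.sem(values)) if values.size >= 2 else float("nan")
    return mean, sem


def anova_tukey(groups: dict) -> GroupComparison:
    """One-way (equal-variance) ANOVA with all-pairs Tukey HSD adjustment.

    ``groups`` maps label -> values. Requires >= 2 groups with n >= 2 each.
    Degenerate input where every value is identical returns F = 0, p = 1
    rather than raising.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InsufficientDataError("need >= 2 groups with n >= 2 each")
    if any(not np.all(np.isfinite(a)) for a in arrays):
        raise RejectedInputError("group values must be finite")
    pooled = np.concatenate(arrays)
    degenerate = np.ptp(pooled) == 0.0
    if degenerate:
        f_stat, p = 0.0, 1.0
        pairwise = [(a, b, 1.0) for a, b in combinations(labels, 2)]
    else:
        f_stat, p = sps.f_oneway(*arrays)
        if not np.isfinite(f_stat):  # identical group means, zero within-variance
            f_stat, p = 0.0, 1.0
        res = sps.tukey_hsd(*arrays)
        pairwise = []
        for i, j in combinations(range(len(labels)), 2):
            pij = float(res.pvalue[i, j])
            pairwise.append((labels[i], labels[j], min(max(pij, 0.0), 1.0)))
    return GroupComparison(
        method="anova_tukey",
        groups=labels,
        statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
        group_means={k: _mean_sem(a) for k, a in zip(labels, arrays)},
    )


def ks_two_sample(a, b, labels=("a", "b")) -> GroupComparison:
    """Two-sided two-sample Kolmogorov-Smirnov test (exact or asymptotic).

    Each sample needs n >= 5. The D statistic depends only on the empirical
    CDFs, so it is invariant under any strictly monotone transform applied to
    both samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise InsufficientDataError("each sample needs n >= 5")
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return GroupComparison(
        method="ks",
        groups=list(labels),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_means={labels[0]: _mean_sem(a), labels[1]: _mean_sem(b)},
    )


def bin_mean_sem(hypnograms) -> pd.DataFrame:
    """Cohort mean and SEM of sleep fraction per bin over non-missing animals.

    Bins are matched on ``bin_start_zt``. SEM is the sample SD over animals
    divided by sqrt(n); a bin observed in a single animal keeps its mean and
    gets a missing SEM.
    """
    hypnograms = list(hypnograms)
    if not hypnograms:
        raise InsufficientDataError("no hypnograms supplied")
    rows = []
    for h in hypnograms:
        for zt, frac, miss in zip(h.bin_start_zt, h.sleep_fraction, h.missing):
            if not miss:
                rows.append((float(zt), float(frac)))
    df = pd.DataFrame(rows, columns=["bin_start_zt", "sleep_fraction"])
    out = (
        df.groupby("bin_start_zt")["sleep_fraction"]
        .agg(mean="mean", sem=lambda v: sps.sem(v) if len(v) >= 2 else np.nan, n="count")
        .reset_index()
    )
    return out
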