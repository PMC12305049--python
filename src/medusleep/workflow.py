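"""Config-driven orchestration: figure-level analyses on synthetic cohorts.

A run config selects an experiment, supplies either input paths or a
synthetic-generation block (with a mandatory seed), and names an output
directory. Outputs are deterministic for a fixed seed, and every output table
carries the config hash in its filename-side JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .droptest import classify_fast_slow, compare_latencies, normalize_baselines
from .ephys import compare_isi_groups, compute_isis, detect_spikes
from .errors import ConfigError
from .pulse import track_pulses
from .schedule import annotate_trace, build_schedule, minutes_per_hour
from .sleep import day_night_summary, rebound_index, score_recording
from .stain import compare_signal_distributions, purple_mask, quantify_image
from .stats import bin_mean_sem
from .synthetic import (
    BehaviorGenParams,
    gen_cohort,
    gen_drop_trials,
    gen_stain_image,
    gen_voltage_trace,
)

log = logging.getLogger("medusleep")

EXPERIMENTS = ("sleep_bins", "drop_test", "ephys", "insitu", "schedules")


@dataclass
class RunConfig:
    experiment: str
    out_dir: str
    synthetic: dict | None = None
    inputs: dict | None = None
    bin_len_min: float = 30.0
    zt_start: float = 0.0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(f"experiment: unknown experiment {self.experiment!r}")
        if (self.synthetic is None) == (self.inputs is None):
            raise ConfigError("synthetic/inputs: exactly one must be present")
        if self.synthetic is not None and "seed" not in self.synthetic:
            raise ConfigError("synthetic.seed: seed is mandatory for synthetic runs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError("config root: expected a mapping")
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(f"config: {e}") from e

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# cohort-level pipeline helpers (also used by the acceptance script)


def score_cohort(traces, bin_len_min: float = 30.0, zt_start: float = 0.0,
                 condition: str = "control"):
    """Run pulse tracking and per-24-h-threshold scoring on each trace."""
    hypnos = []
    for i, trace in enumerate(traces):
        pulses = track_pulses(trace)
        log.info("animal %d: %d pulses, quality=%s", i, pulses.n_pulses, pulses.quality)
        hypnos.append(score_recording(pulses, bin_len_min=bin_len_min,
                                      zt_start=zt_start, animal_id=f"animal{i:02d}",
                                      condition=condition))
    return hypnos


def cohort_day_night(hypnos):
    """Cohort-mean day and night sleep percentages over animals."""
    summaries = [day_night_summary(h) for h in hypnos]
    day = float(np.mean([s.day_sleep_pct for s in summaries]))
    night = float(np.mean([s.night_sleep_pct for s in summaries]))
    return day, night


# ---------------------------------------------------------------------------
# experiment runners


def _gen_params(block: dict) -> BehaviorGenParams:
    fields = {k: v for k, v in block.get("params", {}).items()}
    return BehaviorGenParams(seed=block["seed"], **fields)


def _run_sleep_bins(cfg: RunConfig, out: Path) -> dict:
    blk = cfg.synthetic
    condition = blk.get("condition", "control")
    schedule = None
    if condition == "LSD":
        schedule = build_schedule("light", 5, 25, total_nights=blk.get("days", 2))
    elif condition == "MSD":
        schedule = build_schedule("mechanical", 1, 4, total_nights=blk.get("days", 2))
    params = _gen_params(blk)
    traces, truths = gen_cohort(condition, blk.get("n_animals", 3), blk.get("days", 2),
                                params=params, schedule=schedule, seed=blk["seed"])
    hypnos = score_cohort(traces, bin_len_min=cfg.bin_len_min, zt_start=cfg.zt_start,
                          condition=condition)
    for h in hypnos:
        mio.write_hypnogram_csv(h, out / f"hypnogram_{h.animal_id}.csv")
    bin_mean_sem(hypnos).to_csv(out / "cohort_bins.csv", index=False)
    day, night = cohort_day_night(hypnos)
    return {"condition": condition, "n_animals": len(hypnos),
            "day_sleep_pct": day, "night_sleep_pct": night}


def _run_drop_test(cfg: RunConfig, out: Path) -> dict:
    blk = cfg.synthetic
    trials = (gen_drop_trials(blk.get("n_trials", 40), acclimation_min=5.0, seed=blk["seed"])
              + gen_drop_trials(blk.get("n_trials", 40), acclimation_min=2.0,
                                seed=blk["seed"] + 1))
    trials = classify_fast_slow(normalize_baselines(trials))
    comp = compare_latencies(trials, grouping="speed_acclimation")
    mio.write_comparison_json(comp, out / "latency_comparison.json")
    rows = [{"animal_id": t.animal_id, "light": t.light,
             "acclimation_min": t.acclimation_min, "predrop_mean": t.predrop_mean,
             "normalized_predrop": t.normalized_predrop, "speed_class": t.speed_class,
             "latency_s": t.latency_s, "censored": t.censored} for t in trials]
    import pandas as pd
    pd.DataFrame(rows).to_csv(out / "drop_trials.csv", index=False)
    return {"n_trials": len(trials), "anova_p": comp.p_value}


def _run_ephys(cfg: RunConfig, out: Path) -> dict:
    blk = cfg.synthetic
    seed = blk["seed"]
    groups = {}
    for i, (label, mult) in enumerate(blk.get(
            "treatments", {"ASW-control": 1.0, "DTC-600uM": 2.0, "Nic-75uM": 0.6}).items()):
        isis = []
        for rep in range(blk.get("n_traces", 3)):
            trace, _ = gen_voltage_trace(blk.get("base_isi_ms", 150.0), isi_multiplier=mult,
                                         duration_ms=blk.get("duration_ms", 3000.0),
                                         seed=seed + 97 * i + rep, treatment=label)
            train = detect_spikes(trace)
            isis.extend(compute_isis(train).tolist())
        groups[label] = isis
        log.info("ephys %s: %d ISIs", label, len(isis))
    comp = compare_isi_groups(groups)
    mio.write_comparison_json(comp, out / "isi_comparison.json")
    return {"groups": {k: float(np.mean(v)) for k, v in groups.items()},
            "anova_p": comp.p_value}


def _run_insitu(cfg: RunConfig, out: Path) -> dict:
    blk = cfg.synthetic
    seed = blk["seed"]
    quants = {"control": [], "SD": []}
    fr = blk.get("purple_fractions", {"control": 0.08, "SD": 0.20})
    rng = np.random.default_rng(seed)
    for cond in quants:
        for i in range(blk.get("n_images", 8)):
            pf = float(np.clip(rng.normal(fr[cond], 0.02), 0.0, 0.9))
            img, mask, _ = gen_stain_image(64, 64, purple_fraction=pf,
                                           brown_fraction=0.1, seed=seed + i)
            quants[cond].append(quantify_image(img, mask, image_id=f"{cond}{i}",
                                               condition=cond))
    comp = compare_signal_distributions(quants["control"], quants["SD"],
                                        labels=("control", "SD"))
    mio.write_stainquant_csv(quants["control"] + quants["SD"], out / "stain_quants.csv")
    mio.write_comparison_json(comp, out / "stain_comparison.json")
    return {"ks_p": comp.p_value, "ks_D": comp.statistic}


def _run_schedules(cfg: RunConfig, out: Path) -> dict:
    light = build_schedule("light", 5, 25, total_nights=2)
    mech = build_schedule("mechanical", 1, 4, total_nights=2)
    mio.write_schedule_json(light, out / "light_schedule.json")
    mio.write_schedule_json(mech, out / "mechanical_schedule.json")
    return {"light_min_per_hour": minutes_per_hour(light),
            "mechanical_min_per_hour": minutes_per_hour(mech)}


_RUNNERS = {
    "sleep_bins": _run_sleep_bins,
    "drop_test": _run_drop_test,
    "ephys": _run_ephys,
    "insitu": _run_insitu,
    "schedules": _run_schedules,
}


def run_experiment(config: RunConfig | dict) -> dict:
    """Run one experiment; writes tables/JSONs to the output directory and
    returns the summary dict (also written as ``summary.json``)."""
    if isinstance(config, dict):
        config = RunConfig(**config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run %s config_hash=%s", config.experiment, config.hash())
    summary = _RUNNERS[config.experiment](config, out)
    summary["config_hash"] = config.hash()
    summary["experiment"] = config.experiment
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
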