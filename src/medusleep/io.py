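"""Readers and writers for the package's plain-text formats.

Conventions, enforced by the readers: CSV with a header row, UTF-8, "."
decimal separator; times in seconds, ZT in hours; JSON for sidecars,
schedules, ground truth and comparison results. Every writer's output is
readable by its reader with lossless field recovery.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import Hypnogram, IntensityTrace, PulseSeries, SpikeTrain, StainQuant, VoltageTrace
from .errors import FormatError
from .schedule import StimulusSchedule
from .stats import GroupComparison

# ---------------------------------------------------------------------------
# intensity traces


def write_trace_csv(trace: IntensityTrace, path):
    df = pd.DataFrame({
        "frame": np.arange(trace.n_frames),
        "time_s": trace.time_s,
        "intensity": trace.intensity,
        "light_state": trace.light_state if trace.light_state is not None else "",
        "missing": trace.missing if trace.missing is not None else False,
    })
    df.to_csv(path, index=False)


def read_trace_csv(path, fps: float | None = None) -> IntensityTrace:
    df = pd.read_csv(path)
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise FormatError(f"trace CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if fps is None:
        if t.size < 2:
            raise FormatError("cannot infer fps from a single-row trace")
        fps = 1.0 / float(np.median(np.diff(t)))
    light = df["light_state"].astype(str).to_numpy() if "light_state" in df else None
    if light is not None and np.all((light == "") | (light == "nan")):
        light = None
    missing = df["missing"].to_numpy(dtype=bool) if "missing" in df else None
    return IntensityTrace(time_s=t, intensity=df["intensity"].to_numpy(dtype=float),
                          fps=fps, light_state=light, missing=missing)


# ---------------------------------------------------------------------------
# pulse series (CSV + JSON sidecar)


def write_pulses_csv(pulses: PulseSeries, path, sidecar: bool = True):
    path = Path(path)
    ipis = np.concatenate(([np.nan], pulses.ipis)) if pulses.n_pulses else np.empty(0)
    pd.DataFrame({"pulse_time_s": pulses.pulse_times, "ipi_s": ipis}).to_csv(path, index=False)
    if sidecar:
        meta = {
            "threshold": None if np.isnan(pulses.threshold_used) else pulses.threshold_used,
            "quality": pulses.quality,
            "source_window": list(pulses.source_window) if pulses.source_window else None,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_pulses_csv(path) -> PulseSeries:
    path = Path(path)
    df = pd.read_csv(path)
    if "pulse_time_s" not in df.columns:
        raise FormatError("pulse CSV missing column 'pulse_time_s'")
    meta = {}
    side = path.with_suffix(".json")
    if side.exists():
        meta = json.loads(side.read_text())
    return PulseSeries(
        pulse_times=df["pulse_time_s"].to_numpy(dtype=float),
        threshold_used=meta.get("threshold") if meta.get("threshold") is not None else np.nan,
        quality=meta.get("quality", "ok"),
        source_window=tuple(meta["source_window"]) if meta.get("source_window") else None,
    )


# ---------------------------------------------------------------------------
# hypnograms


def write_hypnogram_csv(h: Hypnogram, path):
    pd.DataFrame({
        "animal_id": h.animal_id,
        "condition": h.condition,
        "bin_start_zt": h.bin_start_zt,
        "bin_len_min": h.bin_len_min,
        "sleep_fraction": h.sleep_fraction,
        "missing": h.missing,
        "analyzable_s": h.analyzable_s,
        "threshold": np.resize(h.threshold, h.bin_start_zt.size),
    }).to_csv(path, index=False)


def read_hypnogram_csv(path) -> Hypnogram:
    df = pd.read_csv(path)
    need = {"animal_id", "bin_start_zt", "sleep_fraction", "missing"}
    if not need <= set(df.columns):
        raise FormatError(f"hypnogram CSV missing columns {sorted(need - set(df.columns))}")
    return Hypnogram(
        animal_id=str(df["animal_id"].iloc[0]),
        condition=str(df["condition"].iloc[0]) if "condition" in df else "control",
        bin_start_zt=df["bin_start_zt"].to_numpy(dtype=float),
        bin_len_min=float(df["bin_len_min"].iloc[0]) if "bin_len_min" in df else 30.0,
        sleep_fraction=df["sleep_fraction"].to_numpy(dtype=float),
        threshold=np.unique(df["threshold"].to_numpy(dtype=float)) if "threshold" in df else np.array([1.0]),
        missing=df["missing"].to_numpy(dtype=bool),
        analyzable_s=df["analyzable_s"].to_numpy(dtype=float) if "analyzable_s" in df else None,
    )


# ---------------------------------------------------------------------------
# voltage traces / spike trains


def read_voltage_csv(path, sampling_interval_ms: float | None = None,
                     treatment: str = "other") -> VoltageTrace:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        t = df[cols["time_ms"]].to_numpy(dtype=float)
        v = df[cols["voltage_mv"]].to_numpy(dtype=float)
    except KeyError as e:
        raise FormatError("voltage file needs 'time_ms' and 'voltage_mV' columns") from e
    if sampling_interval_ms is None:
        sampling_interval_ms = float(np.median(np.diff(t)))
    return VoltageTrace(time_ms=t, voltage_mV=v,
                        sampling_interval_ms=sampling_interval_ms, treatment=treatment)


def write_voltage_csv(trace: VoltageTrace, path):
    pd.DataFrame({"time_ms": trace.time_ms, "voltage_mV": trace.voltage_mV}).to_csv(path, index=False)


def write_spikes_csv(train: SpikeTrain, path):
    isis = np.concatenate(([np.nan], train.isis_ms)) if train.n_spikes else np.empty(0)
    pd.DataFrame({
        "onset_ms": train.onsets_ms,
        "offset_ms": train.offsets_ms,
        "peak_amp_mV": train.peak_amp_mV,
        "isi_ms": isis,
    }).to_csv(path, index=False)


def read_spikes_csv(path) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(
        onsets_ms=df["onset_ms"].to_numpy(dtype=float),
        offsets_ms=df["offset_ms"].to_numpy(dtype=float),
        peak_amp_mV=df["peak_amp_mV"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# stain quantifications, images, masks


def write_stainquant_csv(quants, path):
    pd.DataFrame([{
        "image_id": q.image_id, "condition": q.condition,
        "rhopalium_px": q.rhopalium_px, "purple_px": q.purple_px, "signal": q.signal,
    } for q in quants]).to_csv(path, index=False)


def read_stainquant_csv(path) -> list[StainQuant]:
    df = pd.read_csv(path)
    return [StainQuant(image_id=str(r.image_id), condition=str(r.condition),
                       rhopalium_px=int(r.rhopalium_px), purple_px=int(r.purple_px))
            for r in df.itertuples()]


def write_image(image: np.ndarray, path):
    """Write an RGB float [0,1] or uint8 image as PNG/TIFF."""
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, img)


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.dtype == np.uint8:
        img = img / 255.0
    return np.asarray(img, dtype=float)


def write_mask_png(mask: np.ndarray, path):
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


# ---------------------------------------------------------------------------
# schedules and comparisons


def write_schedule_json(s: StimulusSchedule, path):
    Path(path).write_text(json.dumps({
        "kind": s.kind, "on_min": s.on_min, "off_min": s.off_min,
        "active_window": list(s.active_window), "camera_gated": s.camera_gated,
        "on_intervals": [list(iv) for iv in s.on_intervals],
    }, indent=1))


def read_schedule_json(path) -> StimulusSchedule:
    d = json.loads(Path(path).read_text())
    return StimulusSchedule(
        kind=d["kind"], on_min=d["on_min"], off_min=d["off_min"],
        active_window=tuple(d["active_window"]),
        on_intervals=[tuple(iv) for iv in d["on_intervals"]],
        camera_gated=d["camera_gated"],
    )


def write_comparison_json(c: GroupComparison, path, extra: dict | None = None):
    d = {
        "method": c.method, "groups": list(c.groups),
        "statistic": c.statistic, "p_value": c.p_value,
        "pairwise": [[a, b, p] for a, b, p in c.pairwise],
        "group_means": {str(k): list(v) for k, v in c.group_means.items()},
    }
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1, allow_nan=True))


def read_comparison_json(path) -> GroupComparison:
    d = json.loads(Path(path).read_text())
    return GroupComparison(
        method=d["method"], groups=d["groups"], statistic=d["statistic"],
        p_value=d["p_value"], pairwise=[tuple(p) for p in d["pairwise"]],
        group_means={k: tuple(v) for k, v in d["group_means"].items()},
    )
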