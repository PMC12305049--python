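"""Ground-truth-labeled synthetic inputs for every stage of the pipeline.

The generators emulate the statistical structure the analysis assumes:

* pulse trains whose inter-pulse intervals (IPIs) come from a day (wake)
  distribution or, at night, from a wake/sleep mixture;
* mean-intensity traces with an inverted-Gaussian dip at each pulse, slow
  sinusoidal lighting drift and Gaussian sensor noise;
* cohorts under control / light (LSD) / mechanical (MSD) deprivation
  schedules, with forced wake during stimulus ON windows and a configurable
  next-day rebound;
* extracellular voltage traces with compact smooth spikes at controlled
  interspike intervals (an ISI multiplier > 1 emulates a nicotinic antagonist
  such as tubocurarine, < 1 an agonist such as nicotine);
* purple-on-brown stained rhopalium images with exact pixel-count ground truth.

IPI distributions are truncated Gaussians; the field of the distribution is
not pinned down by behavioral data, and a truncated Gaussian is the simplest
choice that exercises the median-threshold scoring.

The control defaults (:class:`BehaviorGenParams`) were calibrated once so the
full pipeline (rendering -> pulse detection -> per-24-h median threshold ->
30-min binning) scores control night-time sleep near 70%; they are named
constants, not tunable knobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from skimage.color import hsv2rgb

from .containers import DropTrial, GroundTruth, IntensityTrace, VoltageTrace
from .errors import MissingScheduleError, RejectedInputError
from .schedule import StimulusSchedule, in_on_interval

# ---------------------------------------------------------------------------
# behavior generator


@dataclass(frozen=True)
class BehaviorGenParams:
    """Parameters of the behavioral (pulse/intensity) generator.

    Durations are seconds, intensities arbitrary camera units. The defaults
    are the calibrated control condition (see module docstring).
    ``night_sleep_target`` is the probability that a night IPI is drawn from
    the long-IPI (sleep) component rather than the day (wake) component.
    """

    day_ipi_mean: float = 1.2
    day_ipi_sd: float = 0.2
    night_ipi_mean: float = 4.5
    night_ipi_sd: float = 0.9
    night_sleep_target: float = 0.13
    pulse_dip_depth: float = 30.0
    pulse_dip_width: float = 0.2
    noise_sd: float = 3.0
    drift_amplitude: float = 10.0
    drift_period: float = 600.0
    fps: float = 15.0
    seed: int = 0

    def __post_init__(self):
        for name in ("day_ipi_mean", "day_ipi_sd", "night_ipi_mean", "night_ipi_sd",
                     "pulse_dip_width", "drift_period"):
            if getattr(self, name) < 0 or (name.endswith("mean") and getattr(self, name) <= 0):
                raise RejectedInputError(f"{name} must be positive")
        if self.fps <= 0:
            raise RejectedInputError("fps must be > 0")
        if not 0.0 <= self.night_sleep_target <= 1.0:
            raise RejectedInputError("night_sleep_target must lie in [0, 1]")


def _draw_ipi(rng, mean, sd, floor):
    ipi = rng.normal(mean, sd) if sd > 0 else mean
    return max(ipi, floor)


def gen_pulse_times(
    params: BehaviorGenParams,
    duration: float,
    zt_start: float = 0.0,
    rng: np.random.Generator | None = None,
    schedule: StimulusSchedule | None = None,
    day_sleep_prob: float | np.ndarray = 0.0,
    night_sleep_prob_off: float | None = None,
):
    """Generate pulse times over ``[0, duration]`` seconds starting at ``zt_start``.

    Successive differences are drawn from the day (wake) distribution during
    ZT 0-12 and from the wake/sleep mixture during ZT 12-24, truncated below at
    one frame interval. The first pulse is at t=0.

    ``schedule`` forces the wake distribution inside stimulus ON windows.
    ``day_sleep_prob`` sets the daytime sleep-draw probability (scalar, or one
    value per 24-h day to model a deprivation rebound); ``night_sleep_prob_off``
    overrides the nighttime sleep probability outside ON windows (used to model
    deprivation nights).

    Returns ``(pulse_times, GroundTruth)`` with one wake/sleep state per IPI.
    """
    if duration <= 0:
        raise RejectedInputError("duration must be > 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    floor = 1.0 / params.fps
    day_sleep_prob = np.atleast_1d(np.asarray(day_sleep_prob, dtype=float))
    if night_sleep_prob_off is None:
        night_sleep_prob_off = params.night_sleep_target

    times = [0.0]
    states = []
    t = 0.0
    while True:
        zt = (zt_start + t / 3600.0) % 24.0
        day_idx = int((zt_start * 3600.0 + t) // 86400.0)
        if zt < 12.0:
            p_sleep = day_sleep_prob[min(day_idx, day_sleep_prob.size - 1)]
        elif schedule is not None and in_on_interval(
                np.array([zt_start * 3600.0 + t]), schedule)[0]:
            p_sleep = 0.0
        else:
            p_sleep = night_sleep_prob_off
        asleep = rng.random() < p_sleep
        if asleep:
            ipi = _draw_ipi(rng, params.night_ipi_mean, params.night_ipi_sd, floor)
        else:
            ipi = _draw_ipi(rng, params.day_ipi_mean, params.day_ipi_sd, floor)
        if t + ipi > duration + 1e-12:
            break
        t += ipi
        times.append(t)
        states.append("sleep" if asleep else "wake")
    times = np.asarray(times)
    truth = GroundTruth(true_pulse_times=times, true_state_per_ipi=np.asarray(states))
    return times, truth


def render_intensity_trace(
    pulse_times,
    params: BehaviorGenParams,
    duration: float | None = None,
    baseline: float = 100.0,
    zt_start: float = 0.0,
    rng: np.random.Generator | None = None,
) -> IntensityTrace:
    """Render a mean-intensity trace with a negative dip at each pulse.

    Trace = baseline + sinusoidal lighting drift + Gaussian noise, minus an
    inverted Gaussian of depth ``pulse_dip_depth`` and width ``pulse_dip_width``
    (dip sigma = width/2) centered at each pulse time, so the least-intense
    frames coincide with contractions by construction.
    """
    pulse_times = np.asarray(pulse_times, dtype=float)
    if pulse_times.size >= 2 and np.any(np.diff(pulse_times) <= 0):
        raise RejectedInputError("pulse times must be sorted strictly increasing")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    fps = params.fps
    if duration is None:
        duration = float(pulse_times[-1]) if pulse_times.size else 1.0
    n = int(round(duration * fps)) + 1
    t = np.arange(n) / fps
    x = np.full(n, float(baseline))
    if params.drift_amplitude > 0 and params.drift_period > 0:
        x += params.drift_amplitude * np.sin(2 * np.pi * t / params.drift_period)
    if params.noise_sd > 0:
        x += rng.normal(0.0, params.noise_sd, size=n)
    if params.pulse_dip_width < 2.0 / fps:
        warnings.warn("pulse_dip_width < 2 frame intervals; dips may be undetectable")
    if pulse_times.size:
        sigma = params.pulse_dip_width / 2.0
        half = max(1, int(np.ceil(4 * sigma * fps)))
        offsets = np.arange(-half, half + 1)
        centers = np.round(pulse_times * fps).astype(int)
        idx = centers[:, None] + offsets[None, :]
        dt = idx / fps - pulse_times[:, None]
        contrib = params.pulse_dip_depth * np.exp(-0.5 * (dt / sigma) ** 2)
        valid = (idx >= 0) & (idx < n)
        np.subtract.at(x, idx[valid], contrib[valid])
    zt = (zt_start + t / 3600.0) % 24.0
    light = np.where(zt < 12.0, "day", "night")
    return IntensityTrace(time_s=t, intensity=x, fps=fps, light_state=light)


def gen_cohort(
    condition: str,
    n_animals: int,
    days: int,
    params: BehaviorGenParams | None = None,
    schedule: StimulusSchedule | None = None,
    seed: int | None = None,
    rebound_delta: float = 0.3,
    deprivation_night_sleep: float = 0.02,
    render: bool = True,
):
    """Generate a cohort of ``n_animals`` recorded for ``days`` full day/night cycles.

    For LSD/MSD, night IPIs inside scheduled ON intervals are drawn from the
    wake distribution; outside ON intervals the sleep probability drops to
    ``deprivation_night_sleep``; every day after the first deprivation night
    the daytime sleep probability is raised by ``rebound_delta`` (compensatory
    rebound). Returns ``(traces, truths)``; with ``render=False`` the traces
    list holds ``None`` (ground-truth-only cohorts for fast tests).
    """
    if condition not in ("control", "LSD", "MSD"):
        raise RejectedInputError(f"unknown condition {condition!r}")
    if n_animals < 1:
        raise RejectedInputError("n_animals must be >= 1")
    if params is None:
        params = BehaviorGenParams()
    if condition in ("LSD", "MSD") and schedule is None:
        raise MissingScheduleError(f"{condition} requires a stimulus schedule")
    if seed is None:
        seed = params.seed
    duration = days * 86400.0
    if condition == "control":
        day_p = 0.0
        night_off = params.night_sleep_target
        sched = None
    else:
        # day 0 precedes the first deprivation night: no rebound yet
        day_p = np.array([0.0] + [rebound_delta] * max(0, days - 1))
        night_off = deprivation_night_sleep
        sched = schedule
    traces, truths = [], []
    children = np.random.SeedSequence(seed).spawn(n_animals)
    for ss in children:
        rng = np.random.default_rng(ss)
        times, truth = gen_pulse_times(
            params, duration, zt_start=0.0, rng=rng, schedule=sched,
            day_sleep_prob=day_p, night_sleep_prob_off=night_off,
        )
        trace = None
        if render:
            trace = render_intensity_trace(times, params, duration=duration, rng=rng)
        traces.append(trace)
        truths.append(truth)
    return traces, truths


# ---------------------------------------------------------------------------
# image-stack rendering (for the ROI extraction stage)


def render_frame_stack(trace: IntensityTrace, shape=(16, 16), background: float = 0.0):
    """Expand a trace into a uniform grayscale frame stack whose ROI mean
    reproduces the trace exactly (the downstream pipeline consumes only the
    per-frame mean, so uniform frames suffice)."""
    n = trace.n_frames
    h, w = shape
    frames = np.empty((n, h, w), dtype=float)
    frames[:] = trace.intensity[:, None, None]
    if background:
        frames += background
    return frames


# ---------------------------------------------------------------------------
# extracellular voltage generator


def gen_voltage_trace(
    base_isi_ms: float,
    isi_multiplier: float = 1.0,
    spike_amplitude_mV: float = 50.0,
    spike_duration_ms: float = 30.0,
    noise_sd_mV: float = 1.0,
    duration_ms: float = 2000.0,
    sampling_interval_ms: float = 0.08,
    isi_jitter: float = 0.05,
    seed: int = 0,
    treatment: str = "ASW-control",
):
    """Voltage trace with smooth half-sine spikes at controlled ISIs.

    ISIs (offset-to-onset gaps) are drawn near ``base_isi_ms * isi_multiplier``
    with fractional jitter ``isi_jitter``. Spikes outside the 20-50 ms
    physiological waveform range are generated but labeled invalid in the
    ground truth. Warns when the amplitude is within the noise floor.
    """
    if base_isi_ms <= 0 or duration_ms <= 0:
        raise RejectedInputError("base_isi_ms and duration_ms must be > 0")
    rng = np.random.default_rng(seed)
    if spike_amplitude_mV <= 5 * noise_sd_mV:
        warnings.warn("spike amplitude at or below the noise floor; detection unreliable")
    n = int(round(duration_ms / sampling_interval_ms)) + 1
    t = np.arange(n) * sampling_interval_ms
    v = rng.normal(0.0, noise_sd_mV, size=n) if noise_sd_mV > 0 else np.zeros(n)
    target_isi = base_isi_ms * isi_multiplier
    windows = []
    onset = min(50.0, target_isi)  # settle time before the first spike
    while onset + spike_duration_ms < duration_ms:
        offset = onset + spike_duration_ms
        windows.append((onset, offset))
        gap = target_isi * (1.0 + (isi_jitter * rng.standard_normal() if isi_jitter > 0 else 0.0))
        gap = max(gap, 5.0 * sampling_interval_ms)
        onset = offset + gap
    for a, b in windows:
        i0, i1 = int(np.ceil(a / sampling_interval_ms)), int(np.floor(b / sampling_interval_ms))
        tt = t[i0:i1 + 1]
        v[i0:i1 + 1] += spike_amplitude_mV * np.sin(np.pi * (tt - a) / spike_duration_ms)
    valid = np.array([20.0 <= (b - a) <= 50.0 for a, b in windows], dtype=bool)
    trace = VoltageTrace(time_ms=t, voltage_mV=v,
                         sampling_interval_ms=sampling_interval_ms, treatment=treatment)
    truth = GroundTruth(true_spike_windows=windows, true_spike_valid=valid)
    return trace, truth


# ---------------------------------------------------------------------------
# stained-image generator

#: HSV colors used for synthetic stains (hue degrees, saturation, value)
PURPLE_HSV = (290.0, 0.60, 0.55)
BROWN_HSV = (32.0, 0.55, 0.35)
TISSUE_HSV = (35.0, 0.04, 0.92)  # pale, low-saturation tissue background


def gen_stain_image(
    height: int,
    width: int,
    rhopalium_mask_shape: str = "ellipse",
    purple_fraction: float = 0.1,
    brown_fraction: float = 0.1,
    seed: int = 0,
    cast: tuple | None = None,
):
    """Synthetic stained-rhopalium RGB image with exact pixel-count ground truth.

    Within the rhopalium mask, exactly ``round(purple_fraction * mask_area)``
    pixels are colored in the purple hue band (the hybridization signal) and
    ``round(brown_fraction * mask_area)`` distinct pixels in the brown band
    (the melanin confounder); the rest of the mask is pale tissue and the
    background is white. ``cast`` multiplies the RGB channels to emulate a
    nonspecific color cast (exercises white balancing).
    """
    if not (0.0 <= purple_fraction <= 1.0 and 0.0 <= brown_fraction <= 1.0):
        raise RejectedInputError("fractions must lie in [0, 1]")
    if purple_fraction + brown_fraction > 1.0:
        raise RejectedInputError("purple_fraction + brown_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    if rhopalium_mask_shape == "ellipse":
        cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
        ry, rx = height * 0.38, width * 0.38
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    elif rhopalium_mask_shape == "full":
        mask = np.ones((height, width), dtype=bool)
    else:
        raise RejectedInputError(f"unknown mask shape {rhopalium_mask_shape!r}")
    area = int(mask.sum())
    n_purple = int(round(purple_fraction * area))
    n_brown = int(round(brown_fraction * area))
    flat_idx = np.flatnonzero(mask.ravel())
    chosen = rng.choice(flat_idx, size=n_purple + n_brown, replace=False)
    purple_idx, brown_idx = chosen[:n_purple], chosen[n_purple:]

    hsv = np.zeros((height, width, 3), dtype=float)
    hsv[..., 2] = 1.0  # white background
    hsv.reshape(-1, 3)[flat_idx] = (TISSUE_HSV[0] / 360.0, TISSUE_HSV[1], TISSUE_HSV[2])
    hsv.reshape(-1, 3)[purple_idx] = (PURPLE_HSV[0] / 360.0, PURPLE_HSV[1], PURPLE_HSV[2])
    hsv.reshape(-1, 3)[brown_idx] = (BROWN_HSV[0] / 360.0, BROWN_HSV[1], BROWN_HSV[2])
    img = hsv2rgb(hsv)
    if cast is not None:
        img = np.clip(img * np.asarray(cast, dtype=float)[None, None, :], 0.0, 1.0)
    truth = GroundTruth(true_purple_fraction=n_purple / area if area else 0.0)
    return img, mask, truth


# ---------------------------------------------------------------------------
# drop-test generators


def gen_drop_trace(
    params: BehaviorGenParams,
    predrop_ipis,
    drop_time_s: float,
    latency_s: float,
    postdrop_duration_s: float = 60.0,
    rng: np.random.Generator | None = None,
) -> IntensityTrace:
    """Freeze-then-resume trace: steady predrop pulsing, a pulse-free freeze of
    ``latency_s`` after the drop, then resumed day-rate pulsing."""
    predrop_ipis = np.asarray(predrop_ipis, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    # place predrop pulses ending just before the drop
    pre = drop_time_s - 0.5 - np.concatenate(([0.0], np.cumsum(predrop_ipis[::-1])))[::-1]
    t = drop_time_s + latency_s
    post = [t]
    end = drop_time_s + postdrop_duration_s
    while True:
        ipi = _draw_ipi(rng, params.day_ipi_mean, params.day_ipi_sd, 1.0 / params.fps)
        if post[-1] + ipi > end:
            break
        post.append(post[-1] + ipi)
    times = np.concatenate([pre[pre >= 0], np.asarray(post)])
    return render_intensity_trace(times, params, duration=end, rng=rng)


def gen_drop_trials(
    n_trials: int,
    acclimation_min: float = 5.0,
    fast_ipi_s: float = 1.0,
    slow_ipi_s: float = 3.0,
    latency_coupling: float = 4.0,
    base_latency_s: float = 3.0,
    latency_sd_s: float = 1.0,
    seed: int = 0,
):
    """Synthetic drop-test cohort at the trial level.

    Half the trials pulse fast predrop, half slow. After a 5-min acclimation
    the arousal latency is coupled to the predrop IPI (slow/sleeping animals
    take ``latency_coupling`` s longer per predrop-IPI second); after a 2-min
    acclimation (the redrop) the latency is uncoupled — reversibility.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        slow = i % 2 == 1
        mean_ipi = slow_ipi_s if slow else fast_ipi_s
        ipis = np.maximum(rng.normal(mean_ipi, 0.15 * mean_ipi, size=3), 0.1)
        coupled = acclimation_min >= 5.0
        lat = base_latency_s + (latency_coupling * (ipis.mean() - fast_ipi_s) if coupled else 0.0)
        lat = max(0.2, lat + rng.normal(0.0, latency_sd_s))
        drop_t = 100.0
        trials.append(DropTrial(
            animal_id=f"jelly{i:02d}",
            light="night" if slow else "day",
            acclimation_min=acclimation_min,
            predrop_ipis=ipis,
            drop_time_s=drop_t,
            first_pulse_time_s=drop_t + lat,
        ))
    return trials
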