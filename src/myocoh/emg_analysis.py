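"""Surface-EMG preprocessing and the extensor-ratio (ER) individuation statistic.

Processing chain: 15-450 Hz zero-phase bandpass (4th-order Butterworth,
forward-backward), full-wave rectification, normalization to the recorded
maximum grasp. Per trial, the normalized envelope is averaged over the last
3 s of the 4 s hold, and muscle individuation is summarized as

    ER = EMG_extensor / (EMG_extensor + EMG_flexor)

with ER near 1 meaning predominantly extensor activity, near 0
predominantly flexor, and 0.5 comparable recruitment from both groups.
``EMG_extensor``/``EMG_flexor`` are the single channels per group with the
largest hold/rest signal-to-noise ratio, mirroring the online feedback
channel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    DegenerateError,
    ParameterError,
    ScheduleError,
)
from .signal_io import ChannelMap, Recording, TrialSchedule

EMG_BAND = (15.0, 450.0)


@dataclass
class EnvelopeSeries:
    """Rectified, normalized EMG amplitude in fraction-of-maximum units."""

    values: np.ndarray
    rate: float
    label: str
    reference: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.reference <= 0:
            raise ParameterError(f"normalization reference must be > 0, got {self.reference}")
        if (self.values < 0).any():
            raise ParameterError("envelope values must be nonnegative")


@dataclass
class ERResult:
    task: str
    per_trial_er: list[float]
    mean_er: float
    channels_used: tuple[str, str]  # (extensor label, flexor label)


@dataclass
class ScreeningResult:
    per_trial_pass: list[bool]
    passed: bool
    threshold: float = 0.30
    n_trials: int = 10
    hold_s: float = 4.0


def bandpass_emg(recording: Recording, band=EMG_BAND) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass shared by all EMG paths."""
    if recording.rate <= 2 * band[1]:
        raise ParameterError(
            f"rate {recording.rate} Hz below Nyquist for a {band[1]} Hz band edge"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=recording.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    from dataclasses import replace

    return replace(recording, samples=filtered)


def preprocess_emg(
    recording: Recording, max_grasp_reference: dict[str, float] | float
) -> dict[str, EnvelopeSeries]:
    """Bandpass, rectify and normalize each channel; returns label -> envelope.

    ``max_grasp_reference`` is either one reference for all channels or a
    per-label mapping (as returned by :func:`compute_max_grasp`).
    """
    filtered = bandpass_emg(recording)
    out = {}
    for i, label in enumerate(recording.labels):
        ref = (
            max_grasp_reference[label]
            if isinstance(max_grasp_reference, dict)
            else float(max_grasp_reference)
        )
        if ref <= 0:
            raise ParameterError(f"normalization reference for {label!r} must be > 0")
        out[label] = EnvelopeSeries(
            np.abs(filtered.samples[i]) / ref, recording.rate, label, ref
        )
    return out


def compute_max_grasp(
    calibration: Recording | list[Recording], window_s: float = 0.25, percentile: float = 95.0
) -> dict[str, float]:
    """Per-channel maximum-grasp reference.

    The reference is the 95th percentile of a 250 ms moving average of the
    rectified, bandpassed calibration signal — robust to isolated spikes.
    With several calibration repeats, the per-channel maximum across
    repeats is used.
    """
    recs = calibration if isinstance(calibration, list) else [calibration]
    if not recs:
        raise ParameterError("at least one calibration recording required")
    refs: dict[str, float] = {}
    for rec in recs:
        if rec.duration < 2.0:
            raise ParameterError("calibration segment must be at least 2 s")
        filtered = bandpass_emg(rec)
        win = max(int(round(window_s * rec.rate)), 1)
        kernel = np.ones(win) / win
        for i, label in enumerate(rec.labels):
            smoothed = np.convolve(np.abs(filtered.samples[i]), kernel, mode="valid")
            ref = float(np.percentile(smoothed, percentile))
            refs[label] = max(refs.get(label, 0.0), ref)
    return refs


def _interval_slice(rate: float, start: float, stop: float, n: int, t0: float = 0.0):
    i0 = int(round((start - t0) * rate))
    i1 = int(round((stop - t0) * rate))
    return slice(max(i0, 0), min(i1, n))


def select_feedback_channel(
    envelopes: dict[str, EnvelopeSeries],
    schedule: TrialSchedule,
    group: str,
    channel_map: ChannelMap,
) -> str:
    """Channel of ``group`` with the largest hold/rest RMS ratio.

    Ties break deterministically in channel-map order (which is also the
    order candidates are evaluated in).
    """
    candidates = [c for c in channel_map.group_channels(group) if c in envelopes]
    if not candidates:
        raise ParameterError(f"no {group} channel present in the envelopes")
    holds = schedule.hold_intervals()
    rests = schedule.rest_intervals()
    if not holds or not rests:
        raise ScheduleError("schedule must contain at least one hold and one rest")
    best_label, best_snr = None, -np.inf
    any_rest = False
    for label in candidates:
        env = envelopes[label]
        n = env.values.size
        hold_vals = np.concatenate(
            [env.values[_interval_slice(env.rate, a, b, n)] for a, b in holds]
        )
        rest_vals = np.concatenate(
            [env.values[_interval_slice(env.rate, a, b, n)] for a, b in rests]
        )
        rest_rms = float(np.sqrt(np.mean(rest_vals**2)))
        if rest_rms > 0:
            any_rest = True
            snr = float(np.sqrt(np.mean(hold_vals**2))) / rest_rms
            if snr > best_snr:
                best_label, best_snr = label, snr
    if not any_rest:
        raise DegenerateError(f"zero rest RMS on every {group} candidate")
    return best_label


def segment_trials(
    envelope: EnvelopeSeries, schedule: TrialSchedule, analysis_window_s: float = 3.0
) -> list[np.ndarray]:
    """Final ``analysis_window_s`` of each hold, one segment per trial."""
    segments = []
    n = envelope.values.size
    for onset, hold, _ in schedule.trials:
        if hold < analysis_window_s:
            raise ScheduleError(
                f"hold of {hold} s shorter than the {analysis_window_s} s analysis window"
            )
        sl = _interval_slice(envelope.rate, onset + hold - analysis_window_s, onset + hold, n)
        if sl.stop - sl.start <= 0:
            raise ScheduleError("trial window falls outside the recording")
        segments.append(envelope.values[sl])
    return segments


def compute_er(extensor_mean: float, flexor_mean: float) -> float:
    """Extensor ratio: extensor activity over total activity, in [0, 1]."""
    if extensor_mean < 0 or flexor_mean < 0:
        raise ParameterError("activity means must be nonnegative")
    total = extensor_mean + flexor_mean
    if total <= 0:
        raise DegenerateError("ER undefined: both muscle groups silent")
    return extensor_mean / total


def er_pipeline(
    recording: Recording,
    schedule: TrialSchedule,
    channel_map: ChannelMap,
    calibration: Recording | list[Recording],
    analysis_window_s: float = 3.0,
) -> ERResult:
    """Full ER analysis of one tracking session."""
    channel_map.validate_against(recording, "EMG")
    refs = compute_max_grasp(calibration)
    envelopes = preprocess_emg(recording, refs)
    ext_label = select_feedback_channel(envelopes, schedule, "extensor", channel_map)
    flex_label = select_feedback_channel(envelopes, schedule, "flexor", channel_map)
    ext_segments = segment_trials(envelopes[ext_label], schedule, analysis_window_s)
    flex_segments = segment_trials(envelopes[flex_label], schedule, analysis_window_s)
    per_trial = [
        compute_er(float(np.mean(e)), float(np.mean(f)))
        for e, f in zip(ext_segments, flex_segments)
    ]
    return ERResult(
        task=schedule.task,
        per_trial_er=per_trial,
        mean_er=float(np.mean(per_trial)),
        channels_used=(ext_label, flex_label),
    )


def screening_test(
    envelope: EnvelopeSeries,
    schedule: TrialSchedule,
    threshold: float = 0.30,
    n_trials: int = 10,
    hold_s: float = 4.0,
) -> ScreeningResult:
    """Enrollment screen: hold ≥ ``threshold`` of maximum for ``n_trials`` holds.

    A trial passes when its hold-window mean meets the threshold
    (inclusive); the screen passes only if every one of the first
    ``n_trials`` trials passes.
    """
    if schedule.n_trials < n_trials:
        raise ScheduleError(
            f"screen needs {n_trials} trials, schedule has {schedule.n_trials}"
        )
    per_trial = []
    n = envelope.values.size
    for onset, hold, _ in schedule.trials[:n_trials]:
        sl = _interval_slice(envelope.rate, onset, onset + min(hold, hold_s), n)
        # inclusive boundary with a float-accumulation guard
        per_trial.append(bool(np.mean(envelope.values[sl]) >= threshold - 1e-12))
    return ScreeningResult(
        per_trial_pass=per_trial,
        passed=all(per_trial),
        threshold=threshold,
        n_trials=n_trials,
        hold_s=hold_s,
    )


def control_signal(ext_env_sample: float, flex_env_sample: float, epsilon: float = 0.02) -> float:
    """Regularized instantaneous extensor ratio for game control.

    ``(ext + eps/2) / (ext + flex + eps)``: continuous in both inputs,
    0.5 at rest, approaches the raw ratio once activity dominates ``eps``.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    if ext_env_sample < 0 or flex_env_sample < 0:
        raise ParameterError("envelope samples must be nonnegative")
    return (ext_env_sample + epsilon / 2) / (ext_env_sample + flex_env_sample + epsilon)
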