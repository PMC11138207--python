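"""Corticomuscular coherence (CMC) and the hemispheric laterality index.

EEG preprocessing follows the usual resting montage hygiene: 5-100 Hz
zero-phase bandpass, bad-channel removal (channel kurtosis z-scored across
the montage, plus flatlines), common-average re-reference over the retained
channels, per-channel z-scoring. The EMG side is the magnitude of the
analytic (Hilbert) signal of the 15-450 Hz bandpassed EMG, z-scored.

Coherence is Welch magnitude-squared coherence with 128 ms Hann windows and
75% overlap (at 1 kHz: 128-sample windows, 32-sample hop). Each profile
carries a confidence level

    CL = 1 - alpha^(1 / (L - 1)),      alpha = 0.05

where L is the adjusted number of segments — the count of *equivalent
independent* segments ``floor(N / W)``, since the confidence formula
assumes independence and the raw overlapped count would understate the
threshold.

Beta-band (12-30 Hz) coherence is summarized by Fisher-transforming each
bin, ``atanh(sqrt(coh))``, scaling by ``sqrt(2L)`` to an approximately
standard-normal score under independence, and combining in-band bins with
Stouffer's method. Hemispheric asymmetry is the laterality index

    (Coh_ipsilesional - Coh_contralesional) / (Coh_ipsi + Coh_contra)

on the Stouffer-combined band scores: positive values mean the hemisphere
on the lesion side dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal, stats

from .emg_analysis import bandpass_emg
from .errors import (
    DegenerateError,
    MontageError,
    ParameterError,
    QualityError,
    ScheduleError,
)
from .signal_io import ChannelMap, Recording, TrialSchedule, resample_to_common

EEG_BAND = (5.0, 100.0)
BETA_BAND = (12.0, 30.0)

#: neighbouring-electrode fallback priority per motor electrode
FALLBACK_PRIORITY = {
    "C3": ("CP1", "FC1", "CP5", "FC5"),
    "C4": ("CP2", "FC2", "CP6", "FC6"),
}


@dataclass
class CoherenceProfile:
    freqs: np.ndarray
    coherence: np.ndarray
    L: int
    confidence: float
    eeg_channel: str = ""
    emg_channel: str = ""


@dataclass
class BetaSummary:
    band: tuple[float, float]
    stouffer_z: float
    fisher_values: np.ndarray
    peak_coherence: float
    peak_freq: float


@dataclass
class LateralityResult:
    task: str
    value: float
    ipsilesional_coh: float
    contralesional_coh: float


@dataclass
class CMCResult:
    task: str
    summaries: dict  # hemisphere -> BetaSummary
    laterality: LateralityResult
    profiles: list[CoherenceProfile]
    removed_channels: list[str]
    electrodes: dict  # hemisphere -> label actually used


def detect_bad_channels(recording: Recording, kurtosis_z: float = 5.0) -> list[str]:
    """Flag channels by montage-z-scored kurtosis plus flatlines.

    Deterministic: excess kurtosis per channel is z-scored across the
    montage and channels above ``kurtosis_z`` or with near-zero variance
    are flagged. The z-score is robust (median and scaled MAD): a plain
    mean/SD z-score across n channels is bounded by ``(n-1)/sqrt(n)`` and
    could never exceed 5 on montages smaller than 27 channels, masking any
    single artifactual channel.
    """
    if recording.n_channels < 4:
        raise ParameterError("bad-channel detection needs at least 4 channels")
    sd = recording.samples.std(axis=1)
    flat = sd < 1e-12 * max(float(sd.max()), 1.0)
    with warnings.catch_warnings():
        # near-constant channels trip a precision warning; they are flagged
        # as flatlines and their kurtosis is discarded below
        warnings.simplefilter("ignore", RuntimeWarning)
        kurt = stats.kurtosis(recording.samples, axis=1, fisher=True, bias=True)
    kurt = np.where(flat, 0.0, kurt)  # flatline kurtosis is meaningless
    med = np.median(kurt)
    mad = np.median(np.abs(kurt - med))
    spread = 1.4826 * mad if mad > 0 else kurt.std()
    if spread > 0:
        z = (kurt - med) / spread
    else:
        z = np.zeros_like(kurt)
    flagged = flat | (z > kurtosis_z)
    return [l for l, bad in zip(recording.labels, flagged) if bad]


def preprocess_eeg(
    recording: Recording, kurtosis_z: float = 5.0, zscore: bool = True
) -> tuple[Recording, list[str]]:
    """Bandpass, drop bad channels, common-average re-reference, z-score.

    ``zscore=False`` stops after the re-reference (whose per-sample
    cross-channel mean is exactly zero; per-channel scaling afterwards
    necessarily breaks that identity).
    """
    if recording.n_channels < 4:
        raise ParameterError("EEG preprocessing needs at least 4 channels")
    if recording.rate < 250:
        raise ParameterError(
            f"EEG rate {recording.rate} Hz too low for a {EEG_BAND[1]} Hz band edge"
        )
    sos = signal.butter(
        4, EEG_BAND, btype="bandpass", fs=recording.rate, output="sos"
    )
    filtered = replace(
        recording, samples=signal.sosfiltfilt(sos, recording.samples, axis=1)
    )
    removed = detect_bad_channels(filtered, kurtosis_z)
    if len(removed) > recording.n_channels / 2:
        raise QualityError(
            f"{len(removed)} of {recording.n_channels} channels flagged bad"
        )
    kept = filtered.drop(removed)
    car = kept.samples - kept.samples.mean(axis=0, keepdims=True)
    if not zscore:
        return replace(kept, samples=car), removed
    sd = car.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DegenerateError("zero-variance channel after re-referencing")
    z = (car - car.mean(axis=1, keepdims=True)) / sd
    return replace(kept, samples=z), removed


def emg_for_cmc(recording: Recording, mode: str = "envelope") -> Recording:
    """Hilbert-processed, z-scored EMG channels for coherence.

    ``mode='envelope'`` (default) takes the magnitude of the analytic
    signal of the bandpassed EMG; ``mode='analytic_real'`` keeps the real
    part (i.e., the bandpassed signal itself) for the narrowband-oscillation
    reading of "Hilbert-transformed".
    """
    filtered = bandpass_emg(recording)
    if mode == "envelope":
        processed = np.abs(signal.hilbert(filtered.samples, axis=1))
    elif mode == "analytic_real":
        processed = filtered.samples
    else:
        raise ParameterError(f"unknown Hilbert mode {mode!r}")
    sd = processed.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise DegenerateError("zero-variance EMG channel cannot be z-scored")
    z = (processed - processed.mean(axis=1, keepdims=True)) / sd
    return replace(filtered, samples=z)


def confidence_level(L: int, alpha: float = 0.05) -> float:
    """Coherence significance threshold ``1 - alpha^(1/(L-1))``."""
    if L < 2:
        raise ParameterError(f"confidence level needs L >= 2 segments, got {L}")
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    return 1.0 - alpha ** (1.0 / (L - 1))


def compute_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float = 1000.0,
    window_s: float = 0.128,
    overlap: float = 0.75,
    alpha: float = 0.05,
    segment_count: str = "independent",
) -> CoherenceProfile:
    """Welch magnitude-squared coherence with a Hann taper.

    ``segment_count`` chooses the L entering the confidence level:
    'independent' (default) counts equivalent non-overlapping windows,
    ``floor(N / W)``; 'overlapped' counts the raw Welch segments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("coherence inputs must have equal length")
    nperseg = int(round(window_s * rate))
    noverlap = int(round(overlap * nperseg))
    if x.size < 2 * nperseg:
        raise ScheduleError(
            f"need at least two {nperseg}-sample windows, got {x.size} samples"
        )
    freqs, coh = signal.coherence(
        x, y, fs=rate, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    if segment_count == "independent":
        L = x.size // nperseg
    elif segment_count == "overlapped":
        L = 1 + (x.size - nperseg) // (nperseg - noverlap)
    else:
        raise ParameterError(f"unknown segment_count {segment_count!r}")
    return CoherenceProfile(
        freqs=freqs,
        coherence=np.clip(coh, 0.0, 1.0),
        L=int(L),
        confidence=confidence_level(int(L), alpha),
    )


def fisher_coherence(coherence: np.ndarray) -> np.ndarray:
    """Variance-stabilizing transform ``atanh(sqrt(coh))``."""
    c = np.clip(np.asarray(coherence, dtype=float), 0.0, 1.0 - 1e-12)
    return np.arctanh(np.sqrt(c))


def beta_band_summary(
    profile: CoherenceProfile, band: tuple[float, float] = BETA_BAND
) -> BetaSummary:
    """Fisher/Stouffer combination of in-band bins plus the raw peak.

    Each bin contributes ``z_f = atanh(sqrt(coh_f)) * sqrt(2L)`` (unit
    variance under independence); the band score is ``sum(z_f) / sqrt(K)``.
    The peak is taken on raw coherence; ties resolve to the lowest
    frequency.
    """
    if band[0] >= band[1]:
        raise ParameterError(f"empty band {band}")
    mask = (profile.freqs >= band[0]) & (profile.freqs <= band[1])
    if mask.sum() < 1:
        raise ParameterError(f"no frequency bins inside {band}")
    coh = profile.coherence[mask]
    freqs = profile.freqs[mask]
    z = fisher_coherence(coh) * np.sqrt(2 * profile.L)
    peak_idx = int(np.argmax(coh))  # argmax returns the first (lowest-f) max
    return BetaSummary(
        band=band,
        stouffer_z=float(z.sum() / np.sqrt(z.size)),
        fisher_values=z,
        peak_coherence=float(coh[peak_idx]),
        peak_freq=float(freqs[peak_idx]),
    )


def stouffer_combine(z_values: np.ndarray) -> float:
    """Stouffer's method: ``sum(z) / sqrt(K)``."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ParameterError("cannot combine an empty set of scores")
    return float(z.sum() / np.sqrt(z.size))


def laterality(ipsi: float, contra: float, task: str = "extension") -> LateralityResult:
    """Laterality index on band-combined coherence scores, in [-1, 1]."""
    if ipsi < 0 or contra < 0:
        raise ParameterError("band coherence scores must be nonnegative")
    total = ipsi + contra
    if total <= 0:
        raise DegenerateError("laterality undefined: zero total coherence")
    return LateralityResult(
        task=task,
        value=(ipsi - contra) / total,
        ipsilesional_coh=ipsi,
        contralesional_coh=contra,
    )


def electrode_fallback(requested: str, removed_labels, available) -> str:
    """C3/C4 with same-hemisphere neighbour fallback in fixed priority."""
    if requested not in FALLBACK_PRIORITY:
        raise ParameterError(f"fallback defined for C3/C4 only, got {requested!r}")
    removed = set(removed_labels)
    avail = [l for l in available if l not in removed]
    if requested in avail:
        return requested
    for candidate in FALLBACK_PRIORITY[requested]:
        if candidate in avail:
            return candidate
    raise MontageError(
        f"no usable electrode remains in the hemisphere of {requested}"
    )


def _concat_holds(samples: np.ndarray, rate: float, schedule: TrialSchedule, t0: float) -> np.ndarray:
    chunks = []
    n = samples.shape[-1]
    for a, b in schedule.hold_intervals():
        i0 = max(int(round((a - t0) * rate)), 0)
        i1 = min(int(round((b - t0) * rate)), n)
        if i1 > i0:
            chunks.append(samples[..., i0:i1])
    if not chunks:
        raise ScheduleError("no hold epoch overlaps the recording")
    return np.concatenate(chunks, axis=-1)


def cmc_pipeline(
    eeg: Recording,
    emg: Recording,
    channel_map: ChannelMap,
    schedule: TrialSchedule,
    task: str | None = None,
    rate: float = 1000.0,
    band: tuple[float, float] = BETA_BAND,
    hilbert_mode: str = "envelope",
) -> CMCResult:
    """End-to-end CMC analysis of one task.

    Both streams are aligned and resampled to the common ``rate``, the EEG
    is cleaned and re-referenced, the EMG Hilbert-processed, and coherence
    is estimated over concatenated hold epochs between each hemisphere's
    motor electrode (with neighbour fallback) and the two muscles of the
    task's muscle group. Per hemisphere, the in-band Fisher z-scores of
    both muscles are pooled with Stouffer's method; laterality compares the
    two hemispheres.
    """
    task = task or schedule.task
    eeg_r, emg_r = resample_to_common([eeg, emg], rate)
    clean_eeg, removed = preprocess_eeg(eeg_r)
    group = "extensor" if task == "extension" else "flexor"
    muscles = channel_map.group_channels(group)
    emg_z = emg_for_cmc(emg_r.pick(muscles), mode=hilbert_mode)

    t0 = eeg_r.start_time
    summaries: dict[str, BetaSummary] = {}
    electrodes: dict[str, str] = {}
    profiles: list[CoherenceProfile] = []
    for hemisphere in ("ipsilesional", "contralesional"):
        requested = channel_map.motor_electrode(hemisphere)
        label = electrode_fallback(requested, removed, clean_eeg.labels)
        electrodes[hemisphere] = label
        eeg_holds = _concat_holds(clean_eeg.channel(label), rate, schedule, t0)
        pooled_z = []
        peak_c, peak_f = -np.inf, np.nan
        for muscle in muscles:
            emg_holds = _concat_holds(emg_z.channel(muscle), rate, schedule, t0)
            profile = compute_coherence(eeg_holds, emg_holds, rate)
            profile.eeg_channel, profile.emg_channel = label, muscle
            profiles.append(profile)
            summary = beta_band_summary(profile, band)
            pooled_z.append(summary.fisher_values)
            if summary.peak_coherence > peak_c:
                peak_c, peak_f = summary.peak_coherence, summary.peak_freq
        pooled = np.concatenate(pooled_z)
        summaries[hemisphere] = BetaSummary(
            band=band,
            stouffer_z=stouffer_combine(pooled),
            fisher_values=pooled,
            peak_coherence=peak_c,
            peak_freq=peak_f,
        )

    lat = laterality(
        max(summaries["ipsilesional"].stouffer_z, 0.0),
        max(summaries["contralesional"].stouffer_z, 0.0),
        task=task,
    )
    return CMCResult(
        task=task,
        summaries=summaries,
        laterality=lat,
        profiles=profiles,
        removed_channels=removed,
        electrodes=electrodes,
    )
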