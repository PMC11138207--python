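"""Synthetic EMG/EEG sessions and clinical tables with known ground truth.

Every generator is a pure function of its config (which carries the seed),
so each analysis stage can be tested against a recoverable parameter:

* :func:`generate_emg_session` programs an extensor and a flexor activation
  level; the extensor-ratio pipeline should recover
  ``ext / (ext + flex)``.
* :func:`generate_coupled_eeg_emg` injects one shared narrowband beta
  source into both hemispheres' EEG (with independent gains) and into the
  EMG amplitude envelope; beta-band corticomuscular coherence should rise
  monotonically with the hemisphere gain, and laterality should carry the
  sign of the larger gain.
* :func:`generate_clinical_table` draws paired pre/post scores with
  programmed effect sizes and cross-measure correlations.

The EMG carrier is Gaussian noise bandpassed to 20-450 Hz so the analysis
bandpass (15-450 Hz) passes it essentially unchanged; the beta source is a
narrowband (2 Hz) Gaussian process rather than a sine so coherence
estimates across neighbouring bins are non-degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError, ParameterError
from .signal_io import (
    DEFAULT_EEG_MONTAGE,
    EXTENSOR_MUSCLES,
    FLEXOR_MUSCLES,
    MUSCLES,
    ChannelMap,
    Recording,
    TrialSchedule,
)


def default_channel_map(lesion_side: str = "left") -> ChannelMap:
    """Identity channel map for generated sessions (labels = muscle names)."""
    return ChannelMap(
        muscle_channels={m: m for m in MUSCLES},
        eeg_channels=DEFAULT_EEG_MONTAGE,
        lesion_side=lesion_side,
    )


@dataclass
class SynthSignalConfig:
    """Stated recording world: 12 trials of 4 s hold + 6 s rest, EMG at
    2148 Hz, EEG at 500 Hz, tracking target 15% of maximal gross grasp."""

    seed: int = 0
    n_trials: int = 12
    hold_s: float = 4.0
    rest_s: float = 6.0
    lead_in_s: float = 2.0
    emg_rate: float = 2148.0
    eeg_rate: float = 500.0
    task: str = "extension"
    target_level: float = 0.15
    #: hold-epoch activation as a fraction of the simulated maximum
    extensor_level: float = 0.45
    flexor_level: float = 0.15
    #: per-muscle multiplier on the task level (models unequal recruitment
    #: within a group; the SNR-selected feedback channel should be the max)
    channel_gain: dict = field(
        default_factory=lambda: {
            "extensor_carpi_radialis_longus": 1.0,
            "extensor_carpi_ulnaris": 0.8,
            "flexor_carpi_radialis": 1.0,
            "flexor_carpi_ulnaris": 0.8,
        }
    )
    #: resting co-activation floor, fraction of maximum
    baseline_level: float = 0.02
    #: beta-source gain per hemisphere (EEG side)
    ipsilesional_gain: float = 1.0
    contralesional_gain: float = 1.0
    beta_source_freq: float = 20.0
    beta_bandwidth: float = 2.0
    #: EEG sensor-noise SD relative to a unit-variance source
    noise_sd: float = 1.0
    #: depth of beta modulation of the EMG envelope during holds
    modulation_depth: float = 0.4
    n_bad_channels: int = 0
    lesion_side: str = "left"

    def __post_init__(self):
        for name in ("extensor_level", "flexor_level", "baseline_level"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.ipsilesional_gain < 0 or self.contralesional_gain < 0:
            raise ConfigError("coupling gains must be >= 0")
        if not 12 <= self.beta_source_freq <= 30:
            raise ConfigError(
                f"beta_source_freq must lie in the 12-30 Hz band, got {self.beta_source_freq}"
            )
        if self.hold_s < 3.0:
            raise ConfigError(
                "hold_s must cover the 3 s analysis window used downstream"
            )
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")

    @property
    def session_s(self) -> float:
        return self.lead_in_s + self.n_trials * (self.hold_s + self.rest_s)

    def schedule(self) -> TrialSchedule:
        return TrialSchedule.regular(
            self.n_trials,
            self.hold_s,
            self.rest_s,
            self.lead_in_s,
            task=self.task,
            target_level=self.target_level,
        )


def _band_noise(rng, n, rate, low, high, order=4):
    """Unit-RMS Gaussian noise bandpassed to [low, high] Hz."""
    x = rng.standard_normal(n)
    high = min(high, 0.45 * rate)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / np.std(y)


def _hold_profile(config: SynthSignalConfig, rate: float, n: int) -> np.ndarray:
    """1 during holds, 0 during rests, with 100 ms cosine ramps."""
    t = np.arange(n) / rate
    prof = np.zeros(n)
    ramp = 0.1
    for onset, hold, _ in config.schedule().trials:
        rise = np.clip((t - onset) / ramp, 0, 1)
        fall = np.clip((onset + hold - t) / ramp, 0, 1)
        prof = np.maximum(prof, np.minimum(rise, fall))
    return prof


def generate_emg_session(config: SynthSignalConfig):
    """Simulate one 4-muscle tracking session.

    Returns ``(recording, schedule, true_params)`` where ``true_params``
    includes the programmed levels and the extensor ratio they imply.
    """
    rng = np.random.default_rng([config.seed, 0x45_4D_47])
    n = int(round(config.session_s * config.emg_rate))
    prof = _hold_profile(config, config.emg_rate, n)
    samples = np.empty((len(MUSCLES), n))
    for i, muscle in enumerate(MUSCLES):
        level = (
            config.extensor_level
            if muscle in EXTENSOR_MUSCLES
            else config.flexor_level
        )
        gain = config.channel_gain.get(muscle, 1.0)
        envelope = config.baseline_level + level * gain * prof
        carrier = _band_noise(rng, n, config.emg_rate, 20.0, 450.0)
        samples[i] = envelope * carrier

    recording = Recording(
        samples, config.emg_rate, MUSCLES, ("EMG",) * len(MUSCLES)
    )
    e, f = config.extensor_level, config.flexor_level
    true_params = {
        "extensor_level": e,
        "flexor_level": f,
        "expected_er": e / (e + f) if e + f > 0 else float("nan"),
        "channel_gain": dict(config.channel_gain),
        "baseline_level": config.baseline_level,
    }
    return recording, config.schedule(), true_params


def generate_calibration(config: SynthSignalConfig, repeats: int = 2, burst_s: float = 3.0):
    """Maximal-grasp calibration: all muscles at full simulated amplitude.

    Each repeat is a ``burst_s`` burst separated by 2 s of baseline; the
    max-grasp estimator applied to this recording recovers the amplitude
    scale that :func:`generate_emg_session` programs levels against.
    """
    rng = np.random.default_rng([config.seed, 0x43_41_4C])
    gap_s = 2.0
    total_s = repeats * (burst_s + gap_s)
    n = int(round(total_s * config.emg_rate))
    t = np.arange(n) / config.emg_rate
    envelope = np.full(n, config.baseline_level)
    for r in range(repeats):
        t0 = gap_s / 2 + r * (burst_s + gap_s)
        envelope[(t >= t0) & (t < t0 + burst_s)] = 1.0
    samples = np.empty((len(MUSCLES), n))
    for i in range(len(MUSCLES)):
        samples[i] = envelope * _band_noise(rng, n, config.emg_rate, 20.0, 450.0)
    return Recording(samples, config.emg_rate, MUSCLES, ("EMG",) * len(MUSCLES))


def generate_coupled_eeg_emg(config: SynthSignalConfig):
    """Simulate a session with a shared cortical beta drive.

    A unit-variance narrowband source ``s(t)`` centred at
    ``beta_source_freq`` is added to every EEG channel of a hemisphere with
    that hemisphere's gain (plus white sensor noise of SD ``noise_sd``) and
    multiplies the EMG hold envelope as ``1 + depth * s(t)``. The expected
    per-bin EEG-side coherence ceiling is ``g^2 / (g^2 + sigma_n^2 / c)``
    with ``c`` the source-to-noise PSD concentration, further reduced by
    the EMG envelope-extraction SNR; only monotonicity in ``g`` is exact,
    which is what tests and acceptance rely on.

    Returns ``(eeg, emg, true_params)``; ``true_params["schedule"]`` holds
    the trial timeline.
    """
    if (
        config.ipsilesional_gain == 0
        and config.contralesional_gain == 0
        and config.modulation_depth == 0
    ):
        raise ConfigError("all coupling pathways are zero; nothing to couple")
    rng = np.random.default_rng([config.seed, 0x43_4D_43])
    master_rate = 1000.0
    n_master = int(round(config.session_s * master_rate))
    half_bw = config.beta_bandwidth / 2
    source = _band_noise(
        rng,
        n_master,
        master_rate,
        config.beta_source_freq - half_bw,
        config.beta_source_freq + half_bw,
        order=2,
    )
    t_master = np.arange(n_master) / master_rate

    # --- EEG: hemisphere gain x source + white noise -------------------
    # The source is focal: full loading on the hemisphere's motor electrode
    # (C3/C4), 0.3 on its neighbours. A uniform loading would make laterality
    # unidentifiable: common-average re-referencing subtracts the montage-mean
    # source and leaves equal-magnitude content in both hemispheres.
    cmap = default_channel_map(config.lesion_side)
    n_eeg = int(round(config.session_s * config.eeg_rate))
    t_eeg = np.arange(n_eeg) / config.eeg_rate
    source_eeg = np.interp(t_eeg, t_master, source)
    eeg_samples = np.empty((len(DEFAULT_EEG_MONTAGE), n_eeg))
    for i, label in enumerate(DEFAULT_EEG_MONTAGE):
        gain = (
            config.ipsilesional_gain
            if cmap.hemisphere_of(label) == "ipsilesional"
            else config.contralesional_gain
        )
        loading = 1.0 if label in ("C3", "C4") else 0.3
        eeg_samples[i] = (
            gain * loading * source_eeg + config.noise_sd * rng.standard_normal(n_eeg)
        )
    eeg = Recording(
        eeg_samples,
        config.eeg_rate,
        DEFAULT_EEG_MONTAGE,
        ("EEG",) * len(DEFAULT_EEG_MONTAGE),
    )

    # --- EMG: source modulates the hold envelope -----------------------
    n_emg = int(round(config.session_s * config.emg_rate))
    t_emg = np.arange(n_emg) / config.emg_rate
    source_emg = np.interp(t_emg, t_master, source)
    prof = _hold_profile(config, config.emg_rate, n_emg)
    modulation = np.clip(1.0 + config.modulation_depth * source_emg, 0.0, None)
    emg_samples = np.empty((len(MUSCLES), n_emg))
    for i, muscle in enumerate(MUSCLES):
        level = (
            config.extensor_level
            if muscle in EXTENSOR_MUSCLES
            else config.flexor_level
        )
        gain = config.channel_gain.get(muscle, 1.0)
        envelope = config.baseline_level + level * gain * prof * modulation
        emg_samples[i] = envelope * _band_noise(rng, n_emg, config.emg_rate, 20.0, 450.0)
    emg = Recording(emg_samples, config.emg_rate, MUSCLES, ("EMG",) * len(MUSCLES))

    true_params = {
        "ipsilesional_gain": config.ipsilesional_gain,
        "contralesional_gain": config.contralesional_gain,
        "beta_source_freq": config.beta_source_freq,
        "modulation_depth": config.modulation_depth,
        "noise_sd": config.noise_sd,
        "lesion_side": config.lesion_side,
        "schedule": config.schedule(),
    }
    return eeg, emg, true_params


def inject_artifacts(recording: Recording, n_bad_channels: int, seed: int = 0):
    """Corrupt ``n_bad_channels`` randomly chosen channels.

    Channels alternate between a high-kurtosis spike train and a flatline.
    Returns ``(corrupted_recording, corrupted_labels)``.
    """
    if n_bad_channels >= recording.n_channels:
        raise ParameterError(
            f"cannot corrupt {n_bad_channels} of {recording.n_channels} channels"
        )
    if n_bad_channels == 0:
        return recording, []
    rng = np.random.default_rng([seed, 0x42_41_44])
    picks = sorted(rng.choice(recording.n_channels, n_bad_channels, replace=False))
    samples = recording.samples.copy()
    scale = max(float(np.std(recording.samples)), 1.0)
    labels = []
    for k, ch in enumerate(picks):
        if k % 2 == 0:  # sparse spikes: kurtosis far above Gaussian
            spikes = np.zeros(recording.n_samples)
            hits = rng.random(recording.n_samples) < 0.002
            spikes[hits] = 50.0 * scale * rng.standard_normal(hits.sum())
            samples[ch] = spikes
        else:  # flatline
            samples[ch] = 0.0
        labels.append(recording.labels[ch])
    return replace(recording, samples=samples), labels


@dataclass
class MeasureSpec:
    """Pre distribution and paired-difference distribution of one measure."""

    pre_mean: float
    pre_sd: float
    diff_mean: float = 0.0
    diff_sd: float = 1.0

    def __post_init__(self):
        if self.pre_sd <= 0 or self.diff_sd <= 0:
            raise ConfigError("measure SDs must be > 0")


#: defaults mirror the published pre-training group means/SDs (n = 9)
DEFAULT_MEASURES = {
    "ROM extension": MeasureSpec(8.56, 10.0, 0.0, 10.0),
    "ROM flexion": MeasureSpec(19.56, 14.16, 0.0, 10.0),
    "ER extension": MeasureSpec(0.48, 0.13, 0.0, 0.15),
    "ER flexion": MeasureSpec(0.39, 0.12, 0.0, 0.15),
    "SIS ADL": MeasureSpec(37.11, 6.72, 0.0, 5.0),
    "SIS Hand Function": MeasureSpec(9.56, 4.67, 0.0, 3.0),
    "SIS Participation": MeasureSpec(27.44, 5.27, 0.0, 5.0),
    "SIS Strength": MeasureSpec(9.22, 2.54, 0.0, 2.0),
    "FMA": MeasureSpec(26.0, 9.89, 0.0, 3.0),
    "ARAT": MeasureSpec(12.89, 8.78, 0.0, 5.0),
}


@dataclass
class SynthClinicalConfig:
    """Paired pre/post clinical-table generator settings.

    ``correlations`` lists ``(measure_a, measure_b, rho)`` imposed between
    the two measures' paired differences (change scores).
    """

    seed: int = 0
    n_participants: int = 9
    measures: dict = field(default_factory=lambda: dict(DEFAULT_MEASURES))
    correlations: list = field(default_factory=list)

    def __post_init__(self):
        for a, b, rho in self.correlations:
            if not -1 <= rho <= 1:
                raise ConfigError(f"correlation {rho} outside [-1, 1]")
            for m in (a, b):
                if m not in self.measures:
                    raise ConfigError(f"correlated measure {m!r} not defined")
        if self.n_participants < 2:
            raise ConfigError("need at least 2 participants")


class ClinicalTable:
    """Participants x measures x {pre, post} score table."""

    def __init__(self, data: pd.DataFrame):
        # wide frame: index = participant, columns = MultiIndex (measure, timepoint)
        self.data = data

    @property
    def participants(self):
        return list(self.data.index)

    @property
    def measures(self):
        return list(dict.fromkeys(m for m, _ in self.data.columns))

    def pre(self, measure: str) -> np.ndarray:
        return self.data[(measure, "pre")].to_numpy(dtype=float)

    def post(self, measure: str) -> np.ndarray:
        return self.data[(measure, "post")].to_numpy(dtype=float)

    def change(self, measure: str) -> np.ndarray:
        return self.post(measure) - self.pre(measure)

    def to_csv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{m}|{tp}" for m, tp in flat.columns]
        flat.rename_axis("participant").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ClinicalTable":
        flat = pd.read_csv(path, index_col=0)
        cols = [tuple(c.split("|", 1)) for c in flat.columns]
        flat.columns = pd.MultiIndex.from_tuples(cols)
        return cls(flat)


def generate_clinical_table(config: SynthClinicalConfig):
    """Draw a paired pre/post table; returns ``(table, true_params)``.

    Pre scores are independent normals per measure; paired differences are
    jointly normal with the programmed pairwise change correlations
    (identity elsewhere). A non-positive-definite implied correlation
    matrix raises :class:`ConfigError`.
    """
    rng = np.random.default_rng([config.seed, 0x43_4C_49])
    names = list(config.measures)
    m = len(names)
    corr = np.eye(m)
    for a, b, rho in config.correlations:
        ia, ib = names.index(a), names.index(b)
        corr[ia, ib] = corr[ib, ia] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError(
            "implied change-score correlation matrix is not positive definite"
        ) from exc

    n = config.n_participants
    z = rng.standard_normal((n, m)) @ chol.T
    data = {}
    for j, name in enumerate(names):
        spec = config.measures[name]
        pre = spec.pre_mean + spec.pre_sd * rng.standard_normal(n)
        diff = spec.diff_mean + spec.diff_sd * z[:, j]
        data[(name, "pre")] = pre
        data[(name, "post")] = pre + diff
    frame = pd.DataFrame(
        data, index=[f"P{i+1}" for i in range(n)]
    )
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    true_params = {
        "effects": {k: (v.diff_mean, v.diff_sd) for k, v in config.measures.items()},
        "correlations": list(config.correlations),
    }
    return ClinicalTable(frame), true_params
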