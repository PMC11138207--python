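"""Run configuration: defaults, validation, normalization.

Every analysis parameter defaults to the published protocol value: 15-450
Hz EMG band, 5-100 Hz EEG band, 128 ms Hann windows with 75% overlap, beta
band 12-30 Hz, alpha = 0.05, tracking target 15% of maximal grasp,
screening threshold 30% over 10 trials, 3 s trial-analysis window, 1 kHz
common analysis rate. A config file (YAML) overrides defaults; CLI flags
override the file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # paths
    inputs: dict = field(default_factory=dict)
    output_dir: str = "."
    # analysis parameters (protocol defaults)
    emg_band: tuple[float, float] = (15.0, 450.0)
    eeg_band: tuple[float, float] = (5.0, 100.0)
    window_s: float = 0.128
    overlap: float = 0.75
    beta_band: tuple[float, float] = (12.0, 30.0)
    alpha: float = 0.05
    target_level: float = 0.15
    screening_threshold: float = 0.30
    screening_trials: int = 10
    analysis_window_s: float = 3.0
    analysis_rate: float = 1000.0
    segment_count: str = "independent"
    hilbert_mode: str = "envelope"
    bh_family: str = "matrix"
    # reproducibility
    seed: int = 0
    verbosity: int = 1

    @property
    def hop_samples(self) -> int:
        nperseg = int(round(self.window_s * self.analysis_rate))
        return nperseg - int(round(self.overlap * nperseg))


def validate_config(raw: dict | RunConfig | None = None) -> RunConfig:
    """Fill defaults and reject out-of-range values, naming the offending key."""
    if raw is None:
        raw = {}
    if isinstance(raw, RunConfig):
        raw = asdict(raw)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    def check(cond: bool, key: str, message: str) -> None:
        if not cond:
            raise ConfigError(f"{key}: {message}")

    nyquist = cfg.analysis_rate / 2
    check(cfg.analysis_rate > 0, "analysis_rate", "must be > 0")
    check(
        0 < cfg.emg_band[0] < cfg.emg_band[1], "emg_band", "must be increasing and positive"
    )
    check(
        0 < cfg.eeg_band[0] < cfg.eeg_band[1] <= nyquist,
        "eeg_band",
        f"must be increasing and inside the Nyquist limit {nyquist} Hz",
    )
    check(
        0 < cfg.beta_band[0] < cfg.beta_band[1] <= nyquist,
        "beta_band",
        "must be increasing and inside the Nyquist limit",
    )
    check(0 <= cfg.overlap <= 0.95, "overlap", "must lie in [0, 0.95]")
    check(cfg.window_s > 0, "window_s", "must be > 0")
    check(0 < cfg.alpha < 1, "alpha", "must lie in (0, 1)")
    check(0 < cfg.target_level <= 1, "target_level", "must lie in (0, 1]")
    check(
        0 < cfg.screening_threshold <= 1, "screening_threshold", "must lie in (0, 1]"
    )
    check(cfg.screening_trials >= 1, "screening_trials", "must be >= 1")
    check(cfg.analysis_window_s > 0, "analysis_window_s", "must be > 0")
    check(
        cfg.segment_count in ("independent", "overlapped"),
        "segment_count",
        "must be 'independent' or 'overlapped'",
    )
    check(
        cfg.hilbert_mode in ("envelope", "analytic_real"),
        "hilbert_mode",
        "must be 'envelope' or 'analytic_real'",
    )
    check(cfg.seed >= 0, "seed", "must be a nonnegative integer")
    return cfg


def load_config(path: str | None = None, overrides: dict | None = None) -> RunConfig:
    """Read a YAML config file, apply overrides, validate."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return validate_config(raw)
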