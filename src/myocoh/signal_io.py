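"""Biosignal containers and I/O.

The core container is :class:`Recording`: a channels x time array of
microvolt samples with a sampling rate, ordered unique labels, and a
per-channel modality (EMG or EEG). Recordings are read and written as EDF
(for interchange) or as CSV with a YAML sidecar (lossless fixtures, since
EDF quantizes to 16 bits and cannot always represent odd rates exactly).

:class:`ChannelMap` binds the four forearm muscles of the wrist tasks
(extensor carpi radialis longus, extensor carpi ulnaris, flexor carpi
radialis, flexor carpi ulnaris) and a 10-10 EEG subset to recording labels,
and resolves each lateral EEG electrode to the ipsilesional or
contralesional hemisphere given the lesion side.

:class:`TrialSchedule` is the explicit hold/rest timeline of the tracking
task (12 trials of a 4 s hold at 15% of maximal gross grasp followed by
6 s of rest, by default).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import edf as _edf
from .errors import IngestionError, MappingError, ParameterError, ScheduleError

EXTENSOR_MUSCLES = ("extensor_carpi_radialis_longus", "extensor_carpi_ulnaris")
FLEXOR_MUSCLES = ("flexor_carpi_radialis", "flexor_carpi_ulnaris")
MUSCLES = EXTENSOR_MUSCLES + FLEXOR_MUSCLES

#: default sensorimotor 10-10 subset (5 electrodes per hemisphere)
DEFAULT_EEG_MONTAGE = (
    "FC1", "FC5", "C3", "CP1", "CP5",
    "FC2", "FC6", "C4", "CP2", "CP6",
)


@dataclass
class Recording:
    """Multichannel biosignal: ``samples[channel, time]`` in microvolts."""

    samples: np.ndarray
    rate: float
    labels: tuple[str, ...]
    modalities: tuple[str, ...]
    start_time: float = 0.0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(self.labels)
        self.modalities = tuple(self.modalities)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.rate}")
        if self.samples.shape[0] != len(self.labels):
            raise IngestionError(
                f"{self.samples.shape[0]} channels but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise IngestionError("channel labels must be unique")
        if len(self.modalities) != len(self.labels):
            raise IngestionError("one modality per channel required")
        if self.samples.size and not np.isfinite(self.samples).all():
            raise IngestionError("recording contains NaN or infinite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.samples[self.labels.index(label)]
        except ValueError as exc:
            raise MappingError(f"channel {label!r} not in recording") from exc

    def pick(self, labels: Sequence[str]) -> "Recording":
        idx = [self.labels.index(l) for l in labels]
        return replace(
            self,
            samples=self.samples[idx],
            labels=tuple(labels),
            modalities=tuple(self.modalities[i] for i in idx),
        )

    def drop(self, labels: Sequence[str]) -> "Recording":
        keep = [l for l in self.labels if l not in set(labels)]
        return self.pick(keep)


@dataclass
class ChannelMap:
    """Maps muscles and 10-10 EEG labels to recording channels."""

    muscle_channels: dict[str, str]
    eeg_channels: tuple[str, ...] = DEFAULT_EEG_MONTAGE
    lesion_side: str = "left"

    def __post_init__(self):
        self.eeg_channels = tuple(self.eeg_channels)
        missing = set(MUSCLES) - set(self.muscle_channels)
        if missing:
            raise MappingError(f"channel map missing muscles: {sorted(missing)}")
        if self.lesion_side not in ("left", "right"):
            raise MappingError(f"lesion_side must be left|right, got {self.lesion_side!r}")

    @staticmethod
    def side_of(label: str) -> str:
        """Hemisphere of a 10-10 label: odd index = left, even = right."""
        digits = "".join(ch for ch in label if ch.isdigit())
        if not digits:
            raise MappingError(f"{label!r} is a midline or unparseable 10-10 label")
        return "left" if int(digits) % 2 == 1 else "right"

    def hemisphere_of(self, label: str) -> str:
        """'ipsilesional' or 'contralesional' for a lateral EEG label."""
        return (
            "ipsilesional"
            if self.side_of(label) == self.lesion_side
            else "contralesional"
        )

    def motor_electrode(self, hemisphere: str) -> str:
        """Primary motor electrode (C3/C4) for ipsi- or contralesional cortex."""
        side = (
            self.lesion_side
            if hemisphere == "ipsilesional"
            else ("right" if self.lesion_side == "left" else "left")
        )
        return "C3" if side == "left" else "C4"

    def group_channels(self, group: str) -> list[str]:
        muscles = EXTENSOR_MUSCLES if group == "extensor" else FLEXOR_MUSCLES
        return [self.muscle_channels[m] for m in muscles]

    def validate_against(self, recording: Recording, modality: str = "EMG") -> None:
        wanted = (
            list(self.muscle_channels.values())
            if modality == "EMG"
            else list(self.eeg_channels)
        )
        missing = [l for l in wanted if l not in recording.labels]
        if missing:
            raise MappingError(f"mapped channels absent from recording: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "channels": dict(self.muscle_channels),
                    "eeg_channels": list(self.eeg_channels),
                    "lesion_side": self.lesion_side,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ChannelMap":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            muscle_channels=cfg["channels"],
            eeg_channels=tuple(cfg.get("eeg_channels", DEFAULT_EEG_MONTAGE)),
            lesion_side=cfg.get("lesion_side", "left"),
        )


@dataclass
class TrialSchedule:
    """Hold/rest timeline: ``trials`` is a list of (onset, hold_s, rest_s)."""

    trials: list[tuple[float, float, float]]
    task: str = "extension"
    target_level: float = 0.15

    def __post_init__(self):
        self.trials = [tuple(map(float, t)) for t in self.trials]
        if self.task not in ("extension", "flexion"):
            raise ScheduleError(f"task must be extension|flexion, got {self.task!r}")
        last_end = -np.inf
        for onset, hold, rest in self.trials:
            if hold <= 0 or rest < 0:
                raise ScheduleError("hold must be > 0 and rest >= 0")
            if onset < last_end:
                raise ScheduleError("trials overlap or are out of order")
            last_end = onset + hold + rest

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def hold_intervals(self) -> list[tuple[float, float]]:
        return [(onset, onset + hold) for onset, hold, _ in self.trials]

    def rest_intervals(self) -> list[tuple[float, float]]:
        return [
            (onset + hold, onset + hold + rest) for onset, hold, rest in self.trials
        ]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.trials, columns=["onset_s", "hold_s", "rest_s"])
        df.insert(0, "task", self.task)
        df.insert(1, "target_level", self.target_level)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSchedule":
        df = pd.read_csv(path)
        return cls(
            trials=list(zip(df["onset_s"], df["hold_s"], df["rest_s"])),
            task=str(df["task"].iloc[0]),
            target_level=float(df["target_level"].iloc[0]),
        )

    @classmethod
    def regular(
        cls,
        n_trials: int = 12,
        hold_s: float = 4.0,
        rest_s: float = 6.0,
        lead_in_s: float = 2.0,
        task: str = "extension",
        target_level: float = 0.15,
    ) -> "TrialSchedule":
        trials = [
            (lead_in_s + i * (hold_s + rest_s), hold_s, rest_s)
            for i in range(n_trials)
        ]
        return cls(trials=trials, task=task, target_level=target_level)


def _resolve_modalities(labels, channel_map: ChannelMap | None, fallback=None):
    if channel_map is not None:
        emg = set(channel_map.muscle_channels.values())
        eeg = set(channel_map.eeg_channels)
        out = []
        for label in labels:
            if label in emg:
                out.append("EMG")
            elif label in eeg:
                out.append("EEG")
            elif fallback is not None:
                out.append(fallback[labels.index(label)])
            else:
                raise MappingError(f"cannot resolve modality of channel {label!r}")
        return tuple(out)
    if fallback is None:
        raise MappingError("either a channel map or recorded modalities required")
    return tuple(fallback)


def read_recording(path, format: str | None = None, channel_map: ChannelMap | None = None) -> Recording:
    """Read an EDF or CSV(+YAML sidecar) recording.

    ``format`` is inferred from the extension when omitted. If a
    ``channel_map`` is given it must be satisfiable by the file's labels and
    it overrides stored modalities.
    """
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "csv"
    if format == "edf":
        samples, rate, labels, modalities, start = _edf.read_edf(path)
        modalities = tuple(m if m in ("EMG", "EEG") else "EMG" for m in modalities)
    elif format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise IngestionError(f"cannot parse {path}: {exc}") from exc
        labels = [str(c) for c in df.columns]
        samples = df.to_numpy(dtype=float).T
        sidecar = str(path) + ".yaml"
        if not os.path.exists(sidecar):
            raise IngestionError(f"missing sidecar config {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        rate = float(meta["rate"])
        start = float(meta.get("start_time", 0.0))
        stored = meta.get("modalities")
        modalities = tuple(stored) if stored else None
    else:
        raise ParameterError(f"unknown format {format!r}")

    if channel_map is not None:
        for label in channel_map.muscle_channels.values():
            if label not in labels:
                raise MappingError(f"mapped channel {label!r} not in {path}")
        modalities = _resolve_modalities(list(labels), channel_map, modalities)
    elif modalities is None:
        raise IngestionError(f"{path}: no modalities stored and no channel map given")
    return Recording(samples, rate, tuple(labels), tuple(modalities), start)


def write_recording(recording: Recording, path, format: str | None = None) -> None:
    """Write a recording as EDF or CSV + YAML sidecar (see :func:`read_recording`)."""
    if recording.n_samples == 0:
        raise IngestionError("refusing to write an empty recording")
    if format is None:
        format = "edf" if str(path).lower().endswith(".edf") else "csv"
    if format == "edf":
        _edf.write_edf(
            path,
            recording.samples,
            recording.rate,
            recording.labels,
            recording.modalities,
            recording.start_time,
        )
    elif format == "csv":
        pd.DataFrame(recording.samples.T, columns=list(recording.labels)).to_csv(
            path, index=False
        )
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "rate": float(recording.rate),
                    "start_time": float(recording.start_time),
                    "modalities": list(recording.modalities),
                },
                fh,
            )
    else:
        raise ParameterError(f"unknown format {format!r}")


def resample_recording(recording: Recording, target_rate: float = 1000.0) -> Recording:
    """Linearly interpolate one recording onto a uniform ``target_rate`` grid."""
    if target_rate <= 0:
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if recording.rate == target_rate:
        return recording
    old_t = recording.times
    n_new = int(round(recording.duration * target_rate))
    new_t = recording.start_time + np.arange(n_new) / target_rate
    new = np.empty((recording.n_channels, n_new))
    for ch in range(recording.n_channels):
        new[ch] = np.interp(new_t, old_t, recording.samples[ch])
    return replace(recording, samples=new, rate=float(target_rate))


def resample_to_common(
    recordings: Sequence[Recording], target_rate: float = 1000.0
) -> list[Recording]:
    """Align recordings by start time, truncate to the overlap, resample.

    All outputs share the same start time, rate and duration (within one
    sample), emulating offline interpolation of synchronized streams to a
    common 1 kHz grid.
    """
    if target_rate <= 0:
        raise ParameterError(f"target_rate must be > 0, got {target_rate}")
    if not recordings:
        return []
    t0 = max(r.start_time for r in recordings)
    t1 = min(r.start_time + r.duration for r in recordings)
    if t1 <= t0:
        raise ScheduleError("recordings do not overlap in time")
    n_new = int(round((t1 - t0) * target_rate))
    new_t = t0 + np.arange(n_new) / target_rate
    out = []
    for rec in recordings:
        new = np.empty((rec.n_channels, n_new))
        old_t = rec.times
        for ch in range(rec.n_channels):
            new[ch] = np.interp(new_t, old_t, rec.samples[ch])
        out.append(replace(rec, samples=new, rate=float(target_rate), start_time=t0))
    return out
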