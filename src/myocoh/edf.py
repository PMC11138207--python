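"""Minimal EDF (European Data Format) reader and writer.

Implements the subset of EDF needed to round-trip multichannel biosignal
recordings: a fixed-layout ASCII header followed by 16-bit little-endian
data records. Files are written as a single data record spanning the whole
recording, which keeps arbitrary (including non-integer) sampling rates
exact as long as ``n_samples / rate`` fits the 8-character duration field.

Per-channel physical min/max are taken from the data, so amplitudes are
quantized to ``(phys_max - phys_min) / 65535`` — the format's intrinsic
resolution. The channel modality is stored in the transducer field and the
recording start offset (seconds) in the reserved header field.
"""

from __future__ import annotations

import numpy as np

from .errors import IngestionError

_DIG_MIN = -32768
_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten floats to fit the fixed-width field
        if isinstance(value, float):
            s = f"{value:.{max(width - 8, 1)}g}"[:width]
        else:
            raise ValueError(f"{value!r} does not fit in {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def write_edf(path, samples, rate, labels, modalities, start_time=0.0) -> None:
    """Write channels x time ``samples`` (microvolts) to ``path``."""
    samples = np.asarray(samples, dtype=float)
    n_ch, n_samp = samples.shape
    if n_samp == 0:
        raise IngestionError("cannot write an empty recording to EDF")
    duration = n_samp / rate
    dur_str = f"{duration:.6f}".rstrip("0").rstrip(".")
    if len(dur_str) > 8:
        raise IngestionError(
            f"record duration {duration} not representable in EDF header"
        )

    phys_min = samples.min(axis=1)
    phys_max = samples.max(axis=1)
    # avoid a zero physical span on constant channels
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    phys_min = np.where(flat, phys_min - 1.0, phys_min)

    header = b"".join(
        [
            _ascii(0, 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + n_ch), 8),
            _ascii(f"START={start_time:.6f}", 44),
            _ascii(1, 8),  # one data record spanning the file
            _ascii(dur_str, 8),
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        (labels, 16),
        (modalities, 80),
        (["uV"] * n_ch, 8),
        ([f"{v:.6g}"[:8] for v in phys_min], 8),
        ([f"{v:.6g}"[:8] for v in phys_max], 8),
        ([_DIG_MIN] * n_ch, 8),
        ([_DIG_MAX] * n_ch, 8),
        ([""] * n_ch, 80),
        ([n_samp] * n_ch, 8),
        ([""] * n_ch, 32),
    ]
    for values, width in fields:
        header += b"".join(_ascii(v, width) for v in values)

    # re-read the formatted physical bounds so quantization is self-consistent
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint(
        (samples - pmin[:, None]) / scale[:, None] + _DIG_MIN
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path):
    """Read an EDF file; returns (samples, rate, labels, modalities, start_time).

    Handles multi-record files generically even though :func:`write_edf`
    emits a single record.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IngestionError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244])
            duration = float(head[244:252])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise IngestionError(f"{path}: malformed EDF header") from exc
        reserved = head[192:236].decode("ascii", "replace").strip()
        start_time = 0.0
        if reserved.startswith("START="):
            start_time = float(reserved[6:])

        sig = fh.read(256 * n_ch)
        def field(offset, width):
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = field(0, 16)
        modalities = field(16, 80)
        pmin = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in field(16 + 80 + 16, 8)])
        dmin = np.array([float(v) for v in field(16 + 80 + 24, 8)])
        dmax = np.array([float(v) for v in field(16 + 80 + 32, 8)])
        spr = np.array([int(v) for v in field(16 + 80 + 32 + 8 + 80, 8)])

        counts = spr * n_records
        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = int(counts.sum())
    if raw.size < expected:
        raise IngestionError(f"{path}: EDF data shorter than header declares")
    samples = np.empty((n_ch, int(counts.max())), dtype=float)
    scale = (pmax - pmin) / (dmax - dmin)
    pos = 0
    write_at = np.zeros(n_ch, dtype=int)
    raw = raw[:expected]
    for _ in range(n_records):
        for ch in range(n_ch):
            chunk = raw[pos : pos + spr[ch]]
            samples[ch, write_at[ch] : write_at[ch] + spr[ch]] = (
                chunk - dmin[ch]
            ) * scale[ch] + pmin[ch]
            write_at[ch] += spr[ch]
            pos += spr[ch]
    rate = spr[0] / duration
    return samples, rate, labels, modalities, start_time
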