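"""Minimal EDF (European Data Format) reader/writer.

Implements the plain EDF dialect: fixed-width ASCII headers plus
little-endian 16-bit data records.  Only what the pipeline needs is
supported — equal sampling rate across stored signals, 1-second data
records, physical dimensions of uV or mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["EdfSignal", "read_edf", "write_edf"]

_HDR = 256


@dataclass
class EdfSignal:
    label: str
    rate: float
    samples: np.ndarray  # physical units (uV)


class EdfFormatError(ValueError):
    pass


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EdfFormatError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in ("%g", "%.6g", "%.4g", "%.2f"):
        s = fmt % value
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise EdfFormatError(f"cannot encode {value} in {width} chars")


def write_edf(
    path: str,
    signals: list[EdfSignal],
    *,
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write signals to ``path`` as plain EDF with 1 s data records.

    All signals must share one integer sampling rate and a sample count
    that is a whole number of seconds (EDF stores only full records).
    """
    if not signals:
        raise ValueError("write_edf: empty signal list")
    rates = {s.rate for s in signals}
    if len(rates) > 1:
        raise ValueError(f"write_edf: mixed sampling rates {sorted(rates)}")
    rate = rates.pop()
    if rate != int(rate) or rate <= 0:
        raise ValueError(f"write_edf: sampling rate must be a positive integer, got {rate}")
    rate = int(rate)
    lengths = {len(s.samples) for s in signals}
    if len(lengths) > 1:
        raise ValueError("write_edf: signals must have equal length")
    n = lengths.pop()
    if n == 0:
        raise ValueError("write_edf: zero-length signals")
    if n % rate:
        raise ValueError(
            "write_edf: signal length must be a whole number of seconds "
            f"({n} samples at {rate} Hz)"
        )
    n_records = n // rate
    ns = len(signals)

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HDR * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )

    phys_ranges = []
    for s in signals:
        amax = float(np.max(np.abs(s.samples))) if len(s.samples) else 0.0
        # headroom so rounding never clips; keep encodable in 8 ASCII chars
        pmax = max(math.ceil(amax * 1.001), 1)
        phys_ranges.append((-pmax, pmax))

    dmin, dmax = -32768, 32767
    sig_hdr = b"".join(
        [
            b"".join(_field(s.label, 16) for s in signals),
            b"".join(_field("", 80) for _ in signals),
            b"".join(_field("uV", 8) for _ in signals),
            b"".join(_num(pr[0], 8) for pr in phys_ranges),
            b"".join(_num(pr[1], 8) for pr in phys_ranges),
            b"".join(_num(dmin, 8) for _ in signals),
            b"".join(_num(dmax, 8) for _ in signals),
            b"".join(_field("", 80) for _ in signals),
            b"".join(_field(str(rate), 8) for _ in signals),
            b"".join(_field("", 32) for _ in signals),
        ]
    )

    digital = []
    for s, (pmin, pmax) in zip(signals, phys_ranges):
        scale = (dmax - dmin) / (pmax - pmin)
        d = np.round((np.asarray(s.samples, dtype=float) - pmin) * scale + dmin)
        digital.append(np.clip(d, dmin, dmax).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * rate : (r + 1) * rate].tobytes())


def read_edf(path: str) -> list[EdfSignal]:
    """Read all signals from an EDF file; samples returned in uV."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HDR:
        raise EdfFormatError(f"{path}: truncated EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        record_dur = float(raw[244:252].decode("ascii").strip())
        ns = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise EdfFormatError(f"{path}: malformed EDF header") from exc
    off = _HDR

    def block(width: int) -> list[str]:
        nonlocal off
        out = [
            raw[off + i * width : off + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]
        off += ns * width
        return out

    labels = block(16)
    block(80)  # transducer
    dims = block(8)
    pmins = [float(x) for x in block(8)]
    pmaxs = [float(x) for x in block(8)]
    dmins = [int(x) for x in block(8)]
    dmaxs = [int(x) for x in block(8)]
    block(80)  # prefiltering
    spr = [int(x) for x in block(8)]
    block(32)  # reserved

    data_off = _HDR * (ns + 1)
    rec_len = sum(spr)
    payload = np.frombuffer(raw, dtype="<i2", offset=data_off)
    if payload.size < rec_len * n_records:
        raise EdfFormatError(f"{path}: truncated data records")
    payload = payload[: rec_len * n_records].reshape(n_records, rec_len)

    out: list[EdfSignal] = []
    pos = 0
    for i in range(ns):
        dim = dims[i]
        if dim in ("uV", "µV", ""):
            unit = 1.0
        elif dim == "mV":
            unit = 1000.0
        else:
            raise EdfFormatError(
                f"{path}: unsupported physical dimension {dim!r} for {labels[i]!r} "
                "(expected uV or mV)"
            )
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        dig = payload[:, pos : pos + spr[i]].reshape(-1).astype(float)
        phys = (dig - dmins[i]) * gain + pmins[i]
        out.append(EdfSignal(label=labels[i], rate=spr[i] / record_dur, samples=phys * unit))
        pos += spr[i]
    return out
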