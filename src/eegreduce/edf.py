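"""Minimal EDF (European Data Format) reader and writer.

EDF is the standard container for long-term scalp EEG: a fixed-layout
ASCII header followed by 16-bit little-endian sample records, with a
per-channel linear mapping between digital and physical values.  Only the
subset needed for multichannel fixed-rate recordings is implemented:
one-second data records, identical sampling rate on all channels, no
EDF+ annotations.  Physical calibration is chosen per channel from the
data range, so a write/read round trip is exact to within one digital
quantization step.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = ["write_edf", "read_edf", "EDFFormatError"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFFormatError(ValueError):
    """Raised when a file does not parse as EDF."""


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(record, path) -> None:
    """Write a record as EDF with 1 s data records.

    The sampling rate must be a whole number of Hz; a trailing partial
    second of data is dropped with a warning.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per data record, per channel
    n_ch = record.n_channels
    n_rec = record.n_samples // spr
    if n_rec * spr != record.n_samples:
        warnings.warn("trailing partial second dropped when writing EDF")
    data = record.data[:, : n_rec * spr]

    pmins = np.floor(data.min(axis=1)).astype(int)
    pmaxs = np.ceil(data.max(axis=1)).astype(int)
    pmaxs = np.where(pmaxs <= pmins, pmins + 1, pmaxs)

    hdr = b""
    hdr += _field("0", 8)
    hdr += _field(record.record_id[:80], 80)
    hdr += _field("eegreduce synthetic", 80)
    hdr += _field("01.01.01", 8)
    hdr += _field("00.00.00", 8)
    hdr += _field(256 * (1 + n_ch), 8)
    hdr += _field("", 44)
    hdr += _field(n_rec, 8)
    hdr += _field(1, 8)
    hdr += _field(n_ch, 4)
    for name in record.channel_names:
        hdr += _field(name[:16], 16)
    hdr += b"".join(_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_field("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_field(int(p), 8) for p in pmins)
    hdr += b"".join(_field(int(p), 8) for p in pmaxs)
    hdr += b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch))
    hdr += b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_field(spr, 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 32) for _ in range(n_ch))

    scale = (pmaxs - pmins) / (_DIG_MAX - _DIG_MIN)
    dig = np.rint((data - pmins[:, None]) / scale[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr)
        # record-major, channel-blocked layout
        blocks = dig.reshape(n_ch, n_rec, spr).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def _read_fields(buf: bytes, n: int, width: int, pos: int):
    out = []
    for _ in range(n):
        out.append(buf[pos:pos + width].decode("ascii", errors="replace").strip())
        pos += width
    return out, pos


def read_edf(path):
    """Read an EDF file into an :class:`~eegreduce.synthetic_eeg.EEGRecord`.

    All channels must share one sampling rate.  No annotations are read;
    attach events from a summary file separately.
    """
    from .synthetic_eeg import EEGRecord

    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256 or head[:8].strip() not in (b"0", b"0\x00"):
            raise EDFFormatError(f"{path} is not an EDF file")
        try:
            record_id = head[8:88].decode("ascii").strip()
            n_rec = int(head[236:244])
            rec_dur = float(head[244:252])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise EDFFormatError(f"malformed EDF header in {path}") from exc
        if n_ch <= 0 or n_rec < 0 or rec_dur <= 0:
            raise EDFFormatError(f"malformed EDF header in {path}")
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise EDFFormatError(f"truncated EDF header in {path}")
        pos = 0
        labels, pos = _read_fields(sig, n_ch, 16, pos)
        _, pos = _read_fields(sig, n_ch, 80, pos)       # transducer
        _, pos = _read_fields(sig, n_ch, 8, pos)        # physical dimension
        pmin_s, pos = _read_fields(sig, n_ch, 8, pos)
        pmax_s, pos = _read_fields(sig, n_ch, 8, pos)
        dmin_s, pos = _read_fields(sig, n_ch, 8, pos)
        dmax_s, pos = _read_fields(sig, n_ch, 8, pos)
        _, pos = _read_fields(sig, n_ch, 80, pos)       # prefiltering
        spr_s, pos = _read_fields(sig, n_ch, 8, pos)
        try:
            pmins = np.array([float(v) for v in pmin_s])
            pmaxs = np.array([float(v) for v in pmax_s])
            dmins = np.array([float(v) for v in dmin_s])
            dmaxs = np.array([float(v) for v in dmax_s])
            sprs = [int(v) for v in spr_s]
        except ValueError as exc:
            raise EDFFormatError(f"malformed signal header in {path}") from exc
        if len(set(sprs)) != 1:
            raise EDFFormatError("channels with differing sampling rates "
                                 "are not supported")
        spr = sprs[0]
        raw = np.frombuffer(fh.read(), dtype="<i2")
        expect = n_rec * n_ch * spr
        if raw.size < expect:
            raise EDFFormatError(f"truncated EDF data in {path}")
        raw = raw[:expect].reshape(n_rec, n_ch, spr)
        dig = raw.transpose(1, 0, 2).reshape(n_ch, n_rec * spr).astype(float)
        scale = (pmaxs - pmins) / (dmaxs - dmins)
        data = (dig - dmins[:, None]) * scale[:, None] + pmins[:, None]
        fs = spr / rec_dur
        return EEGRecord(data=data, fs=fs, channel_names=labels,
                         record_id=record_id or "record", events=[])
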