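"""Wireless link model: 16-bit uniform coding, bit-flip channel, accounting.

Values are clipped to a configured full-scale range, mapped to unsigned
16-bit codes by a uniform mid-rise quantizer, and serialized MSB-first
into a bitstream.  The channel flips each payload bit independently with
probability BER (no forward error correction, matching a minimal sensor
radio).  Packet accounting assumes an IEEE 802.15.4-style frame: up to
114 payload bytes plus 13 bytes of MAC overhead per packet; the overhead
bytes are not subject to corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

__all__ = [
    "QuantizerSpec",
    "BitStream",
    "PacketAccount",
    "encode",
    "decode",
    "corrupt",
    "packetize_account",
    "bytes_per_epoch",
    "data_rate_bps",
    "MAX_PAYLOAD_BYTES",
    "MAC_OVERHEAD_BYTES",
]

MAX_PAYLOAD_BYTES = 114
MAC_OVERHEAD_BYTES = 13
_BITS = 16
_LEVELS = 1 << _BITS


@dataclass(frozen=True)
class QuantizerSpec:
    """Full-scale range of the 16-bit uniform encoder, in signal units."""

    lo: float
    hi: float
    bits: int = _BITS

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("quantizer range requires lo < hi")
        if self.bits != _BITS:
            raise ValueError("the link uses a fixed 16-bit encoder")

    @property
    def step(self) -> float:
        return (self.hi - self.lo) / _LEVELS

    @classmethod
    def adc_full_scale(cls) -> "QuantizerSpec":
        """Signed 16-bit ADC range; integer samples round-trip to x + ½LSB."""
        return cls(lo=-32768.0, hi=32768.0)

    @classmethod
    def calibrate(cls, values: np.ndarray, margin: float = 1.2
                  ) -> "QuantizerSpec":
        """Symmetric range at ±margin × max |value| of a calibration set."""
        peak = float(np.max(np.abs(values))) if np.size(values) else 0.0
        if peak == 0.0:
            peak = 1.0
        return cls(lo=-margin * peak, hi=margin * peak)


@dataclass
class BitStream:
    """MSB-first bit sequence in 16-bit words."""

    bits: np.ndarray  # uint8 array of 0/1
    n_flipped: int | None = None  # set by corrupt()

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size % _BITS != 0:
            raise ValueError("bitstream length must be a multiple of 16")

    def __len__(self) -> int:
        return self.bits.size

    @property
    def n_words(self) -> int:
        return self.bits.size // _BITS


@dataclass
class PacketAccount:
    n_packets: int
    payload_bytes: int
    overhead_bytes: int

    @property
    def total_bytes(self) -> int:
        return self.payload_bytes + self.overhead_bytes


def encode(values: np.ndarray, spec: QuantizerSpec) -> BitStream:
    """Quantize to unsigned 16-bit codes and serialize MSB-first.

    Out-of-range values are clipped silently (the clip count is available
    via the quantizer step and is logged by the pipeline).
    """
    v = np.asarray(values, dtype=float).ravel()
    codes = np.floor((v - spec.lo) / spec.step)
    codes = np.clip(codes, 0, _LEVELS - 1).astype(np.uint16)
    bits = np.unpackbits(codes.astype(">u2").view(np.uint8))
    return BitStream(bits=bits)


def decode(stream: BitStream, spec: QuantizerSpec) -> np.ndarray:
    """Inverse of :func:`encode` up to quantization (mid-rise levels)."""
    bits = stream.bits
    if bits.size % _BITS != 0:
        raise ValueError("ragged bitstream: length not a multiple of 16")
    if bits.size == 0:
        return np.empty(0)
    codes = np.packbits(bits).view(">u2").astype(np.int64)
    return spec.lo + (codes + 0.5) * spec.step


def corrupt(stream: BitStream, ber: float, seed: int) -> BitStream:
    """Flip each bit independently with probability ``ber`` (seeded).

    The number of flips is recorded on the returned stream.
    """
    if not 0.0 <= ber <= 1.0:
        raise ValueError(f"BER must lie in [0, 1], got {ber}")
    if ber == 0.0:
        return BitStream(bits=stream.bits.copy(), n_flipped=0)
    rng = np.random.default_rng(seed)
    mask = (rng.random(stream.bits.size) < ber).astype(np.uint8)
    return BitStream(bits=stream.bits ^ mask, n_flipped=int(mask.sum()))


def packetize_account(n_bytes: int,
                      max_payload: int = MAX_PAYLOAD_BYTES,
                      mac: int = MAC_OVERHEAD_BYTES) -> PacketAccount:
    """Packets and total on-air bytes for a payload of ``n_bytes``."""
    if n_bytes < 0:
        raise ValueError("byte count must be non-negative")
    n_packets = ceil(n_bytes / max_payload) if n_bytes else 0
    return PacketAccount(n_packets=n_packets, payload_bytes=n_bytes,
                         overhead_bytes=mac * n_packets)


def bytes_per_epoch(approach: str, n_channels: int, n: int,
                    m: int | None = None, bits: int = _BITS) -> int:
    """Payload bytes one epoch contributes under each transmission approach.

    raw: every sample of every channel; compressed: M measurements per
    channel; features: one value per channel (an N:1 reduction).
    """
    if approach == "raw":
        return n_channels * n * bits // 8
    if approach == "compressed":
        if m is None:
            raise ValueError("compressed accounting needs M")
        return n_channels * m * bits // 8
    if approach == "features":
        return n_channels * bits // 8
    raise ValueError(f"unknown approach {approach!r}")


def data_rate_bps(n_channels: int, fs: float, bits: int = _BITS) -> float:
    """Raw acquisition data rate in bits per second."""
    return n_channels * fs * bits
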