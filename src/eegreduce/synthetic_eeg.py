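"""Synthetic annotated multichannel EEG for exercising the detection pipeline.

The generator emulates the structure of long-term pediatric scalp EEG
monitoring data: 23 bipolar channels sampled at 128 Hz with amplitudes in a
signed 16-bit integer range, hour-scale (freely scalable) records, and zero
or more non-overlapping seizure events of 6–752 s annotated at 1 s
resolution.

Background activity is stationary colored noise: per-channel order-2
autoregressive filtering of white Gaussian noise, with complex poles that
concentrate power at low frequencies the way resting scalp EEG does.
Seizure intervals superimpose a periodic spike-and-wave complex (default
3 Hz): a sharp biphasic spike followed by a compensating slow half-wave,
with per-complex amplitude jitter and alternating polarity.  Each channel
sees the same train scaled by a channel-specific attenuation drawn from
[0.5, 1].  The repetitive, similar maxima and minima over successive short
intervals are exactly the morphology the nonlinear-autocorrelation feature
is designed to pick up.

All randomness is derived from one master seed through ordered
``SeedSequence`` substreams (events, spike train, then one per channel) so
that changing the channel count never perturbs earlier channels.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

__all__ = [
    "SeizureEvent",
    "EEGRecord",
    "GeneratorConfig",
    "generate_record",
    "background_std",
    "write_annotations",
    "read_annotations",
    "read_summary",
    "write_edf",
    "read_edf",
]


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure, in seconds from record start."""

    onset_s: float
    offset_s: float

    def __post_init__(self):
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError(
                f"invalid event: onset {self.onset_s} must be >= 0 and "
                f"< offset {self.offset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EEGRecord:
    """Multichannel sampled signal with seizure annotations."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    record_id: str = "record"
    events: list[SeizureEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match data rows")
        dur = self.data.shape[1] / self.fs
        for ev in self.events:
            if ev.offset_s > dur + 1e-9:
                raise ValueError(
                    f"event ({ev.onset_s}, {ev.offset_s}) exceeds record "
                    f"duration {dur:.1f} s"
                )
        self.events = sorted(self.events, key=lambda e: e.onset_s)
        for a, b in zip(self.events, self.events[1:]):
            if b.onset_s < a.offset_s:
                raise ValueError("events overlap")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic record generator.

    ``ar_coeffs`` are the AR(2) recursion coefficients (a1, a2) of the
    background, ``noise_scale`` the innovation standard deviation in
    signal (ADC) units.  ``seizure_gain`` sets the spike-complex peak
    amplitude as a multiple of the stationary background standard
    deviation; 0 turns seizure activity off (events remain annotated).
    """

    n_channels: int = 23
    fs: float = 128.0
    duration_s: float = 3600.0
    n_events: int = 1
    event_duration_bounds: tuple[float, float] = (6.0, 752.0)
    ar_coeffs: tuple[float, float] = (1.746, -0.81)  # poles r=0.9, ~5 Hz
    noise_scale: float = 25.0
    spike_rate_hz: float = 3.0
    seizure_gain: float = 6.0
    amplitude_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0 or self.noise_scale <= 0:
            raise ValueError("fs, duration_s and noise_scale must be positive")
        if self.spike_rate_hz <= 0:
            raise ValueError("spike_rate_hz must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        lo, hi = self.event_duration_bounds
        if not (0 < lo <= hi):
            raise ValueError("event duration bounds must satisfy 0 < lo <= hi")
        if self.seizure_gain < 0:
            raise ValueError("seizure_gain must be non-negative")


def background_std(config: GeneratorConfig) -> float:
    """Stationary standard deviation of the AR(2) background.

    For x_t = a1 x_{t-1} + a2 x_{t-2} + e_t with Var(e) = s²:
    Var(x) = s² (1−a2) / ((1+a2)((1−a2)² − a1²)).
    """
    a1, a2 = config.ar_coeffs
    denom = (1 + a2) * ((1 - a2) ** 2 - a1 ** 2)
    if denom <= 0:
        raise ValueError("AR(2) coefficients are not stationary")
    return config.noise_scale * math.sqrt((1 - a2) / denom)


def _draw_events(config: GeneratorConfig, rng: np.random.Generator
                 ) -> list[SeizureEvent]:
    """Place non-overlapping integer-second events uniformly in the record."""
    if config.n_events == 0:
        return []
    lo, hi = config.event_duration_bounds
    hi = min(hi, config.duration_s)
    if lo > config.duration_s:
        raise ValueError("event duration bounds exceed record duration")
    durations = np.round(rng.uniform(lo, hi, size=config.n_events))
    durations = np.maximum(durations, 1.0)
    if durations.sum() + config.n_events > config.duration_s:
        raise ValueError(
            f"cannot fit {config.n_events} events of total "
            f"{durations.sum():.0f} s in a {config.duration_s:.0f} s record"
        )
    # distribute the leftover time as random integer gaps around the events
    slack = int(config.duration_s - durations.sum())
    cuts = np.sort(rng.integers(0, slack + 1, size=config.n_events))
    gaps = np.diff(np.concatenate([[0], cuts]))
    events = []
    t = 0.0
    for g, d in zip(gaps, durations):
        onset = t + float(g)
        events.append(SeizureEvent(onset_s=onset, offset_s=onset + float(d)))
        t = onset + float(d)
    return events


def _spike_wave_kernel(period: int, spike_width: int) -> np.ndarray:
    """One period of a spike-and-wave complex, peak-normalized to 1."""
    spike_width = min(max(spike_width, 3), period)
    k = np.zeros(period)
    k[:spike_width] = np.hanning(spike_width)
    rest = period - spike_width
    if rest > 0:
        k[spike_width:] = -0.5 * np.sin(np.pi * np.arange(rest) / rest)
    return k


def _seizure_train(n: int, fs: float, gain_units: float, rate_hz: float,
                   jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Additive spike-and-wave train covering ``n`` samples."""
    period = max(int(round(fs / rate_hz)), 4)
    spike_width = max(int(round(0.1 * fs)), 3)
    kernel = _spike_wave_kernel(period, spike_width)
    out = np.zeros(n)
    k = 0
    for start in range(0, n, period):
        amp = gain_units * (1.0 + rng.uniform(-jitter, jitter))
        pol = 1.0 if k % 2 == 0 else -1.0
        seg = kernel[: min(period, n - start)]
        out[start:start + seg.size] = pol * amp * seg
        k += 1
    return out


def generate_record(config: GeneratorConfig, record_id: str = "synthetic"
                    ) -> EEGRecord:
    """Generate one annotated multichannel record.

    Deterministic given ``config`` (including its seed).  Raises if the
    requested events cannot fit in the record without overlap.
    """
    n = int(round(config.duration_s * config.fs))
    master = np.random.SeedSequence(config.seed)
    ev_seq, spike_seq, *ch_seqs = master.spawn(2 + config.n_channels)
    events = _draw_events(config, np.random.default_rng(ev_seq))

    bg_std = background_std(config)
    gain_units = config.seizure_gain * bg_std
    spike_rng = np.random.default_rng(spike_seq)
    trains = []
    for ev in events:
        i0 = int(round(ev.onset_s * config.fs))
        i1 = min(int(round(ev.offset_s * config.fs)), n)
        trains.append((i0, _seizure_train(i1 - i0, config.fs, gain_units,
                                          config.spike_rate_hz,
                                          config.amplitude_jitter, spike_rng)))

    a1, a2 = config.ar_coeffs
    b, a = [1.0], [1.0, -a1, -a2]
    data = np.empty((config.n_channels, n))
    for c, seq in enumerate(ch_seqs):
        rng = np.random.default_rng(seq)
        white = rng.normal(0.0, config.noise_scale, size=n + 512)
        bg = _signal.lfilter(b, a, white)[512:]  # drop filter warm-up
        for i0, train in trains:
            atten = rng.uniform(0.5, 1.0)
            bg[i0:i0 + train.size] += atten * train
        data[c] = bg
    data = np.rint(data)  # integer ADC output, 16-bit range
    names = [f"CH{c + 1:02d}" for c in range(config.n_channels)]
    return EEGRecord(data=data, fs=config.fs, channel_names=names,
                     record_id=record_id, events=events)


# ---------------------------------------------------------------------------
# annotation files (CHB-MIT-summary-style plain text)
# ---------------------------------------------------------------------------

_RE_FILE = re.compile(r"^File Name:\s*(\S+)")
_RE_COUNT = re.compile(r"^Number of Seizures in File:\s*(\d+)")
_RE_START = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*(\d+)\s*seconds")
_RE_END = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*(\d+)\s*seconds")


def write_annotations(record: EEGRecord, path) -> None:
    """Write one summary-style annotation block for a record.

    Times are written as integer seconds (1 s annotation resolution).
    """
    lines = [f"File Name: {record.record_id}.edf",
             f"Number of Seizures in File: {len(record.events)}"]
    for i, ev in enumerate(record.events, start=1):
        lines.append(f"Seizure {i} Start Time: {int(round(ev.onset_s))} seconds")
        lines.append(f"Seizure {i} End Time: {int(round(ev.offset_s))} seconds")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_summary(path) -> dict[str, list[SeizureEvent]]:
    """Parse a (possibly multi-record) summary file.

    Returns a mapping from record name (without extension) to its sorted
    event list.  Malformed seizure lines raise ``ValueError`` naming the
    offending line number.
    """
    blocks: dict[str, list[SeizureEvent]] = {}
    current: str | None = None
    expected: int | None = None
    pending_start: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _RE_FILE.match(line)
            if m:
                current = m.group(1)
                if current.lower().endswith(".edf"):
                    current = current[:-4]
                blocks[current] = []
                pending_start = None
                continue
            m = _RE_COUNT.match(line)
            if m:
                expected = int(m.group(1))
                continue
            m = _RE_START.match(line)
            if m:
                pending_start = int(m.group(1))
                continue
            m = _RE_END.match(line)
            if m:
                if current is None or pending_start is None:
                    raise ValueError(
                        f"{path}: line {lineno}: seizure end with no start")
                blocks[current].append(
                    SeizureEvent(onset_s=pending_start,
                                 offset_s=int(m.group(1))))
                pending_start = None
                continue
            if line.lower().startswith("seizure"):
                raise ValueError(f"{path}: line {lineno}: malformed seizure "
                                 f"line: {line!r}")
            # other metadata lines (channel lists, times) are ignored
    for name in blocks:
        blocks[name] = sorted(blocks[name], key=lambda e: e.onset_s)
    return blocks


def read_annotations(path) -> list[SeizureEvent]:
    """Read the events of a single-record annotation file, sorted by onset."""
    blocks = read_summary(path)
    events: list[SeizureEvent] = []
    for evs in blocks.values():
        events.extend(evs)
    return sorted(events, key=lambda e: e.onset_s)


# re-exported EDF I/O so the generator module covers the full round trip
from .edf import read_edf, write_edf  # noqa: E402
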