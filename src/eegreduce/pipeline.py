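"""End-to-end study orchestration.

Runs the three transmission approaches over a parameter grid and scores
each with leave-one-record-out cross-validation:

* ``raw`` — 16-bit-encode every sample, pass it through the bit-flip
  channel, decode at the server, extract features there, classify;
* ``compressed`` — compress each channel's epoch with the sparse binary
  measurement matrix, transmit the measurements through the channel,
  reconstruct server-side, extract features, classify;
* ``features`` — extract features on the sensor, transmit only the
  per-channel feature values, classify.

Quantizer ranges for features and measurements are calibrated per record
from the *other* records of the subject (the training split of its
leave-one-out fold) at ±1.2× the peak absolute value; raw samples use the
fixed ADC full scale.  Every grid point draws its channel-noise seeds
from the master seed and the point's coordinates, so any sweep subset
reproduces identically.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cs_codec, detection_eval, features as feat, link_model
from .detection_eval import ClassifierSpec, LabeledFeatureSet
from .synthetic_eeg import EEGRecord, GeneratorConfig, generate_record
from .edf import read_edf
from .synthetic_eeg import read_summary

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "make_subject",
    "run_experiment",
    "evaluate_point",
    "load_chbmit",
]

DEFAULT_EPOCH_SWEEP = (384, 512, 640, 768, 896)
DEFAULT_BER_SWEEP = (0.0, 1e-5, 1e-4, 1e-3, 1e-2)


@dataclass
class ExperimentConfig:
    """Grid and data definition for one study run."""

    approaches: tuple[str, ...] = ("raw", "compressed", "features")
    feature_names: tuple[str, ...] = ("nlacc",)
    epoch_lengths: tuple[int, ...] = (512,)
    crs: tuple[float, ...] = (1.0,)          # N:M ratios; 1 = uncompressed
    bers: tuple[float, ...] = (0.0,)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_records: int = 5
    n_seizure_records: int = 3
    master_seed: int = 0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    matrix_d: int = 4
    solver: str = "fista"
    solver_max_iter: int = 60

    def __post_init__(self):
        if not self.approaches or not self.epoch_lengths or not self.bers:
            raise ValueError("sweeps must be non-empty")
        if self.n_seizure_records > self.n_records:
            raise ValueError("more seizure records than records")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        clf = ClassifierSpec(**raw.pop("classifier", {}))
        for key in ("approaches", "feature_names", "epoch_lengths", "crs",
                    "bers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(generator=gen, classifier=clf, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str
    timings_s: dict[str, float]
    outputs: list[str]


def _sub_seed(master: int, *parts) -> int:
    """Deterministic 31-bit stream seed from the master seed and a tag."""
    tag = "|".join(str(p) for p in parts)
    return (master * 2654435761 + zlib.crc32(tag.encode())) % (2 ** 31)


def make_subject(config: ExperimentConfig) -> list[EEGRecord]:
    """Generate one subject: ``n_records`` records, the first
    ``n_seizure_records`` of which carry the configured seizure events."""
    records = []
    for r in range(config.n_records):
        gc = GeneratorConfig(**{**asdict(config.generator),
                                "n_events": (config.generator.n_events
                                             if r < config.n_seizure_records
                                             else 0),
                                "seed": _sub_seed(config.master_seed,
                                                  "record", r)})
        records.append(generate_record(gc, record_id=f"rec{r:02d}"))
    return records


def _labels_and_events(record: EEGRecord, n: int):
    epochs = feat.segment_and_label(record, n)
    labels = np.array([ep.label for ep in epochs], dtype=object)
    return epochs, labels


def _feature_sets_from_matrices(mats, labels_list, records, n):
    sets = []
    for f, labels, rec in zip(mats, labels_list, records):
        sets.append(LabeledFeatureSet(
            features=f, labels=labels, record_id=rec.record_id,
            epoch_duration_s=n / rec.fs, events=list(rec.events)))
    return sets


def _transmit_values(values: np.ndarray, quantizer, ber: float, seed: int
                     ) -> np.ndarray:
    stream = link_model.encode(values, quantizer)
    stream = link_model.corrupt(stream, ber, seed)
    return link_model.decode(stream, quantizer).reshape(values.shape)


def _calibrated_quantizers(per_record_values):
    """Per-record quantizers from the complementary (training) records."""
    quants = []
    for r in range(len(per_record_values)):
        others = [v for j, v in enumerate(per_record_values) if j != r]
        quants.append(link_model.QuantizerSpec.calibrate(
            np.concatenate([np.ravel(v) for v in others])))
    return quants


def evaluate_point(records: list[EEGRecord], approach: str, feature_name: str,
                   n: int, cr: float, ber: float, config: ExperimentConfig
                   ) -> tuple[detection_eval.MetricsReport, dict]:
    """Run one grid point end-to-end and return (metrics, accounting row)."""
    m = max(1, int(round(n / cr)))
    seed0 = (config.master_seed, approach, feature_name, n, cr, ber)
    # CR 1:1 means no compression: the transmitted payload is the raw epoch
    eff = "raw" if (approach == "compressed" and cr <= 1.0) else approach

    if eff == "features":
        exact = []
        labels_list = []
        for rec in records:
            epochs, labels = _labels_and_events(rec, n)
            exact.append(feat.feature_matrix(epochs, feature_name))
            labels_list.append(labels)
        quants = _calibrated_quantizers(exact)
        mats = [_transmit_values(f, q, ber,
                                 _sub_seed(config.master_seed, *seed0, r))
                for r, (f, q) in enumerate(zip(exact, quants))]
    elif eff == "raw":
        quant = link_model.QuantizerSpec.adc_full_scale()
        mats, labels_list = [], []
        for r, rec in enumerate(records):
            rx = _transmit_values(rec.data, quant, ber,
                                  _sub_seed(config.master_seed, *seed0, r))
            rx_rec = EEGRecord(data=rx, fs=rec.fs,
                               channel_names=list(rec.channel_names),
                               record_id=rec.record_id,
                               events=list(rec.events))
            epochs, labels = _labels_and_events(rx_rec, n)
            mats.append(feat.feature_matrix(epochs, feature_name))
            labels_list.append(labels)
    elif eff == "compressed":
        phi = cs_codec.make_matrix(m, n, d=config.matrix_d,
                                   seed=_sub_seed(config.master_seed,
                                                  "phi", n, m))
        params = cs_codec.ReconstructionParams(
            solver=config.solver, dictionary="dct",
            max_iter=config.solver_max_iter)
        measured, labels_list = [], []
        for rec in records:
            epochs, labels = _labels_and_events(rec, n)
            x = np.stack([ep.samples for ep in epochs])  # (E, C, N)
            measured.append(cs_codec.compress(x, phi).astype(float))
            labels_list.append(labels)
        quants = _calibrated_quantizers(measured)
        mats = []
        for r, (y, q, rec) in enumerate(zip(measured, quants, records)):
            y_rx = _transmit_values(y, q, ber,
                                    _sub_seed(config.master_seed, *seed0, r))
            flat = y_rx.reshape(-1, phi.m)
            x_hat = cs_codec.batch_reconstruct(flat, phi, params)
            x_hat = x_hat.reshape(y.shape[0], y.shape[1], n)
            epochs, _ = _labels_and_events(rec, n)
            for ep, xh in zip(epochs, x_hat):
                ep.samples = xh
            mats.append(feat.feature_matrix(epochs, feature_name))
    else:
        raise ValueError(f"unknown approach {approach!r}")

    sets = _feature_sets_from_matrices(mats, labels_list, records, n)
    preds = detection_eval.loro_cv(sets, config.classifier)
    report = detection_eval.compute_metrics(preds, sets)

    n_ch = records[0].n_channels
    payload = link_model.bytes_per_epoch(eff, n_ch, n, m=m)
    account = link_model.packetize_account(payload)
    row = {
        "approach": approach, "feature": feature_name, "N": n, "CR": cr,
        "M": m if eff == "compressed" else n, "BER": ber,
        "bytes_per_epoch": payload,
        "packets_per_epoch": account.n_packets,
        "total_bytes_per_epoch": account.total_bytes,
    }
    row.update(report.as_dict())
    return report, row


def run_experiment(config: ExperimentConfig, outdir) -> tuple[pd.DataFrame,
                                                              RunManifest]:
    """Run the full grid, write results.csv and manifest.json to outdir."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    records = make_subject(config)
    timings["generate"] = time.perf_counter() - t0

    rows = []
    for approach in config.approaches:
        crs = config.crs if approach == "compressed" else (1.0,)
        for feature_name in config.feature_names:
            for n in config.epoch_lengths:
                for cr in crs:
                    for ber in config.bers:
                        t1 = time.perf_counter()
                        _, row = evaluate_point(records, approach,
                                                feature_name, n, cr, ber,
                                                config)
                        timings[f"{approach}/{feature_name}/N{n}/"
                                f"CR{cr}/BER{ber}"] = (time.perf_counter()
                                                       - t1)
                        rows.append(row)
    df = pd.DataFrame(rows)
    results_path = outdir / "results.csv"
    df.to_csv(results_path, index=False)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        master_seed=config.master_seed,
        version=__version__,
        timings_s={k: round(v, 4) for k, v in timings.items()},
        outputs=[results_path.name],
    )
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(manifest), fh, indent=2)
    return df, manifest


def load_chbmit(record_dir) -> list[EEGRecord]:
    """Load a directory of EDF records with summary-style annotations.

    Records at 256 Hz are decimated to 128 Hz (anti-alias low-pass then
    keep every second sample).  A record with no events in any summary
    file is loaded without annotations.  Channel-count mismatches across
    records raise.
    """
    import warnings
    from scipy import signal as _signal

    record_dir = Path(record_dir)
    edf_paths = sorted(record_dir.glob("*.edf"))
    if not edf_paths:
        warnings.warn(f"no EDF files found in {record_dir}")
        return []
    events_by_name: dict[str, list] = {}
    for summ in sorted(record_dir.glob("*.txt")):
        try:
            events_by_name.update(read_summary(summ))
        except ValueError:
            raise
    records = []
    n_ch = None
    for path in edf_paths:
        rec = read_edf(path)
        if n_ch is None:
            n_ch = rec.n_channels
        elif rec.n_channels != n_ch:
            raise ValueError(
                f"{path.name}: channel count {rec.n_channels} does not "
                f"match {n_ch}")
        if abs(rec.fs - 256.0) < 1e-6:
            data = _signal.decimate(rec.data, 2, axis=1, zero_phase=True)
            rec = EEGRecord(data=data, fs=128.0,
                            channel_names=rec.channel_names,
                            record_id=rec.record_id, events=[])
        name = path.stem
        evs = events_by_name.get(name)
        if evs is None:
            warnings.warn(f"{path.name}: no summary entry, loaded without "
                          "events")
            evs = []
        rec.events = sorted(evs, key=lambda e: e.onset_s)
        rec.record_id = name
        records.append(rec)
    return records
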