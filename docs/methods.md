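# Methods

## Problem setting

A wireless EEG sensor node samples n_ch = 23 bipolar scalp channels at
f_s = 128 Hz with 16-bit resolution and must deliver enough information
to a data server for epoch-based seizure detection. The package models
the node-to-server path under three strategies — transmitting the raw
signal, compressive-sensing measurements, or per-epoch features — and
measures both detection quality and transmitted bytes as functions of
epoch size N, compression ratio CR = N:M, and channel bit-error rate.

## Synthetic EEG generator

Real long-term pediatric scalp recordings (hour-long records, a handful
of annotated seizures of 6–752 s) are emulated by
`synthetic_eeg.generate_record`:

- **Background**: per-channel stationary AR(2) noise,
  `x_t = a₁x_{t−1} + a₂x_{t−2} + e_t`, `e_t ~ N(0, σ²)`. Defaults
  a₁ = 1.746, a₂ = −0.81 place the complex pole pair at radius 0.9 and
  ≈5 Hz, giving the low-frequency-weighted spectrum of resting scalp
  EEG; σ = 25 ADC units yields a stationary standard deviation of
  ≈162 units (computed in closed form by `background_std`), comfortably
  inside the ±32768 16-bit range even under seizure gain 10.
- **Seizures**: an additive spike-and-wave train at 3 Hz (the classic
  rhythmic seizure morphology, and the one the NLACC feature targets):
  each period is a sharp biphasic spike (Hann-windowed, ≈0.1 s) followed
  by a compensating slow half-wave; complexes alternate polarity and
  carry ±10% amplitude jitter. Peak amplitude is `seizure_gain` ×
  background SD; each channel sees the same train scaled by a per-event
  attenuation drawn uniformly from [0.5, 1]. Gain 0 leaves events
  annotated but statistically invisible — the generator's negative
  control.
- **Events**: integer-second onsets/offsets (matching 1 s annotation
  resolution), non-overlapping, durations uniform within configured
  bounds (default 6–752 s); impossible placements are rejected.
- **Determinism**: one master `SeedSequence` spawns ordered substreams
  (event placement, spike train, then one per channel), so records are
  bit-reproducible and adding channels never perturbs existing ones.

Deliberately not modeled: ocular/muscle artifacts, realistic 10–20
spatial covariance, focal (channel-restricted) seizures, and the
256→128 Hz resampling of real acquisitions (records are generated at
128 Hz directly; the CHB-MIT-style loader decimates 256 Hz files).
Passing tests therefore demonstrate correctness of the pipeline and the
qualitative degradation behavior — not clinical detection performance on
real EEG, where artifacts inflate false positives and low-amplitude
seizures depress sensitivity.

## Features and epoch handling

Epoch k covers samples [kN, (k+1)N); a trailing partial epoch is
dropped. An epoch is SEIZURE if its span lies entirely within one event
(onset rounded down to samples, offset rounded up), NONSEIZURE if it
overlaps no event, otherwise MIXED; MIXED epochs are excluded from
training and from every metric. Features are computed per channel and
concatenated in record channel order.

NLACC uses w = 15-sample sub-windows with N_S = ⌊N/w⌋; the trailing
N mod w samples are unused, and the high/low sum runs over
i = 1..N_S−2, the range for which HVᵢ/LVᵢ reference existing
sub-windows.

## Operation-count cost model

`features.count_operations` runs instrumented streaming implementations
of the three extractors — the loops a microcontroller would execute —
and tallies elementary operations. The counting conventions are fixed
and worst-case (every data-dependent branch is tallied as taken):

- a squared term or a multiplication by a precomputed reciprocal
  normalization constant: 1 multiplication (forming the N−1 in
  1/(N−1): 1 addition);
- `|d|`: 1 comparison plus 1 addition (the negation, tallied
  worst-case); accessing the successor sample x_{i+1}: 1 addition;
- a running-max/min update: 1 comparison + 1 assignment per sample;
- the compound three-operand high/low selections (HVᵢ, LVᵢ): 1
  comparison + 1 assignment each, reflecting a fused select;
- per completed sub-window: the accumulator update
  `acc = acc + (hv − lv)` (2 additions, 1 assignment; the difference
  register is zero before the first emitted term) and six register
  moves (store the two window extrema into the two-window history,
  reset the running extrema);
- stores to named state registers count as assignments; loop-control
  updates and expression temporaries do not.

Under these conventions the instrumented counts reproduce the closed
forms `(add, assign, cmp, mult)` = energy `(N, N+1, 0, N+1)`,
line length `(4N−3, N, N−1, 1)`, NLACC
`(2N_S, 2N+9N_S−4, 2N+2N_S−4, 0)` exactly for every tested N
(128…896), and the instrumented routines return the same numeric feature
values as the vectorized extractors. Branch-count conventions in
published cost tables are rarely stated; alternative reasonable
conventions (e.g. counting loop-variable updates as assignments) yield
counts that differ by O(N) in single columns, which is why the package
pins the conventions above and verifies them against the closed forms in
the test suite.

## Compressive sensing

Φ is stored as its d = 4 row indices per column (the node keeps only an
index table in flash); `compress` accumulates each input sample into d
measurement registers — additions only, integer-in/integer-out.

Server-side reconstruction is pluggable:

- **BSBL (EM)**: y = As + noise with s partitioned into equal blocks
  (default 32 samples, last block short). Block i has prior
  N(0, γᵢB) with a single Toeplitz AR(1) correlation matrix B shared
  across blocks and re-estimated each iteration from the averaged
  posterior block moments (correlation coefficient clipped to |r| ≤
  0.99); γᵢ are EM-updated and blocks with γᵢ below 10⁻⁴·max γ are
  pruned. The noise floor λ defaults to 10⁻⁸·‖y‖²/M (near-noiseless
  measurements). Convergence is declared at a relative posterior-mean
  change below `tol` (default 10⁻⁶); hitting `max_iter` flags the
  result as non-converged rather than raising.
- **FISTA/DCT**: ℓ1-regularized recovery in the orthonormal DCT
  dictionary, step size from 30 power iterations on ΦᵀΦ, per-column
  regularization λ = 0.01·‖Aᵀy‖∞. This solver is fully vectorized over
  columns (`batch_reconstruct`) and is the default for pipeline-scale
  sweeps, where thousands of channel-epochs must be reconstructed; BSBL
  reconstructs EEG more faithfully but costs an M×M solve per iteration
  per signal.
- M ≥ N (no compression) short-circuits to exact least squares.

The sparsifying basis of the original server implementation is not
pinned down anywhere authoritative; both the time-domain block prior
(BSBL) and the DCT route are standard choices for raw EEG and are
exposed in `ReconstructionParams`.

## Link model

16-bit uniform mid-rise quantizer: codes ⌊(v−lo)/Δ⌋ clipped to
[0, 65535], Δ = (hi−lo)/2¹⁶, decoded to lo + (code+½)Δ, serialized
MSB-first. Ranges: raw EEG uses the fixed ADC full scale
[−32768, 32768) — integer samples decode to x + ½ LSB exactly; features
and compressive measurements use ±1.2× the peak absolute value over the
record's leave-one-out training split, with the range itself treated as
error-free metadata. Out-of-range values clip.

The channel flips each payload bit i.i.d. with probability BER (seeded,
flip count reported); MAC overhead bytes are not corrupted. No forward
error correction is applied — redundant bits would raise transmitter
energy, so the link is evaluated bare. Packetization: ⌈bytes/114⌉
packets, 13 overhead bytes each.

## Detection and metrics

sklearn's SVC implements the epoch classifier: polynomial kernel of
degree 2 with coef0 = 1 (so linear terms participate), gamma = "scale",
C = 1, inverse-class-frequency weights, and z-score standardization fit
on the training split only. The kernel degree is the one modeling
commitment; the remaining hyperparameters are defaults exposed in
`ClassifierSpec`, not tuned claims.

Leave-one-record-out CV trains on all of a subject's records but one and
predicts the withheld record, once per record; folds whose training
split is single-class are skipped with a warning. Metrics follow the
stated definitions exactly; two ambiguities are resolved as: the FPR
denominator is non-seizure recording time (non-seizure epochs × epoch
duration), not wall time, and latency is the delay from event onset to
the *end* of the first correctly labeled seizure epoch inside the event,
averaged over detected events only. Event-level sensitivity dominates
epoch-level sensitivity for trained detectors (one detected epoch
suffices per event); this is asserted on classifier outputs, not on
arbitrary prediction patterns, for which it is not an identity.

## Study conditions at desk scale

The package-level evaluation uses ten seeded synthetic subjects, each
five records of 240 s (three records carrying one 40–60 s seizure,
gain 8× background SD), N = 512, NLACC features: large enough for
~60 epochs/record and 3-fold-seizure LORO, small enough that the full
BER sweep {0, 10⁻⁵, 10⁻³, 10⁻²} × CR sweep {1:1, 5:1, 10:1, 20:1} runs
in a few minutes on one CPU. The clean-channel baseline is deliberately
separable (sensitivity 100%, FPR ≈ 0) so that degradation trends under
rising BER or CR are measured from a common ceiling, mirroring the
median behavior of well-detected subjects. Trends are assessed on
medians across the ten subjects and asserted as one-sided
(sensitivity non-increasing, FPR non-decreasing).

## Known limitations

- The generator's seizure morphology is global across channels; focal
  seizures, artifacts and montage effects are out of scope, so absolute
  metric values on synthetic data exceed what real recordings yield.
- The BSBL solver implements the block-sparse Bayesian framework but is
  not numerically identical to any particular released implementation.
- Power consumption of microcontroller/radio hardware is not modeled;
  the cost surface exposed here is operation counts and transmitted
  bytes/packets.
- EDF support covers the subset needed here (uniform rate, 1 s records,
  no EDF+ annotations).
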