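# Methods

## Problem setting

A sensing node records fixed-length heartbeat segments (140 samples per beat,
the segmentation used by the ECG5000 benchmark) and must tell normal from
abnormal beats locally, forwarding as little data as possible to an edge
node. The approach is one-class: an autoencoder is trained only on normal
beats, and the per-beat mean squared reconstruction error is the anomaly
statistic. Deploying the encoder and decoder as separate models lets the
sensor transmit the 5-value bottleneck code instead of the raw beat while the
edge node reconstructs the signal from its own decoder copy.

## Model and training

* **Topology.** Fully connected encoder 140 → 32 → 16 → 5 (ReLU throughout)
  and mirrored decoder 5 → 16 → 32 → 140 (ReLU hidden, sigmoid output). The
  hard constraints are the input width (140) and latent width (5); the hidden
  widths follow the canonical small autoencoder for this dataset. The sigmoid
  output assumes [0, 1]-scaled inputs, which the normalization stage
  guarantees for training data.
* **Loss and optimiser.** Per-point MSE, Adam (β₁ = 0.9, β₂ = 0.999,
  ε = 1e-8), learning rate 2e-3, batch size 64, default 100 epochs, optional
  early stopping on validation loss with patience 10 and best-weights
  restore. Chosen for robust desk-scale convergence; at these sizes training
  2,043 beats takes a few seconds on one CPU core.
* **Determinism.** Weight initialisation (Glorot uniform) and batch shuffling
  each flow from one integer seed; all arithmetic is single-threaded float64
  numpy, so identical arguments give bit-identical models. Tests rely on
  this.
* **Split equivalence.** The monolithic forward pass is *defined* as
  `decode(encode(x))`; there is no second arithmetic path, so sensor-side and
  edge-side reconstructions can differ only through the float32 encoding of
  the transmitted latent code. The packet payload is IEEE-754 float32, giving
  observed end-to-end discrepancies of order 1e-8 on [0, 1] signals (bounded
  in tests at 1e-6).

## Data handling

* **File dialect.** One beat per line, integer label first (1 = normal, 2–5 =
  abnormal classes), whitespace- or comma-delimited (both circulate);
  delimiter auto-detected, record length inferred from the first line and
  enforced. The writer emits 12 significant digits, so a round trip is exact
  on labels and ≤ 1e-9 on samples.
* **Split.** From the normal beats only: `floor(0.70·n)` drawn uniformly
  without replacement (seeded) for training; the remainder, kept in original
  file order, splits into a first half (validation, `floor`) and the rest
  (test). With n = 2919 this yields (2043, 438, 438). Floor-then-remainder is
  the only rounding that reproduces those counts.
* **Normalization.** Global min–max over all training-set values, mapping the
  training range to [0, 1]; fitted on training normals only, applied to every
  partition, never clipped — out-of-range excursions are precisely the signal
  that makes abnormal beats hard to reconstruct. The (min, max) pair is
  stamped on datasets and stored with the detector.

## Synthetic generator

Each beat is a baseline plus five Gaussian bumps (P, Q, R, S, T) with
template-relative centers and widths, plus i.i.d. Gaussian noise; per-record
noise seeds derive from (dataset seed, record index), so extending a dataset
never alters existing records. The default template has R amplitude 1.0 and
noise sd 0.03 (3% of R), within the regime where normal and abnormal
populations are separable by construction. Abnormal classes apply
severity-scaled, monotone distortions: T-wave inversion, QRS widening
(widths ×(1+s)), R attenuation (×(1−s)), P absence. Default study conditions
generate 2,919 normals (matching the benchmark's normal count) and 520 beats
per abnormal class.

What this emulates is the *shape* of the benchmark — majority normal class
with consistent morphology, minority classes with systematic distortions that
raise reconstruction error. It does not emulate physiological ECG: no
RR-interval dynamics, baseline wander, beat-to-beat morphology variability,
amplitude drift or multi-lead structure, and the four distortion operators
are stylised stand-ins, not reconstructions of the benchmark's actual
abnormal rhythm classes. Passing results on synthetic data therefore
demonstrate pipeline correctness and separability under clean conditions,
not clinical performance.

## Threshold rule and its statistics

The detector flags a beat iff its error strictly exceeds
τ = mean + k·std of the per-record training errors (population std, k = 1
default, configurable). This is the standard one-class reconstruction rule,
but k = 1 has a structural consequence worth knowing: for a well-trained
model the per-beat MSE over L = 140 points is noise-dominated and
approximately σ²·χ²(L)/L distributed, so its coefficient of variation is
≈ √(2/L) ≈ 0.12 and the fraction of *normal* beats above mean + 1·std
converges to ≈ 15% regardless of noise level, training-set size or training
quality. Expected specificity under k = 1 is therefore ≈ 0.85 (measured
0.77–0.90 across seeds); reaching 90% specificity requires k ≈ 1.3 (the 90th
percentile of the error distribution). Sensitivity on clearly distorted beats
(severity ≥ 0.8) is 1.0 throughout. Applications that need a specificity
target should set k accordingly rather than rely on the default.

## Packet format and session simulation

Fixed little-endian header — version (1 B), device id (2 B), sequence number
(4 B), flags (1 B: anomaly bit + payload kind), decoder fingerprint (4 B) —
then a 1-byte payload length and the float32 payload. The fingerprint is a
32-bit BLAKE2s digest of the decoder parameters; the edge node refuses
packets whose fingerprint does not match its own decoder copy, catching
mismatched deployments before reconstruction. The session simulator is
timing-free: no loss, reordering or retransmission; link behaviour enters
only through the latency model's parameters.

## Latency model

Latency is accounted as `total = transmission + inference`, exactly additive.
Transmission over a link is `(points · bytes_per_point + overhead) · 8 /
rate`; alternatively a *measured* component time can be supplied directly,
which is how hardware-derived figures (e.g. 0.028 ms SPI transfer, 0.48 ms
MCU inference, totalling 0.508 ms for the on-device scenario) enter the
comparison. The model deliberately takes component times as inputs rather
than deriving them from nominal link rates: measured transfer times on real
prototypes reflect driver and framing effects that a bare rate calculation
does not, and the two are generally inconsistent (140 points × 2 bytes =
2,240 bits is 140 ms at a nominal 16 kb/s, not a few ms). The package
therefore asserts only what is arithmetically sound: additivity, and the
payload-point accounting (140 vs 5 points per beat, factor 28).

## Problem sizes and numerical choices

The test suite and the reproduction script run entirely on synthetic data at
the study's native scale: 2,919 normals for the split procedure, 2,000
normals / 400-beat balanced test sets for detection power (5 seeds), 100
random beats for split-equivalence, 100 training epochs. Full suite and
script each complete in well under a minute on one CPU core. Ties at the
threshold classify as normal (strict inequality). Degenerate inputs are
errors, not silent defaults: constant datasets cannot fit normalization,
unnormalized data cannot be trained on, empty error lists cannot be
summarised, and undefined confusion-matrix rates are reported as absent
rather than zero.

## Known limitations

* The one-class setup detects *reconstruction* failures; abnormalities that
  happen to lie near the learned 5-dimensional manifold would be missed.
* The default k = 1 threshold caps specificity near 85% (see above).
* The synthetic generator's clean separability overstates real-world
  performance; no claim is made about the benchmark recording itself beyond
  procedure compatibility (file dialect, counts, split sizes).
* Single-lead, fixed-length, pre-segmented beats only; no quantisation or
  integer inference (the software twin stays in floating point).
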