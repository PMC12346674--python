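# Methods

This note records the modelling and numerical choices behind the package:
what is computed, under which assumptions, and where the design was
genuinely open.

## Data model

A measurement is a 10 × T matrix of conductivity ratios G/G₀ (T = 120 at
1 Hz by default), strictly positive, with class / bottle / repetition
labels.  The sensor axis order is frozen to the instrument's listing order
(W1C, W5S, W3C, W6S, W5C, W1S, W1W, W2S, W2W, W3S); because the first
network stage convolves along this axis, the order is part of the data
contract, not a presentation detail.  Records are stored as long-format CSV
(one value per row) — unambiguous to parse, diff-able, and
deterministically ordered so identical datasets serialize byte-identically.
Seconds are 1-based so that "the 21st second" is t = 21.  Class labels are
0-based integers; a YAML sidecar maps them to human names.

Classification operates on single seconds: each record is sliced into
per-second 10-vectors (an instance table), and the train/test split is
performed at the *record* level, stratified by class, before slicing —
instances of one measurement never appear on both sides of the split.

## Synthetic data generator

No machine-readable measurements are available for the study conditions
this package targets, so all training and evaluation run on synthetic data
with the same structure.  For class c, sensor s, bottle b, repetition r:

    R(t) = 1 + A[c,s] · (1 + B[b]) · (1 + P[r]) · ramp(t; d[c], tau[c,s]) + eps(t)
    ramp(t) = max(0, 1 − exp(−(t − d[c]) / tau[c,s]))  for t > d[c], else 0

- **First-order rise** is the standard response kinetic of metal-oxide
  sensors; time constants tau ~ U(8, 25) s put the plateau at ~30–60 s.
- **Contact delay** d[c] ~ U(5, 20) s reproduces the low-information first
  ~20 s in which sample gas has not fully reached the array.
- **Bottle and repetition effects** are multiplicative Gaussian gains
  (fixed per bottle / per repetition), so replicate spread scales with
  response magnitude as it does in practice.
- **Additive noise** eps ~ N(0, σ_eps) per time point; values are clamped
  to a 10⁻³ floor to preserve G/G₀ > 0.
- **Amplitudes**: A[c,s] = base_s · (1 + sep · δ[c,s]) with δ ~ N(0,1) and
  a fixed per-sensor base vector (three sensors respond below baseline,
  i.e. negative amplitude).  The difficulty presets set the separation
  scale and the noise levels:

  | preset | sep | σ_bottle | σ_rep | σ_eps |
  |--------|-----|----------|-------|-------|
  | easy   | 1.0 | 0.02     | 0.01  | 0.01  |
  | medium | 0.25| 0.06     | 0.03  | 0.02  |
  | hard   | 0.06| 0.12     | 0.06  | 0.04  |

  The same seed produces the same δ at every difficulty, so a hard bank is
  an exact shrunk version of the easy bank and cross-difficulty
  comparisons are deterministic.

What the generator does **not** emulate: specific VOC–sensor chemistry,
sensor drift across days, humidity/temperature covariates, or the true
within-class/between-origin effect sizes (unknowable without the real
measurements).  Tests passing on this generator therefore demonstrate that
the pipeline recovers known structure under controlled conditions — not
that any particular accuracy would be attained on real chili-pepper data.

## Network architecture

The classifier is bias-free and pooling-free: with 10 input features,
pooling discards information, and removing biases roughly halves the
parameter count while simplifying the fixed-point datapath.  The pipeline
is local (parallel 1×3 and 1×5 convolutions along the sensor axis) →
global (an FC stage) → local (reshape to a 2D map, a second convolution) →
a linear projection to a 4-unit discriminative space → a linear classifier.

The published description fixes the costs but not the hidden widths.  The
accounting solver recovers them: under the multiply-accumulate convention
(1 MAC = 1 FLOP, activations free — forced by the data, since the
13-vs-7-class FLOP gap equals the parameter gap of the 4→C classifier, and
the constant 96-FLOP excess over the parameter count is exactly conv
kernel reuse), an exhaustive search over ~2 × 10⁷ bounded templates yields
50 shared-trunk architectures matching 268/364 and 244/340
simultaneously.  All of them have trunk costs 216 params / 312 FLOPs and a
4-wide projection (the head gap (268−244)/(13−7) = 4 forces it).

Cost-equivalent candidates are ordered by structural fidelity and
trainability, and the first is canonical:

1. genuinely 2D reshape shapes (the feature map is explicitly 2D);
2. fewest FC layers (parsimony);
3. superimposition (elementwise sum) fusion — the literal reading of
   branch superposition; concatenation remains available;
4. widest narrowest FC layer — in a bias-free network every post-ReLU
   layer input is nonnegative, so a unit whose weight row turns
   all-negative under SGD is permanently dead; narrow layers make such
   collapse catastrophic (we observed stuck training with merged classes
   on 5-wide variants);
5. lexicographic order, for determinism.

Canonical trunk: 1×3 and 1×5 single-filter branches ("same" padding),
sum fusion, FC 10→16, reshape (2, 8), a 1×8 convolution with 3 filters,
projection 9→4.

**Activation placement.**  ReLU follows the branch fusion, the FC stage and
the second convolution.  The 4-unit projection is *linear*: it factorizes
the classifier through a low-dimensional discriminative space (two stacked
linear maps, 9→4→C), and a rectified unit this narrow would be exposed to
the irrecoverable dead-unit failure described above — we measured exactly
that collapse before making it linear.  The classifier emits raw scores;
softmax lives inside the cross-entropy loss for numerical stability.

## Training

Mini-batch SGD exactly per the stated schedule: batch 32, lr
0.01 × 0.95^⌊e/10⌋, cross-entropy, 500 epochs by default.  Weight
initialization is uniform in ±√(1/fan_in), seeded.  Inputs are z-scored
per sensor with statistics from the training split only (a flag;
disabled, raw ratios are used).  Epochs shuffle with the run seed;
identical seeds give bitwise-identical runs.  The backward pass is written
by hand in numpy and verified against central finite differences
(relative error < 10⁻⁴) in the test suite.

`n_restarts` (default 1) trains several independently seeded runs and
keeps the lowest final training loss — the standard guard against the
occasional bad basin when fitting so small a bias-free ReLU network with
plain SGD.  Restart seeds derive from the master seed; the first restart
reproduces the single-run path exactly.

## Evaluation

Per-class one-vs-rest tallies feed the five metrics (accuracy, precision,
recall, specificity, F1).  Precision/recall/specificity/F1 are
macro-averaged (unweighted over classes; with the balanced designs used
here micro and macro nearly coincide); overall accuracy is the multiclass
fraction correct, with the one-vs-rest mean available behind
`accuracy_mode="ovr"`.  Zero-denominator classes contribute 0 and are
flagged.  The implementation is cross-checked against scikit-learn to
10⁻¹² on random tallies.

Two protocols: group 1 slices the full 1–120 s window, group 2 only
21–120 s (the stable phase).  Both report overall test metrics plus the
per-second accuracy curve over test records; `earliest_peak` returns the
first second attaining the curve's maximum — the recommended gas
collection time for rapid detection.  Repeated runs over a seed list with
mean reporting are supported.

## Fixed-point inference

Q(W, b) two's-complement fixed point, default Q(16, 12):
`X_fixed = ⌊X·2ᵇ + 0.5⌋` with saturation to [−2^(W−1), 2^(W−1)−1] (never
wrapping), `X = X_fixed/2ᵇ` back.  Round-half-up applies to negatives too
(⌊−1023.5⌋ = −1024).  The round-trip error for in-range values is at most
2^−(b+1).

The integer forward path stores weights and inputs in Q(16, 12), runs each
layer's MACs in a 64-bit accumulator with fixed left-to-right order
(bit-deterministic), and rescales once per layer by an arithmetic shift of
b with the +2^(b−1) rounding offset.  Two inter-layer schemes:

- **wide** (default): activations stay in the wide register between
  layers, as an HLS pipeline with wide accumulators keeps them; only
  storage (weights, inputs) is 16-bit.
- **narrow**: every inter-layer value saturates to the 16-bit range,
  modelling 16-bit inter-layer buffers.  With one shared format this
  clips activations beyond ±8; on the synthetic benchmark the trained
  model's hidden activations reach ~46, so the narrow scheme loses tens
  of accuracy points — which is why it is not the default.  Per-layer
  format selection (standard post-training calibration) would fix this
  but is out of scope while a single published (W, b) is modelled.

Integer ReLU is exact.  The quantizer reports how many weights saturated.

## Hardware schedule model

Loop unrolling by factor U turns n iterations into ⌈n/U⌉ sequential
stages at U× the loop-body resources; the time saving is (n − ⌈n/U⌉)/n.
The model is first-order on purpose: constant stage time, no pipeline
fill/drain, no memory-port contention beyond the chosen factor.  For the
5-tap convolution loop at U = 2: 3 stages, 2/5 saving, 2× resources.
Device-level latency, power and BRAM/DSP/LUT/FF figures are
toolchain-dependent and not modelled.

## Benchmark sizes

The train-in-the-loop tests use a scaled-down 7-class design (4 bottles ×
3 repetitions = 84 records; full 120 s records), 100 epochs and 3
restarts: small enough to train in seconds, large enough that the split
leaves ~4 test records per class and the per-second curves are
well-defined.  Full-size designs (10 × 10) are exercised for generation
and I/O, where cost is negligible.

## Known limitations

- The synthetic amplitudes, kinetics and noise scales are plausible, not
  calibrated to any instrument; absolute accuracies on synthetic data do
  not transfer to real measurements.
- The architecture solver recovers cost-consistent templates; which of the
  50 the original hardware ran is not decidable from the published costs
  alone, and the canonical choice is a documented convention.
- The fixed-point path simulates arithmetic semantics, not cycle-accurate
  hardware behaviour.
- Single-label classification only; no rejection option, no drift
  compensation, no cross-day generalization modelling.
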