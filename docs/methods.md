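# Methods

This note records the model assumptions, the synthetic-data design, the
numerical choices, and the known limitations of `neorespire`. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external measurements.

## Synthetic interrogation streams

The generator stands in for a programmable-mannequin recording that was never
deposited. It emulates the protocol's statistical structure, not the RF
physics in full:

* **Timeline.** Breathing at 31 breaths/min alternates with apnea pauses.
  The default plan repeats [120 s breathing, 30 s apnea, 120 s breathing,
  45 s apnea, 120 s breathing, 60 s apnea] and truncates the final segment to
  tile the requested duration exactly. The source protocol's breathing
  intervals are described only as "variable", so the 120 s figure is a
  package choice, fixed once. Each breathing segment restarts the chest-motion
  sinusoid at phase zero.
* **Arrivals.** One poll per 1/28 s slot, jittered uniformly within 90% of
  the slot (strictly increasing timestamps, count = ⌊28·duration⌋, within
  the ±5% band the aggregate-rate description implies). Poisson arrivals are
  available via `RFIDConfig(arrival="poisson")`.
* **Channel plan.** 50 equally spaced channel centers inside 902–928 MHz,
  visited round-robin, one hop per poll. Real FCC hopping is pseudo-random;
  round-robin has the same marginal distribution and is deterministic, hence
  testable.
* **Received power.** The radar cross-section link budget with
  `G_tag(t) = G₀(1 + m·sin(2πf_b t))` and `R(t) = R₀(1 + m·sin(2πf_b t))`
  during breathing, modulation depth m = 0.05 (the stretch-induced
  perturbation magnitudes are not published; 0.05 yields a ~0.65 dB
  peak-to-peak RSSI swing, comfortably above the noise floor chosen below).
  During apnea the modulation amplitude is zero, so P_Rx varies only with the
  hop channel (a ~0.5 dB λ⁴ sawtooth across the band) and noise.
* **Noise.** Additive Gaussian noise of 0.1 dB on the dBm reading, modelling
  the interrogator's RSSI estimation error after averaging. Real readers
  quantize RSSI at 0.5 dB and see multipath fading, tag collisions, and
  posture changes; none of that is modelled. Passing tests on this generator
  therefore demonstrates the pipeline's correctness and internal consistency,
  not field performance on infants.

## Features

Feature 1 defaults to `−10·log₁₀ζ` with the residual δ(f) subtracted: the ζ
form cancels the λ⁴ hop ripple exactly, and after per-feature standardization
it differs from de-oscillated dBm only by an affine map (the `deosc_dbm`
variant is exposed). Feature 2 (value minus trailing-window minimum, causal
window of 28 samples ≈ 1 s) is computed on the frequency-normalized series;
computed on raw RSSI the rolling minimum would track the 0.5 dB hop sawtooth
rather than the breathing modulation. Windows are half-open [t, t+1) s,
aggregated by the per-window mean of each feature (the aggregator is
pluggable), labelled by the majority ground-truth state with exact ties going
to the non-breathing class (the safety-critical call). Standardization uses
the population σ; the 3:1 split is a seeded random permutation
(chronological splitting available), with the scaler fitted on the training
partition only.

## Classifier and training

The canonical network (conv 64×k1 → pool 1 → flatten → dropout 0.01 →
dense 200 → dense 100 → dense 1) carries exactly 46,129 parameters; this
count anchors the model-size accounting, and it forces the single sigmoid
output unit — a two-unit softmax head would carry 46,230 parameters and break
the size table. Decision threshold 0.5. Training is minibatch Adam
(lr 0.001, batch 5, shuffle per epoch) on binary cross-entropy with inverted
dropout, up to 100 epochs under early stopping (patience 5 on validation
loss; by default 10% of the training split is held out for it). Weight
initialization is Glorot-uniform from the model seed; every stochastic
element (init, shuffling, dropout masks, fold assignment) flows from explicit
integer seeds. Grid search evaluates every (epochs, learning-rate) pair with
early stopping disabled — the epoch budget is the hyperparameter under test —
and breaks ties on (error, epochs, lr) so the result is order-invariant.
Repeated k-fold reports the mean accuracy, the standard deviation σ of the
per-repeat means, and σ/√n; with a single repeat σ falls back to the
across-fold deviation and the result is flagged degenerate rather than
failing.

## Quantization

The unit quantizer maps [0,1] onto the 2^k-point lattice with
round-half-away-from-zero everywhere (ties at lattice midpoints are exact in
binary for k ≤ 53 and must be deterministic; half-even would move them).
Weights pass through tanh and a per-tensor affine map into [0,1]; biases are
quantized like weights at the same k. Dequantization inverts the full map
(affine inverse, then arctanh with the argument clipped just inside ±1), so
the k=64 forward pass reproduces the full-precision network to ≲1e-9 —
inverting only the affine part would return tanh(w) and destroy that limit.
Activations are quantized as Q(clip(x,0,1)) with an optional per-layer scale
s calibrated as the maximum ReLU activation on training data
(`s·Q(clip(x/s,0,1))`): trained activations exceed 1, and the unscaled clip
would saturate them irrecoverably. The sigmoid output head stays in full
precision. Post-training quantization is the supported path; the model-size
rule is parameter_count × k.

## Spiking conversion

Integrate-and-fire without leak, reset by subtraction: both choices preserve
the proportionality between firing rate and ReLU activation that the
conversion relies on (reset-to-zero and a leaky kernel are available via
configuration, defaults off). Kernel-1 convolutions become block-diagonal
position-wise maps; pool-1 pooling and dropout vanish; flatten is an index
map. Per-layer weight normalization uses the data-based maximum activation λ
on the calibration batch (Ŵ_l = W_l·λ_{l−1}/λ_l, b̂_l = b_l/λ_l), keeping
per-step drives in the encodable range at V_th = 1. Standardized inputs can
be negative, so an affine map g sends the calibrated feature range into
[0,1] for Bernoulli rate encoding; the offset is folded into the first
layer's bias currents, making the encoded network exactly equivalent to the
source on the calibration range. T defaults to 1000 synchronous unit steps.

**Output decoding.** The single output unit is decoded from its spike count.
A fixed decision rate at half the calibrated maximum — the first design
considered — turns out to sit far above the class boundary, because a
confident classifier's logits are heavily right-skewed (positive-class output
rates span roughly 0.08–0.94 while the boundary is near rate 0.05); per-layer
rate/activation correlation exceeds 0.999, so this is a decoding artifact,
not a fidelity failure. The decoder therefore calibrates its threshold by
maximizing accuracy on the calibration batch at the network's operating
point (V_th, T); without labels it falls back to the fraction-of-max rule.
When an operating point silences the output entirely, the decoder
degenerates to the calibration majority class — which is also the correct
limit for the threshold sweep: as V_th → ∞ accuracy collapses to the
majority-class rate of the evaluation set.

**Threshold sweep.** Output rate scales roughly as V_th^(−L) through L
converted layers, so degradation with threshold is steep; the sweep defaults
cover V_th 1–10 with a finer 1–2.5 band where the network still classifies.
The decoder is recalibrated per threshold at the sweep's simulation horizon
(T = 400 by default; mismatched calibration/evaluation horizons mis-place the
threshold on the coarser rate lattice). Within the operating band, accuracy
across the grid fluctuates more for 100-window evaluation sets than for
2000-window sets at the reference seeds; this small-sample effect is
qualitative and can invert for individual seeds at these scales, since the
systematic threshold trend contributes variance at every sample size.

## Energy model

Spiking inference is billed per spike (23.6 pJ, a neuromorphic-hardware
constant calibrated at 30 Hz spike frequency — treated as the constant's
calibration condition, not enforced during simulation) and per routing event
(3 pJ), with one routing event per non-zero outgoing synapse per spike
(a flat per-spike alternative is configurable). Conventional inference is
billed per multiply-accumulate and per parameter access with parametric
coefficients e_mac(k) = 12·k² pJ and e_mem(k) = 1·k pJ — quadratic multiplier
scaling and linear memory-movement scaling, representative of
memory-dominated inference on wearable-class microcontrollers. The absolute
values are a declared parameterization, not device measurements: only
orderings and ratios between variants evaluated under the same table are
meaningful. Under the defaults and T ≤ 1000, per-inference energy orders
SNN < 8-bit ANN < full-precision ANN on the reference pipeline; this is a
property of the default parameters, not a physical claim.

## Reference scale and determinism

The reference study used by the tests and the acceptance script is a
10-minute recording (600 windows, 450/150 split) — large enough for the
classifier to saturate and small enough to run in about a minute on one CPU;
the sweep uses resampled evaluation sets of 100–2000 windows at T = 400.
Pipeline runs derive one sub-seed per stage from a master seed and record a
configuration hash in the run manifest; with the deterministic encoder the
whole pipeline is bit-reproducible, and with the Bernoulli encoder it is
reproducible for a fixed seed.

## Known limitations

* The generator omits multipath fading, tag collisions, RSSI quantization,
  phase/Doppler observables, and infant movement; accuracies measured on it
  are upper bounds with no claim of clinical transfer.
* Spiking conversion supports the converted architecture family (kernel-1
  convolutions, pool-1 pooling, dense ReLU stacks, single-unit heads;
  a Poisson-generator softmax rule would be needed for multi-class heads).
  Inter-spike-interval encoding is not implemented.
* Hardware mapping (cluster decomposition, network-on-chip placement,
  cycle-accurate simulation) is out of scope; energy accounting is purely
  event-counting.
* A converted network cannot represent decision boundaries in the negative
  region of the output drive (rates are one-sided); boundaries at the source
  network's own logit-zero line are represented exactly.
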