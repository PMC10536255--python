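# Methods

## Neuron model

The unit of computation is the leaky integrate-and-fire neuron iterated
along the data's own time axis. Per step: charge
`v_pre(t) = τ·v(t−1) + c(t)`, fire `s(t) = 1[v_pre(t) > V_th]` (strict
inequality — a potential exactly at threshold does not spike), reset
(hard: multiply by `1 − s`; soft: subtract `s·V_th`). The initial potential
is zero for every neuron and every forward pass, which makes the `T = 1`
case collapse to a thresholded activation. All state is float32; spikes are
asserted to be exactly 0.0 or 1.0.

The charge at step `t` is the layer's pre-activation at step `t`
(`c(t) = a[:, :, t]`): one consistent indexing convention, used everywhere.
No repeat-coding of static inputs — the SNN time dimension *is* the
(possibly pooled) sensor time dimension.

### Backward pass

The spike step has zero derivative almost everywhere; the backward pass
substitutes the triangle surrogate `max(0, 1 − |v_pre/V_th − 1|)` for
`∂s/∂v_pre` (peak 1 at `V_th`, feet at 0 and `2·V_th`). The forward pass is
always the exact step. Through time, the potential-to-potential path
carries a factor `τ` per step, modulated by the *literal* derivative of the
reset formula with the surrogate standing in for `∂s/∂v_pre`:

* hard reset: `∂v_post/∂v_pre = (1 − s) − v_pre · surrogate(v_pre)`
* soft reset: `∂v_post/∂v_pre = 1 − V_th · surrogate(v_pre)`

A common alternative detaches the reset from the gradient graph; the
literal chain was chosen because it follows mechanically from the update
rules, and it is what the hand-unrolled scalar-autodiff oracle in the test
suite independently reproduces. This is a documented convention, not a
claim that it is the only defensible one.

The learnable decay is one scalar per layer, parameterized `τ = sigmoid(b)`
with `b` initialized to 0 (τ = 0.5); its gradient accumulates
`∂v_pre/∂τ = v_post(t−1)` times `sigmoid(b)(1 − sigmoid(b))` over steps.

Defaults: `V_th = 0.5`, soft reset. `τ` defaults to 0.75 in `LIFConfig`
(appropriate for smooth, small-range signals) and to 0.25 in the bundled
benchmark, whose sharp, wide-ranging synthetic signals favor a short
memory — mirroring how the optimal decay differs across real HAR corpora.

## Architectures

Both model families are declared in a shared layer-spec language and built
by the same code path, so the spiking and artificial twins share the weight
skeleton exactly (equal trainable-parameter counts, modulo the optional
decay scalars):

* SpikeCNN / CNN: `conv(32,k8) → act → pool2 → conv(64,k8) → act → pool2 →
  conv(64,k8) → act → pool2 → flatten → dense(K)`.
* SpikeDCL / DCL: four `conv(64,k5) → act` stages, a 64-unit LSTM over the
  (spike) sequence, and a per-step dense head summed over time.

Conventions, chosen where the architecture strings leave room:

* Convolutions are 1-D along time with "same" zero padding and stride 1,
  so only pooling shortens the time axis and the LIF time axis stays
  aligned with the sensor clock. Pooling drops a trailing remainder when
  `T` is odd.
* The first conv layer consumes real-valued sensor data (direct coding);
  spikes first appear after the first LIF.
* Max-pooling over binary spikes is a logical OR of the window.
* The DCL stack has no pooling between convolutions, and its LSTM gates are
  conventional (not spiking).
* Class scores are the readout `Σ_t dense(h_t)` — with a zero-initialized,
  non-firing output layer this equals the integrated membrane potential of
  the head. For SpikeCNN the head sees the flattened channels × pooled-time
  tensor, so the sum has a single term.
* ANN twins add dropout p = 0.5 after each activation (the rate is this
  package's choice); spiking models use none. No normalization layers.
* Weight init is uniform fan-in scaling `U(±1/√fan_in)` from the run's
  seeded generator.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8), vanilla cross-entropy on the softmax of the
readout, batch size 128, cosine annealing of the learning rate to zero over
the configured epochs. The reference protocol is 60 epochs with the
learning rate picked from {1e-4, 3e-4, 1e-3} by best validation accuracy
(ties to the smaller rate) and five seeds 1000–1004; reported accuracy is
the test accuracy at the epoch of maximum validation accuracy (ties to the
earliest epoch), as mean ± sample sd over seeds. A NaN loss marks a run
"diverged" rather than raising. Splits are stratified by class at
64/16/20 by *window*, not by subject — a documented limitation for
subject-generalization claims.

Runs are deterministic given (seed, config, dataset fingerprint) in
single-threaded execution: one seeded generator drives init, shuffling and
dropout in a fixed order, and the config fingerprint (hashed into every
record) pins all of it. Multi-threaded BLAS may reorder reductions and is
not guaranteed bit-reproducible.

## Synthetic data

The generator emulates windowed wearable-sensor streams: window `i` of
class `k` is `amp · a_d · sin(2π f_k t/T + φ_i) + drift + noise` with a
random phase per window, per-window per-channel amplitude scaling
`a_d ~ U(0.5, 1.5)` that is deliberately class-independent (so the spatial
pattern carries no label information), a Gaussian random-walk baseline
drift (step sd 0.02 by default, emulating slow sensor bias), and i.i.d.
Gaussian noise. Class identity is carried *only* by the oscillation
frequency. Defaults: 100 windows/class, 3 classes, T = 128, D = 3,
amp = 1, noise sd = amp/2, class frequencies 3 + 2k cycles per window —
at these settings a linear classifier on DFT-peak features exceeds 90%
accuracy (and is perfect at zero noise), which calibrates the difficulty
knob.

The named **temporal benchmark** (`spikehar.benchmark`) sharpens this into
the regime where temporal integration is decisive: frequencies 3/4/5
cycles (periods much longer than one conv kernel) and noise sd = amp, so
per-step evidence is subthreshold and must be accumulated over time.
Training uses 30 epochs at 1e-3 for the conv family — the benchmark's
problem size (300 windows) needs no more — and the full 60 epochs for the
recurrent models, which converge more slowly. These settings are frozen;
they define the conditions under which the package's qualitative claims
(τ > 0 beats τ = 0, soft ≥ hard reset, LIF sparser than ReLU, SNN energy
below ANN energy) are evaluated by the test suite and
`scripts/acceptance.py`.

What the generator does *not* emulate: gravity components, sensor
saturation and calibration error, inter-subject variability, label noise,
class imbalance, and activity transitions inside a window. Passing the
synthetic benchmark therefore demonstrates that the machinery (dynamics,
gradients, protocol) works and that the temporal-memory effect exists in a
controlled setting — not that any particular accuracy transfers to real
recordings.

## Energy model

A transparent op-counting model of a PE-array accelerator with per-PE
input/weight scratchpads, parameterized by normalized per-event costs
(`e_mac = 0.175`, `e_spa = 0`, `e_lif = 0.383`, `e_ispad = 0.107`,
`e_wspad = 1.712`; unit = one ANN MAC). Per weighted layer:

```
compute = macs·e_mac + skipped_inputs·e_spa + lif_updates·e_lif
move    = macs·e_wspad + input_total·e_ispad + weight_count·e_wspad
```

MAC events are counted exactly (convolution boundary taps included), which
is why `LayerStats` stores event totals and derives the average
connections-per-nonzero-input; the estimator is required by the tests to
match a per-event enumeration simulator to machine precision. For spiking
layers a zero input spike skips both the accumulation and the
weight-scratchpad access; artificial layers compute densely (ReLU's exact
zeros are *not* skipped by default, because the skipping mechanism is
defined on spike inputs — `ann_skip_zeros` enables the alternative
accounting for sensitivity analysis). The `weight_count·e_wspad` term is
the one-time per-layer weight load; DRAM traffic beyond it is out of
scope, and membrane-potential storage traffic is folded into `e_lif` as an
approximation. LSTM layers count the dense MACs of their four gates;
input-side MACs are skippable on zero spikes, recurrent-side (real-valued
hidden state) MACs are not. Whether the weight-scratchpad cost applies per
MAC or per reuse window depends on the dataflow; the per-touched-connection
convention here is this package's definition. Array size (128 PEs) and
buffer capacities are carried as metadata only — they affect scheduling,
not op counts.

## Representation similarity

Linear CKA in the cross-covariance form
`‖YᵀX‖²_F / (‖XᵀX‖_F‖YᵀY‖_F)` after column centering — the biased
(plain centered-Gram) estimator, computed in float64. Values outside
`[−1e-8, 1 + 1e-8]` raise (catching implementation bugs rather than
clamping them away); an all-constant matrix after centering is flagged as
degenerate rather than given a number. Spiking layers contribute one
feature per neuron: the time-summed spike count, the same reduction the
readout uses; artificial layers are reduced identically so the comparison
is like-for-like, and a `flatten` option keeps the full channel × time
features instead. Activations are taken post-activation, pre-pooling, on
the full test split in a fixed batch order.

## Problem sizes and tolerances

The bundled studies use the 300-window benchmark (T = 128, D = 3) with
5-seed suites; unit tests use smaller instances (T ≤ 64). Oracle
agreements are asserted bit-exactly for the forward dynamics (same
float32 operation order), at 1e-6 relative for gradients (dyadic-rational
test inputs keep float32 arithmetic exact), at machine precision for
energy totals, and at 1e-8 for CKA identities.

## Known limitations

Pure-numpy training is CPU-bound and practical up to a few thousand
windows; there is no GPU path. Single-threaded determinism is the tested
mode. The energy model is first-order (no cycle-accurate timing, buffer
conflicts, leakage, or technology scaling). Splitting is per-window, so
results do not speak to leave-subject-out generalization. The surrogate
is fixed to the triangle form and the neuron to LIF; other surrogates and
adaptive-threshold variants are out of scope.
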