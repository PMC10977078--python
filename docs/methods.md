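# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic study conditions, the numerical design
choices, and what the tests do and do not establish.

## Signal model of the synthetic generator

`preictal.synth.gen_recording` produces a (channels × samples) recording
with annotated seizures:

* **Interictal background** — per-channel order-2 autoregressive noise,
  `x_t = 0.5 x_{t−1} + 0.2 x_{t−2} + ε_t`, `ε_t ~ N(0, noise_sd²)`,
  independent across channels, with a 500-sample burn-in discarded. The AR
  poles lie inside the unit circle, so the background is stationary and
  low-pass colored, a crude stand-in for EEG background rhythm.
* **Preictal signature** — for each onset, an additive sinusoid at
  `signature_freq_hz` (default 10 Hz) with independent per-channel phase,
  amplitude `signature_gain`, active on `[onset − preictal_len_s, onset)`.
  Its analytic band power is `gain²/2` per channel, which the tests use as
  the closed-form oracle for the injected effect.
* **Ictal segment** — a fixed 60 s high-amplitude 4 Hz burst. Its shape is
  irrelevant: ictal time is excluded from training and scoring.

Everything is a deterministic function of the config (including the seed).
What this generator does **not** emulate: non-stationary background drift,
inter-channel correlation, artifacts (EMG, eye blink, electrode pops),
patient-to-patient variability, or preictal signatures that differ across
channels and seizures. Tests passing on this data show the pipeline's
machinery is correct and that a learnable spectral biomarker is found and
exploited — they do not certify clinical performance on real recordings.

## Windowing and labels

For each onset `o`: preictal = `[o − SPH − PIL, o − SPH)`, clipped at 0 and
at the previous seizure's ictal end; the SPH gap `[o − SPH, o)` and the
ictal interval belong to neither class; interictal is the complement. All
intervals are half-open, in seconds. Preictal windows are extracted with
stride `window − overlap` (overlap 5 s by default, oversampling the minority
class); interictal windows with stride `window`. Window length is a free
parameter; the default is 30 s — long enough to exceed the 5 s overlap and
conventional for prediction-scale features. Training sets are balanced 1:1
by seeded subsampling of the interictal majority.

Leave-one-seizure-out: each split holds out one seizure's preictal windows
together with a matched contiguous chunk of interictal windows (the
time-ordered interictal windows are divided into as many contiguous chunks
as seizures); a strict disjointness check on (recording, time) origins
guards against leakage.

Alarm scoring: a seizure counts as predicted iff a confirmed alarm falls in
its preictal interval (multiple alarms count once); FAR counts every
confirmed alarm in interictal time, divided by interictal hours only —
alarms inside the SPH gap or ictal time count as neither (excluded time is
not a fair denominator for either metric). With zero interictal time the
FAR is reported as undefined rather than zero.

## Search space and controller

The architecture family is a 5-block channel-wise CNN on (channels × time)
maps: blocks 1–3 temporal (height-1 kernels — channels are never mixed, so
per-channel features survive), blocks 4–5 spatial (width-1 kernels — time is
never mixed). Per block the free choices are kernel extent, filter count and
pool extent, from the option sets listed in `preictal.archspace`; strides
are 1, convolutions are valid (no padding — keeps shape arithmetic exact and
matches hardware-friendly designs), pooling is non-overlapping max pooling,
and the head is global average pooling + dense softmax. T = 15 choices give
(4·3·4)³ × (4·3·3)² = 143,327,232 architectures.

The controller is a single tanh recurrent cell (hidden size 32) with
per-position input embeddings and softmax heads, initialized near zero so
the initial policy is near-uniform. It is trained by REINFORCE with an EMA
baseline (decay 0.9) and plain gradient ascent; the step size is a config
parameter (0.05 default; the planted-optimum experiments use 0.3, where the
32-string space makes larger steps safe). These controller sizes and rates
are deliberately minimal — the search spaces here have at most 15 positions
with ≤ 4 options. Candidate rewards are validation accuracy; a candidate
whose training diverges is recorded at chance (0.5) and the search
continues. The search log stores every (architecture, reward) pair and the
loop can resume from a partial log.

## Quantization-aware training

* Weight quantizer (Q ≥ 2): `q = clip(round(2^(Q−1) ω)/2^(Q−1), −1,
  1 − 2^(−(Q−1)))`. `round` is round-half-away-from-zero — the convention
  keeps the grid symmetric about 0; half-to-even would do as well but one
  must be fixed and documented.
* Activations: hard clip to [−1, 1], then the same grid ("quantized tanh");
  true tanh saturation is *not* applied. At Q = 1 the activation is the sign
  function with sign(0) = +1 (documented tie-break, consistent everywhere
  including the bit-packed engine).
* Backward pass: straight-through estimator — the quantizer's gradient is
  `1{|a| ≤ 1}` regardless of Q. Latent float weights are kept, clipped to
  [−1, 1] after each Adam step.
* Binary mode (Q = 1): ±1 weights in every layer including first and last;
  the input path stays at 8 bits (raw signals are not binary), per standard
  binary-network practice; the dense head drops its bias so the integer
  engine needs no extra scale alignment.
* Training: Adam (lr 0.01, batch 32), softmax cross-entropy. Quantized
  (especially binary) training is non-monotone, so the best-training-loss
  epoch snapshot is restored at the end, and batch-norm running statistics
  are recalibrated with one full pass before export.

Model size accounting: weights (conv + dense) at Q bits, dense biases and
folded batch-norm scale/shift at 8 bits each, `count_bn` exposed. The
"float shadow" size prices every parameter at 64 bits.

## Exact fixed-point inference

The exported `QuantizedModel` stores integer weight codes and the folded
batch-norm affine (`g = γ/√(σ²+ε)`, `b = β − μg`) quantized to *dyadic*
rationals: a signed 8-bit mantissa times a power of two, with the exponent
clamped to [−24, 6] so that every barrel shift in the integer datapath fits
a 64-bit accumulator. Because all stored quantities are dyadic, the
reference forward pass (float64) performs only exact arithmetic, and the
integer engine computes the same numbers scaled by known powers of two:

* 8-bit convolutions: radix-4 Booth shift-add with the kernel value as the
  stationary multiplicand, so each kernel's eight Booth products (shifts and
  negations only) are reused across the whole feature map;
* batch-norm scaling and the dense head: the same Booth digit encoding
  applied to a wide multiplicand (the partial sum) — hardware would use a
  wider datapath register for this stage;
* binary convolutions: XNOR + popcount via `dot = 2·pop − n`; the BNN's
  first layer (8-bit input × ±1 weights) is sign-gated accumulation;
* activation re-quantization: integer round-half-away by add-and-shift;
* global average pooling: the 1/N division is never performed — the dense
  scores are compared at scale N (argmax-invariant), keeping the whole path
  division-free.

Decisions therefore agree with the reference graph *exactly*, ties included
(both sides argmax identical integers up to a positive power-of-two scale).
A guarded `general_multiply` counter instruments the engine; it reads 0
after any inference. The scalar units (`popcount_shift`, `booth_encode`,
`booth_mac`, `xnor_popcount_dot`) are verified exhaustively (256 popcounts,
256 encodings, 65,536 MAC pairs) and the vectorised engine is tested
against them and against dense integer reference convolutions.

On the "XNOR vs XOR" question (the register-level description uses both
names): the engine uses XNOR, which is what makes `2·pop − n` the ±1 dot
product; the worked pattern `11010011` is treated as the already-formed bit
pattern entering the popcount, whose value 5 is what the register trace
shows.

## Event-driven cascade

The gate raises an event after `gate_threshold` consecutive positive binary
decisions (default 1 — the event mechanism is deliberately the simplest
consistent choice and is exposed in config). Events outside the post-alarm
refractory period (default = SPH; 30 s in the scaled benchmark) wake the
verifier, which confirms or rejects; only confirmations start a refractory.
The verifier consumes the same window that completed the event. Structural
guarantees, enforced by tests: confirmed alarms ⊆ gate events; verifier
invocations = gate events outside refractory, exactly; with an
always-positive verifier the cascade reproduces gate-only metrics. Power is
proxied by the duty cycle and by per-model operation counts, never by watts
— silicon measurements are out of scope.

## Benchmark study conditions and problem sizes

The standard benchmark (`preictal.fixtures`) is scaled so the full
leave-one-out pipeline runs in about a minute per seed on one CPU: 4
channels at 64 Hz, six seizures 900 s apart (~97 min of recording),
signature gain 2 at 10 Hz over unit-variance background, SPH 30 s, PIL
300 s, 30 s windows with 5 s preictal overlap — 11 preictal windows per
seizure, ~110 balanced training windows per split. The gate is an 8-filter
binary network (125 bytes), the verifier an 8-filter 8-bit network
(882 bytes; 7,056 bytes as its float64 shadow). Gate training runs 20
epochs, verifier 10. Under these conditions the pooled leave-one-out
sensitivity across seeds is ≥ 0.8 (typically 1.0), the verifier rejects the
gate's interictal false alarms (gate FAR ~0–1.4/h per seed → cascade FAR
~0), and the verifier duty cycle stays well below 1 (≈ 0 on seizure-free
recordings, ~0.2 on the benchmark where genuine preictal windows wake it).

## Known limitations

* Training is plain NumPy; it is adequate for the search-space models but
  not for real CHB-MIT-scale experiments (23 channels × 256 Hz × hours).
* Published clinical-dataset results (sensitivities, FARs, model sizes on
  CHB-MIT/AES/Melbourne) require the external datasets and full-scale
  training and are not reproduced here; the synthetic benchmark verifies
  the machinery, not clinical performance.
* The binary gate's accuracy on hard, low-SNR data is untested; on the
  benchmark its false-positive rate varies noticeably across training
  seeds, which is realistic for 1-bit models of this size.
* The EDF writer is minimal (16-bit, 1 s records, integer sampling rates)
  and intended for fixtures and interchange, not archival use.
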