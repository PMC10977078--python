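# preictal

Event-driven seizure prediction from multichannel EEG/iEEG with searched,
quantized, channel-wise CNNs and a bit-accurate multiplier-free inference
engine.

Implantable closed-loop neuromodulation devices must watch a neural signal
stream continuously on a power budget of microwatts, raise an alarm before a
seizure (not merely detect it), and keep false alarms rare enough that
stimulation is not wasted. This package implements the full algorithm stack
for that problem, at desk scale, for researchers in biomedical signal
processing and edge-AI hardware/software co-design:

1. **Windowing** — recordings with annotated onsets are split into *preictal*
   windows from `[onset − SPH − PIL, onset − SPH)` and *interictal* windows
   from the remaining background, where SPH (seizure prediction horizon) is
   the required warning gap and PIL the labeled preictal duration. Preictal
   windows are oversampled with a 5 s overlap; interictal windows do not
   overlap. Evaluation is leave-one-seizure-out.
2. **Architecture search** — a recurrent controller emits a string
   α₁:T (T = 15) describing a 5-block *channel-wise* CNN: three temporal
   blocks (1-D kernels along time, width ∈ {1,2,8,16}, filters ∈ {4,8,16},
   pool width ∈ {1,4,8,16}) that never mix channels, then two spatial blocks
   (height-only kernels, pool height ∈ {1,2,4}) that never mix time; global
   average pooling and a 2-class softmax head close the network. The
   controller maximizes J(ω) = E_{P(α₁:T;ω)}[R] by REINFORCE,

       ∇J ≈ (1/K) Σₖ Σₜ ∇_ω log P(aₜ | a_{t−1:1}; ω) (Rₖ − b),

   with R the candidate's validation accuracy and b an EMA baseline.
3. **Quantization-aware training** — weights and activations are quantized to
   Q bits on the symmetric fixed-point grid
   `q = clip(round(2^(Q−1) ω)/2^(Q−1), −1, 1 − 2^(−(Q−1)))` (activations
   through a quantized hard-tanh; Q = 1 gives sign/±1, a binary network).
   Backpropagation uses the straight-through estimator: the quantizer's
   gradient is that of `Htanh(a) = clip(a, −1, 1)`.
4. **Multiplier-free inference** — binary layers run as XNOR + popcount
   (`dot = 2·popcount(XNOR) − n`), 8-bit layers as radix-4 Booth shift-add
   MACs (an 8-bit multiplier becomes 4 digits in {−2,−1,0,1,2}); the
   popcount is emulated at the register level (shift right, re-insert the
   extracted LSB into the freed high bits). The engine's decisions match the
   quantized training graph exactly and a general-multiply counter verifies
   that no multiplication is ever issued.
5. **Event-driven cascade** — an always-on binary gate scans every window;
   only gate events wake the 8-bit CNN verifier, which confirms or rejects
   the alarm. The verifier's duty cycle is the software proxy for the
   event-driven power saving; sensitivity and false alarms per interictal
   hour (FAR) are the clinical metrics.

A seeded synthetic-data module generates annotated multichannel recordings
(stationary AR(2) background, a band-limited preictal oscillation of
configurable amplitude) so that the whole pipeline is testable end to end
without clinical data. An EDF reader (via `mne`) accepts real recordings.

## Worked example

Six synthetic seizures (10 Hz preictal signature, amplitude 2 over
unit-variance background), leave-one-seizure-out, BNN gate → CNN verifier:

```python
from preictal.fixtures import (benchmark_recording, benchmark_windowing,
                               benchmark_cascade_config)
from preictal.evaluate import run_loocv

report = run_loocv(
    [benchmark_recording(seed=1)],
    windowing=benchmark_windowing(),        # SPH 30 s, PIL 300 s, 30 s windows
    cascade_cfg=benchmark_cascade_config(), # gate threshold 1, refractory 30 s
    seed=1,
)
gate_fa = sum(s.gate_false_alarms for s in report.per_split)
print(f"sensitivity        : {100 * report.sensitivity:.1f} %")
print(f"cascade FAR        : {report.far_per_h:.2f} /h")
print(f"gate-only FAR      : {gate_fa / report.interictal_hours:.2f} /h")
print(f"verifier duty cycle: {100 * report.duty_cycle:.1f} %")
for name, size in report.model_size_bytes.items():
    print(f"{name:20s}: {size} bytes")
```

prints

```
sensitivity        : 100.0 %
cascade FAR        : 0.00 /h
gate-only FAR      : 0.00 /h
verifier duty cycle: 17.7 %
bnn_1bit            : 125 bytes
cnn_8bit            : 882 bytes
cnn_float64_shadow  : 7056 bytes
```

Every held-out seizure is predicted (an alarm falls inside its preictal
interval at least 30 s before onset), no false alarm survives the verifier,
the verifier runs on under a fifth of the stream (it is woken by genuine
preictal windows plus the occasional gate false positive), and the 8-bit
verifier is 8× smaller than the same network in 64-bit floats. Across
training seeds the gate typically shows a false-alarm rate of ~0–1.4/h that
the verifier filters to ~0 — the division of labour the cascade is built
for: the cheap gate governs power, the verifier governs false alarms.

The same pipeline is scriptable from the shell:

```sh
preictal simulate --channels 4 --fs 64 --duration 3000 \
    --onsets 700,1600,2500 --preictal-len 330 --seed 1 --out rec
preictal loocv --rec rec --sph 30 --pil 300 --refractory 30 --out report.json
preictal verify-hw           # exhaustive arithmetic oracles
preictal arch "1x8f8p1x8|1x8f8p1x8|1x1f8p1x1|2x1f8p2x1|1x1f4p1x1"
```

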