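"""The standard synthetic benchmark: 6 seizures, gain 2, seeded.

A single scaled-down configuration shared by the examples, the test suite
and the reproduction script, so every entry point measures the same study
conditions: 4 channels at 64 Hz, six seizures 900 s apart, a 10 Hz preictal
signature of amplitude 2 over unit-variance AR(2) background, and a
proportionally scaled SPH/PIL of 30 s / 300 s with 30 s windows (5 s
preictal overlap).  The cascade refractory equals the SPH.
"""

from __future__ import annotations

from preictal.cascade import CascadeConfig
from preictal.synth import Recording, SynthConfig, gen_recording
from preictal.windowing import WindowingConfig

__all__ = [
    "benchmark_synth_config",
    "benchmark_windowing",
    "benchmark_cascade_config",
    "benchmark_recording",
]

N_SEIZURES = 6
_ONSET0, _SPACING = 700.0, 900.0


def benchmark_synth_config(seed: int = 0, signature_gain: float = 2.0) -> SynthConfig:
    onsets = tuple(_ONSET0 + i * _SPACING for i in range(N_SEIZURES))
    return SynthConfig(
        n_channels=4,
        fs=64.0,
        duration_s=onsets[-1] + 600.0,
        seizure_onsets_s=onsets,
        preictal_len_s=330.0,  # covers PIL + SPH so the signature spans both
        signature_gain=signature_gain,
        signature_freq_hz=10.0,
        noise_sd=1.0,
        seed=seed,
    )


def benchmark_windowing() -> WindowingConfig:
    return WindowingConfig(
        sph_s=30.0, pil_s=300.0, window_len_s=30.0, preictal_overlap_s=5.0
    )


def benchmark_cascade_config() -> CascadeConfig:
    return CascadeConfig(gate_threshold=1, refractory_s=30.0)


def benchmark_recording(seed: int = 0, signature_gain: float = 2.0) -> Recording:
    return gen_recording(benchmark_synth_config(seed, signature_gain))
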