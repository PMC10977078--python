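"""Seeded synthetic multichannel recordings with annotated seizures.

The generator emulates the regimes of scalp/intracranial seizure datasets
(tens of channels at a few hundred Hz) at a configurable scale:

* interictal background: stationary order-2 autoregressive noise per channel,
  independent channels — cheap and spectrally coloured like EEG background;
* preictal signature: an additive band-limited sinusoid with per-channel
  phase jitter in the ``preictal_len_s`` seconds before each annotated onset,
  amplitude ``signature_gain`` — a spectral biomarker a small CNN can learn;
* ictal activity: a fixed 60 s high-amplitude low-frequency burst (ictal
  windows are excluded from training, so its shape is immaterial).

Recordings round-trip through one binary array container (.npz holding the
signal matrix and sampling rate) plus a delimited annotation sidecar
(``onset_s,end_s`` CSV).  An optional EDF reader (via mne) and a minimal
16-bit EDF writer support interchange with real-data tooling.
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "SynthConfig",
    "Recording",
    "gen_recording",
    "write_recording",
    "read_recording",
    "write_edf",
    "read_edf",
    "band_power",
]

ICTAL_LEN_S = 60.0
_AR_COEFFS = (0.5, 0.2)  # stationary: roots of 1 − 0.5z − 0.2z² outside unit circle
_BURN_IN = 500


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; see module docstring for the signal model."""

    n_channels: int = 4
    fs: float = 64.0
    duration_s: float = 600.0
    seizure_onsets_s: tuple = ()
    preictal_len_s: float = 120.0
    signature_gain: float = 2.0
    signature_freq_hz: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signature_gain < 0:
            raise ValueError("signature_gain must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        onsets = tuple(float(o) for o in self.seizure_onsets_s)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("seizure onsets must be strictly increasing")
        for o in onsets:
            if o <= self.preictal_len_s:
                raise ValueError(
                    f"onset {o} s closer to recording start than the "
                    f"preictal length {self.preictal_len_s} s"
                )
            if o >= self.duration_s:
                raise ValueError(f"onset {o} s beyond recording end")
        object.__setattr__(self, "seizure_onsets_s", onsets)


@dataclass
class Recording:
    """Multichannel signal (channels × samples), sampling rate, annotations."""

    signal: np.ndarray
    fs: float
    annotations: list = field(default_factory=list)  # [(onset_s, end_s), ...]

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels × samples")
        dur = self.duration_s
        prev_end = -np.inf
        for onset, end in self.annotations:
            if end < onset:
                raise ValueError(f"annotation end_s {end} < onset_s {onset}")
            if onset < 0 or end > dur + 1e-9:
                raise ValueError(f"annotation ({onset}, {end}) outside [0, {dur}]")
            if onset < prev_end:
                raise ValueError("annotations overlap")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs


def gen_recording(config: SynthConfig) -> Recording:
    """Generate a recording; deterministic for a fixed config (incl. seed)."""
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    a1, a2 = _AR_COEFFS
    eps = rng.normal(0.0, config.noise_sd, size=(config.n_channels, n + _BURN_IN))
    sig = sp_signal.lfilter([1.0], [1.0, -a1, -a2], eps, axis=1)[:, _BURN_IN:]

    t = np.arange(n) / config.fs
    annotations = []
    for onset in config.seizure_onsets_s:
        end = min(onset + ICTAL_LEN_S, config.duration_s)
        annotations.append((float(onset), float(end)))
        # preictal signature: band-limited sinusoid, jittered phase per channel
        pre_mask = (t >= onset - config.preictal_len_s) & (t < onset)
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
        for c in range(config.n_channels):
            sig[c, pre_mask] += config.signature_gain * np.sin(
                2 * np.pi * config.signature_freq_hz * t[pre_mask] + phases[c]
            )
        # ictal burst: large-amplitude slow oscillation (excluded from training)
        ict_mask = (t >= onset) & (t < end)
        for c in range(config.n_channels):
            sig[c, ict_mask] += 3.0 * max(config.noise_sd, 1.0) * np.sin(
                2 * np.pi * 4.0 * t[ict_mask] + phases[c]
            )
    return Recording(signal=sig, fs=float(config.fs), annotations=annotations)


# ---------------------------------------------------------------------------
# container I/O: .npz array file + CSV annotation sidecar
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(".annotations.csv")


def write_recording(rec: Recording, path) -> None:
    """Write ``<path>.npz`` (signal + fs) and ``<path>.annotations.csv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), signal=rec.signal, fs=np.float64(rec.fs))
    with open(_sidecar(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "end_s"])
        for onset, end in rec.annotations:
            w.writerow([repr(float(onset)), repr(float(end))])


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`; validates fields."""
    path = Path(path)
    npz = np.load(path.with_suffix(".npz"))
    if "signal" not in npz or "fs" not in npz:
        missing = {"signal", "fs"} - set(npz.files)
        raise ValueError(f"array container missing field(s): {sorted(missing)}")
    annotations = []
    with open(_sidecar(path), newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["onset_s", "end_s"]:
            raise ValueError(
                f"annotation sidecar header must be onset_s,end_s; "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader):
            try:
                onset, end = float(row["onset_s"]), float(row["end_s"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"unparseable annotation row {i}: {row}") from exc
            if end < onset:
                raise ValueError(f"annotation row {i}: end_s {end} < onset_s {onset}")
            annotations.append((onset, end))
    return Recording(
        signal=np.asarray(npz["signal"], dtype=np.float64),
        fs=float(npz["fs"]),
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# EDF interchange
# ---------------------------------------------------------------------------

def write_edf(rec: Recording, path) -> None:
    """Minimal 16-bit EDF writer (1 s data records; fs must be an integer).

    Physical values are linearly mapped onto the signed 16-bit digital range,
    so the round trip is accurate to the 16-bit quantization step.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    nch = rec.n_channels
    data = rec.signal[:, : n_rec * fs]
    pmin = float(np.floor(data.min() - 1))
    pmax = float(np.ceil(data.max() + 1))
    dmin, dmax = -32768, 32767

    def pad(s, n):
        b = str(s).encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic", 80),
            pad("preictal-synth", 80),
            pad("01.01.01", 8),
            pad("00.00.00", 8),
            pad(256 * (nch + 1), 8),
            pad("", 44),
            pad(n_rec, 8),
            pad(1, 8),
            pad(nch, 4),
        ]
    )
    fields = [
        ("label", 16, [f"EEG ch{c}" for c in range(nch)]),
        ("transducer", 80, [""] * nch),
        ("dim", 8, ["uV"] * nch),
        ("pmin", 8, [f"{pmin:g}"] * nch),
        ("pmax", 8, [f"{pmax:g}"] * nch),
        ("dmin", 8, [str(dmin)] * nch),
        ("dmax", 8, [str(dmax)] * nch),
        ("prefilter", 80, [""] * nch),
        ("spr", 8, [str(fs)] * nch),
        ("reserved", 32, [""] * nch),
    ]
    sig_hdr = b"".join(
        b"".join(pad(v, width) for v in values) for _name, width, values in fields
    )
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((data - pmin) * scale + dmin).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_rec):
            for c in range(nch):
                fh.write(struct.pack(f"<{fs}h", *dig[c, r * fs : (r + 1) * fs]))


def read_edf(path, annotations=None) -> Recording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # mne loads EEG in volts; container uses µV
    return Recording(
        signal=sig, fs=float(raw.info["sfreq"]), annotations=list(annotations or [])
    )


def band_power(
    x: np.ndarray, fs: float, f0: float, half_bw: float = 2.0
) -> float:
    """Mean power spectral density mass in [f0 − half_bw, f0 + half_bw].

    For an additive sinusoid of amplitude A the band captures its analytic
    power A²/2 (per channel) on top of the background.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    nper = min(x.shape[1], int(4 * fs))
    f, pxx = sp_signal.welch(x, fs=fs, nperseg=nper, axis=1)
    mask = (f >= f0 - half_bw) & (f <= f0 + half_bw)
    df = f[1] - f[0]
    return float(pxx[:, mask].sum(axis=1).mean() * df)
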