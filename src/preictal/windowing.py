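"""Preictal/interictal window extraction under the SPH/PIL scheme.

For each seizure onset ``o`` the preictal interval is
``[o − SPH − PIL, o − SPH)`` — SPH (seizure prediction horizon) is the gap
between the scored preictal state and the onset, PIL (preictal interval
length) its duration.  The SPH gap ``[o − SPH, o)`` and the ictal interval
are excluded from both classes; everything else is interictal.  Preictal
intervals are clipped at the recording start and at the previous seizure's
ictal end.  All coordinates are seconds, intervals half-open.

Preictal windows are extracted with overlap (stride = window − overlap) to
oversample the minority class; interictal windows without overlap.
Per-seizure leave-one-out splits hold out each seizure's preictal windows
together with a matched contiguous span of interictal windows, with a strict
no-leakage guarantee on (recording, time) origins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from preictal.synth import Recording

__all__ = [
    "WindowingConfig",
    "LabeledInterval",
    "WindowDataset",
    "label_intervals",
    "label_intervals_from",
    "extract_windows",
    "count_windows",
    "loocv_splits",
    "balance_dataset",
]

INTERICTAL, PREICTAL = 0, 1


@dataclass(frozen=True)
class WindowingConfig:
    """SPH/PIL parameters and window geometry (all seconds)."""

    sph_s: float = 300.0
    pil_s: float = 1800.0
    window_len_s: float = 30.0
    preictal_overlap_s: float = 5.0

    def __post_init__(self):
        if self.sph_s < 0:
            raise ValueError("sph_s must be >= 0")
        if self.pil_s <= 0:
            raise ValueError("pil_s must be > 0")
        if not 0 <= self.preictal_overlap_s < self.window_len_s:
            raise ValueError("need 0 <= preictal_overlap_s < window_len_s")


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open [start_s, end_s) with a class label and seizure provenance."""

    start_s: float
    end_s: float
    label: int                  # INTERICTAL or PREICTAL
    seizure_index: int | None   # the seizure this preictal interval precedes


@dataclass
class WindowDataset:
    """Labeled windows with full provenance.

    ``origin`` rows are (recording_id, start_s, seizure_index-or-−1) —
    enough to audit train/validation disjointness in (recording, time).
    """

    windows: np.ndarray                  # (n, channels, samples)
    labels: np.ndarray                   # (n,) in {0, 1}
    origin: list = field(default_factory=list)
    fs: float = 0.0
    window_len_s: float = 0.0

    def __post_init__(self):
        if len(self.windows) != len(self.labels) or len(self.windows) != len(
            self.origin
        ):
            raise ValueError("windows / labels / origin length mismatch")

    def __len__(self):
        return len(self.windows)

    def subset(self, idx) -> "WindowDataset":
        idx = np.asarray(idx)
        return WindowDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            origin=[self.origin[i] for i in idx],
            fs=self.fs,
            window_len_s=self.window_len_s,
        )

    @staticmethod
    def concat(parts) -> "WindowDataset":
        parts = [p for p in parts if len(p)]
        return WindowDataset(
            windows=np.concatenate([p.windows for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            origin=[o for p in parts for o in p.origin],
            fs=parts[0].fs,
            window_len_s=parts[0].window_len_s,
        )


def label_intervals(rec: Recording, cfg: WindowingConfig) -> list:
    """Partition a recording into preictal and interictal intervals.

    Excluded time (ictal and the SPH gap) appears in neither class.  An
    empty annotation list yields a single interictal interval covering the
    whole recording.
    """
    return label_intervals_from(rec.annotations, rec.duration_s, cfg)


def label_intervals_from(annotations, duration: float, cfg: WindowingConfig) -> list:
    """Interval labeling from raw (onset_s, end_s) annotations."""
    excluded = []   # ictal ∪ SPH gap, to subtract from interictal
    preictal = []
    prev_ictal_end = 0.0
    for si, (onset, ict_end) in enumerate(sorted(annotations)):
        p_start = max(onset - cfg.sph_s - cfg.pil_s, 0.0, prev_ictal_end)
        p_end = max(onset - cfg.sph_s, p_start)
        if p_end > p_start:
            preictal.append(LabeledInterval(p_start, p_end, PREICTAL, si))
        excluded.append((max(onset - cfg.sph_s, 0.0), min(ict_end, duration)))
        prev_ictal_end = ict_end

    blocked = sorted(
        [(iv.start_s, iv.end_s) for iv in preictal] + excluded
    )
    interictal = []
    cursor = 0.0
    for s, e in blocked:
        if s > cursor:
            interictal.append(LabeledInterval(cursor, s, INTERICTAL, None))
        cursor = max(cursor, e)
    if cursor < duration:
        interictal.append(LabeledInterval(cursor, duration, INTERICTAL, None))
    return sorted(preictal + interictal, key=lambda iv: iv.start_s)


def extract_windows(
    rec: Recording,
    intervals,
    cfg: WindowingConfig,
    recording_id: int = 0,
) -> WindowDataset:
    """Slice labeled intervals into fixed-length windows.

    Preictal stride = window − overlap; interictal stride = window.  Windows
    lie entirely inside their interval; intervals shorter than a window yield
    zero windows.  Per-window sample count is round(window_len_s × fs).
    """
    n_samp = int(round(cfg.window_len_s * rec.fs))
    windows, labels, origin = [], [], []
    for iv in intervals:
        stride = (
            cfg.window_len_s - cfg.preictal_overlap_s
            if iv.label == PREICTAL
            else cfg.window_len_s
        )
        start = iv.start_s
        while start + cfg.window_len_s <= iv.end_s + 1e-9:
            i0 = int(round(start * rec.fs))
            if i0 + n_samp > rec.n_samples:
                break
            windows.append(rec.signal[:, i0 : i0 + n_samp])
            labels.append(iv.label)
            origin.append(
                (recording_id, float(start),
                 -1 if iv.seizure_index is None else iv.seizure_index)
            )
            start += stride
    return WindowDataset(
        windows=np.array(windows) if windows else np.zeros((0, rec.n_channels, n_samp)),
        labels=np.array(labels, dtype=np.int64),
        origin=origin,
        fs=rec.fs,
        window_len_s=cfg.window_len_s,
    )


def count_windows(interval_len_s: float, window_len_s: float, stride_s: float) -> int:
    """Closed-form window count: floor((L − w)/stride) + 1 (0 if L < w)."""
    if interval_len_s < window_len_s:
        return 0
    return int(np.floor((interval_len_s - window_len_s) / stride_s + 1e-9)) + 1


def balance_dataset(ds: WindowDataset, seed: int = 0) -> WindowDataset:
    """Subsample the majority class to a 1:1 ratio (seeded, deterministic)."""
    rng = np.random.default_rng(seed)
    idx_pre = np.flatnonzero(ds.labels == PREICTAL)
    idx_int = np.flatnonzero(ds.labels == INTERICTAL)
    n = min(len(idx_pre), len(idx_int))
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(idx_pre, size=n, replace=False),
                rng.choice(idx_int, size=n, replace=False),
            ]
        )
    )
    return ds.subset(keep)


def loocv_splits(ds: WindowDataset, balance_train: bool = True, seed: int = 0):
    """Per-seizure leave-one-out splits.

    Validation side = all preictal windows of the held-out seizure plus a
    matched contiguous interictal span (the interictal windows are ordered by
    time and divided into as many contiguous chunks as there are seizures).
    Training side = everything else, optionally balanced 1:1.  No (recording,
    time) origin appears on both sides.
    """
    seizures = sorted({o[2] for o in ds.origin if o[2] >= 0})
    if len(seizures) < 2:
        raise ValueError(
            f"leave-one-out needs >= 2 seizures, found {len(seizures)}"
        )
    idx_int = [i for i in range(len(ds)) if ds.labels[i] == INTERICTAL]
    idx_int.sort(key=lambda i: (ds.origin[i][0], ds.origin[i][1]))
    chunks = np.array_split(np.array(idx_int), len(seizures))

    splits = []
    for k, sz in enumerate(seizures):
        val_idx = sorted(
            [i for i in range(len(ds)) if ds.origin[i][2] == sz]
            + list(chunks[k])
        )
        val_set = set(val_idx)
        train_idx = [i for i in range(len(ds)) if i not in val_set]
        train = ds.subset(train_idx)
        if balance_train:
            train = balance_dataset(train, seed=seed + k)
        splits.append((train, ds.subset(val_idx)))
    return splits
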