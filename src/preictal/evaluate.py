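"""Seizure-prediction scoring and leave-one-out orchestration.

A seizure counts as predicted iff some confirmed alarm falls inside its
preictal interval [onset − SPH − PIL, onset − SPH).  The false-alarm rate is
the number of confirmed alarms during interictal time divided by the
interictal hours; alarms inside the SPH gap or an ictal interval count as
neither a hit nor a false alarm (excluded time).  Multiple alarms in one
preictal interval count once for sensitivity; every interictal alarm counts
toward the FAR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from preictal.cascade import (
    AlwaysPositiveVerifier,
    CascadeConfig,
    dataset_stream,
    run_cascade,
)
from preictal.windowing import (
    INTERICTAL,
    PREICTAL,
    WindowDataset,
    WindowingConfig,
    label_intervals,
    label_intervals_from,
    extract_windows,
    loocv_splits,
)

__all__ = ["EvalReport", "SplitResult", "score_alarms", "run_loocv"]


@dataclass
class SplitResult:
    seizure_index: int
    hit: bool
    n_false_alarms: int
    interictal_hours: float
    duty_cycle: float
    gate_hit: bool = False
    gate_false_alarms: int = 0
    failed: bool = False


@dataclass
class EvalReport:
    """Aggregate scoring of a cascade run or a full LOOCV experiment."""

    sensitivity: float | None
    far_per_h: float | None
    n_seizures: int = 0
    n_hits: int = 0
    n_false_alarms: int = 0
    interictal_hours: float = 0.0
    duty_cycle: float | None = None
    gate_sensitivity: float | None = None
    gate_far_per_h: float | None = None
    model_size_bytes: dict = field(default_factory=dict)
    per_split: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    partial_coverage: bool = False

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["per_split"] = [dict(s.__dict__) for s in self.per_split]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "EvalReport":
        d = json.loads(s)
        d["per_split"] = [SplitResult(**r) for r in d["per_split"]]
        return cls(**d)

    def summary_rows(self) -> list:
        """CSV-style rows: model, sensitivity (%), FAR (1/h), size (bytes)."""
        rows = []
        for name, size in (self.model_size_bytes or {"cascade": None}).items():
            rows.append(
                {
                    "model": name,
                    "sensitivity_pct": None
                    if self.sensitivity is None
                    else 100.0 * self.sensitivity,
                    "far_per_h": self.far_per_h,
                    "model_size_bytes": size,
                }
            )
        return rows


def _preictal_interval(onset, prev_ictal_end, cfg: WindowingConfig):
    start = max(onset - cfg.sph_s - cfg.pil_s, 0.0, prev_ictal_end)
    end = max(onset - cfg.sph_s, start)
    return start, end


def score_alarms(
    trace,
    annotations,
    cfg: WindowingConfig,
    duration_s: float,
    interictal_hours: float | None = None,
) -> EvalReport:
    """Score a cascade trace against seizure annotations.

    ``interictal_hours`` overrides the denominator when the trace covers only
    a subset of the recording (e.g. a held-out validation span); by default
    it is the total interictal time of the recording under ``cfg``.  With
    zero interictal time the FAR is undefined and reported as None.
    """
    alarms = sorted(float(t) for t in trace.confirmed_alarms)
    if alarms and duration_s < max(alarms):
        raise ValueError("duration_s does not cover all alarm times")
    annotations = sorted(annotations)

    hits = 0
    prev_end = 0.0
    pre_ivs = []
    for onset, end in annotations:
        ps, pe = _preictal_interval(onset, prev_end, cfg)
        pre_ivs.append((ps, pe))
        if any(ps <= t < pe for t in alarms):
            hits += 1
        prev_end = end

    intervals = label_intervals_from(annotations, duration_s, cfg)
    inter_ivs = [
        (iv.start_s, iv.end_s) for iv in intervals if iv.label == INTERICTAL
    ]
    n_fa = sum(
        1 for t in alarms if any(s <= t < e for s, e in inter_ivs)
    )
    if interictal_hours is None:
        interictal_hours = sum(e - s for s, e in inter_ivs) / 3600.0

    n_seiz = len(annotations)
    return EvalReport(
        sensitivity=None if n_seiz == 0 else hits / n_seiz,
        far_per_h=None if interictal_hours <= 0 else n_fa / interictal_hours,
        n_seizures=n_seiz,
        n_hits=hits,
        n_false_alarms=n_fa,
        interictal_hours=float(interictal_hours),
        duty_cycle=trace.duty_cycle,
    )


def _score_split(trace, onset_end, cfg, val_ds) -> tuple[bool, int, float]:
    """Hit / false-alarm / interictal-hour accounting for one held-out split."""
    onset, _end = onset_end
    ps, pe = _preictal_interval(onset, 0.0, cfg)
    hit = any(ps <= t < pe for t in trace.confirmed_alarms)
    n_fa = sum(1 for t in trace.confirmed_alarms if not (ps <= t < pe))
    inter_h = (
        int(np.sum(val_ds.labels == INTERICTAL)) * cfg.window_len_s / 3600.0
    )
    return hit, n_fa, inter_h


def run_loocv(
    recordings,
    windowing: WindowingConfig | None = None,
    cascade_cfg: CascadeConfig | None = None,
    bnn_arch=None,
    cnn_arch=None,
    bnn_epochs: int = 20,
    cnn_epochs: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Per-seizure leave-one-out evaluation of the full two-stage pipeline.

    For every held-out seizure a fresh BNN gate and 8-bit CNN verifier are
    trained on the remaining windows; the cascade then streams the held-out
    preictal windows plus a matched interictal span, and alarms are scored
    against the held-out onset.  The aggregate report pools sensitivity over
    seizures and time-weights the FAR; gate-only metrics come from the same
    stream with the degenerate always-positive verifier.
    """
    from preictal.estimators import QuantizedCNNClassifier

    windowing = windowing or WindowingConfig()
    cascade_cfg = cascade_cfg or CascadeConfig()

    datasets, onset_lookup = [], {}
    seiz_offset = 0
    for rid, rec in enumerate(recordings):
        intervals = label_intervals(rec, windowing)
        ds = extract_windows(rec, intervals, windowing, recording_id=rid)
        # re-key seizure indices globally across recordings
        ds.origin = [
            (o[0], o[1], -1 if o[2] < 0 else o[2] + seiz_offset) for o in ds.origin
        ]
        for si, ann in enumerate(sorted(rec.annotations)):
            onset_lookup[si + seiz_offset] = (rid, ann)
        seiz_offset += len(rec.annotations)
        datasets.append(ds)
    full = WindowDataset.concat(datasets)

    splits = loocv_splits(full, balance_train=True, seed=seed)
    seizures = sorted({o[2] for o in full.origin if o[2] >= 0})

    per_split = []
    sizes = {}
    total_hits = gate_hits = 0
    total_fa = gate_fa = 0
    total_inter_h = 0.0
    duty = []
    any_failed = False

    for k, ((train, val), sz) in enumerate(zip(splits, seizures)):
        _rid, onset_end = onset_lookup[sz]
        try:
            bnn = QuantizedCNNClassifier(
                arch=bnn_arch, bits=1, binary=True,
                epochs=bnn_epochs, random_state=seed * 1000 + 2 * k,
            ).fit(train.windows, train.labels)
            cnn = QuantizedCNNClassifier(
                arch=cnn_arch, bits=8,
                epochs=cnn_epochs, random_state=seed * 1000 + 2 * k + 1,
            ).fit(train.windows, train.labels)
        except FloatingPointError:
            any_failed = True
            per_split.append(
                SplitResult(sz, False, 0, 0.0, 0.0, failed=True)
            )
            continue
        if not sizes:
            sizes = {
                "bnn_1bit": bnn.model_size_bytes(),
                "cnn_8bit": cnn.model_size_bytes(),
                "cnn_float64_shadow": cnn.float_shadow_size_bytes(),
            }

        stream = list(dataset_stream(val))
        trace = run_cascade(bnn, cnn, stream, cascade_cfg)
        gate_trace = run_cascade(bnn, AlwaysPositiveVerifier(), stream, cascade_cfg)

        hit, n_fa, inter_h = _score_split(trace, onset_end, windowing, val)
        g_hit, g_fa, _ = _score_split(gate_trace, onset_end, windowing, val)
        per_split.append(
            SplitResult(
                seizure_index=int(sz),
                hit=bool(hit),
                n_false_alarms=int(n_fa),
                interictal_hours=float(inter_h),
                duty_cycle=float(trace.duty_cycle),
                gate_hit=bool(g_hit),
                gate_false_alarms=int(g_fa),
            )
        )
        total_hits += hit
        gate_hits += g_hit
        total_fa += n_fa
        gate_fa += g_fa
        total_inter_h += inter_h
        duty.append(trace.duty_cycle)

    n_scored = len(seizures)
    report = EvalReport(
        sensitivity=total_hits / n_scored if n_scored else None,
        far_per_h=total_fa / total_inter_h if total_inter_h > 0 else None,
        n_seizures=n_scored,
        n_hits=int(total_hits),
        n_false_alarms=int(total_fa),
        interictal_hours=float(total_inter_h),
        duty_cycle=float(np.mean(duty)) if duty else None,
        gate_sensitivity=gate_hits / n_scored if n_scored else None,
        gate_far_per_h=gate_fa / total_inter_h if total_inter_h > 0 else None,
        model_size_bytes=sizes,
        per_split=per_split,
        provenance={
            "seed": int(seed),
            "windowing": dict(
                sph_s=windowing.sph_s,
                pil_s=windowing.pil_s,
                window_len_s=windowing.window_len_s,
                preictal_overlap_s=windowing.preictal_overlap_s,
            ),
            "cascade": dict(
                gate_threshold=cascade_cfg.gate_threshold,
                refractory_s=cascade_cfg.refractory_s,
            ),
            "bnn_epochs": bnn_epochs,
            "cnn_epochs": cnn_epochs,
        },
        partial_coverage=any_failed,
    )
    return report
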