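"""SPH/PIL interval algebra, window extraction, leave-one-out splits."""

import numpy as np
import pytest

from preictal.synth import Recording, SynthConfig, gen_recording
from preictal.windowing import (
    INTERICTAL,
    PREICTAL,
    WindowingConfig,
    balance_dataset,
    count_windows,
    extract_windows,
    label_intervals,
    label_intervals_from,
    loocv_splits,
)


def _rec(duration, annotations, fs=64.0, n_ch=2):
    sig = np.zeros((n_ch, int(duration * fs)))
    return Recording(signal=sig, fs=fs, annotations=annotations)


class TestLabelIntervals:
    def test_direct_arithmetic(self):
        cfg = WindowingConfig(sph_s=300, pil_s=1800)
        ivs = label_intervals(_rec(4000, [(3600.0, 3660.0)]), cfg)
        pre = [iv for iv in ivs if iv.label == PREICTAL]
        assert len(pre) == 1
        assert (pre[0].start_s, pre[0].end_s) == (1500.0, 3300.0)

    def test_no_seizures_single_interictal(self):
        ivs = label_intervals(_rec(600, []), WindowingConfig())
        assert len(ivs) == 1
        assert (ivs[0].start_s, ivs[0].end_s, ivs[0].label) == (0.0, 600.0, INTERICTAL)

    def test_previous_ictal_clips_next_preictal(self):
        # onsets 1000 s apart, sph+pil = 2100 > 1000: the first seizure's
        # ictal end (1060) clips the second preictal interval's start
        cfg = WindowingConfig(sph_s=300, pil_s=1800)
        ivs = label_intervals(_rec(3000, [(1000.0, 1060.0), (2000.0, 2060.0)]), cfg)
        pre = [iv for iv in ivs if iv.label == PREICTAL]
        assert (pre[1].start_s, pre[1].end_s) == (1060.0, 1700.0)

    def test_interval_algebra_oracle(self):
        """Second-resolution enumeration oracle over random annotation sets."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            duration = 3000
            n = int(rng.integers(1, 4))
            onsets = np.sort(rng.choice(np.arange(400, duration - 100, 10), n, False))
            anns = [(float(o), float(min(o + 60, duration))) for o in onsets]
            sph, pil = float(rng.integers(0, 120)), float(rng.integers(100, 900))
            cfg = WindowingConfig(sph_s=sph, pil_s=pil)
            ivs = label_intervals_from(anns, duration, cfg)

            # oracle: classify every second independently
            labels = np.full(duration, INTERICTAL)
            prev_end = 0.0
            for onset, end in anns:
                ps = max(onset - sph - pil, 0.0, prev_end)
                pe = max(onset - sph, ps)
                labels[int(ps) : int(pe)] = PREICTAL
                labels[int(max(onset - sph, 0)) : int(end)] = -1  # excluded
                prev_end = end
            got = np.full(duration, -1)
            for iv in ivs:
                got[int(iv.start_s) : int(iv.end_s)] = iv.label
            assert np.array_equal(got, labels)


class TestExtraction:
    def test_preictal_overlap_count(self):
        # 1800 s interval, 30 s windows, 5 s overlap -> floor(1770/25)+1 = 71
        cfg = WindowingConfig(sph_s=0, pil_s=1800, window_len_s=30,
                              preictal_overlap_s=5)
        rec = _rec(2000, [(1800.0, 1860.0)])
        ds = extract_windows(rec, label_intervals(rec, cfg), cfg)
        assert int(np.sum(ds.labels == PREICTAL)) == 71

    def test_interictal_no_overlap_count(self):
        cfg = WindowingConfig(window_len_s=30)
        rec = _rec(300, [])
        ds = extract_windows(rec, label_intervals(rec, cfg), cfg)
        assert len(ds) == 10
        assert np.all(ds.labels == INTERICTAL)

    def test_short_interval_yields_zero_windows(self):
        cfg = WindowingConfig(window_len_s=30)
        rec = _rec(20, [])
        ds = extract_windows(rec, label_intervals(rec, cfg), cfg)
        assert len(ds) == 0

    def test_window_sample_count(self):
        cfg = WindowingConfig(window_len_s=12.5)
        rec = _rec(100, [], fs=64.0)
        ds = extract_windows(rec, label_intervals(rec, cfg), cfg)
        assert ds.windows.shape[2] == round(12.5 * 64)

    def test_count_matches_enumeration_oracle(self):
        """Closed-form placement count vs explicit enumeration, 50 triples."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            L = float(rng.integers(5, 2000))
            w = float(rng.integers(5, 60))
            stride = float(rng.integers(1, int(w) + 1))
            # oracle: walk the placements
            n, start = 0, 0.0
            while start + w <= L + 1e-9:
                n += 1
                start += stride
            assert count_windows(L, w, stride) == n

    def test_windows_lie_inside_their_interval(self):
        cfg = WindowingConfig(sph_s=30, pil_s=300, window_len_s=30,
                              preictal_overlap_s=5)
        rec = gen_recording(
            SynthConfig(duration_s=1500, seizure_onsets_s=(800.0,),
                        preictal_len_s=330, seed=0)
        )
        ivs = label_intervals(rec, cfg)
        ds = extract_windows(rec, ivs, cfg)
        for (rid, start, sz), label in zip(ds.origin, ds.labels):
            containing = [
                iv for iv in ivs
                if iv.start_s <= start and start + 30 <= iv.end_s + 1e-9
            ]
            assert any(iv.label == label for iv in containing)


@pytest.fixture(scope="module")
def dataset():
    rec = gen_recording(
        SynthConfig(
            duration_s=3000, seizure_onsets_s=(700.0, 1600.0, 2500.0),
            preictal_len_s=330, seed=2,
        )
    )
    cfg = WindowingConfig(sph_s=30, pil_s=300, window_len_s=30,
                          preictal_overlap_s=5)
    return extract_windows(rec, label_intervals(rec, cfg), cfg)


class TestLOOCV:

    def test_one_split_per_seizure(self, dataset):
        assert len(loocv_splits(dataset)) == 3

    def test_validation_preictal_partition(self, dataset):
        splits = loocv_splits(dataset, balance_train=False)
        seen = []
        for _train, val in splits:
            seen += [o for o, lbl in zip(val.origin, val.labels) if lbl == PREICTAL]
        all_pre = [o for o, lbl in zip(dataset.origin, dataset.labels)
                   if lbl == PREICTAL]
        assert sorted(seen) == sorted(all_pre)
        assert len(seen) == len(set(seen))  # each window exactly once

    def test_no_origin_leakage(self, dataset):
        for train, val in loocv_splits(dataset):
            assert not set(train.origin) & set(val.origin)

    def test_rejects_single_seizure(self, dataset):
        only = dataset.subset(
            [i for i, o in enumerate(dataset.origin) if o[2] in (-1, 0)]
        )
        with pytest.raises(ValueError, match=">= 2 seizures"):
            loocv_splits(only)

    def test_balancing_is_1_to_1_and_seeded(self, dataset):
        bal = balance_dataset(dataset, seed=0)
        assert int(np.sum(bal.labels == 0)) == int(np.sum(bal.labels == 1))
        bal2 = balance_dataset(dataset, seed=0)
        assert np.array_equal(bal.labels, bal2.labels)
        assert bal.origin == bal2.origin
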