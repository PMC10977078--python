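"""Synthetic recording generator: determinism, injected power, containers."""

import numpy as np
import pytest
from scipy import stats

from preictal.synth import (
    Recording,
    SynthConfig,
    band_power,
    gen_recording,
    read_recording,
    write_edf,
    write_recording,
)


def _segment_band_powers(rec, onsets, pre_len, fs, f0, win_s=10.0):
    """Band power of disjoint windows from preictal vs interictal time."""
    pre, inter = [], []
    n = int(win_s * fs)
    sig = rec.signal
    t_end = rec.duration_s
    pre_spans = [(o - pre_len, o) for o in onsets]
    bad_spans = pre_spans + [(o, min(o + 60.0, t_end)) for o in onsets]
    start = 0.0
    while start + win_s <= t_end:
        i0 = int(start * fs)
        seg = sig[:, i0 : i0 + n]
        if any(s <= start and start + win_s <= e for s, e in pre_spans):
            pre.append(band_power(seg, fs, f0))
        elif not any(start < e and s < start + win_s for s, e in bad_spans):
            inter.append(band_power(seg, fs, f0))
        start += win_s
    return np.array(pre), np.array(inter)


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        cfg = SynthConfig(seizure_onsets_s=(300.0,), duration_s=400.0, seed=5)
        a, b = gen_recording(cfg), gen_recording(cfg)
        assert np.array_equal(a.signal, b.signal)
        assert a.annotations == b.annotations

    def test_annotations_match_config(self):
        cfg = SynthConfig(
            duration_s=900.0, seizure_onsets_s=(300.0, 700.0), seed=1
        )
        rec = gen_recording(cfg)
        assert rec.annotations == [(300.0, 360.0), (700.0, 760.0)]
        assert rec.n_samples == round(cfg.duration_s * cfg.fs)

    def test_onset_too_close_to_start_rejected(self):
        with pytest.raises(ValueError, match="closer to recording start"):
            SynthConfig(seizure_onsets_s=(100.0,), preictal_len_s=120.0)

    def test_onsets_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SynthConfig(seizure_onsets_s=(400.0, 300.0), duration_s=600.0)

    def test_zero_gain_distributions_indistinguishable(self):
        cfg = SynthConfig(
            n_channels=2,
            fs=64.0,
            duration_s=4000.0,
            seizure_onsets_s=(1000.0, 2000.0, 3000.0),
            preictal_len_s=300.0,
            signature_gain=0.0,
            seed=3,
        )
        rec = gen_recording(cfg)
        pre, inter = _segment_band_powers(
            rec, cfg.seizure_onsets_s, 300.0, cfg.fs, cfg.signature_freq_hz
        )
        assert len(pre) > 30 and len(inter) > 30
        _u, p = stats.mannwhitneyu(pre, inter)
        assert p > 0.01  # same generating distribution: no rejection

    def test_injected_power_matches_closed_form(self):
        """Monte-Carlo band-power excess ≈ analytic sinusoid power A²/2."""
        gain = 2.0
        cfg = SynthConfig(
            n_channels=2,
            fs=64.0,
            duration_s=6000.0,
            seizure_onsets_s=tuple(range(1000, 6000, 1000)),
            preictal_len_s=400.0,
            signature_gain=gain,
            noise_sd=1.0,
            seed=7,
        )
        rec = gen_recording(cfg)
        pre, inter = _segment_band_powers(
            rec, cfg.seizure_onsets_s, 400.0, cfg.fs, cfg.signature_freq_hz
        )
        excess = pre.mean() - inter.mean()
        analytic = gain**2 / 2.0
        assert abs(excess - analytic) < 0.3 * analytic

    def test_separability_nondecreasing_in_gain(self):
        """A fixed band-power classifier improves monotonically with gain."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        accs = []
        for gain in (0.0, 1.0, 3.0):
            cfg = SynthConfig(
                n_channels=2,
                fs=64.0,
                duration_s=7000.0,
                seizure_onsets_s=tuple(range(1000, 7000, 1000)),
                preictal_len_s=450.0,
                signature_gain=gain,
                seed=17,
            )
            rec = gen_recording(cfg)
            pre, inter = _segment_band_powers(
                rec, cfg.seizure_onsets_s, 450.0, cfg.fs, cfg.signature_freq_hz
            )
            n = min(100, len(pre), len(inter))
            X = np.concatenate([pre[:n], inter[:n]])[:, None]
            y = np.r_[np.ones(n), np.zeros(n)]
            accs.append(
                cross_val_score(LogisticRegression(), X, y, cv=4).mean()
            )
        assert accs[0] <= accs[1] + 0.05  # chance level up to CV noise
        assert accs[0] <= accs[2] and accs[1] <= accs[2]
        assert accs[2] > 0.9


class TestContainers:
    def test_roundtrip_lossless(self, tmp_path):
        rec = gen_recording(
            SynthConfig(duration_s=300.0, seizure_onsets_s=(200.0,), seed=2)
        )
        write_recording(rec, tmp_path / "rec")
        back = read_recording(tmp_path / "rec")
        assert np.array_equal(back.signal, rec.signal)
        assert back.fs == rec.fs
        assert back.annotations == rec.annotations

    def test_sidecar_end_before_onset_rejected(self, tmp_path):
        rec = gen_recording(SynthConfig(duration_s=120.0, seed=0))
        write_recording(rec, tmp_path / "rec")
        (tmp_path / "rec.annotations.csv").write_text(
            "onset_s,end_s\n100.0,40.0\n"
        )
        with pytest.raises(ValueError, match="end_s"):
            read_recording(tmp_path / "rec")

    def test_malformed_header_names_field(self, tmp_path):
        rec = gen_recording(SynthConfig(duration_s=120.0, seed=0))
        write_recording(rec, tmp_path / "rec")
        (tmp_path / "rec.annotations.csv").write_text("start,stop\n1,2\n")
        with pytest.raises(ValueError, match="onset_s,end_s"):
            read_recording(tmp_path / "rec")


class TestEDF:
    def test_edf_roundtrip_shape_and_values(self, tmp_path):
        pytest.importorskip("mne")
        from preictal.synth import read_edf

        rec = gen_recording(
            SynthConfig(n_channels=23, fs=256.0, duration_s=4.0, seed=9)
        )
        path = tmp_path / "rec.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert back.signal.shape == (23, 256 * 4)
        assert back.fs == 256.0
        # 16-bit quantization: tight but not exact
        span = rec.signal.max() - rec.signal.min()
        assert np.max(np.abs(back.signal - rec.signal)) < span / 32768
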