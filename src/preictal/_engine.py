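"""Multiplier-free fixed-point inference engine.

Reproduces the decisions of a :class:`~preictal.quant.QuantizedModel`'s
reference forward pass using only the arithmetic the hardware has:

* binary convolutions → XNOR + popcount (±1 dot-product identity);
* 8-bit convolutions and all scaling → radix-4 Booth shift-add products
  (the kernel value is the stationary multiplicand; its Booth products are
  reused across the whole feature map);
* folded batch norm → Booth scaling by the 8-bit mantissa plus barrel
  shifts by the power-of-two exponents;
* activation re-quantization → integer round-half-away via add-and-shift;
* max pooling, sign, argmax → comparisons.

Because the exported model stores only integer codes and dyadic batch-norm
constants, every quantity here is an exactly scaled integer image of the
reference pass, so decisions agree bit-for-bit (ties included).  No general
multiply is ever issued: :func:`preictal.hwarith.mul_ops_count` stays 0.
"""

from __future__ import annotations

import numpy as np

from preictal.hwarith import (
    _booth_mul_stationary_x,
    booth_mul_wide,
    mul_ops_count,
)

__all__ = ["fixed_point_infer", "EngineCounters"]


class EngineCounters:
    """Operation tallies for one inference (power-proxy bookkeeping)."""

    def __init__(self):
        self.booth_macs = 0
        self.xnor_bits = 0
        self.general_muls_before = mul_ops_count()

    def summary(self) -> dict:
        return {
            "booth_macs": int(self.booth_macs),
            "xnor_bits": int(self.xnor_bits),
            "general_muls": int(mul_ops_count() - self.general_muls_before),
        }


def _shift_right_round_half_away(y: np.ndarray, k: int) -> np.ndarray:
    """sign(y)·((|y| + 2^(k−1)) >> k): integer round-half-away by shift-add."""
    if k <= 0:
        return np.left_shift(y, -k)
    mag = np.abs(y)
    r = np.right_shift(mag + (1 << (k - 1)), k)
    return np.where(y < 0, -r, r)


def _bn_scaled(lyr, S: np.ndarray, in_frac_bits: int):
    """Apply folded BN per filter; returns (Y, E) with y = Y·2^E exactly.

    ``S`` holds per-filter integer partial sums whose value is S·2^−in_frac_bits.
    """
    F = S.shape[0]
    Y = np.empty_like(S)
    E = np.empty(F, dtype=np.int64)
    for f in range(F):
        eg = int(lyr.bn_exp_g[f]) - in_frac_bits
        eb = int(lyr.bn_exp_b[f])
        e = min(eg, eb)
        gs = booth_mul_wide(S[f], int(lyr.bn_mant_g[f]))
        Y[f] = np.left_shift(gs, eg - e) + (int(lyr.bn_mant_b[f]) << (eb - e))
        E[f] = e
    return Y, E


def _maxpool_codes(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    f, h, w = x.shape
    h2, w2 = h // ph, w // pw
    return x[:, : h2 * ph, : w2 * pw].reshape(f, h2, ph, w2, pw).max(axis=(2, 4))


def _conv_booth(codes_in: np.ndarray, w_codes: np.ndarray, counters) -> np.ndarray:
    """8-bit integer convolution from Booth shift-add products only."""
    F, C, kh, kw = w_codes.shape
    _, H, W = codes_in.shape
    H2, W2 = H - kh + 1, W - kw + 1
    out = np.zeros((F, H2, W2), dtype=np.int64)
    for f in range(F):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    wk = int(w_codes[f, c, i, j])
                    if wk == 0:
                        continue
                    out[f] += _booth_mul_stationary_x(
                        wk, codes_in[c, i : i + H2, j : j + W2]
                    )
                    counters.booth_macs += H2 * W2
    return out


def _conv_signed_sum(codes_in: np.ndarray, w_signs: np.ndarray) -> np.ndarray:
    """Σ ±a for ±1 weights over wide inputs: pure sign-gated accumulation."""
    F, C, kh, kw = w_signs.shape
    _, H, W = codes_in.shape
    H2, W2 = H - kh + 1, W - kw + 1
    out = np.zeros((F, H2, W2), dtype=np.int64)
    for f in range(F):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    sl = codes_in[c, i : i + H2, j : j + W2]
                    if w_signs[f, c, i, j] > 0:
                        out[f] += sl
                    else:
                        out[f] -= sl
    return out


def _conv_xnor(bits_in: np.ndarray, w_signs: np.ndarray, counters) -> np.ndarray:
    """±1 × ±1 convolution as XNOR-accumulate: dot = 2·popcount(XNOR) − n.

    ``bits_in`` holds activation bits (−1→0, +1→1).  Per kernel tap the XNOR
    of the weight bit against the activation bit plane is accumulated; the
    identity 2·pop − n then recovers the integer ±1 dot product.  This is the
    vectorised form of chaining :func:`preictal.hwarith.xnor_popcount_dot`
    over output positions.
    """
    F, C, kh, kw = w_signs.shape
    _, H, W = bits_in.shape
    H2, W2 = H - kh + 1, W - kw + 1
    n = C * kh * kw
    pop = np.zeros((F, H2, W2), dtype=np.int64)
    for f in range(F):
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    wbit = 1 if w_signs[f, c, i, j] > 0 else 0
                    abits = bits_in[c, i : i + H2, j : j + W2]
                    # XNOR: equal bits contribute a 1 to the popcount
                    pop[f] += np.where(abits == wbit, 1, 0)
                    counters.xnor_bits += H2 * W2
    return np.left_shift(pop, 1) - n


def fixed_point_infer(model, window, collect_mul_count: bool = False):
    """Integer-only inference for one window.

    Returns ``(scores, decision)`` where ``scores`` are the integer
    N-scaled class scores (argmax-equivalent to the reference logits) and
    ``decision`` the argmax class index.  With ``collect_mul_count`` a third
    element, the :class:`EngineCounters` summary, is appended.
    """
    counters = EngineCounters()
    q = model.qconfig
    codes = model.input_codes(window)  # (channels, samples) int codes
    if codes.ndim != 2:
        raise ValueError(f"window must be 2-D (channels × samples), got {codes.shape}")

    binary = q.binary_mode
    frac = model.input_bits - 1  # fractional bits of the incoming codes
    x_codes = codes[None, :, :]  # feature-map axis first
    x_bits = None  # ±1 planes as 0/1 bits, binary layers only

    for li, lyr in enumerate(model.layers[:-1]):
        w = np.asarray(lyr.weight_codes, dtype=np.int64)
        if binary:
            if li == 0:
                S = _conv_signed_sum(x_codes, w)  # 8-bit input × ±1 weights
                in_frac = frac
            else:
                S = _conv_xnor(x_bits, w, counters)
                in_frac = 0
            Y, _E = _bn_scaled(lyr, S, in_frac)
            a_bits = (Y >= 0).astype(np.int64)  # sign, sign(0) = +1
            x_bits = _maxpool_codes(a_bits, *lyr.pool)  # max of ±1 ≡ max of bits
        else:
            S = _conv_booth(x_codes, w, counters)
            in_frac = frac + (model.qconfig.Q - 1)
            Y, E = _bn_scaled(lyr, S, in_frac)
            # re-quantize to Q-bit codes: round-half-away then clip
            out = np.empty_like(Y)
            half_grid = 1 << (model.qconfig.Q - 1)
            for f in range(Y.shape[0]):
                k = -(int(E[f]) + (model.qconfig.Q - 1))
                out[f] = _shift_right_round_half_away(Y[f], k)
            np.clip(out, -half_grid, half_grid - 1, out=out)
            x_codes = _maxpool_codes(out, *lyr.pool)
            frac = model.qconfig.Q - 1

    head = model.layers[-1]
    hw = np.asarray(head.weight_codes, dtype=np.int64)  # (2, F)
    if binary:
        feat = x_bits.sum(axis=(1, 2))  # popcount per map
        n_map = x_bits.shape[1] * x_bits.shape[2]
        feat = np.left_shift(feat, 1) - n_map  # Σ ±1 per feature map
        scores = np.zeros(hw.shape[0], dtype=np.int64)
        for c in range(hw.shape[0]):
            for f in range(hw.shape[1]):
                scores[c] += feat[f] if hw[c, f] > 0 else -feat[f]
    else:
        feat = x_codes.sum(axis=(1, 2))  # N·GAP in code units
        n_gap = x_codes.shape[1] * x_codes.shape[2]
        scores = np.zeros(hw.shape[0], dtype=np.int64)
        for c in range(hw.shape[0]):
            for f in range(hw.shape[1]):
                wk = int(hw[c, f])
                if wk:
                    scores[c] += int(booth_mul_wide(np.int64(feat[f]), wk))
                    counters.booth_macs += 1
            if head.bias_codes is not None:
                nb = int(booth_mul_wide(np.int64(n_gap), int(head.bias_codes[c])))
                scores[c] += nb << (model.qconfig.Q - 1)

    decision = int(np.argmax(scores))
    if collect_mul_count:
        return scores, decision, counters.summary()
    return scores, decision
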