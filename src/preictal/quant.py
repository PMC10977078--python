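"""Fixed-point quantization primitives and the exported quantized model.

Weights are quantized onto the symmetric fixed-point grid

    q = clip( round(2^(Q−1)·ω) / 2^(Q−1),  −1,  1 − 2^(−(Q−1)) )

with round-half-away-from-zero (keeps the grid symmetric about 0).
Activations pass through a quantized hard-tanh: hard clip to [−1, 1] followed
by the same grid; at Q = 1 this degenerates to the sign function (0 → +1).
During training the quantizer's backward pass is the straight-through
estimator: the gradient of Htanh(a) = clip(a, −1, 1), i.e. 1 on |a| ≤ 1 and 0
outside, regardless of Q.

The exported :class:`QuantizedModel` stores integer weight codes and folded
batch-norm parameters quantized to dyadic rationals (signed 8-bit mantissa ×
power-of-two exponent).  Its reference forward pass therefore performs only
exact dyadic arithmetic in float64, which the integer engine in
:mod:`preictal._engine` reproduces bit-for-bit with shift-add hardware
semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "QuantConfig",
    "QuantizedModel",
    "quantize_weight",
    "quantize_activation",
    "binarize",
    "ste_grad",
    "round_half_away",
    "to_dyadic",
    "qat_train",
]


def round_half_away(x):
    """Round to nearest integer, halves away from zero (sign-symmetric)."""
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_weight(w, Q: int):
    """Quantize weights onto the fixed-point grid k/2^(Q−1).

    Output lies in [−1, 1 − 2^(−(Q−1))] and is an exact grid multiple;
    the map is idempotent and non-decreasing.  Q must be ≥ 2 (1-bit weights
    go through :func:`binarize`).
    """
    if Q < 2:
        raise ValueError("quantize_weight requires Q >= 2; use binarize for 1-bit")
    w = np.asarray(w, dtype=np.float64)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weight passed to quantize_weight")
    s = float(1 << (Q - 1))
    return np.clip(round_half_away(w * s) / s, -1.0, 1.0 - 1.0 / s)


def quantize_activation(a, Q: int):
    """Quantized hard-tanh: clip to [−1, 1], then snap to the Q-bit grid.

    Q = 1 yields the sign function with the documented tie-break sign(0)=+1.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    a = np.asarray(a, dtype=np.float64)
    if Q == 1:
        return np.where(a >= 0, 1.0, -1.0)
    return quantize_weight(np.clip(a, -1.0, 1.0), Q)


def binarize(w):
    """1-bit quantization: sign with binarize(0) = +1."""
    w = np.asarray(w, dtype=np.float64)
    return np.where(w >= 0, 1.0, -1.0)


def ste_grad(a):
    """Straight-through gradient factor: dHtanh/da = 1 on |a| ≤ 1, else 0."""
    a = np.asarray(a, dtype=np.float64)
    return (np.abs(a) <= 1.0).astype(np.float64)


def to_dyadic(
    v: float, mant_bits: int = 8, exp_range: tuple[int, int] = (-24, 6)
) -> tuple[int, int]:
    """Round ``v`` to mantissa·2^exponent with a signed ``mant_bits`` mantissa.

    Returns ``(mantissa, exponent)`` with |mantissa| ≤ 2^(mant_bits−1) − 1 and
    the exponent clamped into ``exp_range``; values below the representable
    range flush to 0 and values above it saturate.  v = 0 maps to (0, 0).
    The relative rounding error inside the range is ≤ 2^−(mant_bits−1).  The
    exponent clamp bounds every barrel-shift of the fixed-point datapath so
    that all intermediate partial sums fit a 64-bit accumulator.
    """
    v = float(v)
    if not np.isfinite(v):
        raise ValueError(f"non-finite value in dyadic quantization: {v}")
    if v == 0.0:
        return 0, 0
    top = (1 << (mant_bits - 1)) - 1  # 127 for 8-bit
    e = int(np.floor(np.log2(abs(v)))) - (mant_bits - 2)
    m = int(round_half_away(v / 2.0**e))
    while abs(m) > top:
        m = int(round_half_away(m / 2.0))
        e += 1
    lo, hi = exp_range
    if e < lo:
        m = int(round_half_away(m * 2.0 ** (e - lo)))
        e = lo
    elif e > hi:
        m = top if m > 0 else -top  # saturate
        e = hi
    if m == 0:
        return 0, 0
    return m, e


@dataclass(frozen=True)
class QuantConfig:
    """Bit-width configuration for quantization-aware training.

    Q = 1 with ``binary_mode`` gives a BNN: ±1 weights everywhere, sign
    activations between blocks, and an 8-bit input path (raw signals are not
    binary), following standard binary-network practice.
    """

    Q: int = 8
    binary_mode: bool = False
    first_layer_activation_bits: int = 8

    def __post_init__(self):
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.binary_mode and self.Q != 1:
            raise ValueError("binary_mode requires Q = 1")
        if self.Q == 1 and not self.binary_mode:
            raise ValueError("Q = 1 requires binary_mode")


@dataclass
class QuantizedLayer:
    """One exported convolution (or dense) stage with folded batch norm."""

    kind: str                      # "conv" | "dense"
    weight_codes: np.ndarray       # int codes; ±1 in binary mode
    pool: tuple = (1, 1)           # (pool_h, pool_w) applied after activation
    bn_mant_g: np.ndarray | None = None
    bn_exp_g: np.ndarray | None = None
    bn_mant_b: np.ndarray | None = None
    bn_exp_b: np.ndarray | None = None
    bias_codes: np.ndarray | None = None  # dense head, 8-bit mode


@dataclass
class QuantizedModel:
    """Architecture + integer weight codes + dyadic folded batch norm.

    ``predict``/``decision_scores`` implement the reference forward pass in
    exact dyadic float64 arithmetic; :func:`preictal.hwarith.fixed_point_infer`
    reproduces its decisions with integer shift-add arithmetic only.
    """

    arch: "object"                 # ArchDescription
    qconfig: QuantConfig
    input_scale: float
    input_bits: int
    layers: list = field(default_factory=list)
    classes_: np.ndarray | None = None

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        """Check grid membership of every stored tensor."""
        for lyr in self.layers:
            codes = np.asarray(lyr.weight_codes)
            if not np.array_equal(codes, np.round(codes)):
                raise ValueError(f"non-integer weight codes in {lyr.kind}")
            if self.qconfig.binary_mode:
                if not np.all(np.isin(codes, [-1, 1])):
                    raise ValueError("binary model weights must be ±1")
            else:
                lo, hi = -(1 << (self.qconfig.Q - 1)), (1 << (self.qconfig.Q - 1)) - 1
                if codes.min() < lo or codes.max() > hi:
                    raise ValueError(f"weight codes out of Q={self.qconfig.Q} range")

    # -- helpers ------------------------------------------------------------

    def _wscale(self) -> float:
        return float(1 << (self.qconfig.Q - 1)) if not self.qconfig.binary_mode else 1.0

    def quantize_input(self, window: np.ndarray) -> np.ndarray:
        """Scale a raw window and quantize it to the input bit width."""
        x = np.asarray(window, dtype=np.float64) * self.input_scale
        return quantize_activation(x, self.input_bits)

    def input_codes(self, window: np.ndarray) -> np.ndarray:
        """Signed integer codes of the quantized input (value = code/2^(b−1))."""
        q = self.quantize_input(window)
        return np.asarray(
            round_half_away(q * (1 << (self.input_bits - 1))), dtype=np.int64
        )

    # -- reference forward pass (exact dyadic float arithmetic) -------------

    def _bn_apply(self, lyr: QuantizedLayer, s: np.ndarray) -> np.ndarray:
        g = lyr.bn_mant_g * np.exp2(lyr.bn_exp_g)
        b = lyr.bn_mant_b * np.exp2(lyr.bn_exp_b)
        return g[:, None, None] * s + b[:, None, None]

    @staticmethod
    def _maxpool(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
        f, h, w = x.shape
        h2, w2 = h // ph, w // pw
        x = x[:, : h2 * ph, : w2 * pw].reshape(f, h2, ph, w2, pw)
        return x.max(axis=(2, 4))

    @staticmethod
    def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Valid 2-D correlation, stride 1.  x: (C,H,W), w: (F,C,kh,kw)."""
        F, C, kh, kw = w.shape
        _, H, W = x.shape
        out = np.zeros((F, H - kh + 1, W - kw + 1), dtype=np.float64)
        for i in range(kh):
            for j in range(kw):
                out += np.einsum(
                    "chw,fc->fhw",
                    x[:, i : i + H - kh + 1, j : j + W - kw + 1],
                    w[:, :, i, j],
                )
        return out

    def decision_scores(self, window: np.ndarray) -> np.ndarray:
        """Scale-invariant class scores (logits × a positive constant).

        The global-average-pool division by the map size N is folded out:
        scores are N·logits, which preserves the argmax exactly and keeps
        every operation an exact dyadic computation.
        """
        x = self.quantize_input(window)[None, :, :]  # (1, channels, samples)
        ws = self._wscale()
        for lyr in self.layers[:-1]:
            w = np.asarray(lyr.weight_codes, dtype=np.float64) / ws
            s = self._conv_valid(x, w)
            y = self._bn_apply(lyr, s)
            if self.qconfig.binary_mode:
                a = np.where(y >= 0, 1.0, -1.0)
            else:
                a = quantize_activation(y, self.qconfig.Q)
            x = self._maxpool(a, *lyr.pool)
        head = self.layers[-1]
        feat_sum = x.sum(axis=(1, 2))                    # (F,), N·GAP
        n_gap = x.shape[1] * x.shape[2]
        wd = np.asarray(head.weight_codes, dtype=np.float64) / ws  # (2, F)
        scores = wd @ feat_sum
        if head.bias_codes is not None:
            scores = scores + n_gap * (
                np.asarray(head.bias_codes, dtype=np.float64) / ws
            )
        return scores

    def predict_window(self, window: np.ndarray) -> int:
        return int(np.argmax(self.decision_scores(window)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return np.array([self.predict_window(w) for w in X], dtype=np.int64)

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize as a JSON descriptor plus an .npz of integer tensors."""
        from preictal.archspace import encode_arch

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "arch": encode_arch(self.arch),
            "Q": self.qconfig.Q,
            "binary_mode": self.qconfig.binary_mode,
            "first_layer_activation_bits": self.qconfig.first_layer_activation_bits,
            "input_scale": self.input_scale,
            "input_bits": self.input_bits,
            "classes": None if self.classes_ is None else self.classes_.tolist(),
            "layers": [
                {"kind": l.kind, "pool": list(l.pool), "has_bias": l.bias_codes is not None}
                for l in self.layers
            ],
        }
        arrays = {}
        for i, l in enumerate(self.layers):
            arrays[f"w{i}"] = np.asarray(l.weight_codes, dtype=np.int64)
            if l.bn_mant_g is not None:
                arrays[f"bn{i}"] = np.stack(
                    [l.bn_mant_g, l.bn_exp_g, l.bn_mant_b, l.bn_exp_b]
                ).astype(np.int64)
            if l.bias_codes is not None:
                arrays[f"b{i}"] = np.asarray(l.bias_codes, dtype=np.int64)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        np.savez(path.with_suffix(".npz"), **arrays)

    @classmethod
    def load(cls, path) -> "QuantizedModel":
        from preictal.archspace import decode_arch_string

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        qcfg = QuantConfig(
            Q=meta["Q"],
            binary_mode=meta["binary_mode"],
            first_layer_activation_bits=meta["first_layer_activation_bits"],
        )
        layers = []
        for i, lmeta in enumerate(meta["layers"]):
            bn = arrays[f"bn{i}"] if f"bn{i}" in arrays else None
            layers.append(
                QuantizedLayer(
                    kind=lmeta["kind"],
                    weight_codes=arrays[f"w{i}"],
                    pool=tuple(lmeta["pool"]),
                    bn_mant_g=None if bn is None else bn[0],
                    bn_exp_g=None if bn is None else bn[1],
                    bn_mant_b=None if bn is None else bn[2],
                    bn_exp_b=None if bn is None else bn[3],
                    bias_codes=arrays[f"b{i}"] if lmeta["has_bias"] else None,
                )
            )
        model = cls(
            arch=decode_arch_string(meta["arch"]),
            qconfig=qcfg,
            input_scale=meta["input_scale"],
            input_bits=meta["input_bits"],
            layers=layers,
            classes_=None if meta["classes"] is None else np.asarray(meta["classes"]),
        )
        model.validate()
        return model


def qat_train(
    spec,
    X,
    y,
    qconfig: QuantConfig,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 0.01,
    batch_size: int = 32,
    X_val=None,
    y_val=None,
):
    """Quantization-aware training; thin wrapper over the estimator class.

    ``spec`` is an :class:`~preictal.archspace.ArchDescription`.  Returns the
    fitted :class:`~preictal.estimators.QuantizedCNNClassifier`, whose
    ``quantized_`` attribute is the exported :class:`QuantizedModel`.
    """
    from preictal.estimators import QuantizedCNNClassifier

    clf = QuantizedCNNClassifier(
        arch=spec,
        bits=qconfig.Q,
        binary=qconfig.binary_mode,
        epochs=epochs,
        lr=lr,
        batch_size=batch_size,
        random_state=seed,
    )
    clf.fit(X, y, X_val=X_val, y_val=y_val)
    return clf
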