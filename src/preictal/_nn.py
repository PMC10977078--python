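"""Minimal NumPy training core for the channel-wise 5-block networks.

Implements exactly the layer vocabulary of the search space — valid 2-D
convolution (stride 1), batch norm, ReLU / quantized-tanh / sign activations,
non-overlapping max pooling, global average pooling, and a softmax dense head
— with hand-written backward passes.  Quantization-aware training follows the
straight-through-estimator recipe: forward passes use quantized weights and
activations, backward passes use the hard-tanh gradient (1 on [−1, 1], 0
outside), and latent weights are clipped to [−1, 1] after each update.

The models in the search space are tiny (≤ 16 filters, 5 blocks), so plain
NumPy einsum loops are entirely adequate for training at desk scale.
"""

from __future__ import annotations

import numpy as np

from preictal.quant import (
    QuantConfig,
    QuantizedLayer,
    QuantizedModel,
    binarize,
    quantize_activation,
    quantize_weight,
    round_half_away,
    ste_grad,
    to_dyadic,
)

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class _Param:
    __slots__ = ("value", "grad", "m", "v", "clip")

    def __init__(self, value: np.ndarray, clip: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)
        self.clip = clip


class Adam:
    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.clip:
                np.clip(p.value, -1.0, 1.0, out=p.value)
            p.grad[...] = 0.0


def _effective_weight(latent: np.ndarray, wmode, shadow: bool) -> np.ndarray:
    if wmode is None:
        return latent
    if shadow:  # float shadow: clip only, no grid
        return np.clip(latent, -1.0, 1.0)
    if wmode == "bin":
        return binarize(latent)
    return quantize_weight(latent, wmode[1])  # ("grid", Q)


class Conv2D:
    """Valid 2-D correlation, stride 1, no bias (batch norm supplies shift)."""

    def __init__(self, in_f, out_f, kh, kw, wmode=None, rng=None):
        fan_in = in_f * kh * kw
        a = min(1.0, np.sqrt(6.0 / (fan_in + out_f)))
        init = rng.uniform(-a, a, size=(out_f, in_f, kh, kw))
        self.W = _Param(init, clip=wmode is not None)
        self.wmode = wmode
        self.kh, self.kw = kh, kw

    def params(self):
        return [self.W]

    def forward(self, x, training=False, shadow=False):
        W = _effective_weight(self.W.value, self.wmode, shadow)
        self._x, self._Weff = x, W
        N, C, H, Wd = x.shape
        kh, kw = self.kh, self.kw
        H2, W2 = H - kh + 1, Wd - kw + 1
        out = np.zeros((N, W.shape[0], H2, W2))
        for i in range(kh):
            for j in range(kw):
                out += np.einsum(
                    "nchw,oc->nohw", x[:, :, i : i + H2, j : j + W2], W[:, :, i, j]
                )
        return out

    def backward(self, g):
        x, W = self._x, self._Weff
        N, C, H, Wd = x.shape
        kh, kw = self.kh, self.kw
        H2, W2 = g.shape[2], g.shape[3]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for i in range(kh):
            for j in range(kw):
                xs = x[:, :, i : i + H2, j : j + W2]
                dW[:, :, i, j] = np.einsum("nohw,nchw->oc", g, xs)
                dx[:, :, i : i + H2, j : j + W2] += np.einsum(
                    "nohw,oc->nchw", g, W[:, :, i, j]
                )
        if self.wmode is not None:  # STE through the weight quantizer
            dW *= ste_grad(self.W.value)
        self.W.grad += dW
        return dx


class BatchNorm:
    def __init__(self, n_f):
        self.gamma = _Param(np.ones(n_f))
        self.beta = _Param(np.zeros(n_f))
        self.run_mean = np.zeros(n_f)
        self.run_var = np.ones(n_f)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False, shadow=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - _BN_MOMENTUM) * self.run_mean + _BN_MOMENTUM * mean
            self.run_var = (1 - _BN_MOMENTUM) * self.run_var + _BN_MOMENTUM * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, g):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += np.einsum("nfhw,nfhw->f", g, xhat)
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gx = g * self.gamma.value[None, :, None, None]
        if not self._training:
            return gx * inv[None, :, None, None]
        m = g.shape[0] * g.shape[2] * g.shape[3]
        return (
            inv[None, :, None, None]
            / m
            * (
                m * gx
                - gx.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * np.einsum("nfhw,nfhw->f", gx, xhat)[None, :, None, None]
            )
        )

    def folded(self):
        """Inference-time affine: y = g·x + b from running statistics."""
        g = self.gamma.value / np.sqrt(self.run_var + _BN_EPS)
        b = self.beta.value - self.run_mean * g
        return g, b


class Activation:
    """'relu', ('qtanh', Q), or 'sign'; quantizers backprop through Htanh."""

    def __init__(self, kind):
        self.kind = kind

    def params(self):
        return []

    def forward(self, x, training=False, shadow=False):
        self._x = x
        if self.kind == "relu":
            return np.maximum(x, 0.0)
        if shadow:  # surrogate forward: hard-tanh, no grid
            return np.clip(x, -1.0, 1.0)
        if self.kind == "sign":
            return np.where(x >= 0, 1.0, -1.0)
        return quantize_activation(x, self.kind[1])

    def backward(self, g):
        if self.kind == "relu":
            return g * (self._x > 0)
        return g * ste_grad(self._x)


class MaxPool:
    """Non-overlapping max pooling; trailing remainder rows/cols are cropped."""

    def __init__(self, ph, pw):
        self.ph, self.pw = ph, pw

    def params(self):
        return []

    def forward(self, x, training=False, shadow=False):
        ph, pw = self.ph, self.pw
        N, F, H, W = x.shape
        H2, W2 = H // ph, W // pw
        xc = x[:, :, : H2 * ph, : W2 * pw].reshape(N, F, H2, ph, W2, pw)
        out = xc.max(axis=(3, 5))
        self._shape = x.shape
        self._mask_src = xc
        self._out = out
        return out

    def backward(self, g):
        ph, pw = self.ph, self.pw
        N, F, H, W = self._shape
        H2, W2 = H // ph, W // pw
        xc = self._mask_src
        flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(N, F, H2, W2, ph * pw)
        idx = flat.argmax(axis=-1)
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dxc = dflat.reshape(N, F, H2, W2, ph, pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((N, F, H, W))
        dx[:, :, : H2 * ph, : W2 * pw] = dxc.reshape(N, F, H2 * ph, W2 * pw)
        return dx


class GlobalAvgPool:
    def params(self):
        return []

    def forward(self, x, training=False, shadow=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g):
        N, F, H, W = self._shape
        return np.broadcast_to(g[:, :, None, None] / (H * W), self._shape).copy()


class Dense:
    def __init__(self, n_in, n_out, bias=True, wmode=None, rng=None):
        a = min(1.0, np.sqrt(6.0 / (n_in + n_out)))
        self.W = _Param(rng.uniform(-a, a, size=(n_out, n_in)), clip=wmode is not None)
        self.b = _Param(np.zeros(n_out), clip=wmode is not None) if bias else None
        self.wmode = wmode

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False, shadow=False):
        W = _effective_weight(self.W.value, self.wmode, shadow)
        self._x, self._Weff = x, W
        out = x @ W.T
        if self.b is not None:
            bias = self.b.value
            if self.wmode is not None and not shadow:
                bias = (
                    binarize(bias)
                    if self.wmode == "bin"
                    else quantize_weight(bias, self.wmode[1])
                )
            self._beff = bias
            out = out + bias
        return out

    def backward(self, g):
        dW = g.T @ self._x
        if self.wmode is not None:
            dW *= ste_grad(self.W.value)
        self.W.grad += dW
        if self.b is not None:
            db = g.sum(axis=0)
            if self.wmode is not None:
                db *= ste_grad(self.b.value)
            self.b.grad += db
        return g @ self._Weff


class InputQuant:
    """Scale raw windows and quantize to the input bit width (no gradient)."""

    def __init__(self, bits, scale=1.0):
        self.bits, self.scale = bits, scale

    def params(self):
        return []

    def forward(self, x, training=False, shadow=False):
        x = x * self.scale
        if shadow:
            return np.clip(x, -1.0, 1.0)
        return quantize_activation(x, self.bits)

    def backward(self, g):
        return g


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A 5-block channel-wise network, optionally quantization-aware."""

    def __init__(self, arch, input_shape, quant: QuantConfig | None = None, seed=0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        self.input_shape = tuple(int(v) for v in input_shape)
        self.quant = quant
        self.layers = []
        self.block_index = []  # (conv, bn, act, pool) per block for export

        if quant is not None:
            in_bits = (
                quant.first_layer_activation_bits if quant.binary_mode else quant.Q
            )
            self.input_quant = InputQuant(in_bits, scale=1.0)
            self.layers.append(self.input_quant)
            wmode = "bin" if quant.binary_mode else ("grid", quant.Q)
            act_kind = "sign" if quant.binary_mode else ("qtanh", quant.Q)
        else:
            self.input_quant = None
            wmode, act_kind = None, "relu"

        in_f = 1
        for b in arch.blocks:
            conv = Conv2D(in_f, b.n_filters, b.kh, b.kw, wmode=wmode, rng=rng)
            bn = BatchNorm(b.n_filters)
            act = Activation(act_kind)
            pool = MaxPool(b.ph, b.pw)
            self.layers += [conv, bn, act, pool]
            self.block_index.append((conv, bn, act, pool))
            in_f = b.n_filters
        self.gap = GlobalAvgPool()
        head_bias = not (quant is not None and quant.binary_mode)
        self.head = Dense(in_f, 2, bias=head_bias, wmode=wmode, rng=rng)
        self.layers += [self.gap, self.head]

    # -- passes -------------------------------------------------------------

    def parameters(self):
        out = []
        for lyr in self.layers:
            out += lyr.params()
        return out

    def forward(self, X, training=False, shadow=False):
        z = X[:, None, :, :] if X.ndim == 3 else X
        for lyr in self.layers:
            z = lyr.forward(z, training=training, shadow=shadow)
        return z

    def loss_and_backward(self, X, y, training=True):
        """Softmax cross-entropy; accumulates parameter gradients."""
        logits = self.forward(X, training=training)
        p = softmax(logits)
        n = len(y)
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        g = p.copy()
        g[np.arange(n), y] -= 1.0
        g /= n
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return loss

    def predict_proba(self, X, shadow=False):
        return softmax(self.forward(X, training=False, shadow=shadow))

    def predict(self, X, shadow=False):
        return self.predict_proba(X, shadow=shadow).argmax(axis=1)

    def recalibrate_bn(self, X):
        """Set batch-norm running statistics from one full pass over ``X``.

        With short training schedules the EMA statistics lag the weights;
        this freezes them to the actual activation statistics before export.
        """
        z = X[:, None, :, :] if X.ndim == 3 else X
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                lyr.run_mean = z.mean(axis=(0, 2, 3))
                lyr.run_var = z.var(axis=(0, 2, 3))
            z = lyr.forward(z, training=False)
        return self

    # -- export -------------------------------------------------------------

    def export_quantized(self, classes=None) -> QuantizedModel:
        """Freeze into a :class:`QuantizedModel` with dyadic folded BN."""
        if self.quant is None:
            raise ValueError("export_quantized requires a quantized network")
        q = self.quant
        wscale = 1 if q.binary_mode else (1 << (q.Q - 1))
        layers = []
        for conv, bn, _act, pool in self.block_index:
            if q.binary_mode:
                codes = binarize(conv.W.value).astype(np.int64)
            else:
                codes = np.asarray(
                    round_half_away(quantize_weight(conv.W.value, q.Q) * wscale),
                    dtype=np.int64,
                )
            g, b = bn.folded()
            mg, eg, mb, eb = [], [], [], []
            for gi, bi in zip(g, b):
                m1, e1 = to_dyadic(gi)
                m2, e2 = to_dyadic(bi)
                mg.append(m1), eg.append(e1), mb.append(m2), eb.append(e2)
            layers.append(
                QuantizedLayer(
                    kind="conv",
                    weight_codes=codes,
                    pool=(pool.ph, pool.pw),
                    bn_mant_g=np.array(mg, dtype=np.int64),
                    bn_exp_g=np.array(eg, dtype=np.int64),
                    bn_mant_b=np.array(mb, dtype=np.int64),
                    bn_exp_b=np.array(eb, dtype=np.int64),
                )
            )
        if q.binary_mode:
            head_codes = binarize(self.head.W.value).astype(np.int64)
            bias_codes = None
        else:
            head_codes = np.asarray(
                round_half_away(quantize_weight(self.head.W.value, q.Q) * wscale),
                dtype=np.int64,
            )
            bias_codes = np.asarray(
                round_half_away(quantize_weight(self.head.b.value, q.Q) * wscale),
                dtype=np.int64,
            )
        layers.append(
            QuantizedLayer(kind="dense", weight_codes=head_codes, bias_codes=bias_codes)
        )
        in_bits = q.first_layer_activation_bits if q.binary_mode else q.Q
        model = QuantizedModel(
            arch=self.arch,
            qconfig=q,
            input_scale=float(self.input_quant.scale),
            input_bits=in_bits,
            layers=layers,
            classes_=None if classes is None else np.asarray(classes),
        )
        model.validate()
        return model
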