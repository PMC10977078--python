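"""Scikit-learn style estimators wrapping the NumPy training core.

:class:`QuantizedCNNClassifier` is the central fit/predict object: it trains
a channel-wise 5-block network with quantization-aware training (or in float
mode), and exposes the exported fixed-point model via ``quantized_``.
Input ``X`` is a 3-D array of windows, shape (n_windows, channels, samples).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from preictal.archspace import (
    ArchDescription,
    build_model,
    decode_arch_string,
    model_size_bytes,
)
from preictal.quant import QuantConfig

__all__ = ["QuantizedCNNClassifier", "DEFAULT_CNN_ARCH", "DEFAULT_BNN_ARCH"]

# modest default architectures from the search space; the verifier is wider,
# the always-on gate deliberately minimal
DEFAULT_CNN_ARCH = "1x8f8p1x8|1x8f8p1x8|1x1f8p1x1|2x1f8p2x1|1x1f4p1x1"
DEFAULT_BNN_ARCH = "1x8f8p1x16|1x2f8p1x4|1x1f8p1x1|2x1f8p2x1|1x1f4p1x1"


class QuantizedCNNClassifier(BaseEstimator, ClassifierMixin):
    """Channel-wise CNN classifier with quantization-aware training.

    Parameters
    ----------
    arch : ArchDescription, str or None
        Architecture (or its token string).  None picks a small default.
    bits : int
        Weight/activation bit width Q.  ``bits=1`` with ``binary=True``
        trains a binary network (±1 weights, sign activations).
    binary : bool
        Train a BNN (requires ``bits=1``).
    float_mode : bool
        Skip quantization entirely (plain float network, ReLU activations).
    epochs, lr, batch_size : training schedule (Adam).
    input_scale : float or None
        Fixed scale mapping raw signal units into [−1, 1] before input
        quantization; None estimates it from the training data (inverse of
        the 99.5th absolute percentile).
    random_state : seed for weight init and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of the two class labels.
    network_ : the underlying training graph.
    quantized_ : exported :class:`~preictal.quant.QuantizedModel`
        (absent in float mode).
    history_ : per-epoch training loss (and validation accuracy if given).
    """

    def __init__(
        self,
        arch=None,
        bits: int = 8,
        binary: bool = False,
        float_mode: bool = False,
        epochs: int = 10,
        lr: float = 0.01,
        batch_size: int = 32,
        input_scale: float | None = None,
        random_state: int = 0,
    ):
        self.arch = arch
        self.bits = bits
        self.binary = binary
        self.float_mode = float_mode
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.input_scale = input_scale
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _resolve_arch(self) -> ArchDescription:
        if self.arch is None:
            return decode_arch_string(
                DEFAULT_BNN_ARCH if self.binary else DEFAULT_CNN_ARCH
            )
        if isinstance(self.arch, str):
            return decode_arch_string(self.arch)
        return self.arch

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (n_windows, channels, samples); got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        from preictal._nn import Adam

        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("expected exactly 2 classes")
        yi = np.searchsorted(self.classes_, y)

        arch = self._resolve_arch()
        if self.float_mode:
            quant = None
        else:
            quant = QuantConfig(
                Q=self.bits,
                binary_mode=self.binary,
                first_layer_activation_bits=8,
            )
        net = build_model(
            arch, X.shape[1:], quant=quant, seed=int(self.random_state)
        )
        if quant is not None:
            scale = self.input_scale
            if scale is None:
                p = np.percentile(np.abs(X), 99.5)
                scale = 1.0 / p if p > 0 else 1.0
            net.input_quant.scale = float(scale)
        self.input_scale_ = float(net.input_quant.scale) if quant else 1.0

        rng = np.random.default_rng(int(self.random_state))
        opt = Adam(net.parameters(), lr=self.lr)
        self.history_ = []
        n = len(X)
        bs = min(self.batch_size, n)
        best_loss, best_params = np.inf, None
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                loss = net.loss_and_backward(X[idx], yi[idx], training=True)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss})"
                    )
                opt.step()
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            if epoch_loss < best_loss:
                # quantized (esp. binary) training is non-monotone: keep the
                # best-loss snapshot and restore it before export
                best_loss = epoch_loss
                best_params = [p.value.copy() for p in net.parameters()]
            rec = {"epoch": epoch, "loss": epoch_loss}
            if X_val is not None:
                rec["val_acc"] = float(
                    np.mean(net.predict(self._validate_X(X_val)) ==
                            np.searchsorted(self.classes_, np.asarray(y_val)))
                )
            self.history_.append(rec)

        if best_params is not None:
            for p, v in zip(net.parameters(), best_params):
                p.value[...] = v

        # freeze BN statistics to the trained weights before export
        calib = X if n <= 256 else X[rng.choice(n, 256, replace=False)]
        net.recalibrate_bn(calib)

        self.network_ = net
        self.arch_ = arch
        if quant is not None:
            self.quantized_ = net.export_quantized(classes=self.classes_)
        return self

    def predict(self, X):
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        if self.float_mode:
            idx = self.network_.predict(X)
        else:
            idx = self.quantized_.predict(X)
        return self.classes_[idx]

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        return self.network_.predict_proba(X)

    def predict_float_shadow(self, X):
        """Predictions of the float shadow (quantizers replaced by hard-tanh)."""
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        return self.classes_[self.network_.predict(X, shadow=True)]

    # -- sizes --------------------------------------------------------------

    def model_size_bytes(self, count_bn: bool = True) -> int:
        """Serialized parameter bytes at the trained bit width."""
        check_is_fitted(self, "arch_")
        Q = 1 if self.binary else (64 if self.float_mode else self.bits)
        return model_size_bytes(
            self.arch_,
            Q,
            count_bn=count_bn,
            with_dense_bias=not self.binary,
        )

    def float_shadow_size_bytes(self, count_bn: bool = True) -> int:
        """Size of the same architecture stored as 64-bit floats throughout."""
        check_is_fitted(self, "arch_")
        from preictal.archspace import parameter_count

        counts = parameter_count(self.arch_)
        n = counts["total_weights"] + counts["dense_bias"]
        if count_bn:
            n += counts["bn_params"]
        return n * 8
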