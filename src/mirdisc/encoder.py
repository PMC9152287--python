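"""CNN feature encoder trained by backpropagation with a softmax head.

Architecture for a fused input row of width ``w`` (1024 by default):

    input (1, w)
      -> 16 one-dimensional convolution kernels of size 1x3, stride 1,
         'same' zero padding                       -> map (16, w)
      -> fully connected hidden layer with ReLU, same neuron count as the
         conv output (dense 16w -> 16w, reshaped back to (16, w))
      -> max pooling, filter 1x2, stride 2          -> map (16, w/2)
      -> linear FC to 256 units (the *code*)        -> (256,)
      -> dropout 50% (training only, inverted scaling)
      -> linear FC to 2 units -> softmax            -> class probabilities

The softmax head exists only to train the stack; downstream prediction
uses the 256-d code (:meth:`CNNEncoder.transform`) as input to an
external classifier. Ablation variants drop exactly one named layer while
keeping the 256-d code and head:

* ``relu_fc_ablation`` — conv feeds pooling directly;
* ``pool_ablation``    — the flattened 16xw hidden map feeds the code FC;
* ``conv_ablation``    — the raw width-w input feeds the ReLU FC (resized).

Training is mini-batch Adam on softmax cross-entropy with early stopping
on a training-loss plateau. All parameters, shuffling and dropout masks
are driven by ``random_state``, so fits are reproducible bit-for-bit in
single-threaded mode.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import log_softmax, softmax
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

VARIANTS = ("full", "relu_fc_ablation", "pool_ablation", "conv_ablation")


class CNNEncoder(BaseEstimator, TransformerMixin):
    """Convolutional feature encoder with a trainable softmax head.

    Parameters
    ----------
    conv_channels : int, default 16
        Number of 1-d convolution kernels.
    kernel_size : int, default 3
        Kernel width; must be odd ('same' padding keeps the map width).
    pool_size, pool_stride : int, default 2, 2
        Max-pooling filter and step along the length axis.
    code_dim : int, default 256
        Width of the intermediate code emitted by :meth:`transform`.
    dropout : float, default 0.5
        Dropout probability before the classification head (train only).
    hidden_mode : {'dense', 'per_position'}, default 'dense'
        'dense' is the literal full connection (16w -> 16w); 'per_position'
        applies one channels-to-channels map at every position instead.
    variant : {'full', 'relu_fc_ablation', 'pool_ablation', 'conv_ablation'}
        Layer-ablation selector; 'full' keeps the whole stack.
    epochs, batch_size, learning_rate : training-loop sizes (Adam).
    patience, tol : early stopping on a training-loss plateau.
    standardize : bool, default False
        Optional per-feature z-scoring of the input (off: embeddings are
        consumed raw).
    dtype : numpy dtype, default float32
        Parameter/activation dtype; float64 is used by gradient checks.
    """

    def __init__(
        self,
        conv_channels: int = 16,
        kernel_size: int = 3,
        pool_size: int = 2,
        pool_stride: int = 2,
        code_dim: int = 256,
        dropout: float = 0.5,
        hidden_mode: str = "dense",
        variant: str = "full",
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 10,
        tol: float = 1e-4,
        standardize: bool = False,
        dtype=np.float32,
        random_state: int = 0,
    ):
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.code_dim = code_dim
        self.dropout = dropout
        self.hidden_mode = hidden_mode
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.tol = tol
        self.standardize = standardize
        self.dtype = dtype
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _validate_config(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.code_dim < 2:
            raise ValueError("code_dim must be >= 2")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd ('same' padding)")
        if self.hidden_mode not in ("dense", "per_position"):
            raise ValueError("hidden_mode must be 'dense' or 'per_position'")
        if self.pool_size != self.pool_stride:
            raise ValueError("pooling with pool_size != pool_stride is not supported")

    def _has(self, layer: str) -> bool:
        return {
            "conv": self.variant != "conv_ablation",
            "hidden": self.variant != "relu_fc_ablation",
            "pool": self.variant != "pool_ablation",
        }[layer]

    def _build(self, width: int, rng: np.random.Generator) -> None:
        self._validate_config()
        C = self.conv_channels if self._has("conv") else 1
        if self._has("pool"):
            if width % self.pool_stride != 0:
                raise ValueError(
                    f"input width {width} not divisible by pool stride {self.pool_stride}"
                )
            pooled = width // self.pool_stride
        else:
            pooled = width
        self._C, self._w, self._wp = C, width, pooled

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
            u = rng.random(shape, dtype=np.float64 if self.dtype == np.float64 else np.float32)
            return ((u * 2.0 - 1.0) * limit).astype(self.dtype)

        params: dict[str, np.ndarray] = {}
        if self._has("conv"):
            params["Wc"] = glorot((self.conv_channels, self.kernel_size))
            params["bc"] = np.zeros(self.conv_channels, dtype=self.dtype)
        if self._has("hidden"):
            if self.hidden_mode == "dense":
                params["W1"] = glorot((C * width, C * width))
                params["b1"] = np.zeros(C * width, dtype=self.dtype)
            else:
                params["W1"] = glorot((C, C))
                params["b1"] = np.zeros(C, dtype=self.dtype)
        params["W2"] = glorot((C * pooled, self.code_dim))
        params["b2"] = np.zeros(self.code_dim, dtype=self.dtype)
        params["W3"] = glorot((self.code_dim, 2))
        params["b3"] = np.zeros(2, dtype=self.dtype)
        self.params_ = params

    # ---------------------------------------------------------------- forward

    def _forward(self, X: np.ndarray, train_mode: bool, rng=None):
        """Full forward pass; returns (probs, code, cache of activations)."""
        p = self.params_
        B, w = X.shape
        cache: dict[str, np.ndarray] = {}
        if self._has("conv"):
            k = self.kernel_size
            pad = k // 2
            xp = np.zeros((B, w + 2 * pad), dtype=X.dtype)
            xp[:, pad : pad + w] = X
            shifts = np.stack([xp[:, i : i + w] for i in range(k)], axis=1)  # (B,k,w)
            h = np.einsum("ck,bkw->bcw", p["Wc"], shifts) + p["bc"][:, None]
            cache["shifts"] = shifts
        else:
            h = X[:, None, :]  # single channel
        cache["conv_out"] = h

        if self._has("hidden"):
            if self.hidden_mode == "dense":
                flat = h.reshape(B, -1)
                pre = flat @ p["W1"] + p["b1"]
                hid = np.maximum(pre, 0.0).reshape(B, self._C, self._w)
                cache["hid_in"] = flat
            else:
                pre = np.einsum("dc,bcw->bdw", p["W1"], h) + p["b1"][None, :, None]
                hid = np.maximum(pre, 0.0)
                cache["hid_in"] = h
            cache["hid_pre"] = pre
            h = hid

        if self._has("pool"):
            r = h.reshape(B, self._C, self._wp, self.pool_stride)
            argmax = r.argmax(axis=-1)
            h = np.take_along_axis(r, argmax[..., None], axis=-1)[..., 0]
            cache["pool_argmax"] = argmax
        pooled_flat = h.reshape(B, -1)
        cache["pooled_flat"] = pooled_flat

        code = pooled_flat @ p["W2"] + p["b2"]
        cache["code"] = code
        if train_mode and self.dropout > 0.0:
            keep = 1.0 - self.dropout
            mask = (rng.random(code.shape) < keep).astype(code.dtype) / keep
            code_d = code * mask
            cache["drop_mask"] = mask
        else:
            code_d = code
        cache["code_d"] = code_d
        logits = code_d @ p["W3"] + p["b3"]
        cache["logits"] = logits
        probs = softmax(logits.astype(np.float64), axis=1)
        return probs, code, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params_
        B = dlogits.shape[0]
        grads: dict[str, np.ndarray] = {}
        grads["W3"] = cache["code_d"].T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dcode = dlogits @ p["W3"].T
        if "drop_mask" in cache:
            dcode = dcode * cache["drop_mask"]
        grads["W2"] = cache["pooled_flat"].T @ dcode
        grads["b2"] = dcode.sum(axis=0)
        dpf = dcode @ p["W2"].T
        dh = dpf.reshape(B, self._C, self._wp)

        if self._has("pool"):
            dr = np.zeros((B, self._C, self._wp, self.pool_stride), dtype=dh.dtype)
            np.put_along_axis(dr, cache["pool_argmax"][..., None], dh[..., None], axis=-1)
            dh = dr.reshape(B, self._C, self._w)

        if self._has("hidden"):
            dpre = dh if self.hidden_mode == "per_position" else dh.reshape(B, -1)
            dpre = dpre * (cache["hid_pre"] > 0.0)
            if self.hidden_mode == "dense":
                grads["W1"] = cache["hid_in"].T @ dpre
                grads["b1"] = dpre.sum(axis=0)
                dh = (dpre @ p["W1"].T).reshape(B, self._C, self._w)
            else:
                grads["W1"] = np.einsum("bdw,bcw->dc", dpre, cache["hid_in"])
                grads["b1"] = dpre.sum(axis=(0, 2))
                dh = np.einsum("dc,bdw->bcw", p["W1"].T, dpre)

        if self._has("conv"):
            grads["Wc"] = np.einsum("bcw,bkw->ck", dh, cache["shifts"])
            grads["bc"] = dh.sum(axis=(0, 2))
        return grads

    # -------------------------------------------------------------- public API

    def forward(self, X: np.ndarray, train_mode: bool = False):
        """Class probabilities and 256-d codes for ``X``.

        ``train_mode`` activates dropout (with the estimator's RNG); with
        it off the pass is a pure function of the parameters.
        """
        check_is_fitted(self, "params_")
        X = self._prepare(X)
        rng = self._dropout_rng if train_mode else None
        probs, code, _ = self._forward(X, train_mode, rng)
        return probs, code

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = check_array(X, dtype=self.dtype)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input width {X.shape[1]} does not match fitted width {self.n_features_in_}"
            )
        if self.standardize:
            X = (X - self._mu) / self._sigma
        return X

    def fit(self, X: np.ndarray, y: np.ndarray):
        """Train the stack on binary labels by mini-batch backpropagation."""
        X = check_array(X, dtype=self.dtype)
        y = np.asarray(y).astype(int).ravel()
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("labels must contain both classes 0 and 1")
        if min(np.bincount(y)) < 2:
            raise ValueError("need at least 2 examples of each class")
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.random_state)
        self._dropout_rng = rng
        self._build(X.shape[1], rng)
        if self.standardize:
            self._mu = X.mean(axis=0)
            self._sigma = X.std(axis=0)
            self._sigma[self._sigma == 0] = 1.0
            X = (X - self._mu) / self._sigma

        # Adam state
        m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        v = {k: np.zeros_like(val) for k, val in self.params_.items()}
        t = 0
        b1, b2, eps = 0.9, 0.999, 1e-8

        n = X.shape[0]
        onehot = np.eye(2, dtype=np.float64)[y]
        self.loss_trace_ = []
        best = np.inf
        stale = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb, yb = X[idx], onehot[idx]
                probs, _, cache = self._forward(xb, True, rng)
                logp = log_softmax(cache["logits"].astype(np.float64), axis=1)
                epoch_loss += -float((yb * logp).sum())
                dlogits = ((probs - yb) / len(idx)).astype(self.dtype)
                grads = self._backward(dlogits, cache)
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2**t) / (1 - b1**t)
                for key, g in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * g
                    v[key] = b2 * v[key] + (1 - b2) * g * g
                    self.params_[key] -= (lr_t * m[key] / (np.sqrt(v[key]) + eps)).astype(
                        self.dtype
                    )
            epoch_loss /= n
            self.loss_trace_.append(epoch_loss)
            if epoch_loss < best - self.tol:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deterministic 256-d codes (first linear FC output, dropout off)."""
        check_is_fitted(self, "params_")
        X = self._prepare(X)
        _, code, _ = self._forward(X, False)
        return np.asarray(code, dtype=np.float64)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax-head probabilities (the training-time classifier)."""
        check_is_fitted(self, "params_")
        X = self._prepare(X)
        probs, _, _ = self._forward(X, False)
        return probs

    # ------------------------------------------------------------ persistence

    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "params_")
        cfg = {k: (v if not isinstance(v, type) else np.dtype(v).name) for k, v in
               self.get_params().items()}
        np.savez(
            path,
            __config__=json.dumps(cfg),
            __loss_trace__=np.asarray(self.loss_trace_),
            __width__=self.n_features_in_,
            **self.params_,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNEncoder":
        data = np.load(path, allow_pickle=False)
        cfg = json.loads(str(data["__config__"]))
        cfg["dtype"] = np.dtype(cfg["dtype"]).type
        enc = cls(**cfg)
        enc.n_features_in_ = int(data["__width__"])
        enc.classes_ = np.array([0, 1])
        rng = np.random.default_rng(enc.random_state)
        enc._dropout_rng = rng
        enc._build(enc.n_features_in_, rng)
        enc.params_ = {
            k: data[k] for k in data.files if not k.startswith("__")
        }
        enc.loss_trace_ = list(data["__loss_trace__"])
        return enc
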