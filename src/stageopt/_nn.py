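"""Minimal numpy CNN used as the tier-1 feature extractor.

Architecture (fixed topology, genotype-controlled sizes): 1-2 blocks of
[3x3 same-padded convolution -> ReLU -> 2x2 max-pool], flatten, 1-2 ReLU
dense layers, a single dropout, and a softmax output trained with one-of-K
cross-entropy and Adam.  Everything runs in float32 on a single seeded
``numpy.random.Generator``, so training is bitwise reproducible.

Convolutions are computed as nine shifted tensor contractions (one per 3x3
tap), which keeps both passes as large GEMMs without materializing im2col
buffers.  The network is small by construction (widths capped at 96,
32x32 inputs), so this is fast enough for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

F32 = np.float32


_TAPS = [(dy, dx) for dy in range(3) for dx in range(3)]


def _tap_patches(x):
    """Nine flattened (n*h*w, cin) shift patches of the 1px-padded input."""
    n, h, wd, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    return [
        np.ascontiguousarray(xp[:, dy:dy + h, dx:dx + wd, :]).reshape(-1, cin)
        for dy, dx in _TAPS
    ]


def _im2col(x):
    """(n,h,w,cin) -> (n*h*w, 9*cin) patch matrix in (tap, cin) column order,
    matching ``w.reshape(9*cin, cout)``.  Worth materializing only for thin
    inputs (the first conv layer, cin=3)."""
    return np.concatenate(_tap_patches(x), axis=1)


def _conv3x3(x, w, b, keep_patches=False, cols=None):
    """Same-padded 3x3 convolution; x (n,h,w,cin), w (3,3,cin,cout).

    Two GEMM strategies: a single wide GEMM over a materialized patch matrix
    (used when ``cols`` is supplied — the thin first layer, where the matrix
    is small and can be cached across epochs), or nine accumulated per-tap
    GEMMs (wide inputs, where materializing the patch matrix is memory-bound).
    Returns (out, patches-or-cols for the backward pass).
    """
    n, h, wd, cin = x.shape
    cout = w.shape[3]
    if cols is not None:
        out = cols @ w.reshape(9 * cin, cout) + b
        return out.reshape(n, h, wd, cout), cols
    patches = _tap_patches(x)
    acc = patches[0] @ w[0, 0]
    for k in range(1, 9):
        dy, dx = _TAPS[k]
        acc += patches[k] @ w[dy, dx]
    out = acc.reshape(n, h, wd, cout) + b
    return out, patches if keep_patches else None


def _conv3x3_backward(x_shape, cache, w, dout, need_dx=True):
    """Gradients of the same-padded 3x3 convolution.

    ``cache`` is either the materialized patch matrix (first layer) or the
    nine per-tap patches kept by the forward pass."""
    n, h, wd, cin = x_shape
    cout = w.shape[3]
    dflat = dout.reshape(-1, cout)
    db = dflat.sum(axis=0)
    if isinstance(cache, np.ndarray):  # materialized (nhw, 9cin) matrix
        dw = (cache.T @ dflat).reshape(3, 3, cin, cout)
        if not need_dx:
            return None, dw, db
        cache = [cache[:, k * cin:(k + 1) * cin] for k in range(9)]
    else:
        dw = np.empty_like(w)
        for k, (dy, dx) in enumerate(_TAPS):
            dw[dy, dx] = cache[k].T @ dflat
    if not need_dx:
        return None, dw, db
    dxp = np.zeros((n, h + 2, wd + 2, cin), dtype=F32)
    for dy, dx in _TAPS:
        dxp[:, dy:dy + h, dx:dx + wd, :] += (dflat @ w[dy, dx].T).reshape(
            n, h, wd, cin
        )
    return dxp[:, 1:-1, 1:-1, :], dw, db


def _pool_views(x):
    return (
        x[:, 0::2, 0::2, :], x[:, 0::2, 1::2, :],
        x[:, 1::2, 0::2, :], x[:, 1::2, 1::2, :],
    )


def _maxpool2(x):
    """2x2 max-pool via the four strided corner views; the backward pass
    recomputes the winner, so only the input is cached."""
    v = _pool_views(x)
    out = np.maximum(np.maximum(v[0], v[1]), np.maximum(v[2], v[3]))
    return out, x


def _maxpool2_backward(dout, x):
    """Route gradient to the first corner attaining the window max."""
    v = _pool_views(x)
    out = np.maximum(np.maximum(v[0], v[1]), np.maximum(v[2], v[3]))
    n, h, w, c = x.shape
    dx = np.zeros_like(x)
    dviews = _pool_views(dx)
    taken = np.zeros(dout.shape, dtype=bool)
    for vi, dvi in zip(v, dviews):
        hit = (vi == out) & ~taken
        dvi += dout * hit
        taken |= hit
    return dx


@dataclass
class _Layer:
    kind: str
    w: Optional[np.ndarray] = None
    b: Optional[np.ndarray] = None


class SmallCNN:
    """Trainable CNN with an embedding tap at the dropout input."""

    def __init__(
        self,
        conv_widths: list[int],
        dense_widths: list[int],
        dropout: float,
        n_classes: int = 4,
        input_shape: tuple[int, int, int] = (32, 32, 3),
        seed: int = 0,
    ):
        if not conv_widths or not dense_widths:
            raise ValueError("need at least one conv and one dense layer")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.conv_widths = [int(w) for w in conv_widths]
        self.dense_widths = [int(w) for w in dense_widths]
        self.dropout = float(dropout)
        self.n_classes = n_classes
        self.input_shape = input_shape
        self.rng = np.random.default_rng(seed)
        self._build()

    # -- construction -----------------------------------------------------
    def _he(self, shape, fan_in):
        return (self.rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)

    def _build(self):
        h, w, c = self.input_shape
        self.layers: list[_Layer] = []
        cin = c
        for cw in self.conv_widths:
            self.layers.append(
                _Layer("conv", self._he((3, 3, cin, cw), 9 * cin),
                       np.zeros(cw, dtype=F32))
            )
            self.layers.append(_Layer("pool"))
            cin = cw
            h, w = h // 2, w // 2
        self.layers.append(_Layer("flatten"))
        fan = h * w * cin
        for dw_ in self.dense_widths:
            self.layers.append(
                _Layer("dense", self._he((fan, dw_), fan), np.zeros(dw_, dtype=F32))
            )
            fan = dw_
        self.layers.append(_Layer("dropout"))
        self.layers.append(
            _Layer("out", self._he((fan, self.n_classes), fan),
                   np.zeros(self.n_classes, dtype=F32))
        )
        self._adam_m = [
            (np.zeros_like(l.w), np.zeros_like(l.b)) if l.w is not None else None
            for l in self.layers
        ]
        self._adam_v = [
            (np.zeros_like(l.w), np.zeros_like(l.b)) if l.w is not None else None
            for l in self.layers
        ]
        self._adam_t = 0

    @property
    def embedding_width(self) -> int:
        return self.dense_widths[-1]

    def n_parameters(self) -> int:
        return sum(l.w.size + l.b.size for l in self.layers if l.w is not None)

    # -- passes -----------------------------------------------------------
    def _forward(self, x, train: bool, first_cols=None):
        """Returns (logits, caches).  The embedding is the dropout input.

        ``first_cols`` optionally supplies the first conv layer's patch
        matrix (it depends only on the input, so callers that reuse a fixed
        batch — full-batch training, the validation set — precompute it)."""
        caches = []
        a = x.astype(F32, copy=False)
        for li, layer in enumerate(self.layers):
            if layer.kind == "conv":
                if li == 0 and first_cols is None:
                    first_cols = _im2col(a)
                z, kept = _conv3x3(
                    a, layer.w, layer.b, keep_patches=train,
                    cols=first_cols if li == 0 else None,
                )
                relu_mask = z > 0
                caches.append((a.shape, kept if train else None, relu_mask))
                a = z * relu_mask
            elif layer.kind == "pool":
                a, mask = _maxpool2(a)
                caches.append(mask)
            elif layer.kind == "flatten":
                caches.append(a.shape)
                a = a.reshape(a.shape[0], -1)
            elif layer.kind == "dense":
                z = a @ layer.w + layer.b
                relu_mask = z > 0
                caches.append((a, relu_mask))
                a = z * relu_mask
            elif layer.kind == "dropout":
                self._embedding = a
                if train and self.dropout > 0:
                    keep = (
                        self.rng.random(a.shape) >= self.dropout
                    ).astype(F32) / F32(1.0 - self.dropout)
                else:
                    keep = None
                caches.append(keep)
                a = a * keep if keep is not None else a
            elif layer.kind == "out":
                caches.append(a)
                a = a @ layer.w + layer.b
        return a, caches

    def _backward(self, dlogits, caches):
        grads = [None] * len(self.layers)
        d = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            layer, cache = self.layers[i], caches[i]
            if layer.kind == "out":
                grads[i] = (cache.T @ d, d.sum(axis=0))
                d = d @ layer.w.T
            elif layer.kind == "dropout":
                if cache is not None:
                    d = d * cache
            elif layer.kind == "dense":
                a_in, relu_mask = cache
                dz = d * relu_mask
                grads[i] = (a_in.T @ dz, dz.sum(axis=0))
                d = dz @ layer.w.T
            elif layer.kind == "flatten":
                d = d.reshape(cache)
            elif layer.kind == "pool":
                d = _maxpool2_backward(d, cache)
            elif layer.kind == "conv":
                x_shape, kept, relu_mask = cache
                dz = d * relu_mask
                d, dw, db = _conv3x3_backward(
                    x_shape, kept, layer.w, dz, need_dx=(i > 0)
                )
                grads[i] = (dw, db)
        return grads

    def _adam_step(self, grads, lr, b1=0.9, b2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for i, layer in enumerate(self.layers):
            if grads[i] is None:
                continue
            for slot, (p, g) in enumerate(
                ((layer.w, grads[i][0]), (layer.b, grads[i][1]))
            ):
                m = self._adam_m[i][slot]
                v = self._adam_v[i][slot]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** t)
                vhat = v / (1 - b2 ** t)
                p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(F32)

    # -- public API -------------------------------------------------------
    def loss_and_probs(self, x, y_onehot, train=False, first_cols=None):
        logits, caches = self._forward(x, train=train, first_cols=first_cols)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        eps = 1e-12
        loss = -float(
            np.mean(np.sum(y_onehot * np.log(probs + eps), axis=1))
        )
        return loss, probs, caches

    def fit(
        self,
        x_train,
        y_train,
        x_val,
        y_val,
        epochs: int,
        learning_rate: float,
        batch_size: int = 512,
        patience: Optional[int] = None,
        verbose: bool = False,
    ) -> dict:
        """Train with Adam, early-stopping on validation loss.

        patience defaults to floor(epochs/3) (at least 1); the best-validation
        weights are restored at the end.  Returns a history dict.
        """
        if len(x_train) == 0 or len(x_val) == 0:
            raise ValueError("train and validation sets must be non-empty")
        if patience is None:
            patience = max(epochs // 3, 1)
        y_tr = np.eye(self.n_classes, dtype=F32)[y_train]
        y_vl = np.eye(self.n_classes, dtype=F32)[y_val]
        n = len(x_train)
        best_loss = np.inf
        best_state = None
        since_best = 0
        hist = {"train_loss": [], "val_loss": []}
        x_train = x_train.astype(F32, copy=False)
        x_val = x_val.astype(F32, copy=False)
        # the first conv layer's patch matrices depend only on the data, so
        # they are computed once when the whole set fits in a single batch
        single_batch = n <= batch_size
        cols_tr = _im2col(x_train) if single_batch else None
        cols_vl = _im2col(x_val)
        for epoch in range(epochs):
            ep_loss = 0.0
            if single_batch:
                loss, probs, caches = self.loss_and_probs(
                    x_train, y_tr, train=True, first_cols=cols_tr
                )
                dlogits = (probs - y_tr).astype(F32) / F32(n)
                grads = self._backward(dlogits, caches)
                self._adam_step(grads, learning_rate)
                ep_loss = loss * n
            else:
                order = self.rng.permutation(n)
                for start in range(0, n, batch_size):
                    idx = order[start:start + batch_size]
                    xb, yb = x_train[idx], y_tr[idx]
                    loss, probs, caches = self.loss_and_probs(xb, yb, train=True)
                    dlogits = (probs - yb).astype(F32) / F32(len(idx))
                    grads = self._backward(dlogits, caches)
                    self._adam_step(grads, learning_rate)
                    ep_loss += loss * len(idx)
            val_loss, _, _ = self.loss_and_probs(
                x_val, y_vl, train=False, first_cols=cols_vl
            )
            hist["train_loss"].append(ep_loss / n)
            hist["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch + 1}: train {ep_loss / n:.4f} val {val_loss:.4f}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = [
                    (l.w.copy(), l.b.copy()) if l.w is not None else None
                    for l in self.layers
                ]
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_state is not None:
            for layer, state in zip(self.layers, best_state):
                if state is not None:
                    layer.w, layer.b = state
        hist["best_val_loss"] = float(best_loss)
        return hist

    def predict_proba(self, x, batch_size: int = 1024) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            logits, _ = self._forward(x[start:start + batch_size], train=False)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out)

    def predict(self, x) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def embed(self, x, batch_size: int = 1024) -> np.ndarray:
        """Inference-mode activations at the dropout input (dropout off)."""
        out = []
        for start in range(0, len(x), batch_size):
            self._forward(x[start:start + batch_size], train=False)
            out.append(self._embedding.copy())
        return np.concatenate(out)
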