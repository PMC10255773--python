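"""A one-dimensional convolutional network for spectral regression.

Architecture (channels-last, valid convolutions, stride 1):

    input (L, 1)
      → Conv1D(64, k) → ReLU → Dropout
      → Conv1D(32, k) → ReLU
      → Conv1D(16, k) → ReLU
      → MaxPool(pool) → Flatten
      → Dense(64) → ReLU → Dense(32) → ReLU → Dense(1)

With the defaults (L = 1803, k = 5, pool = 2) the feature lengths are
1799 → 1795 → 1791 → 895 → flatten 14320, and the per-layer trainable
parameter counts are 384 / 10 272 / 2 576 / 916 544 / 2 080 / 33,
totalling 931 889.

The network is implemented directly in numpy (convolutions as K shifted
batched matrix products, explicit backpropagation, Adam with cosine
learning-rate decay) in float32.  Weight initialization, shuffling and
dropout are all driven by one seeded generator, so training is reproducible
on a fixed thread configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = ["CnnSpec", "CnnModel", "build", "param_count", "relu", "train", "predict"]

_CLIP_NORM = 5.0  # global gradient-norm ceiling during training


@dataclass(frozen=True)
class CnnSpec:
    """Hyperparameters of the 1D CNN regressor."""

    input_length: int = 1803
    conv_filters: tuple[int, int, int] = (64, 32, 16)
    kernel_size: int = 5
    dropout_rate: float = 0.5
    pool_size: int = 2
    dense_units: tuple[int, int, int] = (64, 32, 1)
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 32
    seed: int = 0

    def feature_lengths(self) -> dict[str, int]:
        """Lengths after each conv / pool / flatten stage (valid conv:
        L → L − kernel + 1; pooling floors)."""
        L = self.input_length
        convs = []
        for _ in self.conv_filters:
            L = L - self.kernel_size + 1
            convs.append(L)
        pooled = L // self.pool_size
        return {
            "conv": convs,
            "pooled": pooled,
            "flatten": pooled * self.conv_filters[-1],
        }


@dataclass
class CnnModel:
    """Spec + per-layer weight tensors + per-epoch loss history.

    ``input_mean`` / ``input_scale`` hold the per-wavenumber standardization
    statistics estimated from the calibration set at the start of training
    (and reapplied verbatim at prediction time).  Standardizing the input
    lets gradient descent see the small concentration-dependent band changes
    at the same scale as the large constant matrix bands.
    """

    spec: CnnSpec
    weights: dict[str, np.ndarray]
    training_history: list[dict] = field(default_factory=list)
    input_mean: np.ndarray | None = None
    input_scale: np.ndarray | None = None


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def build(spec: CnnSpec) -> CnnModel:
    """Initialize an untrained network (He-init conv/dense weights, zero
    biases), deterministically from ``spec.seed``.

    Raises if the input is too short to survive three valid convolutions
    and pooling with a non-empty flatten layer.
    """
    lengths = spec.feature_lengths()
    if lengths["conv"][-1] < 1:
        raise ValueError(
            f"input_length {spec.input_length} too small for "
            f"{len(spec.conv_filters)} valid convolutions of kernel {spec.kernel_size}"
        )
    if lengths["flatten"] < 1:
        raise ValueError(
            f"flatten length is {lengths['flatten']} "
            f"(pooled length {lengths['pooled']}): no features reach the dense head"
        )
    rng = np.random.default_rng(spec.seed)
    k = spec.kernel_size
    weights: dict[str, np.ndarray] = {}
    c_in = 1
    for i, c_out in enumerate(spec.conv_filters, start=1):
        fan_in = c_in * k
        weights[f"conv{i}_W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(c_in, k, c_out)
        ).astype(np.float32)
        weights[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    d_in = lengths["flatten"]
    for i, d_out in enumerate(spec.dense_units, start=1):
        weights[f"dense{i}_W"] = rng.normal(
            0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)
        ).astype(np.float32)
        weights[f"dense{i}_b"] = np.zeros(d_out, dtype=np.float32)
        d_in = d_out
    return CnnModel(spec=spec, weights=weights)


def param_count(model: CnnModel) -> tuple[dict[str, int], int]:
    """Per-layer and total trainable parameter counts, computed from the
    actual weight-array shapes (not from the closed-form formulas)."""
    per_layer: dict[str, int] = {}
    for name in ("conv1", "conv2", "conv3", "dense1", "dense2", "dense3"):
        per_layer[name] = int(
            model.weights[f"{name}_W"].size + model.weights[f"{name}_b"].size
        )
    return per_layer, sum(per_layer.values())


# ---------------------------------------------------------------- internals
#
# The convolutions over many channels run as BLAS batched matmuls; the
# memory-bound glue (first conv, ReLU/dropout masks, pooling) is fused into
# single-pass numba kernels so each large activation array is touched once.


@njit(fastmath=True, cache=True)
def _k_conv1_relu(x2d, W, b, out):
    """Single-channel valid conv + ReLU in one pass.
    x2d: (N, L); W: (K, C); b: (C); out: (N, L_out, C)."""
    n_s, l_in = x2d.shape
    k, c_out = W.shape
    l_out = l_in - k + 1
    for n in range(n_s):
        for l in range(l_out):
            for c in range(c_out):
                acc = b[c]
                for j in range(k):
                    acc += x2d[n, l + j] * W[j, c]
                out[n, l, c] = acc if acc > 0.0 else 0.0


@njit(fastmath=True, cache=True)
def _k_apply_dropout(a, drop, inv_keep):
    """a *= drop * inv_keep, elementwise over the flattened activation."""
    flat = a.reshape(-1)
    mask = drop.reshape(-1)
    for i in range(flat.size):
        flat[i] = flat[i] * inv_keep if mask[i] else 0.0


@njit(fastmath=True, cache=True)
def _k_pool_max(a3, p, pooled, arg):
    """Max-pool with argmax record.  a3: (N, L3, C); pooled/arg: (N, Lp, C)."""
    n_s, _, c_out = a3.shape
    l_pool = pooled.shape[1]
    for n in range(n_s):
        for l in range(l_pool):
            base = l * p
            for c in range(c_out):
                best = a3[n, base, c]
                besti = 0
                for j in range(1, p):
                    v = a3[n, base + j, c]
                    if v > best:
                        best = v
                        besti = j
                pooled[n, l, c] = best
                arg[n, l, c] = besti


@njit(fastmath=True, cache=True)
def _k_unpool(dpool, arg, p, da3):
    """Scatter pooled gradients back to the argmax positions (da3 pre-zeroed
    implicitly: every slot is written)."""
    n_s, l_pool, c_out = dpool.shape
    l3 = da3.shape[1]
    for n in range(n_s):
        for l in range(l3):
            for c in range(c_out):
                da3[n, l, c] = 0.0
    for n in range(n_s):
        for l in range(l_pool):
            for c in range(c_out):
                da3[n, l * p + arg[n, l, c], c] = dpool[n, l, c]


@njit(fastmath=True, cache=True)
def _k_relu_mask(grad, act, scale):
    """grad *= scale where act > 0, else 0 — the backward ReLU (+dropout
    rescale) in one pass."""
    g = grad.reshape(-1)
    a = act.reshape(-1)
    for i in range(g.size):
        g[i] = g[i] * scale if a[i] > 0.0 else 0.0


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x: (N, L, C_in); W: (C_in, K, C_out).  Valid convolution, stride 1,
    computed as K shifted batched matmuls (no column matrix is built)."""
    c_in, k, c_out = W.shape
    l_out = x.shape[1] - k + 1
    out = np.empty((x.shape[0], l_out, c_out), dtype=x.dtype)
    out[:] = b
    if c_in == 1:  # degenerate gemm: broadcasting is faster
        for j in range(k):
            out += x[:, j : j + l_out] * W[0, j]
    else:
        for j in range(k):
            out += x[:, j : j + l_out, :] @ W[:, j, :]
    return out


def _conv_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray, need_dx: bool = True):
    """Gradients of a valid stride-1 convolution; ``x`` is the layer input.

    ``need_dx=False`` (first layer) skips the input gradient.
    """
    c_in, k, c_out = W.shape
    n, l_out = dout.shape[:2]
    dW = np.empty_like(W)
    dx = np.zeros_like(x) if need_dx else None
    dout2d = dout.reshape(-1, c_out)
    for j in range(k):
        if c_in == 1:
            dW[:, j, :] = x[:, j : j + l_out, 0].reshape(1, -1) @ dout2d
        else:
            dW[:, j, :] = (x[:, j : j + l_out, :].transpose(0, 2, 1) @ dout).sum(axis=0)
        if need_dx:
            dx[:, j : j + l_out, :] += dout @ W[:, j, :].T
    db = dout.sum(axis=(0, 1))
    return dx, dW, db


def _forward(model: CnnModel, x: np.ndarray, rng: np.random.Generator | None):
    """Full forward pass.  ``rng`` enables dropout (training mode); None
    disables it (inference).  Returns (output, cache-for-backward)."""
    w = model.weights
    spec = model.spec
    cache: dict = {}

    W1 = w["conv1_W"]
    if W1.shape[0] == 1:
        n_s = x.shape[0]
        l1 = x.shape[1] - W1.shape[1] + 1
        a = np.empty((n_s, l1, W1.shape[2]), dtype=x.dtype)
        _k_conv1_relu(np.ascontiguousarray(x[:, :, 0]), W1[0], w["conv1_b"], a)
    else:
        a = _conv_forward(x, W1, w["conv1_b"])
        np.maximum(a, 0, out=a)
    if rng is not None and spec.dropout_rate > 0:
        keep = 1.0 - spec.dropout_rate
        drop = rng.random(a.shape, dtype=np.float32) < keep  # bool mask
        _k_apply_dropout(a, drop, x.dtype.type(1.0 / keep))
        cache["keep"] = keep
    cache["a1"] = a  # post-ReLU(+dropout): a > 0 is the backward mask

    a2 = _conv_forward(a, w["conv2_W"], w["conv2_b"])
    np.maximum(a2, 0, out=a2)
    cache["a2"] = a2

    a3 = _conv_forward(a2, w["conv3_W"], w["conv3_b"])
    np.maximum(a3, 0, out=a3)

    cache["a3"] = a3
    p = spec.pool_size
    l3 = a3.shape[1]
    l_pool = l3 // p
    pooled = np.empty((a3.shape[0], l_pool, a3.shape[2]), dtype=a3.dtype)
    pool_arg = np.empty(pooled.shape, dtype=np.int8)
    _k_pool_max(a3, p, pooled, pool_arg)
    cache["pool_arg"], cache["l3"] = pool_arg, l3

    flat = pooled.reshape(pooled.shape[0], -1)
    cache["flat"] = flat

    h = flat @ w["dense1_W"] + w["dense1_b"]
    cache["dmask1"] = h > 0
    h1 = np.maximum(h, 0)
    cache["h1"] = h1
    h = h1 @ w["dense2_W"] + w["dense2_b"]
    cache["dmask2"] = h > 0
    h2 = np.maximum(h, 0)
    cache["h2"] = h2
    out = h2 @ w["dense3_W"] + w["dense3_b"]
    return out, cache


def _backward(model: CnnModel, x: np.ndarray, dout: np.ndarray, cache: dict):
    w = model.weights
    spec = model.spec
    g: dict[str, np.ndarray] = {}

    g["dense3_W"] = cache["h2"].T @ dout
    g["dense3_b"] = dout.sum(axis=0)
    dh2 = (dout @ w["dense3_W"].T) * cache["dmask2"]
    g["dense2_W"] = cache["h1"].T @ dh2
    g["dense2_b"] = dh2.sum(axis=0)
    dh1 = (dh2 @ w["dense2_W"].T) * cache["dmask1"]
    g["dense1_W"] = cache["flat"].T @ dh1
    g["dense1_b"] = dh1.sum(axis=0)
    dflat = dh1 @ w["dense1_W"].T

    n = x.shape[0]
    c_last = spec.conv_filters[-1]
    p = spec.pool_size
    l3 = cache["l3"]
    l_pool = l3 // p
    dpool = np.ascontiguousarray(dflat).reshape(n, l_pool, c_last)
    da3 = np.empty((n, l3, c_last), dtype=dpool.dtype)
    _k_unpool(dpool, cache["pool_arg"], p, da3)

    # post-activation caches double as ReLU masks: a > 0 iff the unit fired
    # (dropout zeros count as not fired, which also blocks their gradient)
    one = da3.dtype.type(1.0)
    _k_relu_mask(da3, cache["a3"], one)
    da2, g["conv3_W"], g["conv3_b"] = _conv_backward(da3, cache["a2"], w["conv3_W"])
    _k_relu_mask(da2, cache["a2"], one)
    da1, g["conv2_W"], g["conv2_b"] = _conv_backward(da2, cache["a1"], w["conv2_W"])
    scale = da1.dtype.type(1.0 / cache["keep"]) if "keep" in cache else one
    _k_relu_mask(da1, cache["a1"], scale)
    _, g["conv1_W"], g["conv1_b"] = _conv_backward(da1, x, w["conv1_W"], need_dx=False)
    return g


class _Adam:
    def __init__(self, weights: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float | None = None):
        self.t += 1
        lr = self.lr if lr is None else lr
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, gr in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gr
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gr * gr
            weights[k] -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def _as_input(X: np.ndarray, input_length: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.shape[1] != input_length or X.shape[2] != 1:
        raise ValueError(
            f"input shape {X.shape[1:]} does not match spec input_length {input_length}"
        )
    return X


def predict(model: CnnModel, X_new: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Forward pass in inference mode (dropout off); linear output, no
    clipping.  Returns a vector of % w/w predictions."""
    X = _as_input(X_new, model.spec.input_length)
    if model.input_mean is not None:
        X = (X - model.input_mean[None, :, None]) / model.input_scale[None, :, None]
    outs = []
    for i in range(0, X.shape[0], batch_size):
        out, _ = _forward(model, X[i : i + batch_size], rng=None)
        outs.append(out[:, 0])
    return np.concatenate(outs).astype(float)


def train(
    model: CnnModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int | None = None,
    verbose: bool = False,
) -> CnnModel:
    """Minimize mean-squared error with Adam for ``epochs`` passes
    (default: ``spec.epochs``).  The validation set is monitored only — no early
    stopping.  Per-epoch train/validation losses are appended to
    ``model.training_history``.  Aborts on a non-finite loss.
    """
    spec = model.spec
    epochs = spec.epochs if epochs is None else epochs
    X = _as_input(X_cal, spec.input_length)
    y = np.asarray(y_cal, dtype=np.float32).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X_cal and y_cal sample counts differ")
    if model.input_mean is None:
        mean = X.mean(axis=0)[:, 0]
        scale = np.maximum(X.std(axis=0)[:, 0], np.float32(1e-6))
        model.input_mean = mean.astype(np.float32)
        model.input_scale = scale.astype(np.float32)
    X = (X - model.input_mean[None, :, None]) / model.input_scale[None, :, None]
    Xv = yv = None
    if X_val is not None:
        Xv = _as_input(X_val, spec.input_length)
        yv = np.asarray(y_val, dtype=np.float32).ravel()

    rng = np.random.default_rng(spec.seed + 1)
    opt = _Adam(model.weights, spec.learning_rate)
    n = X.shape[0]
    if not model.training_history:
        # start the linear output at the label mean so early epochs refine
        # structure instead of hunting the offset
        model.weights["dense3_b"][:] = np.float32(y.mean())
    warmup = max(1, epochs // 20)
    for epoch in range(epochs):
        # short linear warmup, then cosine decay toward zero: the warmup
        # keeps the very first updates from committing the 931k parameters
        # to a poor basin, the decay settles the weights by the final epochs
        if epoch < warmup:
            lr = spec.learning_rate * (epoch + 1) / warmup
        else:
            lr = spec.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - warmup) / max(1, epochs - warmup))
            )
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, spec.batch_size):
            idx = order[i : i + spec.batch_size]
            xb, yb = X[idx], y[idx]
            out, cache = _forward(model, xb, rng=rng)
            resid = out[:, 0] - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "lower the learning rate or check the input scaling"
                )
            epoch_loss += loss * len(idx)
            dout = (2.0 * resid / len(idx))[:, None].astype(np.float32)
            grads = _backward(model, xb, dout, cache)
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > _CLIP_NORM:  # rare large batches would otherwise kick
                for g in grads.values():  # the weights out of a settled basin
                    g *= _CLIP_NORM / gnorm
            opt.step(model.weights, grads, lr=lr)
        record = {"epoch": epoch + 1, "train_loss": epoch_loss / n}
        if Xv is not None:
            val_pred = predict(model, Xv)
            record["val_loss"] = float(np.mean((val_pred - yv) ** 2))
        model.training_history.append(record)
        if verbose:
            msg = f"epoch {epoch + 1:4d}  train MSE {record['train_loss']:.5f}"
            if "val_loss" in record:
                msg += f"  val MSE {record['val_loss']:.5f}"
            print(msg)
    return model
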