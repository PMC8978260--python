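"""Small 3D convolutional-network core (numpy, manual backpropagation).

Implements exactly what the two segmentation networks need: 3x3x3
convolutions (stride 1 or 2) via im2col, non-overlapping transposed
convolutions (kernel == stride), ReLU/sigmoid, the soft Dice loss and Adam.
Arrays carry no batch axis — the pipeline trains at batch size 1 — and are
laid out channels-first ``(C, D, H, W)`` in float32.

Forward passes on large grids chunk the im2col buffer along the depth axis
so memory stays bounded; training-time passes cache the column matrix for
the weight gradient.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "Conv3d",
    "ConvTranspose3d",
    "ReLU",
    "Sigmoid",
    "Adam",
    "Model3D",
    "TrainConfig",
    "TrainingDiverged",
    "dice_loss",
    "dice_loss_grad",
    "fit",
]

_COL_BYTES_LIMIT = 192 * 1024**2  # im2col chunk budget per slab


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def _out_extent(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(xp: np.ndarray, k: int, stride: int, out_shape) -> np.ndarray:
    """xp is the already-padded input (C, Dp, Hp, Wp) -> (C*k^3, N_out)."""
    C = xp.shape[0]
    od, oh, ow = out_shape
    cols = np.empty((C, k, k, k, od, oh, ow), dtype=xp.dtype)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[:, a, b, c] = xp[
                    :,
                    a : a + od * stride : stride,
                    b : b + oh * stride : stride,
                    c : c + ow * stride : stride,
                ]
    return cols.reshape(C * k**3, od * oh * ow)


def _col2im(dcols, x_shape, k, stride, pad, out_shape) -> np.ndarray:
    C, D, H, W = x_shape
    od, oh, ow = out_shape
    g = np.zeros((C, D + 2 * pad, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(C, k, k, k, od, oh, ow)
    for a in range(k):
        for b in range(k):
            for c in range(k):
                g[
                    :,
                    a : a + od * stride : stride,
                    b : b + oh * stride : stride,
                    c : c + ow * stride : stride,
                ] += d6[:, a, b, c]
    if pad:
        g = g[:, pad:-pad, pad:-pad, pad:-pad]
    return g


class Conv3d:
    """k^3 convolution, 'same'-style padding, stride 1 or 2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, pad: int | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = cin * k**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        return tuple(_out_extent(n, self.k, self.stride, self.pad) for n in in_shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        C, D, H, W = x.shape
        od, oh, ow = self.out_shape((D, H, W))
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        n_out = od * oh * ow
        col_bytes = C * k**3 * n_out * x.itemsize
        if train or col_bytes <= _COL_BYTES_LIMIT:
            cols = _im2col(xp, k, s, (od, oh, ow))
            y = (self.W.value @ cols) + self.b.value[:, None]
            if train:
                self._cache = (cols, x.shape, (od, oh, ow))
            return y.reshape(self.cout, od, oh, ow)
        # chunk the output depth axis to bound the im2col buffer
        y = np.empty((self.cout, od, oh, ow), dtype=np.float32)
        slab = max(1, int(_COL_BYTES_LIMIT // (C * k**3 * oh * ow * x.itemsize)))
        for z0 in range(0, od, slab):
            z1 = min(od, z0 + slab)
            xin = xp[:, z0 * s : (z1 - 1) * s + k]
            cols = _im2col(xin, k, s, (z1 - z0, oh, ow))
            yc = (self.W.value @ cols) + self.b.value[:, None]
            y[:, z0:z1] = yc.reshape(self.cout, z1 - z0, oh, ow)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, x_shape, out_shape = self._cache
        gyf = gy.reshape(self.cout, -1)
        self.W.grad += gyf @ cols.T
        self.b.grad += gyf.sum(axis=1)
        dcols = self.W.value.T @ gyf
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, out_shape)


class ConvTranspose3d:
    """Transposed convolution with kernel == stride (exact, non-overlapping
    upsampling by the stride factor)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 2):
        self.cin, self.cout, self.k = cin, cout, k
        w = rng.normal(0.0, np.sqrt(2.0 / cin), size=(cin, cout * k**3))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def out_shape(self, in_shape):
        return tuple(n * self.k for n in in_shape)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cin, d, h, w = x.shape
        k = self.k
        xf = x.reshape(cin, -1)
        v = self.W.value.T @ xf  # (cout*k^3, N)
        v = v.reshape(self.cout, k, k, k, d, h, w)
        y = v.transpose(0, 4, 1, 5, 2, 6, 3).reshape(self.cout, d * k, h * k, w * k)
        y = y + self.b.value[:, None, None, None]
        if train:
            self._cache = (xf, (d, h, w))
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xf, (d, h, w) = self._cache
        k = self.k
        u = gy.reshape(self.cout, d, k, h, k, w, k)
        u = u.transpose(0, 2, 4, 6, 1, 3, 5).reshape(self.cout * k**3, d * h * w)
        self.W.grad += xf @ u.T
        self.b.grad += gy.sum(axis=(1, 2, 3))
        gx = self.W.value @ u
        return gx.reshape(self.cin, d, h, w)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        return np.maximum(x, 0.0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0.0)


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self):
        return []

    def forward(self, x, train=False):
        y = expit(x)
        if train:
            self._y = y
        return y

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class Model3D:
    """Base for the two encoder–decoder networks: parameter bookkeeping,
    checkpointing and prediction; subclasses define forward/backward."""

    layers: list

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return self.forward(x, train=False)[0]

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        np.savez(Path(path), spec=json.dumps(self.spec_dict()), **arrays)

    def _load_weights_npz(self, path: str | Path):
        with np.load(Path(path), allow_pickle=False) as data:
            self.set_weights([data[f"p{i}"] for i in range(len(self.params()))])


# ---------------------------------------------------------------------------
# Loss and training


def dice_loss(pred: np.ndarray, ref: np.ndarray, eps: float = 1e-7) -> float:
    """Soft Dice loss 1 - 2*sum(p*g) / (sum(p) + sum(g) + eps).

    Differentiable in ``pred``; equals 1 - DSC(pred, ref) when ``pred`` is
    binary. The reference must be non-empty.
    """
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    gsum = ref.sum()
    if gsum == 0:
        raise ValueError("dice_loss: reference mask is empty")
    num = 2.0 * float((pred * ref).sum())
    den = float(pred.sum()) + float(gsum) + eps
    return 1.0 - num / den


def dice_loss_grad(pred: np.ndarray, ref: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    num = 2.0 * float((pred * ref).sum())
    den = float(pred.sum()) + float(ref.sum()) + eps
    return (-(2.0 * ref * den - num) / den**2).astype(np.float32)


class TrainingDiverged(RuntimeError):
    pass


class TrainConfig:
    """Optimisation settings: Adam, batch size 1, mean Dice loss, and the
    best-validation parameter state kept over ``max_epochs`` epochs."""

    def __init__(self, learning_rate: float = 1e-6, batch_size: int = 1,
                 max_epochs: int = 1500, seed: int = 0, lr_decay: float = 1.0):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if batch_size != 1:
            raise ValueError("only batch_size=1 is supported")
        if not (0 < lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        self.learning_rate = float(learning_rate)
        self.batch_size = batch_size
        self.max_epochs = int(max_epochs)
        self.seed = int(seed)
        self.lr_decay = float(lr_decay)


def _as_xy(pair):
    x, y = pair
    x = np.asarray(getattr(x, "voxels", x), dtype=np.float32)
    y = np.asarray(getattr(y, "voxels", y), dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    return x, y


def _mean_loss(model, pairs) -> float:
    losses = []
    for pair in pairs:
        x, y = _as_xy(pair)
        p = model.forward(x, train=False)[0]
        losses.append(dice_loss(p, y))
    return float(np.mean(losses))


def fit(model, train_pairs, val_pairs, config: TrainConfig) -> dict:
    """Train with Adam on the mean Dice loss; return the history and leave the
    model holding the parameter state with the best validation loss.

    ``train_pairs``/``val_pairs`` are sequences of (volume, mask) with shapes
    matching the model's input contract. With no validation pairs the
    training loss is used for best-model selection.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training cohort")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "best_epoch": 0}
    best = (np.inf, None)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        for idx in order:
            x, y = _as_xy(train_pairs[idx])
            p = model.forward(x, train=True)[0]
            loss = dice_loss(p, y)
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at epoch {epoch}")
            epoch_losses.append(loss)
            opt.zero_grad()
            model.backward(dice_loss_grad(p, y)[None])
            opt.step()
        train_loss = float(np.mean(epoch_losses))
        val_loss = _mean_loss(model, val_pairs) if len(val_pairs) else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.get_weights())
            history["best_epoch"] = epoch
        opt.lr *= config.lr_decay
    if best[1] is not None:
        model.set_weights(best[1])
    return history
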