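"""Hybrid flat + convolutional classifier for inter-ROI distance matrices.

The model consumes a subject's n x n inter-ROI Wasserstein matrix through two
branches: a flat branch (the flattened n^2 vector through one linear layer
down to 256 features, capturing pairwise relationships directly) and a
convolutional branch (three conv layers with 16, 32, 64 filters, a 2x2 max
pool, two more conv layers with 128 and 256 filters — all 3x3 kernels with
"same" padding and ReLU — then global average pooling to 256 features,
capturing local spatial patterns). The two 256-vectors are concatenated and
passed through dense layers of widths 128, 64, 32 with 0.2 dropout each and a
softmax head; training minimizes cross-entropy with early stopping (patience
10) and a seeded random search over learning rate, batch size, validation
split and optimizer (SGD or Adam).

Implemented directly on numpy (forward and backward passes via im2col);
matrices at brain-network scale (n <= 34) keep this comfortably tractable on
one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split


@dataclass
class HybridNetConfig:
    conv_filters_block1: tuple = (16, 32, 64)
    conv_filters_block2: tuple = (128, 256)
    kernel_size: int = 3
    flat_branch_width: int = 256
    dense_widths: tuple = (128, 64, 32)
    dropout: float = 0.2
    early_stopping_patience: int = 10
    max_epochs: int = 100
    lr_range: tuple = (1e-4, 1e-1)
    batch_choices: tuple = (4, 8, 16, 32)
    split_choices: tuple = (0.2, 0.25, 0.3)
    optimizer_choices: tuple = ("sgd", "adam")
    n_trials: int = 20
    test_fraction: float = 0.2
    pool_size: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for w in (*self.conv_filters_block1, *self.conv_filters_block2,
                  self.flat_branch_width, *self.dense_widths):
            if w <= 0:
                raise ValueError("all layer widths must be > 0")


# ---------------------------------------------------------------- layers

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,C,H,W) -> (B, H*W, C*k*k) with same padding."""
    pad = k // 2
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # B,C,H,W,k,k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    pad = k // 2
    B, C, H, W = shape
    d = dcols.reshape(B, H, W, C, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + H, kj:kj + W] += d[:, :, :, :, ki, kj]
    return dxp[:, :, pad:pad + H, pad:pad + W]


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.W = rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x):
        B, C, H, W = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W + self.b  # (B, HW, F)
        self.cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(B, -1, H, W)

    def backward(self, dout):
        cols, shape = self.cache
        B, C, H, W = shape
        dflat = dout.reshape(B, -1, H * W).transpose(0, 2, 1)  # (B,HW,F)
        self.dW = np.einsum("bij,bik->jk", cols, dflat)
        self.db = dflat.sum(axis=(0, 1))
        return _col2im(dflat @ self.W.T, shape, self.k)

    def params(self):
        return {"W": self.W, "b": self.b}


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self.cache = x
        return x @ self.W + self.b

    def backward(self, dout):
        x = self.cache
        self.dW = x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}


def _relu_forward(x):
    return np.maximum(x, 0.0)


def _relu_backward(dout, out):
    return dout * (out > 0)


class _MaxPool:
    def __init__(self, size=2):
        self.size = size

    def forward(self, x):
        s = self.size
        B, C, H, W = x.shape
        Ho, Wo = H // s, W // s
        xc = x[:, :, :Ho * s, :Wo * s]
        xw = xc.reshape(B, C, Ho, s, Wo, s).transpose(0, 1, 2, 4, 3, 5)
        xw = xw.reshape(B, C, Ho, Wo, s * s)
        self.idx = np.argmax(xw, axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(xw, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        s = self.size
        B, C, H, W = self.in_shape
        Ho, Wo = H // s, W // s
        dw = np.zeros((B, C, Ho, Wo, s * s))
        np.put_along_axis(dw, self.idx[..., None], dout[..., None], axis=-1)
        dw = dw.reshape(B, C, Ho, Wo, s, s).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self.in_shape)
        dx[:, :, :Ho * s, :Wo * s] = dw.reshape(B, C, Ho * s, Wo * s)
        return dx


# ---------------------------------------------------------------- model

class HybridNet:
    """Two-branch network over n x n matrices; two-class softmax output."""

    def __init__(self, n: int, config: HybridNetConfig | None = None,
                 seed: int = 0, n_classes: int = 2):
        self.config = config or HybridNetConfig()
        self.config.validate()
        self.n = int(n)
        rng = np.random.default_rng(seed)
        cfg = self.config
        k = cfg.kernel_size
        self.flat = _Dense(n * n, cfg.flat_branch_width, rng)
        self.convs1 = []
        c_in = 1
        for f in cfg.conv_filters_block1:
            self.convs1.append(_Conv(c_in, f, k, rng))
            c_in = f
        self.pool = _MaxPool(cfg.pool_size)
        self.convs2 = []
        for f in cfg.conv_filters_block2:
            self.convs2.append(_Conv(c_in, f, k, rng))
            c_in = f
        concat = cfg.flat_branch_width + cfg.conv_filters_block2[-1]
        self.denses = []
        d_in = concat
        for w in cfg.dense_widths:
            self.denses.append(_Dense(d_in, w, rng))
            d_in = w
        self.head = _Dense(d_in, n_classes, rng)

    # -- plumbing -------------------------------------------------------

    def _layers(self):
        yield "flat", self.flat
        for i, c in enumerate(self.convs1):
            yield f"conv1_{i}", c
        for i, c in enumerate(self.convs2):
            yield f"conv2_{i}", c
        for i, d in enumerate(self.denses):
            yield f"dense_{i}", d
        yield "head", self.head

    def parameters(self) -> dict:
        return {f"{name}.{k}": v
                for name, layer in self._layers()
                for k, v in layer.params().items()}

    def parameter_count(self) -> int:
        return sum(int(v.size) for v in self.parameters().values())

    def get_state(self) -> dict:
        return {k: v.copy() for k, v in self.parameters().items()}

    def set_state(self, state: dict) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k][...] = v

    # -- forward / backward --------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities for X of shape (B, n, n)."""
        B = X.shape[0]
        x2d = X.reshape(B, 1, self.n, self.n)
        cfg = self.config

        flat_out = _relu_forward(self.flat.forward(X.reshape(B, -1)))
        self._flat_out = flat_out

        h = x2d
        self._conv_relu = []
        for c in self.convs1:
            h = _relu_forward(c.forward(h))
            self._conv_relu.append(h)
        h = self.pool.forward(h)
        for c in self.convs2:
            h = _relu_forward(c.forward(h))
            self._conv_relu.append(h)
        self._gap_shape = h.shape
        conv_out = h.mean(axis=(2, 3))

        z = np.concatenate([flat_out, conv_out], axis=1)
        self._drop_masks = []
        self._dense_relu = []
        for d in self.denses:
            z = _relu_forward(d.forward(z))
            self._dense_relu.append(z)
            if train and cfg.dropout > 0:
                mask = (rng.random(z.shape) >= cfg.dropout) / (1 - cfg.dropout)
            else:
                mask = 1.0
            self._drop_masks.append(mask)
            z = z * mask
        logits = self.head.forward(z)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        self._probs = e / e.sum(axis=1, keepdims=True)
        return self._probs

    def backward(self, y: np.ndarray) -> None:
        """Cross-entropy gradient for integer labels y; fills layer grads."""
        B = y.size
        dlogits = self._probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dz = self.head.backward(dlogits)
        for d, relu_out, mask in zip(self.denses[::-1],
                                     self._dense_relu[::-1],
                                     self._drop_masks[::-1]):
            dz = dz * mask
            dz = d.backward(_relu_backward(dz, relu_out))
        width = self.config.flat_branch_width
        dflat, dconv = dz[:, :width], dz[:, width:]

        _, _, H, W = self._gap_shape
        dh = np.broadcast_to(dconv[:, :, None, None] / (H * W),
                             self._gap_shape).copy()
        relu_outs = self._conv_relu
        n1 = len(self.convs1)
        for i, c in enumerate(self.convs2[::-1]):
            dh = c.backward(_relu_backward(dh, relu_outs[len(relu_outs) - 1 - i]))
        dh = self.pool.backward(dh)
        for i, c in enumerate(self.convs1[::-1]):
            dh = c.backward(_relu_backward(dh, relu_outs[n1 - 1 - i]))

        self.flat.backward(_relu_backward(dflat, self._flat_out))

    def gradients(self) -> dict:
        return {f"{name}.{k}": v
                for name, layer in self._layers()
                for k, v in {"W": layer.dW, "b": layer.db}.items()}

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.forward(X, train=False)
        return float(-np.log(probs[np.arange(y.size), y] + 1e-12).mean())

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X, train=False), axis=1)


class _Optimizer:
    def __init__(self, kind: str, lr: float):
        if kind not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        self.kind, self.lr, self.t = kind, lr, 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, p in params.items():
            g = grads[key]
            if self.kind == "sgd":
                p -= self.lr * g
                continue
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= 0.9
            m += 0.1 * g
            v *= 0.999
            v += 0.001 * g * g
            mhat = m / (1 - 0.9 ** self.t)
            vhat = v / (1 - 0.999 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _train(model: HybridNet, X_tr, y_tr, X_val, y_val, lr, batch, optimizer,
           rng, cfg: HybridNetConfig) -> tuple[float, float]:
    """Train with early stopping on validation loss; restores best weights."""
    opt = _Optimizer(optimizer, lr)
    best_loss, best_state, patience = np.inf, model.get_state(), 0
    n = len(y_tr)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            model.forward(X_tr[idx], train=True, rng=rng)
            model.backward(y_tr[idx])
            opt.step(model.parameters(), model.gradients())
        val_loss = model.loss(X_val, y_val)
        if val_loss < best_loss - 1e-6:
            best_loss, best_state, patience = val_loss, model.get_state(), 0
        else:
            patience += 1
            if patience >= cfg.early_stopping_patience:
                break
    model.set_state(best_state)
    val_acc = float(np.mean(model.predict(X_val) == y_val))
    return best_loss, val_acc


def fit_hybrid_net(matrices: dict, labels: dict,
                   config: HybridNetConfig | None = None):
    """Train the hybrid classifier on per-subject inter-ROI matrices.

    Parameters
    ----------
    matrices : subject -> n x n ndarray (or DistanceMatrix with .values).
    labels : subject -> class label (exactly two classes).
    config : HybridNetConfig; ``seed`` drives the test split, the
        hyperparameter search, weight initialization and batching.

    Returns (model, report). A stratified ``test_fraction`` of subjects is
    held out up front (splits are by subject identifier, and each subject
    contributes exactly one matrix); the seeded random search samples
    learning rate (log-uniform over ``lr_range``), batch size, validation
    split and optimizer for ``n_trials`` trials, each trained with early
    stopping; the best trial by validation accuracy is evaluated once on the
    held-out subjects.
    """
    config = config or HybridNetConfig()
    config.validate()
    subjects = list(matrices)
    arrays = []
    for s in subjects:
        m = matrices[s]
        arrays.append(np.asarray(getattr(m, "values", m), dtype=float))
    sizes = {a.shape for a in arrays}
    if len(sizes) != 1 or arrays[0].ndim != 2 \
            or arrays[0].shape[0] != arrays[0].shape[1]:
        raise ValueError(f"matrices must share one square size, got {sizes}")
    n = arrays[0].shape[0]
    y_raw = np.array([labels[s] for s in subjects])
    classes = np.unique(y_raw)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    y = np.searchsorted(classes, y_raw)
    X = np.stack(arrays)

    idx = np.arange(len(subjects))
    tr_idx, te_idx = train_test_split(
        idx, test_size=config.test_fraction, stratify=y,
        random_state=config.seed,
    )
    mu, sd = X[tr_idx].mean(), X[tr_idx].std() or 1.0
    Xn = (X - mu) / sd

    rng = np.random.default_rng(config.seed)
    trials = []
    best = None
    for t in range(config.n_trials):
        lo, hi = np.log10(config.lr_range[0]), np.log10(config.lr_range[1])
        lr = float(10 ** rng.uniform(lo, hi))
        batch = int(rng.choice(config.batch_choices))
        split = float(rng.choice(config.split_choices))
        optimizer = str(rng.choice(config.optimizer_choices))
        inner_seed = int(rng.integers(2 ** 31))
        tr2, val = train_test_split(tr_idx, test_size=split,
                                    stratify=y[tr_idx],
                                    random_state=inner_seed)
        model = HybridNet(n, config, seed=inner_seed)
        _, val_acc = _train(model, Xn[tr2], y[tr2], Xn[val], y[val], lr,
                            batch, optimizer, np.random.default_rng(inner_seed),
                            config)
        trial = {"lr": lr, "batch": batch, "split": split,
                 "optimizer": optimizer, "val_accuracy": val_acc}
        trials.append(trial)
        if best is None or val_acc > best[0]:
            best = (val_acc, model, trial)
    _, model, best_trial = best
    acc = float(np.mean(model.predict(Xn[te_idx]) == y[te_idx]))
    report = {
        "classes": [str(c) for c in classes],
        "n_subjects": len(subjects),
        "matrix_size": n,
        "n_test": int(len(te_idx)),
        "trials": trials,
        "best_trial": best_trial,
        "held_out_accuracy": acc,
        "parameter_count": model.parameter_count(),
        "seed": config.seed,
    }
    return model, report
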