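"""Compact convolutional network for scalogram classification, in numpy.

The classifier follows the lightweight design used for small medical image
sets: three Conv(3x3, 'same')-BatchNorm-ReLU-MaxPool(2x2) blocks with 16, 32
and 64 filters, a Dropout(0.4) layer, and one fully connected layer feeding a
two-class softmax (HC vs OA).  Training uses Adam (step 1e-3) with L2 weight
regularization (0.01), minibatches of 32 and on-the-fly augmentation of the
training split (rotation +/-10 deg, scaling 90-110%, translation +/-5 px,
horizontal flip).  Evaluation is stratified k-fold CV with an asymmetric
decision rule: a case is called HC only when P(HC) >= 0.7, otherwise OA —
misclassifying a diseased joint as healthy is the costlier error.

All layers (im2col convolution, batch norm, pooling, dropout, dense, softmax
cross-entropy, Adam) are implemented here in numpy with explicit forward and
backward passes; every stochastic element is driven by one seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from sklearn.model_selection import StratifiedKFold

from .classify import CvReport, metrics_from_confusion, roc_auc

__all__ = [
    "CnnConfig",
    "AugmentationSpec",
    "CompactCnn",
    "build_model",
    "apply_threshold",
    "train_cv",
]


@dataclass(frozen=True)
class CnnConfig:
    filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3
    pool: int = 2
    dropout: float = 0.4
    epochs: int = 30
    batch: int = 32
    l2: float = 0.01
    lr: float = 1e-3
    hc_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.filters[0] < self.filters[1] < self.filters[2]):
            raise ValueError("filter counts must be strictly increasing")
        for name in ("dropout", "hc_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.epochs, self.batch) < 1 or min(self.l2, self.lr) < 0:
            raise ValueError("hyperparameters must be positive")


@dataclass(frozen=True)
class AugmentationSpec:
    rotation_deg: float = 10.0
    scale_lo: float = 0.9
    scale_hi: float = 1.1
    translate_px: float = 5.0
    hflip: bool = True


def apply_threshold(p_hc: float, cutoff: float = 0.7) -> str:
    """HC iff P(HC) >= cutoff, else OA (strictly-below goes to the OA class)."""
    if not 0.0 <= p_hc <= 1.0:
        raise ValueError("probability outside [0, 1]")
    return "HC" if p_hc >= cutoff else "OA"


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patches with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, H, W, C, k, k) -> (N, H, W, k, k, C)
    win = win.transpose(0, 1, 2, 4, 5, 3)
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win).reshape(n * h * w, k * k * x.shape[3])


class _Conv:
    """3x3 'same' convolution via im2col and a single BLAS matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.shape = x.shape
        self.col = _im2col(x, self.k)
        n, h, w, _ = x.shape
        out = self.col @ self.W + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c_out = dout.shape
        dflat = dout.reshape(-1, c_out)
        self.dW = self.col.T @ dflat
        self.db = dflat.sum(axis=0)
        dcol = dflat @ self.W.T
        # fold columns back: add each kernel tap's contribution into place
        k, p = self.k, self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32)
        dcol = dcol.reshape(n, h, w, k, k, self.c_in)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _BatchNorm:
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.x_hat = (x - mean) * self.inv_std
        return self.gamma * self.x_hat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        m = dout.size // dout.shape[-1]
        self.dgamma = (dout * self.x_hat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        return (
            dxhat - dxhat.mean(axis=axes) - self.x_hat * (dxhat * self.x_hat).mean(axis=axes)
        ) * self.inv_std

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask

    def params(self):
        return []


class _MaxPool:
    def __init__(self, k: int = 2):
        self.k = k

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.k
        xr = x.reshape(n, h // k, k, w // k, k, c)
        out = xr.max(axis=(2, 4))
        self.mask = xr == out[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.k
        d = self.mask * dout[:, :, None, :, None, :]
        n, hk, _, wk, _, c = d.shape
        return d.reshape(n, hk * k, wk * k, c)

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self.mask = None
            return x
        keep = 1.0 - self.rate
        self.mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self.mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self.mask is None else dout * self.mask

    def params(self):
        return []


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self.in_shape = x.shape
        self.flat = x.reshape(x.shape[0], -1)
        return self.flat @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self.flat.T @ dout
        self.db = dout.sum(axis=0)
        return (dout @ self.W.T).reshape(self.in_shape)

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CompactCnn:
    """Three conv blocks -> dropout -> dense -> softmax over {HC, OA}."""

    RESOLUTIONS = (128, 256)

    def __init__(self, config: CnnConfig, resolution: int, channels: int = 3):
        if resolution not in self.RESOLUTIONS:
            raise ValueError(f"resolution must be one of {self.RESOLUTIONS}")
        self.config = config
        self.resolution = resolution
        rng = np.random.default_rng(config.seed)
        self.dropout_rng = np.random.default_rng(config.seed + 1)
        layers: list = []
        c_in = channels
        for c_out in config.filters:
            layers += [
                _Conv(c_in, c_out, config.kernel, rng),
                _BatchNorm(c_out),
                _ReLU(),
                _MaxPool(config.pool),
            ]
            c_in = c_out
        layers.append(_Dropout(config.dropout, self.dropout_rng))
        spatial = resolution // config.pool ** len(config.filters)
        layers.append(_Dense(spatial * spatial * c_in, 2, rng))
        self.layers = layers
        self._adam_state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0

    @property
    def n_parameters(self) -> int:
        return sum(p[1].size for layer in self.layers for p in layer.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32)
        for layer in self.layers:
            out = layer.forward(out, train)
        return _softmax(out)

    def train_batch(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs = self.forward(x, train=True)
        n = x.shape[0]
        loss = float(-np.mean(np.sum(y_onehot * np.log(probs + 1e-12), axis=1)))
        dout = (probs - y_onehot).astype(np.float32) / n
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        self._adam_step()
        return loss

    def _adam_step(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        cfg = self.config
        self._adam_t += 1
        t = self._adam_t
        for li, layer in enumerate(self.layers):
            state = self._adam_state.setdefault(li, {})
            for name, param, grad_name in layer.params():
                grad = getattr(layer, grad_name).astype(np.float32)
                if name == "W":  # L2 penalty on weights only
                    grad = grad + cfg.l2 * param
                if name not in state:
                    state[name] = (np.zeros_like(param), np.zeros_like(param))
                m, v = state[name]
                m[:] = beta1 * m + (1 - beta1) * grad
                v[:] = beta2 * v + (1 - beta2) * grad**2
                m_hat = m / (1 - beta1**t)
                v_hat = v / (1 - beta2**t)
                param -= cfg.lr * m_hat / (np.sqrt(v_hat) + eps)

    def predict_proba(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        """Class probabilities, column 0 = HC, column 1 = OA."""
        out = []
        for i in range(0, x.shape[0], batch):
            out.append(self.forward(x[i : i + batch], train=False))
        return np.concatenate(out, axis=0)


def build_model(config: CnnConfig, input_resolution: int, channels: int = 3) -> CompactCnn:
    return CompactCnn(config, input_resolution, channels)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _augment_image(img: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator) -> np.ndarray:
    """Random rotation/scale/translation/flip of one (H, W, C) image."""
    angle = np.deg2rad(rng.uniform(-spec.rotation_deg, spec.rotation_deg))
    scale = rng.uniform(spec.scale_lo, spec.scale_hi)
    tx = rng.uniform(-spec.translate_px, spec.translate_px)
    ty = rng.uniform(-spec.translate_px, spec.translate_px)
    flip = spec.hflip and rng.random() < 0.5
    c, s = np.cos(angle), np.sin(angle)
    # output -> input mapping: rotate by -angle, divide by scale
    m = np.array([[c, -s], [s, c]]) / scale
    if flip:
        m = m @ np.diag([1.0, -1.0])
    center = (np.array(img.shape[:2]) - 1) / 2.0
    offset = center - m @ (center + np.array([ty, tx]))
    out = np.empty_like(img)
    for ch in range(img.shape[2]):
        out[:, :, ch] = affine_transform(
            img[:, :, ch], m, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out


# ---------------------------------------------------------------------------
# cross-validated training
# ---------------------------------------------------------------------------


def train_cv(
    images: np.ndarray,
    labels: np.ndarray,
    config: CnnConfig,
    augmentation: AugmentationSpec | None = AugmentationSpec(),
    k: int = 5,
) -> CvReport:
    """Stratified k-fold CV of the compact CNN.

    ``images`` is (N, H, W, 3) in [0, 1] (or uint8, rescaled internally);
    ``labels`` holds "HC"/"OA" strings.  Training folds are augmented on the
    fly; validation folds are never touched.  The decision rule calls HC only
    when P(HC) >= ``config.hc_threshold``; AUC uses the raw P(OA) scores with
    OA as the positive class.
    """
    images = np.asarray(images)
    if images.dtype == np.uint8:
        images = images.astype(np.float32) / 255.0
    images = images.astype(np.float32)
    labels = np.asarray(labels)
    y_oa = (labels == "OA").astype(int)
    if y_oa.min() == y_oa.max():
        raise ValueError("both classes must be present")
    if min(np.bincount(y_oa)) < k:
        raise ValueError(f"each class needs at least k={k} samples")

    rng = np.random.default_rng(config.seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    rows, confusions, all_scores, all_truth = [], [], [], []
    for fold, (tr, te) in enumerate(skf.split(images, y_oa)):
        model = CompactCnn(
            CnnConfig(**{**config.__dict__, "seed": config.seed + fold}),
            resolution=images.shape[1],
            channels=images.shape[3],
        )
        x_tr, y_tr = images[tr], y_oa[tr]
        onehot = np.eye(2, dtype=np.float32)[y_tr]  # column 0 = HC, 1 = OA
        idx = np.arange(x_tr.shape[0])
        for _ in range(config.epochs):
            rng.shuffle(idx)
            for start in range(0, idx.size, config.batch):
                sel = idx[start : start + config.batch]
                batch = x_tr[sel]
                if augmentation is not None:
                    batch = np.stack(
                        [_augment_image(im, augmentation, rng) for im in batch]
                    )
                model.train_batch(batch, onehot[sel])
        probs = model.predict_proba(images[te])
        p_hc = probs[:, 0]
        pred_oa = np.array(
            [apply_threshold(p, config.hc_threshold) == "OA" for p in p_hc], dtype=int
        )
        truth = y_oa[te]
        tp = int(np.sum((pred_oa == 1) & (truth == 1)))
        fn = int(np.sum((pred_oa == 0) & (truth == 1)))
        tn = int(np.sum((pred_oa == 0) & (truth == 0)))
        fp = int(np.sum((pred_oa == 1) & (truth == 0)))
        m = metrics_from_confusion(tp, fn, tn, fp)
        m["auc"], _ = roc_auc(1.0 - p_hc, truth)
        m["fold"] = fold
        rows.append(m)
        confusions.append((tp, fn, tn, fp))
        all_scores.append(1.0 - p_hc)
        all_truth.append(truth)
    _, roc_points = roc_auc(np.concatenate(all_scores), np.concatenate(all_truth))
    return CvReport(folds=pd.DataFrame(rows), confusions=confusions, roc_points=roc_points)
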