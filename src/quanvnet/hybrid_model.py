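"""Hybrid quantum-classical classifier.

The quanvolutional feature map (per-qubit <Z> expectations over 2x2
patches) feeds a small classical convolutional head: conv blocks with ReLU
and max-pooling, a flatten, hidden dense layers, and a softmax output.
Quantum angles and classical weights are optimized jointly by mini-batch
gradient descent on the categorical cross-entropy.

Gradients with respect to the quantum angles use the parameter-shift rule

    d f / d theta = [f(theta + pi/2) - f(theta - pi/2)] / 2,

which is exact for Pauli-rotation generators, so the quantum gradient is
implementation-independent and checkable against finite differences.
Classical gradients are ordinary backpropagation, written against plain
numpy so the whole model is deterministic given a seed.

Default head (sizes are package choices; the architecture family —
conv/ReLU/max-pool/flatten/dense/softmax — is fixed): one conv block of
8 3x3 filters with 2x2 max-pooling, dense(32, ReLU), dense(n_classes,
softmax). Optimizers: adam, sgd, rmsprop, adamax with standard update
rules; only the learning rate (default 0.001) and epochs (default 40)
are first-class knobs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .quanvolution import (
    N_QUBITS,
    PatchVector,
    VariationalParams,
    image_to_phis,
    quanvolve_patch,
    quanvolve_phis,
)

__all__ = [
    "ClassifierConfig",
    "HybridModel",
    "init_hybrid_model",
    "forward",
    "predict",
    "train",
    "quantum_gradient",
    "save_model",
    "load_model",
]

_OPTIMIZERS = ("adam", "sgd", "rmsprop", "adamax")
_SHIFT = np.pi / 2


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters for the classical head."""

    n_classes: int = 3
    conv_blocks: list = field(default_factory=lambda: [(8, 3, 2)])
    dense_units: list = field(default_factory=lambda: [32])
    optimizer: str = "adam"
    learning_rate: float = 0.001
    epochs: int = 40
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in _OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {_OPTIMIZERS}"
            )
        self.conv_blocks = [tuple(int(v) for v in b) for b in self.conv_blocks]
        self.dense_units = [int(u) for u in self.dense_units]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class HybridModel:
    """Jointly trainable quantum angles + classical head weights."""

    params: VariationalParams
    weights: dict
    config: ClassifierConfig
    image_shape: tuple[int, int]

    @property
    def feature_shape(self) -> tuple[int, int, int]:
        h, w = self.image_shape
        return (h // 2, w // 2, N_QUBITS)

    @property
    def n_quantum_params(self) -> int:
        return int(self.params.theta.size)

    @property
    def n_classical_params(self) -> int:
        return int(sum(w.size for w in self.weights.values()))


def _init_classical(
    config: ClassifierConfig, feature_shape: tuple[int, int, int], rng: np.random.Generator
) -> dict:
    """Seeded uniform init scaled by fan-in for every layer."""
    weights: dict = {}
    h, w, c = feature_shape
    for b, (filters, kernel, pool) in enumerate(config.conv_blocks):
        if h < kernel or w < kernel:
            raise ValueError(
                f"feature map {h}x{w} too small for a {kernel}x{kernel} conv"
            )
        fan_in = kernel * kernel * c
        s = np.sqrt(1.0 / fan_in)
        weights[f"conv{b}_W"] = rng.uniform(-s, s, size=(kernel, kernel, c, filters))
        weights[f"conv{b}_b"] = np.zeros(filters)
        h, w, c = h - kernel + 1, w - kernel + 1, filters
        h, w = h // pool, w // pool
        if h < 1 or w < 1:
            raise ValueError("pooling collapsed the feature map to zero size")
    n_in = h * w * c
    for d, units in enumerate(config.dense_units):
        s = np.sqrt(1.0 / n_in)
        weights[f"dense{d}_W"] = rng.uniform(-s, s, size=(n_in, units))
        weights[f"dense{d}_b"] = np.zeros(units)
        n_in = units
    s = np.sqrt(1.0 / n_in)
    weights["out_W"] = rng.uniform(-s, s, size=(n_in, config.n_classes))
    weights["out_b"] = np.zeros(config.n_classes)
    return weights


def init_hybrid_model(
    config: ClassifierConfig,
    image_shape: tuple[int, int],
    entangler: str = "CZ",
    n_layers: int = 1,
) -> HybridModel:
    """Seeded initialization: theta ~ U[-pi, pi), classical weights by fan-in."""
    h, w = image_shape
    if h % 2 or w % 2:
        raise ValueError(f"image dimensions must be even, got {image_shape}")
    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(-np.pi, np.pi, size=(n_layers, N_QUBITS, 3))
    params = VariationalParams(theta, entangler)
    weights = _init_classical(config, (h // 2, w // 2, N_QUBITS), rng)
    return HybridModel(params, weights, config, (h, w))


# ---------------------------------------------------------------------------
# classical head: forward / backward
# ---------------------------------------------------------------------------


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    kh, kw = W.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # win: (B, Ho, Wo, C, kh, kw)
    out = np.einsum("bxyckl,klcf->bxyf", win, W) + b
    return out, win


def _conv_backward(win, W, dout):
    kh, kw = W.shape[:2]
    dW = np.einsum("bxyckl,bxyf->klcf", win, dout)
    db = dout.sum(axis=(0, 1, 2))
    B, Ho, Wo, _ = dout.shape
    C = W.shape[2]
    dx = np.zeros((B, Ho + kh - 1, Wo + kw - 1, C))
    for k in range(kh):
        for l in range(kw):
            dx[:, k : k + Ho, l : l + Wo, :] += np.einsum(
                "bxyf,cf->bxyc", dout, W[k, l]
            )
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int):
    B, H, W, C = x.shape
    Ho, Wo = H // p, W // p
    xr = (
        x[:, : Ho * p, : Wo * p, :]
        .reshape(B, Ho, p, Wo, p, C)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(B, Ho, Wo, p * p, C)
    )
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (idx, x.shape, p)


def _pool_backward(cache, dout):
    idx, xshape, p = cache
    B, H, W, C = xshape
    Ho, Wo = H // p, W // p
    dxr = np.zeros((B, Ho, Wo, p * p, C))
    np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = np.zeros(xshape)
    dx[:, : Ho * p, : Wo * p, :] = (
        dxr.reshape(B, Ho, Wo, p, p, C).transpose(0, 1, 3, 2, 4, 5).reshape(B, Ho * p, Wo * p, C)
    )
    return dx


def _head_forward(features: np.ndarray, model: HybridModel):
    """Forward pass of the classical head with a cache for backprop."""
    cfg, W = model.config, model.weights
    x = features
    cache = {"blocks": []}
    for b, (_, _, pool) in enumerate(cfg.conv_blocks):
        pre, win = _conv_forward(x, W[f"conv{b}_W"], W[f"conv{b}_b"])
        act = np.maximum(pre, 0.0)
        x, pcache = _pool_forward(act, pool)
        cache["blocks"].append((win, pre, pcache))
    cache["flat_shape"] = x.shape
    x = x.reshape(x.shape[0], -1)
    cache["dense"] = []
    for d in range(len(cfg.dense_units)):
        pre = x @ W[f"dense{d}_W"] + W[f"dense{d}_b"]
        cache["dense"].append((x, pre))
        x = np.maximum(pre, 0.0)
    logits = x @ W["out_W"] + W["out_b"]
    cache["out_in"] = x
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs, cache


def _head_backward(probs, labels, cache, model: HybridModel):
    """Cross-entropy backprop: returns weight grads and d(loss)/d(features)."""
    cfg, W = model.config, model.weights
    B = probs.shape[0]
    grads = {}
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    grads["out_W"] = cache["out_in"].T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    dx = dlogits @ W["out_W"].T
    for d in reversed(range(len(cfg.dense_units))):
        xin, pre = cache["dense"][d]
        dpre = dx * (pre > 0)
        grads[f"dense{d}_W"] = xin.T @ dpre
        grads[f"dense{d}_b"] = dpre.sum(axis=0)
        dx = dpre @ W[f"dense{d}_W"].T
    dx = dx.reshape(cache["flat_shape"])
    for b in reversed(range(len(cfg.conv_blocks))):
        win, pre, pcache = cache["blocks"][b]
        dact = _pool_backward(pcache, dx)
        dpre = dact * (pre > 0)
        dx, dW, db = _conv_backward(win, W[f"conv{b}_W"], dpre)
        grads[f"conv{b}_W"] = dW
        grads[f"conv{b}_b"] = db
    return grads, dx  # dx: d(loss)/d(feature map)


# ---------------------------------------------------------------------------
# quantum feature pass
# ---------------------------------------------------------------------------


def _batch_phis(images: np.ndarray) -> np.ndarray:
    """(B, H, W) stack -> (B, P, 4) patch vectors."""
    return np.stack([image_to_phis(img) for img in images])


def _features_from_phis(phis: np.ndarray, params: VariationalParams, fshape) -> np.ndarray:
    B = phis.shape[0]
    flat = quanvolve_phis(phis.reshape(-1, 4), params)
    return flat.reshape(B, *fshape)


def forward(model: HybridModel, images: np.ndarray) -> np.ndarray:
    """Class probabilities, one row per image; rows sum to 1."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != model.image_shape:
        raise ValueError(
            f"images of shape {images.shape[1:]} do not match the model's "
            f"expected {model.image_shape}"
        )
    feats = _features_from_phis(_batch_phis(images), model.params, model.feature_shape)
    probs, _ = _head_forward(feats, model)
    return probs


def predict(model: HybridModel, images: np.ndarray) -> np.ndarray:
    """Argmax class labels; ties resolve to the lowest class index."""
    return np.argmax(forward(model, images), axis=1)


def quantum_gradient(
    patch: PatchVector, params: VariationalParams, l: int, i: int, k: int
) -> np.ndarray:
    """Parameter-shift gradient of the 4 patch features w.r.t. theta[l][i][k].

    ``l`` is 1-based (matching the layer indexing); ``i`` and ``k`` are
    0-based qubit and axis indices.
    """
    if not 1 <= l <= params.n_layers:
        raise ValueError(f"layer index {l} out of range 1..{params.n_layers}")
    if not 0 <= i < N_QUBITS or not 0 <= k < 3:
        raise ValueError(f"qubit/axis index out of range: i={i}, k={k}")
    plus = params.theta.copy()
    minus = params.theta.copy()
    plus[l - 1, i, k] += _SHIFT
    minus[l - 1, i, k] -= _SHIFT
    f_plus = quanvolve_patch(patch, params.with_theta(plus))
    f_minus = quanvolve_patch(patch, params.with_theta(minus))
    return (f_plus - f_minus) / 2.0


class _Optimizer:
    """Standard first-order update rules over a flat dict of arrays."""

    def __init__(self, kind: str, lr: float):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.state: dict = {}
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.rho = 0.9

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            p = params[key]
            if self.kind == "sgd":
                p -= self.lr * g
                continue
            st = self.state.setdefault(key, {})
            if self.kind == "rmsprop":
                v = st.get("v", np.zeros_like(g))
                v = self.rho * v + (1 - self.rho) * g * g
                st["v"] = v
                p -= self.lr * g / (np.sqrt(v) + self.eps)
            elif self.kind == "adam":
                m = st.get("m", np.zeros_like(g))
                v = st.get("v", np.zeros_like(g))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g * g
                st["m"], st["v"] = m, v
                mh = m / (1 - self.beta1**self.t)
                vh = v / (1 - self.beta2**self.t)
                p -= self.lr * mh / (np.sqrt(vh) + self.eps)
            elif self.kind == "adamax":
                m = st.get("m", np.zeros_like(g))
                u = st.get("u", np.zeros_like(g))
                m = self.beta1 * m + (1 - self.beta1) * g
                u = np.maximum(self.beta2 * u, np.abs(g))
                st["m"], st["u"] = m, u
                p -= (self.lr / (1 - self.beta1**self.t)) * m / (u + self.eps)
            else:  # pragma: no cover - guarded by ClassifierConfig
                raise ValueError(f"unknown optimizer {self.kind!r}")


def _xent(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def train(
    model: HybridModel,
    images: np.ndarray,
    labels: np.ndarray,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
    frozen_quantum: bool = False,
) -> list[dict]:
    """Jointly train quantum angles and classical weights in place.

    Returns the per-epoch history (loss/accuracy, plus val_loss/val_accuracy
    when a validation set is supplied). Fully reproducible given
    ``model.config.seed``. ``frozen_quantum=True`` skips the quantum
    updates, reducing the extractor to a fixed random quanvolution.
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    cfg = model.config
    if labels.min() < 0 or labels.max() >= cfg.n_classes:
        raise ValueError(f"labels must be in 0..{cfg.n_classes - 1}")
    n = len(images)
    rng = np.random.default_rng(cfg.seed)
    opt = _Optimizer(cfg.optimizer, cfg.learning_rate)
    phis_all = _batch_phis(images)  # patch decomposition is theta-independent
    fshape = model.feature_shape
    theta_shape = model.params.theta.shape
    history = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            phis = phis_all[sel]
            y = labels[sel]
            feats = _features_from_phis(phis, model.params, fshape)
            probs, cache = _head_forward(feats, model)
            loss = _xent(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}: {loss}; "
                    "lower the learning rate"
                )
            epoch_loss += loss * len(sel)
            epoch_correct += int((np.argmax(probs, axis=1) == y).sum())
            grads, dfeat = _head_backward(probs, y, cache, model)
            theta_mutable = model.params.theta.copy()
            if not frozen_quantum:
                gtheta = np.zeros(theta_shape)
                for flat in range(theta_mutable.size):
                    l, i, k = np.unravel_index(flat, theta_shape)
                    plus = theta_mutable.copy()
                    minus = theta_mutable.copy()
                    plus[l, i, k] += _SHIFT
                    minus[l, i, k] -= _SHIFT
                    fp = _features_from_phis(phis, model.params.with_theta(plus), fshape)
                    fm = _features_from_phis(phis, model.params.with_theta(minus), fshape)
                    gtheta[l, i, k] = float(np.sum(dfeat * (fp - fm) / 2.0))
                grads = dict(grads)
                grads["theta"] = gtheta
            tensors = dict(model.weights)
            tensors["theta"] = theta_mutable
            opt.step(tensors, grads)
            model.params = model.params.with_theta(tensors["theta"])
        record = {
            "epoch": epoch + 1,
            "loss": epoch_loss / n,
            "accuracy": epoch_correct / n,
        }
        if val_images is not None and val_labels is not None:
            vprobs = forward(model, val_images)
            record["val_loss"] = _xent(vprobs, np.asarray(val_labels, dtype=int))
            record["val_accuracy"] = float(
                np.mean(np.argmax(vprobs, axis=1) == np.asarray(val_labels))
            )
        history.append(record)
    return history


def save_model(path: str | Path, model: HybridModel) -> None:
    """NPZ checkpoint: all classical weights, theta, and a config echo."""
    np.savez(
        path,
        theta=model.params.theta,
        entangler=np.array(model.params.entangler),
        image_shape=np.array(model.image_shape),
        config_json=np.array(json.dumps(model.config.to_dict())),
        **{f"w_{k}": v for k, v in model.weights.items()},
    )


def load_model(path: str | Path) -> HybridModel:
    with np.load(path, allow_pickle=False) as data:
        config = ClassifierConfig(**json.loads(str(data["config_json"])))
        params = VariationalParams(data["theta"], str(data["entangler"]))
        weights = {
            k[2:]: data[k] for k in data.files if k.startswith("w_")
        }
        image_shape = tuple(int(v) for v in data["image_shape"])
    return HybridModel(params, weights, config, image_shape)
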