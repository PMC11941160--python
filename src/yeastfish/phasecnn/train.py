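"""Training loop: focal loss, class-balanced batches, augmentation, Adam.

Class imbalance (G1 dominates asynchronous cultures) is handled twice:
batches draw the nine classes uniformly with replacement, and focal loss
down-weights easy examples.  Augmentation applies right-angle rotations,
flips and per-channel gain ("saturation") and contrast jitter on the fly;
with a fixed seed the entire run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from yeastfish.phasecnn import layers as L
from yeastfish.phasecnn.model import CnnConfig


def focal_loss(
    scores: np.ndarray, truth: int, alpha: float = 1.0, gamma: float = 2.0
) -> float:
    """FL = -alpha * (1 - p_t)**gamma * log(p_t) for one probability vector.

    gamma = 0, alpha = 1 reduces to cross-entropy; p_t is clamped away from
    zero so a confidently wrong prediction yields a large finite loss.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 1 or not np.isclose(scores.sum(), 1.0, atol=1e-6) or (scores < 0).any():
        raise ValueError("scores must be a probability vector")
    p_t = max(float(scores[truth]), 1e-12)
    return float(-alpha * (1.0 - p_t) ** gamma * np.log(p_t))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss_batch(
    logits: np.ndarray, targets: np.ndarray, alpha: float, gamma: float
) -> tuple[float, np.ndarray]:
    """Mean focal loss and its gradient w.r.t. the logits.

    With p = softmax(z) and t the true class,
    dL/dz_j = dL/dp_t * p_t * (delta_tj - p_j), where
    dL/dp_t = alpha * (gamma * (1-p_t)**(gamma-1) * log(p_t) - (1-p_t)**gamma / p_t).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    p_t = np.clip(p[np.arange(n), targets], 1e-12, 1.0)
    one_m = 1.0 - p_t
    loss = float(np.mean(-alpha * one_m**gamma * np.log(p_t)))
    if gamma == 0:
        dl_dpt = -alpha / p_t
    else:
        dl_dpt = alpha * (gamma * one_m ** (gamma - 1) * np.log(p_t) - one_m**gamma / p_t)
    grad = -p * (dl_dpt * p_t)[:, None]
    grad[np.arange(n), targets] += dl_dpt * p_t
    return loss, (grad / n).astype(np.float32)


def augment_batch(
    x: np.ndarray, rng: np.random.Generator, gain: float = 0.2, contrast: float = 0.2
) -> np.ndarray:
    """Right-angle rotations, flips, per-channel gain and contrast jitter.

    x is NCHW in [0, 1]; jittered values are clipped back to [0, 1].
    """
    out = x.copy()
    n = len(out)
    k_rot = rng.integers(0, 4, n)
    do_h = rng.random(n) < 0.5
    do_v = rng.random(n) < 0.5
    g = rng.uniform(1 - gain, 1 + gain, (n, out.shape[1], 1, 1)).astype(np.float32)
    c = rng.uniform(1 - contrast, 1 + contrast, (n, 1, 1, 1)).astype(np.float32)
    for i in range(n):
        if k_rot[i]:
            out[i] = np.rot90(out[i], k_rot[i], axes=(1, 2))
        if do_h[i]:
            out[i] = out[i][:, :, ::-1]
        if do_v[i]:
            out[i] = out[i][:, ::-1, :]
    out *= g
    mean = out.mean(axis=(2, 3), keepdims=True)
    out = (out - mean) * c + mean
    return np.clip(out, 0.0, 1.0)


def balanced_batches(
    y: np.ndarray,
    n_batches: int,
    batch_size: int,
    n_classes: int,
    rng: np.random.Generator,
):
    """Yield index batches with classes drawn uniformly with replacement."""
    by_class = [np.flatnonzero(y == c) for c in range(n_classes)]
    for c, idx in enumerate(by_class):
        if len(idx) == 0:
            from yeastfish.exceptions import ConfigurationError
            from yeastfish.phasecnn.model import CLASSES

            raise ConfigurationError(f"class {CLASSES[c]!r} has no training examples")
    for _ in range(n_batches):
        classes = rng.integers(0, n_classes, batch_size)
        yield np.array(
            [by_class[c][rng.integers(0, len(by_class[c]))] for c in classes]
        )


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def train(
    model: L.Sequential,
    x: np.ndarray,
    y: np.ndarray,
    cfg: CnnConfig | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Train in place; returns per-epoch mean loss and batch accuracy.

    ``x`` may be NHWC (as composites are stored) or NCHW; one epoch is
    ceil(n / batch_size) balanced batches.
    """
    cfg = cfg or model.config
    if x.ndim != 4:
        raise ValueError("x must be a 4-D array of composites")
    if x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    x = np.ascontiguousarray(x, dtype=np.float32)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed + 1)
    for layer in model.layers:  # reseed dropout for reproducible runs
        if isinstance(layer, L.Dropout):
            layer.rng = np.random.default_rng(cfg.seed + 2)
    optimizer = L.Adam(model.params(), lr=cfg.learning_rate)
    n_batches = max(1, int(np.ceil(len(x) / cfg.batch_size)))
    history = TrainHistory()
    for epoch in range(cfg.epochs):
        losses, accs = [], []
        for idx in balanced_batches(y, n_batches, cfg.batch_size, cfg.n_classes, rng):
            xb, yb = x[idx], y[idx]
            if cfg.augment:
                xb = augment_batch(xb, rng)
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogits = focal_loss_batch(logits, yb, cfg.focal_alpha, cfg.focal_gamma)
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
            accs.append(float((logits.argmax(axis=1) == yb).mean()))
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(float(np.mean(accs)))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  loss {history.loss[-1]:.4f}  "
                  f"acc {history.accuracy[-1]:.3f}")
    return history
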