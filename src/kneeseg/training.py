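"""Loss functions and the training harness for the two U-net models.

The segmentation model minimizes soft Dice (negative Dice) and the
detection model minimizes per-pixel binary cross-entropy, both on
sigmoid probability maps.  Training uses Adam (defaults lr 1e-5, batch
16, at most 300 epochs) with early stopping: when the monitored
validation quantity — case-pooled Dice for segmentation, per-slice
detection accuracy for detection — fails to improve for ``patience``
consecutive epochs, training halts and the best epoch's weights are
restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .unet import UNet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "EarlyStopping",
    "soft_dice_loss",
    "binary_cross_entropy_loss",
    "train_model",
]

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 35  # epochs without improvement before stopping (range 30-40)
    loss: str = "soft_dice"  # or "binary_cross_entropy"
    monitor: str = "val_dice"  # or "val_accuracy"
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.loss not in {"soft_dice", "binary_cross_entropy"}:
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.monitor not in {"val_dice", "val_accuracy"}:
            raise ValueError(f"unknown monitor {self.monitor!r}")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)  # {"epoch", "train_loss", "monitor"}
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.epochs).to_csv(path, index=False)


class EarlyStopping:
    """Stop after ``patience`` epochs without strict improvement (maximized metric)."""

    def __init__(self, patience: int):
        self.patience = int(patience)
        self.best = -np.inf
        self.best_epoch = 0
        self._since = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record the epoch's monitored value; True means stop now."""
        if value > self.best:
            self.best = value
            self.best_epoch = epoch
            self._since = 0
            return False
        self._since += 1
        return self._since >= self.patience


# ---------------------------------------------------------------------------
# losses


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1.0) -> float:
    """Negative soft Dice: -(2*sum(p*t) + eps) / (sum(p) + sum(t) + eps).

    ``eps`` smooths the empty/empty case to a perfect -1 and keeps the
    loss differentiable; the range is (-1, 0].  On binary predictions
    this approaches minus the Dice coefficient as eps -> 0.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    num = 2.0 * float((pred * target).sum()) + eps
    den = float(pred.sum()) + float(target.sum()) + eps
    return -num / den


def binary_cross_entropy_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Pixel-mean BCE with predictions clipped to [1e-7, 1 - 1e-7]."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).mean())


def _batch_loss_and_dlogits(p: np.ndarray, t: np.ndarray, loss: str, eps: float = 1.0):
    """Mean per-sample loss over the batch and its gradient w.r.t. logits."""
    n = p.shape[0]
    if loss == "binary_cross_entropy":
        pc = np.clip(p, _BCE_EPS, 1.0 - _BCE_EPS)
        value = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
        # d(mean BCE)/dz through the sigmoid is (p - t) / n_pixels
        return value, (p - t) / p.size
    # soft dice, averaged per sample
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (p * t).sum(axis=axes) + eps  # (n,)
    den = p.sum(axis=axes) + t.sum(axis=axes) + eps
    value = float((-num / den).mean())
    dldp = -(2.0 * t * den.reshape((-1,) + (1,) * (p.ndim - 1)) - num.reshape((-1,) + (1,) * (p.ndim - 1))) / (
        den.reshape((-1,) + (1,) * (p.ndim - 1)) ** 2
    )
    return value, dldp * p * (1.0 - p) / n


# ---------------------------------------------------------------------------
# monitors


def _as_nchw(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None]
    return x


def _predict_in_batches(model: UNet, x: np.ndarray, batch: int = 16) -> np.ndarray:
    out = [model.forward(x[i : i + batch]) for i in range(0, x.shape[0], batch)]
    return np.concatenate(out, axis=0)


def _val_dice(model: UNet, x: np.ndarray, t: np.ndarray) -> float:
    """Dice of thresholded predictions pooled over the whole validation set."""
    p = _predict_in_batches(model, x) >= 0.5
    tt = t.astype(bool)
    inter = int((p & tt).sum())
    den = int(p.sum()) + int(tt.sum())
    return 1.0 if den == 0 else 2.0 * inter / den


def _val_accuracy(model: UNet, x: np.ndarray, t: np.ndarray) -> float:
    """Per-slice presence accuracy: any predicted pixel vs. any true pixel."""
    p = _predict_in_batches(model, x) >= 0.5
    pred_pos = p.any(axis=(1, 2, 3))
    true_pos = t.astype(bool).any(axis=(1, 2, 3))
    return float((pred_pos == true_pos).mean())


# ---------------------------------------------------------------------------
# harness


def train_model(
    model: UNet,
    train_pairs: tuple[np.ndarray, np.ndarray],
    val_pairs: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    monitor_fn=None,
    verbose: bool = False,
) -> tuple[UNet, TrainHistory]:
    """Train in place with Adam, shuffled mini-batches and early stopping.

    ``train_pairs`` / ``val_pairs`` are (images, masks) arrays shaped
    (n, h, w) or (n, 1, h, w).  ``monitor_fn(model) -> float`` overrides
    the built-in validation monitor (higher is better); this is how the
    early-stopping contract is tested in isolation.  Returns the model
    with the best epoch's weights restored, plus the history.
    """
    config.validate()
    x_tr, t_tr = (_as_nchw(a) for a in train_pairs)
    x_va, t_va = (_as_nchw(a) for a in val_pairs)
    if x_tr.shape[0] == 0 or x_va.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    if x_tr.shape != t_tr.shape or x_va.shape != t_va.shape:
        raise ValueError("images and masks must align")

    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(config.learning_rate)
    stopper = EarlyStopping(config.patience)
    history = TrainHistory()
    best_state = model.state_dict()

    if monitor_fn is None:
        builtin = _val_dice if config.monitor == "val_dice" else _val_accuracy
        monitor_fn = lambda m: builtin(m, x_va, t_va)  # noqa: E731

    n = x_tr.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            p = model.forward(x_tr[idx], train=True)
            value, dz = _batch_loss_and_dlogits(p, t_tr[idx], config.loss)
            if not np.isfinite(value):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch}, batch starting {lo}"
                )
            model.backward(dz)
            opt.step()
            losses.append(value)
        monitored = float(monitor_fn(model))
        history.epochs.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "monitor": monitored}
        )
        if verbose:
            print(f"epoch {epoch:3d}  loss {np.mean(losses):+.4f}  monitor {monitored:.4f}")
        improved = monitored > stopper.best
        stop = stopper.update(monitored, epoch)
        if improved:
            best_state = model.state_dict()
        if stop:
            break

    history.stopped_epoch = history.epochs[-1]["epoch"] if history.epochs else 0
    history.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, history
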