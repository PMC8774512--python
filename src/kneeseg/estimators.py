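"""Scikit-learn style estimators wrapping the two U-net models.

``SliceDetector`` is the slice-presence classifier (binary
cross-entropy on coarse-resolution per-pixel maps; a slice is positive
when enough output pixels fire) and ``BoneSegmenter`` the full
resolution mask regressor (soft Dice loss).  Both follow the sklearn
contract: constructor stores hyperparameters untouched, ``fit``
validates input and sets trailing-underscore attributes (``model_``,
``history_``, ``spec_``), so they compose with ``clone``,
``get_params`` and pipelines.  Inputs are stacks of 2D slices shaped
(n, h, w) with masks of the same shape.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .training import TrainConfig, train_model
from .unet import UNet, UNetSpec
from .volumes import resize

__all__ = ["SliceDetector", "BoneSegmenter"]


def _check_stack(X, y=None):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 3:
        raise ValueError(f"expected (n_slices, h, w) input, got shape {X.shape}")
    if y is not None:
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"masks {y.shape} do not align with images {X.shape}")
        y = (y > 0.5).astype(np.float32)
    return X, y


class _UNetEstimator(BaseEstimator):
    _loss: str
    _monitor: str

    def __init__(
        self,
        input_size=128,
        base_width=64,
        depth=5,
        learning_rate=1e-5,
        batch_size=16,
        max_epochs=300,
        patience=35,
        prob_threshold=0.5,
        validation_fraction=0.15,
        seed=0,
    ):
        self.input_size = input_size
        self.base_width = base_width
        self.depth = depth
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.prob_threshold = prob_threshold
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _resize_to_input(self, X, kind):
        if X.shape[1] == self.input_size and X.shape[2] == self.input_size:
            return X
        out = np.stack([resize(sl, self.input_size, kind) for sl in X])
        return out.astype(np.float32)

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = _check_stack(X, y)
        X = self._resize_to_input(X, "intensity")
        y = self._resize_to_input(y, "mask").astype(np.float32)
        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
            if X.shape[0] <= n_val:
                raise ValueError("not enough slices to carve out a validation split")
            X, X_val = X[:-n_val], X[-n_val:]
            y, y_val = y[:-n_val], y[-n_val:]
        else:
            X_val, y_val = _check_stack(X_val, y_val)
            X_val = self._resize_to_input(X_val, "intensity")
            y_val = self._resize_to_input(y_val, "mask").astype(np.float32)

        self.spec_ = UNetSpec(
            in_channels=1,
            out_channels=1,
            base_width=self.base_width,
            depth=self.depth,
            input_size=self.input_size,
        )
        self.model_ = UNet(self.spec_, seed=self.seed)
        config = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            loss=self._loss,
            monitor=self._monitor,
            seed=self.seed,
        )
        self.model_, self.history_ = train_model(self.model_, (X, y), (X_val, y_val), config)
        return self

    def predict_proba(self, X):
        """Per-pixel probability maps at the model's input resolution."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted yet")
        X, _ = _check_stack(X)
        X = self._resize_to_input(X, "intensity")
        out = [self.model_.forward(X[i : i + 16, None]) for i in range(0, X.shape[0], 16)]
        return np.concatenate(out)[:, 0]


class SliceDetector(_UNetEstimator):
    """Per-slice bone-presence detector (coarse U-net + min-area decision)."""

    _loss = "binary_cross_entropy"
    _monitor = "val_accuracy"

    def __init__(
        self,
        input_size=128,
        base_width=64,
        depth=5,
        learning_rate=1e-5,
        batch_size=16,
        max_epochs=300,
        patience=35,
        prob_threshold=0.5,
        validation_fraction=0.15,
        seed=0,
        min_area=1,
    ):
        super().__init__(
            input_size,
            base_width,
            depth,
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            prob_threshold,
            validation_fraction,
            seed,
        )
        self.min_area = min_area

    def predict(self, X) -> np.ndarray:
        """Boolean per-slice presence decisions."""
        p = self.predict_proba(X)
        return (p >= self.prob_threshold).sum(axis=(1, 2)) >= self.min_area


class BoneSegmenter(_UNetEstimator):
    """Full-resolution bone mask segmenter trained with soft Dice."""

    _loss = "soft_dice"
    _monitor = "val_dice"

    def __init__(
        self,
        input_size=352,
        base_width=64,
        depth=5,
        learning_rate=1e-5,
        batch_size=16,
        max_epochs=300,
        patience=35,
        prob_threshold=0.5,
        validation_fraction=0.15,
        seed=0,
    ):
        super().__init__(
            input_size,
            base_width,
            depth,
            learning_rate,
            batch_size,
            max_epochs,
            patience,
            prob_threshold,
            validation_fraction,
            seed,
        )

    def predict(self, X) -> np.ndarray:
        """Binary masks, thresholded at ``prob_threshold``."""
        return (self.predict_proba(X) >= self.prob_threshold).astype(np.uint8)
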