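"""scikit-learn style estimator facade for the segmentation network.

``CaucSegmenter`` is a pixel-wise classifier: ``fit`` takes a stack of RGB
field images with their label rasters (or palette masks), ``predict`` returns
per-pixel class rasters, ``predict_proba`` the per-pixel class probabilities.
It follows the scikit-learn estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``score``), so it composes with
sklearn model selection at desk scale.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import CAUCNet, count_parameters
from .palettes import NUM_CLASSES, mask_to_classes
from .train import _batched_probs, fit_model


class CaucSegmenter(BaseEstimator):
    """Attention U-Net pixel classifier with a scikit-learn interface.

    Parameters
    ----------
    variant : str
        Architecture variant: "V5" (full model), "V4" (no CBAM fusion),
        "V3" (no attention gates), "V2" (neither), "V1" (plain U-Net baseline).
    input_size : int
        Square input resolution; must be divisible by 16.  The parameter count
        is independent of it.
    epochs, batch_size, learning_rate : training regime (Adam, categorical
        cross-entropy).
    random_state : int
        Seed for weight init, batching, and dropout.
    """

    def __init__(self, variant="V5", input_size=224, num_classes=NUM_CLASSES,
                 epochs=50, batch_size=8, learning_rate=1e-3, random_state=0,
                 verbose=False):
        self.variant = variant
        self.input_size = input_size
        self.num_classes = num_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.verbose = verbose

    def _validate_images(self, X):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3) RGB images, got {X.shape}")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"images must be {self.input_size}x{self.input_size}, got "
                f"{X.shape[1]}x{X.shape[2]}")
        X = X.astype(np.float32)
        if X.max() > 1.0 + 1e-6:
            X = X / 255.0
        return X

    def _validate_labels(self, y, n):
        y = np.asarray(y)
        if y.ndim == 4 and y.shape[-1] == 3:  # palette masks
            y = np.stack([mask_to_classes(m) for m in y])
        if y.ndim != 3 or len(y) != n:
            raise ValueError(f"y must be (n, H, W) class rasters or palette masks, got {y.shape}")
        if y.min() < 0 or y.max() >= self.num_classes:
            raise ValueError(f"label entries must lie in [0, {self.num_classes})")
        return y.astype(np.int64)

    def fit(self, X, y):
        X = self._validate_images(X)
        y = self._validate_labels(y, len(X))
        self.model_ = CAUCNet(input_size=self.input_size, num_classes=self.num_classes,
                              variant=self.variant, seed=self.random_state)
        self.history_ = fit_model(self.model_, X, y, self.epochs, self.batch_size,
                                  self.learning_rate, self.random_state,
                                  verbose=self.verbose)
        self.n_params_ = count_parameters(self.model_)
        self.classes_ = np.arange(self.num_classes)
        return self

    def predict_proba(self, X):
        self._check_fitted()
        X = self._validate_images(X)
        return _batched_probs(self.model_, X, self.batch_size)

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y):
        """Mean pixel accuracy."""
        y = self._validate_labels(y, len(np.asarray(X)))
        return float((self.predict(X) == y).mean())

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this CaucSegmenter instance is not fitted yet")
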