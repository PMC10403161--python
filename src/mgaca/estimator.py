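"""Scikit-learn style estimator wrapping the MGACA network and trainer."""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .ablation import ablation_variant
from .config import ModelConfig
from .model import build_mgaca, count_trainable_parameters
from .training import TrainConfig, split_dataset, train


class MGACASegmenter(BaseEstimator):
    """Pixel-wise ACL-region localizer with a fit/predict interface.

    ``fit`` expects images ``X`` of shape (N, H, W, 3) with values in [0, 1]
    (H and W divisible by the encoder stride, 8 at the default taps) and
    binary masks ``y`` of shape (N, H, W) or (N, H, W, 1). ``predict``
    returns binary masks thresholded at ``threshold``; ``predict_proba``
    returns the probability maps; ``score`` returns the Dice coefficient.

    Parameters mirror the published configuration: ``width_multiplier=1``
    is the full 22.9M-parameter network; smaller multipliers give reduced
    models for desk-scale experiments. ``ablation`` selects one of the seven
    named component-removal variants.
    """

    def __init__(self, width_multiplier=1.0, ablation=None, max_epochs=25,
                 n_steps=None, batch_size=32, learning_rate=0.001,
                 validation_fraction=0.0, early_stop_patience=10,
                 plateau_patience=2, plateau_factor=0.2, min_lr=1e-5,
                 dropout_rate=0.0, threshold=0.5, random_state=0):
        self.width_multiplier = width_multiplier
        self.ablation = ablation
        self.max_epochs = max_epochs
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.early_stop_patience = early_stop_patience
        self.plateau_patience = plateau_patience
        self.plateau_factor = plateau_factor
        self.min_lr = min_lr
        self.dropout_rate = dropout_rate
        self.threshold = threshold
        self.random_state = random_state

    def _validate_xy(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be (N, H, W, 3), got {X.shape}")
        if X.min() < 0 or X.max() > 1:
            raise ValueError("X must be normalized to [0, 1]")
        if y is None:
            return X
        y = np.asarray(y, dtype=np.float32)
        if y.ndim == 3:
            y = y[..., None]
        if y.shape[:3] != X.shape[:3] or y.shape[3] != 1:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be strictly binary")
        return X, y

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        seed = 0 if self.random_state is None else int(self.random_state)
        config = ModelConfig(input_shape=X.shape[1:],
                             width_multiplier=self.width_multiplier,
                             dropout_rate=self.dropout_rate, seed=seed)
        if self.ablation is not None:
            self.model_ = ablation_variant(self.ablation, config)
        else:
            self.model_ = build_mgaca(config)
        self.config_ = self.model_.config
        tc = TrainConfig(
            split_fraction=self.validation_fraction or 0.25,
            batch_size=self.batch_size, initial_lr=self.learning_rate,
            plateau_factor=self.plateau_factor,
            plateau_patience=self.plateau_patience, min_lr=self.min_lr,
            early_stop_patience=self.early_stop_patience,
            max_epochs=self.max_epochs, global_seed=seed,
            target_size=X.shape[1:3])
        if self.validation_fraction:
            split = split_dataset(len(X), tc)
            train_data = (X[split.train], y[split.train])
            val_data = (X[split.validation], y[split.validation])
        else:
            train_data, val_data = (X, y), None
        self.history_ = train(self.model_, train_data, tc, val_data=val_data,
                              n_steps=self.n_steps)
        self.n_parameters_ = count_trainable_parameters(self.model_)
        return self

    def predict_proba(self, X):
        self._check_fitted()
        X = self._validate_xy(X)
        return self.model_.predict(X, batch_size=self.batch_size)

    def predict(self, X):
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)[..., 0]

    def score(self, X, y):
        """Dice coefficient of thresholded predictions against y."""
        X, y = self._validate_xy(X, y)
        report = metrics.pixel_metrics(
            metrics.confusion_counts(y[..., 0], self.predict_proba(X),
                                     self.threshold))
        return report.dcs

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("this MGACASegmenter instance is not fitted yet")
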