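"""Scikit-learn style estimators wrapping the training engine.

``AideSegmenter`` is the cross-model self-correcting trainer;
``SupervisedSegmenter`` the plain fully-supervised baseline. Both follow
the sklearn contract: constructor stores hyper-parameters verbatim,
``fit(X, y)`` learns and sets trailing-underscore attributes,
``get_params``/``set_params`` support cloning and grid search. ``X`` is an
(n_samples, n_modalities, H, W) float array (an (n, H, W) array is promoted
to one modality) and ``y`` an (n, H, W) binary mask array.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .engine import (AideConfig, LabelStore, TrainingData, fit,
                     hard_prediction, predict_dataset, predict_ensemble)
from .losses import LossParams
from .nn import ModelSpec
from .standardize import PretrainConfig, pretrain_baseline


def _check_xy(X, y=None):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[:, None]
    if X.ndim != 4:
        raise ValueError("X must be (n_samples, n_modalities, H, W)")
    if y is None:
        return X, None
    y = np.asarray(y)
    if y.shape != (X.shape[0],) + X.shape[2:]:
        raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
    return X, y.astype(np.uint8)


class SupervisedSegmenter(BaseEstimator):
    """Fully-supervised U-Net baseline (Dice + cross-entropy loss)."""

    def __init__(self, base_channels=32, epochs=20, batch_size=8,
                 learning_rate=1e-3, optimizer="adam", alpha=1.0,
                 epsilon=1.0, seed=0, postprocess=False):
        self.base_channels = base_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.alpha = alpha
        self.epsilon = epsilon
        self.seed = seed
        self.postprocess = postprocess

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        spec = ModelSpec(n_modalities=X.shape[1],
                         base_channels=self.base_channels)
        cfg = PretrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                             learning_rate=self.learning_rate,
                             optimizer=self.optimizer, seed=self.seed,
                             loss_params=LossParams(alpha=self.alpha,
                                                    epsilon=self.epsilon))
        self.net_, self.history_ = pretrain_baseline(X, y, spec, cfg)
        self.model_spec_ = spec
        return self

    def predict_proba(self, X):
        X, _ = _check_xy(X)
        return predict_dataset(self.net_, X, self.batch_size)

    def predict(self, X):
        probs = self.predict_proba(X)
        return np.stack([hard_prediction(p, 0.5, self.postprocess)
                         for p in probs])

    def score(self, X, y):
        """Mean Dice similarity coefficient on (X, y)."""
        from .metrics import dice_score
        preds = self.predict(X)
        _, y = _check_xy(X, y)
        return float(np.mean([dice_score(p, t) for p, t in zip(preds, y)]))


class AideSegmenter(BaseEstimator):
    """Cross-model self-correcting segmentation trainer.

    Trains two peer networks that exchange per-sample loss rankings
    (local label filtering), regularize suspected-noisy samples toward
    sharpened pseudo-labels, and periodically rewrite their own copies of
    the worst-agreeing low-quality labels (global label correction).

    ``fit(X, y, quality=...)`` takes a boolean array flagging which labels
    are trusted (high quality); trusted labels are never modified. With no
    flags all labels are treated as potentially noisy.
    """

    def __init__(self, base_channels=32, filter_fraction=0.5,
                 correction_fraction=0.25, warmup_epochs=5,
                 correction_period=10, ramp_epochs=10, k_views=4,
                 temperature=0.5, alpha=1.0, epsilon=1.0, epochs=30,
                 batch_size=8, learning_rate=1e-3, optimizer="adam",
                 seed=0, enable_correction=True, postprocess_corrections=True,
                 suspected_target="stored", postprocess=False):
        self.base_channels = base_channels
        self.filter_fraction = filter_fraction
        self.correction_fraction = correction_fraction
        self.warmup_epochs = warmup_epochs
        self.correction_period = correction_period
        self.ramp_epochs = ramp_epochs
        self.k_views = k_views
        self.temperature = temperature
        self.alpha = alpha
        self.epsilon = epsilon
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.seed = seed
        self.enable_correction = enable_correction
        self.postprocess_corrections = postprocess_corrections
        self.suspected_target = suspected_target
        self.postprocess = postprocess

    def _config(self) -> AideConfig:
        return AideConfig(
            filter_fraction=self.filter_fraction,
            correction_fraction=self.correction_fraction,
            warmup_epochs=self.warmup_epochs,
            correction_period=self.correction_period,
            ramp_epochs=self.ramp_epochs, k_views=self.k_views,
            temperature=self.temperature,
            loss_params=LossParams(alpha=self.alpha, epsilon=self.epsilon),
            epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate, optimizer=self.optimizer,
            seed=self.seed, enable_correction=self.enable_correction,
            postprocess_corrections=self.postprocess_corrections,
            suspected_target=self.suspected_target)

    def fit(self, X, y, quality=None, ids=None):
        X, y = _check_xy(X, y)
        n = len(X)
        if quality is None:
            quality = np.zeros(n, dtype=bool)
        quality = np.asarray(quality, dtype=bool)
        ids = list(ids) if ids is not None else [f"s{i:04d}" for i in range(n)]
        data = TrainingData(images=X, ids=tuple(ids))
        store = LabelStore(y, quality, ids)
        cfg = self._config()
        spec = ModelSpec(n_modalities=X.shape[1],
                         base_channels=self.base_channels)
        self.net_a_, self.net_b_, self.stores_, self.history_ = fit(
            data, store, cfg, spec)
        self.model_spec_ = spec
        self.config_ = cfg
        return self

    def predict_proba(self, X):
        """Ensemble (mean of both networks) foreground probabilities."""
        X, _ = _check_xy(X)
        return np.stack([predict_ensemble(self.net_a_, self.net_b_, x)[1]
                         for x in X])

    def predict(self, X):
        probs = self.predict_proba(X)
        return np.stack([hard_prediction(p, 0.5, self.postprocess)
                         for p in probs])

    def score(self, X, y):
        """Mean Dice similarity coefficient on (X, y)."""
        from .metrics import dice_score
        preds = self.predict(X)
        _, y = _check_xy(X, y)
        return float(np.mean([dice_score(p, t) for p, t in zip(preds, y)]))

    def corrected_labels(self):
        """The two networks' corrected label sets and their audit logs."""
        return self.stores_
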