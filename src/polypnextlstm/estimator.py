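"""Scikit-learn-style estimator wrapping the segmentation network.

`VideoPolypSegmenter` treats each video window (F frames + F masks) as one
sample, so it composes with sklearn model-selection utilities on arrays of
clips.  ``fit`` runs seeded Adam steps on the Dice+BCE objective;
``predict`` returns binary masks and ``score`` the mean Dice.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .arch import ModelConfig, build_model
from .metrics import dice_score
from .train import TrainState

__all__ = ["VideoPolypSegmenter"]


class VideoPolypSegmenter(BaseEstimator):
    """Many-to-many video polyp segmenter (ConvNeXt + BiConvLSTM + UNet).

    Parameters
    ----------
    lr : float
        Adam learning rate (published default 1e-4).
    n_steps : int
        Number of optimization steps over the training windows.
    batch_size : int
        Windows per optimization step.
    seed : int
        Controls weight initialization and batch order; same-seed fits
        are bit-identical.
    threshold : float
        Probability threshold for ``predict``.

    Attributes
    ----------
    model_ : PolypNextLSTM
        The fitted network.
    state_ : TrainState
        Model plus optimizer state.
    loss_history_ : list of float
        Training loss per step.
    n_params_ : int
        Trainable parameter count of the fitted model.
    """

    def __init__(self, lr: float = 1e-4, n_steps: int = 300,
                 batch_size: int = 1, seed: int = 0, threshold: float = 0.5):
        self.lr = lr
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.seed = seed
        self.threshold = threshold

    @staticmethod
    def _validate(X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 5 or X.shape[2] != 3:
            raise ValueError(
                "X must be (n_clips, frames, 3, height, width), got "
                f"{X.shape}"
            )
        if y is not None:
            y = np.asarray(y)
            if y.shape != (X.shape[0], X.shape[1]) + X.shape[3:]:
                raise ValueError(
                    f"y must be (n_clips, frames, height, width) matching X, "
                    f"got {y.shape}"
                )
            return X, y.astype(np.float32)
        return X

    def fit(self, X, y):
        """Fit on clips X (n, F, 3, H, W) with masks y (n, F, H, W)."""
        X, y = self._validate(X, y)
        from .nn import count_parameters

        model = build_model(ModelConfig(seed=self.seed))
        self.state_ = TrainState(model, lr=self.lr)
        self.model_ = model
        self.n_params_ = count_parameters(model)
        self.loss_history_ = []
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        for _ in range(self.n_steps):
            idx = rng.choice(n, size=min(self.batch_size, n), replace=False)
            loss = self.state_.step(X[idx], y[idx][:, :, None])
            self.loss_history_.append(loss)
        return self

    def predict_proba(self, X):
        """Per-pixel foreground probabilities (n, F, H, W)."""
        if not hasattr(self, "state_"):
            raise RuntimeError("estimator is not fitted")
        X = self._validate(X)
        return np.concatenate(
            [self.state_.predict_proba(X[i:i + 1]) for i in range(X.shape[0])]
        )

    def predict(self, X):
        """Binary masks (n, F, H, W) at the configured threshold."""
        return self.predict_proba(X) > self.threshold

    def score(self, X, y):
        """Mean per-frame Dice over all clips."""
        X, y = self._validate(X, y)
        pred = self.predict(X)
        return float(np.mean([
            dice_score(pred[i, t], y[i, t] > 0.5)
            for i in range(X.shape[0]) for t in range(X.shape[1])
        ]))
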