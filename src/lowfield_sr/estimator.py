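"""sklearn-style estimator wrapping the super-resolution network.

`SRDenseNetRegressor` follows the scikit-learn contract (``get_params`` /
``set_params`` / ``fit`` / ``predict``, fitted attributes with a trailing
underscore) so it composes with sklearn tooling, while operating on image
stacks ``(n, h, w)`` rather than flat feature matrices: inputs are
low-resolution patches or images, targets are their 2x high-resolution
counterparts.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .model import ModelConfig, SRDenseNet, build_model
from .training import PatchDataset, TrainConfig, train

__all__ = ["SRDenseNetRegressor"]


class SRDenseNetRegressor(BaseEstimator):
    """2x single-image super-resolution via a dense convolutional network.

    Parameters mirror the architecture and optimization knobs; anything not
    exposed here keeps its calibrated `ModelConfig` default. ``fit`` expects
    aligned stacks ``X`` (LR, shape ``(n, h, w)``) and ``y`` (HR, shape
    ``(n, 2h, 2w)``); a validation fraction is split off for best-epoch
    selection.
    """

    def __init__(
        self,
        n_blocks: int = 8,
        layers_per_block: int = 8,
        growth: int = 16,
        bottleneck_out: int = 256,
        deconv_out: int = 256,
        deconv_kernel: int = 3,
        initial_conv_out: int | None = 16,
        loss: str = "mse",
        learning_rate: float = 1e-3,
        batch_size: int = 20,
        max_epochs: int = 74,
        patience: int | None = None,
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.n_blocks = n_blocks
        self.layers_per_block = layers_per_block
        self.growth = growth
        self.bottleneck_out = bottleneck_out
        self.deconv_out = deconv_out
        self.deconv_kernel = deconv_kernel
        self.initial_conv_out = initial_conv_out
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config assembly ----------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_blocks=self.n_blocks,
            layers_per_block=self.layers_per_block,
            growth=self.growth,
            bottleneck_out=self.bottleneck_out,
            deconv_out=self.deconv_out,
            deconv_kernel=self.deconv_kernel,
            initial_conv_out=self.initial_conv_out,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            loss=self.loss,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.random_state,
        )

    # -- sklearn API ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "SRDenseNetRegressor":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or y.ndim != 3:
            raise ValueError("X and y must be image stacks of shape (n, h, w)")
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        if y.shape[1] != 2 * X.shape[1] or y.shape[2] != 2 * X.shape[2]:
            raise ValueError(
                f"targets must be 2x the input size, got {X.shape[1:]} -> {y.shape[1:]}"
            )
        n_val = max(1, int(round(self.validation_fraction * len(X))))
        if n_val >= len(X):
            raise ValueError("validation fraction leaves no training samples")
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(len(X))
        val_idx, train_idx = order[:n_val], order[n_val:]
        dataset = PatchDataset(
            X_train=X[train_idx], y_train=y[train_idx], X_val=X[val_idx], y_val=y[val_idx]
        )
        model = build_model(self._model_config(), seed=self.random_state)
        model, history = train(model, dataset, self._train_config())
        self.model_ = model
        self.history_ = history
        self.n_parameters_ = model.n_parameters
        self.best_epoch_ = history.best_epoch if len(history) else -1
        return self

    def predict(self, X: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Super-resolve a stack of LR images; raw (unclamped) outputs."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        outs = [
            self.model_.forward(X[i : i + batch_size])[:, 0]
            for i in range(0, len(X), batch_size)
        ]
        out = np.concatenate(outs, axis=0)
        return out[0] if single else out

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        """Negative mean-squared error of clamped predictions (higher is better)."""
        pred = np.clip(self.predict(X), 0.0, 1.0)
        return -float(np.mean((pred - np.asarray(y, dtype=np.float32)) ** 2))
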