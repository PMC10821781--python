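"""scikit-learn-compatible wrapper around the curve regressor.

``NeuralG2Regressor`` follows the sklearn estimator contract (get_params /
set_params / fit / predict, fitted attributes with a trailing underscore) so
it can sit in sklearn pipelines and model-selection utilities.  ``fit``
consumes normalized g2 curves (n_samples, 127) and *physical* targets
(beta, BFi); label encoding/decoding happens inside.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ..dataset import decode_labels, encode_labels, normalize_input
from .model import INPUT_LENGTH, ArchitectureSpec, DCSNet
from .train import TrainingConfig, train_model

__all__ = ["NeuralG2Regressor"]


class NeuralG2Regressor(BaseEstimator, RegressorMixin):
    """Map normalized g2(tau) curves to (beta, BFi).

    Parameters mirror :class:`TrainingConfig` plus the architecture filter
    counts.  ``predict`` returns physical units: column 0 is beta, column 1
    is BFi in mm^2/s.
    """

    def __init__(self, learning_rate: float = 1e-5, batch_size: int = 128,
                 max_epochs: int = 800, patience: int = 20,
                 validation_fraction: float = 0.2, seed: int = 0,
                 architecture: ArchitectureSpec | None = None):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.architecture = architecture

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on curves X (n, 127) and physical targets y (n, 2).

        If a validation set is not given, the trailing
        ``validation_fraction`` of the (already i.i.d.) samples is held out.
        """
        X = check_array(X, dtype=float)
        y = check_array(y, dtype=float)
        if X.shape[1] != INPUT_LENGTH:
            raise ValueError(f"expected {INPUT_LENGTH}-lag curves, "
                             f"got {X.shape[1]}")
        ub, uf = encode_labels(y[:, 0], y[:, 1])
        yy = np.stack([ub, uf], axis=1)
        if X_val is None:
            n_val = max(1, int(self.validation_fraction * X.shape[0]))
            X, X_val = X[:-n_val], X[-n_val:]
            yy, yv = yy[:-n_val], yy[-n_val:]
        else:
            X_val = check_array(X_val, dtype=float)
            y_val = check_array(y_val, dtype=float)
            vb, vf = encode_labels(y_val[:, 0], y_val[:, 1])
            yv = np.stack([vb, vf], axis=1)
        self.network_ = DCSNet(self.architecture, seed=self.seed)
        self.n_parameters_ = self.network_.n_params()
        cfg = TrainingConfig(learning_rate=self.learning_rate,
                             batch_size=self.batch_size,
                             max_epochs=self.max_epochs,
                             patience=self.patience, seed=self.seed)
        self.history_ = train_model(self.network_, X, yy, X_val, yv, cfg)
        return self

    def predict(self, X):
        """Physical (beta, BFi) predictions, shape (n, 2)."""
        check_is_fitted(self, "network_")
        X = check_array(X, dtype=float)
        if X.shape[1] != INPUT_LENGTH:
            raise ValueError(f"expected {INPUT_LENGTH}-lag curves, "
                             f"got {X.shape[1]}")
        u = self.network_.predict(X)
        beta, bfi = decode_labels(u[:, 0], u[:, 1])
        return np.stack([beta, bfi], axis=1)

    def predict_curves(self, curves):
        """Predict from raw (un-normalized) intensity curves or value stacks."""
        vals = np.stack([np.asarray(getattr(c, "values", c), dtype=float)
                         for c in curves])
        return self.predict(normalize_input(vals))
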