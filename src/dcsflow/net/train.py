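"""Adam optimizer and the training loop for the curve regressor.

Training minimizes the mean squared error over the two encoded labels
(beta and log-encoded BFi, both in (0, 1]) jointly, with early stopping on
the validation loss and restoration of the best-validation checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DCSNet

__all__ = ["TrainingConfig", "Adam", "train_model", "TrainingHistory"]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (Adam, fixed learning rate)."""

    learning_rate: float = 1e-5
    batch_size: int = 128
    max_epochs: int = 800
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    stopped_early: bool = False


class Adam:
    """Adam with bias correction over a model's parameter registry.

    Parameters stay owned by the modules; moments and updates run on a
    single flat buffer to keep the per-step overhead independent of the
    number of parameter tensors.
    """

    def __init__(self, net: DCSNet, lr: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr = net, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._slots = []
        off = 0
        for mod in net.modules:
            for k, p in mod.params.items():
                self._slots.append((mod, k, off, p.size, p.shape))
                off += p.size
        self._n = off
        self.m = np.zeros(off)
        self.v = np.zeros(off)
        self._g = np.empty(off)

    def step(self) -> None:
        self.t += 1
        g = self._g
        for mod, k, off, size, shape in self._slots:
            g[off:off + size] = mod.grads[k].ravel()
        self.m += (1 - self.beta1) * (g - self.m)
        self.v += (1 - self.beta2) * (g * g - self.v)
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        upd = (-self.lr) * (self.m / b1c) / (np.sqrt(self.v / b2c)
                                             + self.eps)
        for mod, k, off, size, shape in self._slots:
            mod.params[k] += upd[off:off + size].reshape(shape)


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.sum((pred - y) ** 2, axis=1)))


def evaluate_loss(net: DCSNet, x: np.ndarray, y: np.ndarray,
                  batch: int = 4096) -> float:
    net.set_training(False)
    tot, n = 0.0, x.shape[0]
    for i in range(0, n, batch):
        pred = net.forward(x[i:i + batch])
        tot += np.sum((pred - y[i:i + batch]) ** 2)
    return float(tot / n)


def train_model(net: DCSNet, x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                cfg: TrainingConfig = TrainingConfig(),
                verbose: bool = False) -> TrainingHistory:
    """Mini-batch Adam training with early stopping.

    Mutates ``net`` in place; on return the network carries the
    best-validation weights.  Deterministic for a fixed config seed under
    single-threaded BLAS.  Raises on divergent (non-finite) loss.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net, lr=cfg.learning_rate)
    hist = TrainingHistory()
    best_state = net.state()
    n = x_train.shape[0]
    since_best = 0
    for epoch in range(cfg.max_epochs):
        net.set_training(True)
        order = rng.permutation(n)
        ep_loss, n_batches = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = x_train[idx].astype(float)
            yb = y_train[idx].astype(float)
            pred = net.forward(xb)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}")
            net.backward(2.0 * (pred - yb) / xb.shape[0])
            opt.step()
            ep_loss += loss
            n_batches += 1
        hist.train_loss.append(ep_loss / n_batches)
        vl = evaluate_loss(net, x_val.astype(float), y_val.astype(float))
        hist.val_loss.append(vl)
        if verbose:
            print(f"epoch {epoch:4d}  train {hist.train_loss[-1]:.6f}  "
                  f"val {vl:.6f}")
        if vl < hist.best_val_loss:
            hist.best_val_loss = vl
            hist.best_epoch = epoch
            best_state = net.state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                hist.stopped_early = True
                break
    net.load_state(best_state)
    net.set_training(False)
    return hist
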