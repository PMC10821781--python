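"""The 1-D CNN curve regressor: shared trunk plus two scalar heads.

A normalized g2 curve (1 x 127) passes through a shared feature trunk of two
wide-kernel strided convolutions (kernel 13, stride 5 — a 127-lag curve is
smooth on a log-tau grid, so large receptive fields with aggressive
downsampling lose nothing), each followed by batch normalization and a
rectifier, then splits into two independent branches that regress the
coherence factor beta and the encoded blood flow index.  Each branch mirrors
the trunk's conv+BN structure and ends in a pointwise (kernel-1) convolution
with a logistic output in (0, 1).

Layer-counting convention: a "layer" is any module with parameters or an
activation (conv, batch-norm, ReLU, sigmoid); the reference configuration
below has 18 such modules and 25,506 trainable parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import BatchNorm1d, Conv1d, ReLU, Sigmoid

__all__ = ["ArchitectureSpec", "DCSNet", "build_model",
           "reference_architecture", "find_filter_configs",
           "conv_param_count"]

INPUT_LENGTH = 127


@dataclass(frozen=True)
class ArchitectureSpec:
    """Filter counts of the trunk (c1, c2) and of each head (c3, c4).

    kernel/stride apply to every non-pointwise convolution; the two head
    convolutions are zero-padded (half-kernel) so the short trunk output
    survives the stride.
    """

    c1: int = 16
    c2: int = 32
    c3: int = 16
    c4: int = 12
    kernel: int = 13
    stride: int = 5

    def param_count(self) -> int:
        k = self.kernel
        n = 0
        n += k * 1 * self.c1 + self.c1 + 2 * self.c1            # conv1 + BN
        n += k * self.c1 * self.c2 + self.c2 + 2 * self.c2      # conv2 + BN
        per_head = (k * self.c2 * self.c3 + self.c3 + 2 * self.c3
                    + k * self.c3 * self.c4 + self.c4 + 2 * self.c4
                    + 1 * self.c4 * 1 + 1)                      # pointwise
        return n + 2 * per_head


def conv_param_count(k: int, c_in: int, c_out: int) -> int:
    """k*C_in*C_out weights + C_out biases."""
    return k * c_in * c_out + c_out


def reference_architecture() -> ArchitectureSpec:
    """The configuration anchored at 25,506 parameters / 18 layers."""
    return ArchitectureSpec()


def find_filter_configs(target_params: int = 25506, c_max: int = 64,
                        kernel: int = 13, limit: int = 20):
    """Enumerate (c1, c2, c3, c4) filter counts hitting an exact total
    parameter budget for the fixed two-conv-trunk / two-head topology."""
    hits = []
    for c1 in range(4, c_max + 1, 2):
        for c2 in range(4, c_max + 1, 2):
            base = (kernel * c1 + 3 * c1) + (kernel * c1 * c2 + 3 * c2)
            rem = target_params - base
            if rem <= 0 or rem % 2:
                continue
            per_head = rem // 2
            for c3 in range(4, c_max + 1, 2):
                a = kernel * c2 * c3 + 3 * c3
                num = per_head - a - 1
                den = kernel * c3 + 4
                if num > 0 and num % den == 0:
                    c4 = num // den
                    if 1 <= c4 <= c_max:
                        hits.append(ArchitectureSpec(c1, c2, c3, c4, kernel))
                        if len(hits) >= limit:
                            return hits
    return hits


class DCSNet:
    """Two-output 1-D CNN over 127-lag normalized g2 curves."""

    def __init__(self, spec: ArchitectureSpec | None = None, seed: int = 0):
        self.spec = spec or reference_architecture()
        rng = np.random.default_rng(seed)
        s = self.spec
        k, st = s.kernel, s.stride
        pad = k // 2
        self.trunk = [
            Conv1d(1, s.c1, k, st, 0, rng, needs_input_grad=False),
            BatchNorm1d(s.c1), ReLU(),
            Conv1d(s.c1, s.c2, k, st, 0, rng), BatchNorm1d(s.c2), ReLU(),
        ]
        def head():
            return [
                Conv1d(s.c2, s.c3, k, st, pad, rng), BatchNorm1d(s.c3),
                Conv1d(s.c3, s.c4, k, st, pad, rng), BatchNorm1d(s.c4),
                Conv1d(s.c4, 1, 1, 1, 0, rng), Sigmoid(),
            ]
        self.head_beta = head()
        self.head_bfi = head()
        # fail fast if the topology cannot digest the input length
        L = INPUT_LENGTH
        for i, m in enumerate(self.trunk):
            if isinstance(m, Conv1d):
                L = m.out_length(L)
        Lh = L
        for i, m in enumerate(self.head_beta):
            if isinstance(m, Conv1d):
                Lh = m.out_length(Lh)
        if Lh != 1:
            raise ValueError(f"head output length {Lh} != 1")

    # -- module bookkeeping -------------------------------------------------
    @property
    def modules(self):
        return self.trunk + self.head_beta + self.head_bfi

    def n_layers(self) -> int:
        """Conv/BN/sigmoid module count (the documented convention)."""
        return len(self.modules)

    def n_params(self) -> int:
        return sum(m.n_params() for m in self.modules)

    def set_training(self, flag: bool) -> None:
        for m in self.modules:
            m.training = flag

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (n, 127) normalized curves -> (n, 2) outputs in (0, 1)."""
        h = x[:, None, :]
        for m in self.trunk:
            h = m.forward(h)
        outs = []
        for branch in (self.head_beta, self.head_bfi):
            hb = h
            for m in branch:
                hb = m.forward(hb)
            outs.append(hb[:, 0, 0])
        return np.stack(outs, axis=1)

    def backward(self, dout: np.ndarray) -> None:
        """dout: (n, 2) gradient of the loss w.r.t. the two outputs."""
        dtrunk = 0.0
        for j, branch in enumerate((self.head_beta, self.head_bfi)):
            d = dout[:, j][:, None, None]
            for m in reversed(branch):
                d = m.backward(d)
            dtrunk = dtrunk + d
        d = dtrunk
        for m in reversed(self.trunk):
            d = m.backward(d)

    def predict(self, x: np.ndarray, batch: int = 4096) -> np.ndarray:
        """Inference in eval mode (running BN statistics)."""
        self.set_training(False)
        outs = [self.forward(x[i:i + batch])
                for i in range(0, x.shape[0], batch)]
        return np.concatenate(outs) if len(outs) > 1 else outs[0]

    # -- checkpointing ------------------------------------------------------
    def state(self):
        return [m.state() for m in self.modules]

    def load_state(self, states) -> None:
        for m, s in zip(self.modules, states):
            m.load_state(s)

    def save(self, path: str | Path) -> None:
        """Weights as .npz plus a JSON architecture descriptor alongside."""
        path = Path(path)
        arrays = {}
        for i, s in enumerate(self.state()):
            for k, v in s.items():
                arrays[f"m{i}:{k}"] = v
        np.savez(path, **arrays)
        desc = {"spec": self.spec.__dict__, "n_params": self.n_params(),
                "n_layers": self.n_layers()}
        path.with_suffix(".json").write_text(json.dumps(desc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "DCSNet":
        path = Path(path)
        desc = json.loads(path.with_suffix(".json").read_text())
        net = cls(ArchitectureSpec(**desc["spec"]))
        states = [dict() for _ in net.modules]
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            for key in z.files:
                mi, name = key.split(":", 1)
                states[int(mi[1:])][name] = z[key]
        net.load_state(states)
        return net


def build_model(spec: ArchitectureSpec | None = None,
                seed: int = 0) -> tuple[DCSNet, int]:
    """Construct the network; returns (model, trainable parameter count)."""
    net = DCSNet(spec, seed=seed)
    return net, net.n_params()
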