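"""Training-corpus generation for the neural g2 regressor.

Curves are synthesized with the homogeneous semi-infinite model over broad
uniform parameter ranges (mua, musp, beta, BFi, rho), optionally corrupted
with correlator noise, normalized to (0, 1] by their maximum, and paired
with encoded labels: beta maps to itself (already in (0, 1]) and BFi maps
logarithmically from [1e-8, 1e-5] mm^2/s onto [0, 1] — BFi spans three
decades, so a linear encoding would crush the gradient signal at the low end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forward_models import (AcquisitionSpec, CorrelationCurve, DelayGrid,
                             TissueLayer, make_tau_grid, semi_infinite_g1,
                             siegert_g2)
from .noise_model import NOISE_PRESETS, add_noise, estimate_decay_rate_batch, noise_sigma

__all__ = [
    "ParamRanges",
    "ParamSample",
    "sample_params",
    "synthesize_sample",
    "synthesize_batch",
    "normalize_input",
    "encode_labels",
    "decode_labels",
    "build_dataset",
    "load_split",
    "BFI_LO",
    "BFI_HI",
    "NOISE_CONDITIONS",
]

BFI_LO = 1e-8
BFI_HI = 1e-5

#: Equal-weight noise mixture used when building a corpus.
NOISE_CONDITIONS = ("noiseless", "Tint1", "Tint10", "Tint30")


@dataclass(frozen=True)
class ParamRanges:
    """Half-open uniform sampling ranges of the training distribution.

    BFi is drawn log-uniformly by default: it is a scale parameter spanning
    three decades, and a linear-uniform draw concentrates nearly all mass in
    the top decade, which trains a regressor that ignores flow (its
    MSE-optimal answer is always "a few 1e-6").  Set
    ``bfi_log_uniform=False`` for a linear-uniform draw.
    """

    mua: tuple[float, float] = (0.01, 1.0)
    musp: tuple[float, float] = (0.5, 1.6)
    beta: tuple[float, float] = (0.0, 1.0)
    bfi: tuple[float, float] = (BFI_LO, BFI_HI)
    rho: tuple[float, float] = (5.0, 30.0)
    bfi_log_uniform: bool = True


@dataclass(frozen=True)
class ParamSample:
    mua: float
    musp: float
    beta: float
    bfi: float
    rho: float


def sample_params(rng: np.random.Generator, n: int = 1,
                  ranges: ParamRanges = ParamRanges()) -> np.ndarray:
    """Draw n parameter tuples; returns a structured (n, 5) float array.

    Columns: mua, musp, beta, bfi, rho.  mua, musp and beta are drawn on
    half-open intervals open at the low end, (lo, hi]: a plain U[lo, hi)
    draw is reflected to hi - (x - lo).  BFi is log-uniform by default
    (see :class:`ParamRanges`); rho is U[lo, hi].
    """
    out = np.empty((n, 5))
    for j, (lo, hi) in enumerate((ranges.mua, ranges.musp, ranges.beta)):
        u = rng.uniform(lo, hi, n)
        out[:, j] = hi + lo - u          # (lo, hi] half-open
    lo, hi = ranges.bfi
    if ranges.bfi_log_uniform:
        out[:, 3] = 10 ** rng.uniform(np.log10(lo), np.log10(hi), n)
    else:
        out[:, 3] = rng.uniform(lo, hi, n)
    out[:, 4] = rng.uniform(*ranges.rho, n)
    return out


def normalize_input(g2: np.ndarray) -> np.ndarray:
    """Scale a g2 vector (or stack of rows) into (0, 1] by its maximum."""
    g2 = np.asarray(g2, dtype=float)
    mx = g2.max(axis=-1, keepdims=True)
    if np.any(mx <= 0):
        raise ValueError("g2 must be positive somewhere to normalize")
    return g2 / mx


def encode_labels(beta, bfi):
    """(beta, BFi) -> (u_beta, u_bfi), both in [0, 1].

    beta is the identity; BFi maps as u = (log10(BFi) + 8) / 3.
    """
    beta = np.asarray(beta, dtype=float)
    bfi = np.asarray(bfi, dtype=float)
    if np.any(bfi < BFI_LO) or np.any(bfi > BFI_HI):
        raise ValueError(f"BFi must lie in [{BFI_LO}, {BFI_HI}]")
    return beta, (np.log10(bfi) + 8.0) / 3.0


def decode_labels(u_beta, u_bfi):
    """Inverse of :func:`encode_labels`."""
    return np.asarray(u_beta, dtype=float), 10 ** (3.0 * np.asarray(u_bfi) - 8.0)


def synthesize_sample(p: ParamSample, noise_condition: str = "noiseless",
                      seed: int = 0,
                      grid: DelayGrid | None = None) -> dict:
    """One training pair from one parameter draw.

    Returns a dict with 'input' (normalized g2, shape (127,)), 'labels'
    (encoded beta, bfi) and provenance.
    """
    if noise_condition not in NOISE_PRESETS:
        raise ValueError(f"unknown noise condition {noise_condition!r}")
    grid = grid or make_tau_grid()
    layer = TissueLayer(mua=p.mua, musp=p.musp, Db=p.bfi)
    acq = AcquisitionSpec(rho=p.rho, beta=p.beta)
    curve = siegert_g2(semi_infinite_g1(layer, acq, grid), p.beta)
    if noise_condition != "noiseless":
        curve = add_noise(curve, NOISE_PRESETS[noise_condition], seed)
    x = normalize_input(curve.values)
    ub, uf = encode_labels(p.beta, p.bfi)
    return {"input": x, "labels": np.array([ub, uf]),
            "provenance": {"params": p.__dict__, "noise": noise_condition,
                           "seed": int(seed)}}


def _semi_infinite_g2_batch(params: np.ndarray, tau: np.ndarray,
                            wavelength: float = 785.0,
                            n_medium: float = 1.37) -> np.ndarray:
    """Vectorized semi-infinite g2 for (n, 5) parameter rows."""
    mua, musp, beta, bfi, rho = params.T
    k0 = 2.0 * np.pi * n_medium / (wavelength * 1e-6)
    K = np.sqrt(3.0 * mua[:, None] * musp[:, None]
                + musp[:, None] ** 2 * k0**2 * 6.0 * bfi[:, None] * tau)
    K0 = np.sqrt(3.0 * mua * musp)
    z0 = 1.0 / (mua + musp)
    zb = 5.0 / (3.0 * musp)
    r1 = np.hypot(rho, z0)[:, None]
    r2 = np.hypot(rho, z0 + 2.0 * zb)[:, None]
    G = np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2
    G0 = np.exp(-K0 * r1[:, 0]) / r1[:, 0] - np.exp(-K0 * r2[:, 0]) / r2[:, 0]
    g1 = G / G0[:, None]
    return 1.0 + beta[:, None] * g1**2


def synthesize_batch(params: np.ndarray, noise_conditions: np.ndarray,
                     rng: np.random.Generator,
                     grid: DelayGrid | None = None):
    """Vectorized corpus synthesis.

    params: (n, 5) rows (mua, musp, beta, bfi, rho); noise_conditions: length-n
    array of indices into :data:`NOISE_CONDITIONS`.  Returns (inputs, labels)
    as float32/float64 arrays of shapes (n, 127) and (n, 2).
    """
    grid = grid or make_tau_grid()
    tau = grid.tau
    g2 = _semi_infinite_g2_batch(params, tau)
    noisy = noise_conditions > 0
    if np.any(noisy):
        beta_fit, gamma_fit = estimate_decay_rate_batch(tau, g2[noisy])
        tints = np.array([np.inf, 1.0, 10.0, 30.0])
        tint = tints[noise_conditions[noisy]]
        specs = {c: NOISE_PRESETS[c] for c in NOISE_CONDITIONS[1:]}
        base = NOISE_PRESETS["Tint1"]
        sig1 = np.stack([noise_sigma(base, b, g, grid)
                         for b, g in zip(beta_fit, gamma_fit)])
        # sigma scales exactly as Tint^(-1/2); reuse the Tint=1 evaluation
        sig = sig1 / np.sqrt(tint)[:, None]
        g2 = g2.copy()
        g2[noisy] += rng.normal(size=sig.shape) * sig
    x = normalize_input(g2)
    ub, uf = encode_labels(params[:, 2], params[:, 3])
    return x.astype(np.float32), np.stack([ub, uf], axis=1).astype(np.float32)


def build_dataset(n_total: int, out_dir: str | Path, seed: int = 0,
                  split_fraction: float = 0.8,
                  ranges: ParamRanges = ParamRanges(),
                  noise_mixture: tuple[str, ...] = NOISE_CONDITIONS,
                  chunk: int = 20000) -> dict:
    """Generate, split and store a training corpus.

    Writes ``train.npz`` and ``val.npz`` (inputs, labels, params, noise
    condition index) plus ``metadata.json`` to ``out_dir``.  The first
    floor(split_fraction * n) samples form the training split; draws are
    i.i.d., so the split is random by construction.  Fully deterministic
    given ``seed``.
    """
    if n_total < 10:
        raise ValueError("n_total must be >= 10")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cond_idx = {c: i for i, c in enumerate(NOISE_CONDITIONS)}
    mix = np.array([cond_idx[c] for c in noise_mixture])

    xs, ys, ps, cs = [], [], [], []
    done = 0
    while done < n_total:
        n = min(chunk, n_total - done)
        params = sample_params(rng, n, ranges)
        conds = mix[rng.integers(0, len(mix), n)]
        x, y = synthesize_batch(params, conds, rng)
        xs.append(x); ys.append(y); ps.append(params.astype(np.float32))
        cs.append(conds.astype(np.int8))
        done += n
    X = np.concatenate(xs); Y = np.concatenate(ys)
    P = np.concatenate(ps); C = np.concatenate(cs)
    n_train = int(np.floor(split_fraction * n_total))
    meta = {"n_total": n_total, "n_train": n_train,
            "n_val": n_total - n_train, "seed": int(seed),
            "split_fraction": split_fraction,
            "ranges": ranges.__dict__ | {
                k: list(v) for k, v in ranges.__dict__.items()
                if isinstance(v, tuple)},
            "noise_mixture": list(noise_mixture),
            "noise_conditions": list(NOISE_CONDITIONS)}
    np.savez(out_dir / "train.npz", inputs=X[:n_train], labels=Y[:n_train],
             params=P[:n_train], noise=C[:n_train])
    np.savez(out_dir / "val.npz", inputs=X[n_train:], labels=Y[n_train:],
             params=P[n_train:], noise=C[n_train:])
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=1))
    return meta


def load_split(out_dir: str | Path, split: str):
    """Load a stored split; returns dict of arrays."""
    with np.load(Path(out_dir) / f"{split}.npz") as z:
        return {k: z[k] for k in z.files}
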