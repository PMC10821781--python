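"""Correlator noise model for intensity autocorrelation curves.

The standard deviation sigma(tau) of a measured g2 follows the shot-noise /
speckle model of a linear-bin photon correlator, parameterized by the bin
width Tb, integration time Tint, detected count rate I and the curve's decay
rate Gamma (from a single-exponential fit g2 ~ 1 + beta*exp(-Gamma*tau)).
Noise realizations are zero-mean Gaussian, independent across lags —
a simplification of real correlator noise, which is lag-correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_models import CorrelationCurve, DelayGrid

__all__ = [
    "NoiseSpec",
    "NOISE_PRESETS",
    "FitFailure",
    "estimate_decay_rate",
    "estimate_decay_rate_batch",
    "noise_sigma",
    "add_noise",
]


class FitFailure(RuntimeError):
    """Raised when the single-exponential decay-rate fit is degenerate."""


@dataclass(frozen=True)
class NoiseSpec:
    """Correlator noise parameters.

    Tb: bin width, s.  Tint: integration time, s.  count_rate: detected
    photon rate, counts/s.  The mean photon count per bin <n> = count_rate*Tb
    must be positive.
    """

    Tb: float = 1e-6
    Tint: float = 1.0
    count_rate: float = 8050.0

    def __post_init__(self) -> None:
        if not (self.Tb > 0 and self.Tint > 0 and self.count_rate > 0):
            raise ValueError("Tb, Tint and count_rate must all be positive")

    @property
    def mean_counts(self) -> float:
        return self.count_rate * self.Tb


#: Named noise conditions: integration times of 1, 10 and 30 s at 8.05 kcps.
NOISE_PRESETS: dict[str, NoiseSpec | None] = {
    "noiseless": None,
    "Tint1": NoiseSpec(Tint=1.0),
    "Tint10": NoiseSpec(Tint=10.0),
    "Tint30": NoiseSpec(Tint=30.0),
}


def _gn_exponential_fit(tau: np.ndarray, y: np.ndarray, n_iter: int = 25):
    """Vectorized Gauss-Newton fit of y ~ 1 + beta*exp(-Gamma*tau).

    ``y`` has shape (..., n_lags).  Returns (beta, Gamma) with leading shape.
    Initialized from a log-linear regression of max(y-1, eps).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    d = np.clip(y - 1.0, 1e-12, None)
    logd = np.log(d)
    # weighted linear LS in log space, weights ~ d (emphasize the decaying head)
    wgt = d
    sw = wgt.sum(axis=1)
    mx = (wgt * tau).sum(axis=1) / sw
    my = (wgt * logd).sum(axis=1) / sw
    cov = (wgt * (tau - mx[:, None]) * (logd - my[:, None])).sum(axis=1)
    var = (wgt * (tau - mx[:, None]) ** 2).sum(axis=1)
    slope = cov / np.where(var > 0, var, 1.0)
    gamma = np.clip(-slope, 1.0, 1e9)
    beta = np.clip(np.exp(my + gamma * mx), 1e-6, 2.0)
    for _ in range(n_iter):
        e = np.exp(-gamma[:, None] * tau)
        r = 1.0 + beta[:, None] * e - y
        # Jacobian columns: d/dbeta = e ; d/dgamma = -beta*tau*e
        j11 = (e * e).sum(axis=1)
        j12 = (-beta[:, None] * tau * e * e).sum(axis=1)
        j22 = ((beta[:, None] * tau * e) ** 2).sum(axis=1)
        g1v = (e * r).sum(axis=1)
        g2v = (-beta[:, None] * tau * e * r).sum(axis=1)
        det = j11 * j22 - j12 * j12
        det = np.where(np.abs(det) > 1e-300, det, 1.0)
        db = -(j22 * g1v - j12 * g2v) / det
        dg = -(-j12 * g1v + j11 * g2v) / det
        beta = np.clip(beta + db, 1e-6, 2.0)
        gamma = np.clip(gamma + dg, 1e-3, 1e12)
    return beta, gamma


def estimate_decay_rate_batch(tau: np.ndarray, g2: np.ndarray):
    """(beta, Gamma) per row of a (n_curves, n_lags) stack of g2 values."""
    return _gn_exponential_fit(np.asarray(tau, dtype=float), g2)


def estimate_decay_rate(curve: CorrelationCurve,
                        beta_guess: float = 0.5) -> tuple[float, float]:
    """Least-squares (beta, Gamma) of g2 ~ 1 + beta*exp(-Gamma*tau).

    Raises :class:`FitFailure` for non-decaying input (the fitted curve must
    lose at least half of its initial contrast across the grid).
    """
    if curve.kind != "intensity":
        raise ValueError("decay-rate estimation expects an intensity curve")
    tau = curve.grid.tau
    y = curve.values
    contrast0 = y[0] - 1.0
    if contrast0 <= 0 or (y[-1] - 1.0) > 0.5 * contrast0:
        raise FitFailure("curve does not decay; Gamma is unidentifiable")
    beta, gamma = _gn_exponential_fit(tau, y[None, :])
    return float(beta[0]), float(gamma[0])


def noise_sigma(spec: NoiseSpec, beta: float, gamma: float,
                grid: DelayGrid) -> np.ndarray:
    """Per-lag standard deviation sigma(tau) of the correlator estimate of g2.

    sigma(tau) = sqrt(Tb/Tint) * [ beta^2 ((1+e^(-2 G Tb))(1+e^(-2 G tau))
                 + 2 m (1-e^(-2 G Tb)) e^(-2 G tau)) / (1-e^(-2 G Tb))
                 + 2 <n>^-1 beta (1+e^(-2 G tau))
                 + <n>^-2 (1+e^(-G tau)) ]^(1/2)

    with m = round(tau/Tb) the linear bin index and <n> the mean photon count
    per bin.  Scales exactly as Tint^(-1/2).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    tau = grid.tau
    Tb = spec.Tb
    n_mean = spec.mean_counts
    m = np.round(tau / Tb)
    e2b = np.exp(-2.0 * gamma * Tb)
    e2t = np.exp(-2.0 * gamma * tau)
    e1t = np.exp(-gamma * tau)
    denom = 1.0 - e2b
    if denom <= 0:  # gamma == 0: correlated-speckle term diverges per bin
        raise ValueError("gamma must be > 0 for the speckle term")
    bracket = (beta**2 * ((1.0 + e2b) * (1.0 + e2t)
                          + 2.0 * m * denom * e2t) / denom
               + 2.0 / n_mean * beta * (1.0 + e2t)
               + (1.0 + e1t) / n_mean**2)
    return np.sqrt(Tb / spec.Tint) * np.sqrt(bracket)


def add_noise(curve: CorrelationCurve, spec: NoiseSpec,
              seed: int) -> CorrelationCurve:
    """Add zero-mean Gaussian correlator noise to a noiseless g2 curve.

    The decay rate Gamma is re-estimated from the input curve; the noise is
    i.i.d. across lags with standard deviation ``noise_sigma``.  Deterministic
    for a given seed.  Values are intentionally not clipped: noisy g2 may
    fall below 1 or above 1 + beta, as in real measurements.
    """
    if curve.kind != "intensity":
        raise ValueError("noise injection expects an intensity curve")
    beta, gamma = estimate_decay_rate(curve)
    sig = noise_sigma(spec, beta, gamma, curve.grid)
    rng = np.random.default_rng(seed)
    noisy = curve.values + rng.normal(0.0, 1.0, curve.values.shape) * sig
    return curve.copy_with(noisy, noise={"Tint": spec.Tint, "Tb": spec.Tb,
                                         "count_rate": spec.count_rate,
                                         "seed": int(seed)})
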