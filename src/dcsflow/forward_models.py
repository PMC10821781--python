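"""Analytical field/intensity autocorrelation models for DCS.

Two solvers of the correlation diffusion equation are provided:

* a homogeneous semi-infinite half-space with extrapolated-boundary images,
  the classic model used both for curve fitting and for generating network
  training data; and
* a three-layer slab (scalp / skull / brain) solved in the transverse Fourier
  domain layer by layer and inverted with a zeroth-order Hankel transform.

Internal units are mm and seconds throughout; the wavelength is converted
from nm to mm inside :class:`AcquisitionSpec`, and lag times are reported in
microseconds only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import j0

__all__ = [
    "TissueLayer",
    "HeadModel",
    "AcquisitionSpec",
    "DelayGrid",
    "CorrelationCurve",
    "make_tau_grid",
    "semi_infinite_g1",
    "siegert_g2",
    "three_layer_ghat",
    "three_layer_g1",
    "baseline_head",
    "QMAX_MM",
]

#: Upper bound of the Hankel-transform integral over spatial frequency q.
QMAX_MM = 30.0

#: Speed of light in vacuum, mm/s.
C_VACUUM_MM_S = 2.99792458e11


@dataclass(frozen=True)
class TissueLayer:
    """Optical and dynamic description of one tissue slab.

    Parameters
    ----------
    mua : absorption coefficient, mm^-1.
    musp : reduced scattering coefficient, mm^-1.
    Db : effective Brownian diffusion coefficient of the moving
        scatterers, mm^2/s.  The blood flow index is ``alpha * Db``.
    thickness : slab thickness, mm.  Use ``np.inf`` for a semi-infinite
        deepest layer.
    g_anis : scattering anisotropy (used only by the Monte Carlo transport).
    n_ref : refractive index.
    alpha : fraction of scattering events on moving scatterers, in [0, 1].
    """

    mua: float
    musp: float
    Db: float
    thickness: float = math.inf
    g_anis: float = 0.89
    n_ref: float = 1.37
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not self.mua > 0:
            raise ValueError(f"mua must be > 0, got {self.mua}")
        if not self.musp > 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.Db < 0:
            raise ValueError(f"Db must be >= 0, got {self.Db}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")

    @property
    def bfi(self) -> float:
        """Blood flow index alpha * Db, mm^2/s."""
        return self.alpha * self.Db


@dataclass(frozen=True)
class HeadModel:
    """Ordered stack of tissue layers, top (scalp) first.

    The three-layer solver requires exactly three layers and treats the
    deepest one as semi-infinite.
    """

    layers: tuple[TissueLayer, ...]

    def __init__(self, layers: Sequence[TissueLayer]):
        object.__setattr__(self, "layers", tuple(layers))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative layer boundary depths L0..LN, mm (L0 = 0)."""
        t = [0.0]
        for lay in self.layers:
            t.append(t[-1] + lay.thickness)
        return np.asarray(t)

    def require_three(self) -> None:
        if len(self.layers) != 3:
            raise ValueError(
                f"three-layer solver needs exactly 3 layers, got {len(self.layers)}"
            )

    def with_brain_Db(self, Db: float) -> "HeadModel":
        """Copy of the model with the deepest layer's Db replaced."""
        new = list(self.layers)
        new[-1] = replace(new[-1], Db=Db)
        return HeadModel(new)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Measurement context for one source-detector channel.

    ``rho`` is the source-detector distance in mm, ``wavelength`` in nm,
    ``beta`` the coherence factor of the Siegert relation.  ``Tb``,
    ``Tint`` and ``count_rate`` parameterize the correlator noise model.
    """

    rho: float
    wavelength: float = 785.0
    beta: float = 0.5
    n_medium: float = 1.37
    Tb: float = 1e-6
    Tint: float = 1.0
    count_rate: float = 8050.0

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError(f"rho must be > 0, got {self.rho}")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be > 0")

    @property
    def k0(self) -> float:
        """Wavenumber 2*pi*n/lambda in the medium, mm^-1."""
        lam_mm = self.wavelength * 1e-6
        return 2.0 * math.pi * self.n_medium / lam_mm


@dataclass(frozen=True)
class DelayGrid:
    """Strictly increasing lag-time grid, seconds."""

    tau: np.ndarray

    def __init__(self, tau: np.ndarray):
        tau = np.asarray(tau, dtype=float)
        if tau.ndim != 1 or tau.size < 2:
            raise ValueError("tau grid must be 1-D with at least 2 points")
        if not np.all(np.diff(tau) > 0):
            raise ValueError("tau grid must be strictly increasing")
        if tau[0] <= 0:
            raise ValueError("lag times must be positive")
        object.__setattr__(self, "tau", tau)

    @property
    def n_points(self) -> int:
        return int(self.tau.size)

    @property
    def tau_us(self) -> np.ndarray:
        return self.tau * 1e6


@dataclass
class CorrelationCurve:
    """Lag grid plus g1 (field) or g2 (intensity) values with provenance."""

    grid: DelayGrid
    values: np.ndarray
    kind: Literal["field", "intensity"]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.tau.shape:
            raise ValueError("values and tau grid must have matching shapes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")
        if self.kind not in ("field", "intensity"):
            raise ValueError(f"unknown curve kind {self.kind!r}")

    def copy_with(self, values: np.ndarray, kind: str | None = None,
                  **prov) -> "CorrelationCurve":
        p = dict(self.provenance)
        p.update(prov)
        return CorrelationCurve(self.grid, values, kind or self.kind, p)


def make_tau_grid(n_points: int = 127, tau_min: float = 1e-6,
                  tau_max: float = 1e-2, spacing: str = "log") -> DelayGrid:
    """Build the correlator lag grid on the half-open interval [tau_min, tau_max).

    The default reproduces the standard 127-point grid spanning 1 us to
    10,000 us.  Spacing is logarithmic (multi-tau correlator convention) by
    default; ``spacing="linear"`` is available.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not (0 < tau_min < tau_max):
        raise ValueError("need 0 < tau_min < tau_max")
    if spacing == "log":
        # half-open: n_points steps of a geometric ladder whose (n+1)'th
        # rung would be tau_max
        ratio = (tau_max / tau_min) ** (1.0 / n_points)
        tau = tau_min * ratio ** np.arange(n_points)
    elif spacing == "linear":
        step = (tau_max - tau_min) / n_points
        tau = tau_min + step * np.arange(n_points)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return DelayGrid(tau)


def _semi_infinite_G1(layer: TissueLayer, acq: AcquisitionSpec,
                      tau: np.ndarray) -> np.ndarray:
    """Unnormalized G1 for the homogeneous half-space (extrapolated boundary)."""
    mua, musp = layer.mua, layer.musp
    k0 = acq.k0
    msd = 6.0 * layer.Db * tau                      # <Δr²(τ)>
    K = np.sqrt(3.0 * mua * musp + layer.alpha * musp**2 * k0**2 * msd)
    z0 = 1.0 / (mua + musp)
    zb = 5.0 / (3.0 * musp)
    r1 = math.hypot(acq.rho, z0)
    r2 = math.hypot(acq.rho, z0 + 2.0 * zb)
    pref = 3.0 * musp / (4.0 * math.pi)
    return pref * (np.exp(-K * r1) / r1 - np.exp(-K * r2) / r2)


def semi_infinite_g1(layer: TissueLayer, acq: AcquisitionSpec,
                     grid: DelayGrid) -> CorrelationCurve:
    """Normalized field autocorrelation g1(tau) of a homogeneous half-space.

    g1 = G1(rho, tau) / G1(rho, 0) with the decay constant
    K(tau) = sqrt(3 mua musp + alpha musp^2 k0^2 * 6 Db tau).
    """
    G = _semi_infinite_G1(layer, acq, grid.tau)
    G0 = _semi_infinite_G1(layer, acq, np.zeros(1))[0]
    g1 = G / G0
    return CorrelationCurve(
        grid, g1, "field",
        provenance={"generator": "semi_infinite", "rho_mm": acq.rho,
                    "mua": layer.mua, "musp": layer.musp, "Db": layer.Db,
                    "alpha": layer.alpha, "noise": "noiseless"},
    )


def siegert_g2(curve: CorrelationCurve, beta: float) -> CorrelationCurve:
    """Intensity autocorrelation via the Siegert relation g2 = 1 + beta*g1^2."""
    if curve.kind != "field":
        raise ValueError("siegert_g2 expects a field (g1) curve")
    if not 0.0 < beta <= 1.0:
        raise ValueError(f"beta must be in (0, 1], got {beta}")
    return curve.copy_with(1.0 + beta * curve.values**2, kind="intensity",
                           beta=beta)


# ---------------------------------------------------------------------------
# Three-layer Fourier-domain solution
# ---------------------------------------------------------------------------

def _theta_sq(layer: TissueLayer, k0: float, tau, q):
    """Theta_p^2(q, tau) = 3 mua musp + 6 k0^2 musp^2 Db tau + q^2."""
    return (3.0 * layer.mua * layer.musp
            + 6.0 * k0**2 * layer.musp**2 * (layer.alpha * layer.Db) * tau
            + q**2)


def three_layer_ghat(q, tau, head: HeadModel, acq: AcquisitionSpec):
    """Fourier-domain Green's function G^(q, z=0, tau) of the three-layer slab.

    Solves the transverse-Fourier correlation diffusion equation with a point
    source at depth z' inside the top layer, flux/value continuity at the two
    internal interfaces, a semi-infinite deepest layer, and an extrapolated
    (Dirichlet) boundary at z = -zb above the surface — the same boundary
    construction the semi-infinite image solution uses, so the two solvers
    agree in the homogeneous limit.

    The per-layer plane-wave coefficients are eliminated analytically with a
    bottom-up admittance recursion expressed through tanh and exponentials of
    non-positive arguments, so the result stays finite for arbitrarily large
    q (a literal cosh/sinh Num/Denom form overflows near q = 30 mm^-1).

    ``q`` and ``tau`` may be scalars or broadcastable arrays.
    """
    head.require_three()
    q = np.asarray(q, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be >= 0")
    l1, l2, l3 = head.layers
    k0 = acq.k0
    c_tissue = C_VACUUM_MM_S / acq.n_medium
    D1 = c_tissue / (3.0 * l1.musp)
    D2 = c_tissue / (3.0 * l2.musp)
    D3 = c_tissue / (3.0 * l3.musp)
    th1 = np.sqrt(_theta_sq(l1, k0, tau, q))
    th2 = np.sqrt(_theta_sq(l2, k0, tau, q))
    th3 = np.sqrt(_theta_sq(l3, k0, tau, q))

    zp = 1.0 / (l1.mua + l1.musp)        # source depth (one transport mfp)
    zb = 5.0 / (3.0 * l1.musp)           # extrapolation length
    d1, d2 = l1.thickness, l2.thickness

    # admittance looking down from the top of layer 2 (tanh is saturating,
    # never overflows)
    t2 = np.tanh(th2 * d2)
    h3 = (D3 * th3) / (D2 * th2)
    w = (D2 * th2) * (h3 + t2) / ((D1 * th1) * (1.0 + h3 * t2))
    # source sublayer of layer 1 (z' .. d1)
    t1 = np.tanh(th1 * (d1 - zp))
    # hyperbolics of th1*(zp+zb) and th1*zb factored as exp(-2*th1*...) <= 1
    E = np.exp(-2.0 * th1 * zb)
    F = np.exp(-2.0 * th1 * (zp + zb))
    num = 1.0 + w * t1
    den = th1 * ((1.0 + F) * num + (1.0 - F) * (w + t1))
    return 3.0 * l1.musp * np.exp(-th1 * zp) * (1.0 - E) * num / den


def _hankel_G(taus: np.ndarray, head: HeadModel, acq: AcquisitionSpec,
              n_nodes: int) -> np.ndarray:
    """(1/2pi) * integral_0^QMAX  G^(q,0,tau) q J0(q rho) dq  at each tau."""
    x, wts = leggauss(n_nodes)
    qn = 0.5 * QMAX_MM * (x + 1.0)
    wq = 0.5 * QMAX_MM * wts
    kern = qn * j0(qn * acq.rho) * wq                      # (nq,)
    ghat = three_layer_ghat(qn[:, None], taus[None, :], head, acq)  # (nq, nt)
    G = (kern @ ghat) / (2.0 * math.pi)
    scale = (np.abs(kern) @ ghat) / (2.0 * math.pi)        # cancellation scale
    return G, scale


class QuadratureError(RuntimeError):
    """Raised when the Hankel quadrature fails to converge."""


def three_layer_g1(head: HeadModel, acq: AcquisitionSpec, grid: DelayGrid,
                   n_nodes: int = 300, rtol: float = 1e-8,
                   max_doublings: int = 4) -> CorrelationCurve:
    """Normalized g1(tau) of the three-layer head model.

    The inverse Hankel transform is evaluated with fixed-order
    Gauss-Legendre quadrature on q in [0, 30] mm^-1, starting at ``n_nodes``
    nodes and doubling until two successive estimates of g1 agree to ``rtol``
    at every lag (at most ``max_doublings`` doublings).

    The oscillatory Bessel kernel cancels the O(1) integrand down to the
    e^(-K rho) attenuation scale; when that cancellation exceeds what double
    precision can resolve (strong absorption at large rho) the transform is
    meaningless and a :class:`QuadratureError` is raised.
    """
    head.require_three()
    taus = np.concatenate([[0.0], grid.tau])
    prev, scale = _hankel_G(taus, head, acq, n_nodes)
    for _ in range(max_doublings):
        n_nodes *= 2
        cur, scale = _hankel_G(taus, head, acq, n_nodes)
        g_prev = prev[1:] / prev[0]
        g_cur = cur[1:] / cur[0]
        # the Bessel kernel cancels the integrand down to |G|; roundoff
        # noise on g1 therefore floors near eps * (integrand scale / |G0|)
        noise_floor = 3e-13 * scale[0] / max(abs(cur[0]), 1e-300)
        last_change = float(np.max(np.abs(g_cur - g_prev)))
        if last_change < max(rtol, noise_floor):
            prev = cur
            break
        prev = cur
    else:
        raise QuadratureError(
            f"Hankel quadrature not converged after {max_doublings} doublings "
            f"(last node count {n_nodes}, max change {last_change:.3e})"
        )
    if abs(prev[0]) < 1e-13 * scale[0]:
        raise QuadratureError(
            "Hankel transform lost to cancellation: |G(0)| = "
            f"{abs(prev[0]):.3e} vs integrand scale {scale[0]:.3e}; "
            "the attenuation exp(-K rho) is below double-precision resolution"
        )
    g1 = prev[1:] / prev[0]
    return CorrelationCurve(
        grid, g1, "field",
        provenance={"generator": "three_layer", "rho_mm": acq.rho,
                    "Db": [l.Db for l in head.layers], "noise": "noiseless",
                    "n_nodes": n_nodes},
    )


def three_layer_g1_fixed(head: HeadModel, acq: AcquisitionSpec,
                         grid: DelayGrid, n_nodes: int) -> np.ndarray:
    """g1 at a fixed quadrature order (no adaptive doubling).

    Used inside iterative fitting, where the node count chosen adaptively
    once at the initial point is then frozen so the optimizer sees a smooth
    objective (adaptive switching introduces 1e-8-scale discontinuities
    that corrupt finite-difference Jacobians).
    """
    head.require_three()
    taus = np.concatenate([[0.0], grid.tau])
    G, _ = _hankel_G(taus, head, acq, n_nodes)
    return G[1:] / G[0]


def baseline_head(Db_brain: float = 6e-6) -> HeadModel:
    """Baseline scalp/skull/brain head model (785 nm literature values).

    Scalp 5 mm (mua 0.019, musp 0.660, Db 1e-6), skull 7 mm (mua 0.014,
    musp 0.860, Db 0), brain semi-infinite 50 mm (mua 0.019, musp 1.110,
    Db 6e-6 by default).
    """
    return HeadModel([
        TissueLayer(mua=0.019, musp=0.660, Db=1e-6, thickness=5.0),
        TissueLayer(mua=0.014, musp=0.860, Db=0.0, thickness=7.0),
        TissueLayer(mua=0.019, musp=1.110, Db=Db_brain, thickness=50.0),
    ])
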