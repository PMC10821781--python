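"""Layered-slab photon Monte Carlo with momentum-transfer scoring.

Photons are launched from a flat circular beam into a three-layer slab and
propagated with scattering only: absorption is applied analytically at
re-weighting time through exp(-sum_i mua_i * L_i), which makes one photon set
reusable across arbitrary absorption and layer-dynamics settings ("white"
Monte Carlo).  Each detected photon's history records, per layer, the total
path length L_i (mm) and the total momentum transfer Y_i = sum(1 - cos
theta) over its scattering events; the field autocorrelation follows as

    G1(tau) = <exp(-(k0^2/3) * sum_i Y_i <dr^2(tau)>_i) * exp(-sum_i mua_i L_i)>

with <dr^2(tau)>_i = 6 D_i tau.  The per-event factor exp(-(1/3) k0^2
(1-cos theta) <dr^2>) matches the standard diffusing-wave single-scattering
factor exp(-q^2 <dr^2>/6) with q^2 = 2 k0^2 (1-cos theta).

Scattering uses the Henyey-Greenstein phase function; the top surface has a
refractive mismatch (Fresnel reflection, n_in=1.37 vs n_out=1.0); bottom and
lateral boundaries absorb.  Detectors are concentric annular rings on the
top surface, which azimuthally average the discrete fibers of a physical probe and
raise detection efficiency at desk-scale photon budgets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .forward_models import (AcquisitionSpec, CorrelationCurve, DelayGrid,
                             HeadModel, baseline_head)

__all__ = [
    "SlabGeometry",
    "PhotonHistories",
    "simulate_photons",
    "g1_from_histories",
    "write_histories",
    "read_histories",
]


@dataclass(frozen=True)
class SlabGeometry:
    """Three-layer slab, a flat source beam, and annular ring detectors.

    thicknesses: per-layer, mm (top first).  musp/g per layer give the
    scattering interaction coefficient mus = musp/(1-g).  detector_rho:
    ring center radii, mm; detector_halfwidth: ring half-width, mm.
    """

    thicknesses: tuple[float, float, float] = (5.0, 7.0, 50.0)
    musp: tuple[float, float, float] = (0.660, 0.860, 1.110)
    g: float = 0.89
    n_in: float = 1.37
    n_out: float = 1.0
    source_diameter: float = 1.0
    detector_rho: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    detector_halfwidth: float = 0.5
    max_radius: float = 150.0
    max_path_factor: float = 10.0

    @classmethod
    def from_head(cls, head: HeadModel, **kw) -> "SlabGeometry":
        return cls(thicknesses=tuple(l.thickness for l in head.layers),
                   musp=tuple(l.musp for l in head.layers),
                   g=head.layers[0].g_anis, n_in=head.layers[0].n_ref, **kw)

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PhotonHistories:
    """Columnar per-detected-photon records.

    detector: ring index; L: (n, 3) per-layer path lengths, mm;
    Y: (n, 3) per-layer momentum transfer sums.
    """

    detector: np.ndarray
    L: np.ndarray
    Y: np.ndarray
    geometry_hash: str = ""
    seed: int = 0
    n_launched: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.detector.size)

    def select(self, detector: int) -> "PhotonHistories":
        m = self.detector == detector
        return PhotonHistories(self.detector[m], self.L[m], self.Y[m],
                               self.geometry_hash, self.seed, self.n_launched,
                               dict(self.meta))


@njit(cache=True)
def _transport_kernel(n_photons, seed, mus, boundaries, g, n_rel,
                      src_radius, det_lo, det_hi, max_radius, max_path,
                      out_det, out_L, out_Y):
    """Scattering-only transport loop.  Returns number of detected photons.

    n_rel = n_in / n_out at the top surface.  det_lo/det_hi: ring bounds.
    """
    np.random.seed(seed)
    n_det = 0
    cap = out_det.shape[0]
    for _ in range(n_photons):
        # launch: uniform over the source disk, straight down
        r = src_radius * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        L1 = 0.0; L2 = 0.0; L3 = 0.0
        Y1 = 0.0; Y2 = 0.0; Y3 = 0.0
        layer = 0
        total_path = 0.0
        alive = True
        s = -np.log(np.random.random()) / mus[0]   # geometric step, mm
        while alive:
            # distance to the layer boundary along uz
            if uz > 0.0:
                d_b = (boundaries[layer + 1] - z) / uz
            elif uz < 0.0:
                d_b = (boundaries[layer] - z) / uz
            else:
                d_b = 1e30
            if s < d_b:
                # scatter inside the current layer
                x += ux * s; y += uy * s; z += uz * s
                if layer == 0: L1 += s
                elif layer == 1: L2 += s
                else: L3 += s
                total_path += s
                if total_path > max_path:
                    break
                if x * x + y * y > max_radius * max_radius:
                    break
                # Henyey-Greenstein deflection
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    ct = 2.0 * np.random.random() - 1.0
                if ct > 1.0: ct = 1.0
                elif ct < -1.0: ct = -1.0
                if layer == 0: Y1 += 1.0 - ct
                elif layer == 1: Y2 += 1.0 - ct
                else: Y3 += 1.0 - ct
                st = np.sqrt(1.0 - ct * ct)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi); sp = np.sin(phi)
                if abs(uz) > 0.99999:
                    ux_n = st * cp
                    uy_n = st * sp
                    uz_n = ct * (1.0 if uz >= 0.0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -st * cp * den + uz * ct
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm; uy = uy_n / norm; uz = uz_n / norm
                s = -np.log(np.random.random()) / mus[layer]
            else:
                # move to the boundary
                x += ux * d_b; y += uy * d_b; z += uz * d_b
                if layer == 0: L1 += d_b
                elif layer == 1: L2 += d_b
                else: L3 += d_b
                total_path += d_b
                if total_path > max_path:
                    break
                s -= d_b
                if uz < 0.0 and layer == 0:
                    # top surface: Fresnel reflect or escape
                    ci = -uz          # cosine of incidence from inside
                    si = np.sqrt(1.0 - ci * ci)
                    st_out = n_rel * si
                    if st_out >= 1.0:
                        refl = 1.0    # total internal reflection
                    else:
                        ct_out = np.sqrt(1.0 - st_out * st_out)
                        rs = (n_rel * ci - ct_out) / (n_rel * ci + ct_out)
                        rp = (ci - n_rel * ct_out) / (ci + n_rel * ct_out)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        uz = -uz
                        z = 0.0
                        # rescale the leftover step for the (same) layer
                    else:
                        # escaped: detector test
                        rr = np.sqrt(x * x + y * y)
                        for di in range(det_lo.shape[0]):
                            if det_lo[di] <= rr <= det_hi[di]:
                                if n_det < cap:
                                    out_det[n_det] = di
                                    out_L[n_det, 0] = L1
                                    out_L[n_det, 1] = L2
                                    out_L[n_det, 2] = L3
                                    out_Y[n_det, 0] = Y1
                                    out_Y[n_det, 1] = Y2
                                    out_Y[n_det, 2] = Y3
                                    n_det += 1
                                break
                        alive = False
                elif uz > 0.0 and layer == 2:
                    alive = False      # absorbed at the bottom
                else:
                    # internal interface: uniform n, pass through
                    old = mus[layer]
                    if uz > 0.0:
                        layer += 1
                    else:
                        layer -= 1
                    s *= old / mus[layer]
                    # nudge off the boundary
                    if uz > 0.0:
                        z = boundaries[layer] + 1e-12
                    else:
                        z = boundaries[layer + 1] - 1e-12
    return n_det


def simulate_photons(geom: SlabGeometry, n_photons: int, seed: int,
                     capacity: int | None = None) -> PhotonHistories:
    """Run the transport kernel; returns histories of detected photons.

    Deterministic for a given seed (single-threaded kernel).  An empty
    collection (with a warning in ``meta``) is returned when nothing is
    detected.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mus = np.array([m / (1.0 - geom.g) for m in geom.musp])
    boundaries = np.concatenate([[0.0], np.cumsum(geom.thicknesses)])
    det_rho = np.asarray(geom.detector_rho, dtype=float)
    det_lo = det_rho - geom.detector_halfwidth
    det_hi = det_rho + geom.detector_halfwidth
    if np.any(det_lo <= geom.source_diameter / 2.0):
        raise ValueError("detector rings must not overlap the source footprint")
    cap = capacity or min(n_photons, 5_000_000)
    out_det = np.empty(cap, dtype=np.int32)
    out_L = np.empty((cap, 3))
    out_Y = np.empty((cap, 3))
    n_det = _transport_kernel(
        n_photons, seed & 0x7FFFFFFF, mus, boundaries, geom.g,
        geom.n_in / geom.n_out, geom.source_diameter / 2.0, det_lo, det_hi,
        geom.max_radius, geom.max_path_factor * boundaries[-1],
        out_det, out_L, out_Y)
    meta = {}
    if n_det == 0:
        meta["warning"] = "no photons detected"
    return PhotonHistories(out_det[:n_det].copy(), out_L[:n_det].copy(),
                           out_Y[:n_det].copy(), geom.content_hash(),
                           int(seed), int(n_photons), meta)


def g1_from_histories(histories: PhotonHistories, Db_per_layer,
                      mua_per_layer, acq: AcquisitionSpec,
                      grid: DelayGrid, detector: int | None = None,
                      chunk: int = 200_000) -> CorrelationCurve:
    """Reconstruct normalized g1(tau) from stored histories.

    Supports arbitrary per-layer (Db, mua) without re-simulation.  g1(0) = 1
    exactly by construction.
    """
    h = histories if detector is None else histories.select(detector)
    if len(h) == 0:
        raise ValueError("empty photon history collection")
    Db = np.asarray(Db_per_layer, dtype=float)
    mua = np.asarray(mua_per_layer, dtype=float)
    k0 = acq.k0
    # decay rate per photon: (k0^2/3) * sum_i Y_i * 6 Db_i  [1/s]
    rate = 2.0 * k0**2 * (h.Y @ Db)
    logw = -(h.L @ mua)
    logw -= logw.max()                    # stabilize the exponential weights
    tau = grid.tau
    num = np.zeros(tau.size)
    den = 0.0
    for i in range(0, len(h), chunk):
        w = np.exp(logw[i:i + chunk])
        num += (w[:, None] * np.exp(-rate[i:i + chunk, None] * tau)).sum(axis=0)
        den += w.sum()
    g1 = num / den
    return CorrelationCurve(
        grid, g1, "field",
        provenance={"generator": "mc", "seed": h.seed,
                    "n_launched": h.n_launched, "n_detected": len(h),
                    "detector": detector, "Db": list(Db), "mua": list(mua),
                    "noise": "noiseless"})


def write_histories(histories: PhotonHistories, path: str | Path) -> None:
    """Columnar text table (detector, L1..L3, Y1..Y3) with a JSON header line."""
    path = Path(path)
    header = json.dumps({"geometry_hash": histories.geometry_hash,
                         "seed": histories.seed,
                         "n_launched": histories.n_launched})
    body = np.column_stack([histories.detector.astype(float),
                            histories.L, histories.Y])
    with open(path, "w") as fh:
        fh.write("# " + header + "\n")
        fh.write("detector,L1,L2,L3,Y1,Y2,Y3\n")
        np.savetxt(fh, body, delimiter=",",
                   fmt=["%d"] + ["%.17g"] * 6)


def read_histories(path: str | Path,
                   expect_geometry: SlabGeometry | None = None
                   ) -> PhotonHistories:
    """Inverse of :func:`write_histories`; optionally enforces geometry."""
    path = Path(path)
    with open(path) as fh:
        header = json.loads(fh.readline().lstrip("# ").strip())
    if expect_geometry is not None:
        if header["geometry_hash"] != expect_geometry.content_hash():
            raise ValueError(
                "geometry hash mismatch: histories were simulated for a "
                "different slab geometry")
    data = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
    if data.size == 0:
        data = data.reshape(0, 7)
    return PhotonHistories(data[:, 0].astype(np.int32), data[:, 1:4],
                           data[:, 4:7], header["geometry_hash"],
                           int(header["seed"]), int(header["n_launched"]))
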