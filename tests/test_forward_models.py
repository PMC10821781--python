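"""Forward-model unit tests: grids, the semi-infinite closed form (against
an arbitrary-precision oracle), the Siegert relation, and the three-layer
Fourier-domain solution (against a high-precision hyperbolic-form oracle and
its homogeneous limit)."""

import math

import mpmath as mp
import numpy as np
import pytest

from dcsflow import (AcquisitionSpec, CorrelationCurve, HeadModel,
                     TissueLayer, make_tau_grid, semi_infinite_g1,
                     siegert_g2, baseline_head, three_layer_g1,
                     three_layer_ghat)
from dcsflow.forward_models import C_VACUUM_MM_S, DelayGrid

from conftest import homogeneous_head


class TestTauGrid:
    def test_default_grid_shape_and_bounds(self):
        g = make_tau_grid(127, 1e-6, 1e-2)
        assert g.n_points == 127
        assert g.tau[0] == 1e-6
        assert g.tau[-1] < 1e-2          # half-open upper bound
        assert np.all(np.diff(g.tau) > 0)

    def test_two_point_grid_starts_at_tau_min(self):
        g = make_tau_grid(2, 1e-6, 1e-5)
        assert g.tau[0] == 1e-6

    def test_log_spacing_has_constant_ratio(self):
        g = make_tau_grid(127, 1e-6, 1e-2)
        ratios = g.tau[1:] / g.tau[:-1]
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_linear_spacing(self):
        g = make_tau_grid(10, 1e-6, 1.1e-5, spacing="linear")
        assert np.allclose(np.diff(g.tau), np.diff(g.tau)[0])

    @pytest.mark.parametrize("args", [(1, 1e-6, 1e-2), (10, 0, 1e-2),
                                      (10, 1e-2, 1e-6)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            make_tau_grid(*args)


class TestSemiInfinite:
    def test_normalization_at_small_lag(self, grid):
        layer = TissueLayer(0.019, 1.110, 6e-6)
        g1 = semi_infinite_g1(layer, AcquisitionSpec(rho=30.0), grid)
        # tau -> 0 limit: extrapolate with the first two lags
        assert 0.0 < g1.values[0] < 1.0
        tiny = make_tau_grid(2, 1e-15, 1e-14)
        g1t = semi_infinite_g1(layer, AcquisitionSpec(rho=30.0), tiny)
        assert g1t.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_static_medium_is_flat(self, grid):
        layer = TissueLayer(0.019, 1.110, Db=0.0)
        g1 = semi_infinite_g1(layer, AcquisitionSpec(rho=30.0), grid)
        assert np.allclose(g1.values, 1.0, atol=1e-12)

    def test_monotone_nonincreasing(self, grid, rng):
        for _ in range(5):
            layer = TissueLayer(rng.uniform(0.01, 0.05),
                                rng.uniform(0.5, 1.6),
                                10 ** rng.uniform(-8, -5))
            acq = AcquisitionSpec(rho=rng.uniform(5, 30))
            v = semi_infinite_g1(layer, acq, grid).values
            assert np.all(np.diff(v) <= 0)
            assert np.all((v > 0) & (v <= 1))

    def test_against_arbitrary_precision_oracle(self):
        """Closed form at baseline brain-tissue values, tau=10 us, rho=30 mm."""
        mua, musp, Db, rho = 0.019, 1.110, 6e-6, 30.0
        lam_mm, n = 785e-6, 1.37
        grid = DelayGrid(np.array([1e-5, 2e-5]))
        ours = semi_infinite_g1(TissueLayer(mua, musp, Db),
                                AcquisitionSpec(rho=rho), grid).values[0]
        with mp.workdps(50):
            k0 = 2 * mp.pi * n / mp.mpf(lam_mm)
            z0 = 1 / (mp.mpf(mua) + mp.mpf(musp))
            zb = mp.mpf(5) / (3 * mp.mpf(musp))
            r1 = mp.sqrt(rho**2 + z0**2)
            r2 = mp.sqrt(rho**2 + (z0 + 2 * zb)**2)

            def G(tau):
                K = mp.sqrt(3 * mp.mpf(mua) * mp.mpf(musp)
                            + mp.mpf(musp)**2 * k0**2 * 6 * mp.mpf(Db) * tau)
                return mp.e**(-K * r1) / r1 - mp.e**(-K * r2) / r2

            oracle = float(G(mp.mpf("1e-5")) / G(0))
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_zero_musp_rejected(self):
        with pytest.raises(ValueError):
            TissueLayer(0.019, 0.0, 6e-6)


class TestSiegert:
    def test_constant_field_curve(self, grid):
        c = CorrelationCurve(grid, np.ones(grid.n_points), "field")
        g2 = siegert_g2(c, 0.5)
        assert np.allclose(g2.values, 1.5)
        assert g2.kind == "intensity"

    def test_pointwise_definition(self, grid, rng):
        v = rng.uniform(0, 1, grid.n_points)
        c = CorrelationCurve(grid, v, "field")
        beta = 0.37
        g2 = siegert_g2(c, beta)
        assert np.allclose(g2.values - 1.0, beta * v**2, atol=1e-15)

    def test_intercept_from_physical_curve(self, grid):
        layer = TissueLayer(0.019, 1.110, 6e-6)
        tiny = make_tau_grid(2, 1e-15, 1e-14)
        g2 = siegert_g2(semi_infinite_g1(layer, AcquisitionSpec(rho=30.0),
                                         tiny), 0.5)
        assert g2.values[0] == pytest.approx(1.5, abs=1e-9)

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.5])
    def test_invalid_beta(self, grid, beta):
        c = CorrelationCurve(grid, np.ones(grid.n_points), "field")
        with pytest.raises(ValueError):
            siegert_g2(c, beta)


def _ghat_oracle(q, tau, head, acq):
    """Independent high-precision evaluation via the explicit cosh/sinh
    Num/Denom closed form (no overflow-safe factoring)."""
    l1, l2, l3 = head.layers
    with mp.workdps(60):
        k0 = 2 * mp.pi * acq.n_medium / mp.mpf(acq.wavelength * 1e-6)
        c_t = mp.mpf(C_VACUUM_MM_S) / acq.n_medium
        D = [c_t / (3 * mp.mpf(l.musp)) for l in head.layers]
        th = [mp.sqrt(3 * mp.mpf(l.mua) * mp.mpf(l.musp)
                      + 6 * k0**2 * mp.mpf(l.musp)**2
                      * mp.mpf(l.alpha * l.Db) * tau + mp.mpf(q)**2)
              for l in head.layers]
        zp = 1 / (mp.mpf(l1.mua) + mp.mpf(l1.musp))
        zb = mp.mpf(5) / (3 * mp.mpf(l1.musp))
        d1, d2 = mp.mpf(l1.thickness), mp.mpf(l2.thickness)
        c1 = mp.cosh(th[0] * (d1 - zp))
        s1 = mp.sinh(th[0] * (d1 - zp))
        c2 = mp.cosh(th[1] * d2)
        s2 = mp.sinh(th[1] * d2)
        M = D[1] * th[1] * c2 + D[2] * th[2] * s2
        N = D[2] * th[2] * c2 + D[1] * th[1] * s2
        A = D[0] * th[0] * M * c1 + D[1] * th[1] * N * s1
        B = D[1] * th[1] * N * c1 + D[0] * th[0] * M * s1
        num = 3 * mp.mpf(l1.musp) * mp.sinh(th[0] * zb) * A
        den = th[0] * (mp.cosh(th[0] * (zp + zb)) * A
                       + mp.sinh(th[0] * (zp + zb)) * B)
        return float(num / den)


class TestThreeLayer:
    def test_ghat_against_symbolic_oracle(self, head, acq30):
        for q in (0.1, 1.0, 10.0):
            ours = float(three_layer_ghat(q, 1e-4, head, acq30))
            oracle = _ghat_oracle(q, mp.mpf("1e-4"), head, acq30)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_ghat_static_limit(self, head, acq30):
        """At tau=0 the dynamic terms vanish: same value as a Db=0 head."""
        static = HeadModel([TissueLayer(l.mua, l.musp, 0.0, l.thickness)
                            for l in head.layers])
        a = float(three_layer_ghat(0.5, 0.0, head, acq30))
        b = float(three_layer_ghat(0.5, 123.0, static, acq30))
        assert a == pytest.approx(b, rel=1e-14)

    def test_ghat_homogeneous_matches_half_space(self, acq30):
        """Identical layers equal the extrapolated half-space closed form."""
        mua, musp, Db = 0.019, 1.110, 6e-6
        hh = homogeneous_head(mua, musp, Db)
        k0 = acq30.k0
        zp = 1.0 / (mua + musp)
        zb = 5.0 / (3.0 * musp)
        for q in (0.1, 1.0, 10.0):
            th = math.sqrt(3 * mua * musp
                           + 6 * k0**2 * musp**2 * Db * 1e-4 + q**2)
            ref = (3 * musp / (2 * th)) * (math.exp(-th * zp)
                                           - math.exp(-th * (zp + 2 * zb)))
            ours = float(three_layer_ghat(q, 1e-4, hh, acq30))
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_ghat_finite_at_large_q(self, head, acq30):
        v = three_layer_ghat(np.array([30.0]), 1e-2, head, acq30)
        assert np.all(np.isfinite(v)) and np.all(v > 0)

    def test_wrong_layer_count_rejected(self, grid, acq30):
        two = HeadModel([TissueLayer(0.019, 1.1, 6e-6, 5.0)] * 2)
        with pytest.raises(ValueError):
            three_layer_g1(two, acq30, grid)

    def test_g1_normalization_and_monotonicity(self, head, acq30, grid):
        g = three_layer_g1(head, acq30, grid)
        assert np.all(np.diff(g.values) <= 0)
        assert np.all((g.values > 0) & (g.values <= 1))
        tiny = DelayGrid(np.array([1e-15, 2e-15]))
        gt = three_layer_g1(head, acq30, tiny)
        assert gt.values[0] == pytest.approx(1.0, abs=1e-9)

    def test_faster_decay_at_larger_separation(self, head, grid):
        g30 = three_layer_g1(head, AcquisitionSpec(rho=30.0), grid).values
        g5 = three_layer_g1(head, AcquisitionSpec(rho=5.0), grid).values
        assert np.all(g30[1:] <= g5[1:])

    def test_quadrature_doubling_converged(self, head, acq30, grid):
        a = three_layer_g1(head, acq30, grid, n_nodes=300).values
        b = three_layer_g1(head, acq30, grid, n_nodes=600).values
        assert np.max(np.abs(a - b)) < 1e-6

    def test_speed_of_light_choice_cancels(self, head, acq30, grid):
        """Dp rescales numerator and denominator jointly; g1 is invariant."""
        import dcsflow.forward_models as fm
        ref = three_layer_g1(head, acq30, grid).values
        orig = fm.C_VACUUM_MM_S
        try:
            fm.C_VACUUM_MM_S = orig * 7.3
            scaled = three_layer_g1(head, acq30, grid).values
        finally:
            fm.C_VACUUM_MM_S = orig
        assert np.allclose(ref, scaled, rtol=0, atol=1e-12)

    def test_increasing_any_layer_db_decreases_g1(self, head, acq30, grid,
                                                  rng):
        from dataclasses import replace
        base = three_layer_g1(head, acq30, grid).values
        for i in range(3):
            layers = list(head.layers)
            layers[i] = replace(layers[i], Db=layers[i].Db + 2e-6)
            up = three_layer_g1(HeadModel(layers), acq30, grid).values
            assert np.all(up <= base + 1e-12)
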