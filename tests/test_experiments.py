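"""Protocol tests: percentage-error formulas, relative-flow sweep mechanics,
intrinsic-sensitivity identities, robustness bookkeeping and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from dcsflow import AcquisitionSpec, make_tau_grid, siegert_g2, baseline_head, \
    three_layer_g1
from dcsflow.cli import main as cli_main
from dcsflow.experiments import (bfi_percent_error, brain_flow_sweep_values,
                                 rbfi_sweep, robustness_sweep,
                                 sensitivity_curve)


class TestErrorMetrics:
    def test_exact_estimate_zero_error(self):
        assert bfi_percent_error(6e-6, 6e-6) == 0.0

    def test_double_estimate_is_100(self):
        assert bfi_percent_error(2e-6, 1e-6) == 100.0

    def test_reference_value(self):
        # 5.71e-6 vs 6e-6 -> 4.83%
        assert bfi_percent_error(5.71e-6, 6e-6) == pytest.approx(4.83,
                                                                 abs=0.01)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            bfi_percent_error(1.0, 0.0)


class TestSweepGrid:
    def test_fine_ladder_endpoints(self):
        v = brain_flow_sweep_values()
        assert len(v) == 21
        assert v[0] == 6e-6
        assert v[-1] == pytest.approx(1.2e-5)

    def test_coarse_ladder(self):
        v = brain_flow_sweep_values(step=0.1, n_steps=11)
        assert len(v) == 11
        assert v[-1] == pytest.approx(1.2e-5)


class _OracleEstimator:
    """Estimator stub returning a prescribed function of the true flow."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, x):
        raise NotImplementedError


def test_sensitivity_identities(monkeypatch):
    """A perfect estimator has eta = 100% at every zeta; a deep-blind
    estimator has eta = 0%."""
    import dcsflow.experiments as ex

    calls = {"db": []}

    def fake_generate(head, acq, grid, generator, mc_histories=None):
        from dcsflow.forward_models import CorrelationCurve
        c = CorrelationCurve(grid, np.ones(grid.n_points), "intensity")
        c.provenance["db3"] = head.layers[-1].Db
        return c

    def perfect(curve, acq, method, network):
        return 0.5, curve.provenance["db3"], True

    def blind(curve, acq, method, network):
        return 0.5, 3e-6, True

    monkeypatch.setattr(ex, "generate_test_curve", fake_generate)
    monkeypatch.setattr(ex, "estimate_bfi", perfect)
    res = ex.sensitivity_curve("net", network=object())
    assert np.allclose(res.eta_pct, 100.0)
    assert np.all(res.zeta_pct >= 20.0)

    monkeypatch.setattr(ex, "estimate_bfi", blind)
    res = ex.sensitivity_curve("net", network=object())
    assert np.allclose(res.eta_pct, 0.0)


def test_rbfi_sweep_three_layer_self_consistency(grid):
    """Matched generator and model: relative-flow errors stay below 1%.

    Uses the coarse 6-step ladder for speed; the full 21-step sweep runs in
    the acceptance script."""
    df = rbfi_sweep("three", "analytic3", rho=30.0, step=0.2, n_steps=6)
    assert df.shape[0] == 6
    assert df.loc[0, "rbfi"] == 1.0                  # self-ratio at w=1
    assert df["rbfi_gt"].iloc[-1] == pytest.approx(2.0)
    assert df["err_rbfi_pct"].max() < 1.0
    assert df["converged"].all()


def test_robustness_zero_offset_cell_is_exact(grid):
    """At the 0% offset the assumed and matched fits coincide."""
    df = robustness_sweep("Delta2", "net",
                          network=_ConstNet(), rho=30.0)
    assert np.allclose(df["e_bfi_pct"], 0.0)
    center = df[df["offset_pct"] == 0.0]
    assert len(center) == 1


class _ConstNet:
    def predict(self, x):
        return np.tile([0.5, 5e-6], (np.asarray(x).shape[0], 1))


class TestCli:
    def test_unknown_subcommand_errors(self):
        r = CliRunner().invoke(cli_main, ["frobnicate"])
        assert r.exit_code != 0

    def test_missing_required_flag_errors(self):
        r = CliRunner().invoke(cli_main, ["generate-data"])
        assert r.exit_code != 0
        assert "Missing option" in r.output or "Usage" in r.output

    def test_generate_data_writes_manifest(self, tmp_path):
        r = CliRunner().invoke(cli_main, [
            "generate-data", "--n", "50", "--seed", "3",
            "--out", str(tmp_path / "d")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "d" / "train.npz").exists()
        man = json.loads((tmp_path / "d" /
                          "generate-data_manifest.json").read_text())
        assert man["arguments"]["seed"] == 3

    def test_pipeline_smoke(self, tmp_path):
        """generate -> train (few epochs) -> predict -> fit -> evaluate."""
        runner = CliRunner()
        d = tmp_path / "data"
        r = runner.invoke(cli_main, ["generate-data", "--n", "300",
                                     "--seed", "1", "--out", str(d)])
        assert r.exit_code == 0, r.output
        model = tmp_path / "model.npz"
        r = runner.invoke(cli_main, ["train", "--data", str(d), "--seed",
                                     "1", "--out", str(model),
                                     "--max-epochs", "3", "--patience", "2"])
        assert r.exit_code == 0, r.output
        # store a curve and predict + fit it
        from dcsflow.curve_io import write_curve
        grid = make_tau_grid()
        acq = AcquisitionSpec(rho=30.0, beta=0.5)
        curve = siegert_g2(three_layer_g1(baseline_head(), acq, grid), 0.5)
        cpath = tmp_path / "curve.csv"
        write_curve(curve, cpath)
        r = runner.invoke(cli_main, ["predict", "--model", str(model),
                                     "--curves", str(cpath)])
        assert r.exit_code == 0, r.output
        assert "bfi_hat" in r.output
        r = runner.invoke(cli_main, ["fit", "--model", "semi", "--curves",
                                     str(cpath), "--rho", "30"])
        assert r.exit_code == 0, r.output
        # tiny MC and an evaluation protocol
        r = runner.invoke(cli_main, ["simulate-mc", "--photons", "2000",
                                     "--seed", "2",
                                     "--out", str(tmp_path / "h.csv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["evaluate", "rbfi", "--method", "semi",
                                     "--out", str(tmp_path / "res")])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(tmp_path / "res" / "rbfi_semi_analytic3.csv")
        assert df.shape[0] == 21


def test_curve_io_round_trip(tmp_path, grid):
    from dcsflow.curve_io import read_curve, write_curve
    acq = AcquisitionSpec(rho=20.0, beta=0.5)
    c = siegert_g2(three_layer_g1(baseline_head(), acq, grid), 0.5)
    write_curve(c, tmp_path / "c.csv")
    back = read_curve(tmp_path / "c.csv")
    assert back.kind == "intensity"
    assert np.allclose(back.values, c.values, rtol=1e-15)
    assert np.allclose(back.grid.tau, c.grid.tau, rtol=1e-12)
    assert back.provenance["generator"] == "three_layer"


def test_config_parser(tmp_path):
    from dcsflow.curve_io import read_config
    p = tmp_path / "geom.cfg"
    p.write_text("photons = 1000\n# comment\nmusp = [0.5, 0.5, 0.5]\n"
                 "label = brain\n")
    cfg = read_config(p)
    assert cfg == {"photons": 1000, "musp": [0.5, 0.5, 0.5],
                   "label": "brain"}
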