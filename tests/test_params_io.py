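"""Parameter fixtures, JSON round trips, trace serialization, CLI smoke."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from opsinkit import (
    ClampProtocol,
    current_closed_form,
    fixture,
    fixture_names,
    load_params,
    normalize_conductance,
    save_params,
)
from opsinkit.cli import main as cli_main
from opsinkit.io import load_trace, save_trace


class TestFixtures:
    def test_published_values_spot_checks(self):
        rsrs = fixture("rsrs_final")
        assert rsrs.tauO_I == (1.81, 1.17, 0.021)
        assert rsrs.Grect == (10.77, 1.25, 44.52)
        assert rsrs.g == 1.0 and rsrs.E == 0.0
        assert rsrs.combine_O == rsrs.combine_R == "reciprocal_sum"
        mm = fixture("mm_final")
        assert mm.g == 62.22 and mm.E == -3.62
        assert mm.Grect is None and mm.conductance_mode == "absolute"
        pp = fixture("pp_final")
        assert pp.combine_O == "product"

    def test_all_six_fixtures_load_and_validate(self):
        for name in fixture_names():
            p = fixture(name)
            p.validate()

    def test_unknown_fixture(self):
        with pytest.raises(KeyError):
            fixture("nope")


class TestParamsIO:
    def test_round_trip_is_canonical(self, tmp_path, rsrs_final):
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        save_params(rsrs_final, p1)
        save_params(load_params(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_unknown_keys_rejected(self, tmp_path, rsrs_final):
        path = tmp_path / "p.json"
        d = rsrs_final.to_dict()
        d["mystery"] = 1
        path.write_text(json.dumps(d))
        with pytest.raises(ValueError, match="unknown keys"):
            load_params(path)

    def test_invariant_violations_rejected(self, tmp_path, rsrs_final):
        path = tmp_path / "p.json"
        d = rsrs_final.to_dict()
        d["tauR_I"] = list(d["tauR_I"])
        d["tauR_I"][1] = 1.5          # adaptation weight must be in [0, 1]
        path.write_text(json.dumps(d))
        with pytest.raises(ValueError):
            load_params(path)

    def test_normalize_conductance_preserves_product(self, rsrs_final):
        alt = normalize_conductance(rsrs_final, g=9.91)
        assert alt.g * alt.Grect[0] == pytest.approx(
            rsrs_final.g * rsrs_final.Grect[0])


class TestTraceIO:
    def test_round_trip(self, tmp_path, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=1000.0, t_on=0.05, t_off=0.55, t_end=0.9)
        t = np.arange(0.0, 0.9, 1e-3)
        tr = current_closed_form(t, prot, rsrs_final)
        path = tmp_path / "trace.csv"
        save_trace(tr, path)
        back = load_trace(path)
        np.testing.assert_allclose(back.current, tr.current, rtol=1e-10)
        assert back.protocol == prot

    def test_missing_sidecar(self, tmp_path):
        path = tmp_path / "orphan.csv"
        path.write_text("time_s,current\n0,0\n1,1\n")
        with pytest.raises(FileNotFoundError):
            load_trace(path)


class TestCli:
    def test_simulate_writes_trace(self, tmp_path):
        prot = {"irradiance_W_m2": 1000.0, "voltage_mV": -60.0,
                "t_on_s": 0.05, "t_off_s": 0.55, "t_end_s": 0.9}
        pp = tmp_path / "prot.json"
        pp.write_text(json.dumps(prot))
        out = tmp_path / "trace.csv"
        res = CliRunner().invoke(cli_main, [
            "simulate", "--opsin", "rsrs_final", "--protocol", str(pp),
            "--out", str(out)])
        assert res.exit_code == 0, res.output
        tr = load_trace(out)
        assert np.abs(tr.current).max() > 1.0

    def test_features_from_trace(self, tmp_path, rsrs_final):
        prot = ClampProtocol(V=-60.0, I=1000.0, t_on=0.05, t_off=0.55, t_end=0.9)
        t = np.arange(0.0, 0.9, 1.5e-4)
        save_trace(current_closed_form(t, prot, rsrs_final), tmp_path / "t.csv")
        out = tmp_path / "features.csv"
        res = CliRunner().invoke(cli_main, [
            "features", "--trace", str(tmp_path / "t.csv"), "--out", str(out)])
        assert res.exit_code == 0, res.output
        from opsinkit import FeatureSet
        fs = FeatureSet.from_csv(out)
        assert fs.has(1000.0, -60.0, "I_peak")

    def test_fit_cli_end_to_end_smoke(self, tmp_path, rsrs_final):
        from opsinkit import FitConfig
        from opsinkit.fitting import model_features
        cfg = FitConfig.test(seed=1)
        marks = __import__("opsinkit").FeatureSet()
        for I in (100.0, 1000.0, 10000.0):
            for V in (-80.0, -20.0):
                marks.add(I, V, "I_peak", 1.0)
        feats = model_features(rsrs_final, marks, cfg)
        fpath = tmp_path / "features.csv"
        feats.to_csv(fpath)
        (tmp_path / "fit.yaml").write_text(
            "mode: test\nstep2_starts: 10\nstep3_starts: 15\n"
            "pso_particles: 4\npso_budget_s: 1.0\npolish: false\n")
        out = tmp_path / "fit.json"
        res = CliRunner().invoke(cli_main, [
            "fit", "--features", str(fpath), "--config", str(tmp_path / "fit.yaml"),
            "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert {"intermediate", "final", "cost_final"} <= set(payload)
        assert payload["cost_final"] <= payload["cost_intermediate"] + 1e-12

    def test_unknown_opsin_exits_nonzero(self, tmp_path):
        pp = tmp_path / "prot.json"
        pp.write_text("{}")
        res = CliRunner().invoke(cli_main, [
            "simulate", "--opsin", "missing.json", "--protocol", str(pp),
            "--out", str(tmp_path / "x.csv")])
        assert res.exit_code != 0

    def test_unknown_subcommand_exits_2(self):
        res = CliRunner().invoke(cli_main, ["frobnicate"])
        assert res.exit_code == 2
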