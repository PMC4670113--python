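"""Config round-trips, pipeline outputs and the reproducibility manifest."""

import json

import numpy as np
import pytest
import yaml

from mesowm import RunConfig, SimulationSettings, load_config, paper_defaults, save_config
from mesowm.runner import run_experiment


def write_yaml(tmp_path, doc, name="cfg.yaml"):
    p = tmp_path / name
    p.write_text(yaml.safe_dump(doc))
    return p


class TestLoadConfig:
    def test_paper_defaults_profile(self, tmp_path):
        cfg = load_config(write_yaml(tmp_path, {"profile": "paper_defaults"}))
        assert cfg.params.tau4 == 800.0
        assert cfg.params.w13 == 0.023
        assert cfg.params.w11_star == 0.5588
        assert cfg.settings.dt == 0.001
        assert cfg.settings.n_steps == 120_000

    def test_rejects_invalid_time_constant(self, tmp_path):
        p = write_yaml(tmp_path, {"parameters": {"tau1": -1, "d_max": 3.5}})
        with pytest.raises(ValueError):
            load_config(p)

    def test_rejects_unknown_keys(self, tmp_path):
        with pytest.raises(ValueError, match="unknown"):
            load_config(write_yaml(tmp_path, {"parameters": {"tau9": 1.0}}))
        with pytest.raises(ValueError, match="unknown"):
            load_config(write_yaml(tmp_path, {"bogus_section": {}}))

    def test_missing_d_max_requires_acknowledgement(self, tmp_path):
        doc = {"parameters": {"w34": 0.3}}
        with pytest.raises(ValueError, match="d_max"):
            load_config(write_yaml(tmp_path, doc))
        doc["acknowledge_d_max_default"] = True
        cfg = load_config(write_yaml(tmp_path, doc))
        assert cfg.params.d_max == 3.5

    def test_round_trip(self, tmp_path):
        cfg = RunConfig(
            params=paper_defaults(w34=0.3, d_max=4.0),
            settings=SimulationSettings(dt=0.01, n_steps=100,
                                        n_realizations=10, seed=9),
            sweep_percents=np.array([50.0, 100.0, 150.0]),
            task="bifurcation")
        out = tmp_path / "saved.yaml"
        save_config(cfg, out)
        loaded = load_config(out)
        assert loaded.params == cfg.params
        assert loaded.settings == cfg.settings
        np.testing.assert_array_equal(loaded.sweep_percents, cfg.sweep_percents)
        # saving again reproduces the identical file
        out2 = tmp_path / "saved2.yaml"
        save_config(loaded, out2)
        assert out.read_text() == out2.read_text()


@pytest.fixture
def fast_config():
    return RunConfig(
        params=paper_defaults(),
        settings=SimulationSettings(dt=0.05, n_steps=200, n_realizations=200,
                                    seed=5),
        sweep_percents=np.arange(30.0, 161.0, 10.0),
        task="bifurcation")


class TestRunExperiment:
    def test_bifurcation_outputs(self, fast_config, tmp_path):
        manifest = run_experiment(fast_config, tmp_path / "run")
        assert {"bifurcation.csv", "landmarks.json", "config.yaml"} <= \
            set(manifest.files)
        side = json.loads((tmp_path / "run" / "landmarks.json").read_text())
        assert set(side["landmarks"]) >= {"P", "Q", "R"}
        assert side["landmarks"]["P"] < side["landmarks"]["Q"] < side["landmarks"]["R"]

    def test_manifest_checksums_reproducible(self, fast_config, tmp_path):
        m1 = run_experiment(fast_config, tmp_path / "a")
        m2 = run_experiment(fast_config, tmp_path / "b")
        assert m1.files == m2.files

    def test_manifest_records_caveats(self, fast_config, tmp_path):
        m = run_experiment(fast_config, tmp_path / "c")
        joined = " ".join(m.caveats)
        assert "d_max" in joined and "tau2" in joined

    def test_simulate_refuses_zone_I(self, tmp_path):
        cfg = RunConfig(
            params=paper_defaults().with_w34_percent(30.0),
            settings=SimulationSettings(dt=0.05, n_steps=10, n_realizations=5),
            task="simulate")
        with pytest.raises(ValueError, match="monostable"):
            run_experiment(cfg, tmp_path / "z")

    def test_landscape_task_outputs(self, tmp_path):
        cfg = RunConfig(
            params=paper_defaults(),
            settings=SimulationSettings(dt=0.05, n_steps=2400,
                                        n_realizations=400, seed=2),
            task="landscape")
        m = run_experiment(cfg, tmp_path / "l")
        assert "landscape.csv" in m.files
        side = json.loads((tmp_path / "l" / "landscape.json").read_text())
        assert "separatrix_x1" in side and "bin_edges" in side


class TestCLI:
    def test_bifurcation_command(self, tmp_path):
        from click.testing import CliRunner

        from mesowm.cli import main

        runner = CliRunner()
        out = tmp_path / "cli_run"
        res = runner.invoke(main, [
            "bifurcation", "--w34-range", "30", "160", "10",
            "--n-realizations", "10", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "bifurcation.csv").exists()

    def test_zone_I_exit_code(self, tmp_path):
        from click.testing import CliRunner

        from mesowm.cli import main

        runner = CliRunner()
        res = runner.invoke(main, [
            "simulate", "--w34", "30", "--n-realizations", "5",
            "--out", str(tmp_path / "x")])
        assert res.exit_code == 3

    def test_config_error_exit_code(self, tmp_path):
        from click.testing import CliRunner

        from mesowm.cli import main

        bad = tmp_path / "bad.yaml"
        bad.write_text("parameters: {tau1: -5}\n")
        res = CliRunner().invoke(main, [
            "bifurcation", "--config", str(bad), "--out", str(tmp_path / "y")])
        assert res.exit_code == 2
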