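"""Config loading, packaged scenarios, fixtures, validation and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import focusurf as fu
from focusurf.cli import main as cli_main
from focusurf.config import ConfigError
from focusurf.fixtures import make_fixture, tiny_sweep_config, toy_array_config


class TestPackagedConfigs:
    @pytest.mark.parametrize("name", ["prostate_validation", "pancreas_sweep",
                                      "pancreas_sweep_fast"])
    def test_all_packaged_configs_load(self, name):
        cfg = fu.load_packaged(name)
        assert cfg.name == name
        assert cfg.config_hash

    def test_validation_scenario_published_properties_intact(self):
        cfg = fu.load_packaged("prostate_validation")
        assert cfg.validation_scenario
        p = cfg.media["prostate"]
        assert (p.density, p.sound_speed) == (1060.0, 1500.0)
        assert p.attenuation_coeff == 0.504
        assert p.blood_perfusion == 2.5
        w = cfg.media["water"]
        assert (w.density, w.sound_speed) == (1000.0, 1480.0)
        assert cfg.media["rectal_wall"].attenuation_coeff == 0.5211
        assert cfg.media["periprostate"].attenuation_coeff == 0.4343
        assert cfg.frequency == 2.3e6
        assert cfg.array.nx_elements * cfg.array.ny_elements == 990

    def test_full_sweep_config_enumerates_19227(self):
        cfg = fu.load_packaged("pancreas_sweep")
        assert len(fu.enumerate_sweep(cfg.sweep)) == 19227

    def test_fast_sweep_config_enumerates_120(self):
        cfg = fu.load_packaged("pancreas_sweep_fast")
        assert len(fu.enumerate_sweep(cfg.sweep)) == 120


class TestLoadConfig:
    def test_units_converted_to_si(self):
        cfg = fu.load_config(toy_array_config(seed=0))
        assert cfg.stack.layers[0][1] == pytest.approx(8e-3)   # 8 mm
        assert cfg.frequency == pytest.approx(0.45e6)          # 0.45 MHz
        assert cfg.grid.dz == pytest.approx(2e-3)              # 2 mm
        assert cfg.focus[2] == pytest.approx(cfg.focus[2])
        assert 0 < cfg.focus[2] < 0.05                         # metres, not mm

    def test_missing_required_medium_key(self):
        raw = toy_array_config(seed=0)
        del raw["media"]["water"]["density"]
        with pytest.raises(ConfigError, match=r"media\.water\.density"):
            fu.load_config(raw)

    def test_unknown_key_rejected_with_path(self):
        raw = toy_array_config(seed=0)
        raw["array"]["frequenzy_mhz"] = 1.0
        with pytest.raises(ConfigError, match="frequenzy_mhz"):
            fu.load_config(raw)

    def test_unknown_layer_medium_rejected(self):
        raw = toy_array_config(seed=0)
        raw["stack"]["layers"][0]["medium"] = "mercury"
        with pytest.raises(ConfigError, match="mercury"):
            fu.load_config(raw)

    def test_stack_must_cover_grid_depth(self):
        raw = toy_array_config(seed=0)
        raw["stack"]["layers"][1]["thickness_mm"] = 10  # 18 mm < 32 mm grid
        with pytest.raises(ConfigError, match="thinner"):
            fu.load_config(raw)

    def test_hash_stable_and_sensitive(self):
        a = fu.load_config(toy_array_config(seed=0))
        b = fu.load_config(toy_array_config(seed=0))
        assert a.config_hash == b.config_hash
        raw = toy_array_config(seed=0)
        raw["array"]["v0_m_per_s"] = 2.0
        assert fu.load_config(raw).config_hash != a.config_hash

    def test_excitation_override_rebuilds_array_and_phases(self):
        cfg = fu.load_config(toy_array_config(seed=0))
        arr, exc = cfg.excitation(nx=8, ny=4, focus_mm_z=25.0)
        assert (arr.nx_elements, arr.ny_elements) == (8, 4)
        assert arr.aperture_x == cfg.array.aperture_x  # aperture fixed
        assert exc.focus == (0.0, 0.0, 0.025)
        assert len(exc.phases) == 32


class TestFixtures:
    def test_yaml_fixture_deterministic_bytes(self, tmp_path):
        p1 = make_fixture("toy_array", 5, tmp_path / "a")
        p2 = make_fixture("toy_array", 5, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        p3 = make_fixture("toy_array", 6, tmp_path / "c")
        assert yaml.safe_load(p1.read_text()) != yaml.safe_load(p3.read_text()) \
            or p1.read_bytes() == p3.read_bytes()  # seeds may collide on focus

    def test_tiny_sweep_fixture_has_six_combinations(self, tmp_path):
        path = make_fixture("tiny_sweep", 0, tmp_path)
        cfg = fu.load_config(path)
        assert len(fu.enumerate_sweep(cfg.sweep)) == 6

    def test_gaussian_fixture_round_trips_through_hdf5(self, tmp_path):
        from focusurf.fixtures import gaussian_temperature_field
        from focusurf.io import load_scalar

        path = make_fixture("gaussian_temperature", 2, tmp_path)
        field, truth = gaussian_temperature_field(seed=2)
        loaded = load_scalar(path, "temperature")
        assert np.allclose(loaded, field.values)
        assert loaded.max() == pytest.approx(37.0 + truth["peak_rise_c"])

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown fixture kind"):
            make_fixture("nonsense", 0, tmp_path)


@pytest.fixture(scope="module")
def toy_validation_report():
    """Toy scenario flagged as a validation case, calibrated to 6.2 degC."""
    raw = toy_array_config(seed=0)
    raw["validation_scenario"] = True
    cfg = fu.load_config(raw)
    return fu.validate_scenario(cfg, calibrate_peak_c=6.2, contour_level_c=4.0)


class TestValidateScenario:
    def test_calibrated_peak_is_exact(self, toy_validation_report):
        rep = toy_validation_report
        assert rep["peak_rise_c"] == pytest.approx(6.2, rel=1e-12)
        assert rep["calibrated"] is True
        assert rep["contour_width_mm"] > 0
        assert rep["assumptions"]  # caveats are always reported

    def test_scale_factor_consistent_with_quadratic_power_law(self,
                                                              toy_validation_report):
        """Rise is linear in Q and Q is quadratic in v0, so the reported
        velocity scale squared times the uncalibrated peak gives 6.2."""
        rep = toy_validation_report
        raw = toy_array_config(seed=0)
        raw["validation_scenario"] = True
        cfg = fu.load_config(raw)
        uncal = fu.validate_scenario(cfg)  # no calibration
        assert rep["v0_scale_factor"] ** 2 * uncal["peak_rise_c"] == pytest.approx(
            6.2, rel=1e-9)

    def test_rise_linear_in_deposited_power(self):
        raw = toy_array_config(seed=0)
        raw["validation_scenario"] = True
        cfg1 = fu.load_config(raw)
        raw2 = toy_array_config(seed=0)
        raw2["validation_scenario"] = True
        raw2["array"]["v0_m_per_s"] = 2.0  # doubles v0 -> quadruples Q
        cfg2 = fu.load_config(raw2)
        r1 = fu.validate_scenario(cfg1)
        r2 = fu.validate_scenario(cfg2)
        assert r2["peak_rise_c"] == pytest.approx(4 * r1["peak_rise_c"], rel=1e-6)

    def test_non_validation_config_rejected(self):
        cfg = fu.load_config(toy_array_config(seed=0))
        with pytest.raises(ValueError, match="validation scenario"):
            fu.validate_scenario(cfg)


class TestCli:
    def test_make_fixture_command(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["make-fixture", "--kind", "tiny_sweep",
                                       "--seed", "0", "--out-dir", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "tiny_sweep_seed0.yaml").exists()

    def test_simulate_command_writes_volumes_and_sidecar(self, tmp_path):
        cfg_path = make_fixture("toy_array", 0, tmp_path)
        out = tmp_path / "field.h5"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["--quiet", "simulate", "--config",
                                       str(cfg_path), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert out.exists()
        sidecar = json.loads(out.with_suffix(".json").read_text())
        assert sidecar["max_pressure_pa"] > 0
        assert sidecar["max_temperature_c"] > 37.0
        pressure, _layer_idx = fu.load_pressure(out)
        assert np.abs(pressure).max() >= sidecar["max_pressure_pa"] * (1 - 1e-12)

    def test_sweep_command(self, tmp_path):
        cfg_path = make_fixture("tiny_sweep", 0, tmp_path)
        csv = tmp_path / "data.csv"
        runner = CliRunner()
        res = runner.invoke(cli_main, ["--quiet", "sweep", "--config",
                                       str(cfg_path), "--out", str(csv)])
        assert res.exit_code == 0, res.output
        assert "6 rows" in res.output
        assert csv.exists()

    def test_train_and_evaluate_commands(self, tmp_path):
        # synthetic dataset: every feature must vary for min-max scaling
        import pandas as pd
        rng = np.random.default_rng(0)
        n = 40
        nx, ny = rng.integers(16, 129, n), rng.integers(16, 65, n)
        focus = rng.uniform(25, 75, n)
        df = pd.DataFrame({"nx": nx, "ny": ny, "focus_mm": focus,
                           "max_pressure_pa": 1e6 + 1e4 * nx + 3e3 * ny,
                           "max_power_w_m3": 2e6 + 5e4 * nx - 1e4 * focus,
                           "max_temperature_c": 37 + 0.05 * nx + 0.01 * ny})
        csv = tmp_path / "data.csv"
        df.to_csv(csv, index=False)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["--quiet", "train", "--data", str(csv),
                                       "--out", str(tmp_path / "models")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "models" / "models.joblib").exists()
        report = json.loads((tmp_path / "models" / "report_test.json").read_text())
        assert set(report) == set(fu.MODEL_KINDS)
        # score the persisted models on a disjoint external table
        ext = df.copy()
        ext["focus_mm"] += 0.123
        ext_csv = tmp_path / "external.csv"
        ext.to_csv(ext_csv, index=False)
        res = runner.invoke(cli_main, ["--quiet", "evaluate", "--models",
                                       str(tmp_path / "models"), "--external",
                                       str(ext_csv), "--out",
                                       str(tmp_path / "ext.json")])
        assert res.exit_code == 0, res.output
        assert set(json.loads((tmp_path / "ext.json").read_text())) == set(
            fu.MODEL_KINDS)

    def test_unknown_packaged_config_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", "no_such_config",
                                       "--out", str(tmp_path / "x.h5")])
        assert res.exit_code != 0
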