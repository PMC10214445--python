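"""Config validation, file round-trips, CLI dispatch."""

import json

import numpy as np
import pytest
import yaml

from vesiwrap import io as vio
from vesiwrap.analysis import ObservableSeries
from vesiwrap.cli import cli_dispatch
from vesiwrap.config import default_config, load_config, save_config
from vesiwrap.flicker import ContourSeries
from vesiwrap.synth import synth_pathway


class TestConfig:
    def test_minimal_config_fills_defaults(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("stage: theory\n")
        cfg = load_config(path)
        assert cfg.params["eta_eff"] == 0.8
        assert cfg.seed == 0

    def test_roundtrip_identical(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("stage: simulate\nseed: 5\n"
                        "params:\n  sim:\n    kBT: 0.25\n")
        cfg = load_config(path)
        out = tmp_path / "resolved.yaml"
        save_config(cfg, out)
        cfg2 = load_config(out)
        assert cfg2.to_dict() == cfg.to_dict()
        assert cfg2.params["sim"]["kBT"] == 0.25

    def test_two_loads_identical(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("stage: tension\nparams:\n  n_max: 15\n")
        assert load_config(path).to_dict() == load_config(path).to_dict()

    def test_unknown_key_named_in_error(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("stage: theory\nparams:\n  sigmma: 1.0\n")
        with pytest.raises(ValueError, match="sigmma"):
            load_config(path)

    def test_type_mismatch_named(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("stage: tension\nparams:\n  n_min: three\n")
        with pytest.raises(ValueError, match="n_min"):
            load_config(path)

    def test_missing_stage(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("seed: 1\n")
        with pytest.raises(ValueError, match="stage"):
            load_config(path)

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            default_config("imaginary")


class TestObservablesIO:
    def _series(self, n=1000, seed=0):
        return synth_pathway("parallel_full", seed=seed).observables

    def test_roundtrip(self, tmp_path):
        s = self._series()
        path = tmp_path / "obs.csv"
        vio.write_observables(s, path, seed=7)
        back = vio.read_observables(path)
        assert np.allclose(back.theta, s.theta)
        assert np.allclose(back.d, s.d)
        assert list(back.state) == list(s.state)
        # provenance header present
        head = path.read_text().splitlines()[0]
        assert head.startswith("#") and "seed=7" in head

    def test_empty_series(self, tmp_path):
        empty = ObservableSeries(time=np.empty(0), theta=np.empty(0),
                                 d=np.empty(0), z=np.empty(0),
                                 f1=np.empty(0), f2=np.empty(0),
                                 state=np.empty(0, dtype=object))
        path = tmp_path / "empty.csv"
        vio.write_observables(empty, path)
        back = vio.read_observables(path)
        assert len(back) == 0

    def test_invalid_state_token_reports_line(self, tmp_path):
        s = self._series()
        path = tmp_path / "obs.csv"
        vio.write_observables(s, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5].rsplit(",", 1)[0] + ",Q7"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=r":\d+.*Q7"):
            vio.read_observables(path)


class TestContoursIO:
    def test_roundtrip(self, tmp_path):
        radii = 10.0 * (1 + 0.01 * np.random.default_rng(0).standard_normal((5, 128)))
        series = ContourSeries(radii=radii, frame_interval=0.05)
        path = tmp_path / "contours.csv"
        vio.write_contours(series, path, seed=3)
        back = vio.read_contours(path)
        assert np.allclose(back.radii, series.radii)
        assert back.frame_interval == 0.05


class TestExtXYZ:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        frames = [{"species": ["M"] * 4 + ["S"] * 2,
                   "positions": rng.random((6, 3)) * 10,
                   "normals": np.vstack([rng.random((4, 3)), np.zeros((2, 3))]),
                   "time": 12.5, "box": 30.0}]
        path = tmp_path / "traj.extxyz"
        vio.write_extxyz(path, frames, seed=2)
        back = vio.read_extxyz(path)
        assert len(back) == 1
        assert back[0]["species"] == frames[0]["species"]
        assert np.allclose(back[0]["positions"], frames[0]["positions"],
                           atol=1e-6)
        assert back[0]["time"] == 12.5
        assert back[0]["box"] == 30.0


class TestCLI:
    def test_no_arguments_usage_nonzero(self, capsys):
        assert cli_dispatch([]) != 0

    def test_unknown_subcommand(self):
        with pytest.raises(SystemExit):
            cli_dispatch(["frobnicate"])

    def test_synth_then_tension_end_to_end(self, tmp_path, capsys):
        contours = tmp_path / "contours.csv"
        rc = cli_dispatch(["synth", "contours", "--sigma", "1e-7",
                           "--kappa", "20kT", "--frames", "300",
                           "--seed", "1", "--out", str(contours)])
        assert rc == 0
        rc = cli_dispatch(["tension", "--in", str(contours),
                           "--out", str(tmp_path)])
        assert rc == 0
        fit = json.loads((tmp_path / "tension_fit.json").read_text())
        assert fit["sigma_N_per_m"] == pytest.approx(1e-7, rel=0.3)

    def test_theory_chain(self, tmp_path):
        wt = tmp_path / "wraptime.csv"
        assert cli_dispatch(["synth", "wraptime", "--cv", "0.0",
                             "--seed", "2", "--out", str(wt)]) == 0
        fitfile = tmp_path / "fit.json"
        assert cli_dispatch(["theory", "fit", "--in", str(wt),
                             "--out", str(fitfile)]) == 0
        fit = json.loads(fitfile.read_text())
        assert fit["W_J_per_m2"] == pytest.approx(0.76e-6, rel=1e-3)
        assert fit["eta_eff_Pa_s"] == pytest.approx(0.8, rel=1e-3)
        bar = tmp_path / "barrier.json"
        assert cli_dispatch(["theory", "barrier", "--out", str(bar)]) == 0
        assert 10 < json.loads(bar.read_text())["h_star_nm"] < 500

    def test_synth_pathway_analyze(self, tmp_path):
        obs = tmp_path / "obs.csv"
        assert cli_dispatch(["synth", "pathway", "--template",
                             "perpendicular_half", "--seed", "3",
                             "--out", str(obs)]) == 0
        assert cli_dispatch(["analyze", "--in", str(obs),
                             "--out", str(tmp_path)]) == 0
        trans = json.loads((tmp_path / "transitions.json").read_text())
        assert trans["end_state"] == "D"

    def test_synth_determinism_byte_identical(self, tmp_path):
        a = tmp_path / "a.csv"
        b = tmp_path / "b.csv"
        for path in (a, b):
            assert cli_dispatch(["synth", "pathway", "--seed", "9",
                                 "--out", str(path)]) == 0
        assert a.read_bytes() == b.read_bytes()

    def test_defaults_prints_yaml(self, capsys):
        assert cli_dispatch(["defaults", "simulate"]) == 0
        out = capsys.readouterr().out
        parsed = yaml.safe_load(out)
        assert parsed["stage"] == "simulate"

    def test_simulate_smoke(self, tmp_path):
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(
            "stage: simulate\n"
            "params:\n"
            "  vesicle: {n_beads: 300}\n"
            "  dumbbell: {lobe_radius: 2.0}\n"
            "  sim: {n_steps: 2000, snapshot_stride: 1000}\n")
        out = tmp_path / "run"
        rc = cli_dispatch(["simulate", "--config", str(cfg), "--seed", "4",
                           "--out", str(out)])
        assert rc == 0
        assert (out / "observables.csv").exists()
        assert (out / "trajectory.extxyz").exists()
        assert (out / "resolved_config.yaml").exists()
        series = vio.read_observables(out / "observables.csv")
        assert len(series) >= 2
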