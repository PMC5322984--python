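"""Experiment orchestration, configuration I/O, fixtures, and CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
from click.testing import CliRunner

from mrpool.cli import main
from mrpool.config import (config_hash, load_tissue, save_tissue,
                           timeline_from_dict, timeline_to_dict,
                           tissue_from_dict, tissue_to_dict)
from mrpool.experiments import generate_fixtures, run_experiment
from mrpool.sequence import build_multi_spin_echo
from mrpool.tissue import preset_model, validate_model


class TestConfig:
    def test_tissue_dict_roundtrip(self, preset):
        back = tissue_from_dict(tissue_to_dict(preset))
        assert back.pools == preset.pools
        assert np.array_equal(back.exchange.rates, preset.exchange.rates)

    def test_yaml_file_roundtrip(self, tmp_path):
        m = preset_model("gagcest_three_pool")
        path = tmp_path / "t.yaml"
        save_tissue(m, path)
        back = load_tissue(path)
        assert back.pools == m.pools

    def test_flat_dialect(self, tmp_path):
        text = "\n".join([
            "name=simple",
            "proton_density=1.0",
            "pools.0.name=water",
            "pools.0.kind=free",
            "pools.0.fraction=1.0",
            "pools.0.t1=1.0",
            "pools.0.t2=0.08",
            "exchange.0.0=0.0",
        ])
        path = tmp_path / "t.txt"
        path.write_text(text)
        m = load_tissue(path)
        assert validate_model(m) == []
        assert m.pools[0].t2 == 0.08

    def test_xml_shim(self, tmp_path):
        xml = """<tissue>
          <name>simple</name>
          <proton_density>1.0</proton_density>
          <pools>
            <pool><name>water</name><kind>free</kind>
              <fraction>1.0</fraction><t1>1.0</t1><t2>0.08</t2></pool>
            <pool><name>b</name><kind>bound</kind>
              <fraction>0.0</fraction><t1>1.0</t1><t2>1e-5</t2>
              <lineshape>gaussian</lineshape></pool>
          </pools>
          <exchange>
            <row><v>0</v><v>0</v></row>
            <row><v>0</v><v>0</v></row>
          </exchange>
        </tissue>"""
        path = tmp_path / "t.xml"
        path.write_text(xml)
        d = load_tissue.__globals__["_parse_xml"](xml)
        assert d["pools"][0]["t2"] == 0.08

    def test_timeline_roundtrip(self):
        tl = build_multi_spin_echo(0.010, 4)
        back = timeline_from_dict(timeline_to_dict(tl))
        assert back.segments == tl.segments
        assert back.events == tl.events

    def test_config_hash_order_insensitive(self):
        h1 = config_hash({"a": 1, "b": [1, 2]})
        h2 = config_hash({"b": [1, 2], "a": 1})
        assert h1 == h2
        assert h1 != config_hash({"a": 2, "b": [1, 2]})


class TestRunExperiment:
    def test_bundle_and_outputs(self, tmp_path):
        cfg = {"study": "mwf_exchange_bias", "k_values": [25.0],
               "n_echoes": 16, "seed": 0}
        bundle = run_experiment(cfg, tmp_path)
        assert bundle["config_hash"] == config_hash(cfg)
        assert (tmp_path / "mwf_exchange_bias.json").exists()
        tsv = (tmp_path / "mwf_exchange_bias.tsv").read_text()
        assert "rel_error_percent" in tsv
        err = bundle["result"]["errors_percent"][0]
        assert -75.0 < err < -55.0

    def test_unknown_study(self):
        with pytest.raises(KeyError):
            run_experiment({"study": "nope"})

    def test_reproducible_bundle(self, tmp_path):
        cfg = {"study": "mwf_exchange_bias", "k_values": [4.0],
               "n_echoes": 12}
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert a["result"] == b["result"]


class TestFixtures:
    def test_deterministic_bytes(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        w1 = generate_fixtures(3, d1)
        w2 = generate_fixtures(3, d2)
        assert set(Path(p).name for p in w1.values()) == \
            set(Path(p).name for p in w2.values())
        for name in w1:
            assert Path(w1[name]).read_bytes() == Path(w2[name]).read_bytes()

    def test_includes_all_presets(self, tmp_path):
        w = generate_fixtures(0, tmp_path)
        for name in ("mwf_two_pool", "qmt_two_pool", "gagcest_three_pool",
                     "mt_fat_three_pool"):
            assert name in w
            assert validate_model(load_tissue(w[name])) == []


class TestCli:
    def test_fixtures_command(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["fixtures", "--seed", "1",
                                   "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "cylinder.json").exists()

    def test_sequence_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "seq.json"
        res = runner.invoke(main, ["sequence", "--kind", "cpmg",
                                   "--n", "4", "--out", str(out)])
        assert res.exit_code == 0, res.output
        data = json.loads(out.read_text())
        assert len([s for s in data["segments"] if s["adc"]]) == 4

    def test_simulate_and_fit_commands(self, tmp_path):
        runner = CliRunner()
        tissue = tmp_path / "t.yaml"
        save_tissue(preset_model("mwf_two_pool", {"k": 0.0}), tissue)
        adc = tmp_path / "adc.tsv"
        res = runner.invoke(main, ["simulate", "--tissue", str(tissue),
                                   "--sequence", "cpmg", "--te", "0.01",
                                   "--n", "12", "--out", str(adc)])
        assert res.exit_code == 0, res.output
        data = np.loadtxt(adc)
        assert data.shape == (12, 4)
        train = tmp_path / "train.tsv"
        t = data[:, 0] - (data[0, 0] - 0.01)
        np.savetxt(train, np.column_stack([t, data[:, 3]]))
        fit_out = tmp_path / "fit.json"
        res = runner.invoke(main, ["fit", "--train", str(train),
                                   "--out", str(fit_out)])
        assert res.exit_code == 0, res.output
        payload = json.loads(fit_out.read_text())
        assert payload["mwf"] == pytest.approx(0.15, abs=0.02)

    def test_phantom_command(self, tmp_path):
        runner = CliRunner()
        tissue = tmp_path / "t.yaml"
        save_tissue(preset_model("qmt_two_pool"), tissue)
        out = tmp_path / "ph.json"
        res = runner.invoke(main, ["phantom", "--tissue", str(tissue),
                                   "--radius", "2.0", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert json.loads(out.read_text())["shape"] == [8, 8, 1]

    def test_experiment_command(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("study: mwf_exchange_bias\n"
                       "k_values: [25.0]\nn_echoes: 12\n")
        res = runner.invoke(main, ["experiment", "--config", str(cfg),
                                   "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "mwf_exchange_bias.json").exists()
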