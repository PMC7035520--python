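"""File formats, pipeline driver and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from netpharm import io as npio
from netpharm.cli import main as cli_main
from netpharm.errors import FormatError, NetpharmError
from netpharm.networks import build_bipartite_network, build_target_disease_network
from netpharm.pipeline import PipelineConfig, run_pipeline, simulate_inputs
from netpharm.synthetic import (
    SimulationConfig,
    simulate_bipartite_edges,
    simulate_compound_library,
    simulate_dose_response,
    simulate_flow_events,
)


class TestAdmetTable:
    def test_bundled_table_reads_verbatim(self, candidate_records):
        assert len(candidate_records) == 32
        majudin = candidate_records[0]
        assert majudin.compound_id == "Majudin"
        assert majudin.hia == 0.9933
        assert majudin.cyp == (0.9774, 0.8257, 0.8931, 0.9296, 0.7959)

    def test_unicode_minus_normalized(self, tmp_path):
        path = tmp_path / "t.csv"
        header = ",".join(npio.ADMET_COLUMNS)
        path.write_text(f"{header}\nX,,,0.9,−0.5,0.1,0.2,0.3,0.4,0.5\n")
        (record,) = npio.read_admet_table(path)
        assert record.caco2 == -0.5

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "t.csv"
        cols = [c for c in npio.ADMET_COLUMNS if c != "cyp_3a4"]
        path.write_text(",".join(cols) + "\nX,,,0.9,0.5,0.1,0.2,0.3,0.4\n")
        with pytest.raises(FormatError, match="cyp_3a4"):
            npio.read_admet_table(path)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        path = tmp_path / "t.csv"
        header = ",".join(npio.ADMET_COLUMNS)
        path.write_text(f"{header}\nX,,,0.9,oops,0.1,0.2,0.3,0.4,0.5\n")
        with pytest.raises(FormatError, match="line 2"):
            npio.read_admet_table(path)

    def test_round_trip(self, tmp_path, candidate_records):
        path = tmp_path / "out.tsv"
        npio.write_admet_table(candidate_records, path)
        assert npio.read_admet_table(path) == candidate_records


class TestNetworkFiles:
    def _network(self, seed=0):
        config = SimulationConfig(seed=seed, n_compounds=15, n_targets=25, hub_count=3)
        compounds, targets, edges = simulate_bipartite_edges(config).data
        return build_bipartite_network(compounds, targets, edges)

    def test_edge_list_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "edges.csv"
        npio.write_edges(net.compounds, net.targets, sorted(net.edges), path)
        compounds, targets, edges = npio.read_edges(path)
        rebuilt = build_bipartite_network(compounds, targets, edges)
        assert rebuilt.edges == net.edges and dict(rebuilt.roles) == dict(net.roles)

    def test_sif_round_trip_with_isolated_targets(self, tmp_path):
        net = self._network(seed=1)
        path = tmp_path / "net.sif"
        npio.write_sif(net, path)
        rebuilt = npio.read_sif(path)
        assert rebuilt.edges == net.edges
        assert dict(rebuilt.roles) == dict(net.roles)

    def test_graphml_round_trip_preserves_annotations(self, tmp_path):
        net = build_bipartite_network(
            ["resveratrol", "viniferin"], ["BCL2", "CASP3", "lonely"],
            [("resveratrol", "BCL2"), ("viniferin", "CASP3")],
            metadata={"viniferin": {"family": "stilbene"}},
        )
        path = tmp_path / "net.graphml"
        npio.write_graphml(net, path)
        rebuilt = npio.read_graphml(path)
        assert rebuilt.edges == net.edges
        assert dict(rebuilt.roles) == dict(net.roles)
        assert rebuilt.metadata["viniferin"]["family"] == "stilbene"

    def test_target_disease_sif_and_graphml(self, tmp_path):
        td = build_target_disease_network(
            [("BCR", "cml"), ("ABL1", "cml"), ("TP53", "aml")],
            {"cml": ["C04", "C15"], "aml": ["C04"]},
        )
        sif = tmp_path / "td.sif"
        npio.write_sif(td, sif)
        text = sif.read_text()
        assert "td" in text and "dg" in text
        gml = tmp_path / "td.graphml"
        npio.write_graphml(td, gml)
        rebuilt = npio.read_graphml(gml)
        assert rebuilt.td_edges == td.td_edges and rebuilt.dg_edges == td.dg_edges


class TestAssayFiles:
    def test_plate_round_trip(self, tmp_path):
        sim = simulate_dose_response(SimulationConfig(seed=3))
        path = tmp_path / "plate.csv"
        npio.write_plate_table(sim.data, path)
        rebuilt = npio.read_plate_table(path)
        assert rebuilt.readings == sim.data.readings
        assert rebuilt.timepoint == sim.data.timepoint

    def test_flow_round_trip(self, tmp_path):
        sim = simulate_flow_events(SimulationConfig(seed=4, n_events=200))
        path = tmp_path / "flow.csv"
        npio.write_flow_events(sim.data, path)
        rebuilt = npio.read_flow_events(path, thresholds=sim.data.thresholds)
        assert np.array_equal(rebuilt.events, sim.data.events)


class TestPipeline:
    def test_screen_stage_on_bundled_table(self, tmp_path):
        config = PipelineConfig(stages=("screen",), out_dir=str(tmp_path / "run"))
        report = run_pipeline(config)
        assert report["stages"]["screen"]["n_retained"] == 32
        assert (tmp_path / "run" / "screen_retained.csv").exists()

    def test_synthetic_run_is_byte_identical(self, tmp_path):
        summaries = []
        for name in ("a", "b"):
            config = simulate_inputs(
                PipelineConfig(seed=123, out_dir=str(tmp_path / name))
            )
            run_pipeline(config)
            text = (tmp_path / name / "summary.json").read_text()
            # out_dir differs between the two runs; the digest covers it
            summaries.append(json.loads(text)["stages"])
        assert summaries[0] == summaries[1]

    def test_missing_edge_file_names_the_path(self, tmp_path):
        config = PipelineConfig(
            stages=("network",), edges=str(tmp_path / "nope.csv"),
            out_dir=str(tmp_path / "run"),
        )
        with pytest.raises(NetpharmError, match="nope.csv"):
            run_pipeline(config)

    def test_config_yaml_round_trip(self, tmp_path):
        config = PipelineConfig(seed=9, score_floor=0.5, stages=("screen", "network"))
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        assert PipelineConfig.from_yaml(path) == config


class TestCli:
    def test_screen_defaults_to_bundled_table(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "screen", "--out", str(tmp_path / "kept.csv"),
            "--discard-log", str(tmp_path / "drop.csv"),
        ])
        assert result.exit_code == 0, result.output
        assert "retained 32 of 32" in result.output

    def test_network_command(self, tmp_path):
        config = SimulationConfig(seed=2, n_compounds=30, n_targets=40, hub_count=4)
        compounds, targets, edges = simulate_bipartite_edges(config).data
        edges_path = tmp_path / "edges.csv"
        npio.write_edges(compounds, targets, edges, edges_path)
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "network", "--edges", str(edges_path),
            "--out", str(tmp_path / "net.sif"),
        ])
        assert result.exit_code == 0, result.output
        assert "70 nodes" in result.output
        assert "4 hub targets" in result.output

    def test_missing_input_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, [
            "network", "--edges", str(tmp_path / "absent.csv"),
        ])
        assert result.exit_code != 0
        assert "absent.csv" in result.output

    def test_doseresponse_command(self, tmp_path):
        sim = simulate_dose_response(SimulationConfig(seed=0, noise_sd=0.0))
        plate = tmp_path / "plate.csv"
        npio.write_plate_table(sim.data, plate)
        runner = CliRunner()
        result = runner.invoke(cli_main, ["doseresponse", "--plate", str(plate)])
        assert result.exit_code == 0, result.output
        assert "IC50 = 13.6" in result.output
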