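import json

import networkx as nx
import pandas as pd
import pytest
from click.testing import CliRunner

from trophinet import AnalysisConfig, SyntheticConfig, build_ensemble, generate
from trophinet import netio
from trophinet.background_knowledge import build_cooccurrence
from trophinet.cli import main
from trophinet.ratio_observations import build_observations


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("data")
    eco = generate(SyntheticConfig(n_species=8, n_sites=10, rng_seed=21))
    netio.write_counts(eco.counts, out / "counts.csv")
    netio.write_traits(eco.traits, out / "traits.csv")
    netio.write_points(eco.points, out / "points.csv")
    acfg = AnalysisConfig(rng_seed=21)
    obs = build_observations(eco.counts, acfg)
    cooc = build_cooccurrence(eco.points, eco.counts)
    ensemble = build_ensemble(obs, eco.traits, cooc, acfg)
    return out, eco, ensemble


class TestReaders:
    def test_round_trip_counts(self, small_run):
        out, eco, _ = small_run
        df = netio.read_counts(out / "counts.csv")
        assert len(df) == len(eco.counts)
        assert df["count"].dtype.kind == "i"

    def test_round_trip_traits(self, small_run):
        out, eco, _ = small_run
        assert netio.read_traits(out / "traits.csv") == eco.traits

    def test_negative_count_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "species_id,site_id,treatment,count\na,s1,gmht,1\na,s1,conventional,-2\n"
        )
        with pytest.raises(ValueError, match=r"bad\.csv:3"):
            netio.read_counts(p)

    def test_bad_treatment_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species_id,site_id,treatment,count\na,s1,organic,1\n")
        with pytest.raises(ValueError, match="treatment"):
            netio.read_counts(p)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,count\na,1\n")
        with pytest.raises(ValueError, match="header"):
            netio.read_counts(p)

    def test_unknown_species_named_in_error(self, small_run):
        out, eco, _ = small_run
        counts = netio.read_counts(out / "counts.csv")
        traits = dict(eco.traits)
        traits.pop("sp001")
        with pytest.raises(ValueError, match="sp001"):
            netio.check_species_known(counts, traits)


class TestExport:
    def test_csv_round_trip_reproduces_edge_set(self, small_run, tmp_path):
        _, eco, ensemble = small_run
        path = tmp_path / "edges.csv"
        netio.export_network(ensemble, path, "csv", eco.traits)
        back = netio.read_network_csv(path)
        assert set(zip(back["predator_id"], back["prey_id"])) == set(
            ensemble.link_frequency
        )
        for row in back.itertuples(index=False):
            assert row.probability == pytest.approx(
                ensemble.probability((row.predator_id, row.prey_id)), abs=1e-4
            )

    def test_empty_ensemble_writes_header_only(self, tmp_path):
        from trophinet import PermutationEnsemble

        empty = PermutationEnsemble(networks=[], link_frequency={},
                                    n_permutations=10, rng_seed=0)
        path = tmp_path / "edges.csv"
        netio.export_network(empty, path, "csv")
        assert path.read_text().strip() == ",".join(netio.EDGE_COLUMNS)

    def test_graphml_carries_probability_weights(self, small_run, tmp_path):
        _, eco, ensemble = small_run
        path = tmp_path / "edges.graphml"
        netio.export_network(ensemble, path, "graphml", eco.traits)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == len(ensemble.link_frequency)
        for _, _, data in g.edges(data=True):
            assert 0 < data["probability"] <= 1

    def test_dot_penwidth_scales_with_probability(self, small_run, tmp_path):
        _, eco, ensemble = small_run
        path = tmp_path / "edges.dot"
        netio.export_network(ensemble, path, "dot", eco.traits)
        text = path.read_text()
        assert text.startswith("digraph")
        (pair, count), = list(ensemble.link_frequency.items())[:1]
        p = count / ensemble.n_permutations
        assert f"penwidth={4 * p:.3f}" in text

    def test_unknown_format_rejected(self, small_run, tmp_path):
        _, eco, ensemble = small_run
        with pytest.raises(ValueError, match="format"):
            netio.export_network(ensemble, tmp_path / "x", "svg")


def test_manifest_round_trip(small_run, tmp_path):
    out, _, _ = small_run
    m = netio.RunManifest(seed=21, config=AnalysisConfig().to_dict())
    m.add_input(out / "counts.csv")
    m.save(tmp_path / "manifest.json")
    back = netio.RunManifest.load(tmp_path / "manifest.json")
    assert back == m


class TestCli:
    def test_full_pipeline_is_deterministic(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(main, ["simulate", "--out-dir", str(data), "--seed", "3",
                                 "--n-species", "8", "--n-sites", "10"])
        assert r.exit_code == 0, r.output
        outputs = []
        for name in ("runA", "runB"):
            r = runner.invoke(main, [
                "learn", "--counts", str(data / "counts.csv"),
                "--traits", str(data / "traits.csv"),
                "--points", str(data / "points.csv"),
                "--out-dir", str(tmp_path / name), "--seed", "3",
            ])
            assert r.exit_code == 0, r.output
            outputs.append((tmp_path / name / "edges.csv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_observe_writes_ratio_table(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(main, ["simulate", "--out-dir", str(data), "--seed", "4",
                             "--n-species", "6", "--n-sites", "8"])
        r = runner.invoke(main, ["observe", "--counts", str(data / "counts.csv"),
                                 "--out-dir", str(tmp_path / "obs")])
        assert r.exit_code == 0, r.output
        ratios = pd.read_csv(tmp_path / "obs" / "ratios.csv")
        assert {"L1", "L2", "R", "direction"} <= set(ratios.columns)

    def test_crossval_majority_summary(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(main, ["simulate", "--out-dir", str(data), "--seed", "5",
                             "--n-species", "8", "--n-sites", "10"])
        out = tmp_path / "cv.json"
        r = runner.invoke(main, [
            "crossval", "--counts", str(data / "counts.csv"),
            "--traits", str(data / "traits.csv"),
            "--points", str(data / "points.csv"),
            "--mode", "majority", "--out", str(out), "--seed", "5",
        ])
        assert r.exit_code == 0, r.output
        summary = json.loads(out.read_text())
        assert summary["mode"] == "majority"
        assert 0 <= summary["accuracy"] <= 100

    def test_missing_input_file_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, ["observe", "--counts", str(tmp_path / "nope.csv"),
                                 "--out-dir", str(tmp_path)])
        assert r.exit_code != 0

    def test_export_converts_csv_to_dot(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        runner.invoke(main, ["simulate", "--out-dir", str(data), "--seed", "6",
                             "--n-species", "8", "--n-sites", "10"])
        runner.invoke(main, [
            "learn", "--counts", str(data / "counts.csv"),
            "--traits", str(data / "traits.csv"),
            "--out-dir", str(tmp_path / "net"), "--seed", "6",
        ])
        r = runner.invoke(main, [
            "export", "--edges", str(tmp_path / "net" / "edges.csv"),
            "--fmt", "dot", "--out", str(tmp_path / "net.dot"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "net.dot").read_text().startswith("digraph")
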