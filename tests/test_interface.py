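"""Tests for TSV formats, configuration and the command-line interface."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from grnbench.cli import main
from grnbench.containers import DirectedEdgeSet, ExpressionMatrix, UndirectedNetwork
from grnbench.io import (
    RunConfig,
    export_sif,
    read_config,
    read_edges_tsv,
    read_expression_tsv,
    read_pairs_tsv,
    write_edges_tsv,
    write_expression_tsv,
    write_pairs_tsv,
)


class TestExpressionTSV:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            np.arange(6, dtype=float).reshape(2, 3),
            index=["gA", "gB"], columns=["s1", "s2", "s3"],
        )
        expr = ExpressionMatrix(values=df)
        path = tmp_path / "e.tsv"
        write_expression_tsv(expr, path)
        back = read_expression_tsv(path)
        pd.testing.assert_frame_equal(back.values, df, check_names=False)

    def test_small_wellformed_file(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene\ts1\ts2\ngA\t1.0\t2.0\ngB\t0.5\t-1\n")
        e = read_expression_tsv(p)
        assert e.genes == ["gA", "gB"] and e.samples == ["s1", "s2"]

    def test_duplicate_gene_named_in_error(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene\ts1\ngA\t1.0\ngA\t2.0\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_tsv(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\ts1\ts2\ngA\t1.0\toops\n")
        with pytest.raises(ValueError, match="s2"):
            read_expression_tsv(p)

    def test_missing_value_located(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text("gene\ts1\ts2\ngA\t1.0\t\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_tsv(p)


class TestEdgeTSV:
    def test_directed_roundtrip(self, tmp_path):
        net = DirectedEdgeSet.from_edges({("A", "B"): "+", ("C", "D"): "-"})
        p = tmp_path / "edges.tsv"
        write_edges_tsv(net, p)
        back = read_edges_tsv(p)
        assert back.edges == net.edges

    def test_self_edge_rejected(self, tmp_path):
        p = tmp_path / "self.tsv"
        p.write_text("regulator\ttarget\tsign\nA\tA\t+\n")
        with pytest.raises(ValueError, match="self-edge"):
            read_edges_tsv(p)

    def test_duplicate_edge_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("regulator\ttarget\tsign\nA\tB\t+\nA\tB\t-\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_edges_tsv(p)

    def test_pairs_normalized_lexicographically(self, tmp_path):
        net = UndirectedNetwork.from_pairs([("Z", "A"), ("B", "C")])
        p = tmp_path / "pairs.tsv"
        write_pairs_tsv(net, p)
        body = p.read_text().splitlines()
        assert body[1] == "A\tZ"
        assert read_pairs_tsv(p).pairs == net.pairs

    def test_empty_network_is_header_only(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_pairs_tsv(UndirectedNetwork.from_pairs([], universe=["A"]), p)
        assert p.read_text().strip() == "gene_a\tgene_b"

    def test_sif_export(self, tmp_path):
        net = DirectedEdgeSet.from_edges({("A", "B"): "+"})
        p = tmp_path / "n.sif"
        export_sif(net, p)
        assert p.read_text() == "A\tpd\tB\n"


class TestRunConfig:
    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("n_genes: 10\nbogus_key: 3\n")
        with pytest.raises(ValueError, match="bogus_key"):
            read_config(p)

    def test_roundtrip_defaults(self, tmp_path):
        p = tmp_path / "c.yaml"
        p.write_text("n_genes: 12\nseed: 5\n")
        cfg = read_config(p)
        assert cfg.n_genes == 12 and cfg.seed == 5
        assert cfg.fdr_level == 0.05


@pytest.fixture(scope="module")
def cli_outputs(tmp_path_factory):
    """Run simulate -> build-gold -> infer once for the CLI tests."""
    out = tmp_path_factory.mktemp("cli")
    runner = CliRunner()
    r = runner.invoke(main, [
        "simulate", "--n-genes", "20", "--n-tfs", "4", "--mean-out-degree", "3",
        "--noise-sd", "0.2", "--n-samples", "80", "--seed", "5",
        "--out-dir", str(out),
    ])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, [
        "build-gold", "--de", str(out / "mutant_de.tsv"),
        "--binding", str(out / "binding_scores.tsv"),
        "--threshold", "0.005", "--min-conservation", "0",
        "--out", str(out / "gold.tsv"),
    ])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, [
        "infer", "--data", str(out / "expression_perturbation.tsv"),
        "--test", "z", "--rule", "fdr", "--combine", "or",
        "--out", str(out / "inferred.tsv"),
    ])
    assert r.exit_code == 0, r.output
    return out


class TestCLI:
    def test_stage_artifacts_exist(self, cli_outputs):
        for name in ("true_network.tsv", "mutant_de.tsv", "binding_scores.tsv",
                     "gold.tsv", "inferred.tsv"):
            assert (cli_outputs / name).exists()

    def test_evaluate_stage(self, cli_outputs):
        runner = CliRunner()
        out = cli_outputs / "metrics.tsv"
        r = runner.invoke(main, [
            "evaluate", "--inferred", str(cli_outputs / "inferred.tsv"),
            "--gold", str(cli_outputs / "gold.tsv"), "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(out, sep="\t").set_index("metric")["value"]
        assert 0 <= table["sensitivity"] <= 1
        assert table["hypergeometric_p"] <= 1

    def test_subnet_stage(self, cli_outputs):
        runner = CliRunner()
        r = runner.invoke(main, [
            "subnet", "--inferred", str(cli_outputs / "inferred.tsv"),
            "--gold", str(cli_outputs / "gold.tsv"),
            "--n-perm", "49", "--seed", "2",
            "--out", str(cli_outputs / "subnet.tsv"),
        ])
        assert r.exit_code == 0, r.output
        assert "rho=" in r.output

    def test_missing_input_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(main, [
            "infer", "--data", str(tmp_path / "nope.tsv"),
            "--out", str(tmp_path / "o.tsv"),
        ])
        assert r.exit_code != 0
        assert not (tmp_path / "o.tsv").exists()


def _dir_digest(root: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.iterdir()) if p.is_file()
    }


class TestFullGrid:
    def test_all_runs_and_is_byte_identical(self, tmp_path):
        runner = CliRunner()
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "n_genes: 15\nn_tfs: 3\nmean_out_degree: 2\nnoise_sd: 0.3\n"
            "n_samples: 50\nn_wt: 10\nn_mut: 10\nn_perm: 20\nseed: 4\n"
            "approaches: [BIVARIATE_Z_ALPHA, BIVARIATE_G_FDR_OR, GLL_Z_1_AND]\n"
        )
        digests = []
        for run in ("run1", "run2"):
            r = runner.invoke(main, ["all", "--config", str(cfg),
                                     "--out-dir", str(tmp_path / run)])
            assert r.exit_code == 0, r.output
            digests.append(_dir_digest(tmp_path / run))
        assert digests[0] == digests[1]
        produced = set(digests[0])
        assert "metrics_grid.tsv" in produced
        assert "pareto_summary.tsv" in produced
        assert any(name.startswith("gold_") for name in produced)

    def test_default_scale_grid_emits_every_artifact(self, tmp_path):
        # 30 genes, 5 TFs, 4 designs, all 18 approaches, 3 gold standards
        from grnbench.io import RunConfig
        from grnbench.pipeline import run_all

        cfg = RunConfig(out_dir=str(tmp_path / "grid"), seed=2, n_perm=50)
        res = run_all(cfg)
        assert len(res["inferred"]) == 18 * 4
        assert set(res["golds"]) == {"conservative", "intermediate", "liberal"}
        out = tmp_path / "grid"
        for metric in ("d_ss", "d_pn", "d_rp"):
            assert (out / f"table_{metric}_pairs.tsv").exists()
            assert (out / f"table_{metric}_distance.tsv").exists()
        for name in ("metrics_grid.tsv", "pareto_frontier.tsv",
                     "pareto_summary.tsv", "subnet_significant_counts.tsv"):
            assert (out / name).exists()
        cells = pd.read_csv(out / "metrics_grid.tsv", sep="\t")
        assert len(cells) == 3 * 18 * 4
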