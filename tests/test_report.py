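import logging

import pandas as pd
import pytest
from click.testing import CliRunner
from helpers import write_vcf

from radsexing import (
    RunConfig,
    SimCohortParams,
    load_config,
    run_pipeline,
    write_fixture_triplet,
)
from radsexing.cli import main
from radsexing.report import make_plots

COHORT = SimCohortParams(
    n_individuals=20,
    n_autosomal_loci=400,
    n_x_loci=120,
    n_y_loci=25,
    locus_length=4,
    mean_depth=15.0,
    seed=2024,
)


@pytest.fixture(scope="module")
def triplet(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture_triplet(COHORT, out)


def test_pipeline_calls_match_simulated_truth(triplet, tmp_path):
    cmap, cfg = load_config(triplet["chrom_config"])
    report = run_pipeline(triplet["vcf"], cmap, cfg, out_dir=tmp_path)
    truth = pd.read_csv(triplet["truth"])
    assert len(report.frame) == len(truth) == 20
    merged = report.frame.merge(
        truth, left_on="individual", right_on="individual_id"
    )
    assert (merged["sex"] == merged["true_sex"]).all()
    assert report.csv_path.exists() and report.plot_path.exists()
    assert report.plot_path.stat().st_size > 0


def test_final_csv_round_trips_to_configured_precision(triplet, tmp_path):
    cmap, _ = load_config(triplet["chrom_config"])
    cfg = RunConfig(output_precision=4)
    report = run_pipeline(triplet["vcf"], cmap, cfg, out_dir=tmp_path)
    back = pd.read_csv(report.csv_path)
    assert list(back.columns) == list(report.frame.columns)
    for col in ("index_x", "index_y", "DepthA", "ComX", "ComY"):
        assert back[col].fillna(-1).tolist() == pytest.approx(
            report.frame[col].round(4).fillna(-1).tolist(), abs=1e-9
        )


def test_pipeline_rerun_is_byte_identical(triplet, tmp_path):
    cmap, cfg = load_config(triplet["chrom_config"])
    r1 = run_pipeline(triplet["vcf"], cmap, cfg, out_dir=tmp_path / "r1")
    r2 = run_pipeline(triplet["vcf"], cmap, cfg, out_dir=tmp_path / "r2")
    assert r1.csv_path.read_bytes() == r2.csv_path.read_bytes()


def test_vcf_without_y_sites_warns_and_calls_homogametic(
    tmp_path, standard_map, caplog
):
    records = [("chrA", p, ".", ".", ["0/0:10", "0/0:12"]) for p in range(1, 30)]
    records += [("chrX", p, ".", ".", ["0/0:10", "0/0:6"]) for p in range(1, 30)]
    vcf = write_vcf(tmp_path / "noy.vcf", ["s1", "s2"], records)
    with caplog.at_level(logging.WARNING, logger="radsexing"):
        report = run_pipeline(vcf, standard_map, RunConfig(), out_dir=tmp_path / "o")
    # absent Y data is indistinguishable from a fully missing Y: every
    # defined Index Y is 1 and all calls land on the homogametic side
    assert (report.frame["index_y"] == 1.0).all()
    assert (report.frame["sex"] == "female").all()
    assert any("Y" in rec.message for rec in caplog.records)


def test_missing_input_leaves_no_outputs(tmp_path, standard_map):
    with pytest.raises(FileNotFoundError):
        run_pipeline(tmp_path / "nope.vcf", standard_map, out_dir=tmp_path / "out")
    out = tmp_path / "out"
    assert not (out / "final_sexing.csv").exists()
    assert not (out / "sexing_plots.pdf").exists()


def test_plots_handle_single_row_and_undefined_values(tmp_path, standard_map):
    frame = pd.DataFrame(
        {
            "individual": ["a"],
            "index_x": [None],
            "index_y": [0.9],
            "overall_mean_depth": [12.0],
            "sex": ["female"],
        }
    )
    path = make_plots(frame, tmp_path / "p.pdf", standard_map)
    assert path.exists() and path.stat().st_size > 0


class TestCli:
    def test_simulate_then_sex_end_to_end(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(
            main,
            [
                "simulate",
                "-o", str(tmp_path / "sim"),
                "--n", "8",
                "--loci", "200", "60", "12",
                "--locus-length", "3",
                "--depth", "15",
                "--seed", "11",
            ],
        )
        assert sim.exit_code == 0, sim.output
        res = runner.invoke(
            main,
            [
                "sex",
                str(tmp_path / "sim" / "cohort.vcf"),
                "-c", str(tmp_path / "sim" / "chrom_config.yaml"),
                "-o", str(tmp_path / "out"),
            ],
        )
        assert res.exit_code == 0, res.output
        frame = pd.read_csv(tmp_path / "out" / "final_sexing.csv")
        truth = pd.read_csv(tmp_path / "sim" / "truth.csv")
        merged = frame.merge(truth, left_on="individual", right_on="individual_id")
        assert (merged["sex"] == merged["true_sex"]).all()

    def test_missing_input_exits_nonzero(self, tmp_path, triplet):
        runner = CliRunner()
        res = runner.invoke(
            main,
            [
                "sex",
                str(tmp_path / "missing.vcf"),
                "-c", str(triplet["chrom_config"]),
                "-o", str(tmp_path / "out"),
            ],
        )
        assert res.exit_code != 0

    def test_stats_subcommand_writes_audit_table(self, tmp_path, triplet):
        runner = CliRunner()
        out = tmp_path / "audit.csv"
        res = runner.invoke(
            main,
            [
                "stats",
                str(triplet["vcf"]),
                "-c", str(triplet["chrom_config"]),
                "-o", str(out),
            ],
        )
        assert res.exit_code == 0, res.output
        audit = pd.read_csv(out)
        assert set(audit["class"]) == {"AUTOSOME", "X_LIKE", "Y_LIKE"}
        assert len(audit) == 3 * COHORT.n_individuals

    def test_filter_subcommand_writes_subset_vcf(self, tmp_path, triplet):
        runner = CliRunner()
        out = tmp_path / "filtered.vcf"
        res = runner.invoke(
            main,
            ["filter", str(triplet["vcf"]), "-o", str(out), "--r", "0.3"],
        )
        assert res.exit_code == 0, res.output
        assert out.exists() and out.stat().st_size > 0
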