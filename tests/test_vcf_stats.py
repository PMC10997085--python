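import numpy as np
import pytest
from helpers import naive_recount, vcf_text, write_vcf

from radsexing import ChromClass, VcfValidationError, accumulate_stats, validate_vcf
from radsexing.vcf_stats import stats_table


def test_four_site_fixture_recounts_exactly(tmp_path, standard_map):
    """Two autosomal sites of depth 10 and 30, one X site of depth 10, one
    missing X site: DepthA=20, DepthX=10, X missingness=0.5.

    Expected values were first computed with the independent line-by-line
    recount in helpers.naive_recount and frozen here.
    """
    path = write_vcf(
        tmp_path / "four.vcf",
        ["s1"],
        [
            ("chrA", 100, ".", ".", ["0/0:10"]),
            ("chrA", 101, ".", ".", ["0/0:30"]),
            ("chrX", 100, ".", ".", ["0/0:10"]),
            ("chrX", 101, ".", ".", ["./.:7"]),
        ],
    )
    (st,) = accumulate_stats(path, standard_map)
    assert st.mean_depth(ChromClass.AUTOSOME) == 20.0
    assert st.mean_depth(ChromClass.X_LIKE) == 10.0
    assert st.missingness(ChromClass.X_LIKE) == 0.5
    # the depth carried by the missing genotype is ignored
    assert st.counts[ChromClass.X_LIKE].depth_sum == 10.0
    # overall mean depth pools non-missing sites across classes
    assert st.overall_mean_depth == pytest.approx(50 / 3)


def test_all_missing_y_gives_missingness_one(tmp_path, standard_map):
    records = [("chrY", p, ".", ".", ["./.:0", "0/0:5"]) for p in range(1, 101)]
    path = write_vcf(tmp_path / "y.vcf", ["f1", "m1"], records)
    female, male = accumulate_stats(path, standard_map)
    assert female.missingness(ChromClass.Y_LIKE) == 1.0
    assert female.completeness(ChromClass.Y_LIKE) == 0.0
    assert female.mean_depth(ChromClass.Y_LIKE) is None  # undefined, flagged
    assert male.missingness(ChromClass.Y_LIKE) == 0.0
    assert male.mean_depth(ChromClass.Y_LIKE) == 5.0


def test_half_missing_genotype_counts_as_missing(tmp_path, standard_map):
    path = write_vcf(
        tmp_path / "half.vcf",
        ["s1"],
        [("chrA", 1, ".", "C", ["./1:9"])],
    )
    (st,) = accumulate_stats(path, standard_map)
    assert st.counts[ChromClass.AUTOSOME].n_missing == 1
    assert st.counts[ChromClass.AUTOSOME].depth_sum == 0.0


def test_excluded_contigs_do_not_contribute(tmp_path, standard_map):
    from radsexing import ChromClassMap

    cmap = ChromClassMap(
        entries=dict(standard_map.entries, scaffold_1=ChromClass.EXCLUDED),
    )
    path = write_vcf(
        tmp_path / "ex.vcf",
        ["s1"],
        [
            ("chrA", 1, ".", ".", ["0/0:10"]),
            ("scaffold_1", 1, ".", ".", ["0/0:99"]),
        ],
        header=(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chrA>\n##contig=<ID=scaffold_1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
        ),
    )
    (st,) = accumulate_stats(path, cmap)
    assert st.counts[ChromClass.AUTOSOME].n_sites == 1
    assert st.overall_mean_depth == 10.0


def _random_records(rng, n_sites, samples):
    contigs = ["chrA", "chrB", "chrX", "chrY"]
    records = []
    by_contig = {c: 0 for c in contigs}
    for _ in range(n_sites):
        contig = contigs[rng.integers(len(contigs))]
        by_contig[contig] += 1
        calls = []
        for _ in samples:
            u = rng.random()
            dp = int(rng.integers(0, 60))
            if u < 0.25:
                calls.append(f"./.:{dp}")
            elif u < 0.32:
                calls.append(f"./1:{dp}")
            elif u < 0.4:
                calls.append("0/1:.")
            else:
                calls.append(f"0/{int(rng.integers(0, 2))}:{dp}")
        records.append((contig, by_contig[contig], ".", "C", calls))
    records.sort(key=lambda r: (r[0], r[1]))
    return records


def _assert_matches_oracle(path, text, standard_map):
    stats = accumulate_stats(path, standard_map)
    oracle = naive_recount(text, lambda c: standard_map.classify(c).value)
    for st in stats:
        for cls in (ChromClass.AUTOSOME, ChromClass.X_LIKE, ChromClass.Y_LIKE):
            o = oracle[st.individual_id][cls.value]
            c = st.counts[cls]
            assert (c.n_sites, c.n_missing, c.n_nonmissing, c.depth_sum) == (
                o.n_sites,
                o.n_missing,
                o.n_nonmissing,
                float(o.depth_sum),
            )


def test_accumulator_matches_naive_recount_on_random_fixture(
    tmp_path, standard_map
):
    rng = np.random.default_rng(20240405)
    samples = [f"s{i}" for i in range(6)]
    records = _random_records(rng, 400, samples)
    text = vcf_text(samples, records)
    path = tmp_path / "rand.vcf"
    path.write_text(text)
    _assert_matches_oracle(path, text, standard_map)


def test_record_order_does_not_change_statistics(tmp_path, standard_map):
    rng = np.random.default_rng(7)
    samples = ["s1", "s2", "s3"]
    records = _random_records(rng, 120, samples)
    path_a = write_vcf(tmp_path / "a.vcf", samples, records)
    # permute records across contigs (still sorted within each contig)
    flipped = sorted(records, key=lambda r: (r[0][::-1], r[1]))
    path_b = write_vcf(tmp_path / "b.vcf", samples, flipped)
    stats_a = accumulate_stats(path_a, standard_map)
    stats_b = accumulate_stats(path_b, standard_map)
    ta = stats_table(stats_a).sort_values(["individual", "class"]).reset_index(drop=True)
    tb = stats_table(stats_b).sort_values(["individual", "class"]).reset_index(drop=True)
    assert ta.equals(tb)


def test_class_restricted_run_reproduces_full_run_entries(tmp_path, standard_map):
    rng = np.random.default_rng(11)
    samples = ["s1", "s2"]
    records = _random_records(rng, 200, samples)
    full = accumulate_stats(write_vcf(tmp_path / "f.vcf", samples, records), standard_map)
    x_only = [r for r in records if r[0] == "chrX"]
    restricted = accumulate_stats(
        write_vcf(tmp_path / "x.vcf", samples, x_only), standard_map
    )
    for fst, rst in zip(full, restricted):
        assert fst.counts[ChromClass.X_LIKE] == rst.counts[ChromClass.X_LIKE]


def test_validate_reports_samples_and_depth_field(tmp_path, standard_map):
    path = write_vcf(
        tmp_path / "ok.vcf",
        ["s1", "s2", "s3"],
        [("chrA", 1, ".", ".", ["0/0:1"] * 3)],
    )
    summary = validate_vcf(path, standard_map)
    assert summary.samples == ["s1", "s2", "s3"]
    assert summary.depth_field == "DP"
    assert summary.warnings == []


def test_validate_rejects_vcf_without_depth_format(tmp_path, standard_map):
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=chrA>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    )
    path = tmp_path / "nodp.vcf"
    path.write_text(
        header
        + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        + "chrA\t1\t.\tA\t.\t.\tPASS\t.\tGT\t0/0\n"
    )
    with pytest.raises(VcfValidationError, match="DP"):
        validate_vcf(path, standard_map)


def test_validate_warns_when_no_contig_matches_sex_classes(tmp_path, standard_map):
    header = (
        "##fileformat=VCFv4.2\n##contig=<ID=chr9>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    )
    path = write_vcf(
        tmp_path / "warn.vcf", ["s1"], [("chr9", 1, ".", ".", ["0/0:3"])],
        header=header,
    )
    summary = validate_vcf(path, standard_map)
    assert any("X_LIKE" in w for w in summary.warnings)
    assert any("Y_LIKE" in w for w in summary.warnings)
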