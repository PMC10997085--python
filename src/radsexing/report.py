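"""End-to-end pipeline: VCF in, sexing CSV and dispersion plots out.

Outputs mirror the conventional layout of coverage-based sexing reports:
``final_sexing.csv`` with one row per individual (class depths,
completeness values, both indexes, the call and its flags) and
``sexing_plots.pdf`` with three dispersion panels — Index X vs Index Y,
Index X vs overall depth, Index Y vs overall depth — with a reference
line at the Index Y decision threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .config import ChromClassMap, RunConfig
from .indexes import UNASSIGNED, CohortSummary, SexCall, classify_cohort
from .locus_filter import filter_vcf
from .vcf_stats import accumulate_stats, stats_table, validate_vcf

__all__ = ["SexingReport", "run_pipeline", "make_plots", "report_frame"]

log = logging.getLogger("radsexing")

CSV_COLUMNS = [
    "individual",
    "DepthA",
    "DepthX",
    "DepthY",
    "ComX",
    "ComY",
    "index_x",
    "index_y",
    "overall_mean_depth",
    "sex",
    "sex_by_x",
    "low_depth_flag",
    "agreement_flag",
    "note",
]


@dataclass
class SexingReport:
    frame: pd.DataFrame
    summary: CohortSummary
    csv_path: Path | None
    plot_path: Path | None
    stats_path: Path | None


def _label(call_sex: str, chrom_map: ChromClassMap) -> str:
    if call_sex == UNASSIGNED:
        return UNASSIGNED
    return chrom_map.sex_labels[call_sex]


def report_frame(calls: list[SexCall], chrom_map: ChromClassMap) -> pd.DataFrame:
    """Per-individual report rows in the final CSV column order."""
    rows = []
    for c in calls:
        note = c.index_y_reason if c.sex_by_y == UNASSIGNED else c.index_x_reason
        rows.append(
            {
                "individual": c.individual_id,
                "DepthA": c.depth_a,
                "DepthX": c.depth_x,
                "DepthY": c.depth_y,
                "ComX": c.com_x,
                "ComY": c.com_y,
                "index_x": c.index_x,
                "index_y": c.index_y,
                "overall_mean_depth": c.overall_mean_depth,
                "sex": _label(c.sex_by_y, chrom_map),
                "sex_by_x": _label(c.sex_by_x, chrom_map),
                "low_depth_flag": c.low_depth_flag,
                "agreement_flag": c.agreement_flag,
                "note": note or "",
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def make_plots(
    frame: pd.DataFrame,
    out_path,
    chrom_map: ChromClassMap,
    threshold: float = 0.5,
) -> Path:
    """Three dispersion panels, points colored by assigned sex.

    Rows with an undefined index are omitted from the panels that need it;
    the omission count is noted in the panel title.
    """
    out_path = Path(out_path)
    homog = chrom_map.sex_labels["homogametic"]
    colors = {homog: "black", UNASSIGNED: "tab:gray"}
    point_color = [
        colors.get(s, "red") for s in frame["sex"]
    ]  # heterogametic label → red

    panels = [
        ("index_x", "index_y", "Index X", "Index Y"),
        ("index_x", "overall_mean_depth", "Index X", "Mean coverage depth (X)"),
        ("index_y", "overall_mean_depth", "Index Y", "Mean coverage depth (X)"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))
    any_points = False
    for ax, (xcol, ycol, xlab, ylab) in zip(axes, panels):
        ok = frame[xcol].notna() & frame[ycol].notna()
        n_omitted = int((~ok).sum())
        sub = frame[ok]
        if len(sub):
            any_points = True
            ax.scatter(
                sub[xcol],
                sub[ycol],
                c=[point_color[i] for i in sub.index],
                s=18,
                alpha=0.8,
            )
        title = f"{xlab} vs {ylab}"
        if n_omitted:
            title += f" ({n_omitted} undefined omitted)"
        ax.set_title(title, fontsize=10)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        if xcol == "index_y":
            ax.axvline(threshold, color="blue", linestyle="--", linewidth=1)
        elif ycol == "index_y":
            ax.axhline(threshold, color="blue", linestyle="--", linewidth=1)
    if not any_points:
        for ax in axes:
            ax.text(
                0.5,
                0.5,
                "no defined indexes",
                ha="center",
                va="center",
                transform=ax.transAxes,
            )
        log.warning("all indexes undefined; plots contain placeholder panels")
    fig.tight_layout()
    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    return out_path


def _write_csv(frame: pd.DataFrame, path: Path, precision: int) -> None:
    frame.to_csv(path, index=False, float_format=f"%.{precision}f")


def run_pipeline(
    vcf_path,
    chrom_map: ChromClassMap,
    run_config: RunConfig | None = None,
    out_dir=".",
    apply_locus_filter: bool = False,
    max_gap: int = 1,
    write_stats: bool = True,
) -> SexingReport:
    """Run validation → (optional locus filtering) → statistics →
    index computation → report files.

    Writes ``final_sexing.csv``, ``sexing_plots.pdf`` and (optionally)
    ``stats_audit.csv`` under *out_dir*.  Partial outputs are removed if a
    stage fails.
    """
    cfg = run_config or RunConfig()
    vcf_path = Path(vcf_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "final_sexing.csv"
    plot_path = out_dir / "sexing_plots.pdf"
    stats_path = out_dir / "stats_audit.csv" if write_stats else None
    created: list[Path] = []
    try:
        if not vcf_path.exists():
            raise FileNotFoundError(f"input VCF not found: {vcf_path}")
        summary = validate_vcf(vcf_path, chrom_map, depth_field=cfg.depth_field)
        for w in summary.warnings:
            log.warning("%s", w)
        log.info(
            "validated %s: %d samples, %d contigs",
            vcf_path,
            len(summary.samples),
            len(summary.contigs),
        )

        stats_input = vcf_path
        if apply_locus_filter:
            filtered = out_dir / "filtered.vcf"
            created.append(filtered)
            report = filter_vcf(
                vcf_path,
                filtered,
                r=cfg.min_locus_share_r,
                max_obs_het=cfg.max_obs_het,
                max_gap=max_gap,
            )
            for line in report.lines():
                log.info("filter: %s", line)
            stats_input = filtered

        stats = accumulate_stats(stats_input, chrom_map, depth_field=cfg.depth_field)
        n_sites = sum(stats[0].counts[c].n_sites for c in stats[0].counts)
        log.info("accumulated %d retained sites for %d individuals", n_sites, len(stats))

        calls, cohort = classify_cohort(stats, cfg)
        if all(
            st.counts[cls].n_sites == 0
            for st in stats
            for cls in st.counts
            if cls.value == "Y_LIKE"
        ):
            log.warning(
                "no Y-like sites in the input; every defined Index Y is 1 "
                "and all calls fall on the homogametic side"
            )
        frame = report_frame(calls, chrom_map)

        created.append(csv_path)
        _write_csv(frame, csv_path, cfg.output_precision)
        if stats_path is not None:
            created.append(stats_path)
            _write_csv(stats_table(stats), stats_path, cfg.output_precision)
        created.append(plot_path)
        make_plots(
            frame, plot_path, chrom_map, threshold=cfg.index_y_female_threshold
        )
        log.info(
            "called %d individuals: %d %s, %d %s, %d unassigned (%d low-depth)",
            cohort.n_total,
            cohort.n_homogametic,
            chrom_map.sex_labels["homogametic"],
            cohort.n_heterogametic,
            chrom_map.sex_labels["heterogametic"],
            cohort.n_unassigned,
            cohort.n_low_depth,
        )
        return SexingReport(frame, cohort, csv_path, plot_path, stats_path)
    except Exception:
        for p in created:
            try:
                p.unlink(missing_ok=True)
            except OSError:  # pragma: no cover - best effort cleanup
                pass
        raise
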