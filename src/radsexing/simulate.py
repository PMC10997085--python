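"""Synthetic all-sites VCF cohorts with known sexes.

The generator emulates the statistical structure that coverage-based
sexing relies on, so the whole pipeline is testable without sequencing
data:

* every individual has a mean autosomal depth (X-fold coverage);
* X-like loci receive a reduced copy factor (default 0.5) in the
  heterogametic sex and full copy in the homogametic sex;
* Y-like loci are present in the heterogametic sex and absent (copy
  factor ``y_presence``, default 0) in the homogametic sex;
* each locus has a recoverability in (0, 1] scaling its expected read
  count — capture efficiency varies between restriction fragments.  Y
  loci are drawn from a higher-recoverability distribution by default,
  reflecting that a locus-sharing filter keyed to the minority sex only
  retains the most robust Y loci.  This heterogeneity is what lets the
  completeness index go negative for low-coverage heterogametic
  individuals: their X loci drop out faster than the hardy Y loci.

Realized locus read counts are Poisson (optionally gamma-overdispersed)
with mean ``depth × copy_factor × recoverability``; a locus is missing in
an individual when its count is zero, and all sites of a locus share its
depth and missingness.  Genotypes are placeholders (optionally a fraction
of sites is made biallelic with random genotypes) because only
missingness and per-genotype depth matter to the method.

The output triplet — all-sites VCF, truth table CSV, chromosome-class
config — is self-contained and feeds straight into the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ChromClass, ChromClassMap, serialize_chrom_map

__all__ = [
    "SimCohortParams",
    "simulate_cohort",
    "degrade",
    "write_fixture_triplet",
    "sim_chrom_map",
]

_LOCUS_GAP = 350  # bp between simulated loci; larger than any grouping gap


@dataclass(frozen=True)
class SimCohortParams:
    """Generative parameters for one synthetic cohort.

    ``mean_depth`` may be a scalar (shared by all individuals) or a
    per-individual sequence.  ``sex_ratio`` is the homogametic fraction;
    the first ``round(sex_ratio * n)`` individuals are homogametic.
    Recoverability distributions are Beta(a, b); the defaults give mean
    0.8 for autosomal/X loci and a tighter, higher mean (~0.9) for the Y
    loci that survive a minority-sex sharing filter.
    """

    n_individuals: int = 60
    sex_ratio: float = 0.5
    n_autosomal_loci: int = 2000
    n_x_loci: int = 500
    n_y_loci: int = 50
    locus_length: int = 150
    mean_depth: float | tuple[float, ...] = 15.0
    x_copy_ratio: float = 0.5
    y_presence: float = 0.0
    recoverability_beta: tuple[float, float] = (8.0, 2.0)
    y_recoverability_beta: tuple[float, float] = (18.0, 2.0)
    overdispersion: float | None = None
    snp_fraction: float = 0.0
    n_autosome_contigs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for name in ("n_autosomal_loci", "n_x_loci", "n_y_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive (zero loci is infeasible)")
        if self.locus_length < 1:
            raise ValueError("locus_length must be positive")
        if not 0.0 <= self.y_presence <= 1.0:
            raise ValueError("y_presence must be in [0, 1]")
        if not 0.0 < self.x_copy_ratio <= 1.0:
            raise ValueError("x_copy_ratio must be in (0, 1]")
        if not 0.0 <= self.snp_fraction <= 1.0:
            raise ValueError("snp_fraction must be in [0, 1]")
        if self.n_autosome_contigs < 1:
            raise ValueError("n_autosome_contigs must be positive")
        depths = self.depth_vector()
        if np.any(depths <= 0):
            raise ValueError("mean_depth values must be positive")
        if len(depths) != self.n_individuals:
            raise ValueError(
                "per-individual mean_depth length must equal n_individuals"
            )
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion (gamma shape) must be positive")

    def depth_vector(self) -> np.ndarray:
        if np.isscalar(self.mean_depth):
            return np.full(self.n_individuals, float(self.mean_depth))
        return np.asarray(self.mean_depth, dtype=float)

    @property
    def n_homogametic(self) -> int:
        return round(self.sex_ratio * self.n_individuals)


def sim_chrom_map(params: SimCohortParams) -> ChromClassMap:
    """The chromosome-class map matching the simulated contig names."""
    entries = {
        f"chr{i + 1}": ChromClass.AUTOSOME for i in range(params.n_autosome_contigs)
    }
    entries["chrX"] = ChromClass.X_LIKE
    entries["chrY"] = ChromClass.Y_LIKE
    return ChromClassMap(entries=entries)


def _individual_ids(params: SimCohortParams, prefix: str = "") -> list[str]:
    width = max(3, len(str(params.n_individuals)))
    return [f"{prefix}ind_{i + 1:0{width}d}" for i in range(params.n_individuals)]


def _recoverabilities(params: SimCohortParams, rng: np.random.Generator):
    a, b = params.recoverability_beta
    ya, yb = params.y_recoverability_beta
    return {
        ChromClass.AUTOSOME: rng.beta(a, b, size=params.n_autosomal_loci),
        ChromClass.X_LIKE: rng.beta(a, b, size=params.n_x_loci),
        ChromClass.Y_LIKE: rng.beta(ya, yb, size=params.n_y_loci),
    }


def _copy_factors(params: SimCohortParams) -> dict[ChromClass, np.ndarray]:
    homog = np.arange(params.n_individuals) < params.n_homogametic
    return {
        ChromClass.AUTOSOME: np.ones(params.n_individuals),
        ChromClass.X_LIKE: np.where(homog, 1.0, params.x_copy_ratio),
        ChromClass.Y_LIKE: np.where(homog, params.y_presence, 1.0),
    }


def _draw_counts(lam: np.ndarray, params: SimCohortParams, rng) -> np.ndarray:
    if params.overdispersion is not None:
        k = params.overdispersion
        lam = rng.gamma(shape=k, scale=np.maximum(lam, 0) / k)
    return rng.poisson(lam)


def _locus_layout(params: SimCohortParams):
    """Deterministic (contig, start) for every locus, grouped by contig.

    Autosomal loci are spread block-wise over the autosome contigs; X and
    Y loci sit on chrX / chrY.  Loci are separated by a fixed gap so gap
    grouping can rediscover them.
    """
    layout: list[tuple[str, ChromClass, int, int]] = []  # contig, class, locus_idx, start
    per = -(-params.n_autosomal_loci // params.n_autosome_contigs)
    step = params.locus_length + _LOCUS_GAP
    for j in range(params.n_autosomal_loci):
        contig = f"chr{j // per + 1}"
        start = 1 + (j % per) * step
        layout.append((contig, ChromClass.AUTOSOME, j, start))
    for j in range(params.n_x_loci):
        layout.append(("chrX", ChromClass.X_LIKE, j, 1 + j * step))
    for j in range(params.n_y_loci):
        layout.append(("chrY", ChromClass.Y_LIKE, j, 1 + j * step))
    return layout


def _contig_lengths(params: SimCohortParams) -> dict[str, int]:
    step = params.locus_length + _LOCUS_GAP
    per = -(-params.n_autosomal_loci // params.n_autosome_contigs)
    lengths = {
        f"chr{i + 1}": per * step + _LOCUS_GAP
        for i in range(params.n_autosome_contigs)
    }
    lengths["chrX"] = params.n_x_loci * step + _LOCUS_GAP
    lengths["chrY"] = params.n_y_loci * step + _LOCUS_GAP
    return lengths


def _generate(
    params: SimCohortParams,
    out_vcf: Path,
    ids: list[str],
    rng_recov: np.random.Generator,
    rng_counts: np.random.Generator,
    rng_geno: np.random.Generator,
) -> pd.DataFrame:
    depths = params.depth_vector()
    recov = _recoverabilities(params, rng_recov)
    copies = _copy_factors(params)
    counts = {}
    for cls in (ChromClass.AUTOSOME, ChromClass.X_LIKE, ChromClass.Y_LIKE):
        lam = recov[cls][:, None] * (depths[None, :] * copies[cls][None, :])
        counts[cls] = _draw_counts(lam, params, rng_counts)

    lines = [
        "##fileformat=VCFv4.2",
        "##source=radsexing-simulate",
    ]
    for contig, length in _contig_lengths(params).items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids)
    )

    locus_serial = 0
    for contig, cls, j, start in _locus_layout(params):
        locus_serial += 1
        locus_counts = counts[cls][j]
        present = locus_counts > 0
        invariant_tail = "\t".join(
            f"0/0:{c}" if p else "./.:0"
            for c, p in zip(locus_counts, present)
        )
        prefix = f"{contig}\t"
        mid = f"\t{locus_serial}\tA\t"
        is_snp = (
            rng_geno.random(params.locus_length) < params.snp_fraction
            if params.snp_fraction > 0
            else np.zeros(params.locus_length, dtype=bool)
        )
        for s in range(params.locus_length):
            pos = start + s
            if not is_snp[s]:
                lines.append(
                    f"{prefix}{pos}{mid}.\t.\tPASS\t.\tGT:DP\t{invariant_tail}"
                )
                continue
            draws = rng_geno.random(params.n_individuals)
            fields = []
            for c, p, u in zip(locus_counts, present, draws):
                if not p:
                    fields.append("./.:0")
                elif u < 0.55:
                    fields.append(f"0/0:{c}")
                elif u < 0.85:
                    fields.append(f"0/1:{c}")
                else:
                    fields.append(f"1/1:{c}")
            lines.append(
                f"{prefix}{pos}{mid}C\t.\tPASS\t.\tGT:DP\t" + "\t".join(fields)
            )

    out_vcf = Path(out_vcf)
    out_vcf.parent.mkdir(parents=True, exist_ok=True)
    with open(out_vcf, "w", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")

    chrom_map = sim_chrom_map(params)
    roles = [
        "homogametic" if i < params.n_homogametic else "heterogametic"
        for i in range(params.n_individuals)
    ]
    truth = pd.DataFrame(
        {
            "individual_id": ids,
            "true_role": roles,
            "true_sex": [chrom_map.sex_labels[r] for r in roles],
            "true_mean_depth": depths,
        }
    )
    return truth


def _streams(seed: int):
    return (
        np.random.default_rng([seed, 1]),
        np.random.default_rng([seed, 2]),
        np.random.default_rng([seed, 3]),
    )


def simulate_cohort(
    params: SimCohortParams, out_vcf, id_prefix: str = ""
) -> pd.DataFrame:
    """Write one synthetic all-sites VCF; return its truth table.

    Reproducible: the same ``params`` (including ``seed``) yield a
    byte-identical VCF.
    """
    rng_recov, rng_counts, rng_geno = _streams(params.seed)
    ids = _individual_ids(params, id_prefix)
    return _generate(params, Path(out_vcf), ids, rng_recov, rng_counts, rng_geno)


def degrade(
    params: SimCohortParams,
    depth_schedule: list[float],
    out_dir,
) -> list[tuple[Path, pd.DataFrame]]:
    """One sub-cohort per scheduled mean depth, sharing loci and
    recoverabilities across the gradient.

    Each sub-cohort restarts the count stream from the same derived seed,
    so two equal depths yield identical sub-cohorts apart from individual
    IDs, and a singleton schedule reproduces :func:`simulate_cohort`.
    """
    if not depth_schedule:
        raise ValueError("depth_schedule must be non-empty")
    if any(d <= 0 for d in depth_schedule):
        raise ValueError("scheduled depths must be positive")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for k, depth in enumerate(depth_schedule):
        sub = replace(params, mean_depth=float(depth))
        prefix = "" if len(depth_schedule) == 1 else f"d{k}_"
        rng_recov, rng_counts, rng_geno = _streams(params.seed)
        ids = _individual_ids(sub, prefix)
        path = out_dir / f"cohort_depth{k}_{depth:g}X.vcf"
        truth = _generate(sub, path, ids, rng_recov, rng_counts, rng_geno)
        results.append((path, truth))
    return results


def write_fixture_triplet(params: SimCohortParams, out_dir) -> dict[str, Path]:
    """Write the self-contained fixture triplet: VCF, truth CSV, config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "truth": out_dir / "truth.csv",
        "chrom_config": out_dir / "chrom_config.yaml",
    }
    truth = simulate_cohort(params, paths["vcf"])
    truth.to_csv(paths["truth"], index=False)
    paths["chrom_config"].write_text(serialize_chrom_map(sim_chrom_map(params)))
    return paths
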