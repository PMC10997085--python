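"""Per-individual missingness and depth statistics from an all-sites VCF.

The sexing indexes need, for every individual and every chromosome class
(autosomes, X-like, Y-like), the fraction of retained sites whose genotype
is missing and the mean read depth over non-missing sites.  Both are
accumulated in a single streaming pass with cyvcf2; only the GT and
per-genotype depth (default ``DP``) fields are read, so fixed and variable
sites are treated identically — the statistics depend on the presence or
absence of loci, not on the SNPs they contain.

Conventions (matching the per-individual reports of standard VCF tooling):

* a genotype is *missing* when any of its alleles is the missing symbol
  ``.`` (half-missing diploid calls count as missing);
* mean depth averages over non-missing sites only; a depth value attached
  to a missing genotype is ignored;
* the missingness denominator is the total number of retained sites of
  that class in the file, identical for every individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .config import STAT_CLASSES, ChromClass, ChromClassMap

__all__ = [
    "ClassCounts",
    "IndividualClassStats",
    "VcfSummary",
    "VcfValidationError",
    "validate_vcf",
    "accumulate_stats",
    "stats_table",
]

_INT32_MIN = np.iinfo(np.int32).min


class VcfValidationError(ValueError):
    """Raised when a VCF cannot supply what the sexing pipeline needs."""


@dataclass
class ClassCounts:
    """Raw per-class tallies for one individual."""

    n_sites: int = 0
    n_missing: int = 0
    depth_sum: float = 0.0
    n_nonmissing: int = 0

    @property
    def missingness(self) -> float | None:
        if self.n_sites == 0:
            return None
        return self.n_missing / self.n_sites

    @property
    def completeness(self) -> float | None:
        m = self.missingness
        return None if m is None else 1.0 - m

    @property
    def mean_depth(self) -> float | None:
        if self.n_nonmissing == 0:
            return None
        return self.depth_sum / self.n_nonmissing


@dataclass
class IndividualClassStats:
    """Missingness and depth statistics for one individual, stratified by
    chromosome class.  Houses DepthA/DepthX/DepthY (class mean depths) and
    ComX/ComY (class completeness values) consumed by the indexes."""

    individual_id: str
    counts: dict[ChromClass, ClassCounts] = field(
        default_factory=lambda: {c: ClassCounts() for c in STAT_CLASSES}
    )

    def missingness(self, cls: ChromClass) -> float | None:
        return self.counts[cls].missingness

    def completeness(self, cls: ChromClass) -> float | None:
        return self.counts[cls].completeness

    def mean_depth(self, cls: ChromClass) -> float | None:
        return self.counts[cls].mean_depth

    @property
    def overall_mean_depth(self) -> float | None:
        """Mean depth over non-missing sites of all classes combined."""
        total = sum(c.depth_sum for c in self.counts.values())
        n = sum(c.n_nonmissing for c in self.counts.values())
        return None if n == 0 else total / n


@dataclass(frozen=True)
class VcfSummary:
    samples: list[str]
    contigs: list[str]
    depth_field: str
    warnings: list[str]


def _header_has_format(vcf: VCF, key: str) -> bool:
    return f"##FORMAT=<ID={key}," in vcf.raw_header


def validate_vcf(
    path, chrom_map: ChromClassMap | None = None, depth_field: str = "DP"
) -> VcfSummary:
    """Check that *path* is a usable depth-bearing VCF.

    Returns the sample list, the contigs named in the header, and any
    soft warnings (e.g. no header contig overlaps the X-like set).  Raises
    :class:`VcfValidationError` when there are no samples or no
    per-genotype depth field.
    """
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        contigs = list(vcf.seqnames)
        if not samples:
            raise VcfValidationError(f"{path}: VCF declares no samples")
        if not _header_has_format(vcf, "GT"):
            raise VcfValidationError(f"{path}: VCF declares no GT FORMAT field")
        if not _header_has_format(vcf, depth_field):
            raise VcfValidationError(
                f"{path}: no per-genotype {depth_field!r} FORMAT field declared; "
                "sexing requires an all-sites VCF carrying per-genotype depth "
                "(e.g. a gstacks/populations --vcf-all output)"
            )
        warnings: list[str] = []
        if chrom_map is not None and contigs:
            for cls in (ChromClass.X_LIKE, ChromClass.Y_LIKE):
                wanted = set(chrom_map.contigs(cls))
                if wanted and not wanted.intersection(contigs):
                    warnings.append(
                        f"no VCF contig matches the configured {cls.value} set "
                        f"({sorted(wanted)}); the corresponding statistics "
                        "will be empty"
                    )
        return VcfSummary(samples, contigs, depth_field, warnings)
    finally:
        vcf.close()


def _record_missing_and_depth(variant, n_samples: int, depth_field: str):
    """Per-sample (missing flag, depth) arrays for one record."""
    gts = variant.genotype.array()
    # last column is the phasing flag; an allele of -1 is the '.' symbol
    missing = (gts[:, :-1] == -1).any(axis=1)
    depth = variant.format(depth_field)
    if depth is None:
        depth = np.zeros(n_samples, dtype=np.int64)
    else:
        depth = depth[:, 0].astype(np.int64)
        depth[depth < 0] = 0  # '.' decodes to a negative sentinel
    return missing, depth


def accumulate_stats(
    path,
    chrom_map: ChromClassMap,
    depth_field: str = "DP",
) -> list[IndividualClassStats]:
    """Stream the VCF once and accumulate per-individual, per-class tallies.

    Sites on EXCLUDED contigs are skipped; every retained site increments
    exactly one class's site count for every sample.
    """
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        if not samples:
            raise VcfValidationError(f"{path}: VCF declares no samples")
        n = len(samples)
        idx = {c: i for i, c in enumerate(STAT_CLASSES)}
        n_sites = np.zeros(len(STAT_CLASSES), dtype=np.int64)
        n_missing = np.zeros((len(STAT_CLASSES), n), dtype=np.int64)
        depth_sum = np.zeros((len(STAT_CLASSES), n), dtype=np.int64)
        n_nonmissing = np.zeros((len(STAT_CLASSES), n), dtype=np.int64)

        contig = pos = None
        try:
            for variant in vcf:
                contig, pos = variant.CHROM, variant.POS
                cls = chrom_map.classify(contig)
                if cls is ChromClass.EXCLUDED:
                    continue
                k = idx[cls]
                missing, depth = _record_missing_and_depth(variant, n, depth_field)
                n_sites[k] += 1
                n_missing[k] += missing
                nonmiss = ~missing
                n_nonmissing[k] += nonmiss
                depth_sum[k] += np.where(nonmiss, depth, 0)
        except Exception as exc:
            if isinstance(exc, VcfValidationError):
                raise
            where = f"{contig}:{pos}" if contig is not None else "record 1"
            raise VcfValidationError(
                f"{path}: failed while reading near {where}: {exc}"
            ) from exc

        out = []
        for j, sample in enumerate(samples):
            counts = {
                c: ClassCounts(
                    n_sites=int(n_sites[idx[c]]),
                    n_missing=int(n_missing[idx[c], j]),
                    depth_sum=float(depth_sum[idx[c], j]),
                    n_nonmissing=int(n_nonmissing[idx[c], j]),
                )
                for c in STAT_CLASSES
            }
            out.append(IndividualClassStats(individual_id=sample, counts=counts))
        return out
    finally:
        vcf.close()


def stats_table(stats: list[IndividualClassStats]) -> pd.DataFrame:
    """Tidy audit table: one row per individual per chromosome class."""
    rows = []
    for st in stats:
        for cls in STAT_CLASSES:
            c = st.counts[cls]
            rows.append(
                {
                    "individual": st.individual_id,
                    "class": cls.value,
                    "n_sites": c.n_sites,
                    "n_missing": c.n_missing,
                    "missingness": c.missingness,
                    "mean_depth": c.mean_depth,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "individual",
            "class",
            "n_sites",
            "n_missing",
            "missingness",
            "mean_depth",
        ],
    )
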