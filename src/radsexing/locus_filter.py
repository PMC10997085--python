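"""Locus-level retention filters for all-sites VCFs.

Reduced-representation pipelines usually apply two retention rules before
any per-individual statistic is computed:

* a locus-sharing rule: keep a locus only if it is present (at least one
  non-missing genotype among its sites) in at least a proportion ``r`` of
  the individuals — with ``r`` low enough that loci confined to the
  heterogametic sex survive (0.3 assumes at least 30% males);
* an observed-heterozygosity ceiling: drop a locus if any of its variant
  sites has more than ``max_obs_het`` of its non-missing genotypes
  heterozygous, purging collapsed paralogs.

Users arriving with an already-filtered upstream VCF can skip this stage;
it exists so the same semantics can be reproduced natively when needed.

Sites are grouped into loci by the VCF ID column when the upstream caller
emitted locus identifiers; otherwise runs of consecutive sites on one
contig with inter-site gaps of at most ``max_gap`` are taken as one locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF, Writer

from .vcf_stats import VcfValidationError

__all__ = [
    "Locus",
    "LocusTable",
    "FilterReport",
    "group_sites_into_loci",
    "filter_loci",
    "filter_vcf",
]


@dataclass(frozen=True)
class Locus:
    locus_id: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    positions: tuple[int, ...]


@dataclass
class LocusTable:
    """Loci with per-sample presence flags and per-locus worst-case
    site heterozygosity."""

    loci: list[Locus]
    samples: list[str]
    presence: np.ndarray  # bool, (n_loci, n_samples)
    max_site_obs_het: np.ndarray  # float, (n_loci,)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def presence_counts(self) -> np.ndarray:
        return self.presence.sum(axis=1)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_dropped_share: int
    n_dropped_het: int
    n_retained: int
    min_samples_required: int

    def lines(self) -> list[str]:
        return [
            f"loci in: {self.n_input}",
            f"dropped by locus-sharing rule (< {self.min_samples_required} "
            f"samples): {self.n_dropped_share}",
            f"dropped by observed-heterozygosity ceiling: {self.n_dropped_het}",
            f"loci retained: {self.n_retained}",
        ]


def _site_key(variant, max_gap: int, state: dict) -> str:
    """Locus key for one record; mutates grouping state."""
    vid = variant.ID
    if vid not in (None, "", "."):
        return str(vid)
    # gap rule: new locus when the contig changes or the gap exceeds max_gap
    contig, pos = variant.CHROM, variant.POS
    if (
        state.get("contig") != contig
        or pos - state.get("pos", -(10**12)) > max_gap
    ):
        state["auto_id"] = state.get("auto_id", 0) + 1
    state["contig"], state["pos"] = contig, pos
    return f"__gap_locus_{state['auto_id']}"


def group_sites_into_loci(path, max_gap: int = 1) -> LocusTable:
    """Single pass over a position-sorted VCF building the locus table.

    Raises :class:`VcfValidationError` if sites are not sorted by contig
    then position (gap grouping is meaningless on unsorted input).
    """
    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        order: list[str] = []
        meta: dict[str, dict] = {}
        presence: dict[str, np.ndarray] = {}
        max_het: dict[str, float] = {}
        state: dict = {}
        last: tuple[str, int] | None = None
        seen_contigs: set[str] = set()
        for variant in vcf:
            contig, pos = variant.CHROM, variant.POS
            if last is not None:
                if contig == last[0] and pos < last[1]:
                    raise VcfValidationError(
                        f"{path}: unsorted input at {contig}:{pos} "
                        f"(previous {last[0]}:{last[1]})"
                    )
                if contig != last[0] and contig in seen_contigs:
                    raise VcfValidationError(
                        f"{path}: unsorted input, contig {contig} "
                        "appears in two blocks"
                    )
            seen_contigs.add(contig)
            last = (contig, pos)

            key = _site_key(variant, max_gap, state)
            gts = variant.genotype.array()
            missing = (gts[:, :-1] == -1).any(axis=1)
            nonmiss = ~missing
            n_nonmiss = int(nonmiss.sum())
            if n_nonmiss and len(variant.ALT):
                het = nonmiss & (gts[:, 0] != gts[:, 1])
                obs_het = float(het.sum()) / n_nonmiss
            else:
                obs_het = 0.0

            if key not in meta:
                order.append(key)
                meta[key] = {"contig": contig, "positions": [pos]}
                presence[key] = nonmiss.copy()
                max_het[key] = obs_het
            else:
                if meta[key]["contig"] != contig:
                    raise VcfValidationError(
                        f"{path}: locus ID {key!r} spans contigs "
                        f"{meta[key]['contig']} and {contig}"
                    )
                meta[key]["positions"].append(pos)
                presence[key] |= nonmiss
                max_het[key] = max(max_het[key], obs_het)

        loci = [
            Locus(
                locus_id=key,
                contig=meta[key]["contig"],
                start=min(meta[key]["positions"]),
                end=max(meta[key]["positions"]),
                positions=tuple(meta[key]["positions"]),
            )
            for key in order
        ]
        pres = (
            np.vstack([presence[key] for key in order])
            if order
            else np.zeros((0, len(samples)), dtype=bool)
        )
        hets = np.array([max_het[key] for key in order], dtype=float)
        return LocusTable(
            loci=loci, samples=samples, presence=pres, max_site_obs_het=hets
        )
    finally:
        vcf.close()


def min_samples_for_share(r: float, n_samples: int) -> int:
    """'Present in at least a proportion r of samples' as a ceiling count."""
    return math.ceil(r * n_samples)


def filter_loci(
    table: LocusTable, r: float, max_obs_het: float
) -> tuple[LocusTable, FilterReport]:
    """Apply both retention rules; returns the retained table and a report.

    A locus is retained iff present in at least ``ceil(r * n_samples)``
    individuals AND none of its variant sites exceeds the observed-
    heterozygosity ceiling.  ``r=0`` with ``max_obs_het=1`` is the identity.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must be in [0, 1]")
    if not 0.0 <= max_obs_het <= 1.0:
        raise ValueError("max_obs_het must be in [0, 1]")
    need = min_samples_for_share(r, len(table.samples))
    counts = table.presence_counts()
    share_ok = counts >= need
    het_ok = table.max_site_obs_het <= max_obs_het
    keep = share_ok & het_ok
    report = FilterReport(
        n_input=table.n_loci,
        n_dropped_share=int((~share_ok).sum()),
        n_dropped_het=int((share_ok & ~het_ok).sum()),
        n_retained=int(keep.sum()),
        min_samples_required=need,
    )
    kept = LocusTable(
        loci=[l for l, k in zip(table.loci, keep) if k],
        samples=table.samples,
        presence=table.presence[keep],
        max_site_obs_het=table.max_site_obs_het[keep],
    )
    return kept, report


def filter_vcf(
    in_path,
    out_path,
    r: float,
    max_obs_het: float,
    max_gap: int = 1,
) -> FilterReport:
    """Write a subset VCF with the records of dropped loci removed.

    Two passes: the first builds the locus table, the second re-derives
    each record's locus key identically and copies retained records with
    the header preserved.
    """
    table = group_sites_into_loci(in_path, max_gap=max_gap)
    kept, report = filter_loci(table, r, max_obs_het)
    retained = {l.locus_id for l in kept.loci}
    vcf = VCF(str(in_path))
    writer = Writer(str(out_path), vcf)
    state: dict = {}
    try:
        for variant in vcf:
            key = _site_key(variant, max_gap, state)
            if key in retained:
                writer.write_record(variant)
    finally:
        writer.close()
        vcf.close()
    return report
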