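"""Shared test utilities: a literal VCF text builder and an independent
naive recount of the per-individual per-class statistics.

The oracle deliberately avoids cyvcf2 and the package's accumulator: it
re-parses the VCF text line by line with plain string handling, so the
two routes share no code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrA,length=10000000>
##contig=<ID=chrB,length=10000000>
##contig=<ID=chrX,length=10000000>
##contig=<ID=chrY,length=10000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def vcf_text(samples, records, header=VCF_HEADER):
    """Render VCF text.

    ``records`` is a list of tuples ``(contig, pos, vid, alt, calls)``
    where ``calls`` is one ``"GT:DP"`` string per sample, e.g.
    ``"0/0:12"`` or ``"./.:0"``.
    """
    lines = [header.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for contig, pos, vid, alt, calls in records:
        assert len(calls) == len(samples)
        lines.append(
            f"{contig}\t{pos}\t{vid}\tA\t{alt}\t.\tPASS\t.\tGT:DP\t"
            + "\t".join(calls)
        )
    return "\n".join(lines) + "\n"


def write_vcf(path, samples, records, header=VCF_HEADER):
    path.write_text(vcf_text(samples, records, header))
    return path


@dataclass
class NaiveStats:
    """Oracle tallies for one (sample, class) cell."""

    n_sites: int = 0
    n_missing: int = 0
    depth_sum: int = 0
    n_nonmissing: int = 0


def naive_recount(text, classify):
    """Recount per-sample per-class statistics directly from VCF text.

    ``classify`` maps a contig name to one of "AUTOSOME", "X_LIKE",
    "Y_LIKE", "EXCLUDED".  Returns ``{sample: {class: NaiveStats}}``.
    """
    samples = None
    out: dict[str, dict[str, NaiveStats]] = {}
    classes = ("AUTOSOME", "X_LIKE", "Y_LIKE")
    for line in text.splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            out = {s: {c: NaiveStats() for c in classes} for s in samples}
            continue
        fields = line.split("\t")
        cls = classify(fields[0])
        if cls == "EXCLUDED":
            continue
        fmt = fields[8].split(":")
        gt_i = fmt.index("GT")
        dp_i = fmt.index("DP") if "DP" in fmt else None
        for sample, cell in zip(samples, fields[9:]):
            parts = cell.split(":")
            alleles = re.split(r"[/|]", parts[gt_i])
            missing = "." in alleles
            st = out[sample][cls]
            st.n_sites += 1
            if missing:
                st.n_missing += 1
            else:
                st.n_nonmissing += 1
                if dp_i is not None and dp_i < len(parts) and parts[dp_i] != ".":
                    st.depth_sum += int(parts[dp_i])
    return out
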