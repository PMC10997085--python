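"""The two sexing indexes and the per-individual calling rule.

Both indexes exploit properties of heteromorphic sex chromosomes under a
reduced-representation design mapped to a chromosome-level reference:

* **Index X** = DepthX / DepthA, the mean coverage depth of X-like loci
  over the mean depth of autosomal loci.  The heterogametic sex carries a
  single X copy, so its X loci receive about half the reads: expected 1 in
  the homogametic sex and 0.5 in the heterogametic one.

* **Index Y** = (ComX − ComY) / ComX, where Com (completeness) is one
  minus missingness.  The homogametic sex has no Y, so its Y-like loci are
  entirely missing (ComY = 0, index 1); the heterogametic sex recovers Y
  loci about as well as X loci (index 0).  The index can go negative when
  the retained Y loci are recovered more robustly than X loci, which in
  practice happens at low coverage in the heterogametic sex and only
  widens the separation.

Sex is assigned from Index Y alone; Index X is kept as an advisory
cross-check because the depth ratio drifts toward 1 at low coverage (the
depth of a locus conditional on being seen at all approaches one read for
both X and autosomes) and misassigns low-depth heterogametic individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import ChromClass, ChromClassMap, RunConfig
from .vcf_stats import IndividualClassStats

__all__ = [
    "SexCall",
    "CohortSummary",
    "index_x",
    "index_y",
    "assign_sex",
    "classify_cohort",
    "HOMOGAMETIC",
    "HETEROGAMETIC",
    "UNASSIGNED",
]

HOMOGAMETIC = "homogametic"
HETEROGAMETIC = "heterogametic"
UNASSIGNED = "unassigned"

# advisory Index X call: nearest expected value, 1 vs 0.5; ties go to the
# homogametic side, mirroring the inclusive >= of the Index Y rule
_X_MIDPOINT = 0.75


@dataclass(frozen=True)
class SexCall:
    """Per-individual sexing result."""

    individual_id: str
    index_x: float | None
    index_y: float | None
    index_x_reason: str | None  # why index_x is undefined, when it is
    index_y_reason: str | None
    depth_a: float | None
    depth_x: float | None
    depth_y: float | None
    com_x: float | None
    com_y: float | None
    overall_mean_depth: float | None
    sex_by_y: str  # homogametic | heterogametic | unassigned
    sex_by_x: str  # advisory; unassigned when undefined or low depth
    low_depth_flag: bool
    agreement_flag: bool | None  # None when not comparable


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_homogametic: int
    n_heterogametic: int
    n_unassigned: int
    n_low_depth: int
    n_disagreement: int


def index_x(stats: IndividualClassStats) -> tuple[float | None, str | None]:
    """DepthX / DepthA, or (None, reason) when undefined.

    Undefined when either class has no non-missing site or autosomal mean
    depth is zero.
    """
    depth_x = stats.mean_depth(ChromClass.X_LIKE)
    depth_a = stats.mean_depth(ChromClass.AUTOSOME)
    if depth_a is None:
        return None, "autosomal mean depth undefined (no non-missing sites)"
    if depth_x is None:
        return None, "X mean depth undefined (no non-missing X sites)"
    if depth_a == 0:
        return None, "autosomal mean depth is zero"
    return depth_x / depth_a, None


def index_y(stats: IndividualClassStats) -> tuple[float | None, str | None]:
    """(ComX − ComY) / ComX, or (None, reason) when undefined.

    Undefined exactly when X completeness is zero (including when the VCF
    carries no X-like sites at all).  A VCF with zero Y-like sites is
    indistinguishable from a fully missing Y, so ComY is taken as 0 and
    the index is 1; the pipeline warns separately about absent Y data.
    """
    com_x = stats.completeness(ChromClass.X_LIKE)
    com_y = stats.completeness(ChromClass.Y_LIKE)
    if com_y is None:
        com_y = 0.0
    if com_x is None or com_x == 0:
        return None, "X completeness is zero (no non-missing X-like sites)"
    return (com_x - com_y) / com_x, None


def assign_sex(stats: IndividualClassStats, config: RunConfig) -> SexCall:
    """Assign sex to one individual.

    The binding call uses Index Y only: at or above
    ``config.index_y_female_threshold`` the individual is homogametic,
    below it heterogametic.  The advisory Index X call picks the nearer of
    the two expected values (1 homogametic, 0.5 heterogametic) and is
    suppressed when the overall mean depth is below
    ``config.low_depth_warning``.
    """
    ix, ix_reason = index_x(stats)
    iy, iy_reason = index_y(stats)
    overall = stats.overall_mean_depth
    low_depth = overall is not None and overall < config.low_depth_warning
    if overall is None:
        low_depth = True  # nothing observed at all

    if iy is None:
        sex_by_y = UNASSIGNED
    elif iy >= config.index_y_female_threshold:
        sex_by_y = HOMOGAMETIC
    else:
        sex_by_y = HETEROGAMETIC

    if ix is None:
        sex_by_x = UNASSIGNED
    elif low_depth:
        sex_by_x = UNASSIGNED
        ix_reason = (
            f"advisory X call suppressed: overall mean depth below "
            f"{config.low_depth_warning:g}X"
        )
    else:
        sex_by_x = HOMOGAMETIC if ix >= _X_MIDPOINT else HETEROGAMETIC

    if sex_by_y != UNASSIGNED and sex_by_x != UNASSIGNED:
        agreement: bool | None = sex_by_x == sex_by_y
    else:
        agreement = None

    return SexCall(
        individual_id=stats.individual_id,
        index_x=ix,
        index_y=iy,
        index_x_reason=ix_reason,
        index_y_reason=iy_reason,
        depth_a=stats.mean_depth(ChromClass.AUTOSOME),
        depth_x=stats.mean_depth(ChromClass.X_LIKE),
        depth_y=stats.mean_depth(ChromClass.Y_LIKE),
        com_x=stats.completeness(ChromClass.X_LIKE),
        com_y=stats.completeness(ChromClass.Y_LIKE),
        overall_mean_depth=overall,
        sex_by_y=sex_by_y,
        sex_by_x=sex_by_x,
        low_depth_flag=low_depth,
        agreement_flag=agreement,
    )


def classify_cohort(
    stats: list[IndividualClassStats], config: RunConfig
) -> tuple[list[SexCall], CohortSummary]:
    """Assign sex to every individual and summarize the cohort."""
    if not stats:
        raise ValueError("empty cohort: no individual statistics supplied")
    calls = [assign_sex(st, config) for st in stats]
    summary = CohortSummary(
        n_total=len(calls),
        n_homogametic=sum(c.sex_by_y == HOMOGAMETIC for c in calls),
        n_heterogametic=sum(c.sex_by_y == HETEROGAMETIC for c in calls),
        n_unassigned=sum(c.sex_by_y == UNASSIGNED for c in calls),
        n_low_depth=sum(c.low_depth_flag for c in calls),
        n_disagreement=sum(c.agreement_flag is False for c in calls),
    )
    return calls, summary


def sex_label(call_sex: str, chrom_map: ChromClassMap) -> str:
    """Map a homogametic/heterogametic call to the configured label."""
    return chrom_map.sex_labels.get(call_sex, call_sex)
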