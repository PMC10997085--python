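from __future__ import annotations

import pytest

from radsexing import ChromClass, ChromClassMap, IndividualClassStats
from radsexing.vcf_stats import ClassCounts


@pytest.fixture
def standard_map() -> ChromClassMap:
    """chrA/chrB autosomal, chrX/chrY sex-linked, unlisted → autosome."""
    return ChromClassMap(
        entries={
            "chrA": ChromClass.AUTOSOME,
            "chrB": ChromClass.AUTOSOME,
            "chrX": ChromClass.X_LIKE,
            "chrY": ChromClass.Y_LIKE,
        }
    )


def make_stats(
    individual_id="ind",
    depth_a=None,
    depth_x=None,
    depth_y=None,
    com_x=None,
    com_y=None,
    denom=10,
):
    """Construct IndividualClassStats with exact target statistics.

    Mean depths are realized as ``denom`` non-missing sites of constant
    depth; completeness values must be multiples of ``1/denom`` so the
    missing-site counts are exact integers.
    """

    def counts(mean_depth, completeness):
        if mean_depth is None and completeness is None:
            return ClassCounts()
        comp = 1.0 if completeness is None else completeness
        n_nonmiss = round(comp * denom)
        assert abs(n_nonmiss - comp * denom) < 1e-9, "completeness not exact"
        md = 0.0 if mean_depth is None else mean_depth
        return ClassCounts(
            n_sites=denom,
            n_missing=denom - n_nonmiss,
            depth_sum=md * n_nonmiss,
            n_nonmissing=n_nonmiss,
        )

    return IndividualClassStats(
        individual_id=individual_id,
        counts={
            ChromClass.AUTOSOME: counts(depth_a, None),
            ChromClass.X_LIKE: counts(depth_x, com_x),
            ChromClass.Y_LIKE: counts(depth_y, com_y),
        },
    )
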