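"""Chromosome-class configuration and run parameters.

Sexing from reduced-representation data requires knowing, for every
reference contig in the VCF, whether it is X-like, Y-like, autosomal, or to
be excluded.  The configuration file is a small YAML document::

    contigs:
      NC_045612.1: X_LIKE
      NC_045613.1: Y_LIKE
    default: AUTOSOME
    sex_labels:
      homogametic: female
      heterogametic: male
    run:
      index_y_female_threshold: 0.5
      low_depth_warning: 10.0

ZW systems are handled by relabeling: list the Z contig(s) as ``X_LIKE``
and the W contig(s) as ``Y_LIKE``, and swap the ``sex_labels`` (the
homogametic sex of a ZW system is the male).  All index arithmetic is
identical; only the attached labels change.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "ChromClass",
    "ChromClassMap",
    "RunConfig",
    "ConfigError",
    "parse_chrom_map",
    "load_config",
    "serialize_chrom_map",
    "DEFAULT_SEX_LABELS",
]


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration documents."""


class ChromClass(str, enum.Enum):
    """Role of a reference contig in the sexing model."""

    X_LIKE = "X_LIKE"
    Y_LIKE = "Y_LIKE"
    AUTOSOME = "AUTOSOME"
    EXCLUDED = "EXCLUDED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three classes over which per-individual statistics are accumulated.
STAT_CLASSES = (ChromClass.AUTOSOME, ChromClass.X_LIKE, ChromClass.Y_LIKE)

DEFAULT_SEX_LABELS = {"homogametic": "female", "heterogametic": "male"}


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys instead of silently
    keeping the last one — a duplicated contig is a configuration error."""


def _construct_mapping(loader: _StrictLoader, node: yaml.MappingNode, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ConfigError(f"duplicate key in configuration: {key!r}")
        seen.add(key)
    return yaml.SafeLoader.construct_mapping(loader, node, deep=deep)


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping
)


@dataclass(frozen=True)
class ChromClassMap:
    """Assignment of reference contigs to chromosome classes.

    Parameters
    ----------
    entries
        Mapping from contig identifier (spelled exactly as in the VCF
        header) to :class:`ChromClass`.
    default_class
        Class given to contigs not listed.  ``AUTOSOME`` suits
        chromosome-level assemblies; ``EXCLUDED`` keeps unplaced scaffolds
        out of the autosomal depth denominator.
    sex_labels
        Output labels for the homogametic / heterogametic sex.
    absent_in_homogametic
        The class physically absent from the homogametic sex: Y_LIKE for
        an XY system and, via relabeling, also for ZW.
    """

    entries: dict[str, ChromClass]
    default_class: ChromClass = ChromClass.AUTOSOME
    sex_labels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SEX_LABELS)
    )
    absent_in_homogametic: ChromClass = ChromClass.Y_LIKE

    def __post_init__(self) -> None:
        for cls in (ChromClass.X_LIKE, ChromClass.Y_LIKE):
            if not any(v is cls for v in self.entries.values()):
                raise ConfigError(
                    f"no contig assigned to {cls.value}; sexing requires at "
                    "least one X-like and one Y-like contig"
                )
        if self.default_class not in (ChromClass.AUTOSOME, ChromClass.EXCLUDED):
            raise ConfigError(
                "default class must be AUTOSOME or EXCLUDED, got "
                f"{self.default_class.value}"
            )
        for role in ("homogametic", "heterogametic"):
            if role not in self.sex_labels:
                raise ConfigError(f"sex_labels missing entry for {role!r}")

    def classify(self, contig: str) -> ChromClass:
        """Return the class of *contig* (the default class if unlisted)."""
        return self.entries.get(contig, self.default_class)

    def contigs(self, cls: ChromClass) -> list[str]:
        return [c for c, k in self.entries.items() if k is cls]


@dataclass(frozen=True)
class RunConfig:
    """Tunable run parameters shared across pipeline stages.

    ``min_locus_share_r`` and ``max_obs_het`` mirror the upstream locus
    filters (minimum proportion of individuals sharing a locus; site-wise
    observed-heterozygosity ceiling that purges collapsed paralogs).
    ``index_y_female_threshold`` is the decision boundary on Index Y
    (expected 1 in the homogametic sex, 0 in the heterogametic one; 0.5 is
    the midpoint).  ``low_depth_warning`` is the overall mean depth, in
    X-fold coverage, below which the depth-ratio index is demoted to
    unreliable.
    """

    min_locus_share_r: float = 0.3
    max_obs_het: float = 0.7
    index_y_female_threshold: float = 0.5
    low_depth_warning: float = 10.0
    output_precision: int = 4
    depth_field: str = "DP"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_locus_share_r <= 1.0:
            raise ConfigError("min_locus_share_r must be in [0, 1]")
        if not 0.0 <= self.max_obs_het <= 1.0:
            raise ConfigError("max_obs_het must be in [0, 1]")
        if self.low_depth_warning <= 0:
            raise ConfigError("low_depth_warning must be positive")
        if self.output_precision < 0:
            raise ConfigError("output_precision must be non-negative")

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the given non-None fields replaced."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates) if updates else self


def _coerce_class(label: object, context: str) -> ChromClass:
    try:
        return ChromClass(str(label))
    except ValueError:
        allowed = ", ".join(c.value for c in ChromClass)
        raise ConfigError(
            f"unknown chromosome class {label!r} for {context}; "
            f"allowed: {allowed}"
        ) from None


def parse_chrom_map(config_text: str) -> ChromClassMap:
    """Parse a YAML configuration document into a :class:`ChromClassMap`.

    Raises :class:`ConfigError` on duplicate contigs, unknown class labels,
    or when no X-like / Y-like contig is defined.
    """
    try:
        doc = yaml.load(io.StringIO(config_text), Loader=_StrictLoader)
    except yaml.YAMLError as exc:
        raise ConfigError(f"configuration is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or not doc:
        raise ConfigError(
            "empty configuration: no sex chromosomes defined "
            "(need a 'contigs' mapping with X_LIKE and Y_LIKE entries)"
        )
    contigs = doc.get("contigs")
    if not isinstance(contigs, dict) or not contigs:
        raise ConfigError("configuration must contain a non-empty 'contigs' mapping")
    entries = {
        str(contig): _coerce_class(cls, f"contig {contig!r}")
        for contig, cls in contigs.items()
    }
    default_class = _coerce_class(doc.get("default", "AUTOSOME"), "'default'")
    labels = dict(DEFAULT_SEX_LABELS)
    user_labels = doc.get("sex_labels") or {}
    if not isinstance(user_labels, dict):
        raise ConfigError("'sex_labels' must be a mapping")
    labels.update({str(k): str(v) for k, v in user_labels.items()})
    return ChromClassMap(
        entries=entries, default_class=default_class, sex_labels=labels
    )


def parse_run_config(doc: dict | None) -> RunConfig:
    """Build a :class:`RunConfig` from the optional ``run:`` section."""
    if not doc:
        return RunConfig()
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown run parameter(s): {sorted(unknown)}")
    return RunConfig(**doc)


def load_config(path) -> tuple[ChromClassMap, RunConfig]:
    """Load the chromosome map and run parameters from a YAML file."""
    with open(path) as handle:
        text = handle.read()
    chrom_map = parse_chrom_map(text)
    doc = yaml.load(io.StringIO(text), Loader=_StrictLoader)
    run = parse_run_config(doc.get("run") if isinstance(doc, dict) else None)
    return chrom_map, run


def serialize_chrom_map(chrom_map: ChromClassMap) -> str:
    """Render a :class:`ChromClassMap` back to its YAML document form.

    ``parse_chrom_map(serialize_chrom_map(m))`` reproduces ``m`` exactly.
    """
    doc = {
        "contigs": {c: cls.value for c, cls in chrom_map.entries.items()},
        "default": chrom_map.default_class.value,
        "sex_labels": dict(chrom_map.sex_labels),
    }
    return yaml.safe_dump(doc, sort_keys=False)
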