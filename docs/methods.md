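# Methods

## Model

The package assigns sex from a reduced-representation sequencing
experiment mapped to a reference genome whose contigs can be partitioned
into autosomes, an X-like set and a Y-like set. Two observable
consequences of heteromorphic sex chromosomes are exploited:

1. **Depth halving on X.** The heterogametic sex carries one X copy, so
   reads from X-like loci arrive at about half the autosomal rate:
   Index X = Depth<sub>X</sub>/Depth<sub>A</sub> ≈ 0.5, versus ≈ 1 in
   the homogametic sex.
2. **Y presence/absence.** The homogametic sex has no Y, so Y-like loci
   are (almost) entirely missing. With completeness Com = 1 −
   missingness, Index Y = (Com<sub>X</sub> − Com<sub>Y</sub>)/Com<sub>X</sub>
   is ≈ 1 without a Y and ≈ 0 with one.

Both statistics are computed from genotype missingness and per-genotype
depth only; whether a site is a SNP is irrelevant, which is why the input
must be an *all-sites* VCF (fixed and variable positions within loci).
Missingness is defined against the total number of retained sites of the
class in the file — the same denominator for every individual — and mean
depth averages over non-missing sites only; a depth value attached to a
missing genotype is ignored, and a genotype with any missing allele
(`./1`) counts as missing. These conventions match the per-individual
missingness/depth reports of standard VCF tooling; whether the original
depth reports averaged over all sites or only non-missing ones is not
documented anywhere we could check, so the non-missing convention is the
package's choice (at realistic dropout rates the difference is a
second-order rescaling that cancels almost entirely in the Index X
ratio).

## Decision rule

Sex is called from Index Y alone: `index_y >= threshold` (default 0.5,
inclusive) → homogametic, below → heterogametic. The threshold is the
midpoint of the two expected values — the point maximizing the margin to
both — and is configurable because no canonical cutoff exists; in
practice the two clusters are separated by a wide gap and the dispersion
plots let users audit the placement. The rule is a necessary invention:
the underlying method demonstrates separation graphically rather than
prescribing a numeric boundary.

Index X is demoted to an advisory call (nearest expected value, boundary
at 0.75, ties to the homogametic side to mirror the inclusive Index Y
rule) and suppressed entirely when overall mean depth falls below the
`low_depth_warning` floor (default 10X). The reason is structural, not
empirical tuning: the mean depth of a locus conditional on it being
captured at all is λ/(1 − e<sup>−λ</sup>), which tends to 1 read as
λ → 0 for X and autosomes alike, so the ratio drifts from 0.5 toward 1
and heterogametic individuals cross the boundary. Index Y has no such
failure mode and is, if anything, helped by low coverage (see below).

An `unassigned` outcome exists for degraded inputs (Index Y undefined
exactly when X completeness is zero); silent miscalls are worse than
abstention. A VCF carrying no Y-like sites at all is treated as
Com<sub>Y</sub> = 0 — indistinguishable from a fully missing Y — with a
loud warning, rather than making every call undefined.

## Locus filters

Two optional retention rules reproduce, natively and at locus level, the
filtering conventionally applied upstream: keep a locus iff it is present
(≥1 non-missing genotype among its sites) in at least ⌈r·N⌉ individuals
(default r = 0.3 — low enough that loci confined to a 30%-minority sex
survive), and drop a locus if **any** of its variant sites has observed
heterozygosity above `max_obs_het` (default 0.7), the conservative
site-wise veto reading of a paralog filter. Loci are taken verbatim from
the VCF ID column when present, otherwise reconstructed as runs of
consecutive sites with inter-site gap ≤ `max_gap` (default 1, i.e.
strictly contiguous positions, matching loci assembled from fixed-length
single-end reads). The stage is skipped by default since most users
arrive with an already-filtered `populations` output; single-population
semantics only.

## Synthetic cohorts

The generator produces the joint depth/missingness structure the indexes
exploit, with truth labels:

* per individual: mean autosomal depth `d` (scalar or per-individual),
  default 15X — the middle of the 11.5–13.8X averages typical of the
  motivating datasets;
* per locus: recoverability `r ∈ (0,1]` scaling capture efficiency,
  Beta(8,2) (mean 0.8) for autosomal/X loci and Beta(18,2) (mean 0.9)
  for Y loci. The higher Y distribution is a deliberate modeling choice,
  not a measured quantity: a sharing filter keyed to the minority sex
  retains only the most robust Y loci. It is what makes the
  empirically-observed negative Index Y reachable: at low depth the
  heterogametic X (λ = 0.5·d·r) drops out faster than the hardy Y
  (λ = d·r′), so Com<sub>Y</sub> > Com<sub>X</sub>;
* realized locus read count ~ Poisson(d · copy factor · r), with an
  optional gamma mixture for overdispersion; a locus is missing iff its
  count is 0, and all of a locus's sites share its depth and missing
  flag. The zero-count dropout rule is an assumption — no quantitative
  coverage→missingness model exists for the real data;
* copy factors: autosomes 1; X: 1 (homogametic) / 0.5 (`x_copy_ratio`,
  heterogametic); Y: `y_presence` (default 0, homogametic) / 1
  (heterogametic);
* genotypes are placeholder diploid calls (hemizygous loci included),
  optionally with a fraction of biallelic sites; only GT missingness and
  DP matter to the method.

Default locus counts are 2000 autosomal / 500 X / 50 Y — the real
datasets' ordering (tens of thousands autosomal, ~60% as many X, an
order of magnitude fewer Y) scaled to desk size; tests scale further
(and shorten `locus_length`, which is statistically inert since sites
within a locus are perfectly correlated) to keep cohorts cheap. The
simulation is reproducible: three independent seeded streams
(recoverability / counts / genotypes), so a depth gradient shares loci
across sub-cohorts and equal-depth sub-cohorts are identical apart from
individual IDs.

What the simulator does **not** emulate: read-level artifacts, reference
bias, restriction-site polymorphism, X/Y homologous (pseudo-autosomal)
regions that attract cross-mapping reads, contamination, or
population-genetic structure in genotypes. Passing simulation tests
therefore demonstrates the pipeline arithmetic and the indexes' designed
behavior under the model, not performance on any particular real
dataset.

## Numerical and interface choices

* All statistics are exact integer/rational accumulations (site counts,
  depth sums); no floating-point accumulation issues at realistic scale.
* Mean depth of a class with zero non-missing sites is undefined and
  flagged (`None`, empty CSV cell), never 0.
* Output CSV rounds to 4 decimals by default (index differences of
  interest are ≥0.01); reruns on identical inputs are byte-identical.
* VCF parsing uses cyvcf2; missingness is derived from the genotype
  allele array (any allele `.` → missing) rather than the library's
  genotype-type codes, which classify half-missing calls as
  heterozygous. A `.` depth entry is read as "no depth observed" (0).
* Coordinates are 1-based inclusive VCF positions; no strand handling.
* Unlisted contigs default to `AUTOSOME` (right for chromosome-level
  assemblies); `default: EXCLUDED` is available so unplaced scaffolds do
  not pollute the autosomal depth on draftier references.

## Known limitations

* The decision threshold is fixed, not data-adaptive; a mixture/cluster
  approach could replace it but is out of scope.
* Genuinely intermediate coverage plus extreme dropout can in principle
  produce a heterogametic Index Y above 0.5; the `unassigned` class only
  covers undefined indexes, not low-confidence defined ones.
* Species with homomorphic or aberrant sex-chromosome systems (XO,
  neo-sex chromosomes, pseudo-autosomal dominance) violate the model's
  assumptions and will not separate.
* The locus-sharing filter implements single-population semantics only.
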