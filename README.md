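# radsexing

Coverage-based molecular sexing for RAD-seq / GBS data mapped to a
chromosome-level reference genome.

## The problem

Sex is hard to determine for many wild animals — non-dimorphic species,
juveniles, or non-invasive samples (scat, hair, carcasses) where only
degraded DNA is available. When a study already has reduced-representation
sequencing data (RAD-seq/GBS) and a closely related reference genome with
assembled sex chromosomes, sex can be read directly from how the loci
behave on those chromosomes, with no sex-specific markers, PCR assays or
per-study statistical validation.

`radsexing` takes an **all-sites VCF** (every position within the
assembled RAD loci, fixed and variable, with per-genotype depth — e.g. a
STACKS `populations.all.vcf`) plus a small YAML file labeling each
reference contig as X-like, Y-like, autosomal or excluded, and assigns a
sex to every individual. It targets any heteromorphic XY system; ZW
systems are handled by relabeling (Z → `X_LIKE`, W → `Y_LIKE`, labels
swapped), since the arithmetic only distinguishes the homogametic from
the heterogametic sex.

## The two indexes

For individual *i*, with mean read depth per chromosome class
Depth<sub>A</sub>, Depth<sub>X</sub> (over non-missing sites) and
completeness Com<sub>X</sub>, Com<sub>Y</sub> (one minus the fraction of
the class's sites missing in that individual):

|  | definition | homogametic (XX) | heterogametic (XY) |
|---|---|---|---|
| **Index X** | Depth<sub>X</sub> / Depth<sub>A</sub> | 1 | 0.5 |
| **Index Y** | (Com<sub>X</sub> − Com<sub>Y</sub>) / Com<sub>X</sub> | 1 | 0 |

Index X reflects X hemizygosity: one X copy means half the reads. Index Y
reflects Y presence: an individual without a Y is missing essentially all
Y-like loci.

**Sex is called from Index Y alone** (at or above a configurable
threshold, default 0.5 → homogametic; below → heterogametic). Index X is
reported as an advisory cross-check and suppressed below 10X overall
coverage: at low depth the depth of a locus *conditional on being seen at
all* approaches one read on both X and autosomes, dragging the ratio
toward 1 and misassigning heterogametic individuals. Index Y tolerates
low coverage and even turns negative for low-depth heterogametic
individuals (robustly captured Y loci drop out more slowly than X loci),
which only widens the separation.

## Worked example

Simulate a 12-individual cohort (800 autosomal / 300 X / 40 Y loci,
18X mean depth) and sex it:

```bash
radsexing simulate -o demo --n 12 --loci 800 300 40 \
    --locus-length 6 --depth 18 --seed 42
radsexing sex demo/cohort.vcf -c demo/chrom_config.yaml -o demo/report
```

The log reports the cohort summary:

```
INFO validated demo/cohort.vcf: 12 samples, 10 contigs
INFO accumulated 6840 retained sites for 12 individuals
INFO called 12 individuals: 6 female, 6 male, 0 unassigned (0 low-depth)
```

and `demo/report/final_sexing.csv` holds one row per individual:

```
individual,DepthA,DepthX,DepthY,ComX,ComY,index_x,index_y,overall_mean_depth,sex,...
ind_001,14.4625,14.6267,,1.0000,0.0000,1.0114,1.0000,14.5073,female,...
ind_012,14.6013,6.9667,17.0500,1.0000,1.0000,0.4771,0.0000,12.6781,male,...
```

`ind_001` recovers X loci at autosomal depth (Index X ≈ 1) and has every
Y site missing (`DepthY` empty, Index Y = 1): female. `ind_012` has X
depth half of autosomal (0.48) and equal X/Y completeness (Index Y = 0):
male. The realized depths sit below the simulated 18X because each locus
carries a capture-efficiency (recoverability) factor. A companion
`sexing_plots.pdf` shows the three dispersion plots — Index X vs Index Y,
and each index against overall coverage depth — with the Index Y decision
threshold drawn as a reference line.

A real run looks the same with your own inputs:

```bash
radsexing sex populations.all.vcf -c chrom_config.yaml -o results/
```

where `chrom_config.yaml` names the sex chromosomes of the reference,
e.g. for the California sea lion assembly:

```yaml
contigs:
  NC_045612.1: X_LIKE
  NC_045613.1: Y_LIKE
default: AUTOSOME
```

Other subcommands: `radsexing stats` (the per-individual per-class audit
table), `radsexing filter` (native locus-sharing `--r` and
`--max-obs-het` filters for VCFs not already filtered upstream), and
`radsexing simulate` (self-contained fixture triplets).

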