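# rdipkit

Downstream analysis toolkit for directional RNA:DNA-hybrid (RDIP-seq-style)
mapping experiments, plus a synthetic-data generator that emulates the signal
structure the analyses assume, so the whole pipeline is testable without any
external downloads.

## What it does

- **`rdipkit.genome_io`** — genome/interval model (0-based half-open
  everywhere), BED/FASTA/SAM/bedGraph readers and writers, interval
  arithmetic: union occupancy, overlap basepairs, genome tiling into
  fixed-width windows, within-chromosome interval shuffling.
- **`rdipkit.strandedness`** — classifies the RNA-derived strand of each
  properly paired read from its SAM flag (163 = top strand, 147 = bottom),
  scores each peak with a strandedness value in [−1, +1]
  (`(n_top − n_bottom) / (n_top + n_bottom)`), and removes the 10% of peaks
  with the weakest |strandedness|.
- **`rdipkit.skew_stats`** — AT skew, GC skew and purine fraction per peak,
  the same statistics on the called RNA strand, positional purine profiles
  along RNA-oriented peaks, and the sense/antisense gene-orientation test.
- **`rdipkit.genomic_context`** — exclusive context assignment by precedence,
  observed/expected occupancy enrichment with a permutation null,
  repeat-family breakdowns, overlap proportions, and the peak-vs-genome
  methylation contrast.
- **`rdipkit.metaplot`** — strand-oriented metagene profiles in 100-bp bins
  around TSS/TES, expression-quantile stratification, and a two-sample
  proportions test (chi-square, no continuity correction).
- **`rdipkit.rdna`** — coverage over a named reference span (e.g. an rDNA
  repeat unit): exact-sequence read deduplication, per-bp depth, input
  subtraction (raw or reads-per-million), 50-bp window means.
- **`rdipkit.density_regression`** — lasso coefficient path of window-level
  peak density on genomic covariates by least-angle regression with the
  lasso modification (exact knots, drops included), and the covariance test
  statistic (Exp(1) null) for each covariate entering the path.
- **`rdipkit.synthetic_data`** — seeded generator for genomes, annotations,
  purine-skewed peaks, directional read pairs (SAM), expression tables,
  methylation tracks and window covariates, with truth sidecars for
  parameter-recovery testing.

## Command line

Every stage is a subcommand operating on a run directory; `simulate` creates
one from scratch:

```bash
rdipkit simulate --rundir run --seed 1          # synthetic dataset
rdipkit strandedness --rundir run               # per-peak RNA-strand scores + filter
rdipkit skew --rundir run                       # skew statistics + positional profile
rdipkit context --rundir run --n-perm 999       # permutation enrichment
rdipkit metaplot --rundir run                   # TSS profiles by expression stratum
rdipkit rdna --rundir run                       # windowed coverage
rdipkit lasso --rundir run                      # lasso path + covariance test
rdipkit all --rundir run --seed 1               # everything in order
```

A YAML config (`--config`) can override simulation parameters under a
`simulate:` key. Each stage appends to `run/manifest.json` (parameters, seed,
output SHA-256 checksums); runs are byte-identical for a fixed seed.

## Notes

- Input SAM must be text (not BAM); desk-scale data only.
- The synthetic generator's distributional choices (exponential feature
  lengths, log-normal expression, Beta methylation, Gaussian covariates) are
  stand-ins: real RDIP-seq data has no published generative model. Planted
  parameters are recorded in truth tables and verified by the test suite.
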