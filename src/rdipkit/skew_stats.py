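"""Nucleotide-composition statistics for peaks.

AT skew = (A - T) / (A + T), GC skew = (G - C) / (G + C), purine fraction =
(G + A) / (A + C + G + T); all counted on the top strand unless the peak's
RNA-strand call orients the computation onto the bottom strand (reverse
complement).  N bases are excluded from every denominator.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np
from scipy import stats

from rdipkit.genome_io import Genome, GenomicInterval
from rdipkit.strandedness import Peak

__all__ = [
    "BaseCounts",
    "SkewRecord",
    "base_counts",
    "skew",
    "rna_strand_skew",
    "positional_skew_profile",
    "gene_orientation_bias",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class BaseCounts:
    a: int
    c: int
    g: int
    t: int
    n: int = 0

    @property
    def informative(self) -> int:
        return self.a + self.c + self.g + self.t


@dataclasses.dataclass(frozen=True)
class SkewRecord:
    """Skew statistics of one interval; undefined statistics are NaN."""

    counts: BaseCounts
    at_skew: float
    gc_skew: float
    purine_fraction: float
    interval: GenomicInterval | None = None
    rna_strand_purine_fraction: float = math.nan


def base_counts(sequence: str) -> BaseCounts:
    """Exact A/C/G/T/N counts, case-insensitive.

    Any other character raises a ValueError naming its offset.
    """
    seq = sequence.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    total = sum(counts.values())
    if total != len(seq):
        for offset, char in enumerate(seq):
            if char not in "ACGTN":
                raise ValueError(
                    f"invalid base {char!r} at offset {offset}"
                )
    return BaseCounts(counts["A"], counts["C"], counts["G"], counts["T"], counts["N"])


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def skew(sequence: str, interval: GenomicInterval | None = None) -> SkewRecord:
    """Compute AT skew, GC skew and purine fraction of a top-strand sequence.

    Denominator-zero statistics come back NaN ("undefined"), never 0.
    """
    counts = base_counts(sequence)
    return SkewRecord(
        counts=counts,
        at_skew=_ratio(counts.a - counts.t, counts.a + counts.t),
        gc_skew=_ratio(counts.g - counts.c, counts.g + counts.c),
        purine_fraction=_ratio(counts.g + counts.a, counts.informative),
        interval=interval,
    )


def rna_strand_skew(
    peaks: Sequence[Peak], genome: Genome
) -> tuple[list[SkewRecord], int]:
    """Skew statistics on the called RNA strand of each peak.

    Bottom-strand calls are reverse complemented before counting.  Peaks with
    an ambiguous call are skipped; the second return value is how many were.
    """
    records: list[SkewRecord] = []
    n_ambiguous = 0
    for peak in peaks:
        if peak.rna_strand == ".":
            n_ambiguous += 1
            continue
        seq = genome.sequence(peak.interval)
        top = skew(seq, interval=peak.interval)
        rna_seq = seq if peak.rna_strand == "+" else reverse_complement(seq)
        rna = skew(rna_seq)
        records.append(
            dataclasses.replace(
                top, rna_strand_purine_fraction=rna.purine_fraction
            )
        )
    return records, n_ambiguous


def oriented_sequence(peak: Peak, genome: Genome) -> str:
    """Peak sequence read 5'->3' along the called RNA strand."""
    seq = genome.sequence(peak.interval)
    return seq if peak.rna_strand == "+" else reverse_complement(seq)


def positional_skew_profile(
    peaks: Sequence[Peak], genome: Genome, bins: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean purine fraction per positional bin along RNA-oriented peaks.

    Each peak is rescaled to unit length, split into ``bins`` equal pieces in
    the 5'->3' order of its called RNA strand, and the per-bin purine
    fractions are averaged over peaks.  Peaks shorter than ``bins`` bp or
    with ambiguous calls are skipped and counted.

    Returns (mean per bin, n contributing peaks per bin, n skipped).
    """
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    sums = np.zeros(bins)
    counts = np.zeros(bins, dtype=int)
    n_skipped = 0
    for peak in peaks:
        if peak.rna_strand == "." or len(peak.interval) < bins:
            n_skipped += 1
            continue
        seq = oriented_sequence(peak, genome)
        edges = np.linspace(0, len(seq), bins + 1).round().astype(int)
        for b in range(bins):
            frac = skew(seq[edges[b] : edges[b + 1]]).purine_fraction
            if not math.isnan(frac):
                sums[b] += frac
                counts[b] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts, n_skipped


def gene_orientation_bias(
    peaks: Sequence[Peak], genes: Sequence[GenomicInterval]
) -> tuple[int, int, float]:
    """Sense/antisense orientation of intragenic peaks plus a binomial test.

    A peak overlapping a gene is 'sense' when its RNA-strand call equals the
    gene strand.  Peaks overlapping several genes are labelled by the first
    overlapping gene in genomic order.  Returns (n_sense, n_antisense,
    two-sided binomial p against 0.5).
    """
    stranded_genes = sorted(
        (g for g in genes if g.strand in ("+", "-")),
        key=lambda g: (g.chrom, g.start),
    )
    n_sense = n_antisense = 0
    for peak in peaks:
        if peak.rna_strand == ".":
            continue
        gene = next(
            (g for g in stranded_genes if g.overlaps(peak.interval)), None
        )
        if gene is None:
            continue
        if peak.rna_strand == gene.strand:
            n_sense += 1
        else:
            n_antisense += 1
    total = n_sense + n_antisense
    if total == 0:
        return 0, 0, math.nan
    p = stats.binomtest(n_sense, total, 0.5, alternative="two-sided").pvalue
    return n_sense, n_antisense, float(p)
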