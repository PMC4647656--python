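"""Strand-oriented metagene profiles around TSS/TES.

Bins are 100 bp by default, anchored at the TSS (or TES) and numbered in
transcriptional orientation: bin +1 is the first window downstream of the
anchor, bin -1 the first upstream; there is no bin 0.  For minus-strand
genes the genomic coordinates are flipped accordingly.  A peak intersecting
a gene bin is counted in the 'sense' channel when the RNA strand of the
hybrid equals the gene strand, else 'antisense'; a peak spanning several
bins increments each (presence counting, not bp-weighted).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_chisquare

from rdipkit.genome_io import GenomicInterval
from rdipkit.strandedness import Peak

__all__ = [
    "MetaplotProfile",
    "gene_relative_bins",
    "strand_oriented_profile",
    "expression_strata_profile",
    "proportions_test",
]


@dataclasses.dataclass
class MetaplotProfile:
    """Aggregate sense/antisense peak counts per gene-relative bin."""

    bin_indices: np.ndarray  # ..., -2, -1, 1, 2, ... (no 0)
    width: int
    sense: np.ndarray
    antisense: np.ndarray
    n_genes: int

    def offsets(self) -> np.ndarray:
        """Left edge of each bin in bp relative to the anchor."""
        return np.where(
            self.bin_indices > 0,
            (self.bin_indices - 1) * self.width,
            self.bin_indices * self.width,
        )


def _anchor(gene: GenomicInterval, anchor: str) -> int:
    if gene.strand not in ("+", "-"):
        raise ValueError(f"gene {gene.name or gene.chrom} has no strand")
    if anchor == "TSS":
        return gene.start if gene.strand == "+" else gene.end
    if anchor == "TES":
        return gene.end if gene.strand == "+" else gene.start
    raise ValueError(f"anchor must be 'TSS' or 'TES', got {anchor!r}")


def gene_relative_bins(
    gene: GenomicInterval,
    span_upstream: int,
    span_downstream: int,
    width: int = 100,
    anchor: str = "TSS",
) -> list[tuple[int, GenomicInterval]]:
    """Fixed-width genomic bins around a gene anchor, in gene orientation.

    Returns (bin index, genomic interval) pairs; bins falling off the start
    of the chromosome are dropped.  Spans must be multiples of ``width``.
    """
    if span_upstream % width or span_downstream % width:
        raise ValueError("spans must be multiples of the bin width")
    pos = _anchor(gene, anchor)
    sign = 1 if gene.strand == "+" else -1
    bins: list[tuple[int, GenomicInterval]] = []
    indices = list(range(-span_upstream // width, 0)) + list(
        range(1, span_downstream // width + 1)
    )
    for k in indices:
        offset = (k - 1) * width if k > 0 else k * width
        if sign > 0:
            start = pos + offset
        else:
            start = pos - offset - width
        if start < 0:
            continue
        bins.append((k, GenomicInterval(gene.chrom, start, start + width)))
    return bins


def strand_oriented_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GenomicInterval],
    span_upstream: int = 2000,
    span_downstream: int = 5000,
    width: int = 100,
    anchor: str = "TSS",
) -> MetaplotProfile:
    """Count peaks intersecting gene-relative bins, split by orientation.

    Each (peak, gene, bin) intersection increments exactly one channel:
    sense when the peak's RNA-strand call matches the gene strand.  Peaks
    with ambiguous calls are ignored.
    """
    indices = np.array(
        list(range(-span_upstream // width, 0))
        + list(range(1, span_downstream // width + 1))
    )
    index_pos = {int(k): i for i, k in enumerate(indices)}
    sense = np.zeros(len(indices), dtype=int)
    antisense = np.zeros(len(indices), dtype=int)

    by_chrom: dict[str, list[Peak]] = {}
    for peak in peaks:
        if peak.rna_strand == ".":
            continue
        by_chrom.setdefault(peak.interval.chrom, []).append(peak)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.interval.start)
    starts = {
        chrom: np.array([p.interval.start for p in plist])
        for chrom, plist in by_chrom.items()
    }
    max_len = {
        chrom: max(len(p.interval) for p in plist)
        for chrom, plist in by_chrom.items()
    }

    for gene in genes:
        chrom = gene.chrom
        if chrom not in by_chrom:
            continue
        for k, bin_iv in gene_relative_bins(
            gene, span_upstream, span_downstream, width, anchor
        ):
            lo = int(
                np.searchsorted(starts[chrom], bin_iv.start - max_len[chrom], "left")
            )
            hi = int(np.searchsorted(starts[chrom], bin_iv.end, "left"))
            for peak in by_chrom[chrom][lo:hi]:
                if peak.interval.overlaps(bin_iv):
                    if peak.rna_strand == gene.strand:
                        sense[index_pos[k]] += 1
                    else:
                        antisense[index_pos[k]] += 1
    return MetaplotProfile(
        bin_indices=indices,
        width=width,
        sense=sense,
        antisense=antisense,
        n_genes=len(genes),
    )


def _has_peak(gene: GenomicInterval, peaks: Sequence[Peak]) -> bool:
    return any(p.interval.overlaps(gene) for p in peaks)


def expression_strata_profile(
    peaks: Sequence[Peak],
    genes: Sequence[GenomicInterval],
    expression: Mapping[str, float],
    k_quantiles: int = 4,
    span_upstream: int = 2000,
    span_downstream: int = 5000,
    width: int = 100,
) -> dict[str, tuple[MetaplotProfile, float]]:
    """Metagene profile and peak-bearing gene fraction per expression stratum.

    Genes split into a 'zero' class plus ``k_quantiles`` quantile strata
    ('q1' lowest .. 'qk' highest) among expressed genes.  Every gene must
    appear in the expression table.
    """
    if k_quantiles < 2:
        raise ValueError(f"k_quantiles must be >= 2, got {k_quantiles}")
    missing = [g.name for g in genes if g.name not in expression]
    if missing:
        raise ValueError(f"{len(missing)} genes missing from expression table")
    zero = [g for g in genes if expression[g.name] == 0]
    expressed = [g for g in genes if expression[g.name] > 0]
    strata: dict[str, list[GenomicInterval]] = {}
    if zero:
        strata["zero"] = zero
    if expressed:
        values = np.array([expression[g.name] for g in expressed])
        # rank-based quantile assignment keeps strata sizes even under ties
        order = np.argsort(values, kind="stable")
        labels = np.empty(len(expressed), dtype=int)
        labels[order] = np.minimum(
            (np.arange(len(expressed)) * k_quantiles) // len(expressed),
            k_quantiles - 1,
        )
        for q in range(k_quantiles):
            members = [g for g, lab in zip(expressed, labels) if lab == q]
            if members:
                strata[f"q{q + 1}"] = members
    out: dict[str, tuple[MetaplotProfile, float]] = {}
    for name, members in strata.items():
        profile = strand_oriented_profile(
            peaks, members, span_upstream, span_downstream, width
        )
        frac = sum(_has_peak(g, peaks) for g in members) / len(members)
        out[name] = (profile, frac)
    return out


def proportions_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float, float]:
    """Two-sample test of equal proportions (chi-square, no continuity corr.).

    Returns (difference p1 - p2, chi-square statistic, two-sided p-value).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    diff = x1 / n1 - x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return diff, 0.0, 1.0
    chi2, p, _ = proportions_chisquare([x1, x2], [n1, n2])
    return diff, float(chi2), float(p)
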