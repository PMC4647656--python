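"""Genomic-context assignment and permutation-based occupancy enrichment.

Exclusive context labels follow a precedence order with 'intergenic' as the
fallback; occupancy enrichment compares observed overlap basepairs with the
expectation under independent uniform placement, and significance comes from
shuffling the peak intervals within chromosomes.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats

from rdipkit.genome_io import (
    FeatureSet,
    Genome,
    GenomicInterval,
    overlap_bp,
    shuffle_intervals,
    union_occupancy,
)

__all__ = [
    "EnrichmentResult",
    "assign_context",
    "occupancy_enrichment",
    "permutation_test",
    "repeat_family_breakdown",
    "overlap_proportion",
    "methylation_contrast",
]

INTERGENIC = "intergenic"


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Observed/expected occupancy of a feature class with permutation p."""

    label: str
    observed_bp: int
    expected_bp: float
    ratio: float  # NaN when expected == 0
    p_value: float
    n_permutations: int


def _any_overlap(iv: GenomicInterval, merged: Mapping[str, np.ndarray]) -> bool:
    spans = merged.get(iv.chrom)
    if spans is None or len(spans) == 0:
        return False
    # spans sorted by start; find candidates with start < iv.end
    hi = int(np.searchsorted(spans[:, 0], iv.end, "left"))
    return bool(np.any(spans[:hi, 1] > iv.start))


def _merged(feature: FeatureSet) -> dict[str, np.ndarray]:
    from rdipkit.genome_io import _merged_by_chrom

    return _merged_by_chrom(feature.intervals)


def assign_context(
    peaks: Sequence[GenomicInterval],
    feature_sets: Sequence[FeatureSet],
    precedence: Sequence[str],
) -> tuple[list[str], dict[str, int]]:
    """Assign each peak its single highest-precedence overlapping context.

    A peak gets the first label in ``precedence`` whose feature set it
    overlaps by >= 1 bp, else 'intergenic'.  Returns per-peak labels and a
    tally whose counts sum to the number of peaks.
    """
    by_label = {fs.label: fs for fs in feature_sets}
    for label in precedence:
        if label not in by_label:
            raise ValueError(f"precedence names unknown feature label {label!r}")
    merged = {label: _merged(by_label[label]) for label in precedence}
    labels: list[str] = []
    tally: dict[str, int] = {label: 0 for label in precedence}
    tally[INTERGENIC] = 0
    for peak in peaks:
        assigned = INTERGENIC
        for label in precedence:
            if _any_overlap(peak, merged[label]):
                assigned = label
                break
        labels.append(assigned)
        tally[assigned] += 1
    return labels, tally


def occupancy_enrichment(
    peaks: Sequence[GenomicInterval],
    feature: FeatureSet,
    genome: Genome,
) -> tuple[int, float, float]:
    """Observed vs expected overlap basepairs between peaks and a feature.

    expected = union(peaks) * occupancy(feature) / genome size, i.e. the mean
    overlap under independent uniform placement.  A zero-occupancy feature
    yields a NaN ratio rather than an error downstream.
    """
    observed = overlap_bp(peaks, feature.intervals, strict_namespace=False)
    expected = union_occupancy(peaks) * feature.occupancy / genome.size
    ratio = observed / expected if expected > 0 else math.nan
    return observed, expected, ratio


def permutation_test(
    peaks: Sequence[GenomicInterval],
    feature: FeatureSet,
    genome: Genome,
    n_perm: int = 999,
    seed: int | None = None,
    mask: Sequence[GenomicInterval] | None = None,
) -> EnrichmentResult:
    """Permutation enrichment test of peak/feature overlap occupancy.

    The null shuffles the peak intervals uniformly within their chromosomes
    ``n_perm`` times.  Two-sided empirical p with add-one correction:
    ``p = 2 * min(#(null >= obs), #(null <= obs)) + 1) / (n_perm + 1)``,
    capped at 1; resolution is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    observed, expected, ratio = occupancy_enrichment(peaks, feature, genome)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        shuffled = shuffle_intervals(peaks, genome, rng=rng, mask=mask)
        null[k] = overlap_bp(shuffled, feature.intervals, strict_namespace=False)
    n_ge = int(np.sum(null >= observed))
    n_le = int(np.sum(null <= observed))
    p = min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n_perm + 1))
    return EnrichmentResult(
        label=feature.label,
        observed_bp=observed,
        expected_bp=expected,
        ratio=ratio,
        p_value=p,
        n_permutations=n_perm,
    )


def repeat_family_breakdown(
    peaks: Sequence[GenomicInterval],
    repeat_features: Sequence[GenomicInterval],
    family_of: Mapping[str, str] | None = None,
) -> dict[str, dict[str, tuple[int, int, float]]]:
    """Per-family subfamily composition of repeat-overlapping peaks.

    Repeat intervals carry subfamily labels in ``name``; ``family_of`` maps
    subfamily -> family (identity when omitted).  For each family, reports
    ``subfamily -> (count, denominator, fraction)`` where the denominator is
    the number of peaks overlapping any repeat of that family.  A peak
    overlapping several subfamilies of a family counts once per subfamily
    but once in the denominator.
    """
    if family_of is None:
        family_of = {}
    by_subfamily: dict[str, list[GenomicInterval]] = {}
    for rep in repeat_features:
        sub = rep.name or "unnamed"
        by_subfamily.setdefault(sub, []).append(rep)
    from rdipkit.genome_io import _merged_by_chrom

    merged_sub = {
        sub: _merged_by_chrom(ivs) for sub, ivs in by_subfamily.items()
    }
    families: dict[str, dict[str, int]] = {}
    family_peaks: dict[str, int] = {}
    for peak in peaks:
        hit_families: set[str] = set()
        for sub, merged in merged_sub.items():
            if _any_overlap(peak, merged):
                family = family_of.get(sub, sub)
                families.setdefault(family, {}).setdefault(sub, 0)
                families[family][sub] += 1
                hit_families.add(family)
        for family in hit_families:
            family_peaks[family] = family_peaks.get(family, 0) + 1
    out: dict[str, dict[str, tuple[int, int, float]]] = {}
    for family, subs in families.items():
        denom = family_peaks[family]
        out[family] = {
            sub: (count, denom, count / denom) for sub, count in subs.items()
        }
    return out


def overlap_proportion(
    peaks: Sequence[GenomicInterval],
    feature: FeatureSet | Sequence[GenomicInterval],
) -> tuple[float, list[GenomicInterval]]:
    """Fraction of peaks overlapping the feature by >= 1 bp.

    Also returns the overlapping peaks so calls can be chained ("of those,
    how many also hit track2").  Empty peak set -> NaN fraction.
    """
    intervals = feature.intervals if isinstance(feature, FeatureSet) else feature
    from rdipkit.genome_io import _merged_by_chrom

    merged = _merged_by_chrom(intervals)
    hits = [p for p in peaks if _any_overlap(p, merged)]
    if not peaks:
        return math.nan, hits
    return len(hits) / len(peaks), hits


def methylation_contrast(
    peaks: Sequence[GenomicInterval],
    methylation: Sequence[tuple[str, int, int, float]],
) -> tuple[float, float, float, float]:
    """Mean methylation inside peaks vs genome-wide, plus a rank test.

    ``methylation`` is bedGraph-style per-CpG rows (chrom, start, end,
    fraction in [0, 1]); means are per-CpG, unweighted.  Returns
    (mean_in_peaks, mean_genome_wide, difference, Mann-Whitney two-sided p).
    NaNs when no CpG falls in a peak.
    """
    from rdipkit.genome_io import _merged_by_chrom

    merged = _merged_by_chrom(peaks)
    inside: list[float] = []
    everywhere: list[float] = []
    for chrom, start, end, value in methylation:
        everywhere.append(value)
        if _any_overlap(GenomicInterval(chrom, start, max(end, start + 1)), merged):
            inside.append(value)
    if not everywhere:
        raise ValueError("empty methylation track")
    genome_mean = float(np.mean(everywhere))
    if not inside:
        return math.nan, genome_mean, math.nan, math.nan
    peak_mean = float(np.mean(inside))
    if len(inside) == len(everywhere) or np.ptp(everywhere) == 0:
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(inside, everywhere, alternative="two-sided").pvalue
        )
    return peak_mean, genome_mean, peak_mean - genome_mean, p
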