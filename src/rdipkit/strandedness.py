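"""Per-peak RNA-strand inference from directional paired-end alignments.

In the directional library, the second read of a properly paired fragment
carries the RNA-derived sequence.  Its SAM flag is 163 when it aligns to the
top (forward) reference strand and 147 when it aligns to the bottom
(reverse) strand; every other flag value is excluded from strand evidence.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np

from rdipkit.genome_io import AlignedPairRecord, GenomicInterval

__all__ = [
    "Peak",
    "TOP_STRAND_FLAG",
    "BOTTOM_STRAND_FLAG",
    "classify_rna_strand",
    "strandedness_score",
    "score_peaks",
    "filter_intermediate",
]

# properly paired, second in pair; mate-reverse (163) vs read-reverse (147)
TOP_STRAND_FLAG = 163
BOTTOM_STRAND_FLAG = 147


@dataclasses.dataclass
class Peak:
    """A peak interval annotated with RNA-strand read counts and score.

    ``strandedness`` is (n_top - n_bottom) / (n_top + n_bottom): +1 when all
    RNA-derived reads align to the top strand, -1 when all align to the
    bottom strand, None when no reads classified.
    """

    interval: GenomicInterval
    n_top: int = 0
    n_bottom: int = 0

    @property
    def depth(self) -> int:
        return self.n_top + self.n_bottom

    @property
    def strandedness(self) -> float | None:
        if self.depth == 0:
            return None
        return (self.n_top - self.n_bottom) / self.depth

    @property
    def rna_strand(self) -> str:
        """Derived RNA-strand call: '+', '-' or '.' (ambiguous)."""
        s = self.strandedness
        if s is None or s == 0:
            return "."
        return "+" if s > 0 else "-"


def classify_rna_strand(record: AlignedPairRecord) -> str:
    """Classify a record's RNA-derived strand: 'top', 'bottom' or 'excluded'.

    Only the exact flag values 163 and 147 count; discordant, secondary,
    duplicate and supplementary alignments all fall through to 'excluded'.
    Exclusion is a value, not an error.
    """
    if record.flag == TOP_STRAND_FLAG:
        return "top"
    if record.flag == BOTTOM_STRAND_FLAG:
        return "bottom"
    return "excluded"


def strandedness_score(
    peak_interval: GenomicInterval, records: Iterable[AlignedPairRecord]
) -> Peak:
    """Count classified RNA-derived reads overlapping one peak and score it.

    A read pair contributes if the RNA-derived (second-in-pair) read's
    alignment interval overlaps the peak by at least 1 bp.
    """
    peak = Peak(interval=peak_interval)
    for record in records:
        side = classify_rna_strand(record)
        if side == "excluded" or record.chrom is None:
            continue
        if record.interval().overlaps(peak_interval):
            if side == "top":
                peak.n_top += 1
            else:
                peak.n_bottom += 1
    return peak


def score_peaks(
    peak_intervals: Sequence[GenomicInterval],
    records: Iterable[AlignedPairRecord],
) -> list[Peak]:
    """Score all peaks in one pass over the record stream.

    Uses per-chromosome sorted peak starts so each record touches only the
    peaks it can overlap.  Peaks may overlap each other; a read is credited
    to every peak it intersects.
    """
    peaks = [Peak(interval=iv) for iv in peak_intervals]
    by_chrom: dict[str, list[int]] = {}
    for idx, peak in enumerate(peaks):
        by_chrom.setdefault(peak.interval.chrom, []).append(idx)
    starts: dict[str, np.ndarray] = {}
    order: dict[str, list[int]] = {}
    max_len: dict[str, int] = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: peaks[i].interval.start)
        order[chrom] = idxs
        starts[chrom] = np.array([peaks[i].interval.start for i in idxs])
        max_len[chrom] = max(len(peaks[i].interval) for i in idxs)

    for record in records:
        side = classify_rna_strand(record)
        if side == "excluded" or record.chrom is None:
            continue
        chrom = record.chrom
        if chrom not in order:
            continue
        # candidate peaks: start < record.end and start >= record.pos - max_len
        lo = int(np.searchsorted(starts[chrom], record.pos - max_len[chrom], "left"))
        hi = int(np.searchsorted(starts[chrom], record.end, "left"))
        rec_iv = record.interval()
        for i in order[chrom][lo:hi]:
            if peaks[i].interval.overlaps(rec_iv):
                if side == "top":
                    peaks[i].n_top += 1
                else:
                    peaks[i].n_bottom += 1
    return peaks


def filter_intermediate(
    peaks: Sequence[Peak], fraction: float = 0.10
) -> tuple[list[Peak], list[Peak]]:
    """Remove the ``floor(fraction * n)`` peaks with the weakest strandedness.

    "Weakest" means smallest \\|s\\|, i.e. the decile closest to 0 rather than a
    fixed band; ties are broken by removing the lower read depth first, then
    by genomic order.  Every peak must have a defined score.  Returns
    (retained, removed); their union is the input.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    for peak in peaks:
        if peak.strandedness is None:
            raise ValueError(
                f"peak {peak.interval.chrom}:{peak.interval.start}-"
                f"{peak.interval.end} has no classified reads"
            )
    n_remove = int(fraction * len(peaks))
    ranked = sorted(
        range(len(peaks)),
        key=lambda i: (
            abs(peaks[i].strandedness),  # type: ignore[arg-type]
            peaks[i].depth,
            peaks[i].interval.chrom,
            peaks[i].interval.start,
            i,
        ),
    )
    removed_idx = set(ranked[:n_remove])
    retained = [p for i, p in enumerate(peaks) if i not in removed_idx]
    removed = [p for i, p in enumerate(peaks) if i in removed_idx]
    return retained, removed
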