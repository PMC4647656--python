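"""Genome model, interval arithmetic, and readers/writers for standard formats.

Coordinates are 0-based half-open everywhere in this package.  BED is the
interchange format for interval data; anything 1-based (GFF-style) must be
converted before it reaches these functions.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Sequence
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GenomicInterval",
    "FeatureSet",
    "AlignedPairRecord",
    "BedParseError",
    "SamParseError",
    "compose_flag",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "read_sam_records",
    "union_occupancy",
    "overlap_bp",
    "make_windows",
    "shuffle_intervals",
]


class BedParseError(ValueError):
    """Raised for a malformed BED line; message names the line number."""


class SamParseError(ValueError):
    """Raised for a SAM record missing mandatory fields."""


# SAM flag bits (SAM spec §1.4.2)
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST_IN_PAIR = 0x40
FLAG_SECOND_IN_PAIR = 0x80
FLAG_SECONDARY = 0x100
FLAG_QC_FAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


def compose_flag(
    *,
    paired: bool = False,
    proper_pair: bool = False,
    unmapped: bool = False,
    mate_unmapped: bool = False,
    reverse: bool = False,
    mate_reverse: bool = False,
    first_in_pair: bool = False,
    second_in_pair: bool = False,
    secondary: bool = False,
    duplicate: bool = False,
    supplementary: bool = False,
) -> int:
    """Compose a SAM bit flag from named bits.

    E.g. a properly paired second-in-pair read aligned to the forward strand
    with its mate on the reverse strand has flag
    ``compose_flag(paired=True, proper_pair=True, mate_reverse=True,
    second_in_pair=True) == 163``.
    """
    flag = 0
    if paired:
        flag |= FLAG_PAIRED
    if proper_pair:
        flag |= FLAG_PROPER_PAIR
    if unmapped:
        flag |= FLAG_UNMAPPED
    if mate_unmapped:
        flag |= FLAG_MATE_UNMAPPED
    if reverse:
        flag |= FLAG_REVERSE
    if mate_reverse:
        flag |= FLAG_MATE_REVERSE
    if first_in_pair:
        flag |= FLAG_FIRST_IN_PAIR
    if second_in_pair:
        flag |= FLAG_SECOND_IN_PAIR
    if secondary:
        flag |= FLAG_SECONDARY
    if duplicate:
        flag |= FLAG_DUPLICATE
    if supplementary:
        flag |= FLAG_SUPPLEMENTARY
    return flag


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based genomic span with optional strand and name.

    Invariant: ``0 <= start < end``; end must not exceed the chromosome
    length whenever a genome is in scope (validated at the operation level,
    since intervals may be created before a genome exists).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Genome:
    """Chromosome name/length registry with optional per-chromosome sequence."""

    def __init__(
        self,
        lengths: dict[str, int],
        sequences: dict[str, str] | None = None,
    ) -> None:
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        if sequences is not None:
            for chrom, seq in sequences.items():
                if chrom not in lengths:
                    raise ValueError(f"sequence for unknown chromosome {chrom}")
                if len(seq) != lengths[chrom]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared length "
                        f"{lengths[chrom]} for {chrom}"
                    )
        self.lengths: dict[str, int] = dict(lengths)
        self.sequences: dict[str, str] | None = (
            {c: s.upper() for c, s in sequences.items()} if sequences else None
        )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def size(self) -> int:
        return sum(self.lengths.values())

    def sequence(self, interval: GenomicInterval) -> str:
        if self.sequences is None or interval.chrom not in self.sequences:
            raise ValueError(f"no sequence available for {interval.chrom}")
        self.validate_interval(interval)
        return self.sequences[interval.chrom][interval.start : interval.end]

    def validate_interval(self, interval: GenomicInterval) -> None:
        if interval.chrom not in self.lengths:
            raise ValueError(f"unknown chromosome {interval.chrom}")
        if interval.end > self.lengths[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends past chromosome end {self.lengths[interval.chrom]}"
            )


@dataclasses.dataclass
class FeatureSet:
    """A labelled class of genomic features (e.g. promoter, CpG island)."""

    label: str
    intervals: list[GenomicInterval]

    @property
    def occupancy(self) -> int:
        """Basepairs covered by the union of the intervals."""
        return union_occupancy(self.intervals)


@dataclasses.dataclass(frozen=True)
class AlignedPairRecord:
    """The alignment facts needed to classify a read pair's RNA strand."""

    chrom: str | None
    pos: int  # 0-based leftmost
    flag: int
    read_length: int
    name: str = "*"
    rnext: str | None = None
    pnext: int = -1
    tlen: int = 0

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_second_in_pair(self) -> bool:
        return bool(self.flag & FLAG_SECOND_IN_PAIR)

    @property
    def end(self) -> int:
        return self.pos + self.read_length

    def interval(self) -> GenomicInterval:
        if self.chrom is None:
            raise ValueError("unmapped record has no interval")
        return GenomicInterval(self.chrom, self.pos, self.end)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into GenomicIntervals.

    The strand column (6) is honoured when present; the score column is
    ignored.  Malformed lines raise :class:`BedParseError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) >= 4 else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED3 (unnamed, unstranded) or BED6 records."""
    intervals = list(intervals)
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            if iv.name is None and iv.strand == "." and scores is None:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                score = 0.0 if scores is None else scores[i]
                name = iv.name if iv.name is not None else f"iv{i}"
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
                )


def read_fasta(path: str | Path, lengths_only: bool = False) -> Genome:
    """Load a FASTA file as a :class:`Genome` with sequences."""
    lengths: dict[str, int] = {}
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        lengths[record.id] = len(seq)
        if not lengths_only:
            sequences[record.id] = seq
    return Genome(lengths, sequences or None)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 60) -> None:
    if genome.sequences is None:
        raise ValueError("genome carries no sequence to write")
    records = [
        SeqRecord(Seq(genome.sequences[chrom]), id=chrom, description="")
        for chrom in genome.chromosomes
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph track as (chrom, start, end, value) tuples."""
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    return rows


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for chrom, start, end, value in rows:
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_sam_records(path: str | Path) -> Iterator[AlignedPairRecord]:
    """Stream AlignedPairRecords from a SAM text file.

    Unmapped records are yielded with ``chrom=None`` and flagged via
    ``is_unmapped``; downstream classification excludes them by flag value.
    """
    try:
        samfile = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise SamParseError(str(exc)) from exc
    with samfile:
        for aln in samfile:
            if aln.is_unmapped:
                yield AlignedPairRecord(
                    chrom=None,
                    pos=-1 if aln.reference_start is None else aln.reference_start,
                    flag=aln.flag,
                    read_length=aln.query_length or 0,
                    name=aln.query_name or "*",
                )
                continue
            length = aln.reference_length or aln.query_length or 0
            yield AlignedPairRecord(
                chrom=aln.reference_name,
                pos=aln.reference_start,
                flag=aln.flag,
                read_length=length,
                name=aln.query_name or "*",
                rnext=aln.next_reference_name,
                pnext=aln.next_reference_start
                if aln.next_reference_start is not None
                else -1,
                tlen=aln.template_length,
            )


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def _merged_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chrom: array of shape (k, 2)}`` with disjoint sorted spans.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for start, end in spans:
            if out and start <= out[-1][1]:
                out[-1][1] = max(out[-1][1], end)
            else:
                out.append([start, end])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return merged


def union_occupancy(
    intervals: Iterable[GenomicInterval], genome: Genome | None = None
) -> int:
    """Basepairs covered by the union of the intervals (overlaps once)."""
    intervals = list(intervals)
    if genome is not None:
        for iv in intervals:
            genome.validate_interval(iv)
    merged = _merged_by_chrom(intervals)
    return int(
        sum((spans[:, 1] - spans[:, 0]).sum() for spans in merged.values())
    )


def overlap_bp(
    set_a: Iterable[GenomicInterval],
    set_b: Iterable[GenomicInterval],
    strict_namespace: bool = True,
) -> int:
    """Basepairs in the intersection of the unions of two interval sets.

    Symmetric.  With ``strict_namespace`` (default) the two sets must share
    at least one chromosome name when both are non-empty and use disjoint
    chromosome sets — a guard against mixing 'chr1' with '1' conventions.
    """
    merged_a = _merged_by_chrom(set_a)
    merged_b = _merged_by_chrom(set_b)
    if strict_namespace and merged_a and merged_b:
        if not (set(merged_a) & set(merged_b)) and set(merged_a) != set(merged_b):
            raise ValueError(
                "interval sets share no chromosome names; "
                "mismatched chromosome namespaces?"
            )
    total = 0
    for chrom in set(merged_a) & set(merged_b):
        a, b = merged_a[chrom], merged_b[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
    return total


def make_windows(genome: Genome, width: int) -> list[GenomicInterval]:
    """Tile each chromosome with non-overlapping windows of ``width`` bp.

    The terminal partial window is retained with its true (smaller) extent so
    per-bp normalisation stays correct.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    windows: list[GenomicInterval] = []
    for chrom in genome.chromosomes:
        length = genome.lengths[chrom]
        for start in range(0, length, width):
            windows.append(GenomicInterval(chrom, start, min(start + width, length)))
    return windows


def shuffle_intervals(
    intervals: Sequence[GenomicInterval],
    genome: Genome,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mask: Sequence[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Relocate each interval to a uniformly random start on its chromosome.

    Lengths and chromosome assignments are preserved; overlaps among the
    shuffled intervals are allowed.  Deterministic for a fixed ``seed``.  An
    optional ``mask`` of excluded regions (e.g. assembly gaps) rejects
    placements overlapping it.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    mask_merged = _merged_by_chrom(mask) if mask else {}
    out: list[GenomicInterval] = []
    for iv in intervals:
        genome.validate_interval(iv)
        chrom_len = genome.lengths[iv.chrom]
        span = len(iv)
        if span > chrom_len:
            raise ValueError(
                f"interval of {span} bp does not fit on {iv.chrom} ({chrom_len} bp)"
            )
        max_start = chrom_len - span
        for _ in range(10_000):
            start = int(rng.integers(0, max_start + 1))
            if iv.chrom in mask_merged:
                spans = mask_merged[iv.chrom]
                hit = np.any((spans[:, 0] < start + span) & (spans[:, 1] > start))
                if hit:
                    continue
            break
        else:
            raise RuntimeError(
                f"could not place interval on {iv.chrom} outside the mask"
            )
        out.append(
            GenomicInterval(iv.chrom, start, start + span, iv.strand, iv.name)
        )
    return out
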