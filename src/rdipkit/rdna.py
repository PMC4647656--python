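"""Coverage analysis over the rDNA repeat unit (or any named reference span).

The repeat unit is treated as its own reference span with unit-relative
coordinates; duplicate reads are removed by exact sequence identity, per-bp
coverage is accumulated, the input library is subtracted (optionally after
reads-per-million scaling) and the result is averaged over fixed windows.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np

from rdipkit.genome_io import AlignedPairRecord

__all__ = [
    "WindowedTrack",
    "read_fastq_sequences",
    "dedup_reads",
    "coverage_track",
    "input_subtract",
    "window_mean",
]


@dataclasses.dataclass
class WindowedTrack:
    """Mean signal per non-overlapping fixed-width window over a span."""

    width: int
    span: int
    values: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def window_bounds(self, i: int) -> tuple[int, int]:
        return i * self.width, min((i + 1) * self.width, self.span)


def read_fastq_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from an uncompressed FASTQ file."""
    out: list[tuple[str, str]] = []
    with open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline().rstrip("\n")
            plus = handle.readline()
            qual = handle.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError("truncated or malformed FASTQ record")
            out.append((header[1:].split()[0], seq))
    return out


def dedup_reads(
    reads: Iterable[tuple[str, str]],
) -> tuple[list[tuple[str, str]], int]:
    """Keep the first occurrence of each exact sequence; order preserved.

    Matching is exact and case-sensitive.  Returns (unique reads, number
    removed).  Idempotent.
    """
    seen: set[str] = set()
    unique: list[tuple[str, str]] = []
    removed = 0
    for name, seq in reads:
        if seq in seen:
            removed += 1
        else:
            seen.add(seq)
            unique.append((name, seq))
    return unique, removed


def coverage_track(
    records: Iterable[AlignedPairRecord | tuple[int, int]],
    span: int,
) -> np.ndarray:
    """Per-bp read depth over [0, span) from aligned records.

    Accepts AlignedPairRecords or raw (start, end) tuples on the span.
    A record extending outside the span is an error.
    """
    edges = np.zeros(span + 1, dtype=np.int64)
    for record in records:
        if isinstance(record, AlignedPairRecord):
            start, end = record.pos, record.end
        else:
            start, end = record
        if start < 0 or end > span:
            raise ValueError(f"record [{start}, {end}) outside span [0, {span})")
        edges[start] += 1
        edges[end] -= 1
    return np.cumsum(edges[:-1])


def input_subtract(
    rdip_track: np.ndarray,
    input_track: np.ndarray,
    scale: str = "per-million",
    rdip_library_size: int | None = None,
    input_library_size: int | None = None,
) -> np.ndarray:
    """Subtract the input track from the RDIP track, elementwise.

    ``scale='per-million'`` (default) first scales each track to reads per
    million using the given library sizes (falling back to each track's own
    sum); ``scale='raw'`` subtracts unscaled depths.  Negatives retained.
    """
    rdip = np.asarray(rdip_track, dtype=float)
    inp = np.asarray(input_track, dtype=float)
    if rdip.shape != inp.shape:
        raise ValueError(
            f"span mismatch: {rdip.shape} vs {inp.shape}"
        )
    if scale == "raw":
        return rdip - inp
    if scale != "per-million":
        raise ValueError(f"scale must be 'raw' or 'per-million', got {scale!r}")
    rdip_n = rdip_library_size if rdip_library_size else rdip.sum()
    input_n = input_library_size if input_library_size else inp.sum()
    if rdip_n <= 0 or input_n <= 0:
        raise ValueError("library sizes must be positive for per-million scaling")
    return rdip * 1e6 / rdip_n - inp * 1e6 / input_n


def window_mean(track: Sequence[float] | np.ndarray, width: int = 50) -> WindowedTrack:
    """Mean per-bp value over non-overlapping windows of ``width``.

    The terminal partial window is averaged over its true extent.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    values = np.asarray(track, dtype=float)
    span = len(values)
    n_windows = -(-span // width)
    means = np.empty(n_windows)
    for i in range(n_windows):
        means[i] = values[i * width : (i + 1) * width].mean()
    return WindowedTrack(width=width, span=span, values=means)
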