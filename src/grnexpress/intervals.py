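"""Strand-aware genomic primitives.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention.
GTF input (1-based, inclusive) is converted on read by :mod:`grnexpress.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): start must be < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp on the same chromosome."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class ChipPeak:
    """A TF ChIP-seq peak with its (non-negative) signal value."""

    tf: str
    interval: GenomicInterval
    signal: float = 1.0

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"peak signal must be >= 0, got {self.signal}")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript span with its sorted, non-overlapping exons."""

    tx_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValueError(f"transcript {self.tx_id} has no exons")
        prev_end = None
        for ex in self.exons:
            if not self.span.contains(ex):
                raise ValueError(f"exon {ex} outside transcript span {self.span}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"exons of {self.tx_id} not sorted/non-overlapping")
            prev_end = ex.end

    def __len__(self) -> int:
        return len(self.span)


@dataclass(frozen=True)
class GeneModel:
    """A gene: >= 1 transcript, all on one chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if len(self.transcripts) < 1:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            if tx.span.chrom != self.chrom:
                raise ValueError(f"transcript {tx.tx_id} on wrong chromosome")

    @property
    def span(self) -> GenomicInterval:
        """Union span over all transcripts (the gene body)."""
        start = min(tx.span.start for tx in self.transcripts)
        end = max(tx.span.end for tx in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class RegulatoryWindow:
    """Per-gene regulatory geometry: candidate/CTCF-bounded windows, promoter, introns."""

    gene_id: str
    tss: int
    candidate: GenomicInterval
    bounded: GenomicInterval
    promoter: GenomicInterval | None
    introns: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.candidate.contains(self.bounded):
            raise ValueError("bounded window must lie within the candidate window")
        if not self.candidate.contains_point(self.tss) and self.tss != self.candidate.end:
            raise ValueError("TSS must lie within the candidate window")
        if self.promoter is not None and len(self.promoter) > 5000:
            raise ValueError("promoter longer than 5000 bp")


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent-overlapping intervals (same chrom) into a sorted union."""
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError("cannot merge intervals across chromosomes")
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def subtract_intervals(
    span: GenomicInterval, holes: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Return ``span`` minus the union of ``holes`` as a sorted interval list."""
    pieces: list[GenomicInterval] = []
    cursor = span.start
    for hole in merge_intervals([h for h in holes if h.overlaps(span)]):
        left = max(hole.start, span.start)
        if left > cursor:
            pieces.append(GenomicInterval(span.chrom, cursor, left, span.strand))
        cursor = max(cursor, min(hole.end, span.end))
    if cursor < span.end:
        pieces.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return pieces
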