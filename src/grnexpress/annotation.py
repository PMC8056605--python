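"""Per-gene regulatory geometry.

Builds, for each protein-coding gene, the cis-regulatory window used to collect
TF binding evidence: a 50 kb candidate window around the longest transcript,
truncated at the most distant CTCF insulator peaks, plus the 5 kb promoter and
the intronic interval set.  Peaks falling in the bounded window are partitioned
into promoter / intronic / distal classes.
"""

from __future__ import annotations



from .intervals import (
    ChipPeak,
    GeneModel,
    GenomicInterval,
    RegulatoryWindow,
    TranscriptModel,
    merge_intervals,
    subtract_intervals,
)

DEFAULT_FLANK = 50_000
DEFAULT_PROMOTER = 5_000

PEAK_CATEGORIES = ("promoter", "intronic", "distal")


def longest_transcript(gene: GeneModel) -> TranscriptModel:
    """The transcript with maximal span length; ties broken by smallest tx_id."""
    if not gene.transcripts:
        raise ValueError("no transcripts")
    return sorted(gene.transcripts, key=lambda tx: (-len(tx.span), tx.tx_id))[0]


def gene_tss(gene: GeneModel) -> int:
    """TSS of the longest transcript: span start on '+', span end on '-'."""
    tx = longest_transcript(gene)
    return tx.span.start if gene.strand == "+" else tx.span.end


def candidate_window(gene: GeneModel, flank: int = DEFAULT_FLANK) -> GenomicInterval:
    """Strand-aware window from TSS - flank to the 3' end of the gene body + flank.

    On '+' this is ``[TSS - flank, body_end + flank)``; mirrored on '-'.
    Clipped at position 0.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    tss = gene_tss(gene)
    body = gene.span
    if gene.strand == "+":
        start, end = tss - flank, body.end + flank
    else:
        start, end = body.start - flank, tss + flank
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def ctcf_bounded_window(
    candidate: GenomicInterval,
    gene_body: GenomicInterval,
    ctcf_peaks: list[GenomicInterval],
) -> GenomicInterval:
    """Truncate the candidate window at the most distant CTCF peak on each side.

    A CTCF peak is eligible upstream (downstream) of the gene body when its
    midpoint falls strictly between the candidate edge and the body; "most
    distant" means furthest from the body, i.e. closest to the candidate edge.
    The boundary is the peak midpoint.  Peaks inside the gene body are ignored;
    with no eligible peak on a side, that side keeps the candidate edge.  The
    result always contains the gene body.
    """
    left_mids = [
        p.midpoint
        for p in ctcf_peaks
        if p.chrom == candidate.chrom and candidate.start <= p.midpoint < gene_body.start
    ]
    right_mids = [
        p.midpoint
        for p in ctcf_peaks
        if p.chrom == candidate.chrom and gene_body.end <= p.midpoint < candidate.end
    ]
    start = min(left_mids) if left_mids else candidate.start
    end = max(right_mids) + 1 if right_mids else candidate.end
    # never shrink inside the gene body
    start = min(start, gene_body.start)
    end = max(end, gene_body.end)
    return GenomicInterval(candidate.chrom, start, end, candidate.strand)


def promoter_region(gene: GeneModel, length: int = DEFAULT_PROMOTER) -> GenomicInterval | None:
    """The ``length`` bp immediately upstream of the TSS (strand-aware, clipped at 0).

    Returns None in the degenerate case of a '+'-strand TSS at position 0.
    """
    tss = gene_tss(gene)
    if gene.strand == "+":
        start, end = max(0, tss - length), tss
    else:
        start, end = tss, tss + length
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def intronic_regions(gene: GeneModel) -> list[GenomicInterval]:
    """Transcript spans minus the union of ALL the gene's exons, merged and sorted.

    The exon set pooled over every transcript is subtracted from each
    transcript span, so a base is intronic only if no transcript uses it as
    exon — the result never overlaps any exon of the gene.
    """
    all_exons = [ex for tx in gene.transcripts for ex in tx.exons]
    pieces: list[GenomicInterval] = []
    for tx in gene.transcripts:
        pieces.extend(subtract_intervals(tx.span, all_exons))
    return merge_intervals(pieces)


def build_regulatory_window(
    gene: GeneModel,
    ctcf_peaks: list[GenomicInterval] | None = None,
    flank: int = DEFAULT_FLANK,
    promoter_length: int = DEFAULT_PROMOTER,
) -> RegulatoryWindow:
    """Assemble the full regulatory geometry for one gene."""
    candidate = candidate_window(gene, flank=flank)
    bounded = ctcf_bounded_window(candidate, gene.span, ctcf_peaks or [])
    return RegulatoryWindow(
        gene_id=gene.gene_id,
        tss=gene_tss(gene),
        candidate=candidate,
        bounded=bounded,
        promoter=promoter_region(gene, length=promoter_length),
        introns=tuple(intronic_regions(gene)),
    )


def partition_peaks(
    peaks: list[ChipPeak], window: RegulatoryWindow
) -> dict[str, list[ChipPeak]]:
    """Assign each in-window peak to exactly one of promoter / intronic / distal.

    Overlap rule is >= 1 bp intersection with the CTCF-bounded window; category
    precedence for multi-overlap peaks is promoter > intronic > distal.  Peaks
    outside the bounded window are excluded entirely.
    """
    out: dict[str, list[ChipPeak]] = {cat: [] for cat in PEAK_CATEGORIES}
    for peak in peaks:
        iv = peak.interval
        if not iv.overlaps(window.bounded):
            continue
        if window.promoter is not None and iv.overlaps(window.promoter):
            out["promoter"].append(peak)
        elif any(iv.overlaps(intron) for intron in window.introns):
            out["intronic"].append(peak)
        else:
            out["distal"].append(peak)
    return out
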