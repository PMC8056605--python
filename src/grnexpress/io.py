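"""Readers/writers for the flat-file formats the pipeline exchanges.

GTF is read through pyranges (which converts 1-based inclusive GTF coordinates
to the internal 0-based half-open convention); BED and all labeled-matrix /
edge-list hand-offs are plain TSV via pandas; motifs use the MEME minimal
format; sequences use FASTA via pyfaidx/Biopython.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr

from .intervals import ChipPeak, GeneModel, GenomicInterval, RegulatoryWindow, TranscriptModel

BED_PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "signal"]


# ---------------------------------------------------------------------------
# gene annotations (GTF, Ensembl dialect)
# ---------------------------------------------------------------------------

def read_gtf_genes(path: str | Path, protein_coding_only: bool = True) -> list[GeneModel]:
    """Parse an Ensembl-style GTF into GeneModels (0-based half-open internally).

    Requires ``gene_id``/``transcript_id`` attributes on transcript and exon
    features.  When ``gene_biotype`` is present and ``protein_coding_only`` is
    set, non-protein-coding genes are dropped.
    """
    df = pr.read_gtf(str(path)).df
    has_biotype = "gene_biotype" in df.columns
    genes: list[GeneModel] = []
    tx_feats = df[df.Feature == "transcript"]
    exon_feats = df[df.Feature == "exon"]
    for gene_id, tx_group in tx_feats.groupby("gene_id", sort=True):
        biotype = (
            str(tx_group.gene_biotype.iloc[0]) if has_biotype and pd.notna(tx_group.gene_biotype.iloc[0])
            else "protein_coding"
        )
        if protein_coding_only and has_biotype and biotype != "protein_coding":
            continue
        chrom = str(tx_group.Chromosome.iloc[0])
        strand = str(tx_group.Strand.iloc[0])
        transcripts = []
        gene_exons = exon_feats[exon_feats.gene_id == gene_id]
        for _, tx_row in tx_group.iterrows():
            tx_id = str(tx_row.transcript_id)
            span = GenomicInterval(chrom, int(tx_row.Start), int(tx_row.End), strand)
            ex_rows = gene_exons[gene_exons.transcript_id == tx_id].sort_values("Start")
            exons = tuple(
                GenomicInterval(chrom, int(r.Start), int(r.End), strand)
                for r in ex_rows.itertuples()
            ) or (span,)
            transcripts.append(TranscriptModel(tx_id=tx_id, span=span, exons=exons))
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=chrom,
                strand=strand,
                transcripts=tuple(transcripts),
                biotype=biotype,
            )
        )
    return genes


def write_gtf_genes(genes: list[GeneModel], path: str | Path, source: str = "grnexpress") -> None:
    """Write GeneModels as Ensembl-style GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = (
                    f'gene_id "{gene.gene_id}"; transcript_id "{tx.tx_id}"; '
                    f'gene_biotype "{gene.biotype}";'
                )
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{tx.span.start + 1}\t{tx.span.end}"
                    f"\t.\t{gene.strand}\t.\t{tattrs}\n"
                )
                for ex in tx.exons:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# peaks (BED6+signal)
# ---------------------------------------------------------------------------

def read_bed_peaks(path: str | Path) -> list[ChipPeak]:
    """BED6+ peaks: column 4 = TF name, column 7 (if present) = signal."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    peaks = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if ncol > 5 and str(row[5]) in "+-" else "."
        signal = float(row[6]) if ncol > 6 else 1.0
        peaks.append(
            ChipPeak(
                tf=str(row[3]) if ncol > 3 else "peak",
                interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand),
                signal=signal,
            )
        )
    return peaks


def write_bed_peaks(peaks: list[ChipPeak], path: str | Path) -> None:
    rows = [
        (p.interval.chrom, p.interval.start, p.interval.end, p.tf, 0, p.interval.strand, p.signal)
        for p in peaks
    ]
    pd.DataFrame(rows, columns=BED_PEAK_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def write_windows_bed(windows: list[RegulatoryWindow], path: str | Path) -> None:
    """CTCF-bounded regulatory windows as BED6 (name = gene id)."""
    rows = [
        (w.bounded.chrom, w.bounded.start, w.bounded.end, w.gene_id, 0, w.bounded.strand)
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# labeled matrices and edge lists (TSV)
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Labeled numeric matrix: header row = column labels, first column = row labels."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Long-format (tf, gene, weight) edge list."""
    return pd.read_csv(path, sep="\t")


def write_edge_list(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a TF x gene matrix as a long-format (tf, gene, weight) TSV."""
    long = matrix.stack().rename_axis(["tf", "gene"]).reset_index(name="weight")
    long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# motifs (MEME minimal format)
# ---------------------------------------------------------------------------

_MEME_HEADER = "MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n"


def write_meme_motifs(pwms: dict[str, np.ndarray], path: str | Path,
                      background: np.ndarray | None = None) -> None:
    """Write letter-probability matrices as a MEME minimal motif file."""
    bg = background if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write(_MEME_HEADER)
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for name, probs in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(probs)} "
                f"nsites= 20 E= 0\n"
            )
            for row in probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme_motifs(path: str | Path) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read MOTIF blocks (letter-probability matrices) and background frequencies."""
    text = Path(path).read_text()
    bg = np.full(4, 0.25)
    m = re.search(
        r"Background letter frequencies.*?\nA\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
    )
    if m:
        bg = np.array([float(g) for g in m.groups()])
    pwms: dict[str, np.ndarray] = {}
    for block in re.split(r"\nMOTIF\s+", "\n" + text)[1:]:
        lines = block.strip().splitlines()
        name = lines[0].split()[0]
        rows = []
        in_matrix = False
        for line in lines[1:]:
            if line.startswith("letter-probability"):
                in_matrix = True
                continue
            if in_matrix:
                parts = line.split()
                if len(parts) == 4:
                    rows.append([float(v) for v in parts])
                else:
                    break
        pwms[name] = np.asarray(rows, dtype=float)
    return pwms, bg


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
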