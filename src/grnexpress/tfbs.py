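"""TF -> gene binding evidence, three ways.

* positional: raw ChIP-seq peak overlap with CTCF-bounded regulatory windows;
* motif scanning: PWM log-odds hits under peaks with exact p-values from a
  dynamic-programming null over the discretized score distribution (the
  FIMO-style definition of a significant site);
* affinity: per-gene scores that sum per-site binding strengths with an
  exponential decay in distance from the TSS (TEPIC-style aggregation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .intervals import ChipPeak, GenomicInterval, RegulatoryWindow

PSEUDOCOUNT = 1e-3
SCORE_RESOLUTION = 1e-3  # bits per DP bin
DEFAULT_DECAY_BP = 5_000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: L x 4 column order A, C, G, T."""

    tf: str
    probs: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = np.full(4, 0.25) if self.background is None else np.asarray(self.background, float)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must be L x 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2((p + pseudocount, renormalized) / background), L x 4 in bits."""
        p = self.probs + PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf, self.probs[::-1, ::-1], self.background[::-1])

    def site_strength(self, kmer: str) -> float:
        """Posterior probability p_motif / (p_motif + p_background) of a bound site."""
        idx = [_BASE_INDEX[b] for b in kmer]
        p = self.probs + PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        pm = float(np.prod(p[np.arange(len(self)), idx]))
        pb = float(np.prod(self.background[idx]))
        return pm / (pm + pb)


@dataclass(frozen=True)
class MotifHit:
    tf: str
    gene_id: str | None
    interval: GenomicInterval
    log_odds: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value must be in (0, 1]")


@dataclass(frozen=True)
class AffinityScore:
    tf: str
    gene_id: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("affinity score must be >= 0")


# ---------------------------------------------------------------------------
# positional TFBS
# ---------------------------------------------------------------------------

def positional_tfbs(
    peaks: list[ChipPeak], windows: list[RegulatoryWindow]
) -> list[tuple[str, str, ChipPeak]]:
    """One (tf, gene_id, peak) record per peak x bounded-window overlap.

    A peak serving multiple genes yields one record per gene; the unique
    (tf, gene) pair set is ``{(tf, g) for tf, g, _ in records}``.
    """
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.bounded.chrom, IntervalTree()).addi(
            w.bounded.start, w.bounded.end, w.gene_id
        )
    records = []
    for peak in peaks:
        tree = trees.get(peak.interval.chrom)
        if tree is None:
            continue
        for node in sorted(tree.overlap(peak.interval.start, peak.interval.end),
                           key=lambda n: n.data):
            records.append((peak.tf, node.data, peak))
    return records


# ---------------------------------------------------------------------------
# PWM scanning with exact DP null
# ---------------------------------------------------------------------------

def _int_scores(pwm: PWM, resolution: float) -> np.ndarray:
    """Per-position per-base log-odds, rounded onto an integer grid."""
    return np.round(pwm.log_odds() / resolution).astype(np.int64)

def _null_survival(iscores: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact distribution of the integer score of a random background k-mer.

    Returns (sf, offset): ``sf[s - offset]`` = P(score >= s) for integer
    scores ``s`` in ``[offset, offset + len(sf))``; below/above that range the
    survival probability is 1/0 respectively.
    """
    lo = int(iscores.min(axis=1).sum())
    pmf = np.array([1.0])  # pmf[k] = P(partial sum == running_min + k)
    for row in iscores:
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros(len(pmf) + rmax - rmin)
        for b in range(4):
            if background[b] <= 0:
                continue
            off = int(row[b]) - rmin
            new[off : off + len(pmf)] += background[b] * pmf
        pmf = new
    sf = np.cumsum(pmf[::-1])[::-1]
    return sf, lo


def _survival(sf: np.ndarray, offset: int, score: int) -> float:
    idx = score - offset
    if idx <= 0:
        return 1.0
    if idx >= len(sf):
        return 0.0
    return float(min(sf[idx], 1.0))


def _scan_one_strand(
    sequence: str,
    pwm: PWM,
    strand: str,
    resolution: float,
) -> list[tuple[int, float, float]]:
    """(start, score_bits, pvalue) for every scannable window on one strand."""
    scan_pwm_obj = pwm if strand == "+" else pwm.reverse_complement()
    iscores = _int_scores(scan_pwm_obj, resolution)
    sf, lo = _null_survival(iscores, scan_pwm_obj.background)
    L = len(scan_pwm_obj)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in sequence], dtype=np.int64)
    n = len(sequence) - L + 1
    out = []
    for start in range(max(n, 0)):
        window = idx[start : start + L]
        if (window < 0).any():  # N anywhere in the window: skip
            continue
        s = int(iscores[np.arange(L), window].sum())
        out.append((start, s * resolution, _survival(sf, lo, s)))
    return out


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 0.01,
    chrom: str = "seq",
    offset: int = 0,
    gene_id: str | None = None,
    resolution: float = SCORE_RESOLUTION,
) -> list[MotifHit]:
    """Significant PWM hits on both strands of ``sequence``.

    The per-position p-value is the exact probability, under the background
    model, that a random k-mer scores at least as high — computed by dynamic
    programming over the score distribution discretized at ``resolution`` bits.
    Hits with p <= ``p_threshold`` are returned; windows containing N are
    skipped; forward/reverse hits at the same position are deduplicated to the
    best-scoring strand (ties -> forward).
    """
    sequence = sequence.upper()
    if len(sequence) < len(pwm):
        return []
    best: dict[int, tuple[float, float, str]] = {}
    for strand in ("+", "-"):
        for start, score, pval in _scan_one_strand(sequence, pwm, strand, resolution):
            if pval > p_threshold:
                continue
            cur = best.get(start)
            if cur is None or score > cur[0]:
                best[start] = (score, pval, strand)
    hits = []
    for start in sorted(best):
        score, pval, strand = best[start]
        hits.append(
            MotifHit(
                tf=pwm.tf,
                gene_id=gene_id,
                interval=GenomicInterval(chrom, offset + start, offset + start + len(pwm), strand),
                log_odds=score,
                pvalue=max(pval, np.nextafter(0, 1)),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# affinity scores (exponential distance decay from the TSS)
# ---------------------------------------------------------------------------

def affinity_score(
    sites: list[tuple[GenomicInterval, float]],
    tss: int,
    d0: float = DEFAULT_DECAY_BP,
    window: RegulatoryWindow | None = None,
    tf: str = "",
    gene_id: str = "",
) -> AffinityScore:
    """Sum of per-site strengths decayed exponentially with distance to the TSS.

    value = sum_sites a_site * exp(-|center(site) - tss| / d0).  ``sites`` are
    (interval, strength) pairs with strength in (0, 1] (PWM posterior, or
    normalized peak signal when no PWM is available).  When ``window`` is
    given, only sites overlapping its bounded interval contribute.
    """
    total = 0.0
    for interval, strength in sites:
        if window is not None and not interval.overlaps(window.bounded):
            continue
        total += strength * math.exp(-abs(interval.midpoint - tss) / d0)
    return AffinityScore(tf=tf, gene_id=gene_id, value=total)


def peak_sites(peaks: list[ChipPeak]) -> list[tuple[GenomicInterval, float]]:
    """Turn peaks into affinity sites with signal normalized to (0, 1] by the max."""
    if not peaks:
        return []
    top = max(p.signal for p in peaks)
    scale = top if top > 0 else 1.0
    return [(p.interval, p.signal / scale if top > 0 else 1.0) for p in peaks]
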