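"""Hi-C promoter-contact weighting of motif edges.

For each TF-gene pair with N >= 1 ChIP-seq peaks in the gene's regulatory
region, the mean of the KR-normalized contact counts its peaks make with the
gene promoter is scaled into [0, 0.99] (max-anchored, so "no contacts" maps
exactly to 0) and the edge weight is C = 1 + scaled mean, i.e. C in [1, 1.99].

Two schemes turn these into weighted motif adjacencies: DP multiplies every
motif edge by C; UP additionally boosts promoter-based pairs whose C is
exactly 1 (no contacts) to the maximum weight 2.0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ChipPeak, GenomicInterval

MAX_SCALED = 0.99
UP_BOOST = 2.0

SCHEMES = ("DP", "UP")


@dataclass(frozen=True)
class ContactRecord:
    """KR-normalized contact count between one peak interval and one gene promoter."""

    peak: GenomicInterval
    gene_id: str
    contacts: float

    def __post_init__(self) -> None:
        if self.contacts < 0:
            raise ValueError("contacts must be >= 0")


def mean_contacts(
    tf: str,
    gene: str,
    records: list[ContactRecord],
    peaks_in_window: list[ChipPeak],
) -> float:
    """Mean contact count over the TF's peaks in the gene's regulatory region.

    A peak with no recorded contact contributes 0.  Querying a pair with no
    peaks in the region (absent from the motif network) is an error.
    """
    peaks = [p for p in peaks_in_window if p.tf == tf]
    if not peaks:
        raise ValueError(f"pair ({tf}, {gene}) has no peaks in the regulatory region")
    by_gene = [r for r in records if r.gene_id == gene]
    total = 0.0
    for peak in peaks:
        total += sum(r.contacts for r in by_gene if r.peak.overlaps(peak.interval))
    return total / len(peaks)


def scale_contacts(means: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Scale mean contacts into [0, 0.99]: x -> 0.99 * x / max(x).

    Anchored at the maximum (not min-max) so that zero contacts map exactly to
    0 — and hence, via Eq. C = 1 + scaled, to an edge weight of exactly 1 —
    even when the smallest observed mean is positive.  An all-zero input
    returns all zeros with a warning.
    """
    values = np.asarray(means, dtype=float)
    if values.size == 0:
        raise ValueError("no mean contacts to scale")
    if (values < 0).any():
        raise ValueError("mean contacts must be >= 0")
    top = values.max()
    if top == 0:
        warnings.warn("all mean contacts are zero; no Hi-C signal anywhere", RuntimeWarning)
        return means * 0.0
    return means * (MAX_SCALED / top)


def hic_weight(scaled: float) -> float:
    """Edge weight C = 1 + scaled mean contacts, for scaled in [0, 0.99]."""
    if not 0.0 <= scaled <= MAX_SCALED:
        raise ValueError(f"scaled contact value {scaled} outside [0, {MAX_SCALED}]")
    return 1.0 + scaled


def hic_weight_matrix(mean_matrix: pd.DataFrame, motif: pd.DataFrame) -> pd.DataFrame:
    """Per-pair C weights for every motif edge, from a TF x gene mean-contact matrix.

    Scaling is global across all TF-gene pairs present in the motif network
    (one scaler per cell line).  Pairs absent from the motif network keep
    weight 1 (they carry no edge to weight).
    """
    mean_matrix = mean_matrix.reindex(index=motif.index, columns=motif.columns).fillna(0.0)
    mask = motif.to_numpy() != 0
    means = mean_matrix.to_numpy().copy()
    present = means[mask]
    scaled = np.zeros_like(means)
    if present.size and present.max() > 0:
        scaled[mask] = present * (MAX_SCALED / present.max())
    elif present.size:
        warnings.warn("all mean contacts are zero; no Hi-C signal anywhere", RuntimeWarning)
    return pd.DataFrame(1.0 + scaled, index=motif.index, columns=motif.columns)


def apply_scheme(
    motif: pd.DataFrame,
    weights: pd.DataFrame,
    promoter_pairs: set[tuple[str, str]],
    scheme: str,
) -> pd.DataFrame:
    """Apply the DP or UP weighting scheme to a binary motif adjacency.

    DP: entry -> motif * C everywhere.  UP: DP, then promoter-based pairs
    whose C is exactly 1.0 (no Hi-C contacts) are set to 2.0 * motif.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    vals = motif.to_numpy()
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("Hi-C schemes apply to binary motif adjacencies")
    if not motif.index.equals(weights.index) or not motif.columns.equals(weights.columns):
        raise ValueError("weight matrix labels do not match the motif adjacency")
    out = motif * weights
    if scheme == "UP":
        for tf, gene in promoter_pairs:
            if tf in out.index and gene in out.columns and weights.at[tf, gene] == 1.0:
                out.at[tf, gene] = UP_BOOST * motif.at[tf, gene]
    return out
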