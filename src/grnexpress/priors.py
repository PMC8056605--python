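"""The three PANDA input networks.

Motif adjacency (TF x gene; binary peak/motif evidence or affinity-weighted),
symmetric TF x TF protein-protein interaction network, and gene x gene
Pearson co-expression.  All are labeled pandas DataFrames.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _check_labels(labels: Sequence[str], kind: str) -> list[str]:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate {kind} labels")
    return labels


def motif_adjacency(
    pairs: Iterable[tuple],
    tfs: Sequence[str],
    genes: Sequence[str],
    mode: str = "binary",
) -> pd.DataFrame:
    """TF x gene adjacency from (tf, gene) pairs or (tf, gene, value) triples.

    ``binary`` sets 1 per unique pair (duplicates are idempotent); ``weighted``
    places the supplied affinity values and rejects conflicting duplicates.
    Absent pairs are 0.  Unknown labels raise, naming the offender.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown mode {mode!r}")
    tfs = _check_labels(tfs, "TF")
    genes = _check_labels(genes, "gene")
    adj = pd.DataFrame(0.0, index=tfs, columns=genes)
    tf_set, gene_set = set(tfs), set(genes)
    seen: dict[tuple[str, str], float] = {}
    for rec in pairs:
        tf, gene = rec[0], rec[1]
        if tf not in tf_set:
            raise KeyError(f"unknown TF label {tf!r}")
        if gene not in gene_set:
            raise KeyError(f"unknown gene label {gene!r}")
        if mode == "binary":
            adj.at[tf, gene] = 1.0
        else:
            value = float(rec[2])
            if (tf, gene) in seen and not np.isclose(seen[(tf, gene)], value):
                raise ValueError(f"conflicting duplicate weighted edge ({tf}, {gene})")
            seen[(tf, gene)] = value
            adj.at[tf, gene] = value
    return adj


def ppi_network(edges: Iterable[tuple[str, str]], tfs: Sequence[str]) -> pd.DataFrame:
    """Symmetric 0/1 protein-protein interaction matrix over the modelled TFs.

    Self-interactions fixed at 1 on the diagonal (PANDA convention); edges
    touching unmodelled TFs are dropped with a log message.
    """
    tfs = _check_labels(tfs, "TF")
    net = pd.DataFrame(np.eye(len(tfs)), index=tfs, columns=tfs)
    tf_set = set(tfs)
    dropped = 0
    for a, b in edges:
        if a not in tf_set or b not in tf_set:
            dropped += 1
            continue
        net.at[a, b] = 1.0
        net.at[b, a] = 1.0
    if dropped:
        logger.info("ppi_network: dropped %d edges touching unmodelled TFs", dropped)
    return net


def coexpression_network(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlation across samples (rows = samples).

    Zero-variance genes get 0 off-diagonal and 1 on the diagonal.  Requires
    at least 3 samples.
    """
    if expr.shape[0] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[0]}")
    flat = expr.var(axis=0, ddof=0) == 0
    if flat.any():
        warnings.warn(
            f"coexpression_network: {int(flat.sum())} zero-variance genes "
            "set to 0 correlation",
            UserWarning,
            stacklevel=2,
        )
    corr = expr.corr(method="pearson")
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    # exact symmetry to machine precision
    corr.values[:] = (corr.values + corr.values.T) / 2.0
    return corr


def common_gene_restriction(
    motif: pd.DataFrame, expression_genes: Sequence[str]
) -> pd.DataFrame:
    """Drop motif-network genes absent from the expression data (logged)."""
    keep = [g for g in motif.columns if g in set(expression_genes)]
    missing = motif.shape[1] - len(keep)
    if missing:
        logger.info("dropping %d motif genes absent from expression", missing)
    return motif[keep]
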