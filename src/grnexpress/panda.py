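"""PANDA message passing.

Fuses a motif prior (TF x gene), TF cooperativity (PPI) and gene co-regulation
(co-expression) into refined regulatory edge weights by iterating continuous
Tanimoto-similarity updates until the mean absolute change of the regulatory
network (Hamming distance) falls below a threshold.

The three input networks are z-score normalized; each iteration computes a
responsibility term R = T(P, W) (what the cooperativity network implies about
regulation) and an availability term A = T(W, C) (what co-regulation implies),
moves W a fraction ``update`` toward (R + A) / 2, and then moves P and C the
same fraction toward the cooperativity/co-regulation implied by the new W,
with a diagonal damping term that grows with iteration to keep the
self-similarity diagonal from dominating.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DENOM_FLOOR = 1e-10


def normalize_network(M: np.ndarray) -> np.ndarray:
    """Z-score normalization: entry -> (z_within_row + z_within_column) / sqrt(2).

    Constant rows/columns (zero standard deviation) fall back to the z-score
    within the whole matrix; an all-constant matrix maps to all zeros.
    """
    M = np.asarray(M, dtype=float)
    mu_r, sd_r = M.mean(axis=1, keepdims=True), M.std(axis=1, ddof=1, keepdims=True)
    mu_c, sd_c = M.mean(axis=0, keepdims=True), M.std(axis=0, ddof=1, keepdims=True)
    mu_a, sd_a = M.mean(), M.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_row = (M - mu_r) / sd_r
        z_col = (M - mu_c) / sd_c
        z_all = (M - mu_a) / sd_a if sd_a > 0 else np.zeros_like(M)
    z_row = np.where(np.broadcast_to(sd_r > 0, M.shape), z_row, z_all)
    z_col = np.where(np.broadcast_to(sd_c > 0, M.shape), z_col, z_all)
    return (z_row + z_col) / np.sqrt(2.0)


def tanimoto(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Continuous Tanimoto similarity of the rows of X with the columns of Y.

    T_ij = (x_i . y_j) / sqrt(||x_i||^2 + ||y_j||^2 - |x_i . y_j|), with the
    denominator floored at 1e-10.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    num = X @ Y
    nx = (X**2).sum(axis=1)[:, None]
    ny = (Y**2).sum(axis=0)[None, :]
    den = np.sqrt(np.maximum(nx + ny - np.abs(num), 0.0))
    return num / np.maximum(den, DENOM_FLOOR)


def _update_diagonal(M: np.ndarray, n: int, update: float, step: int) -> None:
    """Replace the diagonal by off-diagonal row std * n * exp(2*update*step).

    The growing factor damps the self-similarity diagonal of the P/C updates
    so it does not swamp the off-diagonal structure as iterations proceed.
    """
    mask = ~np.eye(M.shape[0], dtype=bool)
    offdiag = np.where(mask, M, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(offdiag, axis=1, ddof=1)
    sd = np.nan_to_num(sd)
    np.fill_diagonal(M, sd * n * np.exp(2.0 * update * step))


class PandaGRN(BaseEstimator):
    """Message-passing GRN estimator.

    Parameters
    ----------
    update : float in (0, 1], default 0.1
        Learning rate of the message-passing updates.
    tol : float, default 0.001
        Convergence threshold on the Hamming distance
        mean(|W_t - W_{t-1}|).
    max_iter : int, default 200
        Iteration cap; non-convergence warns and returns the last state.

    Attributes (after fit)
    ----------------------
    W_ : DataFrame, TF x gene refined edge weights.
    n_iter_ : iterations performed.
    hamming_ : final Hamming distance.
    converged_ : whether tol was reached before max_iter.
    """

    def __init__(self, update: float = 0.1, tol: float = 0.001, max_iter: int = 200):
        self.update = update
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, motif: pd.DataFrame, ppi: pd.DataFrame, coexpr: pd.DataFrame) -> "PandaGRN":
        if not 0 <= self.update <= 1:
            raise ValueError("update must be in [0, 1]")
        tfs = list(motif.index)
        genes = list(motif.columns)
        if list(ppi.index) != tfs or list(ppi.columns) != tfs:
            raise ValueError("PPI labels do not match the motif TF labels")
        if list(coexpr.index) != genes or list(coexpr.columns) != genes:
            raise ValueError("co-expression labels do not match the motif gene labels")

        W = normalize_network(motif.to_numpy())
        P = normalize_network(ppi.to_numpy())
        C = normalize_network(coexpr.to_numpy())
        u = self.update
        hamming = np.inf
        converged = False
        n_iter = 0
        for step in range(self.max_iter):
            R = tanimoto(P, W)
            A = tanimoto(W, C)
            W_new = (1.0 - u) * W + u * 0.5 * (R + A)
            hamming = float(np.abs(W_new - W).mean())
            W = W_new
            n_iter = step + 1
            if hamming < self.tol:
                converged = True
                break
            P_new = tanimoto(W, W.T)
            _update_diagonal(P_new, len(tfs), u, step)
            P = (1.0 - u) * P + u * P_new
            C_new = tanimoto(W.T, W)
            _update_diagonal(C_new, len(genes), u, step)
            C = (1.0 - u) * C + u * C_new
        if not converged:
            warnings.warn(
                f"PANDA did not converge in {self.max_iter} iterations "
                f"(hamming={hamming:.3g}); returning last state",
                RuntimeWarning,
            )
        self.W_ = pd.DataFrame(W, index=tfs, columns=genes)
        self.n_iter_ = n_iter
        self.hamming_ = hamming
        self.converged_ = converged
        return self

    def to_edgelist(self) -> pd.DataFrame:
        """Long-format (tf, gene, weight) edge list of the fitted network."""
        return (
            self.W_.stack().rename_axis(["tf", "gene"]).reset_index(name="weight")
        )


def panda_fit(
    motif: pd.DataFrame,
    ppi: pd.DataFrame,
    coexpr: pd.DataFrame,
    update: float = 0.1,
    tol: float = 0.001,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PandaGRN`; returns the refined W."""
    return PandaGRN(update=update, tol=tol, max_iter=max_iter).fit(motif, ppi, coexpr).W_
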