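"""Elastic-net prediction of gene expression from GRN edge-weight features.

Genes are observations, TFs are features.  Each fit draws a random 80/20
train/test split, standardizes features, selects the penalty strength by
20-fold inner cross-validation at a fixed lasso/ridge ratio of 0.5, and
reports test-set MSE and Pearson correlation.  Repeating the fit over 20
random splits and averaging each TF's coefficient gives the per-TF average
effect estimate beta_bar, interpreted as activating (> 0) or repressive
(< 0), and binned into quintiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold, train_test_split
from sklearn.preprocessing import StandardScaler

DEFAULT_ALPHA_RATIO = 0.5
DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_INNER_FOLDS = 20
DEFAULT_ITERATIONS = 20
ALPHA_GRID = np.logspace(-4, 1, 50)


@dataclass(frozen=True)
class ModelFit:
    """Coefficients of one elastic-net instance, on the standardized feature scale."""

    coefficients: pd.Series
    intercept: float
    iteration_id: int
    alpha_ratio: float
    penalty_strength: float


@dataclass(frozen=True)
class PerformanceRecord:
    iteration_id: int
    mse: float
    pcc: float

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("MSE must be >= 0")
        if not -1.0 <= self.pcc <= 1.0:
            raise ValueError("PCC must be in [-1, 1]")


@dataclass
class EffectEstimates:
    """Per-TF averaged effect estimates with (optional) quintile bin labels."""

    beta_mean: pd.Series
    bins: pd.Series | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        out = self.beta_mean.rename("beta_mean").to_frame()
        if self.bins is not None:
            out["bin"] = self.bins
        return out


def assemble_features(
    grn_edges: pd.DataFrame, genes: list[str], tfs: list[str]
) -> pd.DataFrame:
    """Pivot a long (tf, gene, weight) edge list to a gene x TF feature matrix.

    Missing edges become 0; duplicate (tf, gene) entries are an error.
    """
    if grn_edges.duplicated(subset=["tf", "gene"]).any():
        raise ValueError("duplicate (tf, gene) edges in the edge list")
    wide = grn_edges.pivot(index="gene", columns="tf", values="weight")
    return wide.reindex(index=genes, columns=tfs).fillna(0.0)


class ElasticNetExpression(BaseEstimator, RegressorMixin):
    """One resampled elastic-net instance (split, standardize, inner-CV, fit).

    Parameters follow the protocol: ``alpha_ratio`` is the lasso/ridge mixing
    ratio (sklearn's ``l1_ratio``), ``train_frac`` the training fraction of
    genes, ``inner_folds`` the inner CV used to pick the penalty strength
    from a 50-point log grid over [1e-4, 10].

    Fitted attributes: ``coef_`` (Series per TF, standardized scale),
    ``intercept_``, ``penalty_strength_``, ``mse_``, ``pcc_``,
    ``train_genes_``, ``test_genes_``.
    """

    def __init__(
        self,
        alpha_ratio: float = DEFAULT_ALPHA_RATIO,
        train_frac: float = DEFAULT_TRAIN_FRAC,
        inner_folds: int = DEFAULT_INNER_FOLDS,
        random_state: int = 0,
    ):
        self.alpha_ratio = alpha_ratio
        self.train_frac = train_frac
        self.inner_folds = inner_folds
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "ElasticNetExpression":
        X = pd.DataFrame(X)
        y = pd.Series(y).loc[X.index]
        if X.shape[0] < 25:
            raise ValueError(f"need >= 25 genes, got {X.shape[0]}")
        if float(np.std(y.to_numpy())) == 0.0:
            raise ValueError("constant response vector")
        train_idx, test_idx = train_test_split(
            np.arange(X.shape[0]),
            train_size=self.train_frac,
            random_state=self.random_state,
            shuffle=True,
        )
        if self.inner_folds > len(train_idx):
            raise ValueError(
                f"inner_folds={self.inner_folds} exceeds training size {len(train_idx)}"
            )
        Xv, yv = X.to_numpy(float), y.to_numpy(float)
        self._scaler = StandardScaler()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant feature columns scale to 0
            Xtr = self._scaler.fit_transform(Xv[train_idx])
            Xte = self._scaler.transform(Xv[test_idx])
        Xtr = np.nan_to_num(Xtr)
        Xte = np.nan_to_num(Xte)
        if self.alpha_ratio == 0.0:
            # sklearn's coordinate descent rejects l1_ratio=0 in CV; nudge
            l1 = 1e-6
        else:
            l1 = self.alpha_ratio
        cv = KFold(n_splits=self.inner_folds, shuffle=True, random_state=self.random_state)
        model = ElasticNetCV(l1_ratio=l1, alphas=ALPHA_GRID, cv=cv, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, yv[train_idx])
        pred = model.predict(Xte)
        self.coef_ = pd.Series(model.coef_, index=X.columns)
        self.intercept_ = float(model.intercept_)
        self.penalty_strength_ = float(model.alpha_)
        self.mse_ = float(np.mean((pred - yv[test_idx]) ** 2))
        if np.std(pred) < 1e-12 or np.std(yv[test_idx]) < 1e-12:
            warnings.warn("constant predictions; PCC undefined, reported as 0", RuntimeWarning)
            self.pcc_ = 0.0
        else:
            pcc = float(stats.pearsonr(pred, yv[test_idx])[0])
            self.pcc_ = pcc if np.isfinite(pcc) else 0.0
        self.train_genes_ = X.index[train_idx]
        self.test_genes_ = X.index[test_idx]
        self._columns = X.columns
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = np.nan_to_num(self._scaler.transform(pd.DataFrame(X)[self._columns].to_numpy(float)))
        return Xs @ self.coef_.to_numpy() + self.intercept_


def fit_enet(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_ratio: float = DEFAULT_ALPHA_RATIO,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
    iteration_id: int = 0,
) -> tuple[ModelFit, PerformanceRecord]:
    """One resampled elastic-net fit; returns coefficients and test performance."""
    est = ElasticNetExpression(
        alpha_ratio=alpha_ratio,
        train_frac=train_frac,
        inner_folds=inner_folds,
        random_state=seed,
    ).fit(X, y)
    fit = ModelFit(
        coefficients=est.coef_,
        intercept=est.intercept_,
        iteration_id=iteration_id,
        alpha_ratio=alpha_ratio,
        penalty_strength=est.penalty_strength_,
    )
    perf = PerformanceRecord(iteration_id=iteration_id, mse=est.mse_, pcc=est.pcc_)
    return fit, perf


def repeat_fit(
    X: pd.DataFrame,
    y: pd.Series,
    iterations: int = DEFAULT_ITERATIONS,
    base_seed: int = 0,
    **kwargs,
) -> tuple[list[ModelFit], list[PerformanceRecord]]:
    """Repeat the split/fit/evaluate protocol; iteration n uses seed base_seed + n."""
    fits, perfs = [], []
    for n in range(iterations):
        fit, perf = fit_enet(X, y, seed=base_seed + n, iteration_id=n, **kwargs)
        fits.append(fit)
        perfs.append(perf)
    return fits, perfs


def compare_models(
    perf_a: list[PerformanceRecord], perf_b: list[PerformanceRecord]
) -> dict[str, tuple[float, float]]:
    """Two-sided Wilcoxon rank-sum comparison of the PCC and MSE lists.

    Exact null when the combined sample size is <= 20 (and no ties); normal
    approximation with continuity correction otherwise.  Returns
    {"pcc": (statistic, pvalue), "mse": (statistic, pvalue)}.
    """
    if len(perf_a) < 3 or len(perf_b) < 3:
        raise ValueError("need >= 3 performance records per model")
    out = {}
    for metric in ("pcc", "mse"):
        a = [getattr(r, metric) for r in perf_a]
        b = [getattr(r, metric) for r in perf_b]
        method = "exact" if len(a) + len(b) <= 20 and len(set(a + b)) == len(a + b) else "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method=method, use_continuity=True
        )
        out[metric] = (float(res.statistic), float(res.pvalue))
    return out


def average_effects(fits: list[ModelFit]) -> EffectEstimates:
    """Per-TF arithmetic mean of coefficients over the resampling iterations."""
    if not fits:
        raise ValueError("no fits to average")
    index = fits[0].coefficients.index
    for f in fits[1:]:
        if not f.coefficients.index.equals(index):
            raise ValueError("fits have mismatched feature sets")
    beta = pd.concat([f.coefficients for f in fits], axis=1).mean(axis=1)
    return EffectEstimates(beta_mean=beta)


def quintile_bins(effects: EffectEstimates) -> EffectEstimates:
    """Partition TFs into 5 contiguous, roughly equal bins by ascending beta_bar.

    Bin 1 holds the most negative (repressor) estimates, bin 5 the most
    positive (activator) ones.  With n = 5q + r the first r bins get the extra
    member; tied estimates that would straddle a boundary stay together in the
    lower bin.
    """
    beta = effects.beta_mean
    n = len(beta)
    if n < 5:
        raise ValueError(f"need >= 5 TFs to form quintiles, got {n}")
    order = beta.sort_values(kind="stable")
    q, r = divmod(n, 5)
    sizes = [q + 1 if i < r else q for i in range(5)]
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[start : start + size] = b
        start += size
    # keep tie groups together in the lower bin
    values = order.to_numpy()
    for i in range(1, n):
        if values[i] == values[i - 1]:
            bins[i] = bins[i - 1]
    binned = pd.Series(bins, index=order.index).reindex(beta.index)
    return EffectEstimates(beta_mean=beta, bins=binned)
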