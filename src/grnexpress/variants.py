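"""GRN-weighted rare-variant association.

Per-variant TF-binding z-scores (QBiC-Pred-style, consumed from TSV) are
combined with the GRN-derived average TF effect estimates into per-variant,
per-gene merge scores:

    Z_{v,t,g} = beta_bar_t * mean_p z_{v,p}   over the TF's significant peaks
    S_{v,g}   = mean_t Z_{v,t,g}              over the gene's TFs

Aggregate z-scores are the same pipeline with beta_bar_t = 1.  Both are
scaled into [-1, 1] and used as per-variant kernel weights in a SKAT
variance-component score test of the gene's expression on its rare-variant
dosages, adjusting for covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval

DEFAULT_MAF_THRESHOLD = 0.01
DEFAULT_BINDING_P = 1e-4
EIG_TOL = 1e-10


@dataclass(frozen=True)
class RareVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float

    def __post_init__(self) -> None:
        if not 0 <= self.maf <= 0.5:
            raise ValueError("MAF must be in [0, 0.5]")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class BindingZScore:
    """Predicted TF-binding change for one variant inside one peak."""

    variant: str  # variant key
    tf: str
    peak: GenomicInterval
    zscore: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0 < self.pvalue <= 1:
            raise ValueError("p-value must be in (0, 1]")


def filter_rare(
    variants: list[RareVariant], maf_threshold: float = DEFAULT_MAF_THRESHOLD
) -> list[RareVariant]:
    """Keep variants with MAF strictly below the threshold."""
    return [v for v in variants if v.maf < maf_threshold]


def significant_binding(
    zscores: list[BindingZScore], p_threshold: float = DEFAULT_BINDING_P
) -> list[BindingZScore]:
    """Keep binding z-scores whose p-value is <= the significance threshold."""
    return [z for z in zscores if z.pvalue <= p_threshold]


def scaled_z(
    variant: str,
    tf: str,
    gene: str,
    zscores: list[BindingZScore],
    beta_bar: float,
) -> float:
    """beta_bar_t times the mean z over the TF's peaks hit by the variant.

    ``zscores`` should already be restricted to significant records for the
    peaks of ``tf`` within ``gene``'s regulatory region.  An empty peak set is
    an error — the (variant, tf, gene) triple is skipped upstream, not
    zero-filled.
    """
    zs = [z.zscore for z in zscores if z.variant == variant and z.tf == tf]
    if not zs:
        raise ValueError(f"no significant peaks of {tf} hit by {variant} in {gene}")
    return beta_bar * float(np.mean(zs))


def merge_score(variant: str, gene: str, per_tf: dict[str, float]) -> float:
    """Mean over TFs of the per-TF scaled z-scores Z_{v,t,g}."""
    if not per_tf:
        raise ValueError(f"variant {variant} has no scored TFs for gene {gene}")
    return float(np.mean(list(per_tf.values())))


def aggregate_z(
    variant: str,
    gene: str,
    zscores: list[BindingZScore],
    tfs: list[str] | None = None,
) -> float:
    """Merge-score pipeline with the effect estimate removed (beta_bar = 1)."""
    hit = [z for z in zscores if z.variant == variant]
    if tfs is not None:
        hit = [z for z in hit if z.tf in set(tfs)]
    per_tf: dict[str, float] = {}
    for tf in {z.tf for z in hit}:
        per_tf[tf] = scaled_z(variant, tf, gene, hit, beta_bar=1.0)
    return merge_score(variant, gene, per_tf)


def variant_gene_scores(
    zscores: list[BindingZScore],
    gene: str,
    beta_bar: pd.Series,
    weighted: bool = True,
) -> pd.Series:
    """Merge scores (or aggregate z when ``weighted`` is False) for one gene.

    ``zscores`` are the significant records for peaks inside the gene's
    regulatory region; TFs without an effect estimate are skipped.
    """
    out: dict[str, float] = {}
    for variant in sorted({z.variant for z in zscores}):
        hit = [z for z in zscores if z.variant == variant]
        per_tf: dict[str, float] = {}
        for tf in sorted({z.tf for z in hit}):
            if weighted and tf not in beta_bar.index:
                continue
            bb = float(beta_bar[tf]) if weighted else 1.0
            per_tf[tf] = scaled_z(variant, tf, gene, hit, beta_bar=bb)
        if per_tf:
            out[variant] = merge_score(variant, gene, per_tf)
    return pd.Series(out, dtype=float)


def scale_scores(scores: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Scale into [-1, 1] by the maximum absolute value; zeros stay zero.

    All-zero input is returned unchanged.
    """
    values = np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("no scores to scale")
    top = np.abs(values).max()
    if top == 0:
        return scores
    return scores / top


# ---------------------------------------------------------------------------
# SKAT
# ---------------------------------------------------------------------------

@dataclass
class SkatInput:
    genotypes: pd.DataFrame  # individuals x variants, dosages in [0, 2]
    phenotype: pd.Series
    weights: pd.Series  # per-variant kernel weights
    covariates: pd.DataFrame | None = None


def impute_dosages(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Fill missing dosages with twice the observed allele frequency."""
    filled = genotypes.copy()
    for col in filled.columns:
        if filled[col].isna().any():
            af = filled[col].mean(skipna=True) / 2.0
            filled[col] = filled[col].fillna(2.0 * (af if np.isfinite(af) else 0.0))
    return filled


def _liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Survival function of sum_i lambda_i * chi2_1 at q, by moment matching.

    Matches the first cumulants of the mixture to a (possibly non-central)
    chi-square, following Liu, Tang & Zhang (2009).
    """
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        ncp = s1 * a**3 - a**2
        df = a**2 - 2 * ncp
    else:
        ncp = 0.0
        df = 1.0 / s2 if s2 > 0 else 1.0
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x = df + ncp
    sigma_x = np.sqrt(2 * (df + 2 * ncp))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(t, df, ncp)) if ncp > 0 else float(stats.chi2.sf(t, df))


def skat_test(
    genotypes: pd.DataFrame | np.ndarray,
    phenotype: pd.Series | np.ndarray,
    weights: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> tuple[float, float]:
    """Weighted SKAT score test of a quantitative trait on a variant set.

    Null model: least-squares regression of the phenotype on an intercept plus
    covariates; with residuals r and residual variance s2,

        Q = r' G diag(w)^2 G' r / s2

    and the p-value comes from the matching mixture-of-chi-squares null with
    eigenvalues of the projected, weighted kernel, approximated by Liu-type
    moment matching.  Weights enter squared, so their sign is irrelevant.
    Returns (Q, pvalue); a zero kernel gives (0, 1).
    """
    G = np.asarray(pd.DataFrame(genotypes), dtype=float)
    y = np.asarray(phenotype, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, m = G.shape
    if w.shape[0] != m:
        raise ValueError("one weight per variant required")
    if np.isnan(G).any():
        G = impute_dosages(pd.DataFrame(G)).to_numpy()
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        X = np.hstack([X, C])
    k = X.shape[1]
    if n <= k + 2:
        raise ValueError("too few individuals for the covariate model")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular covariate matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sigma2 = float(r @ r) / (n - k)
    if sigma2 == 0:
        raise ValueError("phenotype perfectly explained by covariates")
    Gw = G * w[None, :]
    score = Gw.T @ r
    Q = float(score @ score) / sigma2
    # eigenvalues of Gw' P Gw with P the hat-matrix complement
    XtX_inv = np.linalg.inv(X.T @ X)
    GX = Gw.T @ X
    A = Gw.T @ Gw - GX @ XtX_inv @ GX.T
    lambdas = np.linalg.eigvalsh((A + A.T) / 2.0)
    lambdas = lambdas[lambdas > EIG_TOL * max(lambdas.max(initial=0.0), 1.0)]
    if lambdas.size == 0 or Q == 0:
        return Q, 1.0
    return Q, min(max(_liu_sf(Q, lambdas), 0.0), 1.0)


def skat_per_gene(
    inputs: dict[str, SkatInput],
) -> pd.DataFrame:
    """Run SKAT for each gene; returns (gene, n_variants, Q, pvalue) rows."""
    rows = []
    for gene, si in inputs.items():
        geno = impute_dosages(si.genotypes)
        q, p = skat_test(geno, si.phenotype, si.weights, si.covariates)
        rows.append((gene, si.genotypes.shape[1], q, p))
    return pd.DataFrame(rows, columns=["gene", "n_variants", "Q", "pvalue"])


def significance_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / number of genes tested."""
    if n_genes < 1:
        raise ValueError("need >= 1 gene")
    return alpha / n_genes


# ---------------------------------------------------------------------------
# toy binding-disruption stub (fixtures only)
# ---------------------------------------------------------------------------

def pwm_delta_stub(
    sequence: str,
    variants: list[RareVariant],
    pwm,
    peak: GenomicInterval,
    tf: str | None = None,
    reference_sd: float = 1.0,
) -> list[BindingZScore]:
    """Synthetic binding z-scores: best log-odds delta between ref and alt.

    A deliberately simple synthetic stand-in for a trained binding-change
    predictor, used only to generate fixture z-scores: for each variant
    inside ``peak``, score the best PWM log-odds in a window around the
    position on the reference and on the alternate sequence; the delta in
    bits, divided by ``reference_sd`` (the nominal spread of deltas for
    substitutions outside any motif), is the binding z-score, and the
    p-value is its two-sided normal tail.  Variants that destroy a planted
    motif instance thus get strongly negative z with tiny p.
    """
    lom = pwm.log_odds()
    L = lom.shape[0]
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def best_score(seq: str, center: int) -> float:
        lo = max(0, center - L + 1)
        hi = min(len(seq) - L, center)
        best = -np.inf
        for s in range(lo, hi + 1):
            window = seq[s : s + L]
            if any(b not in base_idx for b in window):
                continue
            best = max(best, sum(lom[i, base_idx[b]] for i, b in enumerate(window)))
        return best if np.isfinite(best) else 0.0

    deltas = []
    inside = []
    for v in variants:
        pos0 = v.pos - 1
        if not peak.contains_point(pos0):
            continue
        alt_seq = sequence[:pos0] + v.alt + sequence[pos0 + 1 :]
        deltas.append(best_score(alt_seq, pos0) - best_score(sequence, pos0))
        inside.append(v)
    if not inside:
        return []
    z = np.asarray(deltas) / reference_sd
    out = []
    for v, zi in zip(inside, z):
        out.append(
            BindingZScore(
                variant=v.key,
                tf=tf or pwm.tf,
                peak=peak,
                zscore=float(zi),
                pvalue=float(max(2 * stats.norm.sf(abs(zi)), np.nextafter(0, 1))),
            )
        )
    return out
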