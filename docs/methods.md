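# Methods

`grnexpress` models transcriptional regulation in three linked layers — where
TFs bind, how strongly each TF influences each gene, and what happens to
expression when a rare variant damages a binding site — and ships a synthetic
data generator that exercises every layer without external downloads.  This
note records the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## Regulatory geometry

Coordinates are 0-based half-open throughout; GTF input (1-based inclusive)
is converted on read and BED is consumed natively, so a single convention
holds internally.  For each protein-coding gene:

* the **TSS** is taken from the longest transcript (ties broken by the
  lexicographically smallest transcript id, for reproducibility);
* the **candidate window** runs from 50 kb upstream of the TSS to 50 kb
  downstream of the gene body (strand-aware, clipped at 0);
* the window is truncated at the **most distant CTCF peak** on each side of
  the gene body.  Distance is measured by peak midpoint and the boundary is
  that midpoint; edge-versus-midpoint is not determined by the underlying
  formulation, and a point boundary avoids any dependence on peak width.
  Peaks inside the gene body never shrink the window;
* the **promoter** is the 5 kb immediately upstream of the TSS;
* **intronic regions** are the transcript spans minus the union of all the
  gene's exons.  Subtracting all exons (not only each transcript's own)
  guarantees that no reported intronic base is exonic in any isoform;
* in-window peaks are partitioned promoter > intronic > distal for peaks
  overlapping several categories (precedence is a free choice; promoters are
  the most specific annotation, so they win).

## Binding evidence

Three definitions of a TF→gene edge, mirroring common practice:

* **positional**: any ChIP-seq peak overlapping the bounded window (≥ 1 bp);
* **motif-confirmed**: PWM log-odds hits under peaks.  Scores use a 1e-3
  pseudocount (renormalized) to avoid −∞ on zero entries.  Per-position
  p-values are exact tail probabilities of the background score
  distribution, computed by dynamic programming over scores discretized at
  1e-3 bits.  The DP is exact for the discretized score; tests compare it
  against exhaustive k-mer enumeration for short motifs, where the only
  discrepancy is background mass sitting within half a grid step of the
  threshold.  Both strands are scanned and same-position hits deduplicate to
  the better strand.  Default significance threshold 0.01;
* **affinity**: sum over sites of strength × exp(−d/d₀) with d the
  site-to-TSS distance and d₀ = 5000 bp.  Site strength is the PWM posterior
  p_motif/(p_motif+p_bg), or peak signal normalized to (0, 1] by the
  per-gene maximum when no PWM is available.  This is an affinity-style
  aggregation contract implemented natively (position-specific energy
  matrices are out of scope), so it is monotone in sites and translation
  invariant by construction.

## PANDA message passing

The motif adjacency (TF×gene), PPI (TF×TF, 0/1 with unit diagonal) and
Pearson co-expression (gene×gene) networks are z-score normalized —
entry → (z_row + z_col)/√2, with constant rows/columns falling back to the
whole-matrix z-score (sample standard deviation, ddof = 1) — and fused by
iterating continuous Tanimoto similarities

    T(X, Y)_ij = x_i·y_j / sqrt(‖x_i‖² + ‖y_j‖² − |x_i·y_j|)

(denominator floored at 1e-10).  Each step computes responsibility
R = T(P, W) and availability A = T(W, C), moves W a fraction `update` = 0.1
toward (R+A)/2, and moves P and C the same fraction toward T(W, Wᵀ) and
T(Wᵀ, W), whose diagonals are replaced by the off-diagonal row standard
deviation × dimension × exp(2·update·step) — a damping that keeps
self-similarity from dominating as iterations proceed.  Convergence is the
Hamming distance mean|W_t − W_{t−1}| < 0.001, capped at 200 iterations with
a warning.  The update equations are pinned by a naive-loop reference
implementation (agreement to 1e-10 on random 5×8 networks) rather than by
any single published code path; the iteration count is data-dependent (on
the default synthetic study the fit converges in the mid-20s of iterations).

## Hi-C edge weighting

For each TF–gene pair with N ≥ 1 peaks in the regulatory region, the mean of
the KR-normalized contacts its peaks make with the promoter (missing records
count 0) is scaled by x → 0.99·x/max(x) and the edge weight is C = 1 +
scaled, so C ∈ [1, 1.99].  The scaler is anchored at the maximum rather than
being a generic min–max: this makes "no contacts ⇒ C = 1" hold exactly even
when the smallest observed mean is positive, which a min–max scaler over a
strictly positive support would violate.  Scaling is global across all pairs
of a study (one scaler per matrix).  The **DP** scheme multiplies every
motif edge by C; the **UP** scheme additionally sets zero-contact
promoter-based pairs (C exactly 1) to weight 2.0, encoding the prior that
promoter-proximal binding is functional even when the contact map is silent
there.  A pair is promoter-based when the TF has at least one
promoter-category peak for the gene.

## Expression modelling

Genes are observations and TFs are features; the response is per-gene log10
FPKM-style expression.  Each instance draws a random 80/20 train/test split,
standardizes features on the training portion (coefficients are reported on
the standardized scale, which makes them comparable across TFs — the basis
for effect-estimate binning), and fits an elastic net with lasso/ridge ratio
0.5, choosing the penalty strength by 20-fold inner cross-validation over 50
log-spaced values in [1e-4, 10] (the grid is our choice; it spans from
effectively unpenalized to fully shrunk at these scales).  Test-set MSE and
Pearson correlation are recorded; a degenerate constant prediction reports
PCC 0 with a warning, since the correlation is mathematically undefined
there.  The protocol repeats for 20 instances (instance n uses seed
base_seed + n) and per-TF coefficients are averaged into effect estimates
β̄_T, interpreted as activating (β̄ > 0) or repressive (β̄ < 0).  TFs are
sorted ascending by β̄ and cut into 5 contiguous bins whose sizes differ by
at most one (remainder assigned from bin 1 upward; tie groups stay together
in the lower bin), bin 1 = strongest repressors, bin 5 = strongest
activators.  Model comparisons use the two-sided Wilcoxon rank-sum test on
the PCC and MSE lists — exact when the combined n ≤ 20 without ties, normal
approximation with continuity correction otherwise.

## Rare-variant scoring and SKAT

Variants are filtered to MAF strictly < 0.01 and to binding z-scores with
p ≤ 1e-4.  For each (variant, TF, gene), Z = β̄_t × mean z over the TF's
significant peaks hit by the variant; the merge score S is the mean of Z
over the gene's scored TFs.  Aggregate z-scores are the same computation
with β̄_t ≡ 1.  Both are scaled into [−1, 1] by the maximum absolute value —
genome-wide by default (one scaler per study, matching the global Hi-C
scaler; a per-gene option exists because the scaling scope is genuinely
open).  Zero maps to zero so sign and relative magnitude survive.

SKAT regresses the phenotype on an intercept plus covariates by least
squares, forms Q = rᵀ G diag(w)² Gᵀ r / σ̂², and evaluates the p-value
against the mixture-of-chi-squares null with the exact eigenvalues of the
projected weighted kernel, using Liu-type moment matching (a non-central
chi-square matched to the mixture's cumulants).  Moment matching was chosen
over characteristic-function integration because it is dependency-free and
its accuracy is directly property-tested: empirical type-I error at nominal
0.05 stays within [0.03, 0.07] over 1000 null replicates.  Weights enter the
kernel squared, so their sign cannot affect the test — the signed scaled
scores carry magnitude information only, and a sign-flip invariance test
pins this down.  Missing dosages are imputed to twice the allele frequency.
The default multiple-testing threshold is 0.05 divided by the number of
genes tested.

## Synthetic study design

The generator plants a known truth and emits exactly the files the pipeline
reads.  Desk-scale defaults: 200 genes, 20 TFs, 50 expression samples, 300
genotyped individuals, one chromosome with ~120 kb per gene slot.  Each
component (annotation, motifs, peaks, expression, Hi-C, genotypes) draws
from its own RNG stream derived from the master seed, so regeneration is
bit-identical and adding a generator never perturbs existing fixtures.

* **Regulation**: genes sit in 5 modules; each TF has a home module and
  regulates ~60% of its module's genes (5% elsewhere).  Five activators
  (β ∈ +[0.4, 0.8]), five repressors (β ∈ −[0.4, 0.8]), the rest near zero.
* **Binding evidence is deliberately imperfect**: 25% of true TF–gene pairs
  lose all their peaks (dropout) and a 2% background rate adds false peaks.
  Peaks carry planted motif instances in the genome sequence.
* **Expression** = baseline + Σ_t β_t·binding + 0.5 × per-sample module
  activity + N(0, 0.3) noise.  The module activity produces the
  block-structured co-expression that lets PANDA recover dropped-out edges —
  the mechanism behind the GRN-versus-affinity comparison: affinity features
  see only the (incomplete) cis evidence, while the GRN borrows strength
  from co-regulated genes.
* **Hi-C** contacts are Poisson draws with rate decaying as exp(−d/20 kb)
  from the TSS, jittered multiplicatively to emulate matrix balancing.
* **Variants**: 8 per gene placed inside ChIP-seq peaks, MAF ~ Beta(1.5,
  300) capped at 0.009.  Binding z-scores come from a toy synthetic
  PWM-delta predictor (best log-odds under ref minus alt, in bits) plus
  N(0, 0.3) noise; a variant destroying a planted motif scores strongly
  negative.  In half the genes, motif-destroying variants perturb the
  phenotype by 1.5 × β_t per allele — so disruptions of near-zero-β TFs are
  phenotypically inert, which is exactly the situation where β̄-informed
  merge weights should beat unweighted aggregate z-scores.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), read-level noise, alternative TSS usage, peak-width
variation, dosage uncertainty, population structure, and trans-effects
beyond the module factor.  Passing tests therefore demonstrate that the
implementation recovers planted structure under the stated generative
assumptions, not that the biological findings transfer to any real cohort.

## Numerical choices and degenerate inputs

* PWM DP resolution 1e-3 bits; p-values floored at the smallest positive
  float so they stay in (0, 1].
* Tanimoto denominator floored at 1e-10; all-constant matrices normalize to
  zero.
* An all-zero contact table warns and leaves every weight at 1; an all-zero
  score vector is returned unchanged by the [−1, 1] scaler.
* Constant response vectors, singular covariate matrices, inner folds
  exceeding the training size, and out-of-range scaled contacts raise
  immediately rather than propagating.
* Transcript-length ties, quintile remainders and tie groups all break by
  fixed deterministic rules so identical inputs give identical outputs
  everywhere (no stage of the pipeline is stochastic given its seed).

## Problem sizes used by the test suite

The default synthetic study (200 genes / 20 TFs / 50 samples / 300
individuals) drives the recovery and directional tests; oracle-equivalence
tests run on 5×8 networks, 12-individual kernels and ≤ 6 bp motifs where
exhaustive enumeration is feasible; SKAT calibration uses 1000 null
replicates of 100 individuals × 10 variants.  These sizes were chosen so the
planted effects are comfortably detectable while every check runs in
seconds to a couple of minutes on a single core.

## Known limitations

* The elastic-net coefficients (and hence β̄ and merge scores) are on the
  standardized feature scale; magnitudes are not comparable across studies
  with different feature dispersions.
* The Liu-type SKAT p-value is slightly conservative in the extreme tail
  compared with exact integration of the mixture distribution.
* The affinity scorer is a contract-faithful native implementation, not a
  reimplementation of any specific published energy model.
* Hi-C weighting assumes pre-normalized contacts; no matrix balancing is
  performed internally.
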