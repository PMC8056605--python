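# grnexpress

Multi-omics gene regulatory networks (GRNs) for predicting gene expression
and scoring rare regulatory variants.

## What problem this solves

Which transcription factors (TFs) drive a gene's expression, how strongly,
and in which direction?  And when a rare DNA variant damages a TF binding
site, does the gene's expression actually change?  `grnexpress` answers both
questions with one framework, aimed at regulatory genomicists working with
ChIP-seq, co-expression, Hi-C and genotype data:

1. **Binding geometry** — each protein-coding gene gets a cis-regulatory
   window: 50 kb around the gene anchored at the TSS of its longest
   transcript, truncated at the most distant flanking CTCF insulator peaks.
   TF ChIP-seq peaks in the window are classified promoter / intronic /
   distal, confirmed by PWM motif scanning (exact p-values from the
   background score distribution), or summarized as affinity scores
   Σ a·exp(−d/5 kb).
2. **Network inference** — the motif adjacency W (TF×gene), protein–protein
   interactions P (TF×TF) and expression correlation C (gene×gene) are fused
   by PANDA message passing: iterate responsibility R = T(P, W) and
   availability A = T(W, C) with the continuous Tanimoto similarity
   T(X,Y)ᵢⱼ = xᵢ·yⱼ / √(‖xᵢ‖² + ‖yⱼ‖² − |xᵢ·yⱼ|), update
   W ← 0.9 W + 0.1 (R+A)/2, and stop when mean|ΔW| < 0.001.
3. **Hi-C weighting** — motif edges are multiplied by C_{i,g} = 1 +
   scaled(mean KR-normalized promoter contacts of TF i's peaks at gene g),
   scaled into [0, 0.99] so C ∈ [1, 1.99] ("DP" scheme); the "UP" scheme
   boosts zero-contact promoter edges to 2.0.
4. **Expression models** — elastic nets (lasso/ridge ratio 0.5, penalty from
   20-fold inner CV) predict per-gene log expression from GRN edge weights
   over 20 random 80/20 splits.  Per-TF coefficients averaged over splits,
   β̄_T = (1/|N|) Σₙ β_{T,n}, rank TFs from repressors (β̄ < 0) to
   activators (β̄ > 0) in quintile bins.
5. **Rare-variant association** — per-variant TF-binding z-scores are
   combined with β̄ into merge scores
   S_{v,g} = meanₜ ( β̄_t · mean_p z_{v,p} ), scaled to [−1, 1], and used as
   per-variant weights in a SKAT kernel test of gene expression on rare
   (MAF < 1%) genotypes with covariates.

A first-class synthetic-data module generates annotation, sequence, motifs,
peaks, expression with planted activator/repressor effects, block
co-expression, distance-decaying Hi-C contacts, and rare variants with
planted binding-disruption effects — so the whole pipeline runs and is
tested with no downloads.

## Worked example

```python
import numpy as np
from grnexpress import (
    SimConfig, simulate_annotation, simulate_regulation,
    positional_tfbs, motif_adjacency, ppi_network, coexpression_network,
    panda_fit, repeat_fit, average_effects, quintile_bins,
)

cfg = SimConfig(seed=11, n_genes=60, n_tfs=10, n_samples=40)
ann = simulate_annotation(cfg)
reg = simulate_regulation(cfg, ann)

records = positional_tfbs(reg.peaks, list(reg.windows.values()))
pairs = sorted({(tf, g) for tf, g, _ in records})
tfs = sorted({tf for tf, _ in pairs})
motif = motif_adjacency(pairs, tfs, list(reg.expression.columns))
W = panda_fit(motif, ppi_network(reg.ppi_edges, tfs),
              coexpression_network(reg.expression))

y = reg.expression.mean(axis=0)            # per-gene log expression
fits, perfs = repeat_fit(W.T, y, iterations=20, base_seed=11)
effects = quintile_bins(average_effects(fits))

print(f"median test-set PCC over 20 fits: {np.median([p.pcc for p in perfs]):.3f}")
print(f"median test-set MSE over 20 fits: {np.median([p.mse for p in perfs]):.3f}")
print(effects.to_frame().sort_values('beta_mean').head(3))
```

prints

```
median test-set PCC over 20 fits: 0.663
median test-set MSE over 20 fits: 0.190
      beta_mean  bin
TF08  -0.303612    1
TF07  -0.166308    1
TF05  -0.163920    2
```

The median Pearson correlation (0.663) says the GRN edge weights predict
two-thirds of the held-out genes' expression ordering; the most negative
averaged coefficients land in bin 1 — and indeed TF08, TF07 and TF05 are
three of this fixture's five planted repressors (true β = −0.70, −0.44,
−0.50), recovered with the correct sign from binding evidence and
expression alone.

## Command line

Every stage also runs from the shell with flat-file TSV hand-offs and a run
manifest:

```bash
grnexpress all --out run/ --seed 11            # simulate → … → skat
grnexpress fit --out run/ --config run.yaml    # rerun one stage
```

Stages: `simulate`, `regions`, `tfbs`, `grn`, `hic`, `fit`, `effects`,
`varscore`, `skat`.  Parameters (window 50 kb, promoter 5 kb, motif p 0.01,
PANDA update 0.1 / tolerance 0.001, elastic-net ratio 0.5, 20 iterations,
MAF 1%, binding-z p 1e-4, Hi-C scheme none/DP/UP) live in a YAML config;
reruns with unchanged inputs are no-ops unless `--force`.

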