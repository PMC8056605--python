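"""Self-consistent synthetic inputs for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* non-overlapping multi-transcript genes with exon/intron structure on both
  strands, flanked by CTCF sites, on a random sequence with motif instances
  planted under ChIP-seq peaks;
* TF binding enriched at promoters and introns of true targets, with peak
  dropout (false-negative binding evidence) and background (false-positive)
  peaks;
* expression = sum of planted activator/repressor TF effects on bound genes
  + a module-level trans component shared by co-regulated genes + Gaussian
  noise, giving block-structured co-expression;
* Hi-C promoter contacts decaying exponentially with distance, with Poisson
  sampling and a multiplicative normalization jitter;
* rare variants (MAF < 1%) inside and outside TFBS, where variants that
  destroy a planted motif of a large-effect TF perturb the phenotype
  proportionally to that TF's planted effect.

Every component draws from its own RNG stream derived from the master seed,
so adding a generator never perturbs existing fixtures, and regeneration with
the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import build_regulatory_window, gene_tss, partition_peaks
from .hic import ContactRecord
from .intervals import ChipPeak, GeneModel, GenomicInterval, RegulatoryWindow, TranscriptModel
from .tfbs import PWM
from .variants import BindingZScore, RareVariant, pwm_delta_stub

_STREAMS = {
    "annotation": 0,
    "motifs": 1,
    "peaks": 2,
    "expression": 3,
    "hic": 4,
    "genotypes": 5,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic fixture.

    Defaults are desk-scale: 200 genes, 20 TFs, 50 expression samples and 300
    genotyped individuals.  Effect sizes plant 5 activators (+0.4..0.8), 5
    repressors (-0.8..-0.4) and near-zero effects for the remaining TFs.
    """

    seed: int
    n_genes: int = 200
    n_tfs: int = 20
    n_samples: int = 50
    n_modules: int = 5
    gene_slot_bp: int = 120_000
    genome_length: int | None = None
    motif_length: int = 8
    n_activators: int = 5
    n_repressors: int = 5
    noise_sd: float = 0.3
    trans_loading: float = 0.5
    p_regulate_in: float = 0.6
    p_regulate_out: float = 0.05
    peak_dropout: float = 0.25
    background_peak_rate: float = 0.02
    hic_decay_bp: float = 20_000.0
    hic_mean_contacts: float = 20.0
    n_individuals: int = 300
    n_variants_per_gene: int = 8
    causal_fraction: float = 0.5
    variant_effect_scale: float = 1.5
    effect_sizes: dict[str, float] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_tfs", "n_samples", "n_individuals", "n_variants_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.genome_length is None:
            self.genome_length = self.n_genes * self.gene_slot_bp + 2 * 60_000
        if self.genome_length < self.n_genes * 60_000:
            raise ValueError("genome_length too small for the gene count (needs 50 kb spacing)")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), _STREAMS[stream]])

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i:02d}" for i in range(self.n_tfs)]

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SimAnnotation:
    genes: list[GeneModel]
    sequence: str
    chrom: str
    pwms: dict[str, PWM]


@dataclass
class SimRegulation:
    peaks: list[ChipPeak]
    ctcf_peaks: list[GenomicInterval]
    windows: dict[str, RegulatoryWindow]
    ppi_edges: list[tuple[str, str]]
    expression: pd.DataFrame  # samples x genes, log10-FPKM-like
    contacts: list[ContactRecord]
    sequence: str  # with motif instances planted under peaks
    truth: dict


@dataclass
class SimGenotypes:
    genotypes: dict[str, pd.DataFrame]  # gene -> individuals x variants
    phenotypes: dict[str, pd.Series]  # gene -> per-individual expression
    covariates: pd.DataFrame
    variants: dict[str, list[RareVariant]]
    zscores: dict[str, list[BindingZScore]]
    truth: dict


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def simulate_annotation(cfg: SimConfig) -> SimAnnotation:
    """Gene models on one synthetic chromosome plus per-TF motifs."""
    rng = cfg.rng("annotation")
    margin = 60_000
    slot = (cfg.genome_length - 2 * margin) // cfg.n_genes
    if slot < 40_000:
        raise ValueError("overcrowded genome: genes would overlap")
    chrom = "chr1"
    genes: list[GeneModel] = []
    for i, gene_id in enumerate(cfg.gene_names):
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(8_000, 20_000))
        start = margin + i * slot + int(rng.integers(0, max(slot - body_len - 10_000, 1)))
        span = GenomicInterval(chrom, start, start + body_len, strand)
        transcripts = []
        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            if t == 0:
                tx_span = span
            else:
                cut = int(rng.integers(0, body_len // 3))
                tx_span = GenomicInterval(chrom, start + cut, start + body_len, strand)
            n_exons = int(rng.integers(2, 6))
            bounds = np.sort(
                rng.choice(
                    np.arange(tx_span.start + 200, tx_span.end - 200),
                    size=2 * (n_exons - 1),
                    replace=False,
                )
            )
            edges = [tx_span.start, *bounds.tolist(), tx_span.end]
            exons = tuple(
                GenomicInterval(chrom, edges[2 * k], edges[2 * k + 1], strand)
                for k in range(n_exons)
            )
            transcripts.append(TranscriptModel(tx_id=f"{gene_id}.T{t}", span=tx_span, exons=exons))
        genes.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, transcripts=tuple(transcripts))
        )
    seq_arr = _random_sequence(cfg.rng("annotation"), cfg.genome_length)

    mrng = cfg.rng("motifs")
    pwms = {}
    for tf in cfg.tf_names:
        probs = mrng.dirichlet(np.full(4, 0.2), size=cfg.motif_length)
        pwms[tf] = PWM(tf, probs)
    return SimAnnotation(genes=genes, sequence=seq_arr.tobytes().decode(), chrom=chrom, pwms=pwms)


def _plant_motif(seq: np.ndarray, rng: np.random.Generator, pwm: PWM, pos: int) -> None:
    """Write a consensus-sampled motif instance into the sequence at ``pos``."""
    for i in range(len(pwm)):
        base = rng.choice(4, p=pwm.probs[i])
        seq[pos + i] = _BASES[base]


def simulate_regulation(cfg: SimConfig, ann: SimAnnotation) -> SimRegulation:
    """Peaks, PPI, expression, Hi-C contacts and the planted truth record."""
    rng = cfg.rng("peaks")
    genes = {g.gene_id: g for g in ann.genes}
    gene_ids = cfg.gene_names
    tfs = cfg.tf_names
    n_per_module = -(-cfg.n_genes // cfg.n_modules)
    gene_module = {g: i // n_per_module for i, g in enumerate(gene_ids)}
    tf_module = {t: i % cfg.n_modules for i, t in enumerate(tfs)}

    # planted effect sizes
    if cfg.effect_sizes is not None:
        beta = pd.Series(cfg.effect_sizes).reindex(tfs).fillna(0.0)
    else:
        erng = cfg.rng("expression")
        n_act = min(cfg.n_activators, cfg.n_tfs // 2)
        n_rep = min(cfg.n_repressors, cfg.n_tfs - n_act)
        vals = np.concatenate(
            [
                erng.uniform(0.4, 0.8, n_act),
                -erng.uniform(0.4, 0.8, n_rep),
                erng.normal(0.0, 0.02, cfg.n_tfs - n_act - n_rep),
            ]
        )
        beta = pd.Series(vals, index=tfs)

    # true regulation: module-enriched bipartite structure
    B = pd.DataFrame(0.0, index=tfs, columns=gene_ids)
    for t in tfs:
        for g in gene_ids:
            p = cfg.p_regulate_in if tf_module[t] == gene_module[g] else cfg.p_regulate_out
            if rng.random() < p:
                B.at[t, g] = 1.0

    # CTCF sites flanking most gene bodies
    ctcf: list[GenomicInterval] = []
    for g in gene_ids:
        body = genes[g].span
        if rng.random() < 0.7:
            mid = body.start - int(rng.integers(30_000, 48_000))
            ctcf.append(GenomicInterval(ann.chrom, max(mid - 150, 0), mid + 150))
        if rng.random() < 0.7:
            mid = body.end + int(rng.integers(30_000, 48_000))
            ctcf.append(GenomicInterval(ann.chrom, mid - 150, mid + 150))

    windows = {g: build_regulatory_window(genes[g], ctcf) for g in gene_ids}

    # ChIP-seq peaks with planted motif instances; binding evidence is
    # incomplete (dropout) and slightly contaminated (background peaks)
    seq = np.frombuffer(ann.sequence.encode(), dtype=np.uint8).copy()
    peaks: list[ChipPeak] = []
    dropped_pairs: list[tuple[str, str]] = []

    def place_peak(tf: str, g: str, region: GenomicInterval) -> None:
        width = 200
        if len(region) <= width + 2 * len(ann.pwms[tf]):
            return
        start = int(rng.integers(region.start, region.end - width))
        iv = GenomicInterval(ann.chrom, start, start + width)
        signal = float(rng.lognormal(0.0, 0.5))
        _plant_motif(seq, rng, ann.pwms[tf], start + width // 2)
        peaks.append(ChipPeak(tf=tf, interval=iv, signal=signal))

    for g in gene_ids:
        w = windows[g]
        regions = {
            "promoter": w.promoter,
            "intronic": w.introns[0] if w.introns else None,
            "distal": w.bounded,
        }
        for t in tfs:
            if B.at[t, g] == 1.0:
                if rng.random() < cfg.peak_dropout:
                    dropped_pairs.append((t, g))
                    continue
                n_peaks = 1 + int(rng.poisson(0.7))
                for _ in range(n_peaks):
                    u = rng.random()
                    if u < 0.4 and regions["promoter"] is not None:
                        place_peak(t, g, regions["promoter"])
                    elif u < 0.7 and regions["intronic"] is not None:
                        place_peak(t, g, regions["intronic"])
                    else:
                        place_peak(t, g, regions["distal"])
            elif rng.random() < cfg.background_peak_rate:
                place_peak(t, g, regions["distal"])

    # PPI: TFs sharing a home module tend to interact
    ppi_edges = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1 :]:
            if tf_module[a] == tf_module[b] and rng.random() < 0.6:
                ppi_edges.append((a, b))

    # expression: cis effects + module-level trans activity + noise
    erng = cfg.rng("expression")
    cis = B.T.to_numpy() @ beta.to_numpy()  # per gene
    baseline = erng.normal(1.0, 0.3, cfg.n_genes)
    module_activity = erng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_modules))
    module_of = np.array([gene_module[g] for g in gene_ids])
    expr = (
        baseline[None, :]
        + cis[None, :]
        + cfg.trans_loading * module_activity[:, module_of]
        + erng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_genes))
    )
    expression = pd.DataFrame(
        expr, index=[f"S{i:03d}" for i in range(cfg.n_samples)], columns=gene_ids
    )

    # Hi-C: distance-decaying promoter contacts for in-window peaks
    hrng = cfg.rng("hic")
    contacts: list[ContactRecord] = []
    for g in gene_ids:
        w = windows[g]
        tss = w.tss
        for cat_peaks in partition_peaks(peaks, w).values():
            for p in cat_peaks:
                d = abs(p.interval.midpoint - tss)
                lam = cfg.hic_mean_contacts * np.exp(-d / cfg.hic_decay_bp)
                c = hrng.poisson(lam) * hrng.uniform(0.8, 1.2)
                if c > 0:
                    contacts.append(ContactRecord(peak=p.interval, gene_id=g, contacts=float(c)))

    truth = {
        "beta": beta,
        "regulation": B,
        "gene_module": gene_module,
        "tf_module": tf_module,
        "dropped_pairs": dropped_pairs,
    }
    return SimRegulation(
        peaks=peaks,
        ctcf_peaks=ctcf,
        windows=windows,
        ppi_edges=ppi_edges,
        expression=expression,
        contacts=contacts,
        sequence=seq.tobytes().decode(),
        truth=truth,
    )


def simulate_genotypes(cfg: SimConfig, ann: SimAnnotation, reg: SimRegulation) -> SimGenotypes:
    """Rare variants in TFBS, genotype dosages, phenotypes and binding z-scores.

    Variants are placed inside ChIP-seq peaks in each gene's bounded window.
    A variant that lands in (and destroys) a planted motif of TF t gets a
    strongly negative binding z-score from the toy PWM-delta stub; its effect
    on the gene's phenotype is proportional to t's planted expression effect,
    so only disruptions of large-effect TFs are phenotypically causal.
    """
    rng = cfg.rng("genotypes")
    beta = reg.truth["beta"]
    n = cfg.n_individuals
    covariates = pd.DataFrame(
        rng.normal(size=(n, 2)),
        columns=["cov1", "cov2"],
        index=[f"I{i:04d}" for i in range(n)],
    )
    cov_effect = np.array([0.3, -0.2])

    causal_genes = set(
        rng.choice(
            cfg.gene_names,
            size=int(round(cfg.causal_fraction * cfg.n_genes)),
            replace=False,
        ).tolist()
    )

    genotypes: dict[str, pd.DataFrame] = {}
    phenotypes: dict[str, pd.Series] = {}
    variants: dict[str, list[RareVariant]] = {}
    zscores: dict[str, list[BindingZScore]] = {}
    causal_variants: dict[str, list[str]] = {}

    seq = reg.sequence
    base_set = "ACGT"
    for g in cfg.gene_names:
        w = reg.windows[g]
        in_window = [
            p for cat in partition_peaks(reg.peaks, w).values() for p in cat
        ]
        if not in_window:
            genotypes[g] = pd.DataFrame(index=covariates.index)
            phenotypes[g] = pd.Series(rng.normal(size=n), index=covariates.index)
            variants[g], zscores[g], causal_variants[g] = [], [], []
            continue
        vlist: list[RareVariant] = []
        for _ in range(cfg.n_variants_per_gene):
            peak = in_window[int(rng.integers(len(in_window)))]
            pos0 = int(rng.integers(peak.interval.start, peak.interval.end))
            ref = seq[pos0]
            alt = base_set[(base_set.index(ref) + int(rng.integers(1, 4))) % 4]
            maf = float(np.clip(rng.beta(1.5, 300.0), 1.0 / (2 * n), 0.009))
            vlist.append(RareVariant(ann.chrom, pos0 + 1, ref, alt, maf))
        variants[g] = vlist

        # binding z-scores from the toy stub, per peak the variant falls in
        zs: list[BindingZScore] = []
        for peak in in_window:
            zs.extend(
                pwm_delta_stub(seq, vlist, ann.pwms[peak.tf], peak.interval, tf=peak.tf)
            )
        # measurement noise on the stub scores
        zs = [
            BindingZScore(
                z.variant,
                z.tf,
                z.peak,
                z.zscore + float(rng.normal(0.0, 0.3)),
                z.pvalue,
            )
            for z in zs
        ]
        zscores[g] = zs

        G = pd.DataFrame(
            {v.key: rng.binomial(2, v.maf, size=n).astype(float) for v in vlist},
            index=covariates.index,
        )
        genotypes[g] = G

        # phenotype: covariates + causal variant effects + noise
        y = covariates.to_numpy() @ cov_effect + rng.normal(0.0, 1.0, size=n)
        causal_here: list[str] = []
        if g in causal_genes:
            disrupt = {}
            for z in zs:
                if z.pvalue <= 1e-4:
                    disrupt.setdefault(z.variant, []).append(z)
            for vkey, zlist in disrupt.items():
                # losing an activator's site lowers expression (and vice versa)
                gamma = cfg.variant_effect_scale * float(
                    np.mean([beta[z.tf] * np.sign(z.zscore) for z in zlist])
                )
                if abs(gamma) > 0.05 and vkey in G.columns:
                    y = y + gamma * G[vkey].to_numpy()
                    causal_here.append(vkey)
        phenotypes[g] = pd.Series(y, index=covariates.index)
        causal_variants[g] = causal_here

    truth = {
        "causal_genes": sorted(causal_genes),
        "causal_variants": causal_variants,
        "beta": beta,
    }
    return SimGenotypes(
        genotypes=genotypes,
        phenotypes=phenotypes,
        covariates=covariates,
        variants=variants,
        zscores=zscores,
        truth=truth,
    )
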