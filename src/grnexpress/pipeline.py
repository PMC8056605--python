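"""Stage orchestration with flat-file TSV hand-offs and a run manifest.

Stages (in dependency order): simulate -> regions -> tfbs -> grn -> hic ->
fit -> effects -> varscore -> skat.  Every stage reads the previous stage's
files from the output directory, writes its own, and appends a manifest line
(stage, parameters, input hashes, outputs).  Re-running a stage with
unchanged inputs and parameters is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .annotation import build_regulatory_window, partition_peaks
from .expression import (
    assemble_features,
    average_effects,
    quintile_bins,
    repeat_fit,
)
from .hic import apply_scheme, hic_weight_matrix
from .intervals import ChipPeak, GenomicInterval
from .panda import PandaGRN
from .priors import coexpression_network, common_gene_restriction, motif_adjacency, ppi_network
from .simulate import SimConfig, simulate_annotation, simulate_genotypes, simulate_regulation
from .tfbs import affinity_score, peak_sites, positional_tfbs
from .variants import (
    BindingZScore,
    RareVariant,
    filter_rare,
    scale_scores,
    significant_binding,
    skat_test,
)

logger = logging.getLogger("grnexpress")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "flank": 50_000,
    "promoter": 5_000,
    "fimo_p": 0.01,
    "panda_update": 0.1,
    "panda_tol": 0.001,
    "panda_max_iter": 200,
    "alpha_ratio": 0.5,
    "iterations": 20,
    "train_frac": 0.8,
    "inner_folds": 20,
    "maf": 0.01,
    "qbic_p": 1e-4,
    "scheme": "none",  # none | DP | UP
    "features": "grn",  # grn | affinity
    "adjacency": "binary",  # binary | affinity
    "sim": {},
}

STAGE_ORDER = [
    "simulate",
    "regions",
    "tfbs",
    "grn",
    "hic",
    "fit",
    "effects",
    "varscore",
    "skat",
]


def load_config(path: str | Path | None) -> dict:
    import yaml

    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if key not in cfg:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict) and isinstance(value, dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _hash_file(path: Path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(outdir: Path) -> Path:
    return outdir / "manifest.jsonl"


def _read_manifest(outdir: Path) -> list[dict]:
    path = _manifest_path(outdir)
    if not path.exists():
        return []
    return [json.loads(line) for line in path.read_text().splitlines() if line.strip()]


def _append_manifest(outdir: Path, entry: dict) -> None:
    with open(_manifest_path(outdir), "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _stage_params(stage: str, config: dict) -> dict:
    keys = {
        "simulate": ["seed", "sim"],
        "regions": ["flank", "promoter"],
        "tfbs": ["fimo_p"],
        "grn": ["panda_update", "panda_tol", "panda_max_iter", "adjacency", "scheme"],
        "hic": ["scheme"],
        "fit": ["alpha_ratio", "iterations", "train_frac", "inner_folds", "seed", "features"],
        "effects": [],
        "varscore": ["maf", "qbic_p"],
        "skat": [],
    }[stage]
    return {k: config[k] for k in keys}


def _windows_from_tsv(outdir: Path) -> dict:
    df = pd.read_csv(outdir / "windows.tsv", sep="\t")
    from .intervals import RegulatoryWindow

    windows = {}
    for row in df.itertuples(index=False):
        promoter = (
            GenomicInterval(row.chrom, int(row.prom_start), int(row.prom_end))
            if row.prom_end > row.prom_start
            else None
        )
        introns = tuple(
            GenomicInterval(row.chrom, int(s), int(e))
            for s, e in (
                (piece.split("-") for piece in str(row.introns).split(",") if piece and piece != "nan")
            )
        )
        windows[row.gene] = RegulatoryWindow(
            gene_id=row.gene,
            tss=int(row.tss),
            candidate=GenomicInterval(row.chrom, int(row.cand_start), int(row.cand_end)),
            bounded=GenomicInterval(row.chrom, int(row.bounded_start), int(row.bounded_end)),
            promoter=promoter,
            introns=introns,
        )
    return windows


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path) -> list[Path]:
    sim_cfg = SimConfig(seed=int(config["seed"]), **config.get("sim", {}))
    ann = simulate_annotation(sim_cfg)
    reg = simulate_regulation(sim_cfg, ann)
    gen = simulate_genotypes(sim_cfg, ann, reg)

    gio.write_gtf_genes(ann.genes, outdir / "annotation.gtf")
    gio.write_fasta({ann.chrom: reg.sequence}, outdir / "genome.fa")
    gio.write_meme_motifs({t: p.probs for t, p in ann.pwms.items()}, outdir / "motifs.meme")
    gio.write_bed_peaks(reg.peaks, outdir / "peaks.bed")
    ctcf_peaks = [ChipPeak("CTCF", iv) for iv in reg.ctcf_peaks]
    gio.write_bed_peaks(ctcf_peaks, outdir / "ctcf.bed")
    pd.DataFrame(reg.ppi_edges, columns=["tf_a", "tf_b"]).to_csv(
        outdir / "ppi.tsv", sep="\t", index=False
    )
    gio.write_matrix_tsv(reg.expression, outdir / "expression.tsv")
    pd.DataFrame(
        [
            (c.peak.chrom, c.peak.start, c.peak.end, c.gene_id, c.contacts)
            for c in reg.contacts
        ],
        columns=["chrom", "peak_start", "peak_end", "gene_id", "kr_contacts"],
    ).to_csv(outdir / "contacts.tsv", sep="\t", index=False)

    # variant-side fixtures
    rows = []
    for g, vs in gen.variants.items():
        for v in vs:
            rows.append((g, v.key, v.chrom, v.pos, v.ref, v.alt, v.maf))
    pd.DataFrame(
        rows, columns=["gene", "variant", "chrom", "pos", "ref", "alt", "maf"]
    ).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    zrows = []
    for g, zs in gen.zscores.items():
        for z in zs:
            zrows.append(
                (g, z.variant, z.tf, z.peak.chrom, z.peak.start, z.peak.end, z.zscore, z.pvalue)
            )
    pd.DataFrame(
        zrows,
        columns=["gene", "variant", "tf", "chrom", "peak_start", "peak_end", "zscore", "pvalue"],
    ).to_csv(outdir / "binding_zscores.tsv", sep="\t", index=False)
    geno_wide = pd.concat(
        {g: gen.genotypes[g] for g in sim_cfg.gene_names if not gen.genotypes[g].empty},
        axis=1,
    )
    geno_wide.columns = [f"{g}|{v}" for g, v in geno_wide.columns]
    gio.write_matrix_tsv(geno_wide, outdir / "genotypes.tsv")
    gio.write_matrix_tsv(pd.DataFrame(gen.phenotypes), outdir / "phenotypes.tsv")
    gio.write_matrix_tsv(gen.covariates, outdir / "covariates.tsv")
    reg.truth["beta"].rename("beta").to_frame().rename_axis("tf").to_csv(
        outdir / "truth_beta.tsv", sep="\t"
    )
    return sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed")) + [
        outdir / "annotation.gtf",
        outdir / "genome.fa",
        outdir / "motifs.meme",
    ]


def stage_regions(config: dict, outdir: Path) -> list[Path]:
    genes = gio.read_gtf_genes(outdir / "annotation.gtf")
    ctcf = [p.interval for p in gio.read_bed_peaks(outdir / "ctcf.bed")]
    rows = []
    windows = []
    for gene in genes:
        w = build_regulatory_window(
            gene, ctcf, flank=int(config["flank"]), promoter_length=int(config["promoter"])
        )
        windows.append(w)
        prom = w.promoter
        rows.append(
            (
                w.gene_id,
                w.candidate.chrom,
                w.tss,
                w.candidate.start,
                w.candidate.end,
                w.bounded.start,
                w.bounded.end,
                prom.start if prom else 0,
                prom.end if prom else 0,
                ",".join(f"{iv.start}-{iv.end}" for iv in w.introns),
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "gene", "chrom", "tss", "cand_start", "cand_end",
            "bounded_start", "bounded_end", "prom_start", "prom_end", "introns",
        ],
    ).to_csv(outdir / "windows.tsv", sep="\t", index=False)
    gio.write_windows_bed(windows, outdir / "windows.bed")
    return [outdir / "windows.tsv", outdir / "windows.bed"]


def stage_tfbs(config: dict, outdir: Path) -> list[Path]:
    peaks = gio.read_bed_peaks(outdir / "peaks.bed")
    windows = _windows_from_tsv(outdir)
    records = positional_tfbs(peaks, list(windows.values()))
    rows = []
    for tf, gene, peak in records:
        cats = partition_peaks([peak], windows[gene])
        category = next(cat for cat, plist in cats.items() if plist)
        rows.append(
            (tf, gene, peak.interval.chrom, peak.interval.start, peak.interval.end,
             peak.signal, category)
        )
    pd.DataFrame(
        rows, columns=["tf", "gene", "chrom", "start", "end", "signal", "category"]
    ).to_csv(outdir / "positional_tfbs.tsv", sep="\t", index=False)

    # TEPIC-style affinity matrix from peak signals with exponential decay
    expr = gio.read_matrix_tsv(outdir / "expression.tsv")
    tfs = sorted({tf for tf, _, _ in records})
    genes = list(expr.columns)
    aff = pd.DataFrame(0.0, index=tfs, columns=genes)
    by_pair: dict[tuple[str, str], list[ChipPeak]] = {}
    for tf, gene, peak in records:
        by_pair.setdefault((tf, gene), []).append(peak)
    for (tf, gene), plist in by_pair.items():
        if gene not in aff.columns:
            continue
        score = affinity_score(
            peak_sites(plist), windows[gene].tss, window=windows[gene], tf=tf, gene_id=gene
        )
        aff.at[tf, gene] = score.value
    gio.write_matrix_tsv(aff, outdir / "affinity.tsv")
    return [outdir / "positional_tfbs.tsv", outdir / "affinity.tsv"]


def stage_grn(config: dict, outdir: Path) -> list[Path]:
    pos = pd.read_csv(outdir / "positional_tfbs.tsv", sep="\t")
    expr = gio.read_matrix_tsv(outdir / "expression.tsv")
    genes = list(expr.columns)
    tfs = sorted(pos.tf.unique())

    scheme = str(config.get("scheme", "none"))
    if str(config["adjacency"]) == "affinity":
        aff = gio.read_matrix_tsv(outdir / "affinity.tsv")
        motif = aff.reindex(index=tfs, columns=genes).fillna(0.0)
    else:
        pairs = list(pos[["tf", "gene"]].drop_duplicates().itertuples(index=False))
        motif = motif_adjacency(pairs, tfs, genes, mode="binary")
        if scheme in ("DP", "UP"):
            weights = gio.read_matrix_tsv(outdir / "hic_weights.tsv")
            promoter_pairs = set(
                pos[pos.category == "promoter"][["tf", "gene"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            motif = apply_scheme(motif, weights, promoter_pairs, scheme)
    motif = common_gene_restriction(motif, genes)

    ppi_df = pd.read_csv(outdir / "ppi.tsv", sep="\t")
    ppi = ppi_network(list(ppi_df.itertuples(index=False, name=None)), tfs)
    coexpr = coexpression_network(expr[list(motif.columns)])

    model = PandaGRN(
        update=float(config["panda_update"]),
        tol=float(config["panda_tol"]),
        max_iter=int(config["panda_max_iter"]),
    ).fit(motif, ppi, coexpr)
    gio.write_matrix_tsv(motif, outdir / "motif_adjacency.tsv")
    gio.write_matrix_tsv(model.W_, outdir / "panda_W.tsv")
    model.to_edgelist().to_csv(outdir / "panda_edges.tsv", sep="\t", index=False)
    logger.info("PANDA converged=%s after %d iterations", model.converged_, model.n_iter_)
    return [outdir / "motif_adjacency.tsv", outdir / "panda_W.tsv", outdir / "panda_edges.tsv"]


def stage_hic(config: dict, outdir: Path) -> list[Path]:
    pos = pd.read_csv(outdir / "positional_tfbs.tsv", sep="\t")
    contacts = pd.read_csv(outdir / "contacts.tsv", sep="\t")
    expr = gio.read_matrix_tsv(outdir / "expression.tsv")
    genes = list(expr.columns)
    tfs = sorted(pos.tf.unique())

    # mean KR-normalized contacts per (tf, gene): zero-fill peaks with no record
    key = ["gene_id", "peak_start", "peak_end"]
    contact_by_peak = contacts.set_index(key)["kr_contacts"]
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for row in pos.itertuples(index=False):
        pair = (row.tf, row.gene)
        c = float(
            contact_by_peak.get((row.gene, row.start, row.end), 0.0)
        )
        sums[pair] = sums.get(pair, 0.0) + c
        counts[pair] = counts.get(pair, 0) + 1
    means = pd.DataFrame(0.0, index=tfs, columns=genes)
    for (tf, gene), total in sums.items():
        if gene in means.columns:
            means.at[tf, gene] = total / counts[(tf, gene)]
    pairs = list(pos[["tf", "gene"]].drop_duplicates().itertuples(index=False))
    motif = motif_adjacency(pairs, tfs, genes, mode="binary")
    weights = hic_weight_matrix(means, motif)
    gio.write_matrix_tsv(means, outdir / "mean_contacts.tsv")
    gio.write_matrix_tsv(weights, outdir / "hic_weights.tsv")
    return [outdir / "mean_contacts.tsv", outdir / "hic_weights.tsv"]


def stage_fit(config: dict, outdir: Path) -> list[Path]:
    expr = gio.read_matrix_tsv(outdir / "expression.tsv")
    if str(config["features"]) == "affinity":
        feats = gio.read_matrix_tsv(outdir / "affinity.tsv").T
    else:
        edges = pd.read_csv(outdir / "panda_edges.tsv", sep="\t")
        feats = assemble_features(
            edges, sorted(edges.gene.unique()), sorted(edges.tf.unique())
        )
    # gene-level response: per-gene mean log-expression across profiles
    y = expr.mean(axis=0)
    common = [g for g in feats.index if g in y.index]
    feats, y = feats.loc[common], y.loc[common]
    fits, perfs = repeat_fit(
        feats,
        y,
        iterations=int(config["iterations"]),
        base_seed=int(config["seed"]),
        alpha_ratio=float(config["alpha_ratio"]),
        train_frac=float(config["train_frac"]),
        inner_folds=int(config["inner_folds"]),
    )
    pd.DataFrame(
        [(p.iteration_id, p.mse, p.pcc) for p in perfs],
        columns=["iteration", "mse", "pcc"],
    ).to_csv(outdir / "performance.tsv", sep="\t", index=False)
    coef = pd.DataFrame({f.iteration_id: f.coefficients for f in fits}).T.rename_axis("iteration")
    gio.write_matrix_tsv(coef, outdir / "coefficients.tsv")
    return [outdir / "performance.tsv", outdir / "coefficients.tsv"]


def stage_effects(config: dict, outdir: Path) -> list[Path]:
    coef = gio.read_matrix_tsv(outdir / "coefficients.tsv")
    beta = coef.mean(axis=0)
    from .expression import EffectEstimates

    effects = quintile_bins(EffectEstimates(beta_mean=beta))
    effects.to_frame().rename_axis("tf").to_csv(outdir / "effects.tsv", sep="\t")
    return [outdir / "effects.tsv"]


def stage_varscore(config: dict, outdir: Path) -> list[Path]:
    variants = pd.read_csv(outdir / "variants.tsv", sep="\t")
    zscores = pd.read_csv(outdir / "binding_zscores.tsv", sep="\t")
    effects = pd.read_csv(outdir / "effects.tsv", sep="\t").set_index("tf")
    beta_bar = effects["beta_mean"]

    rare = {
        v.key
        for v in filter_rare(
            [
                RareVariant(r.chrom, int(r.pos), r.ref, r.alt, float(r.maf))
                for r in variants.itertuples(index=False)
            ],
            maf_threshold=float(config["maf"]),
        )
    }
    rows = []
    for gene, zdf in zscores.groupby("gene"):
        recs = [
            BindingZScore(
                variant=r.variant,
                tf=r.tf,
                peak=GenomicInterval(r.chrom, int(r.peak_start), int(r.peak_end)),
                zscore=float(r.zscore),
                pvalue=float(r.pvalue),
            )
            for r in zdf.itertuples(index=False)
            if r.variant in rare
        ]
        recs = significant_binding(recs, p_threshold=float(config["qbic_p"]))
        from .variants import variant_gene_scores

        merge = variant_gene_scores(recs, gene, beta_bar, weighted=True)
        aggz = variant_gene_scores(recs, gene, beta_bar, weighted=False)
        for vkey in merge.index:
            rows.append((gene, vkey, merge[vkey], aggz.get(vkey, np.nan)))
    scores = pd.DataFrame(rows, columns=["gene", "variant", "merge", "aggz"])
    # genome-wide [-1, 1] scaling, one scaler per score type
    if len(scores):
        scores["merge_scaled"] = scale_scores(scores["merge"].to_numpy())
        scores["aggz_scaled"] = scale_scores(scores["aggz"].to_numpy())
    scores.to_csv(outdir / "variant_scores.tsv", sep="\t", index=False)
    return [outdir / "variant_scores.tsv"]


def stage_skat(config: dict, outdir: Path) -> list[Path]:
    scores = pd.read_csv(outdir / "variant_scores.tsv", sep="\t")
    geno = gio.read_matrix_tsv(outdir / "genotypes.tsv")
    pheno = gio.read_matrix_tsv(outdir / "phenotypes.tsv")
    covar = gio.read_matrix_tsv(outdir / "covariates.tsv")
    rows = []
    for gene, sdf in scores.groupby("gene"):
        cols = [f"{gene}|{v}" for v in sdf.variant]
        cols = [c for c in cols if c in geno.columns]
        if len(cols) < 2 or gene not in pheno.columns:
            continue
        G = geno[cols]
        for weighting in ("merge_scaled", "aggz_scaled"):
            w = sdf.set_index("variant")[weighting]
            w = w.reindex([c.split("|", 1)[1] for c in cols]).fillna(0.0)
            q, p = skat_test(G, pheno[gene], w, covar)
            rows.append((gene, len(cols), weighting, q, p))
    pd.DataFrame(rows, columns=["gene", "n_variants", "weighting", "Q", "pvalue"]).to_csv(
        outdir / "skat_results.tsv", sep="\t", index=False
    )
    return [outdir / "skat_results.tsv"]


STAGES = {
    "simulate": (stage_simulate, []),
    "regions": (stage_regions, ["annotation.gtf", "ctcf.bed"]),
    "tfbs": (stage_tfbs, ["peaks.bed", "windows.tsv", "expression.tsv"]),
    "grn": (stage_grn, ["positional_tfbs.tsv", "expression.tsv", "ppi.tsv"]),
    "hic": (stage_hic, ["positional_tfbs.tsv", "contacts.tsv"]),
    "fit": (stage_fit, ["expression.tsv"]),
    "effects": (stage_effects, ["coefficients.tsv"]),
    "varscore": (stage_varscore, ["variants.tsv", "binding_zscores.tsv", "effects.tsv"]),
    "skat": (stage_skat, ["variant_scores.tsv", "genotypes.tsv", "phenotypes.tsv"]),
}


def run_stage(name: str, config: dict, outdir: str | Path, force: bool = False) -> list[Path]:
    """Run one pipeline stage; skipped when inputs and parameters are unchanged."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGE_ORDER}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    func, inputs = STAGES[name]
    missing = [f for f in inputs if not (outdir / f).exists()]
    if missing:
        producer = {
            "annotation.gtf": "simulate", "ctcf.bed": "simulate", "peaks.bed": "simulate",
            "expression.tsv": "simulate", "ppi.tsv": "simulate", "contacts.tsv": "simulate",
            "variants.tsv": "simulate", "binding_zscores.tsv": "simulate",
            "genotypes.tsv": "simulate", "phenotypes.tsv": "simulate",
            "windows.tsv": "regions", "positional_tfbs.tsv": "tfbs",
            "coefficients.tsv": "fit", "effects.tsv": "effects",
            "variant_scores.tsv": "varscore", "hic_weights.tsv": "hic",
        }
        raise FileNotFoundError(
            f"stage {name!r} is missing {missing}; run stage "
            f"{producer.get(missing[0], 'simulate')!r} first"
        )
    if str(config.get("scheme", "none")) in ("DP", "UP") and name == "grn":
        if not (outdir / "hic_weights.tsv").exists():
            raise FileNotFoundError("stage 'grn' with a Hi-C scheme requires stage 'hic' first")
    params = _stage_params(name, config)
    in_hashes = {f: _hash_file(outdir / f) for f in inputs}
    for entry in reversed(_read_manifest(outdir)):
        if (
            not force
            and entry["stage"] == name
            and entry["params"] == json.loads(json.dumps(params))
            and entry["inputs"] == in_hashes
            and all(Path(p).exists() for p in entry["outputs"])
        ):
            logger.info("stage %s: up to date, skipping", name)
            return [Path(p) for p in entry["outputs"]]
    t0 = time.monotonic()
    outputs = func(config, outdir)
    _append_manifest(
        outdir,
        {
            "stage": name,
            "params": params,
            "inputs": in_hashes,
            "outputs": [str(p) for p in outputs],
            "elapsed_s": round(time.monotonic() - t0, 3),
        },
    )
    logger.info("stage %s: done in %.1fs", name, time.monotonic() - t0)
    return outputs


def run_all(config: dict, outdir: str | Path, force: bool = False) -> None:
    """Run every stage in dependency order.

    With a Hi-C scheme configured, the ``hic`` stage runs before ``grn`` so
    the weighted adjacency exists when the GRN is fit; without one, ``hic``
    still runs (its weights are a standalone output) but after ``grn``.
    """
    if str(config.get("scheme", "none")) in ("DP", "UP"):
        order = ["simulate", "regions", "tfbs", "hic", "grn", "fit", "effects", "varscore", "skat"]
    else:
        order = STAGE_ORDER
    for name in order:
        run_stage(name, config, outdir, force=force)
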