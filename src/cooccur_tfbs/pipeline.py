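"""End-to-end orchestration: filter -> merge -> test -> q-values ->
top-N -> scan -> enrich -> co-occur -> summaries.

A run takes a flat configuration (synthetic or real mode), executes
every stage, and writes all stage outputs plus a machine-readable
``summary.json`` and a plain-text log into the run directory.  One
top-level seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so a single integer reproduces the whole
run byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .deg_selection import (
    ExpressionMatrix,
    bh_qvalues,
    dendrogram_newick,
    filter_present,
    merge_probes,
    paired_tests,
    pca_scores,
    sam_statistic,
    select_top_variance,
)
from .enrichment import (
    EnrichmentParams,
    empirical_enrichment,
    find_cooccurrence,
    presence_summary,
    rank_enriched,
)
from .io_formats import (
    read_annotation_tsv,
    read_design_tsv,
    read_expression_tsv,
    read_fasta,
    read_matrices,
    write_fasta,
    write_hits_bed,
    write_matrix,
    write_tsv,
)
from .motif_scan import ScanParams, build_model, scan_geneset
from .synthetic_data import SimulationConfig, simulate_study


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclasses.dataclass
class PipelineConfig:
    mode: str = "synthetic"
    seed: int = 0
    # selection
    q_max: float = 0.05
    top_n: int = 100
    call_threshold: float = 6.0
    call_k: int = 3
    sam_perms: int = 100
    # scanning
    upstream: int = 1500
    downstream: int = 500
    css_min: float = 0.90
    mss_min: float = 0.80
    # enrichment / co-occurrence
    n_resamples: int = 100_000
    statistic: str = "total_hits"
    window: int = 50
    # synthetic-mode study conditions
    n_genes_universe: int = 2000
    n_samples_per_group: int = 3
    n_de: int = 100
    effect: float = 2.0
    noise_sd: float = 0.05
    gc: float = 0.45
    promoter_length: int = 2000
    cluster_span: int = 50
    cluster_fraction: float = 0.70
    n_decoys: int = 20
    # real-mode inputs
    expression_path: Optional[str] = None
    design_path: Optional[str] = None
    annotation_path: Optional[str] = None
    promoters_path: Optional[str] = None
    matrix_paths: Optional[list] = None
    matrix_dialect: str = "jaspar"
    factor_trio: Optional[list] = None
    make_plots: bool = False


_BOUNDS = {
    "q_max": (0.0, 1.0),
    "css_min": (0.0, 1.0),
    "mss_min": (0.0, 1.0),
    "gc": (1e-9, 1.0 - 1e-9),
    "cluster_fraction": (0.0, 1.0),
    "noise_sd": (0.0, float("inf")),
    "effect": (float("-inf"), float("inf")),
    "call_threshold": (float("-inf"), float("inf")),
}
_POSITIVE_INTS = (
    "top_n", "sam_perms", "upstream", "downstream", "n_resamples", "window",
    "n_genes_universe", "n_samples_per_group", "n_de", "promoter_length",
    "cluster_span", "call_k",
)


def validate_config(config: dict) -> PipelineConfig:
    """Fill defaults, reject unknown keys and out-of-range values."""
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(config) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**config)
    if cfg.mode not in ("synthetic", "real"):
        raise ValueError(f"mode must be 'synthetic' or 'real', got {cfg.mode!r}")
    for name in _POSITIVE_INTS:
        v = getattr(cfg, name)
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    for name, (lo, hi) in _BOUNDS.items():
        v = getattr(cfg, name)
        if not lo <= float(v) <= hi:
            raise ValueError(f"{name} out of range [{lo}, {hi}]: {v!r}")
    if cfg.statistic not in ("total_hits", "genes_with_hit"):
        raise ValueError(f"statistic must be total_hits or genes_with_hit, got {cfg.statistic!r}")
    if cfg.mode == "real":
        required = ("expression_path", "design_path", "promoters_path", "matrix_paths")
        for name in required:
            if not getattr(cfg, name):
                raise ValueError(f"real mode requires {name}")
        if not cfg.factor_trio or len(cfg.factor_trio) != 3:
            raise ValueError("real mode requires factor_trio with exactly 3 names")
    return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss]


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full analysis; returns the run directory.

    Every stage's tabular output is written as TSV/BED, the
    configuration is echoed as JSON, and ``summary.json`` collects the
    headline results (selected genes, top enriched factors,
    co-occurrence fraction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    log(f"cooccur-tfbs {__version__} | numpy {np.__version__} | pandas {pd.__version__}")
    log(f"mode={config.mode} seed={config.seed}")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)

    seeds = _child_seeds(config.seed, 3)
    log(f"child seeds: simulate={config.seed} enrichment={seeds[0]} sam={seeds[1]}")
    t0 = time.time()

    truth = None
    annotation = None
    try:
        if config.mode == "synthetic":
            sim = SimulationConfig(
                n_genes_universe=config.n_genes_universe,
                n_samples_per_group=config.n_samples_per_group,
                n_de=config.n_de,
                effect=config.effect,
                noise_sd=config.noise_sd,
                gc=config.gc,
                promoter_length=config.promoter_length,
                cluster_span=config.cluster_span,
                cluster_fraction=config.cluster_fraction,
                seed=config.seed,
            )
            study = simulate_study(sim, n_decoys=config.n_decoys)
            values, design = study["values"], study["design"]
            promoters = study["promoters"]
            matrices = study["factors"] + study["decoys"]
            trio = [m.factor_name for m in study["factors"]]
            truth = study["truth"]
            truth.to_json(outdir / "truth.json")
            write_fasta(promoters, outdir / "promoters.fasta")
            for m in matrices:
                write_matrix(m, outdir / f"matrix_{m.factor_name}.pfm", "jaspar")
            write_tsv(values.rename_axis("gene"), outdir / "expression.tsv",
                      comment="synthetic log2 expression", index=True)
            write_tsv(design.reset_index(), outdir / "design.tsv", comment="sample design")
        else:
            values = read_expression_tsv(config.expression_path)
            design = read_design_tsv(config.design_path)
            promoters = read_fasta(config.promoters_path)
            matrices = read_matrices(config.matrix_paths, config.matrix_dialect)
            trio = list(config.factor_trio)
            if config.annotation_path:
                annotation = read_annotation_tsv(config.annotation_path)
    except Exception as exc:
        raise PipelineError(f"stage=load_inputs: {exc}") from exc

    # ----- selection ------------------------------------------------------
    try:
        em = ExpressionMatrix(values, design)
        em = filter_present(
            em, k=config.call_k, threshold=config.call_threshold, annotation=annotation
        )
        if annotation is not None:
            em = merge_probes(em, annotation)
        p = paired_tests(em).dropna()
        em = ExpressionMatrix(em.values.loc[p.index], em.design)
        q = pd.Series(bh_qvalues(p.to_numpy()), index=p.index, name="q")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selection = select_top_variance(
                em, q, q_max=config.q_max, n=config.top_n, p_values=p
            )
        sel_flag = em.values.index.isin(selection.top_genes)
        write_tsv(
            pd.DataFrame(
                {
                    "gene": em.values.index,
                    "p": p,
                    "q": q,
                    "variance": selection.variance,
                    "selected": sel_flag,
                }
            ),
            outdir / "selection.tsv",
            comment=f"paired test + BH q + variance rank; q_max={config.q_max} top_n={config.top_n}",
        )
        log(
            f"selection: {len(em.values)} genes tested, {len(selection.q_pass)} at q<={config.q_max}, "
            f"{len(selection.top_genes)} selected, variance fraction {selection.variance_fraction:.4f}, "
            f"max p in top {selection.max_p_in_top:.3g}"
        )
    except Exception as exc:
        raise PipelineError(f"stage=selection: {exc}") from exc

    # ----- PCA + SAM verification ----------------------------------------
    try:
        sel_em = ExpressionMatrix(em.values.loc[selection.top_genes], em.design)
        scores, loadings, evr = pca_scores(sel_em)
        write_tsv(scores.rename_axis("sample").reset_index(), outdir / "pca_samples.tsv",
                  comment=f"explained variance ratio: {evr.round(4).tolist()}")
        write_tsv(loadings.rename_axis("gene").reset_index(), outdir / "pca_genes.tsv")
        sam = sam_statistic(em, n_perm=config.sam_perms, seed=seeds[1])
        write_tsv(sam.rename_axis("gene").reset_index(), outdir / "sam.tsv",
                  comment=f"paired SAM, {config.sam_perms} sign-flip permutations")
        sam_confirm = float((sam.loc[selection.top_genes, "q_sam"] <= 0.05).mean()) if selection.top_genes else 0.0
        # with few pairs the sign-flip FDR is floor-limited (2 * 2^-n_pairs),
        # so also verify by rank agreement of |d| with the selected set
        sam_top = set(sam["d"].abs().nlargest(len(selection.top_genes)).index)
        sam_overlap = (
            len(sam_top & set(selection.top_genes)) / len(selection.top_genes)
            if selection.top_genes
            else 0.0
        )
        (outdir / "selected_dendrogram.nwk").write_text(dendrogram_newick(sel_em) + "\n")
        log(f"pca: PC1/PC2 explain {evr[: 2].sum():.3f} of variance; "
            f"sam: {sam_confirm:.3f} of selected at q_sam<=0.05, "
            f"|d|-rank overlap {sam_overlap:.3f}")
        if config.make_plots:
            _plot_pca(scores, em.design, outdir / "pca_samples.png")
    except Exception as exc:
        raise PipelineError(f"stage=pca_sam: {exc}") from exc

    # ----- scanning -------------------------------------------------------
    try:
        models = [build_model(m) for m in matrices]
        params = ScanParams(
            upstream=config.upstream,
            downstream=config.downstream,
            css_min=config.css_min,
            mss_min=config.mss_min,
        )
        scan = scan_geneset(promoters, models, params)
        counts = scan.count_table()
        write_tsv(counts.rename_axis("gene"), outdir / "universe_hit_counts.tsv", index=True)
        hits_by_gene = scan.hits_by_gene()
        sel_hits = [
            h
            for g in selection.top_genes
            if g in promoters
            for h in hits_by_gene.get(g, [])
        ]
        write_hits_bed(sel_hits, promoters, outdir / "selected_hits.bed")
        if scan.skipped_genes:
            log(f"scan: skipped genes without promoters: {scan.skipped_genes[:10]}")
        log(f"scan: {sum(scan.factor_totals().values())} hits over "
            f"{len(scan.genes)} promoters x {len(models)} factors")
    except Exception as exc:
        raise PipelineError(f"stage=scan: {exc}") from exc

    # ----- enrichment -----------------------------------------------------
    try:
        gene_list = [g for g in selection.top_genes if g in counts.index]
        eparams = EnrichmentParams(
            n_resamples=config.n_resamples, statistic=config.statistic, seed=seeds[0]
        )
        enr = empirical_enrichment(gene_list, counts, eparams)
        ranked = rank_enriched(enr, top_k=100)
        write_tsv(ranked, outdir / "enrichment.tsv",
                  comment=f"empirical enrichment, R={config.n_resamples}, statistic={config.statistic}")
        log("enrichment: top factors " + ", ".join(
            f"{r.factor}(p={r.p_emp:.3g})" for r in ranked.head(5).itertuples()))
    except Exception as exc:
        raise PipelineError(f"stage=enrichment: {exc}") from exc

    # ----- co-occurrence --------------------------------------------------
    try:
        sel_hits_by_gene = {g: hits_by_gene.get(g, []) for g in gene_list}
        clusters = find_cooccurrence(
            sel_hits_by_gene, trio, window=config.window, known_factors=scan.factors
        )
        cluster_rows = [
            {
                "gene": c.gene,
                "kind": c.kind,
                "factors": ",".join(c.factors),
                "starts": ",".join(str(h.start) for h in c.members),
                "strands": ",".join(h.strand for h in c.members),
                "span": c.span,
                "min_mss": min(h.mss for h in c.members),
            }
            for c in clusters
        ]
        write_tsv(pd.DataFrame(cluster_rows), outdir / "clusters.tsv",
                  comment=f"co-occurring TFBS clusters, window={config.window} bp, trio={trio}")
        summary_table, fraction = presence_summary(
            [c for c in clusters], gene_list
        )
        write_tsv(summary_table, outdir / "cooccurrence_summary.tsv",
                  comment="per-gene triple presence over the selected list")
        log(f"cooccurrence: {fraction:.3f} of {len(gene_list)} selected genes carry a "
            f"distinct-factor triple within {config.window} bp")
        # universe-wide per-gene triple presence (for recovery diagnostics)
        universe_clusters = find_cooccurrence(
            hits_by_gene, trio, window=config.window, known_factors=scan.factors
        )
        universe_table, universe_fraction = presence_summary(
            universe_clusters, scan.genes
        )
        write_tsv(universe_table, outdir / "cooccurrence_universe.tsv",
                  comment="per-gene triple presence over the whole promoter universe")
    except Exception as exc:
        raise PipelineError(f"stage=cooccurrence: {exc}") from exc

    summary = {
        "mode": config.mode,
        "seed": config.seed,
        "n_genes_tested": int(len(em.values)),
        "n_q_pass": int(len(selection.q_pass)),
        "selected_genes": list(selection.top_genes),
        "variance_fraction": selection.variance_fraction,
        "max_p_in_top": selection.max_p_in_top,
        "pc12_explained": float(np.asarray(evr)[:2].sum()),
        "sam_confirmation_rate": sam_confirm,
        "sam_top_overlap": sam_overlap,
        "factor_trio": trio,
        "top_enriched": ranked.head(10).to_dict(orient="records"),
        "cooccurrence_fraction": fraction,
        "n_selected_with_triple": int(summary_table["has_triple"].sum()),
        "n_selected": len(gene_list),
        "cooccurrence_fraction_universe": universe_fraction,
    }
    if truth is not None:
        recovered = set(selection.top_genes) & truth.de_genes
        union = set(selection.top_genes) | truth.de_genes
        has_triple = dict(
            zip(universe_table["gene"], universe_table["has_triple"].astype(bool))
        )
        cluster = truth.cluster_genes & set(has_triple)
        non_cluster = set(has_triple) - truth.cluster_genes
        summary["truth"] = {
            "n_de": len(truth.de_genes),
            "n_cluster_genes": len(truth.cluster_genes),
            "jaccard_top_vs_de": len(recovered) / len(union) if union else 0.0,
            "triple_sensitivity": (
                sum(has_triple[g] for g in cluster) / len(cluster) if cluster else 0.0
            ),
            "triple_fpr": (
                sum(has_triple[g] for g in non_cluster) / len(non_cluster)
                if non_cluster
                else 0.0
            ),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log(f"done in {time.time() - t0:.1f}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def _plot_pca(scores: pd.DataFrame, design: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, marker in (("control", "o"), ("wounded", "s")):
        idx = design.index[design["group"] == group]
        sub = scores.loc[scores.index.intersection(idx)]
        ax.scatter(sub["PC1"], sub.get("PC2", 0.0), marker=marker, label=group)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
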