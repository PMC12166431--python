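"""End-to-end orchestration: dose response -> correlation predictors ->
differential expression -> signature store -> enrichment -> similarity ->
ranking, with per-stage artifacts, record-count logging and a provenance
block (config hash, seed, versions) in every run directory."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diffexpr, dose_response, enrichment, predictors, ranking, similarity
from .config import PipelineConfig, config_hash
from .signature_store import SignatureStore
from .synthetic import Scenario, write_scenario

logger = logging.getLogger("deathmark")

__all__ = ["PipelineResult", "run_pipeline", "validate_pancancer", "config_for_scenario"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineResult:
    auc_table: pd.DataFrame
    corr_expression: pd.DataFrame
    corr_depscore: pd.DataFrame
    signatures: dict[str, pd.DataFrame]
    consensus: pd.DataFrame | None
    enrichment: pd.DataFrame
    similarity: pd.DataFrame
    predictor_matrix: pd.DataFrame
    best_predictors: pd.DataFrame
    umap_coords: pd.DataFrame | None
    neighbor_lists: dict[str, pd.DataFrame] = field(default_factory=dict)
    candidates_best: list[str] = field(default_factory=list)
    candidates_neighbors: dict[str, list[str]] = field(default_factory=dict)
    text_mining_genes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _write(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage from the declarative config; artifacts land in
    ``config.outdir``. Raises on the failing stage with partial artifacts
    preserved on disk."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    prov = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "deathmark_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": {},
    }

    def log_stage(name: str, **counts) -> None:
        prov["stages"][name] = counts
        logger.info("stage %s: %s", name, counts)

    stage = "dose_response"
    try:
        auc_pieces = []
        for inducer, path in sorted(config.inputs.dose_response.items()):
            long = dose_response.read_dose_response(path)
            mean_tbl, per_rep = dose_response.auc_table(long, inducer)
            _write(per_rep, out / f"auc_per_replicate_{inducer.replace(' ', '_')}.tsv", index=False)
            auc_pieces.append(mean_tbl.set_index("Cell_line"))
        aucs = pd.concat(auc_pieces, axis=1).reset_index()
        _write(aucs, out / "aucs.tsv", index=False)
        inducers = [c for c in aucs.columns if c != "Cell_line"]
        log_stage(stage, cell_lines=len(aucs), inducers=len(inducers))

        stage = "predictors"
        model_map = pd.read_csv(config.inputs.model_map)
        expr = predictors.read_depmap_matrix(config.inputs.expression, model_map)
        dep = predictors.read_depmap_matrix(config.inputs.gene_effect, model_map)
        joined_expr, rep_e = predictors.harmonize_cell_lines(aucs, expr)
        joined_dep, _ = predictors.harmonize_cell_lines(aucs, dep)
        corr_expr = predictors.correlate_auc_to_omics(joined_expr, inducers, source="expression")
        corr_dep = predictors.correlate_auc_to_omics(joined_dep, inducers, source="essentiality")
        _write(corr_expr, out / "correlations_expression.tsv", index=False)
        _write(corr_dep, out / "correlations_depscore.tsv", index=False)
        log_stage(stage, matched_lines=len(rep_e.matched), genes_expr=corr_expr["gene"].nunique(),
                  genes_dep=corr_dep["gene"].nunique())

        stage = "diffexpr"
        counts = pd.read_csv(config.inputs.counts, sep="\t", index_col=0)
        design = pd.read_csv(config.inputs.design)
        logexpr = diffexpr.normalize_log_counts(counts, min_group_size=p.min_cpm_samples)
        signatures = diffexpr.fit_contrasts(logexpr, design)
        de_long = pd.concat(signatures.values(), ignore_index=True)
        _write(de_long, out / "drug_signatures.tsv", index=False)
        log_stage(stage, genes_kept=logexpr.shape[0], genes_in=counts.shape[0], contrasts=len(signatures))

        stage = "consensus"
        consensus = None
        kept_contrasts = list(signatures)
        if len(signatures) >= 2:
            fc = pd.DataFrame({name: frame.set_index("gene")["logFC"] for name, frame in signatures.items()})
            consensus = similarity.consensus_weights(fc, threshold=p.consensus_threshold)
            _write(consensus, out / "consensus_weights.tsv", index=False)
            if p.consensus_filter:
                flagged = set(consensus.loc[consensus["flagged"], "signature"])
                kept_contrasts = [c for c in kept_contrasts if c not in flagged]
                if not kept_contrasts:
                    raise RuntimeError("consensus filter removed every drug signature")
        log_stage(stage, kept=len(kept_contrasts), flagged=len(signatures) - len(kept_contrasts))

        stage = "signature_store"
        gene_info_tbl = pd.read_csv(config.inputs.gene_info, dtype=str)
        gene_info = gene_info_tbl.set_index("gene_id")["symbol"]
        if config.inputs.signatures_format == "gctx":
            store = SignatureStore.from_gctx(config.inputs.signatures, config.inputs.sig_info, gene_info)
        else:
            store = SignatureStore.from_long_tsv(config.inputs.signatures, config.inputs.sig_info, gene_info)
        sig_ids = store.consensus_shrna_ids(time_filter=p.time_filter)
        up_sets, down_sets = store.extract_collections(sig_ids, k=p.k)
        from .signature_store import write_gmt

        write_gmt(up_sets, out / "sets_up.gmt")
        write_gmt(down_sets, out / "sets_down.gmt")
        log_stage(stage, signatures_in=store.matrix.shape[1], consensus_shrna=len(sig_ids))

        stage = "enrichment"
        t_stats = {name: signatures[name].set_index("gene")["t_stat"] for name in kept_contrasts}
        enr = enrichment.enrich_all(t_stats, up_sets, down_sets, rho=p.rho)
        _write(enr, out / "enrichment.tsv", index=False)
        log_stage(stage, records=len(enr))

        stage = "similarity"
        sim = similarity.similarity_table(enr)
        _write(sim, out / "similarity.tsv")
        log_stage(stage, genes=sim.shape[0], perts=sim.shape[1])

        stage = "ranking"
        matrix = predictors.assemble_predictor_matrix(corr_expr, corr_dep, sim)
        _write(matrix, out / "predictor_matrix.tsv")
        best = ranking.best_predictors_rank(matrix, similarity_best=p.similarity_best)
        _write(best, out / "best_predictors.tsv")
        text_genes = ranking.top_genes_by_mean_similarity(sim, n=p.text_mining_n, similarity_best=p.similarity_best)

        citations = None
        if config.inputs.citations:
            client = ranking.OfflineCitationClient(config.inputs.citations)
            terms = p.pubmed_terms or []
            if terms:
                all_query_genes = sorted(set(best.index[: p.top_n]) | set(text_genes))
                citations = ranking.citation_counts(all_query_genes, terms, client)
                _write(citations, out / "citation_counts.tsv", index=False)

        candidates_best = ranking.select_candidates(
            best.index, citations, top_n=p.top_n, max_citations=p.citation_max
        )
        _write_candidates(out / "candidates_best_predictors.tsv", candidates_best, prov)

        umap_coords = None
        neighbor_lists: dict[str, pd.DataFrame] = {}
        candidates_nn: dict[str, list[str]] = {}
        if p.key_genes:
            umap_coords = ranking.embed_predictors(
                matrix, seed=config.seed, min_dist=p.umap_min_dist, n_neighbors=p.umap_n_neighbors
            )
            _write(umap_coords, out / "umap_coordinates.tsv")
            for key in p.key_genes:
                nn = ranking.nearest_neighbors(umap_coords, key, n=p.top_n)
                neighbor_lists[key] = nn
                _write(nn, out / f"neighbors_{key}.tsv", index=False)
                cites_nn = citations
                if config.inputs.citations and p.pubmed_terms:
                    client = ranking.OfflineCitationClient(config.inputs.citations)
                    cites_nn = ranking.citation_counts(nn["gene"], p.pubmed_terms, client)
                cand = ranking.select_candidates(nn["gene"], cites_nn, top_n=p.top_n, max_citations=p.citation_max)
                candidates_nn[key] = cand
                _write_candidates(out / f"candidates_neighbors_{key}.tsv", cand, prov)
        log_stage(stage, genes_ranked=len(best), candidates_best=len(candidates_best))
    except Exception:
        logger.exception("pipeline failed at stage %r (partial artifacts kept in %s)", stage, out)
        raise

    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)

    return PipelineResult(
        auc_table=aucs,
        corr_expression=corr_expr,
        corr_depscore=corr_dep,
        signatures=signatures,
        consensus=consensus,
        enrichment=enr,
        similarity=sim,
        predictor_matrix=matrix,
        best_predictors=best,
        umap_coords=umap_coords,
        neighbor_lists=neighbor_lists,
        candidates_best=candidates_best,
        candidates_neighbors=candidates_nn,
        text_mining_genes=text_genes,
        provenance=prov,
    )


def _write_candidates(path: Path, genes: list[str], prov: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={prov['config_hash']}\tseed={prov['seed']}\tversion={prov['deathmark_version']}\n")
        fh.write("gene\n")
        for g in genes:
            fh.write(f"{g}\n")


def validate_pancancer(
    candidates,
    expression: pd.DataFrame,
    aucs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    model_map: pd.DataFrame | None = None,
):
    """Pan-cancer validation: per-gene mean correlation of expression with the
    drugs' sensitivity AUCs, then a preranked GSEA of the candidate set
    against that correlation ranking. A set of true protectors should be
    enriched in the negative-correlation tail (ES < 0, small p)."""
    joined, _ = predictors.harmonize_cell_lines(aucs, expression, model_map)
    inducers = [c for c in aucs.columns if c != "Cell_line"]
    corr = predictors.correlate_auc_to_omics(joined, inducers, source="expression")
    mean_r = predictors.mean_gene_correlations(corr)
    overlap = [g for g in candidates if g in mean_r.index]
    if not overlap:
        raise ValueError("candidate set has no overlap with the expression gene universe")
    result = enrichment.preranked_gsea(mean_r, overlap, n_perm=n_perm, seed=seed)
    return result, corr


def config_for_scenario(scenario: Scenario, outdir, data_dir=None, **param_overrides) -> PipelineConfig:
    """Write a scenario to disk and return a ready-to-run config for it.

    The first planted suppressor (if any) becomes the nearest-neighbour key
    gene; the manifest's PubMed terms drive the novelty filter.
    """
    data_dir = Path(data_dir) if data_dir is not None else Path(outdir) / "inputs"
    paths = write_scenario(scenario, data_dir)
    m = scenario.manifest
    params = {
        "key_genes": m.planted_suppressors[:1],
        "pubmed_terms": list(m.pubmed_terms),
        "k": m.k,
    }
    params.update(param_overrides)
    return PipelineConfig(
        inputs={
            "dose_response": {ind: paths[f"dose_response:{ind}"] for ind in m.inducers},
            "expression": paths["expression"],
            "gene_effect": paths["gene_effect"],
            "model_map": paths["model_map"],
            "signatures": paths["signatures"],
            "sig_info": paths["sig_info"],
            "gene_info": paths["gene_info"],
            "counts": paths["counts"],
            "design": paths["design"],
            "citations": paths["citations"],
            "signatures_format": "gctx",
        },
        params=params,
        seed=m.seed,
        outdir=str(outdir),
    )
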