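"""Synthetic study generator with planted ground truth.

Emulates the four input classes the pipeline consumes — dose-response
viability tables, DepMap-style cell-line omics, a knockdown signature store
with metadata, and drug-vs-vehicle RNA-seq counts — with a set of *planted
suppressor* genes whose evidence is coupled across all three channels:

* expression and CRISPR gene effect decrease with the cell lines' sensitivity
  AUC (negative Pearson r, the correlation arm);
* their knockdown signatures are concordant with the latent drug-response
  direction (the transcriptomic-similarity arm).

Partial-evidence decoys carry only one of the two arms (correlation-only and
signature-only) and exercise the aggregation. Background genes are
independent noise. Everything is drawn from one master seed through spawned
child generators, so a manifest determines every emitted file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signature_store import write_gctx

__all__ = ["ScenarioManifest", "Scenario", "null_manifest", "generate_scenario", "write_scenario"]


@dataclass
class ScenarioManifest:
    """Study conditions; the defaults are the default scenario used by the
    acceptance checks (2000 genes, 20 cell lines, 500 knockdowns, 10 planted
    suppressors)."""

    seed: int = 42
    n_genes: int = 2000
    n_cell_lines: int = 20
    n_knockdowns: int = 500
    n_planted: int = 10
    n_corr_decoys: int = 10
    n_signature_decoys: int = 10
    inducers: tuple[str, ...] = ("inducer 1", "inducer 2")
    n_signature_cell_lines: int = 2  # cell lines profiled by RNA-seq
    n_reps: int = 3
    n_doses: int = 8
    dose_min: float = 5e-8
    dose_max: float = 2e-5
    viability_sigma: float = 3.0  # percent-of-control noise on viability
    corr_strength: float = 1.5  # log-TPM drop per SD of sensitivity AUC (planted)
    expr_noise: float = 0.4
    dep_strength: float = 0.25  # gene-effect drop per SD of AUC (planted)
    dep_noise: float = 0.1
    rho_sig: float = 0.8  # knockdown-signature concordance with the drug direction
    drug_effect: float = 1.0  # log2FC scale of the latent direction in counts
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    min_store_cells: int = 4
    max_store_cells: int = 9
    k: int = 20
    pubmed_terms: tuple[str, ...] = ("cell death", "oxidative stress")
    n_cited_decoys: int = 10
    planted_suppressors: list[str] = field(default_factory=list)  # filled by generate_scenario
    corr_decoys: list[str] = field(default_factory=list)
    signature_decoys: list[str] = field(default_factory=list)


def null_manifest(seed: int = 42) -> ScenarioManifest:
    """Same sizes as the default scenario but nothing planted: no correlated
    genes, no concordant knockdown signatures."""
    return ScenarioManifest(
        seed=seed,
        n_planted=0,
        n_corr_decoys=0,
        n_signature_decoys=0,
        corr_strength=0.0,
        dep_strength=0.0,
        rho_sig=0.0,
        n_cited_decoys=0,
    )


@dataclass
class Scenario:
    manifest: ScenarioManifest
    genes: list[str]
    gene_ids: list[str]  # numeric ids, matched 1:1 to symbols
    cell_lines: list[str]
    model_map: pd.DataFrame  # model_id, cell_line_name
    dose_response: dict[str, pd.DataFrame]  # inducer -> wide Table-1 style frame
    true_parameters: pd.DataFrame  # cell_line, inducer, slope, ec50_log, auc_true
    true_auc: pd.DataFrame  # Cell_line + one column per inducer (noise-free)
    expression: pd.DataFrame  # model_id x "SYMBOL (entrez)" columns
    gene_effect: pd.DataFrame
    signature_matrix: pd.DataFrame  # gene_id x sig_id
    signature_meta: pd.DataFrame
    gene_info: pd.Series  # gene_id -> symbol
    counts: pd.DataFrame  # gene symbol x sample
    design: pd.DataFrame  # sample, cell_line, condition, replicate
    latent_directions: pd.DataFrame  # gene x inducer latent drug-response direction
    knockdown_genes: list[str]
    citations: dict[str, dict[str, int]]


def _fourpl(x: np.ndarray, b: float, e: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp(b * (x - e)))


def generate_scenario(manifest: ScenarioManifest | None = None) -> Scenario:
    m = dataclasses.replace(manifest) if manifest is not None else ScenarioManifest()
    streams = np.random.SeedSequence(m.seed).spawn(8)
    rng_plant, rng_drc, rng_omics, rng_latent, rng_store, rng_counts, rng_cells, rng_cite = (
        np.random.default_rng(s) for s in streams
    )

    genes = [f"GEN{i:04d}" for i in range(m.n_genes)]
    gene_ids = [str(10000 + i) for i in range(m.n_genes)]
    gene_info = pd.Series(genes, index=pd.Index(gene_ids, name="gene_id"), name="symbol")
    cell_lines = [f"CL{i:02d}" for i in range(1, m.n_cell_lines + 1)]
    model_map = pd.DataFrame(
        {"model_id": [f"ACH-{i:06d}" for i in range(1, m.n_cell_lines + 1)], "cell_line_name": cell_lines}
    )

    # --- role assignment -------------------------------------------------
    n_special = m.n_planted + m.n_corr_decoys + m.n_signature_decoys
    special = rng_plant.choice(m.n_genes, size=n_special, replace=False)
    planted = sorted(genes[i] for i in special[: m.n_planted])
    corr_decoys = sorted(genes[i] for i in special[m.n_planted : m.n_planted + m.n_corr_decoys])
    sig_decoys = sorted(genes[i] for i in special[m.n_planted + m.n_corr_decoys :])
    m.planted_suppressors, m.corr_decoys, m.signature_decoys = planted, corr_decoys, sig_decoys

    remaining = [g for g in genes if g not in set(planted) | set(corr_decoys) | set(sig_decoys)]
    n_bg_kd = m.n_knockdowns - m.n_planted - m.n_corr_decoys - m.n_signature_decoys
    bg_kd = sorted(rng_plant.choice(remaining, size=n_bg_kd, replace=False).tolist())
    knockdown_genes = sorted(planted + corr_decoys + sig_decoys + bg_kd)

    # --- dose response ---------------------------------------------------
    doses = np.geomspace(m.dose_min, m.dose_max, m.n_doses)
    log_doses = np.log10(doses)
    # one latent sensitivity per cell line drives the EC50 of every inducer:
    # inducers of the same death pathway have concordant potency profiles
    latent_sens = {cell: rng_drc.normal(0.0, 1.0) for cell in cell_lines}
    mid_log = float(np.median(log_doses))
    drc_tables: dict[str, pd.DataFrame] = {}
    true_rows = []
    for inducer in m.inducers:
        rows = []
        for cell in cell_lines:
            b = rng_drc.uniform(0.8, 2.5)
            e = mid_log - 0.35 * latent_sens[cell] + rng_drc.normal(0.0, 0.08)
            e = float(np.clip(e, log_doses[1], log_doses[-2]))
            clean = _fourpl(log_doses, b, e)
            auc_true = 100.0 - np.trapezoid(clean, log_doses) / (log_doses[-1] - log_doses[0])
            true_rows.append(
                {"cell_line": cell, "inducer": inducer, "slope": b, "ec50_log": e, "auc_true": auc_true}
            )
            reps = {
                f"Repeat_{r + 1}": np.maximum(clean + rng_drc.normal(0.0, m.viability_sigma, size=clean.size), 0.0)
                for r in range(m.n_reps)
            }
            rows.append(
                pd.DataFrame({"Cell_line": cell, "Concentration": doses, "logConc": log_doses, **reps})
            )
        drc_tables[inducer] = pd.concat(rows, ignore_index=True)
    true_parameters = pd.DataFrame(true_rows)
    true_auc = (
        true_parameters.pivot(index="cell_line", columns="inducer", values="auc_true")
        .reset_index()
        .rename(columns={"cell_line": "Cell_line"})
    )
    true_auc.columns.name = None

    # --- omics matrices --------------------------------------------------
    auc_mean = true_parameters.groupby("cell_line")["auc_true"].mean().loc[cell_lines].to_numpy()
    auc_z = (auc_mean - auc_mean.mean()) / auc_mean.std(ddof=0)

    expr = rng_omics.normal(5.0, 1.0, size=(m.n_cell_lines, m.n_genes))
    dep = rng_omics.normal(-0.1, 0.15, size=(m.n_cell_lines, m.n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in planted + corr_decoys:
        j = gene_pos[g]
        expr[:, j] = 5.0 - m.corr_strength * auc_z + rng_omics.normal(0.0, m.expr_noise, size=m.n_cell_lines)
        dep[:, j] = -0.3 - m.dep_strength * auc_z + rng_omics.normal(0.0, m.dep_noise, size=m.n_cell_lines)
    dep = np.clip(dep, -1.5, 0.5)
    depmap_cols = [f"{g} ({gid})" for g, gid in zip(genes, gene_ids)]
    expression = pd.DataFrame(expr, index=pd.Index(model_map["model_id"], name="model_id"), columns=depmap_cols)
    gene_effect = pd.DataFrame(dep, index=pd.Index(model_map["model_id"], name="model_id"), columns=depmap_cols)

    # --- latent drug-response directions ---------------------------------
    latent = pd.DataFrame(
        rng_latent.normal(0.0, 1.0, size=(m.n_genes, len(m.inducers))), index=genes, columns=list(m.inducers)
    )
    dbar = latent.mean(axis=1).to_numpy()
    dbar = dbar / dbar.std(ddof=0)  # unit-variance consensus direction

    # --- knockdown signature store ---------------------------------------
    store_cells = [f"KC{i:02d}" for i in range(1, m.max_store_cells + 1)]
    concordant = set(planted) | set(sig_decoys)
    sig_cols: list[np.ndarray] = []
    sig_ids: list[str] = []
    meta_rows: list[dict] = []
    noise_scale = float(np.sqrt(max(0.0, 1.0 - m.rho_sig**2)))
    for idx, g in enumerate(knockdown_genes, start=1):
        n_cells = int(rng_cells.integers(m.min_store_cells, m.max_store_cells + 1))
        chosen = rng_cells.choice(store_cells, size=n_cells, replace=False)
        for cell in sorted(chosen):
            if g in concordant:
                col = m.rho_sig * dbar + noise_scale * rng_store.normal(0.0, 1.0, size=m.n_genes)
            else:
                col = rng_store.normal(0.0, 1.0, size=m.n_genes)
            sig_id = f"CGS{idx:04d}_{cell}_{g}:96H"
            sig_cols.append(col)
            sig_ids.append(sig_id)
            meta_rows.append(
                {"sig_id": sig_id, "pert_type": "trt_sh.cgs", "pert_gene": g, "cell": cell, "time": "96H"}
            )
    # distractors the metadata filter must exclude: other perturbation types
    # and consensus shRNA measured at a different timepoint
    distract_genes = rng_cells.choice(knockdown_genes, size=6, replace=False)
    for i, g in enumerate(distract_genes):
        if i < 3:
            ptype, time_label = ("trt_oe", "96H")
        else:
            ptype, time_label = ("trt_sh.cgs", "120H")
        sig_id = f"CGS{9000 + i:04d}_{store_cells[0]}_{g}:{time_label}"
        sig_cols.append(rng_store.normal(0.0, 1.0, size=m.n_genes))
        sig_ids.append(sig_id)
        meta_rows.append({"sig_id": sig_id, "pert_type": ptype, "pert_gene": g, "cell": store_cells[0], "time": time_label})
    signature_matrix = pd.DataFrame(
        np.column_stack(sig_cols), index=pd.Index(gene_ids, name="gene_id"), columns=sig_ids
    )
    signature_meta = pd.DataFrame(meta_rows)

    # --- RNA-seq counts ---------------------------------------------------
    sc_lines = cell_lines[: m.n_signature_cell_lines]
    baseline = rng_counts.normal(m.baseline_log2_mean, m.baseline_log2_sd, size=m.n_genes)
    samples, design_rows, count_cols = [], [], []
    r_nb = 1.0 / m.nb_dispersion
    for cell in sc_lines:
        cell_shift = rng_counts.normal(0.0, 0.1, size=m.n_genes)
        for cond in ("vehicle", *m.inducers):
            effect = 0.0 if cond == "vehicle" else m.drug_effect * latent[cond].to_numpy()
            mu = np.power(2.0, baseline + cell_shift + effect)
            for rep in range(1, m.n_reps + 1):
                sample = f"{cell}_{cond.replace(' ', '')}_{rep}"
                p = r_nb / (r_nb + mu)
                count_cols.append(rng_counts.negative_binomial(r_nb, p))
                samples.append(sample)
                design_rows.append({"sample": sample, "cell_line": cell, "condition": cond, "replicate": rep})
    counts = pd.DataFrame(
        np.column_stack(count_cols), index=pd.Index(genes, name="gene"), columns=samples
    )
    design = pd.DataFrame(design_rows)

    # --- citation fixture -------------------------------------------------
    citations: dict[str, dict[str, int]] = {g: {t: 0 for t in m.pubmed_terms} for g in knockdown_genes}
    if m.n_cited_decoys > 0:
        cited = rng_cite.choice(bg_kd, size=min(m.n_cited_decoys, len(bg_kd)), replace=False)
        for g in cited:
            for t in m.pubmed_terms:
                citations[g][t] = int(rng_cite.integers(1, 60))

    return Scenario(
        manifest=m,
        genes=genes,
        gene_ids=gene_ids,
        cell_lines=cell_lines,
        model_map=model_map,
        dose_response=drc_tables,
        true_parameters=true_parameters,
        true_auc=true_auc,
        expression=expression,
        gene_effect=gene_effect,
        signature_matrix=signature_matrix,
        signature_meta=signature_meta,
        gene_info=gene_info,
        counts=counts,
        design=design,
        latent_directions=latent,
        knockdown_genes=knockdown_genes,
        citations=citations,
    )


def write_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Emit every file the pipeline reads; returns {role: path}.

    All text outputs use a fixed float format so a manifest reproduces the
    files byte for byte. The signature store is written as GCTX (HDF5 with
    timestamp tracking disabled, so it too is reproducible).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    fmt = "%.10g"

    for inducer, table in scenario.dose_response.items():
        p = out / f"dose_response_{inducer.replace(' ', '_')}.csv"
        table.to_csv(p, index=False, float_format=fmt)
        paths[f"dose_response:{inducer}"] = str(p)

    for name, frame in (("expression", scenario.expression), ("gene_effect", scenario.gene_effect)):
        p = out / f"{name}.csv"
        frame.to_csv(p, float_format=fmt)
        paths[name] = str(p)
    p = out / "model_map.csv"
    scenario.model_map.to_csv(p, index=False)
    paths["model_map"] = str(p)

    p = out / "signatures.gctx"
    write_gctx(scenario.signature_matrix, p)
    paths["signatures"] = str(p)
    p = out / "sig_info.tsv"
    scenario.signature_meta.to_csv(p, sep="\t", index=False)
    paths["sig_info"] = str(p)
    p = out / "gene_info.csv"
    scenario.gene_info.rename_axis("gene_id").reset_index().to_csv(p, index=False)
    paths["gene_info"] = str(p)

    p = out / "counts.tsv"
    scenario.counts.to_csv(p, sep="\t")
    paths["counts"] = str(p)
    p = out / "design.csv"
    scenario.design.to_csv(p, index=False)
    paths["design"] = str(p)

    p = out / "citations.json"
    with open(p, "w") as fh:
        json.dump(scenario.citations, fh, indent=0, sort_keys=True)
    paths["citations"] = str(p)

    p = out / "manifest.json"
    manifest_dict = dataclasses.asdict(scenario.manifest)
    manifest_dict["files"] = {k: str(Path(v).name) for k, v in paths.items()}
    with open(p, "w") as fh:
        json.dump(manifest_dict, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(p)
    return paths
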