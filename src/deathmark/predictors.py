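"""Correlation predictors: join sensitivity AUCs to cell-line omics and
compute per-gene Pearson correlations.

Two omics sources are supported with the same code path: expression
(log-scaled TPM-like values, one column per gene) and CRISPR gene effect
("depscore", ~0 for non-essential genes, ~-1 for essential ones). A negative
correlation between a gene's expression (or essentiality) and the drugs'
sensitivity AUCs marks the gene as a candidate protector against the drug.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HarmonizeReport",
    "read_depmap_matrix",
    "harmonize_cell_lines",
    "correlate_auc_to_omics",
    "mean_gene_correlations",
    "assemble_predictor_matrix",
]

_ENTREZ_SUFFIX = re.compile(r"\s*\(\d+\)$")


def read_depmap_matrix(path, model_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a DepMap-style CSV (rows keyed by model id, genes in columns).

    Column headers of the form ``"SYMBOL (entrez)"`` are stripped to the bare
    symbol. If *model_map* is given the index is translated from model ids to
    cell-line names immediately.
    """
    mat = pd.read_csv(path, index_col=0)
    mat.columns = [_ENTREZ_SUFFIX.sub("", c) for c in mat.columns]
    if mat.columns.duplicated().any():
        dupes = mat.columns[mat.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols after header stripping: {dupes[:5]}")
    if model_map is not None:
        mapping = dict(zip(model_map["model_id"], model_map["cell_line_name"]))
        mat.index = [mapping.get(i, i) for i in mat.index]
    return mat


@dataclass
class HarmonizeReport:
    matched: list[str]
    unmatched_auc: list[str]
    unmatched_omics: list[str]


def harmonize_cell_lines(
    aucs: pd.DataFrame,
    omics: pd.DataFrame,
    model_map: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Inner-join the AUC table (Cell_line + inducer columns) with an omics
    matrix (cell lines in rows, genes in columns).

    The omics index may be model ids; *model_map* (columns ``model_id``,
    ``cell_line_name``) translates them. Returns the joined frame (cell lines
    in rows: AUC columns then gene columns) and a report of unmatched names.
    Raises if the intersection is empty, listing near-miss names.
    """
    omics = omics.copy()
    if model_map is not None:
        mapping = dict(zip(model_map["model_id"], model_map["cell_line_name"]))
        omics.index = [mapping.get(i, i) for i in omics.index]
    auc_lines = list(aucs["Cell_line"])
    shared = [c for c in auc_lines if c in set(omics.index)]
    unmatched_auc = [c for c in auc_lines if c not in set(omics.index)]
    unmatched_omics = [c for c in omics.index if c not in set(auc_lines)]
    if not shared:
        import difflib

        hints = {
            name: difflib.get_close_matches(name, list(map(str, omics.index)), n=2)
            for name in auc_lines[:10]
        }
        raise ValueError(f"no cell lines shared between AUC table and omics; near misses: {hints}")
    if unmatched_auc:
        warnings.warn(f"{len(unmatched_auc)} AUC cell line(s) not in omics: {unmatched_auc}", stacklevel=2)
    joined = aucs.set_index("Cell_line").loc[shared].join(omics.loc[shared])
    report = HarmonizeReport(matched=shared, unmatched_auc=unmatched_auc, unmatched_omics=unmatched_omics)
    return joined, report


def _pairwise_pearson(x: np.ndarray, genes: np.ndarray, auc: np.ndarray, min_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of x against auc on pairwise-complete rows.

    Returns (gene subset, r); genes with < min_pairs complete pairs or zero
    variance on the complete rows are omitted.
    """
    finite = np.isfinite(x)
    auc_f = np.isfinite(auc)
    rs = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        m = finite[:, j] & auc_f
        if m.sum() < min_pairs:
            continue
        xv, av = x[m, j], auc[m]
        sx, sa = xv.std(), av.std()
        if sx == 0 or sa == 0:
            continue
        rs[j] = np.corrcoef(xv, av)[0, 1]
    keep = np.isfinite(rs)
    return genes[keep], rs[keep]


def correlate_auc_to_omics(
    joined: pd.DataFrame,
    inducers: list[str],
    source: str,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Per-gene Pearson correlation to each inducer's AUC.

    *joined* is the output of :func:`harmonize_cell_lines`; *inducers* names
    its AUC columns, every other column is a gene. Pairwise-complete
    observations per gene; genes with fewer than *min_pairs* complete pairs or
    zero variance are omitted (not errored). Returns a long frame
    (gene, inducer, r, source).
    """
    gene_cols = [c for c in joined.columns if c not in inducers]
    x = joined[gene_cols].to_numpy(dtype=float)
    genes = np.asarray(gene_cols)
    frames = []
    for ind in inducers:
        auc = joined[ind].to_numpy(dtype=float)
        g, r = _pairwise_pearson(x, genes, auc, min_pairs)
        frames.append(pd.DataFrame({"gene": g, "inducer": ind, "r": r, "source": source}))
    return pd.concat(frames, ignore_index=True)


def mean_gene_correlations(corr: pd.DataFrame) -> pd.Series:
    """Mean r per gene across inducers (used by the pan-cancer validation)."""
    return corr.groupby("gene")["r"].mean()


def assemble_predictor_matrix(
    corr_expression: pd.DataFrame,
    corr_depscore: pd.DataFrame,
    similarity: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full outer join of the correlation and similarity predictors.

    One row per gene; columns named ``"<inducer> AUC cor to expression"``,
    ``"<inducer> AUC cor to depscore"`` and
    ``"Transcriptomic similarity to <pert>"`` (the wide similarity table's
    columns are the perturbation labels). Duplicate gene symbols are an error.
    """
    pieces = []
    for corr, label in ((corr_expression, "AUC cor to expression"), (corr_depscore, "AUC cor to depscore")):
        wide = corr.pivot(index="gene", columns="inducer", values="r")
        wide.columns = [f"{ind} {label}" for ind in wide.columns]
        pieces.append(wide)
    if similarity is not None:
        sim = similarity.copy()
        if sim.index.name != "gene" and "gene" in sim.columns:
            sim = sim.set_index("gene")
        sim.columns = [f"Transcriptomic similarity to {p}" for p in sim.columns]
        pieces.append(sim)
    for piece in pieces:
        if piece.index.duplicated().any():
            raise ValueError("duplicate gene symbols in a predictor block")
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.join(piece, how="outer")
    out.index.name = "gene"
    return out
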