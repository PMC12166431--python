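"""Aggregation of enrichment scores into one transcriptomic-similarity value
per knockdown gene per drug signature, plus consensus weights for flagging
outlier drug signatures.

For each knockdown gene the public store holds signatures in 4-9 cell lines.
Per drug signature the scores are aggregated by taking the maximum over cell
lines (separately for the up and the down gene-set score), both aggregates
are competition-ranked across all knockdown genes (ascending, rank 1 = lowest
score), and the final similarity is

    total = rank(up score) - rank(down score)

bounded by +/-(N - 1) for N knockdown genes. A gene whose silencing mimics
the drug's transcriptomic response has a strongly Up-enriched up-set and a
strongly Down-enriched down-set, hence a large positive total under the
default polarity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "max_over_cells",
    "competition_rank",
    "combine_up_down",
    "similarity_table",
    "consensus_weights",
]


def max_over_cells(long_scores: pd.DataFrame) -> pd.DataFrame:
    """Maximum signed score over cell lines per (gene, pert, direction).

    Input is the long enrichment table (columns gene, cell, pert, direction,
    signed_score); missing cell lines simply do not contribute.
    """
    return (
        long_scores.groupby(["gene", "pert", "direction"], sort=True)["signed_score"]
        .max()
        .reset_index()
    )


def competition_rank(values) -> np.ndarray:
    """Ascending competition ("min") ranks: ties share the smallest rank of
    their block; 1 = lowest value."""
    return rankdata(np.asarray(values, dtype=float), method="min").astype(int)


def combine_up_down(rank_up: pd.Series, rank_down: pd.Series) -> pd.Series:
    """total = rank_up - rank_down on the shared gene index.

    Genes missing either direction are excluded with a warning.
    """
    shared = rank_up.index.intersection(rank_down.index)
    dropped = rank_up.index.symmetric_difference(rank_down.index)
    if len(dropped):
        warnings.warn(f"{len(dropped)} gene(s) missing one direction; excluded", stacklevel=2)
    return (rank_up.loc[shared] - rank_down.loc[shared]).astype(int)


def similarity_table(long_scores: pd.DataFrame) -> pd.DataFrame:
    """Full aggregation: max over cells, rank per direction, up - down.

    Returns a wide frame (genes in rows, one integer column per drug
    signature / pert).
    """
    agg = max_over_cells(long_scores)
    out: dict[str, pd.Series] = {}
    for pert, grp in agg.groupby("pert", sort=True):
        wide = grp.pivot(index="gene", columns="direction", values="signed_score")
        for d in ("up", "down"):
            if d not in wide.columns:
                wide[d] = np.nan
        complete = wide.dropna(subset=["up", "down"])
        if len(complete) < len(wide):
            warnings.warn(
                f"{len(wide) - len(complete)} gene(s) missing one direction for {pert!r}; excluded",
                stacklevel=2,
            )
        r_up = pd.Series(competition_rank(complete["up"]), index=complete.index)
        r_down = pd.Series(competition_rank(complete["down"]), index=complete.index)
        out[pert] = combine_up_down(r_up, r_down)
    table = pd.DataFrame(out)
    table.index.name = "gene"
    return table


def consensus_weights(fold_changes: pd.DataFrame, threshold: float = 9.0) -> pd.DataFrame:
    """Consensus weight per drug signature from pairwise fold-change Pearson.

    Self-correlations and negative correlations contribute zero; each
    signature's weight is its row sum as a percentage of the grand total
    (weights sum to 100). Signatures with weight below *threshold* are
    flagged as outliers. A constant fold-change vector is an error naming
    the offending signature.
    """
    if fold_changes.shape[1] < 2:
        raise ValueError("need >= 2 signatures for consensus weights")
    clean = fold_changes.dropna()
    if len(clean) < 3:
        raise ValueError("need >= 3 genes with complete fold changes")
    sds = clean.std(ddof=1)
    if (sds == 0).any():
        bad = sds.index[sds == 0].tolist()
        raise ValueError(f"constant fold-change vector(s): {bad}")
    corr = np.corrcoef(clean.to_numpy(dtype=float), rowvar=False)
    np.fill_diagonal(corr, 0.0)
    corr[corr < 0] = 0.0
    sums = corr.sum(axis=1)
    grand = sums.sum()
    if grand == 0:
        raise ValueError("all pairwise correlations are non-positive; consensus undefined")
    weights = sums / grand * 100.0
    return pd.DataFrame(
        {
            "signature": clean.columns,
            "weight": weights,
            "flagged": weights < threshold,
        }
    ).reset_index(drop=True)
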