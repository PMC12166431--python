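"""Final candidate ranking: best-predictors aggregation, 2-D embedding with
nearest-neighbour ranking around a key gene, PCA/k-means fallback, and
PubMed-citation novelty filtering.

Rank orientation. Every per-family competition rank is oriented so that the
strongest candidate receives the HIGHEST rank: for the correlation families
"stronger" means a more negative mean Pearson r (high expression or
essentiality of a protective gene tracks resistance, i.e. low sensitivity
AUC); for the similarity family it is governed by ``similarity_best``
("positive" by default: silencing a true protector mimics the drug response,
giving a large positive rank-difference total). With this orientation the
elementwise max of the two correlation ranks picks the better of the two
correlation arms, and the top of the final ranking is simply the genes with
the highest ``rank_total``.
"""

from __future__ import annotations

import difflib
import json
import time
import warnings

import numpy as np
import pandas as pd

from .similarity import competition_rank

__all__ = [
    "split_predictor_columns",
    "best_predictors_rank",
    "top_genes_by_mean_similarity",
    "embed_predictors",
    "nearest_neighbors",
    "pca_kmeans_fallback",
    "OfflineCitationClient",
    "EntrezCitationClient",
    "citation_counts",
    "select_candidates",
]

EXPRESSION_TAG = "AUC cor to expression"
DEPSCORE_TAG = "AUC cor to depscore"
SIMILARITY_TAG = "Transcriptomic similarity"


def split_predictor_columns(matrix: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    expr = [c for c in matrix.columns if EXPRESSION_TAG in c]
    dep = [c for c in matrix.columns if DEPSCORE_TAG in c]
    sim = [c for c in matrix.columns if SIMILARITY_TAG.lower() in c.lower()]
    return expr, dep, sim


def best_predictors_rank(matrix: pd.DataFrame, similarity_best: str = "positive") -> pd.DataFrame:
    """Aggregate the predictor matrix into one competition rank per gene.

    Steps: family row-means (expression correlations, depscore correlations,
    similarity totals); competition rank of each family mean (strongest =
    highest, see module docstring); rank_corr = elementwise max of the two
    correlation ranks; mean_rank = (rank_corr + rank_similarity) / 2;
    rank_total = competition rank of mean_rank. Genes with no similarity
    value are dropped before ranking. The result is sorted strongest first.
    ``biggest_r`` (the larger of the two mean correlations) is reported but
    not used for ranking.
    """
    if similarity_best not in ("positive", "negative"):
        raise ValueError("similarity_best must be 'positive' or 'negative'")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene symbols in predictor matrix")
    expr_cols, dep_cols, sim_cols = split_predictor_columns(matrix)
    for cols, fam in ((expr_cols, EXPRESSION_TAG), (dep_cols, DEPSCORE_TAG), (sim_cols, SIMILARITY_TAG)):
        if not cols:
            raise ValueError(f"predictor matrix has no '{fam}' columns")
    out = pd.DataFrame(index=matrix.index)
    out["mean_r_expression"] = matrix[expr_cols].mean(axis=1)
    out["mean_r_depscore"] = matrix[dep_cols].mean(axis=1)
    out["biggest_r"] = out[["mean_r_expression", "mean_r_depscore"]].max(axis=1)
    out["mean_similarity"] = matrix[sim_cols].mean(axis=1)
    out = out.dropna(subset=["mean_similarity"])
    if out[["mean_r_expression", "mean_r_depscore"]].isna().all().any():
        raise ValueError("a correlation family is entirely missing after filtering")
    out = out.dropna(subset=["mean_r_expression", "mean_r_depscore"])

    # strongest candidate -> highest rank in every family
    rank_expr = competition_rank(-out["mean_r_expression"].to_numpy())
    rank_dep = competition_rank(-out["mean_r_depscore"].to_numpy())
    sim_sign = 1.0 if similarity_best == "positive" else -1.0
    rank_sim = competition_rank(sim_sign * out["mean_similarity"].to_numpy())
    out["rank_corr_expression"] = rank_expr
    out["rank_corr_depscore"] = rank_dep
    out["rank_corr"] = np.maximum(rank_expr, rank_dep)
    out["rank_similarity"] = rank_sim
    out["mean_rank"] = (out["rank_corr"] + out["rank_similarity"]) / 2.0
    out["rank_total"] = competition_rank(out["mean_rank"].to_numpy())
    out.index.name = "gene"
    out = (
        out.reset_index()
        .sort_values(["rank_total", "mean_rank", "gene"], ascending=[False, False, True], kind="mergesort")
        .set_index("gene")
    )
    return out


def top_genes_by_mean_similarity(
    similarity: pd.DataFrame, n: int = 100, similarity_best: str = "positive"
) -> list[str]:
    """Genes with the strongest mean similarity total across drug signatures
    (default 100; feeds the text-mining validation)."""
    means = similarity.mean(axis=1)
    ascending = similarity_best == "negative"
    order = means.sort_values(ascending=ascending, kind="mergesort")
    return order.head(n).index.tolist()


def _standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    complete = matrix.dropna().sort_index()
    sds = complete.std(ddof=1)
    keep = sds[sds > 0].index
    return (complete[keep] - complete[keep].mean()) / complete[keep].std(ddof=1)


def embed_predictors(
    matrix: pd.DataFrame,
    seed: int = 5023,
    min_dist: float = 0.05,
    n_neighbors: int = 15,
) -> pd.DataFrame:
    """UMAP embedding of the standardized predictor matrix.

    Rows with any missing predictor are dropped and the rest sorted by gene so
    the embedding is reproducible at a fixed seed regardless of input order;
    columns are standardized to zero mean, unit variance. Returns a frame
    indexed by gene with columns x, y.
    """
    z = _standardize(matrix)
    if len(z) < 15:
        raise ValueError(
            f"only {len(z)} complete rows; too few for a UMAP embedding - consider pca_kmeans_fallback"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2,
        random_state=int(seed),
        min_dist=min_dist,
        n_neighbors=n_neighbors,
    )
    coords = reducer.fit_transform(z.to_numpy(dtype=np.float32))
    out = pd.DataFrame(coords, index=z.index, columns=["x", "y"])
    out.index.name = "gene"
    return out


def nearest_neighbors(coords: pd.DataFrame, key_gene: str, n: int = 75) -> pd.DataFrame:
    """Genes ordered by Euclidean distance to *key_gene* in the embedding.

    Returns at least *n* genes (ties at the cutoff distance are all kept,
    matching slice_min semantics); the key gene itself is first with distance
    0. Unknown key genes raise with close symbol suggestions.
    """
    if key_gene not in coords.index:
        hints = difflib.get_close_matches(key_gene, [str(g) for g in coords.index], n=3)
        raise KeyError(f"key gene {key_gene!r} not in embedding; close matches: {hints}")
    delta = coords[["x", "y"]].to_numpy(dtype=float) - coords.loc[key_gene, ["x", "y"]].to_numpy(dtype=float)
    dist = np.sqrt((delta**2).sum(axis=1))
    frame = pd.DataFrame({"gene": coords.index, "distance": dist})
    frame = frame.sort_values(["distance", "gene"], kind="mergesort").reset_index(drop=True)
    if len(frame) > n:
        cutoff = frame["distance"].iloc[n - 1]
        frame = frame[frame["distance"] <= cutoff]
    frame["order"] = np.arange(1, len(frame) + 1)
    return frame


def pca_kmeans_fallback(matrix: pd.DataFrame, k_clusters: int = 8, seed: int = 0) -> pd.DataFrame:
    """First two principal components of the standardized predictors with
    k-means cluster labels; deterministic at a fixed seed."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    z = _standardize(matrix)
    if len(z) < max(3, k_clusters):
        raise ValueError(f"only {len(z)} complete rows; too few for PCA/k-means")
    pca = PCA(n_components=2, random_state=int(seed))
    coords = pca.fit_transform(z.to_numpy(dtype=float))
    km = KMeans(n_clusters=k_clusters, random_state=int(seed), n_init=10)
    labels = km.fit_predict(coords)
    out = pd.DataFrame(coords, index=z.index, columns=["x", "y"])
    out["cluster"] = labels
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    out.index.name = "gene"
    return out


class OfflineCitationClient:
    """Citation counts served from a JSON/dict fixture: {gene: {term: count}}.

    Genes absent from the fixture count as 0 with a warning, so an offline run
    never fabricates literature evidence.
    """

    def __init__(self, fixture):
        if isinstance(fixture, (str, bytes)) or hasattr(fixture, "read"):
            with open(fixture) as fh:
                fixture = json.load(fh)
        self.fixture = dict(fixture)

    def count(self, gene: str, term: str) -> int:
        if gene not in self.fixture:
            warnings.warn(f"gene {gene!r} not in fixture; counting 0", stacklevel=2)
            return 0
        return int(self.fixture[gene].get(term, 0))


class EntrezCitationClient:
    """Live PubMed counts via Entrez esearch ('GENE AND TERM'), with polite
    rate limiting and exponential-backoff retries. Requires network access."""

    def __init__(self, email: str, api_key: str | None = None, delay: float = 0.34, retries: int = 3):
        from Bio import Entrez

        Entrez.email = email
        if api_key:
            Entrez.api_key = api_key
        self._entrez = Entrez
        self.delay = delay
        self.retries = retries

    def count(self, gene: str, term: str) -> int:
        query = f"{gene} AND {term}"
        last_err: Exception | None = None
        for attempt in range(self.retries):
            try:
                time.sleep(self.delay * (2**attempt if attempt else 1))
                handle = self._entrez.esearch(db="pubmed", term=query, retmax=0)
                record = self._entrez.read(handle)
                handle.close()
                return int(record["Count"])
            except Exception as err:  # noqa: BLE001 - network layer
                last_err = err
        raise RuntimeError(f"PubMed query failed after {self.retries} attempts: {query!r}") from last_err


def citation_counts(genes, terms, client) -> pd.DataFrame:
    """One row per (gene, term) with the client's citation count."""
    rows = [{"gene": g, "term": t, "count": client.count(g, t)} for g in genes for t in terms]
    return pd.DataFrame(rows, columns=["gene", "term", "count"])


def select_candidates(
    ranked_genes,
    citations: pd.DataFrame | None = None,
    top_n: int = 75,
    max_citations: int = 0,
) -> list[str]:
    """Top-*top_n* genes of an ordered ranking, minus genes whose summed
    pathway-term citations exceed *max_citations* (novelty filter; filtering
    happens after truncation)."""
    top = list(ranked_genes)[:top_n]
    if citations is None or citations.empty:
        return top
    totals = citations.groupby("gene")["count"].sum()
    return [g for g in top if totals.get(g, 0) <= max_citations]
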