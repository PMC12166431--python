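"""Best-predictors aggregation, embeddings, neighbours and citation filtering."""

import numpy as np
import pandas as pd
import pytest

from deathmark import ranking as rk
from deathmark.examples import example_path


@pytest.fixture(scope="module")
def example_matrix():
    return pd.read_csv(example_path("predictors")).set_index("Gene")


def min_rank(values):
    return [1 + sum(1 for y in values if y < x) for x in values]


def spreadsheet_oracle(matrix, similarity_best="positive"):
    """Independent plain-Python recomputation of the best-predictors ranking."""
    rows = {}
    for gene, row in matrix.iterrows():
        me = np.mean([row[c] for c in matrix.columns if "cor to expression" in c])
        md = np.mean([row[c] for c in matrix.columns if "cor to depscore" in c])
        ms = np.mean([row[c] for c in matrix.columns if "similarity" in c.lower()])
        rows[gene] = (me, md, ms)
    genes = list(rows)
    # strongest = highest rank: negate correlations; similarity per polarity
    re_ = min_rank([-rows[g][0] for g in genes])
    rd_ = min_rank([-rows[g][1] for g in genes])
    sgn = 1.0 if similarity_best == "positive" else -1.0
    rs_ = min_rank([sgn * rows[g][2] for g in genes])
    rc = [max(a, b) for a, b in zip(re_, rd_)]
    mr = [(a + b) / 2 for a, b in zip(rc, rs_)]
    rt = min_rank(mr)
    return {g: (rc[i], rs_[i], mr[i], rt[i]) for i, g in enumerate(genes)}


def test_example_table_family_means():
    matrix = pd.read_csv(example_path("predictors")).set_index("Gene")
    out = rk.best_predictors_rank(matrix)
    assert out.loc["CYP1B1", "mean_r_expression"] == pytest.approx((-0.279 + -0.234) / 2)
    assert out.loc["CYP1B1", "mean_r_expression"] == pytest.approx(-0.2565)
    assert out.loc["CYP1B1", "mean_r_depscore"] == pytest.approx(-0.0755)
    assert out.loc["CYP1B1", "biggest_r"] == pytest.approx(-0.0755)


def test_full_ranking_matches_spreadsheet_oracle(example_matrix):
    out = rk.best_predictors_rank(example_matrix)
    oracle = spreadsheet_oracle(example_matrix)
    for gene in example_matrix.index:
        rc, rs, mr, rt = oracle[gene]
        assert out.loc[gene, "rank_corr"] == rc
        assert out.loc[gene, "rank_similarity"] == rs
        assert out.loc[gene, "mean_rank"] == mr
        assert out.loc[gene, "rank_total"] == rt
    # sorted strongest first
    assert list(out["rank_total"]) == sorted(out["rank_total"], reverse=True)


def test_single_gene_matrix_all_ranks_one(example_matrix):
    out = rk.best_predictors_rank(example_matrix.iloc[[0]])
    assert out[["rank_corr", "rank_similarity", "rank_total"]].iloc[0].tolist() == [1, 1, 1]


def test_ranking_invariances(example_matrix):
    base = rk.best_predictors_rank(example_matrix)
    shuffled = rk.best_predictors_rank(example_matrix.sample(frac=1, random_state=2))
    pd.testing.assert_frame_equal(base, shuffled)
    # duplicating a predictor column within a family leaves family means intact
    dup = example_matrix.copy()
    col = [c for c in dup.columns if "cor to expression" in c][0]
    dup[col + " copy"] = dup[col]
    # means change unless the duplicate equals the family mean; check explicit case
    const = example_matrix.copy()
    expr_cols = [c for c in const.columns if "cor to expression" in c]
    family_mean = const[expr_cols].mean(axis=1)
    for c in expr_cols:
        const[c] = family_mean
    doubled = const.copy()
    doubled["extra AUC cor to expression"] = const[[c for c in const.columns if "cor to expression" in c]].iloc[:, 0]
    out_c = rk.best_predictors_rank(const)
    out_d = rk.best_predictors_rank(doubled)
    assert np.allclose(out_c["mean_r_expression"], out_d.loc[out_c.index, "mean_r_expression"])


def test_polarity_flip_reverses_similarity_ranks(example_matrix):
    pos = rk.best_predictors_rank(example_matrix, similarity_best="positive")
    neg = rk.best_predictors_rank(example_matrix, similarity_best="negative")
    # with no ties, the two orientations give mirrored similarity ranks
    n = len(example_matrix)
    merged = pos["rank_similarity"] + neg.loc[pos.index, "rank_similarity"]
    assert (merged == n + 1).all()
    with pytest.raises(ValueError):
        rk.best_predictors_rank(example_matrix, similarity_best="sideways")


def test_ranking_drops_genes_without_similarity(example_matrix):
    matrix = example_matrix.copy()
    sim_cols = [c for c in matrix.columns if "similarity" in c.lower()]
    matrix.loc["CYP1B1", sim_cols] = np.nan
    out = rk.best_predictors_rank(matrix)
    assert "CYP1B1" not in out.index
    with pytest.raises(ValueError, match="no .* columns"):
        rk.best_predictors_rank(matrix.drop(columns=sim_cols))


def test_top_genes_by_mean_similarity_default_n(rng):
    table = pd.DataFrame(
        rng.normal(size=(500, 4)), index=[f"g{i:03d}" for i in range(500)], columns=list("wxyz")
    )
    top = rk.top_genes_by_mean_similarity(table)
    assert len(top) == 100
    means = table.mean(axis=1)
    assert means[top[0]] == means.max()
    bottom_first = rk.top_genes_by_mean_similarity(table, n=10, similarity_best="negative")[0]
    assert means[bottom_first] == means.min()


@pytest.fixture(scope="module")
def blob_matrix():
    rng = np.random.default_rng(99)
    a = rng.normal(0, 0.3, size=(40, 6)) + np.array([3, 3, 3, 0, 0, 0])
    b = rng.normal(0, 0.3, size=(40, 6)) - np.array([3, 3, 3, 0, 0, 0])
    mat = pd.DataFrame(np.vstack([a, b]), index=[f"g{i:03d}" for i in range(80)])
    mat.columns = [f"pred{j}" for j in range(6)]
    return mat


def test_embed_determinism_and_standardization(blob_matrix):
    c1 = rk.embed_predictors(blob_matrix, seed=5023)
    c2 = rk.embed_predictors(blob_matrix, seed=5023)
    pd.testing.assert_frame_equal(c1, c2)
    z = rk._standardize(blob_matrix)
    assert np.allclose(z.mean(), 0, atol=1e-12)
    assert np.allclose(z.std(ddof=1), 1, atol=1e-12)


def test_embed_identical_rows_near_coincident(blob_matrix):
    mat = blob_matrix.copy()
    mat.loc["g001"] = mat.loc["g000"]  # duplicate predictor row
    coords = rk.embed_predictors(mat, seed=5023)
    d = np.linalg.norm(coords.loc["g000"] - coords.loc["g001"])
    from scipy.spatial.distance import pdist

    all_d = pdist(coords[["x", "y"]].to_numpy())
    assert d <= np.percentile(all_d, 1)


def test_embed_requires_enough_complete_rows():
    tiny = pd.DataFrame(np.eye(5), index=list("abcde"))
    with pytest.raises(ValueError, match="pca_kmeans_fallback"):
        rk.embed_predictors(tiny)


def test_nearest_neighbors_cases(rng):
    coords = pd.DataFrame({"x": [0.0, 3.0, 6.0], "y": [0.0, 4.0, 8.0]}, index=["k", "a", "b"])
    nn = rk.nearest_neighbors(coords, "k", n=3)
    assert nn["gene"].tolist() == ["k", "a", "b"]
    assert nn["distance"].tolist() == [0.0, 5.0, 10.0]
    assert nn["order"].tolist() == [1, 2, 3]
    big = pd.DataFrame(rng.normal(size=(500, 2)), columns=["x", "y"], index=[f"g{i:03d}" for i in range(500)])
    out = rk.nearest_neighbors(big, "g000")
    assert len(out) == 75
    with pytest.raises(KeyError, match="close matches"):
        rk.nearest_neighbors(big, "g00")


def test_nearest_neighbors_keeps_boundary_ties():
    coords = pd.DataFrame(
        {"x": [0.0, 1.0, 1.0, 1.0, 5.0], "y": [0.0, 0.0, 0.0, 0.0, 0.0]},
        index=["k", "a", "b", "c", "far"],
    )
    nn = rk.nearest_neighbors(coords, "k", n=3)
    assert nn["gene"].tolist() == ["k", "a", "b", "c"]  # tie at the cutoff kept


def test_nearest_neighbors_metric_axioms(rng):
    coords = pd.DataFrame(rng.normal(size=(20, 2)), columns=["x", "y"], index=[f"g{i}" for i in range(20)])
    d01 = rk.nearest_neighbors(coords, "g0", n=20).set_index("gene")["distance"]["g1"]
    d10 = rk.nearest_neighbors(coords, "g1", n=20).set_index("gene")["distance"]["g0"]
    assert d01 == pytest.approx(d10, abs=1e-12)
    d = lambda a, b: float(np.linalg.norm(coords.loc[a] - coords.loc[b]))
    for a, b, c in [("g0", "g1", "g2"), ("g3", "g7", "g11")]:
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


def test_pca_single_axis_variance():
    # one latent direction shared by every standardized column -> PC1 captures it
    rng = np.random.default_rng(17)
    base = rng.normal(size=60)
    mat = pd.DataFrame({f"p{j}": base + rng.normal(0, 0.05, 60) for j in range(6)}, index=[f"g{i}" for i in range(60)])
    out = rk.pca_kmeans_fallback(mat, k_clusters=2, seed=4)
    assert out.attrs["explained_variance_ratio"][0] > 0.99


def test_pca_kmeans_fallback(blob_matrix):
    out = rk.pca_kmeans_fallback(blob_matrix, k_clusters=2, seed=4)
    labels_a = set(out["cluster"].iloc[:40])
    labels_b = set(out["cluster"].iloc[40:])
    assert labels_a.isdisjoint(labels_b)  # blobs recovered up to label permutation
    out2 = rk.pca_kmeans_fallback(blob_matrix, k_clusters=2, seed=4)
    pd.testing.assert_frame_equal(out, out2)


def test_offline_citations_and_selection(tmp_path):
    fixture = {"GPX4": {"Ferroptosis": 812, "Iron": 95}, "NEWGENE": {"Ferroptosis": 0}}
    client = rk.OfflineCitationClient(fixture)
    assert client.count("GPX4", "Ferroptosis") == 812
    with pytest.warns(UserWarning, match="not in fixture"):
        assert client.count("UNKNOWN", "Ferroptosis") == 0
    table = rk.citation_counts(["GPX4", "NEWGENE"], ["Ferroptosis", "Iron", "GSH"], client)
    assert len(table) == 6
    ranked = ["GPX4", "NEWGENE", "OTHER"]
    kept = rk.select_candidates(ranked, table, top_n=2, max_citations=0)
    assert kept == ["NEWGENE"]
    assert rk.select_candidates(ranked, None, top_n=2) == ["GPX4", "NEWGENE"]
    # json round trip
    import json

    p = tmp_path / "cites.json"
    p.write_text(json.dumps(fixture))
    assert rk.OfflineCitationClient(str(p)).count("GPX4", "Iron") == 95


def test_select_candidates_survivor_count(rng):
    genes = [f"g{i:03d}" for i in range(75)]
    cited = rng.choice(genes, size=10, replace=False)
    rows = [{"gene": g, "term": "t", "count": 5 if g in set(cited) else 0} for g in genes]
    kept = rk.select_candidates(genes, pd.DataFrame(rows), top_n=75, max_citations=0)
    assert len(kept) == 65
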