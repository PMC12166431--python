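"""Camera-style competitive enrichment and preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deathmark import enrichment as en
from deathmark.signature_store import GeneSetCollection


def brute_force_es(values, hits):
    """Independent weighted-KS walk written as an explicit loop."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    v = [values[i] for i in order]
    h = [hits[i] for i in order]
    m = sum(h)
    n = len(v)
    # accumulate in walk order so an exact magnitude tie resolves the same
    # way as the implementation (first occurrence wins)
    denom = 0.0
    for i in range(n):
        if h[i]:
            denom += abs(v[i])
    use_equal = denom <= 0
    hit_raw = p_miss = 0.0
    best = 0.0
    for i in range(n):
        if h[i]:
            hit_raw += 1.0 if use_equal else abs(v[i])
        else:
            p_miss += 1.0 / (n - m)
        dev = hit_raw / (m if use_equal else denom) - p_miss
        if abs(dev) > abs(best):
            best = dev
    return best


def test_camera_rho_zero_equals_pooled_t_test(rng):
    """At rho = 0 camera reduces exactly to the textbook pooled two-sample
    t-test on the set/complement partition (200 random instances)."""
    for _ in range(200):
        n = int(rng.integers(10, 51))
        m = int(rng.integers(2, n - 1))
        stats = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        members = rng.choice(stats.index, size=m, replace=False)
        rec = en.camera_test(stats, members, rho=0.0)
        in_set = stats.index.isin(members)
        t, p = sps.ttest_ind(stats[in_set], stats[~in_set], equal_var=True)
        assert rec.p == pytest.approx(p, abs=1e-10)
        assert rec.direction == ("Up" if t > 0 else "Down")


def test_camera_direction_and_complement_symmetry(rng):
    stats = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
    top = stats.nlargest(8).index
    rec = en.camera_test(stats, top, rho=0.05)
    assert rec.direction == "Up" and rec.signed_score > 0
    comp = en.camera_test(stats, stats.index.difference(top), rho=0.0)
    rec0 = en.camera_test(stats, top, rho=0.0)
    assert comp.direction == "Down"
    assert comp.p == pytest.approx(rec0.p, abs=1e-12)


def test_camera_shift_invariance_and_rho_monotonicity(rng):
    stats = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
    members = stats.index[:6]
    base = en.camera_test(stats, members, rho=0.01)
    shifted = en.camera_test(stats + 7.5, members, rho=0.01)
    assert shifted.p == pytest.approx(base.p, abs=1e-10)
    assert shifted.direction == base.direction
    ps = [en.camera_test(stats, members, rho=r).p for r in (0.0, 0.01, 0.1, 0.3)]
    assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


def test_camera_size_preconditions(rng):
    stats = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
    with pytest.raises(ValueError):
        en.camera_test(stats, ["g0"])
    with pytest.raises(ValueError):
        en.camera_test(stats, stats.index)


@pytest.mark.parametrize(
    "p, direction, expected",
    [(0.001, "Up", 3.0), (0.01, "Down", -2.0), (1.0, "Up", 0.0)],
)
def test_signed_log_score_values(p, direction, expected):
    assert en.signed_log_score(p, direction) == pytest.approx(expected)


def test_signed_log_score_rejects_bad_inputs():
    with pytest.raises(ValueError):
        en.signed_log_score(0.0, "Up")
    with pytest.raises(ValueError):
        en.signed_log_score(0.5, "Sideways")


def make_collections(sig_ids, gene_pool, rng, k=5):
    up, down = GeneSetCollection(), GeneSetCollection()
    for sid in sig_ids:
        up.add(sid, list(rng.choice(gene_pool, size=k, replace=False)))
        down.add(sid, list(rng.choice(gene_pool, size=k, replace=False)))
    return up, down


def test_enrich_all_cardinality_and_permutation_invariance(rng):
    genes = [f"g{i}" for i in range(60)]
    sig_ids = [f"CGS{i:03d}_A375_T{i}:96H" for i in range(4)]
    up, down = make_collections(sig_ids, genes, rng)
    signatures = {
        "c1": pd.Series(rng.normal(size=60), index=genes),
        "c2": pd.Series(rng.normal(size=60), index=genes),
    }
    table = en.enrich_all(signatures, up, down, rho=0.0)
    assert len(table) == 4 * 2 * 2  # sets x signatures x directions
    assert set(table["direction"]) == {"up", "down"}
    assert set(table["cell"]) == {"A375"}
    perm = {k: v.sample(frac=1, random_state=5) for k, v in signatures.items()}
    table_perm = en.enrich_all(perm, up, down, rho=0.0)
    merged = table.merge(table_perm, on=["sig_id", "pert", "direction"], suffixes=("", "_p"))
    assert np.allclose(merged["signed_score"], merged["signed_score_p"], atol=1e-9)


def test_enrich_all_matches_single_camera(rng):
    genes = [f"g{i}" for i in range(50)]
    up, down = make_collections(["CGS001_A375_X:96H"], genes, rng, k=8)
    stats = pd.Series(rng.normal(size=50), index=genes)
    table = en.enrich_all({"c1": stats}, up, down, rho=0.01)
    for direction, coll in (("up", up), ("down", down)):
        rec = en.camera_test(stats, coll["CGS001_A375_X:96H"], rho=0.01)
        row = table[table["direction"] == direction].iloc[0]
        assert row["signed_score"] == pytest.approx(rec.signed_score, abs=1e-9)


def test_enrich_all_planted_mimic_is_up(rng):
    genes = [f"g{i}" for i in range(100)]
    stats = pd.Series(rng.normal(size=100), index=genes)
    mimic = stats.nlargest(10).index.tolist()
    up = GeneSetCollection()
    up.add("CGS001_A375_MIM:96H", mimic)
    down = GeneSetCollection()
    down.add("CGS001_A375_MIM:96H", stats.nsmallest(10).index.tolist())
    table = en.enrich_all({"c1": stats}, up, down, rho=0.01)
    up_row = table[table["direction"] == "up"].iloc[0]
    down_row = table[table["direction"] == "down"].iloc[0]
    assert up_row["signed_score"] > 0 > down_row["signed_score"]


def test_enrich_all_skips_sets_without_overlap(rng):
    genes = [f"g{i}" for i in range(30)]
    up = GeneSetCollection()
    up.add("CGS001_A375_X:96H", ["absent1", "absent2", "absent3"])
    down = GeneSetCollection()
    down.add("CGS001_A375_X:96H", genes[:3])
    stats = pd.Series(rng.normal(size=30), index=genes)
    with pytest.warns(UserWarning, match="loses"):
        table = en.enrich_all({"c1": stats}, up, down, rho=0.0)
    assert set(table["direction"]) == {"down"}  # up-set recorded as missing


def test_gsea_top_set_equal_weights_closed_form():
    """Set = top-3 of 10 with all-equal |value|: the walk climbs to exactly 1
    at the third gene, so ES = 1; the bottom mirror gives -1."""
    ranks = pd.Series(np.linspace(1.0, 1.0, 10), index=[f"g{i}" for i in range(10)])
    # equal values: descending order ties broken by gene name -> g0..g9
    res = en.preranked_gsea(ranks, ["g0", "g1", "g2"], n_perm=10, seed=0)
    assert res.es == pytest.approx(1.0)
    signed = pd.Series(np.arange(10, 0, -1, dtype=float), index=[f"g{i}" for i in range(10)])
    res_bottom = en.preranked_gsea(-signed, ["g0", "g1", "g2"], n_perm=10, seed=0)
    assert res_bottom.es == pytest.approx(-1.0)


def test_gsea_matches_brute_force_walk(rng):
    """Property: ES equals an independent explicit-loop walk on 200 random
    12-gene instances."""
    for _ in range(200):
        values = rng.normal(size=12)
        m = int(rng.integers(1, 11))
        hit_idx = rng.choice(12, size=m, replace=False)
        hits = np.zeros(12, dtype=bool)
        hits[hit_idx] = True
        genes = [f"g{i:02d}" for i in range(12)]
        ranks = pd.Series(values, index=genes)
        res = en.preranked_gsea(ranks, [genes[i] for i in hit_idx], n_perm=5, seed=1)
        assert res.es == pytest.approx(brute_force_es(list(values), list(hits)), abs=1e-12)


def test_gsea_reversal_negates_es(rng):
    genes = [f"g{i}" for i in range(40)]
    ranks = pd.Series(rng.normal(size=40), index=genes)
    members = list(rng.choice(genes, size=6, replace=False))
    es1 = en.preranked_gsea(ranks, members, n_perm=5, seed=0).es
    es2 = en.preranked_gsea(-ranks, members, n_perm=5, seed=0).es
    assert es2 == pytest.approx(-es1, abs=1e-9)


def test_gsea_p_value_range_and_preconditions(rng):
    genes = [f"g{i}" for i in range(30)]
    ranks = pd.Series(rng.normal(size=30), index=genes)
    res = en.preranked_gsea(ranks, genes[:5], n_perm=99, seed=3)
    assert 1 / 100 <= res.p_perm <= 1.0
    with pytest.raises(ValueError, match="no overlap"):
        en.preranked_gsea(ranks, ["missing"], n_perm=10, seed=0)
    with pytest.raises(ValueError, match="whole ranking"):
        en.preranked_gsea(ranks, genes, n_perm=10, seed=0)
    with pytest.raises(ValueError, match="duplicate"):
        en.preranked_gsea(pd.Series([1.0, 2.0], index=["a", "a"]), ["a"], n_perm=10, seed=0)
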