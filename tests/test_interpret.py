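import itertools

import numpy as np
import pytest

from orthoae import (
    GseaResult,
    benjamini_hochberg,
    gsea_preranked,
    gsea_saliency_map,
    hypergeometric_overlap,
    significant_pathway_counts,
)
from orthoae.data_io import GeneSetCollection
from orthoae.interpret import enrichment_score, rank_genes


def brute_force_es(weights, hits):
    """Textbook running-sum ES: walk the list, track the extreme deviation."""
    n = len(weights)
    nh = int(hits.sum())
    denom = float((weights * hits).sum())
    if denom == 0:
        step_hit = [1.0 / nh if h else 0.0 for h in hits]
    else:
        step_hit = [w / denom if h else 0.0 for w, h in zip(weights, hits)]
    running, best = 0.0, 0.0
    for i in range(n):
        running += step_hit[i] if hits[i] else -1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


def test_rank_genes_descending_with_id_ties():
    genes = ["b", "a", "c", "d"]
    scores = [1.0, 2.0, 1.0, -1.0]
    ranked, s = rank_genes(genes, scores)
    assert ranked == ["a", "b", "c", "d"]
    assert list(s) == [2.0, 1.0, 1.0, -1.0]
    with pytest.raises(ValueError, match="finite"):
        rank_genes(["a"], [np.nan])


def test_enrichment_score_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = 30
        weights = np.abs(rng.normal(size=n))
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, size=rng.integers(2, 10), replace=False)] = True
        es = enrichment_score(weights, hits)
        assert es == pytest.approx(brute_force_es(weights, hits), abs=1e-12)
        assert -1.0 <= es <= 1.0


def test_enrichment_score_all_zero_inset_weights():
    weights = np.zeros(10)
    hits = np.zeros(10, dtype=bool)
    hits[:3] = True
    es = enrichment_score(weights, hits)
    assert es == pytest.approx(brute_force_es(weights, hits), abs=1e-12)


def test_enrichment_score_rejects_trivial_sets():
    w = np.ones(5)
    with pytest.raises(ValueError):
        enrichment_score(w, np.zeros(5, dtype=bool))
    with pytest.raises(ValueError):
        enrichment_score(w, np.ones(5, dtype=bool))


def test_es_invariant_to_monotone_transform_at_p0():
    rng = np.random.default_rng(1)
    genes = [f"g{i}" for i in range(40)]
    scores = rng.normal(size=40)
    gene_set = [genes[i] for i in rng.choice(40, 8, replace=False)]
    r1 = gsea_preranked(genes, scores, gene_set, weight_p=0.0, seed=0)
    r2 = gsea_preranked(genes, 3.0 * scores + 10.0, gene_set, weight_p=0.0,
                        seed=0)
    assert r1.es == pytest.approx(r2.es, abs=1e-12)


def test_gsea_preranked_basics():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(50)]
    scores = rng.normal(size=50)
    # a set concentrated at the top of the ranking
    top = [genes[i] for i in np.argsort(scores)[::-1][:6]]
    res = gsea_preranked(genes, scores, top, n_perm=500, seed=0, pathway="T")
    assert res.testable and res.pathway == "T"
    assert res.es > 0 and res.nes > 0
    assert res.p_nominal >= 1.0 / 501  # +1 correction: never exactly 0
    assert res.n_hits == 6


def test_gsea_preranked_untestable_sets():
    genes = ["a", "b", "c"]
    r0 = gsea_preranked(genes, [3, 2, 1], ["zzz"], n_perm=100)
    assert not r0.testable and np.isnan(r0.es)
    r_all = gsea_preranked(genes, [3, 2, 1], genes, n_perm=100)
    assert not r_all.testable


def test_gsea_preranked_seed_determinism_and_nperm_floor():
    genes = [f"g{i}" for i in range(30)]
    scores = list(range(30))
    gene_set = genes[:5]
    a = gsea_preranked(genes, scores, gene_set, n_perm=200, seed=3)
    b = gsea_preranked(genes, scores, gene_set, n_perm=200, seed=3)
    assert (a.es, a.nes, a.p_nominal) == (b.es, b.nes, b.p_nominal)
    with pytest.raises(ValueError, match="n_perm"):
        gsea_preranked(genes, scores, gene_set, n_perm=50)


def test_null_calibration_uniform_p():
    """Random sets on a random ranking: P(p < 0.05) = 0.05 +/- 0.03.

    Each set gets an independent permutation null; sharing one finite null
    sample across sets would correlate the p-values and inflate the variance
    of the observed fraction."""
    rng = np.random.default_rng(123)
    genes = [f"g{i}" for i in range(100)]
    scores = rng.normal(size=100)
    hits = 0
    n_sets = 200
    for _ in range(n_sets):
        members = [genes[i] for i in rng.choice(100, 10, replace=False)]
        res = gsea_preranked(genes, scores, members, n_perm=400,
                             seed=int(rng.integers(2**31)))
        if res.p_nominal < 0.05:
            hits += 1
    assert abs(hits / n_sets - 0.05) <= 0.03


def test_benjamini_hochberg_reference():
    # worked example against the step-up definition
    p = [0.01, 0.04, 0.03, 0.005]
    q = benjamini_hochberg(p)

    def bh_reference(pvals):
        m = len(pvals)
        order = np.argsort(pvals)
        out = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            val = min(prev, pvals[i] * m / (rank_idx + 1))
            out[i] = val
            prev = val
        return out

    np.testing.assert_allclose(q, bh_reference(p), rtol=1e-12)
    # monotone: lowering alpha never adds a significant test
    rng = np.random.default_rng(4)
    p2 = rng.random(60)
    q2 = benjamini_hochberg(p2)
    sig_01 = set(np.flatnonzero(q2 < 0.01))
    sig_05 = set(np.flatnonzero(q2 < 0.05))
    assert sig_01 <= sig_05
    assert np.all(q2 <= 1.0)


def test_gsea_saliency_map_fdr_over_all_tests():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(60)]
    sal = rng.normal(size=(3, 60))
    gs = GeneSetCollection({
        "S1": genes[:8], "S2": genes[8:16], "S3": ["not_in_matrix"],
    })
    results = gsea_saliency_map(sal, genes, gs, n_perm=200, seed=0)
    assert len(results) == 9  # 3 units x 3 sets
    testable = [r for r in results if r.testable]
    assert len(testable) == 6  # S3 never hits
    assert all(np.isfinite(r.q_fdr) for r in testable)
    assert all(r.q_fdr >= r.p_nominal - 1e-12 for r in testable)
    assert {r.unit for r in results} == {0, 1, 2}


def test_significant_pathway_counts_degenerate_single_type(small_logcpm,
                                                           small_model):
    ml, modules = small_logcpm
    from dataclasses import replace
    single = replace(ml, labels=["only"] * ml.n_cells)
    counts, res = significant_pathway_counts(
        small_model, single, modules, n_perm=100, seed=0
    )
    # one cell type: corrected map is exactly zero, nothing can be enriched
    assert int(counts.values.sum()) == 0


def test_significant_pathway_counts_bounds(small_logcpm, small_model):
    ml, modules = small_logcpm
    counts, res = significant_pathway_counts(
        small_model, ml, modules, n_perm=200, seed=0
    )
    n_types = len(set(ml.labels))
    assert counts.shape == (small_model.bottleneck_size, len(modules.sets))
    assert counts.values.max() <= n_types
    assert counts.values.min() >= 0
    assert set(res.columns) == {
        "cell_type", "unit", "pathway", "es", "nes", "p", "q", "testable"
    }
    assert len(res) == n_types * small_model.bottleneck_size * len(modules.sets)
    from dataclasses import replace
    with pytest.raises(ValueError, match="labels"):
        significant_pathway_counts(small_model, replace(ml, labels=None),
                                   modules, n_perm=100)


# --------------------------------------------------------------------------
# hypergeometric overlap


def exhaustive_overlap_p(a_size, b, universe, k_obs):
    """P(overlap >= k_obs) by enumerating every draw of a_size from the
    universe."""
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, a_size):
        total += 1
        if len(set(combo) & b) >= k_obs:
            hits += 1
    return hits / total


def test_hypergeometric_matches_exhaustive_enumeration():
    universe = [f"g{i}" for i in range(10)]
    b = set(universe[:4])
    for a_size in (2, 3, 5):
        a = set(universe[1 : 1 + a_size])
        k = len(a & b)
        p = hypergeometric_overlap(a, b, universe)
        expected = exhaustive_overlap_p(a_size, b, universe, k)
        assert p == pytest.approx(expected, rel=1e-9)


def test_hypergeometric_edge_cases():
    universe = ["a", "b", "c", "d"]
    assert hypergeometric_overlap(["a"], ["b"], universe) <= 1.0
    # zero observed overlap: P(X >= 0) = 1
    assert hypergeometric_overlap(["a"], ["b"], universe) == pytest.approx(
        1.0 if len({"a"} & {"b"}) == 0 else 0.0
    )
    with pytest.raises(ValueError, match="universe"):
        hypergeometric_overlap(["zz"], ["b"], universe)
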