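"""Enrichment scoring, combined score, normalization, permutation p-values,
FDR, and full store queries — checked against naive enumeration oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigmatch.matching import (
    NoOverlapError,
    QueryGeneSet,
    bh_fdr,
    combined_score,
    ks_enrichment,
    normalize_score,
    permutation_pvalue,
    query_database,
)
from sigmatch.signatures import DataError
from sigmatch.simulate import StoreSpec, make_synthetic_store
from util import naive_bh, naive_running_sum_es, random_signature


class TestKsEnrichment:
    def test_single_top_hit_scores_plus_one(self, toy_signature):
        assert ks_enrichment(toy_signature, {"A"}) == 1.0

    def test_single_bottom_hit_scores_minus_one(self, toy_signature):
        # running sum -1/3, -2/3, -1, 0: max |deviation| at position 3
        assert ks_enrichment(toy_signature, {"D"}) == -1.0

    def test_top_pair_unweighted(self, toy_signature):
        # hits +1/2 each, misses -1/2: running sum 0.5, 1.0, 0.5, 0.0
        assert ks_enrichment(toy_signature, {"A", "B"}, weighted=False) == 1.0

    def test_all_genes_hit_is_degenerate(self, toy_signature):
        with pytest.raises(DataError):
            ks_enrichment(toy_signature, {"A", "B", "C", "D"})

    def test_no_overlap_raises_sentinel(self, toy_signature):
        with pytest.raises(NoOverlapError):
            ks_enrichment(toy_signature, {"ZZZ"})

    def test_zero_weight_hits_fall_back_to_unweighted(self):
        sig = random_signature(np.random.default_rng(0), 10)
        sig.stats = np.array([5.0, 4, 3, 2, 1, 0, 0, 0, -1, -2])
        mid = {sig.genes[5], sig.genes[6]}
        assert ks_enrichment(sig, mid, weighted=True) == ks_enrichment(
            sig, mid, weighted=False
        )

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_naive_running_sum_oracle(self, weighted):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(5, 200))
            sig = random_signature(rng, n)
            k = int(rng.integers(1, n))
            hit_idx = rng.choice(n, size=k, replace=False)
            genes = {sig.genes[i] for i in hit_idx}
            mask = [g in genes for g in sig.genes]
            expected = naive_running_sum_es(sig.stats, mask, weighted)
            assert ks_enrichment(sig, genes, weighted=weighted) == pytest.approx(
                expected, abs=1e-12
            )

    def test_case_insensitive_gene_matching(self, toy_signature):
        assert ks_enrichment(toy_signature, {"a"}) == 1.0


class TestCombinedAndNormalize:
    @pytest.mark.parametrize(
        "es_up, es_down, expected",
        [
            (1.0, -1.0, 1.0),
            (0.4, 0.4, 0.0),     # same strict sign -> discordant, nulled
            (-1.0, 1.0, -1.0),
            (None, -0.6, 0.3),   # missing half counts as zero
            (0.0, -0.4, 0.2),    # zero is not a strict sign
        ],
    )
    def test_combined_score(self, es_up, es_down, expected):
        assert combined_score(es_up, es_down) == pytest.approx(expected)

    def test_nulling_can_be_disabled(self):
        assert combined_score(0.4, 0.4, nulling=False) == pytest.approx(0.0)
        assert combined_score(0.6, 0.2, nulling=False) == pytest.approx(0.2)

    @pytest.mark.parametrize(
        "c, mode, expected",
        [(1.0, "direct", 100.0), (0.0, "direct", 50.0), (0.0, "inverse", 50.0),
         (-1.0, "inverse", 100.0), (-1.0, "direct", 0.0)],
    )
    def test_normalize_affine_map(self, c, mode, expected):
        assert normalize_score(c, mode) == expected

    def test_out_of_range_combined_rejected(self):
        with pytest.raises(ValueError):
            normalize_score(1.5, "direct")

    @given(st.floats(-1.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_mode_duality_of_the_affine_map(self, c):
        assert normalize_score(c, "inverse") == pytest.approx(
            normalize_score(-c, "direct")
        )


class TestPermutationPvalue:
    def test_self_query_attains_minimum_p(self):
        sig = random_signature(np.random.default_rng(3), 60)
        query = QueryGeneSet.from_lists(up=sig.genes[:6], down=sig.genes[-6:])
        assert permutation_pvalue(sig, query, b=999, seed=0) == pytest.approx(
            1.0 / 1000.0
        )

    def test_nulled_observed_score_gives_p_one(self):
        # craft a discordant query: both halves enriched at the top
        sig = random_signature(np.random.default_rng(4), 60)
        query = QueryGeneSet.from_lists(up=sig.genes[:5], down=sig.genes[5:10])
        assert permutation_pvalue(sig, query, b=199, seed=1) == 1.0

    def test_reproducible_given_seed(self):
        sig = random_signature(np.random.default_rng(5), 80)
        query = QueryGeneSet.from_lists(up=sig.genes[10:18], down=sig.genes[40:48])
        p1 = permutation_pvalue(sig, query, b=200, seed=7)
        p2 = permutation_pvalue(sig, query, b=200, seed=7)
        assert p1 == p2

    def test_swap_invariance_of_p(self):
        """|c| depends only on the unordered surrogate pair, so swapping the
        query's up/down lists leaves the permutation p-value unchanged."""
        sig = random_signature(np.random.default_rng(6), 80)
        query = QueryGeneSet.from_lists(up=sig.genes[:5], down=sig.genes[-9:])
        p = permutation_pvalue(sig, query, b=300, seed=9)
        p_swapped = permutation_pvalue(sig, query.swapped(), b=300, seed=9)
        assert p == p_swapped

    def test_zero_permutations_rejected(self, toy_signature):
        query = QueryGeneSet.from_lists(up=["A"])
        with pytest.raises(ValueError):
            permutation_pvalue(toy_signature, query, b=0)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.25], [0.25]),
            ([0.01, 0.04, 0.03], [0.03, 0.04, 0.04]),
            ([], []),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_matches_naive_step_up_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 40))).tolist()
            np.testing.assert_allclose(bh_fdr(p), naive_bh(p), atol=1e-12)


@pytest.fixture(scope="module")
def planted_store():
    query = QueryGeneSet.from_lists(
        up=[f"U{i:02d}" for i in range(10)],
        down=[f"D{i:02d}" for i in range(10)],
    )
    store, truth = make_synthetic_store(
        query, StoreSpec(n_decoys=50, n_genes=120, rho=1.0, seed=42)
    )
    return query, store, truth


class TestQueryDatabase:
    def test_planted_concordant_signature_ranks_first(self, planted_store):
        query, store, truth = planted_store
        results = query_database(store, query, b=99, seed=0)
        assert results.iloc[0]["signature_id"] == truth["planted_signature_id"]
        assert results.iloc[0]["score"] == 100.0
        assert results.iloc[0]["p_value"] == pytest.approx(1.0 / 100.0)

    def test_swap_antisymmetry_of_scores(self, planted_store):
        query, store, _ = planted_store
        direct = query_database(store, query, b=49, seed=1)
        swapped = query_database(store, query.swapped(), b=49, seed=1)
        merged = direct.merge(swapped, on="signature_id", suffixes=("", "_sw"))
        np.testing.assert_allclose(
            merged["score_sw"], 100.0 - merged["score"], atol=1e-9
        )

    def test_inverse_mode_equals_direct_mode_of_swapped_query(self, planted_store):
        query, store, _ = planted_store
        inverse = query_database(store, query, mode="inverse", b=49, seed=2)
        direct_sw = query_database(store, query.swapped(), mode="direct", b=49, seed=2)
        assert list(inverse["signature_id"]) == list(direct_sw["signature_id"])
        np.testing.assert_array_equal(inverse["score"], direct_sw["score"])
        np.testing.assert_array_equal(inverse["p_value"], direct_sw["p_value"])
        np.testing.assert_array_equal(inverse["q_value"], direct_sw["q_value"])

    def test_result_invariants_hold_everywhere(self, planted_store):
        query, store, _ = planted_store
        results = query_database(store, query, b=49, seed=3)
        assert results["score"].between(0, 100).all()
        assert results["combined"].between(-1, 1).all()
        assert results["p_value"].between(0, 1).all()
        assert results["q_value"].between(0, 1).all()
        assert (
            results[["n_hits_up", "n_hits_down"]].sum(axis=1) >= 1
        ).all()

    def test_byte_identical_given_same_seed(self, planted_store, tmp_path):
        from sigmatch.io import write_results

        query, store, _ = planted_store
        for name in ("a.tsv", "b.tsv"):
            write_results(
                query_database(store, query, b=99, seed=5), tmp_path / name
            )
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_empty_query_rejected(self):
        with pytest.raises(DataError):
            QueryGeneSet.from_lists()

    def test_min_overlap_filters_rows(self, planted_store):
        query, store, _ = planted_store
        few = query_database(store, query, b=9, seed=6, min_overlap=21)
        assert few.empty  # universe holds all 20 query genes at most
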