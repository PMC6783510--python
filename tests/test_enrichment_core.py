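import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfgmr import (
    NullDistribution,
    build_ranked_list,
    enrichment_score,
    nominal_p,
    permutation_null,
    rank_compounds,
    tes_index,
)
from tfgmr.module_builder import GeneModule, ModulePair

from _oracles import naive_enrichment_score
from conftest import random_ranked_list


@pytest.fixture
def five_gene_list():
    return build_ranked_list({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0, "g5": 0.5})


def make_pair(pos, neg):
    return ModulePair(
        positive=GeneModule("P", "t:pos", frozenset(pos), frozenset()),
        negative=GeneModule("N", "t:neg", frozenset(neg), frozenset()),
    )


class TestEnrichmentScore:
    def test_weighted_worked_example(self, five_gene_list):
        res = enrichment_score(five_gene_list, {"g1", "g4"}, exponent=1.0)
        assert res.es == pytest.approx(0.8)
        assert res.peak_index == 1
        assert res.leading_edge == ("g1",)
        assert res.hit_positions == (1, 4)

    def test_classic_ks_worked_example(self, five_gene_list):
        res = enrichment_score(five_gene_list, {"g1", "g4"}, exponent=0.0)
        assert res.es == pytest.approx(0.5)
        assert res.leading_edge == ("g1",)

    def test_boundary_single_top_and_bottom_hit(self, five_gene_list):
        assert enrichment_score(five_gene_list, {"g1"}, 0.0).es == pytest.approx(1.0)
        assert enrichment_score(five_gene_list, {"g5"}, 0.0).es == pytest.approx(-1.0)

    def test_es_equals_extreme_of_running_sum(self, rng):
        ranked = random_ranked_list(rng, 30)
        res = enrichment_score(ranked, set(ranked.genes[::3]), 1.0)
        dev = res.running_sum
        assert res.es == dev[np.argmax(np.abs(dev))]
        assert res.es == dev[res.peak_index - 1]

    def test_absent_members_dropped_with_count(self, five_gene_list):
        res = enrichment_score(five_gene_list, {"g1", "g4", "missing"}, 1.0)
        assert res.n_dropped == 1
        assert res.es == pytest.approx(0.8)

    def test_no_member_present_raises(self, five_gene_list):
        with pytest.raises(ValueError, match="no module member"):
            enrichment_score(five_gene_list, {"zz"}, 1.0)

    def test_all_hit_membership_raises(self, five_gene_list):
        with pytest.raises(ValueError, match="P_miss"):
            enrichment_score(five_gene_list, set(five_gene_list.genes), 1.0)

    def test_negative_leading_edge_after_peak(self):
        ranked = build_ranked_list({f"g{i}": float(10 - i) for i in range(10)})
        res = enrichment_score(ranked, {"g8", "g9"}, exponent=0.0)
        assert res.es < 0
        assert set(res.leading_edge) == {"g8", "g9"}
        assert all(ranked.genes.index(g) + 1 > res.peak_index for g in res.leading_edge)

    @settings(derandomize=True, max_examples=200)
    @given(data=st.data(), exponent=st.sampled_from([0.0, 1.0, 2.0]))
    def test_matches_brute_force_oracle_and_bounds(self, data, exponent):
        n = data.draw(st.integers(4, 20))
        raw = data.draw(
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
        )
        scores = {f"g{i:02d}": s + i * 1e-6 for i, s in enumerate(raw)}
        ranked = build_ranked_list(scores)
        k = data.draw(st.integers(1, n - 1))
        members = set(data.draw(st.permutations(list(ranked.genes)))[:k])
        weights_ok = any(abs(s) > 0 for g, s in ranked.entries if g in members)
        if exponent > 0 and not weights_ok:
            return
        res = enrichment_score(ranked, members, exponent)
        es, _, trace = naive_enrichment_score(
            list(ranked.genes), list(ranked.scores), members, exponent
        )
        assert abs(res.es) == pytest.approx(abs(es), abs=1e-12)
        if abs(abs(max(trace)) - abs(min(trace))) > 1e-9:  # sign unambiguous
            assert res.es == pytest.approx(es, abs=1e-12)
        assert abs(trace[res.peak_index - 1]) == pytest.approx(
            max(abs(d) for d in trace), abs=1e-12
        )
        assert -1.0 <= res.es <= 1.0

    def test_reversed_list_negates_classic_ks(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 30))
            ranked = random_ranked_list(rng, n)
            k = int(rng.integers(1, n - 1))
            members = set(rng.choice(ranked.genes, size=k, replace=False))
            reversed_list = build_ranked_list(
                {g: -s for g, s in ranked.entries}
            )
            res_fwd = enrichment_score(ranked, members, 0.0)
            es_rev = enrichment_score(reversed_list, members, 0.0).es
            assert abs(es_rev) == pytest.approx(abs(res_fwd.es), abs=1e-9)
            trace = res_fwd.running_sum
            if abs(abs(trace.max()) - abs(trace.min())) > 1e-9:
                # sign flips whenever the extreme is unambiguous
                assert es_rev == pytest.approx(-res_fwd.es, abs=1e-9)


class TestTesIndex:
    @pytest.mark.parametrize(
        "es_p, es_n, expected",
        [(0.19, -0.23, 0.42), (0.0, 0.0, 0.0), (-0.1, 0.2, -0.3), (1.0, -1.0, 2.0)],
    )
    def test_arithmetic(self, es_p, es_n, expected):
        assert tes_index(es_p, es_n) == pytest.approx(expected)

    @pytest.mark.parametrize("es_p, es_n", [(1.2, 0.0), (0.0, -1.01)])
    def test_inputs_outside_es_range_rejected(self, es_p, es_n):
        with pytest.raises(ValueError, match="range"):
            tes_index(es_p, es_n)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, rng):
        ranked = random_ranked_list(rng, 60)
        pair = make_pair(ranked.genes[:5], ranked.genes[5:10])
        a = permutation_null(ranked, pair, B=50, seed=11)
        b = permutation_null(ranked, pair, B=50, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        c = permutation_null(ranked, pair, B=50, seed=12)
        assert not np.array_equal(a.values, c.values)

    def test_single_draw_within_tes_bounds(self, rng):
        ranked = random_ranked_list(rng, 40)
        pair = make_pair(ranked.genes[:4], ranked.genes[4:8])
        null = permutation_null(ranked, pair, B=1, seed=0)
        assert len(null) == 1
        assert -2.0 <= null.values[0] <= 2.0

    def test_all_draws_within_tes_bounds(self, rng):
        ranked = random_ranked_list(rng, 50)
        pair = make_pair(ranked.genes[:6], ranked.genes[6:14])
        null = permutation_null(ranked, pair, B=300, seed=5)
        assert np.all(null.values >= -2.0) and np.all(null.values <= 2.0)
        assert null.module_sizes == (6, 8)

    def test_mean_zero_on_exchangeable_scores(self, rng):
        ranked = random_ranked_list(rng, 200)
        pair = make_pair(ranked.genes[:20], ranked.genes[20:40])
        null = permutation_null(ranked, pair, B=4000, seed=3)
        se = null.values.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.values.mean()) < 4 * se + 0.01

    def test_universe_smaller_than_modules_rejected(self, rng):
        ranked = random_ranked_list(rng, 10)
        pair = make_pair(ranked.genes[:5], ranked.genes[5:10])
        with pytest.raises(ValueError, match="universe"):
            permutation_null(ranked, pair, B=5, seed=0)

    def test_disjoint_option_also_reproducible(self, rng):
        ranked = random_ranked_list(rng, 60)
        pair = make_pair(ranked.genes[:5], ranked.genes[5:10])
        a = permutation_null(ranked, pair, B=20, seed=1, disjoint=True)
        b = permutation_null(ranked, pair, B=20, seed=1, disjoint=True)
        np.testing.assert_array_equal(a.values, b.values)


class TestNominalP:
    def test_add_one_estimator(self):
        null = NullDistribution(values=np.array([0.1, 0.2, 0.3, 0.4]), seed=0,
                                module_sizes=(2, 2))
        assert nominal_p(0.35, null) == pytest.approx(0.4)

    def test_observed_below_all_gives_one(self):
        null = NullDistribution(values=np.array([0.1, 0.2, 0.3]), seed=0,
                                module_sizes=(2, 2))
        assert nominal_p(-5.0, null) == 1.0

    def test_floor_is_one_over_b_plus_one(self):
        null = NullDistribution(values=np.zeros(1000), seed=0, module_sizes=(2, 2))
        assert nominal_p(0.5, null) == pytest.approx(1 / 1001)

    def test_two_sided_uses_magnitudes(self):
        null = NullDistribution(values=np.array([-0.9, 0.1, 0.2]), seed=0,
                                module_sizes=(2, 2))
        assert nominal_p(0.5, null, side="two_sided") == pytest.approx(2 / 4)


class TestRankCompounds:
    def test_planted_ordering_recovered(self, rng):
        genes = [f"g{i:03d}" for i in range(100)]
        pair = make_pair(genes[:10], genes[10:20])

        def profile(strength):
            scores = {g: float(rng.normal(0, 0.1)) for g in genes}
            for g in pair.positive.members:
                scores[g] += strength
            for g in pair.negative.members:
                scores[g] -= strength
            return build_ranked_list(scores)

        profiles = {"high": profile(3.0), "medium": profile(1.0), "low": profile(0.0)}
        scores = rank_compounds(profiles, pair, B=50, seed=2)
        assert [s.compound_id for s in scores] == ["high", "medium", "low"]
        for s in scores:
            assert s.tes == s.es_pfgm - s.es_nfgm
            assert s.leading_edge_pfgm or s.es_pfgm < 0

    def test_singleton_profile(self, rng):
        ranked = random_ranked_list(rng, 50)
        pair = make_pair(ranked.genes[:4], ranked.genes[4:8])
        scores = rank_compounds({"only": ranked}, pair, B=10, seed=0)
        assert len(scores) == 1 and scores[0].compound_id == "only"

    def test_duplicate_compound_id_rejected(self, rng):
        ranked = random_ranked_list(rng, 30)
        pair = make_pair(ranked.genes[:3], ranked.genes[3:6])
        with pytest.raises(ValueError, match="duplicate"):
            rank_compounds([("c1", ranked), ("c1", ranked)], pair, B=5, seed=0)

    def test_profile_without_module_genes_excluded(self, rng, caplog):
        ranked = random_ranked_list(rng, 40)
        other = random_ranked_list(rng, 40, prefix="h")
        pair = make_pair(ranked.genes[:4], ranked.genes[4:8])
        with caplog.at_level("WARNING"):
            scores = rank_compounds({"good": ranked, "bad": other}, pair, B=10, seed=0)
        assert [s.compound_id for s in scores] == ["good"]
        assert any("excluded" in r.message for r in caplog.records)

    def test_per_compound_seeds_order_independent(self, rng):
        ranked_a = random_ranked_list(rng, 60)
        ranked_b = random_ranked_list(rng, 60)
        pair = make_pair(ranked_a.genes[:5], ranked_a.genes[5:10])
        both = rank_compounds({"a": ranked_a, "b": ranked_b}, pair, B=30, seed=9)
        solo = rank_compounds({"a": ranked_a}, pair, B=30, seed=9)
        p_a_both = next(s.p_value for s in both if s.compound_id == "a")
        assert p_a_both == solo[0].p_value
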