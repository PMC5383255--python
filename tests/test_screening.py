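"""Permutation p-values, interaction-score and function-score screens."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netprio as npr
from netprio.errors import ValidationError
from netprio.records import CandidateRecord
from netprio.screening import (AnnotationProfile, ScreeningThresholds,
                               association, build_annotation_profile,
                               draw_permutation_sets, filter_by_pvalue, mfs,
                               mfs_table, mis, permutation_test)


def _stub_candidates(stats):
    return [CandidateRecord(gene=g, method="rwr", statistic=s) for g, s in stats]


def _stub_statistic(network, genes, stub_seed=99):
    """Deterministic pseudo-random statistic per (gene, seed set)."""
    def stat(seed_ids):
        h = hash((tuple(seed_ids), stub_seed))
        rng = np.random.default_rng(abs(h) % 2**31)
        return rng.random(len(genes))
    return stat


class TestPermutationTest:
    def test_pvalue_equals_exact_exceed_fraction(self, bundle):
        genes = ["gA", "gB", "gC"]
        observed = [0.5, 2.0, -1.0]  # mid, above-all, below-all
        stat = _stub_statistic(bundle.network, genes)
        res = permutation_test(
            stat, bundle.network, bundle.seeds,
            _stub_candidates(zip(genes, observed)),
            n_perm=500, rng_seed=7,
        )
        # independent recount from the same reproducible draw
        sets = draw_permutation_sets(bundle.network, len(bundle.seeds), 500, 7)
        exceed = np.zeros(3, dtype=int)
        for s in sets:
            exceed += stat(s) > np.array(observed)
        for i, g in enumerate(genes):
            assert res.entries[g].exceed_count == exceed[i]
            assert res.entries[g].p_value == exceed[i] / 500
        assert res.entries["gB"].p_value == 0.0   # observed above every draw
        assert res.entries["gC"].p_value == 1.0   # observed below every draw

    def test_exact_count_of_37_in_1000_gives_0p037(self, bundle):
        genes = ["g"]
        stat = _stub_statistic(bundle.network, genes)
        sets = draw_permutation_sets(bundle.network, len(bundle.seeds), 1000, 3)
        vals = np.sort(np.concatenate([stat(s) for s in sets]))
        observed = float((vals[-38] + vals[-37]) / 2)  # exactly 37 draws above
        res = permutation_test(stat, bundle.network, bundle.seeds,
                               _stub_candidates([("g", observed)]),
                               n_perm=1000, rng_seed=3)
        assert res.entries["g"].p_value == pytest.approx(0.037)

    def test_same_rng_seed_is_bit_identical(self, bundle):
        genes = ["x", "y"]
        cands = _stub_candidates([("x", 0.4), ("y", 0.6)])
        stat = _stub_statistic(bundle.network, genes)
        r1 = permutation_test(stat, bundle.network, bundle.seeds, cands,
                              n_perm=200, rng_seed=11)
        r2 = permutation_test(stat, bundle.network, bundle.seeds, cands,
                              n_perm=200, rng_seed=11)
        assert r1.entries == r2.entries

    def test_pvalue_monotone_in_observed_statistic(self, bundle):
        # same gene, same null draws: a larger observed value cannot raise p
        stat = _stub_statistic(bundle.network, ["g"])
        ps = []
        for obs in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = permutation_test(stat, bundle.network, bundle.seeds,
                                   _stub_candidates([("g", obs)]),
                                   n_perm=300, rng_seed=5)
            ps.append(res.entries["g"].p_value)
        assert ps == sorted(ps, reverse=True)

    def test_oversized_seed_set_rejected(self, path_network):
        with pytest.raises(ValidationError):
            draw_permutation_sets(path_network, size=10, n_perm=5, rng_seed=0)

    def test_rwr_null_ignores_candidates_drawn_as_seeds(self, bundle):
        # a candidate drawn into a permuted seed set contributes no
        # candidate statistic for that replicate (it is a seed there, and
        # its restart-held probability is not comparable)
        seed_ids = bundle.seeds.as_set()
        gene = next(g for g in bundle.network.node_order if g not in seed_ids)
        cands = _stub_candidates([(gene, 1.0)])  # observed above any true probability
        res = permutation_test("rwr", bundle.network, bundle.seeds, cands,
                               n_perm=50, rng_seed=2)
        assert res.entries[gene].p_value == 0.0


class TestFilterByPvalue:
    def test_boundary_is_strict(self):
        from netprio.screening import PermutationEntry, PermutationResult
        res = PermutationResult(
            entries={
                "at": PermutationEntry(1.0, 50, 0.05),
                "below": PermutationEntry(1.0, 49, 0.049),
            },
            n_perm=1000, rng_seed=0,
        )
        assert filter_by_pvalue(res, 0.05) == ["below"]

    def test_empty_input(self):
        from netprio.screening import PermutationResult
        res = PermutationResult(entries={}, n_perm=10, rng_seed=0)
        assert filter_by_pvalue(res) == []

    def test_invalid_cutoff(self):
        from netprio.screening import PermutationResult
        res = PermutationResult(entries={}, n_perm=10, rng_seed=0)
        with pytest.raises(ValidationError):
            filter_by_pvalue(res, 1.0)


class TestMis:
    def _net(self):
        return npr.build_network([
            npr.InteractionRecord("g", "s1", 400),
            npr.InteractionRecord("g", "s2", 950),
            npr.InteractionRecord("far", "s1", 800),
            npr.InteractionRecord("lonely", "far", 300),
        ])

    def test_maximum_over_seed_edges(self):
        net = self._net()
        assert mis("g", npr.SeedSet(("s1", "s2")), net) == 950

    def test_no_seed_edge_gives_zero(self):
        net = self._net()
        assert mis("lonely", npr.SeedSet(("s1", "s2")), net) == 0

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            mis("nope", npr.SeedSet(("s1",)), self._net())

    def test_never_exceeds_999(self, bundle, hyper_profile):
        seed_ids = bundle.seeds.as_set()
        for g in bundle.network.node_order:
            if g not in seed_ids:
                assert mis(g, bundle.seeds, bundle.network) <= 999


class TestAnnotationProfile:
    def test_indicator_encoding(self):
        net = npr.build_network([npr.InteractionRecord("g1", "g2", 500)])
        prof = build_annotation_profile({"t1": ["g1"], "t2": ["zz"]}, net,
                                        scorer="indicator")
        assert prof.vector("g1").tolist() == [1.0, 0.0]
        assert prof.vector("g2").tolist() == [0.0, 0.0]
        assert prof.zero_genes == ("g2",)

    def test_zero_overlap_scores_zero(self):
        net = npr.build_network([npr.InteractionRecord("g1", "g2", 500),
                                 npr.InteractionRecord("g3", "g4", 500)])
        prof = build_annotation_profile({"t": ["g3", "g4"]}, net,
                                        scorer="neighborhood-hypergeometric")
        assert prof.vector("g1")[0] == 0.0

    def test_hypergeometric_tail_matches_brute_force(self):
        # 20-gene universe: compare against the exhaustive combinatorial sum
        rng = np.random.default_rng(4)
        from conftest import random_weighted_records
        recs, names = random_weighted_records(rng, 20, 0.2)
        net = npr.build_network(recs)
        terms = {"tA": list(names[3:9]), "tB": list(names[0:12:2])}
        prof = build_annotation_profile(terms, net,
                                        scorer="neighborhood-hypergeometric")
        N = net.n_nodes
        for g in names:
            nb = set(net.neighbors(g)) | {g}
            for j, t in enumerate(prof.terms):
                members = set(terms[t])
                k, K, n = len(nb & members), len(members), len(nb)
                tail = sum(
                    math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
                    for x in range(k, min(K, n) + 1)
                )
                expect = max(0.0, -math.log10(tail)) if k > 0 else 0.0
                assert prof.vector(g)[j] == pytest.approx(expect, abs=1e-9)

    def test_empty_term_universe_rejected(self, path_network):
        with pytest.raises(ValidationError):
            build_annotation_profile({}, path_network)


class TestAssociation:
    def _profile(self, vectors):
        genes = tuple(vectors)
        mat = np.array([vectors[g] for g in genes], dtype=float)
        return AnnotationProfile(terms=tuple(f"t{i}" for i in range(mat.shape[1])),
                                 genes=genes, matrix=mat, scorer="indicator")

    def test_identical_vectors_give_one(self):
        prof = self._profile({"a": [2, 1, 0], "b": [2, 1, 0]})
        assert association("a", "b", prof) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        prof = self._profile({"a": [1, 0], "b": [0, 1]})
        assert association("a", "b", prof) == 0.0

    def test_half_overlap_gives_inverse_sqrt_two(self):
        prof = self._profile({"a": [1, 0], "b": [1, 1]})
        assert association("a", "b", prof) == pytest.approx(1 / math.sqrt(2), abs=1e-5)

    def test_zero_norm_vector_defined_as_zero(self):
        prof = self._profile({"a": [1, 1], "z": [0, 0]})
        assert association("a", "z", prof) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=6),
           st.lists(st.floats(0, 10), min_size=2, max_size=6))
    def test_nonnegative_vectors_keep_association_in_unit_interval(self, va, vb):
        n = min(len(va), len(vb))
        prof = self._profile({"a": va[:n], "b": vb[:n]})
        m = association("a", "b", prof)
        assert 0.0 <= m <= 1.0 + 1e-12


class TestMfs:
    def test_maximum_over_seeds(self):
        prof = TestAssociation()._profile(
            {"g": [1, 0], "s1": [0, 1], "s2": [1, 1]})
        seeds = npr.SeedSet(("s1", "s2"))
        assert mfs("g", seeds, prof) == pytest.approx(1 / math.sqrt(2))

    def test_gene_identical_to_a_seed_scores_one(self):
        prof = TestAssociation()._profile({"g": [3, 1], "s": [3, 1]})
        assert mfs("g", npr.SeedSet(("s",)), prof) == pytest.approx(1.0)

    def test_vectorized_table_matches_scalar_route(self, bundle, hyper_profile):
        seed_ids = bundle.seeds.as_set()
        genes = [g for g in bundle.network.node_order if g not in seed_ids][:25]
        table = mfs_table(genes, bundle.seeds, hyper_profile)
        for g in genes:
            assert table[g] == pytest.approx(mfs(g, bundle.seeds, hyper_profile),
                                             abs=1e-9)


class TestThresholds:
    @pytest.mark.parametrize("kwargs", [
        {"p_cutoff": 0.0}, {"p_cutoff": 1.0}, {"p_mis": -1}, {"p_mis": 1000},
        {"p_mfs": 1.5},
    ])
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            ScreeningThresholds(**kwargs)
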