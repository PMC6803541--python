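"""Partner selection, enrichment, expression filtering, full gene flow."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from oiassoc.errors import DomainError
from oiassoc.network import (NetworkConfig, PathwayCollection, build_ppi_graph,
                             expression_filter, hypergeometric_enrichment,
                             prioritize_genes, select_partners, set_a, set_b)
from oiassoc.simulate import NetworkSpec, gen_network_fixture


def _graph(rows):
    return build_ppi_graph(pd.DataFrame(rows, columns=["gene_a", "gene_b",
                                                       "confidence", "relevance"]))


class TestGraphConstruction:
    def test_self_loops_dropped_and_duplicates_merged_by_max(self):
        g = _graph([("A", "A", 1.0, 1.0), ("A", "B", 0.4, 0.9),
                    ("B", "A", 0.8, 0.2)])
        assert not g.has_edge("A", "A")
        assert g["A"]["B"] == {"confidence": 0.8, "relevance": 0.9}

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(DomainError):
            _graph([("A", "B", 1.2, 0.5)])


class TestSelectPartners:
    def test_threshold_excludes_sub_maximal_edges(self):
        g = _graph([("X", "seed1", 1.0, 1.0), ("X", "seed2", 1.0, 1.0),
                    ("Y", "seed1", 0.99, 1.0)])
        partners = select_partners(g, {"seed1", "seed2"})
        assert partners == {"X": {"seed1", "seed2"}}

    def test_relaxed_bounds_admit_more_partners(self):
        g = _graph([("X", "seed1", 1.0, 1.0), ("Y", "seed1", 0.99, 1.0)])
        partners = select_partners(g, {"seed1"}, min_conf=0.9)
        assert set(partners) == {"X", "Y"}

    def test_seeds_never_appear_as_partners(self):
        g = _graph([("seed1", "seed2", 1.0, 1.0), ("X", "seed1", 1.0, 1.0)])
        assert set(select_partners(g, {"seed1", "seed2"})) == {"X"}

    def test_no_qualifying_edges_gives_empty_map(self):
        g = _graph([("X", "seed1", 0.5, 0.5)])
        assert select_partners(g, {"seed1"}) == {}

    def test_empty_seed_set_is_an_error(self):
        with pytest.raises(DomainError):
            select_partners(_graph([("A", "B", 1.0, 1.0)]), set())

    def test_planted_fixture_partner_count(self):
        # 18 qualifying partners: 3 planted + 4 uncorrelated (>=2 seed edges)
        # + 11 single-seed, mirroring the published 18-partner subnetwork
        fx = gen_network_fixture(NetworkSpec(n_planted=3, n_decoy_uncorrelated=4,
                                             n_decoy_single_seed=11,
                                             n_decoy_low_conf=4, seed=9))
        partners = select_partners(fx.graph, fx.seeds)
        assert len(partners) == 18


class TestSetA:
    def test_multi_seed_threshold(self):
        pm = {"X": {"s1", "s2"}, "Y": {"s1"}}
        assert set_a(pm, 2) == {"X"}
        assert set_a(pm, 1) == {"X", "Y"}

    def test_monotone_in_seed_degree(self, rng):
        pm = {f"g{i}": set(rng.choice(20, size=rng.integers(1, 6), replace=False).tolist())
              for i in range(30)}
        for k in range(1, 6):
            assert set_a(pm, k + 1) <= set_a(pm, k)

    def test_fixture_recovers_planted_multi_seed_partners(self):
        # 14 multi-seed partners of 18, mirroring the published set A
        fx = gen_network_fixture(NetworkSpec(n_planted=10, n_decoy_uncorrelated=4,
                                             n_decoy_single_seed=4,
                                             n_decoy_low_conf=2, seed=13))
        partners = select_partners(fx.graph, fx.seeds)
        assert len(partners) == 18
        a = set_a(partners, 2)
        assert len(a) == 14
        assert a == set(fx.truth["planted"]) | set(fx.truth["decoys"]["uncorrelated_expression"])


class TestEnrichment:
    def test_pathway_equal_to_universe_has_p_one(self):
        universe = frozenset(f"g{i}" for i in range(50))
        pc = PathwayCollection({"all": universe}, universe)
        seeds = set(list(universe)[:10])
        df = hypergeometric_enrichment(seeds, pc)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_disjoint_pathway_has_p_one(self):
        universe = frozenset(f"g{i}" for i in range(100))
        pc = PathwayCollection({"away": frozenset(list(sorted(universe))[:10])}, universe)
        seeds = set(sorted(universe)[50:70])
        df = hypergeometric_enrichment(seeds, pc)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_tail_sum_matches_brute_force_enumeration(self):
        # universe 1000, 20 seeds, pathway of 30 containing 5 seeds
        N, n, K, k = 1000, 20, 30, 5
        expected = sum(
            math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1)
        ) / math.comb(N, n)
        genes = [f"g{i}" for i in range(N)]
        pathway = frozenset(genes[:K])
        seeds = set(genes[:k]) | set(genes[K:K + (n - k)])
        pc = PathwayCollection({"pw": pathway}, frozenset(genes))
        df = hypergeometric_enrichment(seeds, pc)
        assert df.loc[0, "overlap"] == k
        assert df.loc[0, "p_value"] == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_survival_function(self, rng):
        for _ in range(50):
            N = int(rng.integers(20, 200))
            genes = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            pathway = frozenset(rng.choice(genes, size=K, replace=False).tolist())
            seeds = set(rng.choice(genes, size=n, replace=False).tolist())
            pc = PathwayCollection({"pw": pathway}, frozenset(genes))
            ours = hypergeometric_enrichment(seeds, pc).loc[0, "p_value"]
            k = len(pathway & seeds)
            theirs = float(hypergeom.sf(k - 1, N, K, n))
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_invariant_under_gene_relabeling(self, rng):
        genes = [f"g{i}" for i in range(60)]
        pathway = set(genes[:12])
        seeds = set(genes[5:25])
        pc = PathwayCollection({"pw": frozenset(pathway)}, frozenset(genes))
        p0 = hypergeometric_enrichment(seeds, pc).loc[0, "p_value"]
        perm = dict(zip(genes, rng.permutation(genes)))
        pc2 = PathwayCollection({"pw": frozenset(perm[g] for g in pathway)},
                                frozenset(genes))
        p1 = hypergeometric_enrichment({perm[g] for g in seeds}, pc2).loc[0, "p_value"]
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_stray_seeds_dropped_with_warning(self):
        universe = frozenset(["a", "b", "c", "d"])
        pc = PathwayCollection({"pw": frozenset(["a", "b"])}, universe)
        with pytest.warns(UserWarning, match="outside the pathway universe"):
            df = hypergeometric_enrichment({"a", "zzz"}, pc)
        assert df.loc[0, "overlap"] == 1

    def test_empty_universe_rejected(self):
        with pytest.raises(DomainError):
            PathwayCollection({}, frozenset())

    def test_set_b_membership(self):
        pm = {"X": {"s1"}, "Y": {"s2"}}
        pc = PathwayCollection({"sig": frozenset(["X", "s1"]),
                                "null": frozenset(["Y"])},
                               frozenset(["X", "Y", "s1", "s2"]))
        enr = pd.DataFrame([{"pathway": "sig", "significant": True},
                            {"pathway": "null", "significant": False}])
        assert set_b(pm, pc, enr) == {"X"}

    def test_set_b_empty_without_significant_pathways(self):
        pm = {"X": {"s1"}}
        pc = PathwayCollection({"pw": frozenset(["X"])}, frozenset(["X", "s1"]))
        enr = pd.DataFrame([{"pathway": "pw", "significant": False}])
        assert set_b(pm, pc, enr) == set()


class TestExpressionFilter:
    def _expr(self, rows: dict) -> pd.DataFrame:
        tissues = ["transformed_fibroblasts"] + [f"t{i}" for i in range(1, 6)]
        return pd.DataFrame.from_dict(rows, orient="index", columns=tissues)

    def test_profile_identical_to_consensus_kept(self):
        consensus = [50.0, 1, 2, 3, 4, 5]
        expr = self._expr({"s1": consensus, "s2": consensus, "cand": consensus})
        kept, detail = expression_filter({"cand"}, {"s1", "s2"}, expr,
                                         ("transformed_fibroblasts",))
        assert kept == {"cand"}
        assert detail.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_ranking_dropped(self):
        expr = self._expr({"s1": [50, 1, 2, 3, 4, 5], "s2": [52, 1, 2, 3, 4, 5],
                           "cand": [1, 50, 40, 30, 20, 10]})
        kept, detail = expression_filter({"cand"}, {"s1", "s2"}, expr,
                                         ("transformed_fibroblasts",))
        assert kept == set()
        assert detail.loc[0, "rho"] < 0

    def test_marker_dominance_required_even_when_correlated(self):
        # correlated profile whose marker-tissue value sits below its own median
        expr = self._expr({"s1": [50, 1, 2, 3, 4, 5], "s2": [52, 1, 2, 3, 4, 5],
                           "cand": [2.5, 1, 2, 3, 4, 5]})
        kept, detail = expression_filter({"cand"}, {"s1", "s2"}, expr,
                                         ("transformed_fibroblasts",))
        assert kept == set()
        assert detail.loc[0, "rho"] >= 0.5 and not detail.loc[0, "marker_ok"]

    def test_candidate_missing_from_matrix_warns(self):
        expr = self._expr({"s1": [50, 1, 2, 3, 4, 5], "s2": [52, 1, 2, 3, 4, 5]})
        with pytest.warns(UserWarning, match="ghost"):
            kept, _ = expression_filter({"ghost"}, {"s1", "s2"}, expr,
                                        ("transformed_fibroblasts",))
        assert kept == set()

    def test_needs_two_seeds_and_known_marker(self):
        expr = self._expr({"s1": [50, 1, 2, 3, 4, 5], "c": [50, 1, 2, 3, 4, 5]})
        with pytest.raises(DomainError):
            expression_filter({"c"}, {"s1"}, expr, ("transformed_fibroblasts",))
        expr2 = self._expr({"s1": [50, 1, 2, 3, 4, 5], "s2": [50, 1, 2, 3, 4, 5]})
        with pytest.raises(DomainError):
            expression_filter(set(), {"s1", "s2"}, expr2, ("lung",))


class TestPrioritizeGenes:
    def test_full_fixture_flow(self):
        fx = gen_network_fixture(NetworkSpec(seed=21))
        report = prioritize_genes(fx.graph, fx.seeds, fx.pathways, fx.expression)
        planted = set(fx.truth["planted"])
        assert set(report.final) == planted
        # provenance columns present and coherent
        assert (report.table["seed_degree"] >= 2).all() or report.table["in_set_b"].any()
        assert set(report.a) <= set(report.partners)
        assert set(report.b) <= set(report.partners)
        final = set(report.final)
        assert final <= (report.a | report.b)
        assert final.isdisjoint(fx.seeds)

    def test_seeds_with_no_partners_give_empty_report(self):
        g = _graph([("s1", "s2", 1.0, 1.0)])
        pc = PathwayCollection({"pw": frozenset(["s1"])}, frozenset(["s1", "s2"]))
        expr = pd.DataFrame(
            np.abs(np.random.default_rng(0).normal(size=(2, 4))) + 0.1,
            index=["s1", "s2"],
            columns=["transformed_fibroblasts", "t1", "t2", "t3"],
        )
        report = prioritize_genes(g, {"s1", "s2"}, pc, expr)
        assert report.final == []

    def test_union_idempotent_when_sets_coincide(self):
        pm_a = {"X": {"s1", "s2"}}
        assert set_a(pm_a, 2) | {"X"} == {"X"}

    def test_report_ordering_deterministic(self):
        fx = gen_network_fixture(NetworkSpec(n_planted=5, seed=3))
        r1 = prioritize_genes(fx.graph, fx.seeds, fx.pathways, fx.expression)
        r2 = prioritize_genes(fx.graph, fx.seeds, fx.pathways, fx.expression)
        assert r1.table.equals(r2.table)
        deg = r1.table["seed_degree"].tolist()
        assert deg == sorted(deg, reverse=True)
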