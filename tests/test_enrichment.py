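"""Annotation propagation, DAG levels, hypergeometric test, BH FDR."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pycher.enrichment import (
    AnnotationSet,
    TermGraph,
    bh_adjust,
    enrich,
    hypergeometric_test,
    intersect_with_expression,
    propagate_annotations,
    term_level,
    term_levels,
)
from pycher.errors import ValidationError


def chain_graph():
    return TermGraph.from_edges([("B", "A"), ("A", "root")])


class TestPropagation:
    def test_chain_closure(self):
        result = propagate_annotations(chain_graph(), {"g1": {"B"}})
        assert result.propagated["g1"] == {"B", "A", "root"}

    def test_root_annotation_is_fixed_point(self):
        result = propagate_annotations(chain_graph(), {"g1": {"root"}})
        assert result.propagated["g1"] == {"root"}

    def test_unknown_terms_skipped_and_counted(self):
        result = propagate_annotations(chain_graph(), {"g1": {"B", "NOPE"}})
        assert result.n_skipped == 1
        assert result.propagated["g1"] == {"B", "A", "root"}

    def test_random_dag_matches_reachability_oracle(self, rng):
        # random DAG on 50 terms: edges only from higher to lower index
        terms = [f"t{i}" for i in range(50)]
        edges = []
        parents = {t: [] for t in terms}
        for i in range(1, 50):
            for j in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
                edges.append((terms[i], terms[int(j)]))
                parents[terms[i]].append(terms[int(j)])
        graph = TermGraph.from_edges(edges)

        def reach(term):  # hand-rolled DFS over the parent lists
            seen, stack = set(), [term]
            while stack:
                t = stack.pop()
                if t in seen:
                    continue
                seen.add(t)
                stack.extend(parents[t])
            return seen

        direct = {f"g{i}": {terms[int(rng.integers(0, 50))]} for i in range(20)}
        result = propagate_annotations(graph, direct)
        for gene, annotated in direct.items():
            assert result.propagated[gene] == reach(next(iter(annotated)))

    def test_direct_subset_of_propagated(self):
        result = propagate_annotations(chain_graph(), {"g": {"B"}, "h": {"A"}})
        for gene in result.direct:
            assert result.direct[gene] <= result.propagated[gene]

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValidationError):
            TermGraph.from_edges([("A", "B"), ("B", "A")])


class TestLevels:
    def test_root_is_level_one_child_level_two(self):
        graph = chain_graph()
        assert term_level(graph, "root") == 1
        assert term_level(graph, "A") == 2
        assert term_level(graph, "B") == 3

    def test_level_is_shortest_path_from_any_root(self, rng):
        terms = [f"t{i}" for i in range(30)]
        edges, parents = [], {t: [] for t in terms}
        for i in range(1, 30):
            for j in rng.choice(i, size=min(i, 2), replace=False):
                edges.append((terms[i], terms[int(j)]))
                parents[terms[i]].append(terms[int(j)])
        graph = TermGraph.from_edges(edges)

        def oracle(term):  # recursive shortest-path depth over parents
            if not parents[term]:
                return 1
            return 1 + min(oracle(p) for p in parents[term])

        levels = term_levels(graph)
        for t in terms:
            assert levels[t] == oracle(t)

    def test_unknown_term_rejected(self):
        with pytest.raises(ValidationError):
            term_level(chain_graph(), "missing")


def exact_tail(k, K, n, N):
    """Upper tail from exact integer arithmetic."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestHypergeometric:
    def test_zero_successes_is_certain(self):
        assert hypergeometric_test(0, 3, 3, 10) == pytest.approx(1.0)

    def test_forced_draw_is_certain(self):
        assert hypergeometric_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_full_enumeration(self):
        # literal enumeration over all C(10, 3) draws
        universe = range(10)
        annotated = set(range(3))
        draws = list(itertools.combinations(universe, 3))
        frac = sum(1 for d in draws if len(annotated & set(d)) >= 2) / len(draws)
        assert hypergeometric_test(2, 3, 3, 10) == pytest.approx(frac, abs=1e-12)

    def test_matches_exact_integer_tail(self, rng):
        for _ in range(100):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_test(k, K, n, N) == pytest.approx(
                exact_tail(k, K, n, N), abs=1e-12
            )

    def test_tail_non_increasing_in_k(self):
        tails = [hypergeometric_test(k, 10, 15, 40) for k in range(11)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_test(4, 3, 5, 10)
        with pytest.raises(ValidationError):
            hypergeometric_test(1, 11, 5, 10)


def bh_oracle(pvalues):
    """Literal step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    out = [None] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvalues[i] / rank)
        out[i] = min(1.0, running)
    return out


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_hand_enumerated_example(self):
        # m=4: q4=0.5; q3=min(0.5, 4*0.03/3)=0.04; q2=min(0.04, 4*0.02/2)=0.04;
        # q1=min(0.04, 4*0.01/1)=0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.5]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.5]
        )

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_literal_step_up_oracle(self, pvalues):
        np.testing.assert_allclose(bh_adjust(pvalues), bh_oracle(pvalues), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.random(int(rng.integers(1, 80)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_along_sorted_order(self, rng):
        p = rng.random(50)
        adjusted = bh_adjust(p)
        assert np.all(np.diff(adjusted[np.argsort(p)]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestEnrich:
    def flat_annotations(self):
        # 7400-gene universe, every gene annotated to ALL; term T covers 248
        # reference genes, 30 of the 100 target genes
        genes = [f"g{i}" for i in range(7400)]
        target = genes[:100]
        in_term = set(genes[:30]) | set(genes[100 : 100 + 218])
        direct = {g: ({"ALL", "T"} if g in in_term else {"ALL"}) for g in genes}
        return genes, target, direct

    def test_counts_and_p_match_composed_oracles(self):
        genes, target, direct = self.flat_annotations()
        results = enrich(target, genes, direct, graph=None, min_k=2)
        by_id = {r.term_id: r for r in results}
        r = by_id["T"]
        assert (r.k, r.K, r.n, r.N) == (30, 248, 100, 7400)
        assert r.expected == pytest.approx(100 * 248 / 7400)
        assert r.p == pytest.approx(exact_tail(30, 248, 100, 7400), rel=1e-9)
        assert r.fdr == pytest.approx(
            bh_oracle([by_id["ALL"].p, r.p])[1], rel=1e-9
        )

    def test_target_equal_reference_gives_p_one(self):
        genes, _, direct = self.flat_annotations()
        results = enrich(genes, genes, direct, graph=None)
        assert all(r.p == pytest.approx(1.0) for r in results)

    def test_min_k_excludes_singleton_overlaps(self):
        direct = {"g1": {"T1"}, "g2": {"T2"}, "g3": {"T2"}, "g4": {"T2"}}
        results = enrich({"g1", "g2", "g3"}, set(direct), direct, graph=None, min_k=2)
        assert {r.term_id for r in results} == {"T2"}

    def test_dag_mode_reports_levels_and_level_filter(self):
        graph = chain_graph()
        direct = {f"g{i}": {"B"} for i in range(6)}
        direct.update({f"h{i}": {"A"} for i in range(6)})
        ann = propagate_annotations(graph, direct)
        target = {"g0", "g1", "g2", "h0"}
        results = enrich(target, set(ann.propagated), ann, graph)
        levels = {r.term_id: r.level for r in results}
        assert levels["root"] == 1 and levels["A"] == 2 and levels["B"] == 3
        only_b = enrich(target, set(ann.propagated), ann, graph, level_filter=3)
        assert {r.term_id for r in only_b} == {"B"}

    def test_unannotated_target_rejected(self):
        direct = {"g1": {"T"}, "g2": {"T"}}
        with pytest.raises(ValidationError):
            enrich({"x1", "x2"}, {"g1", "g2", "x1", "x2"}, direct, graph=None)


class TestExpressionIntersection:
    def make_de(self, genes, fcs):
        import pandas as pd

        return pd.DataFrame({"gene": genes, "log2fc": fcs, "fdr": [0.01] * len(genes)})

    def test_disjoint_sets_empty(self):
        de = self.make_de(["a", "b"], [1.0, -1.0])
        assert intersect_with_expression({"x", "y"}, de) == (set(), set(), set())

    def test_de_subset_partitions_by_direction(self):
        de = self.make_de(["a", "b", "c"], [2.0, -1.0, 1.5])
        all_de, up, down = intersect_with_expression({"a", "b", "c", "d"}, de)
        assert all_de == {"a", "b", "c"}
        assert up == {"a", "c"} and down == {"b"}

    def test_random_sets_match_set_oracle(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        targets = set(rng.choice(universe, 200, replace=False))
        de_genes = list(rng.choice(universe, 300, replace=False))
        fcs = rng.normal(size=300)
        de = self.make_de(de_genes, fcs)
        all_de, up, down = intersect_with_expression(targets, de)
        up_oracle = {g for g, f in zip(de_genes, fcs) if f > 0} & targets
        down_oracle = {g for g, f in zip(de_genes, fcs) if f < 0} & targets
        assert all_de == set(de_genes) & targets
        assert up == up_oracle and down == down_oracle
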