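"""Graph-level machinery: validity, d-separation, separators, enumeration."""

import itertools

import networkx as nx
import numpy as np
import pytest

from foodsecbn import (
    CausalOrdering,
    IndependenceRelation,
    NetworkStructure,
    Variable,
    d_separated,
    find_minimal_separator,
    implied_independencies,
    reduce_relationships,
    validate_dag,
)

from conftest import dsep_moral, random_dag


def _structure(names: str, edges: set[tuple[str, str]]) -> NetworkStructure:
    return NetworkStructure([Variable(n, ("0", "1")) for n in names], edges)


class TestValidateDag:
    def test_chain_is_valid(self):
        report = validate_dag(_structure("ABC", {("A", "B"), ("B", "C")}))
        assert report.ok and report.violations == []

    def test_two_cycle_reported(self):
        report = validate_dag(_structure("AB", {("A", "B"), ("B", "A")}))
        assert not report.ok
        assert any("cycle" in v and "A" in v and "B" in v for v in report.violations)

    def test_unknown_endpoint_reported(self):
        report = validate_dag(_structure("AB", {("A", "X")}))
        assert not report.ok
        assert any("unknown variable" in v for v in report.violations)

    def test_self_loop_reported(self):
        report = validate_dag(_structure("AB", {("A", "A")}))
        assert not report.ok
        assert any("self-loop" in v for v in report.violations)


class TestDSeparation:
    def test_chain_blocked_by_middle(self):
        s = _structure("ABC", {("A", "B"), ("B", "C")})
        assert d_separated(s, "A", "C", {"B"})
        assert not d_separated(s, "A", "C", set())

    def test_collider_opens_when_conditioned(self):
        s = _structure("ABC", {("A", "C"), ("B", "C")})
        assert d_separated(s, "A", "B", set())
        assert not d_separated(s, "A", "B", {"C"})

    def test_descendant_of_collider_opens_path(self):
        s = _structure("ABCD", {("A", "C"), ("B", "C"), ("C", "D")})
        assert not d_separated(s, "A", "B", {"D"})

    def test_unknown_variable_raises(self):
        s = _structure("AB", set())
        with pytest.raises(KeyError):
            d_separated(s, "A", "X", set())

    def test_matches_moral_graph_oracle_on_random_dags(self):
        """200 random queries agree with an independent moral-graph oracle."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            s = random_dag(rng, int(rng.integers(4, 11)))
            g = s.to_networkx()
            names = s.names
            for _ in range(10):
                a, b = rng.choice(names, size=2, replace=False)
                rest = [n for n in names if n not in (a, b)]
                cond = {
                    n for n in rest if rng.random() < 0.3
                }
                ours = d_separated(s, a, b, cond)
                assert ours == dsep_moral(s, a, b, cond)
                assert ours == nx.is_d_separator(g, {a}, {b}, cond)
                checked += 1

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            s = random_dag(rng, 7)
            names = s.names
            a, b = rng.choice(names, size=2, replace=False)
            cond = {n for n in names if n not in (a, b) and rng.random() < 0.3}
            assert d_separated(s, a, b, cond) == d_separated(s, b, a, cond)

    def test_adding_edge_never_creates_separation(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            s = random_dag(rng, 6, edge_prob=0.3)
            names = s.names
            non_edges = [
                (names[i], names[j])
                for i, j in itertools.combinations(range(len(names)), 2)
                if (names[i], names[j]) not in s.edges
            ]
            if not non_edges:
                continue
            extra = non_edges[int(rng.integers(len(non_edges)))]
            bigger = NetworkStructure(
                s.variables.values(), s.edges | {extra}
            )
            for a, b in itertools.combinations(names, 2):
                for cond_size in (0, 1):
                    for cond in itertools.combinations(
                        [n for n in names if n not in (a, b)], cond_size
                    ):
                        if d_separated(bigger, a, b, set(cond)):
                            assert d_separated(s, a, b, set(cond))


class TestMinimalSeparator:
    def test_chain_middle_node(self):
        s = _structure("ABC", {("A", "B"), ("B", "C")})
        assert find_minimal_separator(s, "A", "C") == {"B"}

    def test_collider_pair_marginally_independent(self):
        s = _structure("ABC", {("A", "C"), ("B", "C")})
        assert find_minimal_separator(s, "A", "B") == frozenset()

    def test_adjacent_pair_raises(self):
        s = _structure("AB", {("A", "B")})
        with pytest.raises(ValueError, match="adjacent"):
            find_minimal_separator(s, "A", "B")

    def test_cardinality_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            s = random_dag(rng, int(rng.integers(4, 9)), edge_prob=0.3)
            names = s.names
            for a, b in itertools.combinations(names, 2):
                if s.adjacent(a, b):
                    continue
                rest = [n for n in names if n not in (a, b)]
                brute_best = None
                for size in range(len(rest) + 1):
                    found = [
                        set(c)
                        for c in itertools.combinations(rest, size)
                        if dsep_moral(s, a, b, set(c))
                    ]
                    if found:
                        brute_best = size
                        break
                ours = find_minimal_separator(s, a, b)
                if brute_best is None:
                    assert ours is None
                else:
                    assert ours is not None and len(ours) == brute_best
                    assert d_separated(s, a, b, ours)


class TestReduceRelationships:
    def test_chain_reports_later_variable_first(self):
        s = _structure("ABC", {("A", "B"), ("B", "C")})
        ordering = CausalOrdering([["A"], ["B"], ["C"]])
        rels = reduce_relationships(s, ordering)
        assert rels == [IndependenceRelation("C", "A", frozenset({"B"}))]

    def test_complete_dag_yields_nothing(self):
        names = "ABCD"
        edges = {
            (names[i], names[j])
            for i, j in itertools.combinations(range(4), 2)
        }
        s = _structure(names, edges)
        ordering = CausalOrdering([[n] for n in names])
        assert reduce_relationships(s, ordering) == []

    def test_count_matches_exhaustive_pair_search(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            s = random_dag(rng, 7, edge_prob=0.25)
            ordering = CausalOrdering([[n] for n in s.names])
            rels = reduce_relationships(s, ordering)
            expected = 0
            for a, b in itertools.combinations(s.names, 2):
                if s.adjacent(a, b):
                    continue
                rest = [n for n in s.names if n not in (a, b)]
                separable = any(
                    dsep_moral(s, a, b, set(c))
                    for size in range(len(rest) + 1)
                    for c in itertools.combinations(rest, size)
                )
                expected += separable
            assert len(rels) == expected
            for rel in rels:
                assert ordering.before(rel.B, rel.A)
                assert d_separated(s, rel.A, rel.B, rel.C)

    def test_uncovered_ordering_rejected(self):
        s = _structure("ABC", set())
        with pytest.raises(ValueError, match="cover"):
            reduce_relationships(s, CausalOrdering([["A"], ["B"]]))


class TestImpliedIndependencies:
    def test_chain_single_relation(self):
        s = _structure("ABC", {("A", "B"), ("B", "C")})
        rels = implied_independencies(s, max_conditioning=1)
        assert rels == [IndependenceRelation("A", "C", frozenset({"B"}))]

    def test_empty_graph_everything_independent(self):
        s = _structure("ABC", set())
        rels = implied_independencies(s, max_conditioning=1)
        # 3 pairs at |C|=0 plus 3 pairs each conditioned on the third node
        assert len(rels) == 6
        assert all(d_separated(s, r.A, r.B, r.C) for r in rels)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(41)
        for _ in range(8):
            s = random_dag(rng, 6, edge_prob=0.3)
            rels = implied_independencies(s, max_conditioning=2)
            count = 0
            for a, b in itertools.combinations(sorted(s.names), 2):
                rest = [n for n in s.names if n not in (a, b)]
                for size in range(3):
                    for cond in itertools.combinations(sorted(rest), size):
                        if dsep_moral(s, a, b, set(cond)):
                            count += 1
            assert len(rels) == count
            assert all(d_separated(s, r.A, r.B, r.C) for r in rels)

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            implied_independencies(_structure("AB", set()), -1)


class TestDomainTypes:
    def test_variable_needs_two_states(self):
        with pytest.raises(ValueError):
            Variable("X", ("only",))

    def test_independence_relation_disjointness(self):
        with pytest.raises(ValueError):
            IndependenceRelation("A", "A")
        with pytest.raises(ValueError):
            IndependenceRelation("A", "B", frozenset({"A"}))

    def test_ordering_rejects_duplicates(self):
        with pytest.raises(ValueError):
            CausalOrdering([["A"], ["A"]])

    def test_cpt_row_normalisation_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            from foodsecbn import CPT

            CPT("X", [], np.array([0.5, 0.6]))
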