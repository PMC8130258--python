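"""Graph-surgery interventions and the sensitivity metrics."""

import itertools

import numpy as np
import pytest

from foodsecbn import (
    CPT,
    BayesianNetwork,
    InterventionSpec,
    NetworkStructure,
    Variable,
    do_surgery,
    expected_change_of_belief,
    interventional_query,
    mutual_information_reduction,
    posterior,
    sensitivity_table,
)

from conftest import enumerated_joint, random_dag, random_network


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestDoSurgery:
    def test_root_intervention_keeps_structure(self, chain_network):
        cut = do_surgery(chain_network, InterventionSpec({"A": 1}))
        assert cut.structure.edges == chain_network.structure.edges
        np.testing.assert_array_equal(cut.cpts["A"].table, [0.0, 1.0])

    def test_non_intervened_cpts_bit_identical(self, confounder_network):
        cut = do_surgery(confounder_network, InterventionSpec({"X": 0}))
        for name in ("Z", "Y"):
            assert cut.cpts[name].table is confounder_network.cpts[name].table

    def test_incoming_edges_removed(self, confounder_network):
        cut = do_surgery(confounder_network, InterventionSpec({"X": 1}))
        assert cut.structure.parents("X") == []
        assert ("Z", "Y") in cut.structure.edges

    def test_unknown_variable_rejected(self, chain_network):
        with pytest.raises(KeyError):
            do_surgery(chain_network, InterventionSpec({"Q": 0}))

    def test_backdoor_adjustment_identity(self, confounder_network):
        """P(Y | do(X=x)) equals the adjustment sum over the confounder."""
        net = confounder_network
        for x in range(2):
            surgical = interventional_query(
                net, "Y", InterventionSpec({"X": x})
            ).distribution
            p_z = posterior(net, "Z").distribution
            adjusted = sum(
                p_z[z] * posterior(net, "Y", {"X": x, "Z": z}).distribution
                for z in range(2)
            )
            np.testing.assert_allclose(surgical, adjusted, atol=1e-10)

    def test_backdoor_adjustment_on_random_networks(self):
        """Surgery equals parent-set adjustment computed from the raw joint."""
        rng = np.random.default_rng(19)
        for _ in range(20):
            net = random_network(rng, random_dag(rng, 5))
            names = net.names
            x = names[int(rng.integers(len(names) - 1))]
            y = names[-1]
            if x == y:
                continue
            parents = net.structure.parents(x)
            x_state = int(rng.integers(net.structure.cardinality(x)))
            surgical = interventional_query(
                net, y, InterventionSpec({x: x_state})
            ).distribution

            joint_names, joint = enumerated_joint(net)
            y_card = net.structure.cardinality(y)
            adjusted = np.zeros(y_card)
            parent_cards = [net.structure.cardinality(p) for p in parents]
            for k in itertools.product(*(range(c) for c in parent_cards)):
                ev = dict(zip(parents, k))
                p_k = _marginal_prob(joint_names, joint, ev)
                if p_k <= 0:
                    continue
                cond = _conditional(joint_names, joint, y, {**ev, x: x_state})
                adjusted += p_k * cond
            np.testing.assert_allclose(surgical, adjusted, atol=1e-9)


def _marginal_prob(names, joint, assignment) -> float:
    idx = [slice(None)] * joint.ndim
    for var, s in assignment.items():
        idx[names.index(var)] = s
    return float(joint[tuple(idx)].sum())


def _conditional(names, joint, target, assignment) -> np.ndarray:
    t_ax = names.index(target)
    card = joint.shape[t_ax]
    out = np.zeros(card)
    for s in range(card):
        out[s] = _marginal_prob(names, joint, {**assignment, target: s})
    return out / out.sum()


class TestInterventionalQuery:
    def test_do_on_root_equals_conditioning(self, chain_network):
        for a in range(2):
            do_p = interventional_query(
                chain_network, "C", InterventionSpec({"A": a})
            ).distribution
            see_p = posterior(chain_network, "C", {"A": a}).distribution
            np.testing.assert_allclose(do_p, see_p, atol=1e-12)

    def test_do_without_directed_path_leaves_marginal(self, confounder_network):
        """Intervening on the effect does not move its causes."""
        base = posterior(confounder_network, "Z").distribution
        cut = interventional_query(
            confounder_network, "Z", InterventionSpec({"Y": 1})
        ).distribution
        np.testing.assert_allclose(cut, base, atol=1e-12)

    def test_target_inside_spec_rejected(self, chain_network):
        with pytest.raises(ValueError):
            interventional_query(chain_network, "A", InterventionSpec({"A": 0}))

    def test_multi_variable_surgery(self, confounder_network):
        post = interventional_query(
            confounder_network, "Y", InterventionSpec({"X": 1, "Z": 0})
        )
        # both incoming edge sets removed: Y's CPT row is the answer
        np.testing.assert_allclose(
            post.distribution,
            confounder_network.cpts["Y"].table[1, 0],
            atol=1e-12,
        )


def _disconnected_pair() -> BayesianNetwork:
    v = [Variable("X", ("0", "1")), Variable("FS", ("secure", "insecure"))]
    s = NetworkStructure(v, set())
    return BayesianNetwork(
        s,
        {
            "X": CPT("X", [], np.array([0.4, 0.6])),
            "FS": CPT("FS", [], np.array([0.9, 0.1])),
        },
    )


def _copy_pair() -> BayesianNetwork:
    v = [Variable("X", ("0", "1")), Variable("FS", ("secure", "insecure"))]
    s = NetworkStructure(v, {("X", "FS")})
    return BayesianNetwork(
        s,
        {
            "X": CPT("X", [], np.array([0.7, 0.3])),
            "FS": CPT("FS", ["X"], np.eye(2)),
        },
    )


class TestSensitivityMetrics:
    def test_disconnected_variable_carries_no_information(self):
        net = _disconnected_pair()
        i, ratio, degenerate = mutual_information_reduction(net, "FS", "X")
        assert i == pytest.approx(0.0, abs=1e-12)
        assert ratio == pytest.approx(0.0, abs=1e-12)
        assert not degenerate
        assert expected_change_of_belief(net, "FS", "X") == pytest.approx(0.0, abs=1e-12)

    def test_perfect_copy_saturates_the_ratio(self):
        net = _copy_pair()
        i, ratio, _ = mutual_information_reduction(net, "FS", "X")
        h = _entropy_bits(np.array([0.7, 0.3]))
        assert i == pytest.approx(h, abs=1e-10)
        assert ratio == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_from_enumerated_joint(self, confounder_network):
        net = confounder_network
        names, joint = enumerated_joint(net)
        for variable in ("X", "Z"):
            p_y = _conditional(names, joint, "Y", {})
            h_y = _entropy_bits(p_y)
            i_brute = h_y
            s2_brute = 0.0
            card = net.structure.cardinality(variable)
            for x in range(card):
                p_x = _marginal_prob(names, joint, {variable: x})
                cond = _conditional(names, joint, "Y", {variable: x})
                i_brute -= p_x * _entropy_bits(cond)
                s2_brute += p_x * float(np.sum((cond - p_y) ** 2))
            i, ratio, _ = mutual_information_reduction(net, "Y", variable)
            assert i == pytest.approx(i_brute, abs=1e-10)
            assert ratio == pytest.approx(i_brute / h_y, abs=1e-10)
            assert expected_change_of_belief(net, "Y", variable) == pytest.approx(
                s2_brute, abs=1e-10
            )

    def test_information_bounded_by_both_entropies(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            net = random_network(rng, random_dag(rng, 6))
            target = net.names[-1]
            h_t = _entropy_bits(posterior(net, target).distribution)
            for variable in net.names[:-1]:
                i, ratio, _ = mutual_information_reduction(net, target, variable)
                h_x = _entropy_bits(posterior(net, variable).distribution)
                assert -1e-10 <= i <= min(h_t, h_x) + 1e-9
                assert -1e-10 <= ratio <= 1 + 1e-9

    def test_same_variable_rejected(self, chain_network):
        with pytest.raises(ValueError):
            mutual_information_reduction(chain_network, "A", "A")


class TestSensitivityTable:
    def test_rows_sorted_and_consistent_with_single_ops(self, confounder_network):
        rows = sensitivity_table(confounder_network, target="Y")
        assert [r.variable for r in rows] == ["X", "Z"]
        for row in rows:
            i, ratio, _ = mutual_information_reduction(
                confounder_network, "Y", row.variable
            )
            assert row.I == pytest.approx(i)
            assert row.I_over_H == pytest.approx(ratio)
            assert row.S2 == pytest.approx(
                expected_change_of_belief(confounder_network, "Y", row.variable)
            )
            assert 0 <= row.I_over_H <= 1

    def test_disconnected_outcome_gives_zero_table(self):
        rows = sensitivity_table(_disconnected_pair(), target="FS")
        assert all(r.I == pytest.approx(0, abs=1e-12) for r in rows)
        assert all(r.S2 == pytest.approx(0, abs=1e-12) for r in rows)
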