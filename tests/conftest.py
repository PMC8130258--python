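"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own algorithms:
d-separation is re-derived via moral ancestral graphs, joint distributions
by explicit product-of-CPT accumulation over all assignments, and the
Jonckheere-Terpstra null moments by exhaustive permutation enumeration.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from foodsecbn import (
    CPT,
    BayesianNetwork,
    NetworkStructure,
    Variable,
)


# ---------------------------------------------------------------------------
# random model construction


def random_dag(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.35,
    max_card: int = 3,
) -> NetworkStructure:
    """Random DAG over nodes V0..V{n-1}; edges only forward in index order."""
    names = [f"V{i}" for i in range(n_nodes)]
    cards = rng.integers(2, max_card + 1, size=n_nodes)
    variables = [
        Variable(n, tuple(f"s{j}" for j in range(c)))
        for n, c in zip(names, cards)
    ]
    edges = set()
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            edges.add((names[i], names[j]))
    return NetworkStructure(variables, edges)


def random_network(
    rng: np.random.Generator,
    structure: NetworkStructure,
    concentration: float = 1.0,
) -> BayesianNetwork:
    """Strictly positive Dirichlet CPTs on a given structure."""
    cpts = {}
    for name in structure.variables:
        parents = structure.parents(name)
        card = structure.cardinality(name)
        shape = tuple(structure.cardinality(p) for p in parents) + (card,)
        flat = rng.dirichlet(np.full(card, concentration), size=int(np.prod(shape[:-1], dtype=int)))
        flat = np.clip(flat, 1e-6, None)
        flat /= flat.sum(axis=-1, keepdims=True)
        cpts[name] = CPT(name, parents, flat.reshape(shape))
    return BayesianNetwork(structure, cpts)


# ---------------------------------------------------------------------------
# d-separation oracle: moral ancestral graph reachability


def dsep_moral(structure: NetworkStructure, a: str, b: str, cond) -> bool:
    cond = set(cond)
    parents = {n: set() for n in structure.variables}
    for p, c in structure.edges:
        parents[c].add(p)
    # ancestral set of {a, b} | cond
    anc: set[str] = set()
    frontier = {a, b, *cond}
    while frontier:
        n = frontier.pop()
        if n in anc:
            continue
        anc.add(n)
        frontier |= parents[n]
    # moralise: undirected edges among ancestors, plus co-parent marriages
    adj: dict[str, set[str]] = {n: set() for n in anc}
    for p, c in structure.edges:
        if p in anc and c in anc:
            adj[p].add(c)
            adj[c].add(p)
    for c in anc:
        ps = [p for p in parents[c] if p in anc]
        for u, v in itertools.combinations(ps, 2):
            adj[u].add(v)
            adj[v].add(u)
    # remove conditioned nodes, test connectivity a -> b
    queue = deque([a])
    seen = {a} | cond
    while queue:
        n = queue.popleft()
        if n == b:
            return False
        for m in adj[n]:
            if m not in seen:
                seen.add(m)
                queue.append(m)
    return True


# ---------------------------------------------------------------------------
# joint-distribution oracle


def enumerated_joint(network: BayesianNetwork) -> tuple[list[str], np.ndarray]:
    """Full joint table by direct product of CPT entries per assignment."""
    names = network.names
    cards = [network.structure.cardinality(n) for n in names]
    joint = np.zeros(cards)
    for assignment in itertools.product(*(range(c) for c in cards)):
        m = dict(zip(names, assignment))
        p = 1.0
        for n in names:
            cpt = network.cpts[n]
            key = tuple(m[q] for q in cpt.parents) + (m[n],)
            p *= float(cpt.table[key])
        joint[assignment] = p
    return names, joint


def conditional_mutual_information(
    names: list[str], joint: np.ndarray, a: str, b: str, cond
) -> float:
    """Exact CMI I(a; b | cond) in nats from a full joint table."""
    keep = [a, b, *sorted(cond)]
    axes = tuple(i for i, n in enumerate(names) if n not in keep)
    marg = joint.sum(axis=axes)
    order = [n for n in names if n in keep]
    marg = np.moveaxis(
        marg, [order.index(n) for n in keep], range(len(keep))
    )
    p_abc = marg.reshape(marg.shape[0], marg.shape[1], -1)
    p_c = p_abc.sum(axis=(0, 1))
    p_ac = p_abc.sum(axis=1)
    p_bc = p_abc.sum(axis=0)
    cmi = 0.0
    for i, j, k in itertools.product(
        range(p_abc.shape[0]), range(p_abc.shape[1]), range(p_abc.shape[2])
    ):
        p = p_abc[i, j, k]
        if p <= 0:
            continue
        cmi += p * np.log(p * p_c[k] / (p_ac[i, k] * p_bc[j, k]))
    return cmi


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra oracles


def jt_statistic_brute(x: np.ndarray, y: np.ndarray) -> float:
    """T by direct pairwise comparison, ties in y counted 1/2."""
    t = 0.0
    n = len(x)
    for u in range(n):
        for v in range(n):
            if x[u] < x[v]:
                if y[u] < y[v]:
                    t += 1.0
                elif y[u] == y[v]:
                    t += 0.5
    return t


def jt_null_moments_exhaustive(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Exact permutation-null mean and variance of T (n small)."""
    values = []
    for perm in itertools.permutations(y):
        values.append(jt_statistic_brute(x, np.array(perm)))
    values = np.array(values)
    return float(values.mean()), float(values.var())


# ---------------------------------------------------------------------------
# small worked networks


@pytest.fixture
def chain_network() -> BayesianNetwork:
    """A -> B -> C, binary, strong monotone dependence."""
    v = [Variable(n, ("0", "1")) for n in "ABC"]
    s = NetworkStructure(v, {("A", "B"), ("B", "C")})
    cpts = {
        "A": CPT("A", [], np.array([0.6, 0.4])),
        "B": CPT("B", ["A"], np.array([[0.8, 0.2], [0.2, 0.8]])),
        "C": CPT("C", ["B"], np.array([[0.9, 0.1], [0.3, 0.7]])),
    }
    return BayesianNetwork(s, cpts)


@pytest.fixture
def confounder_network() -> BayesianNetwork:
    """Z -> X -> Y with Z -> Y: the textbook backdoor situation."""
    v = [Variable(n, ("0", "1")) for n in "ZXY"]
    s = NetworkStructure(v, {("Z", "X"), ("X", "Y"), ("Z", "Y")})
    cpts = {
        "Z": CPT("Z", [], np.array([0.7, 0.3])),
        "X": CPT("X", ["Z"], np.array([[0.9, 0.1], [0.4, 0.6]])),
        "Y": CPT(
            "Y",
            ["X", "Z"],
            np.array([[[0.8, 0.2], [0.5, 0.5]], [[0.6, 0.4], [0.1, 0.9]]]),
        ),
    }
    return BayesianNetwork(s, cpts)
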