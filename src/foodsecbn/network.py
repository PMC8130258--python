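"""Core domain types for discrete Bayesian belief networks.

A belief network over household characteristics is a directed acyclic graph
(DAG) whose nodes are ordinal discrete variables (e.g. socio-economic status,
water access) and whose edges encode direct probabilistic dependence, read
causally: an edge A -> B says A is a direct cause of B.  Each node carries a
conditional probability table (CPT) giving P(node = j | parents = k) for every
state j and parent configuration k.

This module holds the graph-level machinery: structural validation,
d-separation, minimal separating sets, and the enumeration of implied
conditional-independence relations used to audit a structure against domain
expectations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Variable",
    "NetworkStructure",
    "CausalOrdering",
    "CPT",
    "BayesianNetwork",
    "IndependenceRelation",
    "validate_dag",
    "d_separated",
    "find_minimal_separator",
    "reduce_relationships",
    "implied_independencies",
]


@dataclass(frozen=True)
class Variable:
    """A named ordinal discrete variable.

    States are ordered; state index 0..r-1 carries ordinal meaning (for the
    food-security outcome FS, index 0 means "food secure").
    """

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def cardinality(self) -> int:
        return len(self.states)


class NetworkStructure:
    """A DAG over named variables.

    Edge set is stored as ordered (parent, child) pairs.  Construction does not
    enforce acyclicity (``validate_dag`` reports violations instead of raising)
    but most operations assume a valid DAG.
    """

    def __init__(
        self,
        variables: Iterable[Variable],
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.variables: dict[str, Variable] = {}
        for v in variables:
            if v.name in self.variables:
                raise ValueError(f"duplicate variable {v.name!r}")
            self.variables[v.name] = v
        self.edges: set[tuple[str, str]] = set()
        for parent, child in edges:
            self.edges.add((parent, child))

    # -- basic accessors -------------------------------------------------

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    def parents(self, name: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == name)

    def children(self, name: str) -> list[str]:
        return sorted(c for p, c in self.edges if p == name)

    def adjacent(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def cardinality(self, name: str) -> int:
        return self.variables[name].cardinality

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(sorted(self.edges))
        return g

    def topological_order(self) -> list[str]:
        # lexicographic tie-break: stable across processes and hash seeds
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def copy(self) -> "NetworkStructure":
        return NetworkStructure(self.variables.values(), set(self.edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkStructure):
            return NotImplemented
        return self.variables == other.variables and self.edges == other.edges

    def __repr__(self) -> str:
        return (
            f"NetworkStructure({len(self.variables)} variables, "
            f"{len(self.edges)} edges)"
        )


@dataclass
class CausalOrdering:
    """Variables grouped into causal levels; earlier levels may cause later.

    The implied total order is by level, then by position within a level (the
    elicitation list order).  The outcome variable (food security) sits alone
    in the last level: it causes nothing.
    """

    levels: list[list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for level in self.levels:
            for name in level:
                if name in seen:
                    raise ValueError(f"variable {name!r} appears twice in ordering")
                seen.add(name)

    @property
    def names(self) -> list[str]:
        return [n for level in self.levels for n in level]

    def index(self, name: str) -> int:
        """Position of ``name`` in the implied total order."""
        for i, n in enumerate(self.names):
            if n == name:
                return i
        raise KeyError(f"variable {name!r} not in ordering")

    def level_of(self, name: str) -> int:
        for li, level in enumerate(self.levels):
            if name in level:
                return li
        raise KeyError(f"variable {name!r} not in ordering")

    def covers(self, names: Iterable[str]) -> bool:
        return set(names) <= set(self.names)

    def before(self, a: str, b: str) -> bool:
        """True iff ``a`` precedes ``b`` in the implied total order."""
        return self.index(a) < self.index(b)


class CPT:
    """Conditional probability table P(variable = j | parents = k).

    ``table`` has one axis per parent (in ``parents`` order) and a trailing
    axis over the variable's own states; every slice along the trailing axis
    sums to one.
    """

    def __init__(
        self,
        variable: str,
        parents: Sequence[str],
        table: np.ndarray,
    ) -> None:
        self.variable = variable
        self.parents = list(parents)
        self.table = np.asarray(table, dtype=float)
        if self.table.ndim != len(self.parents) + 1:
            raise ValueError(
                f"CPT for {variable!r}: table rank {self.table.ndim} does not "
                f"match {len(self.parents)} parents + 1"
            )
        if np.any(self.table < 0) or np.any(self.table > 1):
            raise ValueError(f"CPT for {variable!r}: probabilities outside [0,1]")
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError(f"CPT for {variable!r}: rows do not sum to 1")

    @property
    def cardinality(self) -> int:
        return self.table.shape[-1]

    def row(self, parent_states: Sequence[int]) -> np.ndarray:
        """Distribution of the variable given one parent configuration."""
        return self.table[tuple(parent_states)]

    def copy(self) -> "CPT":
        return CPT(self.variable, self.parents, self.table.copy())


class BayesianNetwork:
    """A network structure plus one CPT per variable."""

    def __init__(self, structure: NetworkStructure, cpts: Mapping[str, CPT]) -> None:
        self.structure = structure
        self.cpts = dict(cpts)
        for name in structure.variables:
            if name not in self.cpts:
                raise ValueError(f"missing CPT for {name!r}")
            cpt = self.cpts[name]
            if sorted(cpt.parents) != structure.parents(name):
                raise ValueError(
                    f"CPT parents {cpt.parents} for {name!r} disagree with "
                    f"structure parents {structure.parents(name)}"
                )
            if cpt.cardinality != structure.cardinality(name):
                raise ValueError(f"CPT cardinality mismatch for {name!r}")
            for ax, p in enumerate(cpt.parents):
                if cpt.table.shape[ax] != structure.cardinality(p):
                    raise ValueError(
                        f"CPT for {name!r}: axis {ax} does not match "
                        f"cardinality of parent {p!r}"
                    )

    @property
    def names(self) -> list[str]:
        return self.structure.names

    def copy(self) -> "BayesianNetwork":
        return BayesianNetwork(
            self.structure.copy(), {n: c.copy() for n, c in self.cpts.items()}
        )


@dataclass(frozen=True)
class IndependenceRelation:
    """A statement A independent of B given the set C."""

    A: str
    B: str
    C: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "C", frozenset(self.C))
        if self.A == self.B:
            raise ValueError("A and B must differ")
        if self.A in self.C or self.B in self.C:
            raise ValueError("conditioning set must exclude A and B")

    def __str__(self) -> str:
        cond = "{" + ",".join(sorted(self.C)) + "}" if self.C else "{}"
        return f"{self.A} _||_ {self.B} | {cond}"


# ---------------------------------------------------------------------------
# structural validation


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str]


def validate_dag(structure: NetworkStructure) -> ValidationReport:
    """Check acyclicity, referential integrity and absence of self-loops."""
    violations: list[str] = []
    declared = set(structure.variables)
    for parent, child in sorted(structure.edges):
        if parent not in declared:
            violations.append(f"unknown variable {parent!r} in edge ({parent},{child})")
        if child not in declared:
            violations.append(f"unknown variable {child!r} in edge ({parent},{child})")
        if parent == child:
            violations.append(f"self-loop on {parent!r}")
    g = nx.DiGraph()
    g.add_nodes_from(declared)
    g.add_edges_from(e for e in structure.edges if set(e) <= declared)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        members = ",".join(sorted({n for e in cycle for n in e[:2]}))
        violations.append(f"cycle {members}")
    return ValidationReport(ok=not violations, violations=violations)


# ---------------------------------------------------------------------------
# d-separation (Bayes-ball reachability)


def d_separated(
    structure: NetworkStructure, A: str, B: str, C: Iterable[str] = ()
) -> bool:
    """True iff every path between A and B is blocked given the set C.

    Implemented by Bayes-ball reachability: explore (node, direction) states;
    a collider passes the ball only if it or a descendant is conditioned on.
    """
    C = set(C)
    for name in [A, B, *C]:
        if name not in structure.variables:
            raise KeyError(f"unknown variable {name!r}")
    if A == B or A in C or B in C:
        raise ValueError("A, B and C must be disjoint")

    parents = {n: set() for n in structure.variables}
    children = {n: set() for n in structure.variables}
    for p, c in structure.edges:
        parents[c].add(p)
        children[p].add(c)

    # nodes with a conditioned descendant (including themselves)
    an_c: set[str] = set()
    stack = list(C)
    while stack:
        n = stack.pop()
        if n in an_c:
            continue
        an_c.add(n)
        stack.extend(parents[n])

    # states: (node, "up") ball arrived from a child; (node, "down") from a parent
    visited: set[tuple[str, str]] = set()
    agenda: list[tuple[str, str]] = [(A, "up")]
    while agenda:
        node, direction = agenda.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node == B and node not in C:
            return False
        if direction == "up" and node not in C:
            for p in parents[node]:
                agenda.append((p, "up"))
            for ch in children[node]:
                agenda.append((ch, "down"))
        elif direction == "down":
            if node not in C:
                for ch in children[node]:
                    agenda.append((ch, "down"))
            if node in an_c:  # collider (or conditioned chain head) opens upwards
                for p in parents[node]:
                    agenda.append((p, "up"))
    return True


def find_minimal_separator(
    structure: NetworkStructure, A: str, B: str
) -> frozenset[str] | None:
    """Smallest C with A d-separated from B given C, or None if none exists.

    Ties at equal cardinality are broken lexicographically on the sorted
    member list so the choice is reproducible.
    """
    if structure.adjacent(A, B):
        raise ValueError(f"adjacent pair ({A},{B}) has no separating set")
    others = sorted(n for n in structure.variables if n not in (A, B))
    for size in range(len(others) + 1):
        candidates = sorted(
            itertools.combinations(others, size), key=lambda c: sorted(c)
        )
        for combo in candidates:
            if d_separated(structure, A, B, combo):
                return frozenset(combo)
    return None


def reduce_relationships(
    structure: NetworkStructure, ordering: CausalOrdering
) -> list[IndependenceRelation]:
    """One minimal independence statement per separable non-adjacent pair.

    For every unordered non-adjacent pair the relation is reported as
    A independent of B given C with A the *later* variable in the causal
    ordering and C a minimum-cardinality separating set; inseparable pairs are
    skipped.  Output is sorted by (A, B).  This is the mechanical part of the
    structure-audit procedure in which implied independencies are put to
    domain experts; any further human triage of which relations look
    surprising is out of scope here.
    """
    if not ordering.covers(structure.variables):
        raise ValueError("ordering does not cover the structure's variables")
    out: list[IndependenceRelation] = []
    for x, y in itertools.combinations(sorted(structure.variables), 2):
        if structure.adjacent(x, y):
            continue
        sep = find_minimal_separator(structure, x, y)
        if sep is None:
            continue
        a, b = (x, y) if ordering.before(y, x) else (y, x)
        out.append(IndependenceRelation(a, b, sep))
    out.sort(key=lambda r: (r.A, r.B))
    return out


def implied_independencies(
    structure: NetworkStructure, max_conditioning: int
) -> list[IndependenceRelation]:
    """All singleton relations A _||_ B | C with |C| <= max_conditioning.

    Enumerates every unordered pair and every conditioning subset of the
    remaining variables up to the given size, keeping the relations that hold
    by d-separation.  Deterministic order: by (A, B), then |C|, then sorted C.
    """
    if max_conditioning < 0:
        raise ValueError("max_conditioning must be >= 0")
    out: list[IndependenceRelation] = []
    names = sorted(structure.variables)
    for a, b in itertools.combinations(names, 2):
        rest = [n for n in names if n not in (a, b)]
        for size in range(min(max_conditioning, len(rest)) + 1):
            for combo in itertools.combinations(rest, size):
                if d_separated(structure, a, b, combo):
                    out.append(IndependenceRelation(a, b, frozenset(combo)))
    out.sort(key=lambda r: (r.A, r.B, len(r.C), sorted(r.C)))
    return out
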