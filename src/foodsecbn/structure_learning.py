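"""Constraint-based structure learning for ordinal household data.

The skeleton is discovered with the Max-Min Parents and Children (MMPC)
algorithm driven by a stratified, asymptotically normal Jonckheere-Terpstra
(JT) conditional-independence test.  The JT test targets monotone trend of an
ordinal response Y across the ordered states of X, which suits household
variables such as education level or socio-economic status far better than an
omnibus chi-square: a monotone gradient concentrated on the trend alternative
is detected with much higher power.

Conditioning on a set C is handled by stratification: the JT statistic, its
null mean and its tie-corrected null variance are computed inside each
configuration of C with enough rows, summed across strata, and referred to a
single standard-normal deviate.

Edge directions are not inferred from data.  Every learned undirected edge is
oriented from the earlier to the later variable in a causal ordering fixed in
advance, which guarantees acyclicity; the outcome variable (food security,
last level of the ordering, a cause of nothing) is additionally barred from
every other variable's candidate-cause set from the start.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import CausalOrdering, NetworkStructure, Variable

__all__ = [
    "CITestResult",
    "Skeleton",
    "jt_ci_test",
    "mmpc_skeleton",
    "orient_edges",
    "learn_structure",
]


@dataclass
class CITestResult:
    """Outcome of one stratified JT conditional-independence test."""

    statistic: float
    null_mean: float
    null_var: float
    z: float
    p_value: float
    effective_n: int
    degenerate: bool = False


@dataclass
class Skeleton:
    """An undirected graph over named variables."""

    variables: list[str]
    edges: set[frozenset[str]] = field(default_factory=set)

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges


# ---------------------------------------------------------------------------
# Jonckheere-Terpstra machinery (contingency-table form)


def _jt_moments(table: np.ndarray) -> tuple[float, float, float]:
    """JT statistic T and its tie-corrected null moments for one stratum.

    ``table[i, a]`` counts observations with X in ordered group i and Y at
    ordered value a.  Ties in Y contribute 1/2 to T; the null variance uses
    the standard tie correction in terms of the group sizes n_i and the
    Y tie-group sizes t_a.
    """
    table = np.asarray(table, dtype=float)
    ni = table.sum(axis=1)
    ta = table.sum(axis=0)
    n = ni.sum()
    if n < 2:
        return 0.0, 0.0, 0.0

    cum = np.cumsum(table, axis=1)
    t_stat = 0.0
    rx = table.shape[0]
    for i in range(rx):
        for j in range(i + 1, rx):
            less = float(np.dot(table[j, 1:], cum[i, :-1])) if table.shape[1] > 1 else 0.0
            tied = 0.5 * float(np.dot(table[i], table[j]))
            t_stat += less + tied

    mean = (n * n - np.dot(ni, ni)) / 4.0

    def _s(v: np.ndarray, f) -> float:
        return float(np.sum(f(v)))

    a_term = (
        n * (n - 1) * (2 * n + 5)
        - _s(ni, lambda v: v * (v - 1) * (2 * v + 5))
        - _s(ta, lambda v: v * (v - 1) * (2 * v + 5))
    ) / 72.0
    if n > 2:
        b_term = (
            _s(ni, lambda v: v * (v - 1) * (v - 2))
            * _s(ta, lambda v: v * (v - 1) * (v - 2))
            / (36.0 * n * (n - 1) * (n - 2))
        )
    else:
        b_term = 0.0
    c_term = (
        _s(ni, lambda v: v * (v - 1))
        * _s(ta, lambda v: v * (v - 1))
        / (8.0 * n * (n - 1))
    )
    var = a_term + b_term + c_term
    return t_stat, mean, max(var, 0.0)


class _CodedData:
    """Integer-coded columns with per-column cardinalities, for fast tests."""

    def __init__(self, data: pd.DataFrame) -> None:
        if len(data) == 0:
            raise ValueError("empty data")
        self.columns = list(data.columns)
        self.codes: dict[str, np.ndarray] = {}
        self.cards: dict[str, int] = {}
        for col in self.columns:
            arr = data[col].to_numpy()
            arr = arr.astype(np.int64)
            if arr.min() < 0:
                raise ValueError(f"negative state code in column {col!r}")
            self.codes[col] = arr
            self.cards[col] = int(arr.max()) + 1
        self.n = len(data)

    def contingency(self, names: list[str]) -> np.ndarray:
        cards = [self.cards[c] for c in names]
        code = np.ravel_multi_index([self.codes[c] for c in names], cards)
        flat = np.bincount(code, minlength=int(np.prod(cards)))
        return flat.reshape(cards)


def _jt_from_coded(
    coded: _CodedData, x: str, y: str, cond: tuple[str, ...], min_stratum: int
) -> CITestResult:
    names = list(cond) + [x, y]
    table = coded.contingency(names)
    strata = table.reshape(-1, coded.cards[x], coded.cards[y])

    t_sum = e_sum = v_sum = 0.0
    eff_n = 0
    usable = 0
    for stratum in strata:
        rows = int(stratum.sum())
        if rows < min_stratum:
            continue
        usable += 1
        eff_n += rows
        t, e, v = _jt_moments(stratum)
        t_sum += t
        e_sum += e
        v_sum += v
    if usable == 0:
        raise ValueError(
            f"no stratum of {cond} with at least {min_stratum} rows"
        )
    if v_sum <= 0:
        return CITestResult(t_sum, e_sum, v_sum, 0.0, 1.0, eff_n, degenerate=True)
    z = (t_sum - e_sum) / np.sqrt(v_sum)
    p = 2.0 * stats.norm.sf(abs(z))
    return CITestResult(t_sum, e_sum, v_sum, float(z), float(p), eff_n)


def jt_ci_test(
    data: pd.DataFrame,
    x: str,
    y: str,
    cond: set[str] | tuple[str, ...] = (),
    min_stratum: int = 5,
) -> CITestResult:
    """Stratified JT test of X independent of Y given the set ``cond``.

    Within each configuration of ``cond`` holding at least ``min_stratum``
    rows, the JT statistic for ordered alternatives of Y across ordered
    groups of X is computed with its tie-corrected null moments; statistics
    and moments are summed across usable strata and the combined deviate is
    referred to N(0, 1), two-sided.  Strata below ``min_stratum`` are dropped
    and excluded from ``effective_n``.

    A test in which X or Y carries no variation in any usable stratum is
    degenerate: statistic 0, p-value 1.
    """
    for col in [x, y, *cond]:
        if col not in data.columns:
            raise KeyError(f"column {col!r} missing from data")
    coded = _CodedData(data[[*dict.fromkeys([x, y, *cond])]])
    return _jt_from_coded(coded, x, y, tuple(sorted(cond)), min_stratum)


# ---------------------------------------------------------------------------
# MMPC skeleton discovery


class _TestCache:
    def __init__(self, coded: _CodedData, min_stratum: int) -> None:
        self.coded = coded
        self.min_stratum = min_stratum
        self.cache: dict[tuple[str, str, tuple[str, ...]], float] = {}
        self.n_tests = 0

    def p_value(self, x: str, y: str, cond: frozenset[str]) -> float:
        a, b = sorted((x, y))
        key = (a, b, tuple(sorted(cond)))
        if key not in self.cache:
            self.n_tests += 1
            try:
                res = _jt_from_coded(
                    self.coded, a, b, tuple(sorted(cond)), self.min_stratum
                )
                p = res.p_value
            except ValueError:  # no usable stratum: treat as uninformative
                p = 1.0
            self.cache[key] = p
        return self.cache[key]


def _subsets(pool: list[str], max_size: int):
    for size in range(min(max_size, len(pool)) + 1):
        yield from itertools.combinations(pool, size)


def _mmpc_one(
    target: str,
    candidates: list[str],
    tests: _TestCache,
    alpha_for: "dict[frozenset[str], float]",
    default_alpha: float,
    max_conditioning: int,
    seeded: list[str],
) -> list[str]:
    """Forward/backward MMPC for one target; returns its parents-children set."""

    def alpha_of(other: str) -> float:
        return alpha_for.get(frozenset((target, other)), default_alpha)

    cpc: list[str] = list(seeded)
    # running worst (largest) p-value per candidate over subsets tried so far
    maxp: dict[str, float] = {}
    rejected: set[str] = set()
    for x in candidates:
        if x not in cpc:
            maxp[x] = tests.p_value(target, x, frozenset())
            if maxp[x] >= alpha_of(x):
                rejected.add(x)
    fresh = list(cpc)  # CPC members whose conditioning subsets are untried

    while True:
        # extend each candidate's worst p with subsets touching new members
        for x in sorted(maxp):
            if x in rejected or x in cpc:
                continue
            others = [c for c in cpc if c != x]
            for new in fresh:
                if new == x:
                    continue
                rest = [c for c in others if c != new]
                for sub in _subsets(rest, max_conditioning - 1):
                    p = tests.p_value(target, x, frozenset((new, *sub)))
                    if p > maxp[x]:
                        maxp[x] = p
                    if maxp[x] >= alpha_of(x):
                        rejected.add(x)
                        break
                if x in rejected:
                    break
        fresh = []
        viable = [
            x for x in sorted(maxp) if x not in rejected and x not in cpc
        ]
        if not viable:
            break
        best = min(viable, key=lambda x: (maxp[x], x))
        cpc.append(best)
        fresh = [best]
        del maxp[best]

    # backward: drop members independent of the target given some subset
    for x in list(cpc):
        others = [c for c in cpc if c != x]
        for sub in _subsets(others, max_conditioning):
            if tests.p_value(target, x, frozenset(sub)) >= alpha_of(x):
                cpc.remove(x)
                break
    return cpc


def _resolve_outcome(ordering: CausalOrdering) -> str | None:
    last = ordering.levels[-1]
    return last[0] if len(last) == 1 else None


def mmpc_skeleton(
    data: pd.DataFrame,
    ordering: CausalOrdering,
    alpha: float = 0.05,
    max_conditioning: int = 3,
    min_stratum: int = 5,
    seed_edges: set[frozenset[str]] | None = None,
    seed_alpha: float | None = None,
) -> Skeleton:
    """Learn the undirected skeleton with MMPC under the JT test.

    For each variable the forward phase repeatedly adds the candidate whose
    *minimum* association (1 - p) over conditioning subsets of the current
    parents-children set (up to ``max_conditioning``) is largest, provided
    that worst-case association is still significant at ``alpha``; the
    backward phase removes members rendered independent by some subset.  An
    edge survives only if each endpoint that was allowed to consider the
    other retains it (AND rule).  The outcome variable is excluded from every
    other variable's candidate set: it may have causes but causes nothing.

    ``seed_edges`` (with the laxer ``seed_alpha``) pre-loads expert-proposed
    pairs into the relevant candidate sets; see :func:`learn_structure`.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(data) == 0:
        raise ValueError("empty data")
    names = [c for c in data.columns]
    if not ordering.covers(names):
        raise ValueError("ordering does not cover the data columns")
    coded = _CodedData(data)
    tests = _TestCache(coded, min_stratum)
    outcome = _resolve_outcome(ordering)

    seed_edges = seed_edges or set()
    alpha_for: dict[frozenset[str], float] = {}
    if seed_edges:
        if seed_alpha is None:
            raise ValueError("seed_alpha required when seed_edges given")
        alpha_for = {pair: seed_alpha for pair in seed_edges}

    candidates_of: dict[str, list[str]] = {}
    cpc: dict[str, list[str]] = {}
    for target in names:
        cand = [v for v in names if v != target]
        if outcome is not None and target != outcome:
            cand = [v for v in cand if v != outcome]
        candidates_of[target] = cand
        seeded = sorted(
            v for v in cand if frozenset((target, v)) in seed_edges
        )
        cpc[target] = _mmpc_one(
            target, cand, tests, alpha_for, alpha, max_conditioning, seeded
        )

    edges: set[frozenset[str]] = set()
    for a, b in itertools.combinations(names, 2):
        a_side = b in cpc[a] or b not in candidates_of[a]
        b_side = a in cpc[b] or a not in candidates_of[b]
        claimed = (b in cpc[a]) or (a in cpc[b])
        if claimed and a_side and b_side:
            edges.add(frozenset((a, b)))
    return Skeleton(names, edges)


def orient_edges(
    skeleton: Skeleton,
    ordering: CausalOrdering,
    variables: dict[str, Variable] | None = None,
) -> NetworkStructure:
    """Direct every edge from the earlier to the later ordering position.

    The result is acyclic by construction because all edges point forward in
    one fixed total order.  ``variables`` may supply declared state labels;
    otherwise integer-labelled placeholder states of cardinality 2 are used
    (sufficient for purely structural work).
    """
    missing = [v for v in skeleton.variables if not ordering.covers([v])]
    if missing:
        raise ValueError(f"variables missing from ordering: {missing}")
    if variables is None:
        variables = {
            n: Variable(n, ("s0", "s1")) for n in skeleton.variables
        }
    edges = set()
    for pair in skeleton.edges:
        a, b = sorted(pair)
        if ordering.before(a, b):
            edges.add((a, b))
        else:
            edges.add((b, a))
    return NetworkStructure(
        [variables[n] for n in skeleton.variables], edges
    )


def learn_structure(
    data: pd.DataFrame,
    ordering: CausalOrdering,
    alpha: float = 0.05,
    max_conditioning: int = 3,
    expert_prior: NetworkStructure | None = None,
    alpha_keep: float = 0.20,
    min_stratum: int = 5,
    variables: dict[str, Variable] | None = None,
) -> NetworkStructure:
    """Learn a directed structure, optionally seeded by an expert network.

    Without a prior this is ``orient_edges(mmpc_skeleton(...))``.  With a
    prior, every expert edge is injected into the initial candidate sets of
    both endpoints and is retained unless the data fail to reject
    independence at the laxer level ``alpha_keep`` (> ``alpha``); non-expert
    edges must pass the ordinary ``alpha``.  The expert structure must itself
    respect the causal ordering.
    """
    seed_edges: set[frozenset[str]] | None = None
    if expert_prior is not None:
        for parent, child in expert_prior.edges:
            if not ordering.before(parent, child):
                raise ValueError(
                    f"expert edge {parent}->{child} violates the causal ordering"
                )
        seed_edges = {frozenset(e) for e in expert_prior.edges}
    if variables is None:
        # infer cardinalities from the observed state codes
        variables = {
            col: Variable(
                col, tuple(f"s{i}" for i in range(int(data[col].max()) + 1))
            )
            for col in data.columns
        }
    skel = mmpc_skeleton(
        data,
        ordering,
        alpha=alpha,
        max_conditioning=max_conditioning,
        min_stratum=min_stratum,
        seed_edges=seed_edges or None,
        seed_alpha=alpha_keep if seed_edges else None,
    )
    return orient_edges(skel, ordering, variables)
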