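"""Interventional (do-operator) queries and sensitivity analysis.

An intervention do(X = x) is modelled by graph surgery: every edge into X is
removed and X's CPT is replaced by a point mass on the forced state, so X no
longer responds to its usual causes.  Querying the surgically modified
network then gives the causal effect P(target | do(X = x)), which differs
from the observational conditional whenever X and the target share unblocked
backdoor paths.

Sensitivity analysis ranks the other variables by how much observing them
moves beliefs about food security:

* mutual information reduction ``I = H(FS) - sum_x P(x) H(FS | x)`` in bits,
  also reported relative to the outcome entropy as ``I / H``;
* expected change of belief
  ``S2 = sum_x P(x) sum_s (P(FS=s | x) - P(FS=s))^2``.

Both are observational (belief-change) measures: the weights P(x) are the
variable's ordinary marginal, not an interventional distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inference import Posterior, posterior
from .network import CPT, BayesianNetwork

__all__ = [
    "InterventionSpec",
    "SensitivityRow",
    "do_surgery",
    "interventional_query",
    "mutual_information_reduction",
    "expected_change_of_belief",
    "sensitivity_table",
]


@dataclass(frozen=True)
class InterventionSpec:
    """One or more variables forced to fixed states."""

    assignments: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        if not self.assignments:
            raise ValueError("intervention assigns no variables")


@dataclass
class SensitivityRow:
    variable: str
    I: float
    I_over_H: float
    S2: float
    degenerate: bool = False


def do_surgery(
    network: BayesianNetwork, spec: InterventionSpec
) -> BayesianNetwork:
    """Return the post-intervention network.

    Each intervened variable loses all incoming edges and receives a
    point-mass CPT on its forced state; every other CPT is left untouched.
    Multi-variable interventions are applied simultaneously.
    """
    structure = network.structure.copy()
    cpts = {n: c for n, c in network.cpts.items()}
    for var, state in spec.assignments.items():
        if var not in structure.variables:
            raise KeyError(f"unknown intervention variable {var!r}")
        card = structure.cardinality(var)
        if not 0 <= int(state) < card:
            raise ValueError(f"state {state} out of range for {var!r}")
        structure.edges = {(p, c) for p, c in structure.edges if c != var}
        point = np.zeros(card)
        point[int(state)] = 1.0
        cpts[var] = CPT(var, [], point)
    return BayesianNetwork(structure, cpts)


def interventional_query(
    network: BayesianNetwork, target: str, spec: InterventionSpec
) -> Posterior:
    """P(target | do(spec)) by exact inference on the mutilated network."""
    if target in spec.assignments:
        raise ValueError(f"target {target!r} cannot be intervened on")
    cut = do_surgery(network, spec)
    return posterior(cut, target, {v: s for v, s in spec.assignments.items()})


def _entropy(dist: np.ndarray) -> float:
    p = np.asarray(dist, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information_reduction(
    network: BayesianNetwork, target: str, variable: str
) -> tuple[float, float, bool]:
    """Mutual information I(target; variable) in bits and its share of H(target).

    Returns (I, I / H, degenerate); when the outcome entropy is zero the ratio
    is reported as 0 with the degeneracy flag set.
    """
    if variable == target:
        raise ValueError("variable must differ from the target")
    p_t = posterior(network, target).distribution
    h_t = _entropy(p_t)
    p_x = posterior(network, variable).distribution
    cond = 0.0
    for x, px in enumerate(p_x):
        if px <= 0:
            continue
        p_t_given_x = posterior(network, target, {variable: x}).distribution
        cond += px * _entropy(p_t_given_x)
    i = max(h_t - cond, 0.0)
    if h_t <= 0:
        return 0.0, 0.0, True
    return i, i / h_t, False


def expected_change_of_belief(
    network: BayesianNetwork, target: str, variable: str
) -> float:
    """S2: marginal-weighted squared shift of the target's belief.

    Zero exactly when observing the variable never moves the target's
    distribution.
    """
    if variable == target:
        raise ValueError("variable must differ from the target")
    p_t = posterior(network, target).distribution
    p_x = posterior(network, variable).distribution
    s2 = 0.0
    for x, px in enumerate(p_x):
        if px <= 0:
            continue
        p_t_given_x = posterior(network, target, {variable: x}).distribution
        s2 += px * float(np.sum((p_t_given_x - p_t) ** 2))
    return s2


def sensitivity_table(
    network: BayesianNetwork, target: str = "FS"
) -> list[SensitivityRow]:
    """One sensitivity row per non-target variable, sorted by name."""
    rows = []
    for name in sorted(network.structure.variables):
        if name == target:
            continue
        i, i_over_h, degenerate = mutual_information_reduction(
            network, target, name
        )
        s2 = expected_change_of_belief(network, target, name)
        rows.append(SensitivityRow(name, i, i_over_h, s2, degenerate))
    return rows
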