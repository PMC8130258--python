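"""MAP estimation of conditional probability tables from complete data.

The likelihood of a discrete network factorises into independent multinomials,
one per (variable, parent-configuration) cell.  With a Dirichlet prior the
posterior mode has the closed form

    theta_jk = (n_jk + a) / (n_k + r * a)

where n_jk counts rows with the variable in state j under parent configuration
k, n_k is the configuration margin, r the variable's cardinality and a the
pseudocount (a = 1, add-one smoothing, by default).  Smoothing keeps every CPT
entry strictly positive even for parent configurations never observed, which
in turn keeps downstream inference free of zero-probability evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import CPT, BayesianNetwork, NetworkStructure

__all__ = ["CountTable", "state_counts", "fit_cpts"]


@dataclass
class CountTable:
    """Cross-tabulation n_jk of a variable against its parent configurations.

    ``counts`` has one axis per parent plus a trailing axis over the
    variable's own states, mirroring the CPT layout.
    """

    variable: str
    parents: list[str]
    counts: np.ndarray

    @property
    def margins(self) -> np.ndarray:
        """n_k: rows observed per parent configuration."""
        return self.counts.sum(axis=-1)


def _check_column(
    data: pd.DataFrame, name: str, cardinality: int
) -> np.ndarray:
    if name not in data.columns:
        raise KeyError(f"column {name!r} missing from data")
    col = data[name].to_numpy()
    bad = (col < 0) | (col >= cardinality)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"out-of-range state {col[row]} for column {name!r} at row {row} "
            f"(cardinality {cardinality})"
        )
    return col.astype(np.int64)


def state_counts(
    data: pd.DataFrame,
    structure: NetworkStructure,
    variable: str,
    parents: Sequence[str] | None = None,
) -> CountTable:
    """Exact counts of ``variable`` against every parent configuration.

    Configurations absent from the data appear with zero counts; an empty
    table yields an all-zero count array.
    """
    if parents is None:
        parents = structure.parents(variable)
    parents = list(parents)
    cards = [structure.cardinality(p) for p in parents] + [
        structure.cardinality(variable)
    ]
    flat = np.zeros(int(np.prod(cards)), dtype=np.int64)
    if len(data) > 0:
        cols = [_check_column(data, p, structure.cardinality(p)) for p in parents]
        cols.append(_check_column(data, variable, structure.cardinality(variable)))
        code = np.ravel_multi_index(cols, cards)
        flat = np.bincount(code, minlength=flat.size).astype(np.int64)
    return CountTable(variable, parents, flat.reshape(cards))


def fit_cpts(
    structure: NetworkStructure,
    data: pd.DataFrame,
    pseudocount: float = 1.0,
) -> BayesianNetwork:
    """Fit every CPT by the smoothed MAP formula (n_jk + a) / (n_k + r a)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if len(data) > 0:
        missing = [n for n in structure.variables if n not in data.columns]
        if missing:
            raise KeyError(f"data lacks columns for variables {missing}")
    cpts = {}
    for name in structure.variables:
        ct = state_counts(data, structure, name)
        r = structure.cardinality(name)
        table = (ct.counts + pseudocount) / (
            ct.margins[..., None] + r * pseudocount
        )
        cpts[name] = CPT(name, ct.parents, table)
    return BayesianNetwork(structure, cpts)
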