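"""Synthetic Agincourt-like household data.

The real household surveillance data behind the food-security analysis are
restricted, so every pipeline stage here is exercised on data sampled from a
known ground-truth network over the same 15 variables: child grant status
(CGS), education level (EdL), employment level (EmL), household head gender
(HHG), local vegetation level (LLV), number of dependants (ND), number of
working-age adults (NWAA), receipt of communal aid (RCA), refugee status
(RS), selling of crops and livestock (SCL), socio-economic status (SES), use
of crops and livestock (UCL), use of wild foods (UWF), water access (WA) and
the binary outcome food security (FS; state 0 = food secure, state 1 = food
insecure, a minority class).

The generator emulates three features of such data: a five-level causal
ordering with FS alone at the bottom (it causes nothing), ordinal variables
of small cardinality (2-4 states), and monotone dose-response style
dependence — each child's distribution is a random baseline tilted up or
down its ordinal scale by a weighted sum of its parents' (centred) states.
Monotone conditional effects are what one expects of gradients such as
education -> employment -> socio-economic status, and they are the
alternative the Jonckheere-Terpstra test is designed for.  The level
assignment and cardinalities are plausible stand-ins, configurable, and not
a claim about the original study's ordering.

The FS conditional table is tilted on the logit scale so that the marginal
probability of food insecurity matches a configurable target rate (default
0.10, a realistic minority share).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .network import (
    CPT,
    BayesianNetwork,
    CausalOrdering,
    NetworkStructure,
    Variable,
)
from .inference import joint_marginal

__all__ = [
    "DEFAULT_LEVELS",
    "DEFAULT_CARDINALITIES",
    "GeneratorConfig",
    "default_ordering",
    "make_agincourt_like_network",
    "sample_households",
    "coarsen_rare_states",
]

DEFAULT_LEVELS: list[list[str]] = [
    ["HHG", "RS", "EdL", "NWAA", "ND", "LLV", "WA"],
    ["EmL", "CGS", "RCA"],
    ["SES", "UCL", "UWF"],
    ["SCL"],
    ["FS"],
]

DEFAULT_CARDINALITIES: dict[str, int] = {
    "HHG": 2,
    "RS": 2,
    "EdL": 4,
    "NWAA": 3,
    "ND": 3,
    "LLV": 3,
    "WA": 3,
    "EmL": 3,
    "CGS": 2,
    "RCA": 2,
    "SES": 4,
    "UCL": 2,
    "UWF": 2,
    "SCL": 2,
    "FS": 2,
}


@dataclass
class GeneratorConfig:
    """Ground-truth network and sampling configuration.

    ``edge_density`` is the Bernoulli probability of an edge between any
    variable of an earlier level and any variable of a later level.
    ``dirichlet_concentration`` controls baseline CPT randomness (1 = flat
    Dirichlet) and ``effect_strength`` the magnitude of the monotone ordinal
    tilt each parent exerts; the default gives strong but noisy gradients.
    """

    n_households: int = 11_739
    seed: int = 0
    levels: list[list[str]] = field(
        default_factory=lambda: [list(l) for l in DEFAULT_LEVELS]
    )
    cardinalities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CARDINALITIES)
    )
    edge_density: float = 0.25
    dirichlet_concentration: float = 2.0
    effect_strength: float = 1.5
    insecure_rate: float = 0.10
    max_parents: int = 4

    def __post_init__(self) -> None:
        names = [n for level in self.levels for n in level]
        if sorted(names) != sorted(self.cardinalities):
            raise ValueError("levels and cardinalities disagree on variables")
        outcome = self.levels[-1]
        if len(outcome) != 1:
            raise ValueError("outcome level must contain exactly one variable")
        if self.cardinalities[outcome[0]] != 2:
            raise ValueError("outcome must be binary")
        for name, r in self.cardinalities.items():
            if not 2 <= r <= 4:
                raise ValueError(f"cardinality of {name!r} outside 2..4")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("edge_density outside [0, 1]")
        if not 0 < self.insecure_rate < 1:
            raise ValueError("insecure_rate outside (0, 1)")

    @property
    def outcome(self) -> str:
        return self.levels[-1][0]


def default_ordering() -> CausalOrdering:
    return CausalOrdering([list(l) for l in DEFAULT_LEVELS])


def _state_labels(name: str, r: int) -> tuple[str, ...]:
    if name == "FS":
        return ("secure", "insecure")
    return tuple(f"s{i}" for i in range(r))


def _centred_scale(r: int) -> np.ndarray:
    """States mapped to [-1, 1]: state 0 -> -1, state r-1 -> +1."""
    return 2.0 * np.arange(r) / (r - 1) - 1.0


def _tilted_cpt(
    rng: np.random.Generator,
    child_card: int,
    parent_cards: list[int],
    concentration: float,
    effect_strength: float,
) -> np.ndarray:
    """Random baseline distribution tilted monotonely by each parent."""
    base = rng.dirichlet(np.full(child_card, concentration))
    base = np.clip(base, 1e-4, None)
    base /= base.sum()
    signs = rng.choice([-1.0, 1.0], size=len(parent_cards))
    magnitudes = rng.uniform(0.5, 1.0, size=len(parent_cards)) * effect_strength
    weights = signs * magnitudes
    child_scale = _centred_scale(child_card)

    shape = tuple(parent_cards) + (child_card,)
    table = np.empty(shape)
    for k in np.ndindex(*parent_cards) if parent_cards else [()]:
        score = sum(
            w * _centred_scale(pc)[s]
            for w, pc, s in zip(weights, parent_cards, k)
        )
        row = base * np.exp(score * child_scale)
        table[k] = row / row.sum()
    return table


def _tilt_outcome_to_rate(
    network: BayesianNetwork, outcome: str, rate: float
) -> BayesianNetwork:
    """Shift the outcome CPT on the logit scale to hit the target marginal."""
    cpt = network.cpts[outcome]
    parent_marginal = joint_marginal(network, cpt.parents)
    base_logits = logit(np.clip(cpt.table[..., 1], 1e-9, 1 - 1e-9))

    def marginal_gap(t: float) -> float:
        p_ins = expit(base_logits + t)
        return float((parent_marginal * p_ins).sum()) - rate

    t_star = brentq(marginal_gap, -30.0, 30.0)
    p_ins = expit(base_logits + t_star)
    table = np.stack([1.0 - p_ins, p_ins], axis=-1)
    cpts = dict(network.cpts)
    cpts[outcome] = CPT(outcome, cpt.parents, table)
    return BayesianNetwork(network.structure, cpts)


def make_agincourt_like_network(
    config: GeneratorConfig | None = None,
) -> BayesianNetwork:
    """Sample a ground-truth network from the generator configuration.

    Edges run from earlier to later levels only, each drawn independently at
    ``edge_density`` (capped at ``max_parents`` per child, keeping a random
    subset when over); the outcome is guaranteed at least one parent.  CPTs
    follow the monotone-tilt construction, and the outcome CPT is calibrated
    so its exact marginal insecurity probability equals ``insecure_rate``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    names = [n for level in config.levels for n in level]
    variables = [
        Variable(n, _state_labels(n, config.cardinalities[n])) for n in names
    ]
    level_of = {
        n: li for li, level in enumerate(config.levels) for n in level
    }

    parents_of: dict[str, list[str]] = {n: [] for n in names}
    for child in names:
        eligible = [p for p in names if level_of[p] < level_of[child]]
        chosen = [p for p in eligible if rng.random() < config.edge_density]
        if len(chosen) > config.max_parents:
            keep = rng.choice(
                len(chosen), size=config.max_parents, replace=False
            )
            chosen = [chosen[i] for i in sorted(keep)]
        parents_of[child] = chosen
    outcome = config.outcome
    if not parents_of[outcome]:
        for _ in range(100):
            eligible = [p for p in names if p != outcome]
            chosen = [p for p in eligible if rng.random() < config.edge_density]
            if chosen:
                parents_of[outcome] = chosen[: config.max_parents]
                break
        else:
            raise ValueError(
                "edge density too low: outcome remained parentless after retries"
            )

    edges = {
        (p, c) for c, parents in parents_of.items() for p in parents
    }
    structure = NetworkStructure(variables, edges)
    cpts = {}
    for name in names:
        parents = parents_of[name]
        cpts[name] = CPT(
            name,
            parents,
            _tilted_cpt(
                rng,
                config.cardinalities[name],
                [config.cardinalities[p] for p in parents],
                config.dirichlet_concentration,
                config.effect_strength,
            ),
        )
    network = BayesianNetwork(structure, cpts)
    return _tilt_outcome_to_rate(network, outcome, config.insecure_rate)


def sample_households(
    network: BayesianNetwork, n: int, seed: int = 0
) -> pd.DataFrame:
    """Forward ancestral sampling of n complete household rows.

    Columns follow the network's declared variable order; values are integer
    state indices.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = network.structure.topological_order()
    columns: dict[str, np.ndarray] = {}
    for name in order:
        cpt = network.cpts[name]
        if cpt.parents:
            idx = tuple(columns[p] for p in cpt.parents)
            probs = cpt.table[idx]
        else:
            probs = np.broadcast_to(cpt.table, (n, cpt.cardinality))
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        drawn = (u[:, None] > cum).sum(axis=1).astype(np.int64)
        columns[name] = np.minimum(drawn, cpt.cardinality - 1)
    return pd.DataFrame({name: columns[name] for name in network.names})


def coarsen_rare_states(
    data: pd.DataFrame, variable: str, min_frequency: float
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Merge rare ordinal states into neighbours until all pass the threshold.

    Repeatedly takes the rarest state below ``min_frequency`` and merges it
    into whichever ordinal neighbour is less rare (ties resolve toward the
    interior of the scale), stopping when every state meets the threshold or
    only two remain.  Returns the recoded table and the old-state -> new-state
    map; the retained states keep their ordinal order.
    """
    if not 0 < min_frequency < 1:
        raise ValueError("min_frequency must be in (0, 1)")
    if variable not in data.columns:
        raise KeyError(f"column {variable!r} missing")
    col = data[variable].to_numpy().astype(np.int64)
    if len(col) == 0:
        raise ValueError("empty data")
    n_states = int(col.max()) + 1
    counts = np.bincount(col, minlength=n_states).astype(float)
    groups: list[list[int]] = [[s] for s in range(n_states)]
    freqs: list[float] = list(counts / len(col))

    while len(groups) > 2:
        below = [i for i, f in enumerate(freqs) if f < min_frequency]
        if not below:
            break
        victim = min(below, key=lambda i: (freqs[i], i))
        neighbours = [i for i in (victim - 1, victim + 1) if 0 <= i < len(groups)]
        mid = (len(groups) - 1) / 2.0
        target = max(
            neighbours,
            key=lambda i: (freqs[i], -abs(i - mid)),
        )
        lo, hi = sorted((victim, target))
        groups[lo] = groups[lo] + groups[hi]
        freqs[lo] = freqs[lo] + freqs[hi]
        del groups[hi], freqs[hi]

    state_map = {
        old: new for new, members in enumerate(groups) for old in members
    }
    recoded = data.copy()
    recoded[variable] = np.array([state_map[s] for s in col], dtype=np.int64)
    return recoded, state_map
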