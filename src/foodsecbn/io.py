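"""Readers and writers for the pipeline's on-disk formats.

* Network JSON: ``{"variables": [{"name", "states", "level"}...],
  "edges": [["parent", "child"], ...], "cpts": {name: {"parents": [...],
  "table": {"<k0,k1,...>": [probabilities]}}}}`` where the table key is the
  comma-joined parent state indices in declared parent order (the empty
  string for parentless variables).  ``cpts`` may be omitted for a
  structure-only file.  ``level`` is optional and records the causal
  ordering level when one is attached.
* Household CSV: header row of variable names, integer state indices as
  values; incomplete rows are rejected (complete-case contract).
* Ordering YAML: ``levels:`` as a list of lists of variable names.
* DOT export for quick visual inspection of a learned structure.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .network import (
    CPT,
    BayesianNetwork,
    CausalOrdering,
    NetworkStructure,
    Variable,
)

__all__ = [
    "SchemaError",
    "save_network",
    "load_network",
    "save_structure",
    "load_structure",
    "load_ordering",
    "save_ordering",
    "load_table",
    "export_dot",
    "write_manifest",
]

_ROW_SUM_TOL = 1e-9


class SchemaError(ValueError):
    """A file violates the documented format; the message carries a JSON pointer."""


def _structure_payload(
    structure: NetworkStructure, ordering: CausalOrdering | None
) -> dict[str, Any]:
    variables = []
    for name, var in structure.variables.items():
        entry: dict[str, Any] = {"name": name, "states": list(var.states)}
        if ordering is not None:
            entry["level"] = ordering.level_of(name)
        variables.append(entry)
    return {
        "variables": variables,
        "edges": sorted([p, c] for p, c in structure.edges),
    }


def _cpt_payload(cpt: CPT, structure: NetworkStructure) -> dict[str, Any]:
    parent_cards = [structure.cardinality(p) for p in cpt.parents]
    table: dict[str, list[float]] = {}
    for k in itertools.product(*(range(c) for c in parent_cards)):
        key = ",".join(str(i) for i in k)
        table[key] = [float(v) for v in cpt.table[k]]
    return {"parents": list(cpt.parents), "table": table}


def save_structure(
    structure: NetworkStructure,
    path: str | Path,
    ordering: CausalOrdering | None = None,
) -> None:
    payload = _structure_payload(structure, ordering)
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def save_network(
    network: BayesianNetwork,
    path: str | Path,
    ordering: CausalOrdering | None = None,
) -> None:
    payload = _structure_payload(network.structure, ordering)
    payload["cpts"] = {
        name: _cpt_payload(cpt, network.structure)
        for name, cpt in sorted(network.cpts.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _parse_structure(doc: dict[str, Any]) -> NetworkStructure:
    if "variables" not in doc:
        raise SchemaError("/variables: missing")
    variables = []
    declared: set[str] = set()
    for i, entry in enumerate(doc["variables"]):
        for key in ("name", "states"):
            if key not in entry:
                raise SchemaError(f"/variables/{i}/{key}: missing")
        try:
            variables.append(Variable(entry["name"], tuple(entry["states"])))
        except ValueError as exc:
            raise SchemaError(f"/variables/{i}: {exc}") from exc
        declared.add(entry["name"])
    edges = []
    for i, edge in enumerate(doc.get("edges", [])):
        if len(edge) != 2:
            raise SchemaError(f"/edges/{i}: expected [parent, child]")
        parent, child = edge
        for name in (parent, child):
            if name not in declared:
                raise SchemaError(f"/edges/{i}: unknown variable {name!r}")
        edges.append((parent, child))
    return NetworkStructure(variables, edges)


def load_structure(path: str | Path) -> NetworkStructure:
    doc = json.loads(Path(path).read_text())
    return _parse_structure(doc)


def load_network(path: str | Path) -> BayesianNetwork:
    doc = json.loads(Path(path).read_text())
    structure = _parse_structure(doc)
    if "cpts" not in doc:
        raise SchemaError("/cpts: missing (structure-only file?)")
    cpts: dict[str, CPT] = {}
    for name, entry in doc["cpts"].items():
        if name not in structure.variables:
            raise SchemaError(f"/cpts/{name}: unknown variable")
        parents = entry.get("parents", [])
        parent_cards = [structure.cardinality(p) for p in parents]
        card = structure.cardinality(name)
        shape = tuple(parent_cards) + (card,)
        table = np.zeros(shape)
        seen = set()
        for key, row in entry.get("table", {}).items():
            k = tuple(int(s) for s in key.split(",")) if key else ()
            if len(k) != len(parents):
                raise SchemaError(f"/cpts/{name}/table/{key}: bad key arity")
            if len(row) != card:
                raise SchemaError(f"/cpts/{name}/table/{key}: bad row length")
            if abs(sum(row) - 1.0) > _ROW_SUM_TOL:
                raise SchemaError(
                    f"/cpts/{name}/table/{key}: row sums to {sum(row)}, not 1"
                )
            table[k] = row
            seen.add(k)
        expected = set(itertools.product(*(range(c) for c in parent_cards)))
        if seen != expected:
            raise SchemaError(f"/cpts/{name}/table: incomplete parent coverage")
        cpts[name] = CPT(name, parents, table)
    try:
        return BayesianNetwork(structure, cpts)
    except ValueError as exc:
        raise SchemaError(f"/cpts: {exc}") from exc


def load_ordering(path: str | Path) -> CausalOrdering:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "levels" not in doc:
        raise SchemaError("/levels: missing")
    levels = doc["levels"]
    if not all(isinstance(level, list) for level in levels):
        raise SchemaError("/levels: expected a list of lists")
    return CausalOrdering([list(map(str, level)) for level in levels])


def save_ordering(ordering: CausalOrdering, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({"levels": [list(l) for l in ordering.levels]})
    )


def load_table(
    path: str | Path, structure: NetworkStructure | None = None
) -> pd.DataFrame:
    """Read a household CSV; complete cases only, states range-checked.

    Rows containing any missing cell are rejected outright with a count in
    the raised message, matching the complete-case contract of the fitting
    and learning steps.
    """
    data = pd.read_csv(path)
    if data.isna().any().any():
        bad = data.isna().any(axis=1)
        raise ValueError(
            f"{int(bad.sum())} rows with missing cells "
            f"(first at row {int(np.flatnonzero(bad)[0])}); complete cases required"
        )
    if structure is not None:
        unknown = [c for c in data.columns if c not in structure.variables]
        if unknown:
            raise ValueError(f"unknown columns {unknown}")
        for col in data.columns:
            card = structure.cardinality(col)
            values = data[col].to_numpy()
            bad_mask = (values < 0) | (values >= card)
            if bad_mask.any():
                row = int(np.flatnonzero(bad_mask)[0])
                raise ValueError(
                    f"out-of-range value {values[row]} in column {col!r} "
                    f"at row {row} (cardinality {card})"
                )
    return data.astype(np.int64)


def export_dot(structure: NetworkStructure, path: str | Path) -> None:
    lines = ["digraph G {"]
    for name in structure.variables:
        lines.append(f'  "{name}";')
    for parent, child in sorted(structure.edges):
        lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, command: str, **params: Any) -> None:
    """Record the command, parameters and seed of a run for reproducibility."""
    from . import __version__

    manifest = {"command": command, "version": __version__, **params}
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
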