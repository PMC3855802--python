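"""File formats: dataset CSV + JSON schema sidecar, DAG adjacency CSV / DOT,
and BayesNet JSON serialisation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    MISSING_LABEL,
    BayesNet,
    ConfigurationError,
    Cpt,
    Dag,
    Dataset,
    VariableSpec,
)
from .preprocess import DiscretisationRule, ExclusionRule, encode_missing


# -- schema sidecar ---------------------------------------------------------

def schema_to_dict(
    specs: Sequence[VariableSpec],
    rules: Sequence[DiscretisationRule] = (),
    exclusions: Sequence[ExclusionRule] = (),
) -> dict:
    return {
        "variables": [
            {
                "name": s.name,
                "states": list(s.states),
                "has_missing_state": s.has_missing_state,
                "tier": s.tier,
            }
            for s in specs
        ],
        "discretisation": [
            {"variable": r.variable, "cut_points": list(r.cut_points), "labels": list(r.labels)}
            for r in rules
        ],
        "exclusion_rules": [
            {
                "column": r.column,
                "drop_states": list(r.drop_states),
                "drop_null": r.drop_null,
                "name": r.name,
            }
            for r in exclusions
        ],
    }


def schema_from_dict(doc: dict):
    specs = [
        VariableSpec(
            d["name"], tuple(d["states"]), d.get("has_missing_state", False), d.get("tier", "pre_treatment")
        )
        for d in doc["variables"]
    ]
    rules = [
        DiscretisationRule(d["variable"], tuple(d["cut_points"]), tuple(d["labels"]))
        for d in doc.get("discretisation", [])
    ]
    exclusions = [
        ExclusionRule(d["column"], tuple(d.get("drop_states", ())), d.get("drop_null", False), d.get("name"))
        for d in doc.get("exclusion_rules", [])
    ]
    return specs, rules, exclusions


def write_schema(path, specs, rules=(), exclusions=()):
    Path(path).write_text(json.dumps(schema_to_dict(specs, rules, exclusions), indent=1))


def read_schema(path):
    return schema_from_dict(json.loads(Path(path).read_text()))


# -- dataset CSV ------------------------------------------------------------

def write_dataset(data: Dataset, csv_path, schema_path=None) -> None:
    """Write decoded labels as UTF-8 CSV; originally-null cells are written
    empty so the round trip reconstructs the mask."""
    frame = data.to_frame()
    arr = frame.to_numpy(dtype=object)
    arr[data.mask == 0] = None
    pd.DataFrame(arr, columns=frame.columns).to_csv(csv_path, index=False, encoding="utf-8")
    if schema_path is not None:
        write_schema(schema_path, data.variables)


def read_dataset(csv_path, schema_path) -> Dataset:
    specs, _, _ = read_schema(schema_path)
    frame = pd.read_csv(csv_path, dtype=object, keep_default_na=True, encoding="utf-8")
    if list(frame.columns) != [s.name for s in specs]:
        raise ConfigurationError("CSV header does not match schema variables")
    # strip the sentinel from specs so encode_missing re-derives the flags;
    # cells explicitly holding the sentinel label count as missing
    bare = []
    for s in specs:
        if s.has_missing_state:
            bare.append(VariableSpec(s.name, s.states[:-1], False, s.tier))
        else:
            bare.append(s)
    for s in bare:
        frame[s.name] = frame[s.name].where(frame[s.name] != MISSING_LABEL, other=pd.NA)
    return encode_missing(frame, bare)


# -- DAG adjacency / DOT ----------------------------------------------------

def write_dag_csv(dag: Dag, path) -> None:
    """Square 0/1 adjacency matrix, row = parent, column = child."""
    names = list(dag.variables)
    idx = {v: i for i, v in enumerate(names)}
    m = np.zeros((len(names), len(names)), dtype=int)
    for a, b in dag.edges:
        m[idx[a], idx[b]] = 1
    pd.DataFrame(m, index=names, columns=names).to_csv(path)


def read_dag_csv(path) -> Dag:
    frame = pd.read_csv(path, index_col=0)
    names = list(frame.columns)
    if list(frame.index) != names:
        raise ConfigurationError("adjacency matrix rows and columns must match")
    m = frame.to_numpy()
    edges = [(names[i], names[j]) for i, j in zip(*np.nonzero(m))]
    return Dag(names, edges)


def dag_to_dot(dag: Dag) -> str:
    lines = ["digraph G {"]
    for v in dag.variables:
        lines.append(f'  "{v}";')
    for a, b in sorted(dag.edges):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_dag_dot(dag: Dag, path) -> None:
    Path(path).write_text(dag_to_dot(dag))


# -- BayesNet JSON ----------------------------------------------------------

def net_to_dict(net: BayesNet) -> dict:
    return {
        "variables": [
            {
                "name": s.name,
                "states": list(s.states),
                "has_missing_state": s.has_missing_state,
                "tier": s.tier,
            }
            for s in net.variable_list()
        ],
        "edges": sorted(list(e) for e in net.dag.edges),
        "cpts": {
            v: {
                "parents": list(net.cpts[v].parents),
                "parent_cards": list(net.cpts[v].parent_cards),
                "table": net.cpts[v].table.tolist(),
                "pseudocount": net.cpts[v].pseudocount,
            }
            for v in net.variables
        },
    }


def net_from_dict(doc: dict) -> BayesNet:
    specs = {
        d["name"]: VariableSpec(
            d["name"], tuple(d["states"]), d.get("has_missing_state", False), d.get("tier", "pre_treatment")
        )
        for d in doc["variables"]
    }
    order = [d["name"] for d in doc["variables"]]
    dag = Dag(order, [tuple(e) for e in doc["edges"]])
    cpts = {
        v: Cpt(
            v,
            tuple(c["parents"]),
            tuple(c["parent_cards"]),
            np.asarray(c["table"], dtype=float),
            c.get("pseudocount", 1.0),
        )
        for v, c in doc["cpts"].items()
    }
    return BayesNet(dag, cpts, specs)


def write_net(net: BayesNet, path) -> None:
    Path(path).write_text(json.dumps(net_to_dict(net)))


def read_net(path) -> BayesNet:
    return net_from_dict(json.loads(Path(path).read_text()))
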