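"""Core types for discrete Bayesian-network modelling of categorical registries.

The central objects are :class:`Dataset` (encoded categorical records with a
missingness mask), :class:`Dag`, :class:`Cpt` and :class:`BayesNet`, together
with parameter estimation under uniform Dirichlet priors and the decomposable
K2 (Cooper–Herskovits) Bayesian graph score.

Missing values are modelled *explicitly*: a sentinel category
``"Unknown/Missing"`` is appended to a variable's state space and participates
in counting, scoring and inference like any other state.  This encodes
informative (NMAR) missingness rather than imputing it away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.special import gammaln

MISSING_LABEL = "Unknown/Missing"

TIERS = ("pre_treatment", "treatment", "post_treatment")
TIER_INDEX = {t: i for i, t in enumerate(TIERS)}


class ConfigurationError(ValueError):
    """A rule, schema or prior refers to variables/states that do not exist."""


class CyclicGraphError(ValueError):
    """A directed cycle where a DAG was required."""


class InconsistentEvidenceError(ValueError):
    """Evidence with zero probability under the model."""


class DegenerateDataError(ValueError):
    """Data unusable for the requested operation (e.g. constant class)."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: ordered states, sentinel flag, temporal tier.

    If ``has_missing_state`` is set, the sentinel ``"Unknown/Missing"`` must be
    the last state; it is then an ordinary category for all downstream counts.
    """

    name: str
    states: tuple
    has_missing_state: bool = False
    tier: str = "pre_treatment"

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if not self.states:
            raise ConfigurationError(f"{self.name}: empty state list")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError(f"{self.name}: duplicate states")
        if self.tier not in TIERS:
            raise ConfigurationError(f"{self.name}: unknown tier {self.tier!r}")
        if self.has_missing_state:
            if self.states.count(MISSING_LABEL) != 1 or self.states[-1] != MISSING_LABEL:
                raise ConfigurationError(
                    f"{self.name}: sentinel must appear exactly once, last"
                )
        elif MISSING_LABEL in self.states:
            raise ConfigurationError(
                f"{self.name}: sentinel present but has_missing_state is False"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def missing_index(self) -> int:
        if not self.has_missing_state:
            raise ConfigurationError(f"{self.name} has no sentinel state")
        return len(self.states) - 1

    def index_of(self, label) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ConfigurationError(f"{self.name}: unknown state {label!r}") from None

    def with_missing_state(self) -> "VariableSpec":
        if self.has_missing_state:
            return self
        return VariableSpec(self.name, self.states + (MISSING_LABEL,), True, self.tier)


class Dataset:
    """Encoded categorical records: ``records[i, j]`` is a state index of
    variable ``j``; ``mask[i, j] == 0`` marks a cell that was originally null
    (such cells hold the sentinel index)."""

    def __init__(self, variables: Sequence[VariableSpec], records, mask=None):
        self.variables = list(variables)
        self.records = np.asarray(records, dtype=np.int64)
        if self.records.ndim != 2:
            raise ValueError("records must be 2-D")
        n, p = self.records.shape
        if p != len(self.variables):
            raise ValueError("records width != number of variables")
        if mask is None:
            mask = np.ones((n, p), dtype=np.int8)
        self.mask = np.asarray(mask, dtype=np.int8)
        if self.mask.shape != self.records.shape:
            raise ValueError("mask shape mismatch")
        self._index = {v.name: j for j, v in enumerate(self.variables)}
        for j, v in enumerate(self.variables):
            col = self.records[:, j]
            if n == 0:
                continue
            if col.min() < 0 or col.max() >= v.n_states:
                raise ValueError(f"invalid state index in column {v.name}")
            if v.has_missing_state:
                bad = (self.mask[:, j] == 0) & (col != v.missing_index)
            else:
                bad = self.mask[:, j] == 0
            if bad.any():
                raise ValueError(f"masked cells must hold the sentinel ({v.name})")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.records.shape[0]

    @property
    def p(self) -> int:
        return self.records.shape[1]

    @property
    def names(self):
        return [v.name for v in self.variables]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown variable {name!r}") from None

    def spec(self, name: str) -> VariableSpec:
        return self.variables[self.index(name)]

    def card(self, name: str) -> int:
        return self.spec(name).n_states

    def column(self, name: str) -> np.ndarray:
        return self.records[:, self.index(name)]

    def subset(self, rows) -> "Dataset":
        rows = np.asarray(rows)
        return Dataset(self.variables, self.records[rows], self.mask[rows])

    def to_frame(self):
        """Decode to a pandas DataFrame of state labels."""
        import pandas as pd

        return pd.DataFrame(
            {
                v.name: np.asarray(v.states, dtype=object)[self.records[:, j]]
                for j, v in enumerate(self.variables)
            }
        )


class Dag:
    """A directed acyclic graph over named variables."""

    def __init__(self, variables: Sequence[str], edges: Iterable[tuple] = ()):
        self.variables = tuple(variables)
        if len(set(self.variables)) != len(self.variables):
            raise ConfigurationError("duplicate variable names")
        vs = set(self.variables)
        self.edges = frozenset((str(a), str(b)) for a, b in edges)
        for a, b in self.edges:
            if a not in vs or b not in vs:
                raise ConfigurationError(f"edge endpoint not a variable: {(a, b)}")
            if a == b:
                raise CyclicGraphError(f"self-loop on {a}")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise CyclicGraphError("graph contains a directed cycle")
        self._parents = {v: tuple(sorted(g.predecessors(v))) for v in self.variables}
        self._children = {v: tuple(sorted(g.successors(v))) for v in self.variables}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def parents(self, v: str) -> tuple:
        return self._parents[v]

    def children(self, v: str) -> tuple:
        return self._children[v]

    def topological_order(self):
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def __eq__(self, other):
        return (
            isinstance(other, Dag)
            and set(self.variables) == set(other.variables)
            and self.edges == other.edges
        )

    def __hash__(self):
        return hash((frozenset(self.variables), self.edges))

    def __repr__(self):
        return f"Dag({len(self.variables)} vars, {len(self.edges)} edges)"


@dataclass
class Cpt:
    """Conditional probability table: one probability row per joint parent
    configuration, parent configurations in row-major (ravel) order of the
    ordered parent list."""

    child: str
    parents: tuple
    parent_cards: tuple
    table: np.ndarray  # shape (prod(parent_cards), r_child)
    pseudocount: float = 1.0

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.parent_cards = tuple(int(c) for c in self.parent_cards)
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if self.table.ndim != 2 or self.table.shape[0] != q:
            raise ValueError(f"{self.child}: CPT must have {q} rows")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if (self.table < -1e-12).any() or (self.table > 1 + 1e-12).any():
            raise ValueError(f"{self.child}: probabilities outside [0, 1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError(f"{self.child}: CPT rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.table.shape[1]

    def row_index(self, parent_states) -> int:
        """Flat row index for a tuple of parent state indices."""
        if not self.parents:
            return 0
        return int(np.ravel_multi_index(tuple(parent_states), self.parent_cards))


@dataclass
class BayesNet:
    """A DAG plus one CPT per variable; the joint factorises as
    P(x) = prod_i P(x_i | pa(x_i))."""

    dag: Dag
    cpts: dict
    specs: dict  # name -> VariableSpec

    def __post_init__(self):
        for v in self.dag.variables:
            if v not in self.cpts:
                raise ConfigurationError(f"missing CPT for {v}")
            if tuple(self.cpts[v].parents) != self.dag.parents(v):
                raise ConfigurationError(f"CPT parents for {v} disagree with DAG")
            if v not in self.specs:
                raise ConfigurationError(f"missing VariableSpec for {v}")
            if self.cpts[v].n_states != self.specs[v].n_states:
                raise ConfigurationError(f"CPT cardinality mismatch for {v}")

    @property
    def variables(self):
        return self.dag.variables

    def card(self, name: str) -> int:
        return self.specs[name].n_states

    def variable_list(self):
        """VariableSpecs in DAG variable order (Dataset column order)."""
        return [self.specs[v] for v in self.dag.variables]


# ---------------------------------------------------------------------------
# counting, fitting, scoring
# ---------------------------------------------------------------------------

def family_counts(data: Dataset, child: str, parents: Sequence[str]) -> np.ndarray:
    """N_ijk matrix: rows = joint parent configurations (ravel order of
    ``parents``), columns = child states."""
    r = data.card(child)
    child_col = data.column(child)
    parents = tuple(parents)
    if not parents:
        return np.bincount(child_col, minlength=r).reshape(1, r)
    cards = tuple(data.card(p) for p in parents)
    cols = tuple(data.column(p) for p in parents)
    cfg = np.ravel_multi_index(cols, cards)
    q = int(np.prod(cards))
    flat = np.bincount(cfg * r + child_col, minlength=q * r)
    return flat.reshape(q, r)


def fit_parameters(dag: Dag, data: Dataset, pseudocount: float = 1.0) -> BayesNet:
    """Estimate all CPTs as (N_ijk + a) / (N_ij + r_i * a) with a uniform
    Dirichlet pseudocount ``a`` per cell.  Rows with no data reduce to the
    uniform prior."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for v in dag.variables:
        data.index(v)  # raises ConfigurationError on unknown variable
    cpts = {}
    for v in dag.variables:
        parents = dag.parents(v)
        counts = family_counts(data, v, parents)
        r = counts.shape[1]
        table = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + r * pseudocount
        )
        cards = tuple(data.card(p) for p in parents)
        cpts[v] = Cpt(v, parents, cards, table, pseudocount)
    specs = {v: data.spec(v) for v in dag.variables}
    return BayesNet(dag, cpts, specs)


def family_score_from_counts(counts: np.ndarray) -> float:
    """K2 family term: sum_j [lnG(r) - lnG(N_ij + r) + sum_k lnG(N_ijk + 1)]."""
    r = counts.shape[1]
    n_ij = counts.sum(axis=1)
    return float(
        np.sum(gammaln(r) - gammaln(n_ij + r)) + np.sum(gammaln(counts + 1.0))
    )


def family_score(data: Dataset, child: str, parents: Sequence[str]) -> float:
    return family_score_from_counts(family_counts(data, child, parents))


def log_bayesian_score(dag: Dag, data: Dataset, graph_prior: float = 0.0) -> float:
    """Log of the K2 joint score P(G, D): the product over nodes of the
    Cooper–Herskovits closed-form marginal likelihood, plus a log structure
    prior (0 = uniform over structures).

    Decomposable: the total is the sum of per-node family terms, so moving a
    single edge only changes the affected child's contribution.
    """
    total = graph_prior
    for v in dag.variables:
        total += family_score(data, v, dag.parents(v))
    return float(total)


def joint_probability(net: BayesNet, assignment: Mapping[str, object]) -> float:
    """Probability of one complete assignment (labels) under the factorisation."""
    missing = set(net.variables) - set(assignment)
    if missing:
        raise ValueError(f"assignment incomplete, missing {sorted(missing)}")
    idx = {v: net.specs[v].index_of(assignment[v]) for v in net.variables}
    p = 1.0
    for v in net.variables:
        cpt = net.cpts[v]
        row = cpt.row_index(tuple(idx[u] for u in cpt.parents))
        p *= cpt.table[row, idx[v]]
    return float(p)
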