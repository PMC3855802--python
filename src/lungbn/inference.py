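"""Exact inference on discrete Bayesian networks, and do-operator interventions.

Posterior queries are answered by sum-product variable elimination, which is
exact (the contract the junction-tree family of algorithms also satisfies);
on the 13 small-arity clinical variables either is trivial.  A causal
intervention on a treatment variable T is performed graphically: every edge
into T is cut, T's mechanism is replaced by a parent-free table, and T is then
clamped as evidence — Pearl's truncated factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .data_model import (
    BayesNet,
    ConfigurationError,
    Cpt,
    Dag,
    Dataset,
    InconsistentEvidenceError,
    family_counts,
)


@dataclass(frozen=True)
class EvidenceSet:
    """A partial assignment of state labels to variables."""

    assignments: tuple  # tuple of (variable, state) pairs

    @classmethod
    def of(cls, mapping: Mapping[str, object]) -> "EvidenceSet":
        return cls(tuple(sorted(mapping.items())))

    def as_dict(self) -> dict:
        d = dict(self.assignments)
        if len(d) != len(self.assignments):
            raise ValueError("a variable appears more than once in evidence")
        return d


@dataclass(frozen=True)
class InterventionQuery:
    """do(target = value) combined with observational evidence."""

    target: str
    value: object
    evidence: EvidenceSet = EvidenceSet(())

    def __post_init__(self):
        if self.target in self.evidence.as_dict():
            raise ValueError("intervention target may not also appear in evidence")


# -- factor algebra ---------------------------------------------------------

class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars_, values):
        self.vars = tuple(vars_)
        self.values = np.asarray(values, dtype=float)

    def reduce(self, var, state_idx):
        if var not in self.vars:
            return self
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1 :], np.take(self.values, state_idx, axis=ax)
        )

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(out_vars)
        b = other._broadcast(out_vars)
        return _Factor(out_vars, a * b)

    def _broadcast(self, out_vars):
        shape = [1] * len(out_vars)
        src = list(range(len(self.vars)))
        dst = [out_vars.index(v) for v in self.vars]
        arr = np.moveaxis(
            self.values.reshape(self.values.shape + (1,) * (len(out_vars) - len(self.vars))),
            src,
            dst,
        )
        for i, v in enumerate(out_vars):
            shape[i] = self.values.shape[self.vars.index(v)] if v in self.vars else 1
        return arr.reshape(shape)

    def sum_out(self, var) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1 :], self.values.sum(axis=ax))


def _cpt_factor(net: BayesNet, v: str) -> _Factor:
    cpt = net.cpts[v]
    shape = tuple(cpt.parent_cards) + (cpt.n_states,)
    return _Factor(tuple(cpt.parents) + (v,), cpt.table.reshape(shape))


def _eliminate(factors, var):
    touching = [f for f in factors if var in f.vars]
    rest = [f for f in factors if var not in f.vars]
    if not touching:
        return factors
    prod = touching[0]
    for f in touching[1:]:
        prod = prod.multiply(f)
    rest.append(prod.sum_out(var))
    return rest


def posterior(net: BayesNet, evidence, query: str) -> np.ndarray:
    """Exact P(query | evidence) as a probability vector over the query's
    states.  Raises :class:`InconsistentEvidenceError` if the evidence has
    zero probability under the net."""
    if isinstance(evidence, EvidenceSet):
        ev = evidence.as_dict()
    else:
        ev = EvidenceSet.of(dict(evidence)).as_dict()
    if query not in net.specs:
        raise ConfigurationError(f"unknown query variable {query!r}")
    if query in ev:
        raise ValueError("query variable appears in evidence")
    ev_idx = {}
    for k, v in ev.items():
        if k not in net.specs:
            raise ConfigurationError(f"unknown evidence variable {k!r}")
        ev_idx[k] = net.specs[k].index_of(v)

    factors = [_cpt_factor(net, v) for v in net.variables]
    factors = [
        f
        for f in (
            _reduce_all(f, ev_idx) for f in factors
        )
    ]
    # eliminate hidden variables, smallest-cardinality-first greedy order
    hidden = [v for v in net.variables if v != query and v not in ev_idx]
    hidden.sort(key=lambda v: (net.card(v), v))
    for v in hidden:
        factors = _eliminate(factors, v)
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f)
    vec = result.values.reshape(net.card(query)) if result.vars else np.atleast_1d(result.values)
    total = vec.sum()
    if total <= 0.0:
        raise InconsistentEvidenceError("evidence has zero probability under the net")
    return vec / total


def _reduce_all(factor: _Factor, ev_idx: dict) -> _Factor:
    for k, i in ev_idx.items():
        factor = factor.reduce(k, i)
    return factor


# -- interventions ----------------------------------------------------------

def mutilate(
    net: BayesNet,
    target: str,
    data: Optional[Dataset] = None,
    pseudocount: float = 1.0,
) -> BayesNet:
    """Cut every edge into ``target`` and replace its CPT by a parent-free
    marginal table.

    The marginal is re-learned from ``data`` when given (the operational
    choice when the net is re-parameterised on a training subset before
    recommendation); otherwise it is the exact marginal implied by the net.
    All other CPTs are untouched.  Idempotent.
    """
    if target not in net.specs:
        raise ConfigurationError(f"unknown variable {target!r}")
    if not net.dag.parents(target) and data is None:
        return net
    new_edges = {(a, b) for a, b in net.dag.edges if b != target}
    new_dag = Dag(net.dag.variables, new_edges)
    if data is not None:
        counts = family_counts(data, target, ()).astype(float)
        r = counts.shape[1]
        table = (counts + pseudocount) / (counts.sum() + r * pseudocount)
    else:
        table = posterior(net, {}, target).reshape(1, -1)
    cpts = dict(net.cpts)
    cpts[target] = Cpt(target, (), (), table, pseudocount)
    return BayesNet(new_dag, cpts, dict(net.specs))


def interventional_survival(
    net: BayesNet, q: InterventionQuery, outcome: str, outcome_state=None
) -> object:
    """P(outcome | evidence, do(target = value)).

    If the net still has edges into the target it is mutilated first (exact
    marginal).  Returns the full posterior vector, or the single entry for
    ``outcome_state`` when given.
    """
    if outcome == q.target:
        raise ValueError("outcome must differ from the intervention target")
    if net.dag.parents(q.target):
        net = mutilate(net, q.target)
    ev = dict(q.evidence.as_dict())
    ev[q.target] = q.value
    vec = posterior(net, ev, outcome)
    if outcome_state is None:
        return vec
    return float(vec[net.specs[outcome].index_of(outcome_state)])


# -- vectorised full-evidence prediction ------------------------------------

def markov_blanket_scores(net: BayesNet, data: Dataset, outcome: str) -> np.ndarray:
    """P(outcome | all other variables) for every record, exactly, via the
    Markov-blanket closed form.

    Valid whenever every non-outcome variable is observed (the explicit
    sentinel state counts as an observation), in which case
    P(s | e) ∝ P(s | pa(s)) · Π_{c ∈ children(s)} P(x_c | pa(c), s).
    Returns an (n, r_outcome) matrix of posterior probabilities.
    """
    n = data.n
    r = net.card(outcome)
    j_out = data.index(outcome)
    logp = np.zeros((n, r))

    cpt = net.cpts[outcome]
    if cpt.parents:
        cols = tuple(data.column(p) for p in cpt.parents)
        rows = np.ravel_multi_index(cols, cpt.parent_cards)
    else:
        rows = np.zeros(n, dtype=np.int64)
    with np.errstate(divide="ignore"):
        logp += np.log(cpt.table[rows])

        for c in net.dag.children(outcome):
            ccpt = net.cpts[c]
            child_col = data.column(c)
            pa_cols = [data.column(p).copy() for p in ccpt.parents]
            k = ccpt.parents.index(outcome)
            for s in range(r):
                pa_cols[k][:] = s
                rows_c = np.ravel_multi_index(tuple(pa_cols), ccpt.parent_cards)
                logp[:, s] += np.log(ccpt.table[rows_c, child_col])

    logp -= logp.max(axis=1, keepdims=True)
    w = np.exp(logp)
    return w / w.sum(axis=1, keepdims=True)


def predict_outcome(
    net: BayesNet,
    data: Dataset,
    outcome: str,
    positive_state: object,
    exclude: tuple = (),
) -> np.ndarray:
    """P(outcome = positive_state | evidence) per record.

    By default the evidence is every other variable (fast exact Markov-blanket
    path).  ``exclude`` names variables to withhold from the evidence, which
    falls back to per-record variable elimination.
    """
    k = net.specs[outcome].index_of(positive_state)
    if not exclude:
        return markov_blanket_scores(net, data, outcome)[:, k]
    out = np.empty(data.n)
    names = [v for v in data.names if v != outcome and v not in exclude]
    cols = {v: data.column(v) for v in names}
    specs = {v: data.spec(v) for v in names}
    for i in range(data.n):
        ev = {v: specs[v].states[cols[v][i]] for v in names}
        out[i] = posterior(net, ev, outcome)[k]
    return out
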