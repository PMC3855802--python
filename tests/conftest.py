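"""Shared fixtures and independent oracles.

Oracles here deliberately avoid the library's own computation paths: exact
scores use integer factorial arithmetic, posteriors use brute-force
enumeration of the joint, AUC uses pairwise counting.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from lungbn.data_model import (
    BayesNet,
    Cpt,
    Dag,
    Dataset,
    VariableSpec,
    joint_probability,
)
from lungbn.synthetic_data import (
    GeneratorConfig,
    apply_nmar,
    build_truth_net,
    sample_cohort,
)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------

def make_dataset(columns, states=None, tiers=None, mask=None):
    """Dataset from a dict name -> list of state indices (ints)."""
    names = list(columns)
    specs = []
    for name in names:
        vals = np.asarray(columns[name])
        k = (
            len(states[name])
            if states and name in states
            else int(vals.max()) + 1 if vals.size else 2
        )
        st = tuple(states[name]) if states and name in states else tuple(
            f"s{i}" for i in range(k)
        )
        tier = tiers.get(name, "pre_treatment") if tiers else "pre_treatment"
        has_missing = st[-1] == "Unknown/Missing"
        specs.append(VariableSpec(name, st, has_missing, tier))
    records = np.column_stack([np.asarray(columns[n]) for n in names])
    return Dataset(specs, records, mask)


def random_discrete_net(rng, n_vars=6, max_states=3, edge_prob=0.35):
    names = [f"V{i}" for i in range(n_vars)]
    cards = rng.integers(2, max_states + 1, n_vars)
    edges = [
        (names[i], names[j])
        for i in range(n_vars)
        for j in range(i + 1, n_vars)
        if rng.random() < edge_prob
    ]
    dag = Dag(names, edges)
    specs = {
        n: VariableSpec(n, tuple(f"s{k}" for k in range(c)))
        for n, c in zip(names, cards)
    }
    cpts = {}
    for v in names:
        ps = dag.parents(v)
        pc = tuple(specs[p].n_states for p in ps)
        q = int(np.prod(pc)) if ps else 1
        cpts[v] = Cpt(v, ps, pc, rng.dirichlet(np.ones(specs[v].n_states), size=q), 1.0)
    return BayesNet(dag, cpts, specs)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def enum_posterior(net, evidence, query):
    """P(query | evidence) by summing joint_probability over all assignments."""
    names = list(net.variables)
    states = {v: net.specs[v].states for v in names}
    out = np.zeros(net.card(query))
    free = [v for v in names if v not in evidence]
    for combo in itertools.product(*[states[v] for v in free]):
        asg = dict(evidence)
        asg.update(zip(free, combo))
        out[states[query].index(asg[query])] += joint_probability(net, asg)
    return out / out.sum()


def enum_do(net, target, value, evidence, query):
    """Truncated factorisation: drop the target's own factor, clamp target."""
    names = list(net.variables)
    states = {v: net.specs[v].states for v in names}
    out = np.zeros(net.card(query))
    free = [v for v in names if v != target and v not in evidence]
    for combo in itertools.product(*[states[v] for v in free]):
        asg = dict(evidence)
        asg[target] = value
        asg.update(zip(free, combo))
        idx = {v: states[v].index(asg[v]) for v in names}
        p = 1.0
        for v in names:
            if v == target:
                continue
            cpt = net.cpts[v]
            row = cpt.row_index(tuple(idx[u] for u in cpt.parents))
            p *= cpt.table[row, idx[v]]
        out[idx[query]] += p
    return out / out.sum()


def exact_k2_family(counts):
    """Exact-integer K2 family term via factorials; returns a log float."""
    counts = np.asarray(counts, dtype=int)
    r = counts.shape[1]
    value = Fraction(1)
    for row in counts:
        n_ij = int(row.sum())
        value *= Fraction(math.factorial(r - 1), math.factorial(n_ij + r - 1))
        for n_ijk in row:
            value *= math.factorial(int(n_ijk))
    return math.log(value.numerator) - math.log(value.denominator)


def pairwise_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# session fixtures: the default synthetic registry
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def truth_net():
    return build_truth_net(GeneratorConfig())


@pytest.fixture(scope="session")
def cohort20k(truth_net):
    return sample_cohort(truth_net, 20_000, GeneratorConfig().sample_seed)


@pytest.fixture(scope="session")
def nmar_cohort(cohort20k):
    return apply_nmar(cohort20k, GeneratorConfig(), seed=13)
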