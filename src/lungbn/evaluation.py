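"""Cross-validated evaluation of structures, baseline classifiers, and the
missingness-informativeness experiment.

The harness mirrors the standard registry protocol: stratified k-fold
partitions with approximately equal outcome prevalence, per-fold structure +
parameter learning, held-out AUC / accuracy, aggregation of the fold DAGs
into a final structure, and the final structure's Bayesian score on the full
data.  Naive Bayes and ridge-penalised logistic regression serve as baseline
classifiers; running them on the observed/missing indicator matrix tests
whether the missingness pattern itself predicts the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .data_model import (
    Dag,
    Dataset,
    DegenerateDataError,
    family_counts,
    fit_parameters,
    log_bayesian_score,
)
from .inference import predict_outcome
from .preprocess import indicator_matrix
from .structure_learning import aggregate_dags


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: probability that a random positive outranks a random
    negative, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    return float(np.mean((scores >= threshold) == labels))


def stratified_folds(data: Dataset, k: int, outcome: str, seed: int):
    """k index partitions of near-equal size with per-fold outcome prevalence
    matching the global rate; deterministic by seed."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > data.n:
        raise ValueError("more folds than records")
    j = data.index(outcome)
    if (data.mask[:, j] == 0).any():
        raise ValueError("outcome must be fully observed")
    y = data.records[:, j]
    if k == data.n:  # leave-one-out: stratification is vacuous
        perm = np.random.default_rng(seed).permutation(data.n)
        return [np.array([i]) for i in perm]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(data.n), y)]


def _positive_index(data: Dataset, outcome: str, positive_state):
    spec = data.spec(outcome)
    if positive_state is None:
        return 0, spec.states[0]
    return spec.index_of(positive_state), positive_state


@dataclass
class FoldResult:
    dag: Dag
    auc: float
    accuracy: float


@dataclass
class CVReport:
    """Per-fold structures and metrics plus the aggregated final DAG."""

    per_fold: list
    dag_final: Dag
    log_score_final: float
    seed: int

    @property
    def mean_auc(self):
        return float(np.mean([f.auc for f in self.per_fold]))

    @property
    def sd_auc(self):
        return float(np.std([f.auc for f in self.per_fold], ddof=1))

    @property
    def mean_accuracy(self):
        return float(np.mean([f.accuracy for f in self.per_fold]))

    @property
    def sd_accuracy(self):
        return float(np.std([f.accuracy for f in self.per_fold], ddof=1))

    def to_dict(self):
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "log_score_final": self.log_score_final,
            "dag_final_edges": sorted(list(e) for e in self.dag_final.edges),
            "seed": self.seed,
        }


def cross_validate(
    data: Dataset,
    learner: Union[Dag, Callable[[Dataset], Dag]],
    outcome: str,
    k: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
    positive_state=None,
    exclude: tuple = (),
    folds: Optional[list] = None,
) -> CVReport:
    """Stratified k-fold evaluation of a structure learner (or fixed DAG).

    Per fold: learn the DAG and CPTs on the other k-1 parts, score
    P(outcome | all other observed variables) on the held-out part, and
    compute AUC and accuracy at posterior threshold 0.5.  All fold DAGs are
    then merged by maximum-weight branching into ``dag_final``, scored on the
    full data.  Precomputed ``folds`` may be passed to compare learners on
    identical partitions.
    """
    pos_idx, pos_state = _positive_index(data, outcome, positive_state)
    if folds is None:
        folds = stratified_folds(data, k, outcome, seed)
    all_idx = np.arange(data.n)
    results = []
    for fold_id, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train, test = data.subset(train_idx), data.subset(test_idx)
        try:
            dag = learner if isinstance(learner, Dag) else learner(train)
            net = fit_parameters(dag, train, pseudocount)
        except Exception as exc:
            raise RuntimeError(f"learner failed on fold {fold_id}: {exc}") from exc
        scores = predict_outcome(net, test, outcome, pos_state, exclude=exclude)
        labels = test.column(outcome) == pos_idx
        results.append(FoldResult(dag, auc(scores, labels), accuracy(scores, labels)))
    dag_final = aggregate_dags([f.dag for f in results])
    return CVReport(results, dag_final, log_bayesian_score(dag_final, data), seed)


# ---------------------------------------------------------------------------
# baseline classifiers
# ---------------------------------------------------------------------------

def naive_bayes_fit_predict(
    train: Dataset,
    test: Dataset,
    outcome: str,
    pseudocount: float = 1.0,
    positive_state=None,
) -> np.ndarray:
    """P(outcome | x) ∝ P(outcome) Π_i P(x_i | outcome), all tables smoothed
    with the same uniform Dirichlet pseudocount as the BN parameter fits.

    Identical, by construction, to exact posterior inference on the
    star-shaped BN (outcome → every predictor) with the same smoothing — a
    cross-module consistency tested elsewhere.
    """
    pos_idx, _ = _positive_index(train, outcome, positive_state)
    r = train.card(outcome)
    y = train.column(outcome)
    prior = np.bincount(y, minlength=r) + pseudocount
    log_post = np.tile(np.log(prior / prior.sum()), (test.n, 1))
    for v in train.names:
        if v == outcome:
            continue
        counts = family_counts(train, v, (outcome,)).astype(float)  # (r, r_v)
        cond = (counts + pseudocount) / (
            counts.sum(axis=1, keepdims=True) + counts.shape[1] * pseudocount
        )
        log_post += np.log(cond[:, test.column(v)]).T
    log_post -= log_post.max(axis=1, keepdims=True)
    w = np.exp(log_post)
    return (w / w.sum(axis=1, keepdims=True))[:, pos_idx]


def one_hot(data: Dataset, exclude: tuple = ()) -> np.ndarray:
    """Deterministic full one-hot encoding from each variable's declared
    state space (unseen states therefore cause no trouble)."""
    blocks = []
    for v in data.variables:
        if v.name in exclude:
            continue
        col = data.column(v.name)
        block = np.zeros((data.n, v.n_states))
        block[np.arange(data.n), col] = 1.0
        blocks.append(block)
    return np.hstack(blocks)


def logistic_fit_predict(
    train: Dataset,
    test: Dataset,
    outcome: str,
    ridge: float = 1e-8,
    positive_state=None,
    max_iter: int = 2000,
) -> np.ndarray:
    """L2-penalised logistic regression on one-hot-encoded predictors.

    Minimises the negative log-likelihood plus (ridge/2)·||w||² (intercept
    unpenalised) by L-BFGS to tight tolerance; raises on non-convergence.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    pos_idx, _ = _positive_index(train, outcome, positive_state)
    x_train = one_hot(train, exclude=(outcome,))
    x_test = one_hot(test, exclude=(outcome,))
    y = (train.column(outcome) == pos_idx).astype(int)
    if ridge == 0:
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter, tol=1e-10)
    else:
        model = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=max_iter, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x_train, y)
    if int(np.max(model.n_iter_)) >= max_iter:
        raise RuntimeError(
            f"logistic regression failed to converge in {max_iter} iterations "
            f"(ridge={ridge}, n={train.n}, p={x_train.shape[1]})"
        )
    return model.predict_proba(x_test)[:, 1]


def _baseline_cv(data, outcome, folds, predictor, pos_idx):
    aucs, accs = [], []
    all_idx = np.arange(data.n)
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        train, test = data.subset(train_idx), data.subset(test_idx)
        scores = predictor(train, test)
        labels = test.column(outcome) == pos_idx
        aucs.append(auc(scores, labels))
        accs.append(accuracy(scores, labels))
    return {
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)),
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)),
    }


def missingness_experiment(
    data: Dataset,
    outcome: str,
    k: int = 10,
    seed: int = 0,
    ridge: float = 1e-8,
    positive_state=None,
) -> pd.DataFrame:
    """Can the missingness pattern alone predict the outcome?

    Builds the observed/missing indicator matrix over the predictor columns
    and cross-validates naive Bayes and logistic regression on it.  Under
    MCAR deletion the expected AUC is 0.5; informative (NMAR) deletion pushes
    it above.  Returns one row per model with mean/sd AUC and accuracy.
    """
    j = data.index(outcome)
    pred_mask = np.delete(data.mask, j, axis=1)
    if (pred_mask == 1).all():
        warnings.warn("no missingness in predictors; indicator matrix is constant")
    indicator = indicator_matrix(data, outcome)
    pos_idx, pos_state = _positive_index(indicator, outcome, positive_state)
    folds = stratified_folds(indicator, k, outcome, seed)
    rows = {
        "naive_bayes": _baseline_cv(
            indicator,
            outcome,
            folds,
            lambda tr, te: naive_bayes_fit_predict(tr, te, outcome, positive_state=pos_state),
            pos_idx,
        ),
        "logistic": _baseline_cv(
            indicator,
            outcome,
            folds,
            lambda tr, te: logistic_fit_predict(tr, te, outcome, ridge, positive_state=pos_state),
            pos_idx,
        ),
    }
    return pd.DataFrame(rows).T
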