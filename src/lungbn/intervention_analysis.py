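"""Survival-maximising treatment recommendation and concordance analysis.

Given a network mutilated at the treatment node (all incoming edges cut), the
recommended plan for a patient is the candidate treatment maximising the
interventional survival probability P(Survival = Alive | evidence, do(T = t)).
Recommendations are compared against the recorded plans of an eligible cohort
(lung-cancer diagnosis, curative recorded plan, fully observed record):
an *exact* match is the same plan code, a *partial* match is a different code
sharing at least one treatment modality (e.g. surgery alone vs surgery
followed by adjuvant chemotherapy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import BayesNet, ConfigurationError, Dataset
from .inference import EvidenceSet, markov_blanket_scores, mutilate, posterior


@dataclass(frozen=True)
class TreatmentPlan:
    """One treatment-plan option: registry code, name, modality set and
    curative flag (palliative care and active monitoring are non-curative)."""

    code: int
    label: str
    modalities: frozenset
    curative: bool


def _plan(code, label, mods, curative=True):
    return TreatmentPlan(code, label, frozenset(mods), curative)


TREATMENT_PLANS = {
    p.code: p
    for p in (
        _plan(1, "Surgery", {"surgery"}),
        _plan(2, "Radiotherapy", {"radio"}),
        _plan(3, "Chemotherapy", {"chemo"}),
        _plan(5, "Palliative care", {"palliative"}, curative=False),
        _plan(6, "Active Monitoring", {"monitoring"}, curative=False),
        _plan(7, "Sequential chemotherapy and radiotherapy", {"chemo", "radio"}),
        _plan(8, "Concurrent chemotherapy and radiotherapy", {"chemo", "radio"}),
        _plan(9, "Induction chemotherapy to downstage before surgery", {"chemo", "surgery"}),
        _plan(10, "Neo-adjuvant chemotherapy and surgery", {"chemo", "surgery"}),
        _plan(11, "Surgery followed by adjuvant chemotherapy", {"surgery", "chemo"}),
    )
}

CURATIVE_CODES = tuple(sorted(c for c, p in TREATMENT_PLANS.items() if p.curative))
SURGICAL_CODES = (1, 9, 10, 11)

#: TNM stage strata used for concordance breakdowns
STAGE_GROUPS = {
    "early": ("IA", "IB", "IIA", "IIB"),
    "locally_advanced": ("IIIA", "IIIB"),
    "advanced": ("IV",),
    "uncertain": ("Uncertain",),
}


def curative_plans() -> list:
    return [TREATMENT_PLANS[c] for c in CURATIVE_CODES]


def non_surgical_curative_plans() -> list:
    return [TREATMENT_PLANS[c] for c in CURATIVE_CODES if c not in SURGICAL_CODES]


def match_level(recorded: TreatmentPlan, recommended: TreatmentPlan) -> str:
    """'exact' for identical codes, 'partial' for different codes sharing a
    modality, 'none' otherwise."""
    if recorded.code == recommended.code:
        return "exact"
    if recorded.modalities & recommended.modalities:
        return "partial"
    return "none"


def joint_from_conditional(p_surv_given_t: float, p_t: float) -> float:
    """P(Survival, Treatment) = P(Survival | Treatment) * P(Treatment)."""
    for v in (p_surv_given_t, p_t):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"probability {v} outside [0, 1]")
    return p_surv_given_t * p_t


@dataclass
class EligibilityConfig:
    """Cohort filters: study diagnoses, curative recorded plan, no missing
    cells.  Diagnosis states are configurable because synthetic registries
    may use abstract labels; None admits every non-sentinel diagnosis."""

    diagnosis_var: str = "Diagnosis"
    allowed_diagnoses: Optional[tuple] = None
    treatment_var: str = "Treatment"
    curative_codes: tuple = CURATIVE_CODES


def select_eligible(data: Dataset, config: Optional[EligibilityConfig] = None):
    """Rows with a study diagnosis, a curative recorded treatment and no
    missing cell.  Returns (cohort, per-filter removal counts); removals are
    attributed to the first failing filter."""
    config = config or EligibilityConfig()
    spec_d = data.spec(config.diagnosis_var)
    diag = data.column(config.diagnosis_var)
    if config.allowed_diagnoses is None:
        ok_diag = np.ones(data.n, dtype=bool)
        if spec_d.has_missing_state:
            ok_diag = diag != spec_d.missing_index
    else:
        allowed = [spec_d.index_of(s) for s in config.allowed_diagnoses]
        ok_diag = np.isin(diag, allowed)
    spec_t = data.spec(config.treatment_var)
    cur_idx = [
        spec_t.index_of(str(c)) for c in config.curative_codes if str(c) in spec_t.states
    ]
    ok_treat = np.isin(data.column(config.treatment_var), cur_idx)
    ok_complete = (data.mask == 1).all(axis=1)
    counts = {
        "diagnosis": int((~ok_diag).sum()),
        "non_curative_treatment": int((ok_diag & ~ok_treat).sum()),
        "missing_data": int((ok_diag & ok_treat & ~ok_complete).sum()),
    }
    keep = ok_diag & ok_treat & ok_complete
    return data.subset(np.flatnonzero(keep)), counts


@dataclass
class Recommendation:
    """Candidate treatments ranked by interventional survival probability."""

    evidence: EvidenceSet
    ranking: list  # (code, probability), best first
    top: int
    tie: bool


_TIE_TOL = 1e-9


def recommend(
    net: BayesNet,
    evidence,
    candidates: Sequence[TreatmentPlan],
    treatment_var: str = "Treatment",
    outcome: str = "Survival",
    alive_state: str = "Alive",
) -> Recommendation:
    """argmax over candidate plans of P(outcome=alive | evidence, do(T=t)).

    The net must already be mutilated at the treatment variable (or have no
    edges into it).  Ties within 1e-9 are flagged and broken by the lower
    plan code.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if net.dag.parents(treatment_var):
        raise ValueError("net must be mutilated at the treatment variable first")
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet.of(dict(evidence))
    ev = evidence.as_dict()
    k = net.specs[outcome].index_of(alive_state)
    probs = []
    for plan in sorted(candidates, key=lambda p: p.code):
        e = dict(ev)
        e[treatment_var] = str(plan.code)
        probs.append((plan.code, float(posterior(net, e, outcome)[k])))
    best_p = max(p for _, p in probs)
    tied = [c for c, p in probs if best_p - p <= _TIE_TOL]
    ranking = sorted(probs, key=lambda cp: (-cp[1], cp[0]))
    return Recommendation(evidence, ranking, min(tied), len(tied) > 1)


@dataclass
class ConcordanceReport:
    """Recorded-vs-recommended confusion matrix with exact / partial-or-exact
    concordance rates and per-treatment / per-stage-group breakdowns."""

    confusion: pd.DataFrame  # rows recorded, columns recommended
    exact_rate: float
    partial_or_exact_rate: float
    by_treatment: pd.DataFrame  # rows recorded code, cols exact/partial/none
    by_stage_group: pd.DataFrame
    n: int
    ties: int

    def to_dict(self):
        return {
            "n": self.n,
            "exact_rate": self.exact_rate,
            "partial_or_exact_rate": self.partial_or_exact_rate,
            "ties": self.ties,
            "confusion": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.to_dict(orient="index").items()
            },
            "by_treatment": self.by_treatment.to_dict(orient="index"),
            "by_stage_group": self.by_stage_group.to_dict(orient="index"),
        }


def _recommend_matrix(net, cohort, candidates, treatment_var, outcome, alive_state):
    """Vectorised interventional survival per (record, candidate).

    On the mutilated net every variable except the outcome is observed once
    the treatment is clamped, so the Markov-blanket closed form applies; the
    treatment column is simply overwritten with each candidate in turn.
    """
    k = net.specs[outcome].index_of(alive_state)
    j_t = cohort.index(treatment_var)
    spec_t = cohort.spec(treatment_var)
    probs = np.empty((cohort.n, len(candidates)))
    records = cohort.records.copy()
    for c, plan in enumerate(candidates):
        records[:, j_t] = spec_t.index_of(str(plan.code))
        clamped = Dataset(cohort.variables, records, cohort.mask)
        probs[:, c] = markov_blanket_scores(net, clamped, outcome)[:, k]
    return probs


def concordance(
    net: BayesNet,
    cohort: Dataset,
    candidates: Optional[Sequence[TreatmentPlan]] = None,
    treatment_var: str = "Treatment",
    outcome: str = "Survival",
    alive_state: str = "Alive",
    stage_var: str = "TNM",
    stage_groups: Optional[dict] = None,
) -> ConcordanceReport:
    """Compare recorded vs survival-maximising recommended plans per patient.

    Evidence per patient is every pre-treatment variable; the net must be
    mutilated at the treatment variable and should be parameterised on data
    excluding the cohort.  The cohort must contain no missing cells.
    """
    if (cohort.mask == 0).any():
        raise ValueError("cohort contains missing cells; run select_eligible first")
    if net.dag.parents(treatment_var):
        raise ValueError("net must be mutilated at the treatment variable first")
    candidates = sorted(candidates or curative_plans(), key=lambda p: p.code)
    stage_groups = stage_groups or STAGE_GROUPS
    probs = _recommend_matrix(net, cohort, candidates, treatment_var, outcome, alive_state)

    codes = np.array([p.code for p in candidates])
    best_p = probs.max(axis=1)
    is_tied = (best_p[:, None] - probs) <= _TIE_TOL
    # lowest code among tied maxima (candidates sorted ascending by code)
    rec_codes = codes[is_tied.argmax(axis=1)]
    n_ties = int((is_tied.sum(axis=1) > 1).sum())

    spec_t = cohort.spec(treatment_var)
    recorded_codes = np.array(
        [int(spec_t.states[i]) for i in cohort.column(treatment_var)]
    )
    all_codes = sorted(set(recorded_codes) | set(codes))
    confusion = pd.DataFrame(0, index=all_codes, columns=all_codes, dtype=int)
    levels = np.empty(cohort.n, dtype=object)
    for i in range(cohort.n):
        confusion.loc[recorded_codes[i], rec_codes[i]] += 1
        levels[i] = match_level(
            TREATMENT_PLANS[recorded_codes[i]], TREATMENT_PLANS[rec_codes[i]]
        )
    exact = levels == "exact"
    partial = levels == "partial"
    exact_rate = float(exact.mean())
    partial_or_exact = float((exact | partial).mean())

    by_treatment = pd.DataFrame(
        {
            code: {
                "n": int((recorded_codes == code).sum()),
                "exact": int((exact & (recorded_codes == code)).sum()),
                "partial": int((partial & (recorded_codes == code)).sum()),
                "none": int(
                    ((~exact & ~partial) & (recorded_codes == code)).sum()
                ),
            }
            for code in all_codes
        }
    ).T

    spec_s = cohort.spec(stage_var)
    stage_labels = np.array([spec_s.states[i] for i in cohort.column(stage_var)])
    rows = {}
    for group, stages in stage_groups.items():
        in_group = np.isin(stage_labels, stages)
        n_g = int(in_group.sum())
        rows[group] = {
            "n": n_g,
            "exact_rate": float(exact[in_group].mean()) if n_g else np.nan,
            "partial_or_exact_rate": float((exact | partial)[in_group].mean())
            if n_g
            else np.nan,
        }
    by_stage = pd.DataFrame(rows).T

    return ConcordanceReport(
        confusion, exact_rate, partial_or_exact, by_treatment, by_stage, cohort.n, n_ties
    )
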