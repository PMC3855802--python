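"""Treatment recommendation, eligibility filtering and concordance analysis."""

import itertools

import numpy as np
import pytest

from lungbn.data_model import BayesNet, Cpt, Dag, VariableSpec
from lungbn.inference import EvidenceSet, mutilate, posterior
from lungbn.intervention_analysis import (
    CURATIVE_CODES,
    SURGICAL_CODES,
    TREATMENT_PLANS,
    EligibilityConfig,
    concordance,
    curative_plans,
    joint_from_conditional,
    match_level,
    non_surgical_curative_plans,
    recommend,
    select_eligible,
)
from .conftest import make_dataset


class TestTreatmentPlans:
    def test_curative_flags(self):
        assert set(CURATIVE_CODES) == {1, 2, 3, 7, 8, 9, 10, 11}
        assert not TREATMENT_PLANS[5].curative
        assert not TREATMENT_PLANS[6].curative

    def test_surgical_codes_contain_surgery_modality(self):
        for code in SURGICAL_CODES:
            assert "surgery" in TREATMENT_PLANS[code].modalities
        for code in (2, 3, 7, 8):
            assert "surgery" not in TREATMENT_PLANS[code].modalities


class TestMatchLevel:
    def test_surgery_vs_surgery_plus_chemo_is_partial(self):
        assert match_level(TREATMENT_PLANS[1], TREATMENT_PLANS[11]) == "partial"

    def test_same_code_exact(self):
        assert match_level(TREATMENT_PLANS[2], TREATMENT_PLANS[2]) == "exact"

    def test_disjoint_modalities_none(self):
        assert match_level(TREATMENT_PLANS[2], TREATMENT_PLANS[3]) == "none"

    def test_full_curative_table_matches_set_intersection_oracle(self):
        for a, b in itertools.product(CURATIVE_CODES, CURATIVE_CODES):
            got = match_level(TREATMENT_PLANS[a], TREATMENT_PLANS[b])
            if a == b:
                want = "exact"
            elif TREATMENT_PLANS[a].modalities & TREATMENT_PLANS[b].modalities:
                want = "partial"
            else:
                want = "none"
            assert got == want


class TestJointFromConditional:
    def test_in_text_worked_example(self):
        assert joint_from_conditional(0.81, 0.02) == pytest.approx(0.016, abs=5e-4)

    def test_identity_and_zero(self):
        assert joint_from_conditional(0.37, 1.0) == 0.37
        assert joint_from_conditional(0.0, 0.9) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            joint_from_conditional(1.2, 0.5)


def _cohort_fixture():
    """20 rows: 5 bad diagnosis, 5 non-curative treatment, 5 with a missing
    cell, 5 fully eligible - all disjoint."""
    n = 20
    diag = np.zeros(n, dtype=int)
    diag[:5] = 2  # sentinel diagnosis
    treat = np.zeros(n, dtype=int)  # code "1"
    treat[5:10] = 2  # "5" palliative
    mask = np.ones((n, 3), dtype=int)
    stage = np.zeros(n, dtype=int)
    for i in range(10, 15):
        mask[i, 2] = 0
        stage[i] = 2  # TNM sentinel
    return make_dataset(
        {"Diagnosis": diag, "Treatment": treat, "TNM": stage},
        states={
            "Diagnosis": ("C34", "C33", "Unknown/Missing"),
            "Treatment": ("1", "2", "5"),
            "TNM": ("IA", "IV", "Unknown/Missing"),
        },
        mask=mask,
    )


class TestSelectEligible:
    def test_disjoint_violations_counted_per_filter(self):
        data = _cohort_fixture()
        out, counts = select_eligible(
            data, EligibilityConfig(diagnosis_var="Diagnosis", treatment_var="Treatment")
        )
        assert out.n == 5
        assert counts == {"diagnosis": 5, "non_curative_treatment": 5, "missing_data": 5}

    def test_clean_curative_table_is_identity(self):
        data = make_dataset(
            {"Diagnosis": [0, 0], "Treatment": [0, 1], "TNM": [0, 1]},
            states={
                "Diagnosis": ("C34", "C33"),
                "Treatment": ("1", "3"),
                "TNM": ("IA", "IV"),
            },
        )
        out, _ = select_eligible(data)
        assert out.n == 2

    def test_single_sentinel_cell_excludes_row(self):
        data = _cohort_fixture()
        out, _ = select_eligible(data)
        assert (out.mask == 1).all()


def _recommendation_net(bonus=None):
    """E -> S with parentless T feeding S; treatment effects set by `bonus`."""
    t_states = tuple(str(c) for c in CURATIVE_CODES)
    specs = {
        "E": VariableSpec("E", ("lo", "hi"), tier="pre_treatment"),
        "T": VariableSpec("T", t_states, tier="treatment"),
        "S": VariableSpec("S", ("Alive", "Dead"), tier="post_treatment"),
    }
    bonus = bonus or {c: 0.05 * i for i, c in enumerate(CURATIVE_CODES)}
    rows = []
    for e in (0, 1):
        for c in CURATIVE_CODES:
            p = min(0.9, 0.2 + 0.3 * e + bonus[c])
            rows.append([p, 1 - p])
    cpts = {
        "E": Cpt("E", (), (), np.array([[0.5, 0.5]]), 1.0),
        "T": Cpt("T", (), (), np.full((1, 8), 1 / 8), 1.0),
        "S": Cpt("S", ("E", "T"), (2, 8), np.array(rows), 1.0),
    }
    dag = Dag(["E", "T", "S"], [("E", "S"), ("T", "S")])
    return BayesNet(dag, cpts, specs)


class TestRecommend:
    def test_single_candidate_is_top(self):
        net = _recommendation_net()
        rec = recommend(net, {"E": "lo"}, [TREATMENT_PLANS[2]],
                        treatment_var="T", outcome="S")
        assert rec.top == 2 and not rec.tie

    def test_dominant_treatment_found_by_enumeration_oracle(self):
        bonus = {c: 0.02 * i for i, c in enumerate(CURATIVE_CODES)}
        bonus[9] = 0.45  # dominant
        net = _recommendation_net(bonus)
        # exhaustive interventional oracle over candidates
        want = max(
            CURATIVE_CODES,
            key=lambda c: posterior(net, {"E": "hi", "T": str(c)}, "S")[0],
        )
        rec = recommend(net, {"E": "hi"}, curative_plans(), treatment_var="T", outcome="S")
        assert rec.top == want == 9
        assert [c for c, _ in rec.ranking][0] == 9

    def test_dseparated_treatment_ties_flagged_lowest_code(self):
        bonus = {c: 0.0 for c in CURATIVE_CODES}
        net = _recommendation_net(bonus)
        rec = recommend(net, {"E": "lo"}, curative_plans(), treatment_var="T", outcome="S")
        assert rec.tie and rec.top == 1
        probs = [p for _, p in rec.ranking]
        assert max(probs) - min(probs) < 1e-12

    def test_unmutilated_net_rejected(self):
        specs = {
            "P": VariableSpec("P", ("0", "1")),
            "T": VariableSpec("T", ("1", "2")),
            "S": VariableSpec("S", ("Alive", "Dead")),
        }
        cpts = {
            "P": Cpt("P", (), (), np.array([[0.5, 0.5]]), 1.0),
            "T": Cpt("T", ("P",), (2,), np.array([[0.5, 0.5]] * 2), 1.0),
            "S": Cpt("S", ("T",), (2,), np.array([[0.5, 0.5]] * 2), 1.0),
        }
        net = BayesNet(Dag(["P", "T", "S"], [("P", "T"), ("T", "S")]), cpts, specs)
        with pytest.raises(ValueError):
            recommend(net, {}, [TREATMENT_PLANS[1]], treatment_var="T", outcome="S")


def _concordance_cohort(net, recorded):
    e = [0, 1] * 5
    t_states = net.specs["T"].states
    return make_dataset(
        {
            "E": e,
            "T": [t_states.index(str(c)) for c in recorded],
            "S": [0] * 10,
            "TNM": [0, 1, 2, 0, 1, 2, 0, 1, 2, 0],
        },
        states={
            "E": ("lo", "hi"),
            "T": t_states,
            "S": ("Alive", "Dead"),
            "TNM": ("IA", "IIIA", "IV"),
        },
        tiers={"E": "pre_treatment", "T": "treatment",
               "S": "post_treatment", "TNM": "pre_treatment"},
    )


class TestConcordance:
    def _net_with_tnm(self, bonus=None):
        net = _recommendation_net(bonus)
        specs = dict(net.specs)
        specs["TNM"] = VariableSpec("TNM", ("IA", "IIIA", "IV"), tier="pre_treatment")
        cpts = dict(net.cpts)
        cpts["TNM"] = Cpt("TNM", (), (), np.array([[0.4, 0.3, 0.3]]), 1.0)
        dag = Dag(["E", "T", "S", "TNM"], net.dag.edges)
        return BayesNet(dag, cpts, specs)

    def test_hand_enumerated_fixture(self):
        bonus = {c: 0.02 * i for i, c in enumerate(CURATIVE_CODES)}
        net = self._net_with_tnm(bonus)
        # recommendation is always code 11 (largest bonus) for every patient
        recorded = [1, 11, 2, 3, 11, 7, 8, 9, 10, 1]
        cohort = _concordance_cohort(net, recorded)
        rep = concordance(net, cohort, curative_plans(), treatment_var="T",
                          outcome="S", stage_var="TNM")
        assert rep.n == 10
        assert rep.confusion[11].sum() == 10  # every recommendation is 11
        # hand tally: exact on the two recorded 11s; partial whenever the
        # recorded plan shares a modality with 11 = {surgery, chemo}
        assert rep.exact_rate == pytest.approx(2 / 10)
        partial_codes = {1, 3, 7, 8, 9, 10}
        want_partial = sum(1 for c in recorded if c in partial_codes) / 10
        assert rep.partial_or_exact_rate == pytest.approx(2 / 10 + want_partial)
        assert rep.by_treatment.loc[2, "none"] == 1

    def test_restricting_candidates_zeroes_excluded_columns(self):
        net = self._net_with_tnm()
        recorded = [2, 3, 7, 8, 2, 3, 7, 8, 2, 3]
        cohort = _concordance_cohort(net, recorded)
        rep = concordance(net, cohort, non_surgical_curative_plans(),
                          treatment_var="T", outcome="S", stage_var="TNM")
        for code in SURGICAL_CODES:
            if code in rep.confusion.columns:
                assert rep.confusion[code].sum() == 0

    def test_rate_ordering_invariant(self):
        net = self._net_with_tnm()
        recorded = [1, 2, 3, 7, 8, 9, 10, 11, 1, 2]
        cohort = _concordance_cohort(net, recorded)
        rep = concordance(net, cohort, curative_plans(), treatment_var="T",
                          outcome="S", stage_var="TNM")
        assert 0.0 <= rep.exact_rate <= rep.partial_or_exact_rate <= 1.0
        assert rep.confusion.to_numpy().sum() == rep.n

    def test_stage_groups_partition_cohort(self):
        net = self._net_with_tnm()
        recorded = [1, 2, 3, 7, 8, 9, 10, 11, 1, 2]
        cohort = _concordance_cohort(net, recorded)
        rep = concordance(net, cohort, curative_plans(), treatment_var="T",
                          outcome="S", stage_var="TNM")
        assert rep.by_stage_group["n"].sum() == rep.n

    def test_missing_cells_rejected(self):
        net = self._net_with_tnm()
        recorded = [1, 2, 3, 7, 8, 9, 10, 11, 1, 2]
        cohort = _concordance_cohort(net, recorded)
        mask = cohort.mask.copy()
        # blank one evidence cell (E has no sentinel, so fake one via TNM spec)
        bad = make_dataset(
            {"E": [0], "T": [0], "S": [0], "TNM": [3]},
            states={"E": ("lo", "hi"), "T": net.specs["T"].states,
                    "S": ("Alive", "Dead"),
                    "TNM": ("IA", "IIIA", "IV", "Unknown/Missing")},
            mask=np.array([[1, 1, 1, 0]]),
        )
        with pytest.raises(ValueError):
            concordance(net, bad, curative_plans(), treatment_var="T",
                        outcome="S", stage_var="TNM")
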