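"""Synthetic lung-cancer cohorts from a configurable ground-truth network.

The real audit registry behind this kind of analysis is available only under
a data-sharing agreement, so every pipeline stage is exercised on cohorts
drawn from a hand-authored, tier-respecting ground-truth Bayesian network
over the 13 standard clinical variables.  The generator is calibrated to the
registry's published marginals — a 1-year survival rate of 0.33, the
treatment-plan frequency table, and ~32% overall missingness — while the
cross-variable dependence strengths are documented defaults (the registry
publishes no joint statistics).

Two deliberate design features shape downstream experiments:

* treatment assignment follows clinical *eligibility* (stage, performance
  status, lung function), not survival maximisation, so recommendation
  concordance has realistic structure to detect;
* cell deletion is informative (NMAR): the probability a pre-treatment value
  is missing rises with disease severity, which itself drives survival, so
  the missingness indicator pattern carries predictive signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import (
    MISSING_LABEL,
    BayesNet,
    Cpt,
    Dag,
    Dataset,
    VariableSpec,
)
from .inference import posterior

# -- the 13 variables -------------------------------------------------------

AGE_STATES = ("<50", "50-60", "60-70", "70-80", ">80")
STAGING_ID_STATES = ("6", "7")
FEV1_ABS_STATES = ("<1.0", "1-1.5", "1.5-2.0", ">2.0")
FEV1_PCT_STATES = ("<30", "30-40", "40-80", ">80")
PS_STATES = ("0", "1", "2", "3", "4")
COMORB_STATES = ("0", "1", "2", "3", "4", "5")
DIAGNOSIS_STATES = (
    "C33", "C34", "C34.0", "C34.1", "C34.2", "C34.3",
    "C34.8", "C34.9", "C38.4", "C38.3", "C38.8",
)
LATERALITY_STATES = ("Left", "Right", "Midline", "Bilateral", "Not Applicable")
TNM_STATES = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "Uncertain")
HISTOLOGY_STATES = (
    "M8010/2", "M8041/3", "M8046/3", "M8070/3", "M8140/3", "M8250/3",
    "M8012/3", "M8020/3", "M8013/3", "M8240", "M8980/3", "M8940/3", "M9999/9",
)
SITE_STAGING_STATES = ("Limited", "Extensive", "Unknown")
TREATMENT_STATES = ("1", "2", "3", "5", "6", "7", "8", "9", "10", "11", "Null")
SURVIVAL_STATES = ("Alive", "Dead")

#: small-cell histology codes (drive the limited/extensive site staging)
SCLC_HISTOLOGY = ("M8041/3", "M8012/3", "M8013/3")

#: published treatment-plan frequencies used as calibration targets
DEFAULT_TREATMENT_MARGINALS = {
    "1": 0.10, "2": 0.1479, "3": 0.19, "5": 0.23, "6": 0.09,
    "7": 0.07, "8": 0.01, "9": 0.0008, "10": 0.0013, "11": 0.02,
    "Null": 0.14,
}

PRE_TREATMENT = (
    "Age", "StagingID", "FEV1Abs", "FEV1Pct", "PerformanceStatus",
    "Comorbidities", "Diagnosis", "Laterality", "TNM", "Histology",
    "SiteStaging",
)


def default_variables():
    """The 13 VariableSpecs; pre-treatment variables carry the sentinel state
    (they are the ones the deletion mechanism may blank)."""
    base = [
        VariableSpec("Age", AGE_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("StagingID", STAGING_ID_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("FEV1Abs", FEV1_ABS_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("FEV1Pct", FEV1_PCT_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("PerformanceStatus", PS_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("Comorbidities", COMORB_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("Diagnosis", DIAGNOSIS_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("Laterality", LATERALITY_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("TNM", TNM_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("Histology", HISTOLOGY_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("SiteStaging", SITE_STAGING_STATES + (MISSING_LABEL,), True, "pre_treatment"),
        VariableSpec("Treatment", TREATMENT_STATES, False, "treatment"),
        VariableSpec("Survival", SURVIVAL_STATES, False, "post_treatment"),
    ]
    return base


def default_truth_dag() -> Dag:
    """Tier-respecting generating structure: pre-treatment dependencies feed
    Treatment, and Treatment plus direct pre-treatment drivers feed Survival."""
    names = [v.name for v in default_variables()]
    edges = [
        ("Histology", "Diagnosis"),
        ("Histology", "SiteStaging"),
        ("Histology", "TNM"),
        ("Diagnosis", "Laterality"),
        ("Age", "Comorbidities"),
        ("Age", "PerformanceStatus"),
        ("Age", "FEV1Abs"),
        ("FEV1Abs", "FEV1Pct"),
        ("TNM", "PerformanceStatus"),
        ("TNM", "Treatment"),
        ("PerformanceStatus", "Treatment"),
        ("FEV1Pct", "Treatment"),
        ("Treatment", "Survival"),
        ("TNM", "Survival"),
        ("PerformanceStatus", "Survival"),
    ]
    return Dag(names, edges)


def misspecified_manual_dag() -> Dag:
    """A clinician-plausible but wrong variant of the truth DAG with four
    edges rewired (four informative edges deleted, four spurious
    tier-respecting edges added).  Plays the role of a hand-elicited
    structure that misses dependencies present in the data."""
    truth = default_truth_dag()
    removed = {
        ("TNM", "Survival"),
        ("PerformanceStatus", "Treatment"),
        ("Histology", "TNM"),
        ("FEV1Abs", "FEV1Pct"),
    }
    added = {
        ("Laterality", "Survival"),
        ("StagingID", "Treatment"),
        ("Age", "Diagnosis"),
        ("Comorbidities", "FEV1Pct"),
    }
    return Dag(truth.variables, (set(truth.edges) - removed) | added)


#: per-state severity proxies on [0, 1] (sentinel mid-scale)
TNM_SEVERITY = np.array([0.0, 1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6, 1.0, 0.5, 0.5])
PS_SEVERITY = np.array([0.0, 0.25, 0.5, 0.75, 1.0, 0.5])


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic registry.

    Defaults are the published registry figures: survival marginal 0.33,
    treatment-plan frequencies (with a 14% null-treatment mass), 32%
    missingness.  ``nmar_strength`` is the log-odds span of the severity-
    driven deletion mechanism; 0 reduces it to MCAR.
    """

    cpt_seed: int = 7
    sample_seed: int = 11
    survival_target: float = 0.33
    treatment_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_MARGINALS)
    )
    missing_rate_target: float = 0.32
    nmar_strength: float = 5.0
    truth_dag: Optional[Dag] = None
    max_calibration_iter: int = 500

    def __post_init__(self):
        total = sum(self.treatment_marginals.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"treatment marginals sum to {total}, not 1")
        for t in (self.survival_target, self.missing_rate_target):
            if not (0.0 < t < 1.0):
                raise ValueError("targets must be in (0, 1)")
        if self.nmar_strength < 0:
            raise ValueError("nmar_strength must be >= 0")


# -- CPT construction helpers ----------------------------------------------

def _pad_sentinel(table: np.ndarray, spec: VariableSpec) -> np.ndarray:
    """Append a zero-probability sentinel column (the truth net never emits
    missing values; deletion happens afterwards)."""
    if not spec.has_missing_state:
        return table
    return np.hstack([table, np.zeros((table.shape[0], 1))])


def _rows_with_sentinel_parents(parent_specs):
    """Boolean flat-row mask of parent configurations involving a sentinel
    parent state; those rows are unreachable and set uniform."""
    cards = [s.n_states for s in parent_specs]
    grids = np.meshgrid(*[np.arange(c) for c in cards], indexing="ij")
    flag = np.zeros(grids[0].shape, dtype=bool)
    for g, s in zip(grids, parent_specs):
        if s.has_missing_state:
            flag |= g == s.missing_index
    return flag.reshape(-1)


def _finish_cpt(child_spec, parent_specs, core: np.ndarray) -> np.ndarray:
    """Combine a core table over non-sentinel child states with sentinel
    padding and uniform unreachable rows."""
    table = _pad_sentinel(core / core.sum(axis=1, keepdims=True), child_spec)
    if parent_specs:
        bad = _rows_with_sentinel_parents(parent_specs)
        table[bad] = 1.0 / child_spec.n_states
    return table


def _bell(centre: float, k: int, width: float = 1.15) -> np.ndarray:
    """Unnormalised discretised bell over k ordered categories."""
    idx = np.arange(k)
    return np.exp(-((idx - centre) ** 2) / width)


def build_truth_net(cfg: Optional[GeneratorConfig] = None) -> BayesNet:
    """Construct and calibrate the ground-truth network.

    CPTs are built from structured effect models (severity-driven performance
    status, eligibility-driven treatment assignment, treatment- and
    stage-driven survival) with seeded jitter, then calibrated by iterative
    proportional scaling until the exact survival marginal is within 0.005 of
    target and every treatment-state marginal within 0.01.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.cpt_seed)
    specs = {s.name: s for s in default_variables()}
    dag = cfg.truth_dag or default_truth_dag()
    order = [s.name for s in default_variables()]
    cpts = {}

    def spec_of(names):
        return [specs[n] for n in names]

    def jitter(shape, scale=0.12):
        return np.exp(rng.normal(0.0, scale, shape))

    # roots
    age = np.array([0.05, 0.13, 0.27, 0.33, 0.22]) * jitter(5, 0.05)
    cpts["Age"] = _finish_cpt(specs["Age"], [], age[None, :])
    sid = np.array([0.45, 0.55]) * jitter(2, 0.05)
    cpts["StagingID"] = _finish_cpt(specs["StagingID"], [], sid[None, :])
    hist_base = np.array(
        [0.05, 0.12, 0.04, 0.20, 0.18, 0.04, 0.06, 0.05, 0.04, 0.02, 0.02, 0.03, 0.15]
    )
    cpts["Histology"] = _finish_cpt(specs["Histology"], [], (hist_base * jitter(13, 0.2))[None, :])

    # pre-treatment conditionals (parents in lexicographic order, matching Dag.parents)
    n_hist = specs["Histology"].n_states  # includes sentinel row
    diag = rng.dirichlet(np.full(11, 0.6), size=n_hist)
    cpts["Diagnosis"] = _finish_cpt(specs["Diagnosis"], spec_of(["Histology"]), diag)

    sclc = np.array([s in SCLC_HISTOLOGY for s in HISTOLOGY_STATES] + [False])
    site = np.where(
        sclc[:, None], np.array([0.50, 0.40, 0.10]), np.array([0.05, 0.05, 0.90])
    ) * jitter((n_hist, 3), 0.1)
    cpts["SiteStaging"] = _finish_cpt(specs["SiteStaging"], spec_of(["Histology"]), site)

    tnm_base = np.array([0.08, 0.06, 0.06, 0.08, 0.14, 0.16, 0.36, 0.06])
    tnm = tnm_base[None, :] * jitter((n_hist, 8), 0.35)
    cpts["TNM"] = _finish_cpt(specs["TNM"], spec_of(["Histology"]), tnm)

    n_diag = specs["Diagnosis"].n_states
    lat = rng.dirichlet(np.array([0.35, 0.35, 0.08, 0.07, 0.15]) * 8.0, size=n_diag)
    cpts["Laterality"] = _finish_cpt(specs["Laterality"], spec_of(["Diagnosis"]), lat)

    n_age = specs["Age"].n_states
    comorb = np.vstack(
        [
            np.exp(-0.5 * (np.arange(6) - (0.5 + 0.5 * a)) ** 2 / 1.2)
            for a in range(n_age)
        ]
    ) * jitter((n_age, 6), 0.08)
    cpts["Comorbidities"] = _finish_cpt(specs["Comorbidities"], spec_of(["Age"]), comorb)

    fev_abs = np.vstack([_bell(2.6 - 0.45 * a, 4) for a in range(n_age)]) * jitter(
        (n_age, 4), 0.08
    )
    cpts["FEV1Abs"] = _finish_cpt(specs["FEV1Abs"], spec_of(["Age"]), fev_abs)

    n_fa = specs["FEV1Abs"].n_states
    fev_pct = np.vstack([_bell(0.35 + 0.85 * k, 4, 0.8) for k in range(n_fa)]) * jitter(
        (n_fa, 4), 0.08
    )
    cpts["FEV1Pct"] = _finish_cpt(specs["FEV1Pct"], spec_of(["FEV1Abs"]), fev_pct)

    # PerformanceStatus | Age, TNM  (lexicographic parent order: Age, TNM)
    n_tnm = specs["TNM"].n_states
    ps_rows = []
    for a in range(n_age):
        for t in range(n_tnm):
            mu = 0.35 * a + 2.4 * TNM_SEVERITY[t]
            ps_rows.append(_bell(mu, 5, 1.3))
    ps = np.vstack(ps_rows) * jitter((n_age * n_tnm, 5), 0.08)
    cpts["PerformanceStatus"] = _finish_cpt(
        specs["PerformanceStatus"], spec_of(["Age", "TNM"]), ps
    )

    # Treatment | FEV1Pct, PerformanceStatus, TNM (lexicographic order)
    targets = np.array([cfg.treatment_marginals[s] for s in TREATMENT_STATES])
    n_fp, n_ps = specs["FEV1Pct"].n_states, specs["PerformanceStatus"].n_states
    surgical = np.array([s in ("1", "9", "10", "11") for s in TREATMENT_STATES])
    rows = []
    for f in range(n_fp):
        fev_ok = 1.0 if (f in (2, 3)) else 0.0
        for p in range(n_ps):
            for t in range(n_tnm):
                sev, psv = TNM_SEVERITY[t], PS_SEVERITY[p]
                fit = (1.0 - sev) * (1.0 - psv)
                mid = 1.0 - 2.0 * abs(sev - 0.5)
                logit = np.log(np.maximum(targets, 1e-4)).copy()
                logit[surgical] += 2.2 * fit + 0.8 * fev_ok - 1.2
                logit[TREATMENT_STATES.index("2")] += 0.6 * sev
                logit[TREATMENT_STATES.index("3")] += 0.3 + 0.5 * sev
                logit[TREATMENT_STATES.index("7")] += 0.8 * mid
                logit[TREATMENT_STATES.index("8")] += 0.8 * mid
                logit[TREATMENT_STATES.index("5")] += 2.5 * sev + 1.2 * psv - 1.0
                logit[TREATMENT_STATES.index("6")] += 0.8 * (1.0 - sev)
                rows.append(np.exp(logit))
    treat = np.vstack(rows) * jitter((n_fp * n_ps * n_tnm, 11), 0.08)
    cpts["Treatment"] = _finish_cpt(
        specs["Treatment"], spec_of(["FEV1Pct", "PerformanceStatus", "TNM"]), treat
    )

    # Survival | PerformanceStatus, TNM, Treatment (lexicographic order)
    bonus = {
        "1": 1.10, "9": 1.25, "10": 1.25, "11": 1.30,
        "7": 0.65, "8": 0.60, "2": 0.30, "3": 0.35,
        "5": -0.90, "6": -0.20, "Null": -0.50,
    }
    n_tr = specs["Treatment"].n_states
    surv_rows = []
    for p in range(n_ps):
        for t in range(n_tnm):
            for k in range(n_tr):
                z = (
                    1.1
                    - 2.8 * TNM_SEVERITY[t]
                    - 1.1 * PS_SEVERITY[p]
                    + bonus[TREATMENT_STATES[k]]
                    + rng.normal(0.0, 0.05)
                )
                alive = 1.0 / (1.0 + np.exp(-z))
                surv_rows.append([alive, 1.0 - alive])
    surv = np.asarray(surv_rows)
    cpts["Survival"] = _finish_cpt(
        specs["Survival"], spec_of(["PerformanceStatus", "TNM", "Treatment"]), surv
    )

    # a custom truth_dag may alter families; such families get seeded
    # Dirichlet tables (the structural properties under test do not depend
    # on the particular conditionals)
    default_dag = default_truth_dag()
    rng2 = np.random.default_rng(cfg.cpt_seed + 1)
    for v in order:
        if dag.parents(v) != default_dag.parents(v):
            parent_specs = spec_of(dag.parents(v))
            q = int(np.prod([s.n_states for s in parent_specs])) if parent_specs else 1
            r = len(specs[v].states) - (1 if specs[v].has_missing_state else 0)
            core = rng2.dirichlet(np.full(r, 0.8), size=q)
            cpts[v] = _finish_cpt(specs[v], parent_specs, core)

    def assemble():
        built = {
            v: Cpt(
                v,
                dag.parents(v),
                tuple(specs[p].n_states for p in dag.parents(v)),
                cpts[v],
                1.0,
            )
            for v in order
        }
        return BayesNet(Dag(order, dag.edges), built, specs)

    cpts = {v: np.asarray(t, dtype=float) for v, t in cpts.items()}

    # -- calibration: treatment marginals first (upstream of survival) ------
    if set(cfg.treatment_marginals) != set(TREATMENT_STATES):
        raise ValueError("treatment_marginals must cover exactly the treatment states")
    converged_t = converged_s = False
    for _ in range(cfg.max_calibration_iter):
        net = assemble()
        marg = posterior(net, {}, "Treatment")
        err = np.abs(marg - targets)
        if err.max() < 0.002:
            converged_t = True
            break
        factor = np.clip(targets / np.maximum(marg, 1e-12), 0.2, 5.0)
        table = cpts["Treatment"] * factor[None, :]
        cpts["Treatment"] = table / table.sum(axis=1, keepdims=True)
    for _ in range(cfg.max_calibration_iter):
        net = assemble()
        alive = float(posterior(net, {}, "Survival")[0])
        if abs(alive - cfg.survival_target) < 0.001:
            converged_s = True
            break
        factor = np.clip(cfg.survival_target / max(alive, 1e-12), 0.2, 5.0)
        table = cpts["Survival"].copy()
        table[:, 0] *= factor
        cpts["Survival"] = table / table.sum(axis=1, keepdims=True)
    net = assemble()
    if not (converged_t and converged_s):
        marg = posterior(net, {}, "Treatment")
        alive = float(posterior(net, {}, "Survival")[0])
        raise RuntimeError(
            "calibration did not converge: "
            f"P(Alive)={alive:.4f}, max treatment error={np.abs(marg - targets).max():.4f}"
        )
    return net


# -- sampling ---------------------------------------------------------------

def sample_cohort(net: BayesNet, n: int, seed: int) -> Dataset:
    """Draw n complete records by ancestral sampling; deterministic by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order_all = list(net.dag.variables)
    topo = net.dag.topological_order()
    cols = {}
    for v in topo:
        cpt = net.cpts[v]
        if cpt.parents:
            rows = np.ravel_multi_index(
                tuple(cols[p] for p in cpt.parents), cpt.parent_cards
            )
        else:
            rows = np.zeros(n, dtype=np.int64)
        cdf = np.cumsum(cpt.table, axis=1)
        u = rng.random(n)
        cols[v] = (u[:, None] > cdf[rows]).sum(axis=1).astype(np.int64)
    records = np.column_stack([cols[v] for v in order_all])
    return Dataset([net.specs[v] for v in order_all], records)


# -- informative missingness ------------------------------------------------

def _severity(data: Dataset) -> np.ndarray:
    tnm = TNM_SEVERITY[data.column("TNM")]
    ps = PS_SEVERITY[data.column("PerformanceStatus")]
    return 0.65 * tnm + 0.35 * ps


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def apply_nmar(data: Dataset, cfg: Optional[GeneratorConfig] = None, seed: int = 0) -> Dataset:
    """Delete pre-treatment cells with probability that rises with the
    record's latent severity (TNM stage and performance status), calibrated
    so the expected deleted fraction over deletable cells equals the target.
    Treatment and outcome columns are never deleted.  MCAR at strength 0.
    """
    cfg = cfg or GeneratorConfig()
    if (data.mask == 0).any():
        raise ValueError("apply_nmar expects a complete dataset")
    sev = _severity(data)
    b = cfg.nmar_strength

    def mean_rate(a):
        return float(np.mean(_sigmoid(a + b * (sev - 0.5))))

    lo, hi = -30.0, 30.0
    if not (mean_rate(lo) <= cfg.missing_rate_target <= mean_rate(hi)):
        raise RuntimeError("missing-rate target infeasible under the mechanism")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < cfg.missing_rate_target:
            lo = mid
        else:
            hi = mid
    p_row = _sigmoid(0.5 * (lo + hi) + b * (sev - 0.5))

    rng = np.random.default_rng(seed)
    records = data.records.copy()
    mask = data.mask.copy()
    del_cols = [data.index(v) for v in PRE_TREATMENT]
    hits = rng.random((data.n, len(del_cols))) < p_row[:, None]
    for k, j in enumerate(del_cols):
        spec = data.variables[j]
        col_hits = hits[:, k]
        records[col_hits, j] = spec.missing_index
        mask[col_hits, j] = 0
    return Dataset(data.variables, records, mask)


def missing_fraction(data: Dataset) -> float:
    """Fraction of deletable (pre-treatment) cells that are missing."""
    cols = [data.index(v) for v in PRE_TREATMENT]
    return float((data.mask[:, cols] == 0).mean())


# -- small demonstration net for structure-recovery tests -------------------

def five_variable_demo_net() -> BayesNet:
    """A 5-binary-variable net (A→B, A→C, {B,C}→D, D→E) with solid effect
    sizes, used to check that score search recovers a known edge set."""
    names = ["A", "B", "C", "D", "E"]
    specs = {n: VariableSpec(n, ("0", "1"), False, "pre_treatment") for n in names}
    dag = Dag(names, [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")])
    tables = {
        "A": np.array([[0.6, 0.4]]),
        "B": np.array([[0.8, 0.2], [0.25, 0.75]]),
        "C": np.array([[0.7, 0.3], [0.2, 0.8]]),
        "D": np.array([[0.9, 0.1], [0.6, 0.4], [0.35, 0.65], [0.08, 0.92]]),
        "E": np.array([[0.75, 0.25], [0.3, 0.7]]),
    }
    cpts = {
        v: Cpt(v, dag.parents(v), tuple(2 for _ in dag.parents(v)), tables[v], 1.0)
        for v in names
    }
    return BayesNet(dag, cpts, specs)
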