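# Methods

## The model

All thirteen variables are categorical; the joint distribution is a discrete
Bayesian network `P(x) = Π_i P(x_i | pa_i(G))`. CPTs are estimated by
smoothed maximum likelihood under a uniform Dirichlet prior with pseudocount
α = 1 per cell (exposed as a parameter everywhere; no equivalent-sample-size
convention is imposed). A row whose parent configuration never occurs in the
training data therefore reduces to the uniform distribution.

Missingness is modelled explicitly, not imputed: a sentinel category
`"Unknown/Missing"` is appended to a variable's state space and participates
in counting, scoring, inference and prediction as an ordinary state. This is
the appropriate treatment when missingness is informative (NMAR), which the
missingness-indicator experiment (below) is designed to detect; EM and
multiple imputation are deliberately out of scope because their validity
rests on the MAR assumption.

## Structure score

Structures are compared by the decomposable K2 (Cooper–Herskovits) marginal
likelihood; per node *i* with r_i states and parent configurations *j*,

    Σ_j [ log Γ(r_i) − log Γ(N_ij + r_i) + Σ_k log Γ(N_ijk + 1) ]

plus a log structure prior (zero, i.e. uniform, unless the expert-knowledge
prior is in use). All arithmetic is in log-gamma space; an exact
integer-factorial evaluation exists only as a test oracle (overflow begins
around n ≈ 10⁵ otherwise). One property worth knowing: this score is *not*
direction-symmetric in general (it is not a BDeu-style score-equivalent
metric). For two variables, score(A→B) − score(B→A) depends on the marginal
count vectors; the directions tie exactly when those marginals coincide, and
the test suite asserts the symmetry only in that case.

## Structure learning

* **TAN** — class node parents every predictor; predictors form the maximum
  spanning tree under conditional mutual information I(X_i; X_j | class),
  oriented outward from the lexicographically first predictor.
* **K2** — greedy parent addition per node from its predecessors in a
  supplied total order, accepting the best single improvement until none
  remains or `max_parents` (default 4, bounding CPT size given arities up to
  13) is reached.
* **Simulated annealing** — add/delete/reverse moves preserving acyclicity,
  Metropolis acceptance on Δ(log score + log prior), geometric cooling
  (factor 0.99 per sweep, 200 sweeps by default, one sweep = p(p−1)
  proposals). The initial temperature is auto-calibrated so that a typical
  score-decreasing move is accepted with probability ≈ ½. The best structure
  seen is returned, so the result never scores below the empty start graph.
* **MCMC** — the same move kernel at unit temperature; the
  highest-posterior structure visited is returned, and post-burn-in edge
  visit frequencies are available. The proposal is uniform over the move
  lattice without a neighbourhood-size Hastings correction; the quantities
  used downstream (best-visited structure, seeded reproducibility) do not
  depend on exact stationarity of the chain.
* **Constraint-based (PC/IC-style)** — skeleton by G² conditional-
  independence tests with conditioning sets grown from the adjacency
  structure (a test is skipped, keeping the edge and warning, when
  n < 10·df); collider orientation from separating sets; Meek rules 1–3;
  remaining undirected edges oriented by temporal tier, then
  lexicographically, with acyclicity enforced.
* **Knowledge-constrained search** — annealing on log P(D|G) + log P(G).
  Temporal tiers at confidence 1.0 make later-tier → earlier-tier edges
  hard-forbidden (moves proposing them are rejected outright, so the output
  provably contains zero violations). A pairwise relation at confidence
  c < 1 adds log(c/(1−c)) when satisfied: "A precedes B" is satisfied by the
  absence of B→A, "A related to B" by adjacency in either direction,
  "A influences B" by the A→B edge. Hard presence constraints are seeded
  into the initial graph and locked. The default hyperparameters
  (sweeps, cooling, chain length 50,000 with 10,000 burn-in) are exposed in
  `SearchConfig`; every stochastic search is deterministic given its seed.

Cross-validation DAGs are merged into a final structure by weighting each
directed edge with its fold frequency and extracting the maximum-weight
directed branching (Chu–Liu/Edmonds). This guarantees acyclicity, resolves
direction conflicts by majority, and handles forests; edge weights by raw
fold frequency is a deliberate simplicity choice (score-weighted variants
were considered and rejected).

## Inference and causal intervention

Posterior queries run exact sum-product variable elimination (hidden
variables eliminated smallest-cardinality first). With 13 small-arity
variables exactness is cheap; any exact backend (junction tree included)
would produce identical numbers, which is the contract the oracle tests pin
(agreement with full-joint enumeration to 1e-10). Evidence with zero
probability raises rather than returning NaN, surfacing state/schema
mismatches early.

An intervention do(T = t) cuts every edge into the treatment node, replaces
its CPT by a parent-free marginal — re-learned from the designated training
data in the recommendation pipeline, or computed exactly from the net
otherwise — and then clamps T as evidence. Clamping after mutilation and
summing a degenerate CPT are equivalent; the truncated-factorisation oracle
in the tests verifies the implementation against the definition. Mutilation
is idempotent, and for a parentless treatment interventional and
observational conditioning coincide (also tested).

For the cross-validated survival predictions every non-outcome variable is
used as evidence (sentinel states included — they are genuine observations
under explicit-missingness modelling; the recorded treatment is included by
default with a flag to exclude it). Since evidence is then complete, the
posterior reduces to the Markov-blanket closed form, which is evaluated
vectorised over all records; a generic per-record elimination path covers
the evidence-exclusion flag. Accuracy uses a fixed 0.5 posterior threshold.

## Recommendation and concordance

Eligible cohort: study diagnosis, curative recorded plan (palliative care
and active monitoring are the non-curative codes), and a fully observed
record. The recommended plan is argmax over the candidate set of
P(Survival = Alive | pre-treatment evidence, do(T = t)) on a network
re-parameterised on data excluding the cohort. Ties within 1e-9 are flagged
and broken toward the lower plan code, making results deterministic (the two
chemo-radiotherapy plans are frequent near-ties). Partial concordance is
formalised as non-empty intersection of modality sets (surgery / chemo /
radio / palliative / monitoring); the full curative match table is asserted
against an independent set-intersection enumeration in the tests. TNM stage
strata: early IA–IIB, locally advanced IIIA–IIIB, advanced IV, with
"Uncertain" its own stratum (boundaries overridable).

## The synthetic registry

The generator emulates the registry conditions the pipeline was designed
for; its defaults are study conditions, not tuning knobs:

* 13 variables with the registry state spaces; the 11 pre-treatment
  variables carry the sentinel state.
* A hand-authored tier-respecting truth DAG (pre-treatment dependencies →
  treatment → survival, plus direct TNM and performance-status → survival
  edges). The real registry's dependence structure is unknowable; this shape
  is what the pipeline must be able to recover and exploit.
* Structured CPTs: performance status worsens with age and stage; treatment
  assignment follows clinical *eligibility* (early stage, good performance
  status and lung function favour surgical codes; advanced disease favours
  palliation) — deliberately not survival maximisation, so concordance
  analysis has a realistic discrepancy to detect; survival follows a
  logistic severity model in which surgery-containing plans carry the
  largest conditional benefit. Cross-variable effect sizes are documented
  defaults, not estimates: the registry publishes only marginals.
* Calibration by iterative proportional scaling against *exact* marginals
  (variable elimination, not sampling): treatment-plan frequencies to the
  published table (including the 14% null-treatment mass, which exercises
  the filtering path) within 0.002 each, then the survival marginal to 0.33
  within 0.001; treatment is upstream of survival so the two loops do not
  interact. Bounded at 500 iterations, with achieved marginals reported on
  failure. Deterministic given `cpt_seed`.
* NMAR deletion: each pre-treatment cell of a record is deleted with
  probability sigmoid(a + s·(severity − ½)), severity being a fixed convex
  combination of TNM stage (weight 0.65) and performance status (0.35)
  mapped to [0, 1]. The intercept *a* is solved by bisection so the expected
  deleted fraction equals the 32% target; the default strength s = 5 yields
  indicator-matrix AUCs near 0.7, the scale of informativeness reported for
  real audit data. s = 0 reduces to MCAR at the same rate. Outcome and
  treatment columns are never deleted.

What passing tests on this generator do and do not show: they verify the
*machinery* (scores, inference, search, harness) exactly, and the
*phenomena* (manual-vs-learned ranking, informative missingness, low exact /
higher partial concordance, surgical bias) qualitatively. They cannot
certify performance numbers on the real registry, whose dependence
strengths, unobserved confounding and coding artefacts the generator does
not model. Real-data headline metrics are therefore explicitly not
reproduction targets.

## Numerical and design notes

* Discretisation intervals are left-closed/right-open ([50, 60) → "50-60");
  the published tables do not state a boundary convention, and this one is
  standard and testable. Boundary handling for lung-function fields follows
  the same rule.
* Parameter-recovery checks on the 13-variable net are restricted to parent
  rows with at least 500 observations and use a 4σ binomial band plus the
  smoothing bias r/N: rare configurations (e.g. treatments with 0.08%
  marginal mass) cannot be estimated to fixed absolute precision at any
  desk-scale n.
* Tie-breaks are lexicographic throughout (K2 candidate parents, PC edge
  orientation, branching construction), making every deterministic algorithm
  reproducible bit-for-bit.
* Test problem sizes (cohorts of 20,000, 100 random nets up to 8 variables,
  100 seeded constrained-search runs at reduced sweep counts) were chosen so
  the full suite completes in seconds while keeping every statistical
  assertion comfortably inside its noise bounds.

## Known limitations

Five-year survival, decision-network utility analysis (quality of life,
cost), suitability-for-surgery modelling, approximate inference, counterfactual
(twin-network) queries, and MML-metric hybrid search are out of scope. The
expert-knowledge prior replaces the MML machinery of hybrid causal discovery
with a Bayesian-score search under the same kinds of constraints; claims
about prior-constrained versus unconstrained learning carry over, claims
about the MML metric itself do not.
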