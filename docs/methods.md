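# Methods

## Model and assumptions

The analysis operates on constraint-based metabolic models: a
stoichiometric matrix **S** (metabolites × reactions), flux bounds, a
designated biomass objective, boolean GPR rules, subsystem labels and
compartment assignments.  Everything is steady state — `S v = 0` — so
the package predicts attainable flux *capability*, never kinetics,
concentrations or time courses.  Accumulation predictions are therefore
qualitative: "all routes that could drain this metabolite are gone", not
"its concentration rises at rate x".

Sign convention: negative stoichiometric coefficient = consumed at
positive flux.  Bounds are finite; an explicit infinity in input is
stored as the conventional ±1000 proxy so every LP stays bounded.
SBML input must be Level 3 with FBC v2 and explicit flux-bound
parameters; Level 2 files and bound-less reactions are rejected rather
than guessed at, because silently invented bounds corrupt every FVA
range downstream.  Subsystems are read from SBML groups, defaulting to
`"unassigned"`.

## Knockout semantics

A single-gene deletion sets the gene's GPR leaves to false and disables
(pins to `[0, 0]`) every reaction whose rule evaluates false.  `and`
models enzyme complexes, `or` isozymes; `and` binds tighter than `or`;
a reaction with no GPR can never be disabled.  Only complete single-gene
loss is modelled — no partial activity, no double deletions.

## FBA / FVA

FBA maximizes `v_obj`; FVA minimizes and maximizes each reaction's flux
under the extra floor `v_obj ≥ fraction · Z_opt`.  The KO FVA uses the
KO model's own re-derived optimum, the standard convention (for a purely
catabolic knockout the two optima coincide anyway).  The fraction is the
decimal of the printed percentage (90% → 0.9).

Solver: HiGHS via `scipy.optimize.linprog`.  Primal feasibility
tolerance 1e-9 by default.  Each FVA endpoint is an independent LP
(2·N per model); constraint order is fixed by the model, nothing is
randomized, and repeated runs are identical.  Endpoints are `NaN` (with
a logged warning) if an individual LP fails; the run continues.

## Δrange and classification

`Δrange = |max_KO − max_WT| + |min_KO − min_WT|` per reaction.  Absolute
values on both terms prevent opposite-signed endpoint shifts from
cancelling, and make the statistic symmetric in which model is labelled
WT.  Significance threshold: 1.0 flux units by default (configurable);
it sits in the gap of the strongly bimodal Δrange distribution that
knockouts of gated branches produce — near-zero solver jitter versus
wholesale range collapse.

Noise handling is deterministic and documented rather than judgmental:
every above-threshold record is re-solved with the solver tolerance
tightened to 1e-10; if the recomputed Δrange falls to or below the
threshold the original excess is attributed to numerical noise,
otherwise the reaction is affected.  The originally computed Δrange
stays on the record, so `unchanged ⇔ Δrange ≤ threshold` holds exactly.

## Sensitivity sweeps

Capacity curves evaluate the FVA maximum of a reaction over a fraction
grid (default `{1.0, 0.9, 0.75, 0.5}`).  Because the feasible regions
are nested in the fraction, curves must be non-increasing; the
`CapacityCurve` constructor enforces this (tolerance 1e-6) so a solver
failure cannot masquerade as a result.  Robustness sweeps re-run the
entire knockout pipeline per fraction and report *set identity* of the
affected sets (plus symmetric differences), not just equal counts.

Note a detectability edge: a blocked branch is only visible at fractions
where its wild-type capacity exceeds the significance threshold.  On the
synthetic networks this bound is analytic
(`GroundTruth.max_detectable_fraction`).

## Reporter metabolites

"Active" and "blocked" are defined on FVA ranges at the analysis
fraction with tolerance 1e-6: a reaction can consume a metabolite if its
coefficient is negative and the range admits flux above +1e-6, or
positive with flux below −1e-6 (reversible reactions count by attainable
direction, not nominal direction).  A candidate's consumers are taken
from the *wild-type* ranges; all of them must have KO ranges entirely
within ±1e-6.  Candidates are labelled by compartment and by the
majority subsystem of their consumers (ties → `"other"`).  The scanned
universe defaults to metabolites participating in affected reactions,
with an `all_metabolites` option; on networks where the blockade is
localized the two scopes coincide.

## Synthetic networks and what they do (not) show

The generator builds the situation the analysis assumes, at toy scale:
a biomass objective drawing on a shared bounded resource
(`resource_budget`, default 10; `biomass_yield` resource units per unit
growth, default 1), and a catabolic chain of `n_intermediates + 1` steps
(default 5) whose first `chain_length` steps (default 3, mirroring a
three-reaction desulfation block) are gated by one gene and jointly
consume `degradation_cost` resource units per unit branch flux (default
1).  Chain intermediates live in the lysosome compartment; optional
decoy nutrient pairs pad the network; an optional bypass consumer keeps
the polymer drainable in the knockout.  The random seed shuffles
presentation order and decoy bounds only — ground truth is analytic and
seed-independent:

* WT biomass optimum `resource_budget / biomass_yield`;
* branch capacity `resource_budget · (1 − fraction) / degradation_cost`;
* knockout growth change exactly 0;
* affected set = chain steps (+ the polymer source when no bypass);
* accumulating set = chain intermediates (+ the polymer when no bypass).

The shared-resource construction makes capacity *linear* in
(1 − fraction), chosen so the oracle stays exact; real genome-scale
networks show saturating curves instead.  The properties being tested —
zero capacity at full optimality, monotone growth of capacity as the
constraint relaxes, locality and completeness of the blockade, exact
reporter recovery — hold in both regimes, but passing tests on these
toys says nothing about medium composition, pathway redundancy or
degree-distribution effects in a real reconstruction.

## Problem sizes and numerical choices

Unit and acceptance tests run on networks of ~5–25 reactions; the
randomized-recovery suite uses 20 generated networks analysed at
fraction 0.5 (where branch capacity comfortably exceeds the threshold
for the sampled parameter ranges: budget 5–50, cost 0.5–2).  The
brute-force FVA oracle enumerates polytope vertices on ≤ 6-reaction
integer-bound networks and is solver-independent; agreement is required
to 1e-6.  An independent cross-check against the COBRA toolbox's FVA
(GLPK backend) runs on one generated network.  Genome-scale inputs are
supported by the same code path (2·N LPs per model per fraction) but are
not exercised in the test suite.

Tie-breaks and degenerate inputs: FVA endpoints that cross by solver
jitter are re-ordered; `-0.0` is normalized to `0.0`; a gene absent from
all GPRs yields a warning and an identity knockout; an empty GPR rule is
always active; `capacity_loss_percent` of a zero-capacity wild-type
range is defined as 0.

## Known limitations

* Steady-state only; no kinetics, no substrate accumulation dynamics.
* No loopless/thermodynamic FVA, no parsimonious FBA.
* Single-gene, complete-loss knockouts only.
* The noise-retest rule is a deterministic surrogate for what is, in
  practice, often a manual judgment; counts of noise-excluded reactions
  on large reconstructions can be solver- and tolerance-dependent.
* SBML round-trips preserve values to ~15 significant digits (the XML
  writer's double formatting); the JSON dialect round-trips exactly.
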