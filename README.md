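# gemko

Gene-knockout flux analysis for constraint-based metabolic models.

`gemko` is for systems biologists who want to ask, of a genome-scale
metabolic reconstruction: *if this gene is lost, which parts of the
network actually change, and which metabolites should pile up?*  The
motivating use case is inherited enzyme deficiencies — e.g. loss of the
lysosomal sulfatase IDS in mucopolysaccharidosis type II, where a single
gene gates a handful of glycosaminoglycan-degradation reactions — but
the machinery is generic: any SBML Level 3 + FBC model and any gene in
its GPR rules.

## The method

A metabolic network with stoichiometric matrix **S** and flux vector
**v** is analysed at steady state, **S v = 0**, with flux bounds
**lb ≤ v ≤ ub**.

1. **Knockout via GPR rules.** Each reaction carries a boolean
   gene–protein–reaction rule (`and` = enzyme complex, `or` = isozymes).
   Deleting gene *g* sets its leaves to false; every reaction whose rule
   evaluates false gets bounds pinned to `[0, 0]`.
2. **FBA** maximizes the biomass objective `v_obj`, giving `Z_opt` for
   the wild-type (WT) and knockout (KO) models.
3. **FVA** computes, per reaction, `min v_r` and `max v_r` subject to the
   steady-state constraints plus an optimality floor
   `v_obj ≥ f · Z_opt`, at a chosen fraction *f* (0.9 = hold 90% of
   optimal growth).  This exposes alternative optima that a single FBA
   solution hides.
4. **Δrange statistic.** Per reaction,
   `Δrange = |max_KO − max_WT| + |min_KO − min_WT|`.
   Reactions with `Δrange` above a significance threshold (default 1.0)
   are re-solved at a tightened solver tolerance; those whose excess
   collapses are numerical noise, the rest are genuinely affected.
5. **Sensitivity.** Capacity curves (FVA max vs *f*) and re-runs of the
   whole pipeline across fractions test whether the affected set depends
   on the optimality choice.
6. **Reporter metabolites.** A metabolite is flagged as potentially
   accumulating when every reaction able to consume it (judged on FVA
   ranges, so reversible reactions count by attainable direction) was
   active in WT but is fully blocked in KO — the steady-state signature
   of a storage defect.

LPs are solved with HiGHS through `scipy.optimize.linprog`;
deterministic, no randomization.

## Worked example

A synthetic network with a growth objective, a shared limited resource
(budget 10) and a 5-step catabolic chain whose first 3 steps are gated by
one gene (`examples/02_knockout_delta_range.py`):

```
disabled reactions: ['STEP_1', 'STEP_2', 'STEP_3']
biomass WT 10.00 -> KO 10.00 (0% change)
6 affected, 9 unchanged of 15 reactions
  degradation: 5
  exchange/demand: 1
```

Growth is untouched — the chain is purely catabolic — yet all five chain
steps (including the two downstream, non-gated ones) and the now-pointless
polymer source lose their entire flux range: a highly localized but
complete blockade.  The reporter stage
(`examples/03_reporter_metabolites.py`) then flags exactly the stranded
chain intermediates:

```
5 potentially accumulating metabolites:
  ...
compartment l: 5 (100%)
```

all in the lysosome compartment.  The other examples cover FBA/FVA
basics, capacity curves versus the optimality fraction, and the full
five-table report pipeline (`gemko report` on the CLI).

## Layout

- `src/gemko/` — the library: `model` (network + JSON dialect), `sbml`
  (L3/FBC I/O), `gpr`, `lp` (FBA/FVA), `perturbation` (knockout +
  Δrange), `sensitivity`, `reporters`, `synthetic` (ground-truth
  generator), `pipeline` + `cli`.
- `examples/` — one short narrative script per capability.
- `docs/methods.md` — model assumptions, parameter meanings, numerical
  choices and limitations.
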