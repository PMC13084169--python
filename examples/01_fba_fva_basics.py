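"""FBA and FVA on a minimal shared-resource network.

A single resource (supply ceiling 10) feeds both the growth objective and
a catabolic branch, one unit each per unit flux.  FBA gives the growth
optimum; FVA shows how much branch flux is attainable while growth is
held at a fraction of that optimum.
"""

from gemko import Metabolite, MetabolicModel, Reaction, fba, fva

model = MetabolicModel(
    metabolites=[Metabolite("R", compartment="c")],
    reactions=[
        Reaction("SRC_R", stoichiometry={"R": 1}, lower_bound=0, upper_bound=10),
        Reaction("BIO", stoichiometry={"R": -1}, lower_bound=0, upper_bound=1000),
        Reaction("BRANCH", stoichiometry={"R": -1}, lower_bound=0, upper_bound=1000),
    ],
    objective_id="BIO",
)

solution = fba(model)
print(f"growth optimum: {solution.objective_value:.2f}")

for fraction in (1.0, 0.9, 0.5):
    rng = fva(model, fraction, ["BRANCH"])["BRANCH"]
    print(f"branch range at {fraction:.0%} optimality: "
          f"[{rng.min_flux:.2f}, {rng.max_flux:.2f}]")

# The branch ceiling is exactly the resource left over once growth claims
# its share: 10*(1-fraction).  At full optimality the branch is forced to
# zero -- the growth/degradation trade-off in its purest form.
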