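import pytest

from gemko import Metabolite, MetabolicModel, Reaction
from gemko.gpr import parse_gpr


def make_model(mets, rxns, objective, genes=None):
    """Terse model builder for tests.

    ``mets``: {met_id: compartment}; ``rxns``: {rxn_id: (stoich, lb, ub)}
    or (stoich, lb, ub, gpr) or (stoich, lb, ub, gpr, subsystem).
    """
    metabolites = [Metabolite(mid, compartment=c) for mid, c in mets.items()]
    reactions = []
    for rid, parts in rxns.items():
        stoich, lb, ub = parts[0], parts[1], parts[2]
        gpr = parse_gpr(parts[3]) if len(parts) > 3 else parse_gpr("")
        subsystem = parts[4] if len(parts) > 4 else "unassigned"
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
            )
        )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective,
        genes=genes,
    )


@pytest.fixture
def chain_model():
    """Linear chain EX_A(ub 10) -> A -> B -> biomass; optimum 10."""
    return make_model(
        {"A": "c", "B": "c"},
        {
            "EX_A": ({"A": 1}, 0, 10),
            "A2B": ({"A": -1, "B": 1}, 0, 1000),
            "BIO": ({"B": -1}, 0, 1000),
        },
        objective="BIO",
    )


@pytest.fixture
def resource_toy():
    """Shared resource (supply 10) consumed 1:1 by both growth and a
    branch; at optimality fraction f the branch ceiling is 10*(1-f)."""
    return make_model(
        {"R": "c"},
        {
            "SRC_R": ({"R": 1}, 0, 10),
            "BIO": ({"R": -1}, 0, 1000),
            "BRANCH": ({"R": -1}, 0, 1000, "G1", "degradation"),
        },
        objective="BIO",
    )
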