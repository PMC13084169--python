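"""FBA/FVA correctness: hand-computed LPs, oracle equivalence, invariants."""

import numpy as np
import pytest

from gemko import FvaError, fba, fva
from gemko.synthetic import SyntheticSpec, generate

from conftest import make_model
from oracles import fva_by_enumeration


class TestFba:
    def test_bound_limited_chain(self, chain_model):
        sol = fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)
        assert sol.fluxes["BIO"] == pytest.approx(sol.objective_value)

    def test_all_bounds_zero_gives_zero_optimum(self):
        model = make_model(
            {"A": "c"},
            {"EX_A": ({"A": 1}, 0, 0), "BIO": ({"A": -1}, 0, 0)},
            objective="BIO",
        )
        sol = fba(model)
        assert sol.optimal and sol.objective_value == pytest.approx(0.0)

    def test_infeasible_model_reported(self):
        # forced production of A with no consumer able to drain it
        model = make_model(
            {"A": "c"},
            {"EX_A": ({"A": 1}, 5, 10), "BIO": ({"A": -1}, 0, 1)},
            objective="BIO",
        )
        sol = fba(model)
        assert sol.status == "infeasible" and sol.fluxes is None

    def test_steady_state_and_bounds_hold_at_optimum(self, resource_toy):
        sol = fba(resource_toy)
        S = resource_toy.stoichiometric_matrix().toarray()
        v = np.array([sol.fluxes[r] for r in resource_toy.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-7
        lb, ub = resource_toy.bounds_arrays()
        assert np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7)


class TestFva:
    def test_shared_resource_branch_range(self, resource_toy):
        ranges = fva(resource_toy, 0.9, ["BRANCH"])
        rng = ranges["BRANCH"]
        assert rng.min_flux == pytest.approx(0.0, abs=1e-8)
        assert rng.max_flux == pytest.approx(1.0, abs=1e-6)

    def test_no_slack_at_full_optimality(self, resource_toy):
        rng = fva(resource_toy, 1.0, ["BRANCH"])["BRANCH"]
        assert rng.min_flux == pytest.approx(0.0, abs=1e-6)
        assert rng.max_flux == pytest.approx(0.0, abs=1e-6)

    def test_fraction_zero_equals_unconstrained_per_reaction_lps(self, resource_toy):
        # at fraction 0 the objective floor (>= 0) is vacuous here, so FVA
        # must agree with independent min/max LPs without the floor
        ranges = fva(resource_toy, 0.0)
        for rid, rng in ranges.items():
            as_obj = make_model(
                {"R": "c"},
                {
                    "SRC_R": ({"R": 1}, 0, 10),
                    "BIO": ({"R": -1}, 0, 1000),
                    "BRANCH": ({"R": -1}, 0, 1000),
                },
                objective=rid,
            )
            assert rng.max_flux == pytest.approx(
                fba(as_obj).objective_value, abs=1e-6
            )

    def test_infeasible_base_model_raises(self):
        model = make_model(
            {"A": "c"},
            {"EX_A": ({"A": 1}, 5, 10), "BIO": ({"A": -1}, 0, 1)},
            objective="BIO",
        )
        with pytest.raises(FvaError, match="infeasible"):
            fva(model, 0.9)

    def test_invalid_fraction_rejected(self, resource_toy):
        with pytest.raises(ValueError):
            fva(resource_toy, 1.5)

    def test_endpoints_are_attainable(self, resource_toy):
        """Each FVA endpoint must be realized by a full feasible flux
        vector, checked by re-solving with the reaction pinned there."""
        for fraction in (0.5, 0.9, 1.0):
            z = fba(resource_toy).objective_value
            for rid, rng in fva(resource_toy, fraction).items():
                for endpoint in (rng.min_flux, rng.max_flux):
                    pinned = resource_toy.copy()
                    rxn = pinned.get_reaction(rid)
                    rxn.lower_bound = rxn.upper_bound = endpoint
                    sol = fba(pinned)
                    assert sol.optimal
                    assert sol.objective_value >= fraction * z - 1e-6

    def test_monotone_nesting_in_fraction(self, resource_toy):
        prev = None
        for fraction in (0.0, 0.25, 0.5, 0.75, 0.9, 1.0):
            cur = fva(resource_toy, fraction)
            if prev is not None:
                for rid in cur:
                    assert cur[rid].max_flux <= prev[rid].max_flux + 1e-6
                    assert cur[rid].min_flux >= prev[rid].min_flux - 1e-6
            prev = cur

    def test_deterministic_repeat(self, resource_toy):
        a = fva(resource_toy, 0.9)
        b = fva(resource_toy, 0.9)
        assert a == b


# -- oracle equivalence -----------------------------------------------------

ORACLE_MODELS = {
    "chain": (
        {"A": "c", "B": "c"},
        {
            "EX_A": ({"A": 1}, 0, 10),
            "A2B": ({"A": -1, "B": 1}, 0, 1000),
            "BIO": ({"B": -1}, 0, 1000),
        },
        "BIO",
    ),
    "reversible_middle": (
        {"A": "c", "B": "c"},
        {
            "EX_A": ({"A": 1}, 0, 8),
            "A2B": ({"A": -1, "B": 1}, -5, 5),
            "EX_B": ({"B": -1}, -3, 10),
            "BIO": ({"A": -1}, 0, 6),
        },
        "BIO",
    ),
    "shared_resource": (
        {"R": "c"},
        {
            "SRC_R": ({"R": 1}, 0, 10),
            "BIO": ({"R": -1}, 0, 1000),
            "BRANCH": ({"R": -1}, 0, 1000),
        },
        "BIO",
    ),
    "branched_six": (
        {"A": "c", "B": "c", "C": "c"},
        {
            "EX_A": ({"A": 1}, 0, 7),
            "A2B": ({"A": -1, "B": 1}, 0, 5),
            "A2C": ({"A": -1, "C": 1}, -2, 6),
            "B2C": ({"B": -1, "C": 1}, -4, 4),
            "EX_C": ({"C": -1}, 0, 9),
            "BIO": ({"B": -1}, 0, 3),
        },
        "BIO",
    ),
    "stoichiometric_coupling": (
        {"A": "c", "B": "c"},
        {
            "EX_A": ({"A": 1}, 0, 12),
            "SPLIT": ({"A": -2, "B": 1}, 0, 1000),
            "BIO": ({"B": -1}, 0, 4),
            "DM_B": ({"B": -1}, 0, 2),
        },
        "BIO",
    ),
}


@pytest.mark.parametrize("name", sorted(ORACLE_MODELS))
@pytest.mark.parametrize("fraction", [0.0, 0.5, 0.9, 1.0])
def test_fva_matches_vertex_enumeration(name, fraction):
    """On small integer-bound networks, FVA endpoints must equal the
    solver-independent vertex-enumeration optimum to 1e-6."""
    mets, rxns, obj = ORACLE_MODELS[name]
    model = make_model(mets, rxns, objective=obj)
    z_oracle, oracle = fva_by_enumeration(model, fraction)
    assert fba(model).objective_value == pytest.approx(z_oracle, abs=1e-6)
    for rid, rng in fva(model, fraction).items():
        omin, omax = oracle[rid]
        assert rng.min_flux == pytest.approx(omin, abs=1e-6), rid
        assert rng.max_flux == pytest.approx(omax, abs=1e-6), rid


def test_fva_matches_cobra_on_synthetic_model():
    """Independent cross-check against the COBRA toolbox implementation
    (GLPK backend) on a generated network."""
    import cobra
    from cobra.flux_analysis import flux_variability_analysis

    model, _ = generate(SyntheticSpec(seed=5))
    cm = cobra.Model("syn")
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.bounds = (r.lower_bound, r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = model.objective_id
    ours = fva(model, 0.9)
    theirs = flux_variability_analysis(cm, fraction_of_optimum=0.9)
    for rid in model.reaction_ids:
        assert ours[rid].min_flux == pytest.approx(
            theirs.loc[rid, "minimum"], abs=1e-5
        )
        assert ours[rid].max_flux == pytest.approx(
            theirs.loc[rid, "maximum"], abs=1e-5
        )
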