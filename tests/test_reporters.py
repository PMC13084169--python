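"""Reporter-metabolite rule: WT-active, KO-blocked consumption."""

import pytest

from gemko import (
    compartment_summary,
    consuming_reactions,
    find_accumulating,
    simulate_knockout,
)
from gemko.lp import FluxRange
from gemko.reporters import AccumulationCandidate, AccumulationReport
from gemko.synthetic import SyntheticSpec, generate

from conftest import make_model


def _rng(rid, lo, hi):
    return FluxRange(reaction_id=rid, min_flux=lo, max_flux=hi, fraction=0.9)


def _ranges_of(result):
    wt = {r.reaction_id: r.wt_range for r in result.records}
    ko = {r.reaction_id: r.ko_range for r in result.records}
    return wt, ko


class TestConsumingReactions:
    @pytest.fixture
    def two_reaction_model(self):
        return make_model(
            {"M": "c"},
            {"R1": ({"M": -1}, 0, 5), "R2": ({"M": 1}, -3, 4)},
            objective="R1",
        )

    def test_irreversible_consumer_detected(self, two_reaction_model):
        ranges = {"R1": _rng("R1", 0, 5), "R2": _rng("R2", 0, 4)}
        assert consuming_reactions(two_reaction_model, "M", ranges) == {"R1"}

    def test_reversible_producer_consumes_in_reverse(self, two_reaction_model):
        # R2 makes M left-to-right but its range admits reverse flux
        ranges = {"R1": _rng("R1", 0, 0), "R2": _rng("R2", -3, 4)}
        assert consuming_reactions(two_reaction_model, "M", ranges) == {"R2"}

    def test_all_blocked_gives_empty_set(self, two_reaction_model):
        ranges = {"R1": _rng("R1", 0, 0), "R2": _rng("R2", 0, 0)}
        assert consuming_reactions(two_reaction_model, "M", ranges) == set()

    def test_exhaustive_sign_direction_cases(self, two_reaction_model):
        """Enumerated oracle over coefficient sign x attainable direction:
        consumption iff (coef < 0 and forward possible) or
        (coef > 0 and reverse possible)."""
        for coef_sign in (-1, 1):
            model = make_model(
                {"M": "c"},
                {"R": ({"M": coef_sign}, -5, 5), "D": ({"M": -coef_sign}, -5, 5)},
                objective="R",
            )
            for lo, hi in [(-5, 5), (0, 5), (-5, 0), (0, 0)]:
                ranges = {"R": _rng("R", lo, hi)}
                expected = (coef_sign < 0 and hi > 1e-6) or (
                    coef_sign > 0 and lo < -1e-6
                )
                got = "R" in consuming_reactions(model, "M", ranges)
                assert got == expected, (coef_sign, lo, hi)

    def test_unknown_metabolite_rejected(self, two_reaction_model):
        with pytest.raises(KeyError):
            consuming_reactions(two_reaction_model, "ghost", {})


class TestFindAccumulating:
    def test_synthetic_ground_truth_recovered(self):
        model, truth = generate(SyntheticSpec(seed=41))
        result = simulate_knockout(model, truth.gene, 0.5)
        wt, ko = _ranges_of(result)
        report = find_accumulating(model, wt, ko, gene=truth.gene)
        assert {c.metabolite_id for c in report.candidates} \
            == truth.expected_accumulating

    def test_bypass_consumer_prevents_false_positive(self):
        """A metabolite with one surviving active consumer in the
        knockout must never be flagged."""
        model, truth = generate(SyntheticSpec(seed=42, bypass=True))
        result = simulate_knockout(model, truth.gene, 0.5)
        wt, ko = _ranges_of(result)
        report = find_accumulating(model, wt, ko)
        flagged = {c.metabolite_id for c in report.candidates}
        assert "gag_l" not in flagged
        assert flagged == truth.expected_accumulating

    def test_model_against_itself_flags_nothing(self):
        model, truth = generate(SyntheticSpec(seed=43))
        result = simulate_knockout(model, truth.gene, 0.5)
        wt, _ = _ranges_of(result)
        report = find_accumulating(model, wt, wt)
        assert report.candidates == []

    def test_candidates_confined_to_affected_reaction_metabolites(self):
        model, truth = generate(SyntheticSpec(seed=44))
        result = simulate_knockout(model, truth.gene, 0.5)
        wt, ko = _ranges_of(result)
        report = find_accumulating(model, wt, ko)
        participants = {
            met
            for rec in result.affected
            for met in model.get_reaction(rec.reaction_id).stoichiometry
        }
        assert {c.metabolite_id for c in report.candidates} <= participants

    def test_candidates_carry_compartment_and_category(self):
        model, truth = generate(SyntheticSpec(seed=45))
        result = simulate_knockout(model, truth.gene, 0.5)
        wt, ko = _ranges_of(result)
        report = find_accumulating(model, wt, ko)
        for c in report.candidates:
            assert c.compartment == "l"
            assert c.category == "degradation"
            assert c.consuming_reactions


class TestCompartmentSummary:
    def _report(self, compartments):
        candidates = [
            AccumulationCandidate(f"m{i}", comp, ("r",), "x")
            for i, comp in enumerate(compartments)
        ]
        return AccumulationReport(gene="g", candidates=candidates,
                                  universe_size=len(candidates))

    def test_printed_lysosomal_share(self):
        report = self._report(["lysosome"] * 32 + ["cytosol", "extracellular"])
        summary = compartment_summary(report)
        assert summary["lysosome"] == (32, 94)
        assert sum(n for n, _ in summary.values()) == 34

    def test_single_candidate_is_hundred_percent(self):
        assert compartment_summary(self._report(["l"])) == {"l": (1, 100)}

    def test_empty_report_gives_empty_map(self):
        assert compartment_summary(self._report([])) == {}
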