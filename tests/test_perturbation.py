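"""Knockout application, the Δrange statistic and classification."""

import pytest

from gemko import apply_knockout, delta_range, simulate_knockout
from gemko.lp import FluxRange, fva
from gemko.perturbation import (
    AFFECTED,
    UNCHANGED,
    build_records,
    capacity_loss_percent,
    classify_records,
    reachable_reactions,
    subsystem_distribution,
)
from gemko.synthetic import SyntheticSpec, generate

from conftest import make_model


def _rng(rid, lo, hi, fraction=0.9):
    return FluxRange(reaction_id=rid, min_flux=lo, max_flux=hi, fraction=fraction)


class TestApplyKnockout:
    def test_gated_reactions_pinned_to_zero(self, resource_toy):
        ko = apply_knockout(resource_toy, "G1")
        branch = ko.get_reaction("BRANCH")
        assert (branch.lower_bound, branch.upper_bound) == (0.0, 0.0)
        assert resource_toy.get_reaction("BRANCH").upper_bound == 1000

    def test_other_reactions_untouched(self, resource_toy):
        ko = apply_knockout(resource_toy, "G1")
        for rid in ("SRC_R", "BIO"):
            orig = resource_toy.get_reaction(rid)
            assert (ko.get_reaction(rid).lower_bound,
                    ko.get_reaction(rid).upper_bound) == (
                orig.lower_bound, orig.upper_bound)

    def test_isozyme_backup_survives(self):
        model = make_model(
            {"A": "c"},
            {"EX_A": ({"A": 1}, 0, 10),
             "BIO": ({"A": -1}, 0, 1000, "g1 or g2")},
            objective="BIO",
        )
        ko = apply_knockout(model, "g1")
        assert ko.get_reaction("BIO").upper_bound == 1000

    def test_unreferenced_gene_returns_identity(self, resource_toy, caplog):
        ko = apply_knockout(resource_toy, "nobody")
        assert all(
            (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
            for a, b in zip(ko.reactions, resource_toy.reactions)
        )


class TestDeltaRange:
    def test_full_block_equals_wt_capacity(self):
        assert delta_range(_rng("MAR07517", 0, 140.0), _rng("MAR07517", 0, 0)) \
            == pytest.approx(140.0)

    def test_identical_ranges_give_zero(self):
        assert delta_range(_rng("r", -3, 7), _rng("r", -3, 7)) == 0.0

    def test_hand_computed_mixed_shift(self):
        # |3-5| + |-2-(-5)| = 5
        assert delta_range(_rng("r", -5, 5), _rng("r", -2, 3)) == pytest.approx(5.0)

    def test_symmetric_in_wt_ko(self):
        a, b = _rng("r", -5, 5), _rng("r", -2, 3)
        assert delta_range(a, b) == delta_range(b, a)

    def test_mismatched_reaction_or_fraction_rejected(self):
        with pytest.raises(ValueError, match="reactions"):
            delta_range(_rng("r1", 0, 1), _rng("r2", 0, 1))
        with pytest.raises(ValueError, match="fraction"):
            delta_range(_rng("r", 0, 1, 0.9), _rng("r", 0, 1, 0.5))


class TestClassification:
    def test_all_zero_deltas_unchanged(self, resource_toy):
        ranges = fva(resource_toy, 0.9)
        records = build_records(resource_toy, ranges, ranges)
        out = classify_records(records, 1.0, resource_toy, resource_toy)
        assert all(r.classification == UNCHANGED for r in out)

    def test_counts_conserved(self, resource_toy):
        result = simulate_knockout(resource_toy, "G1", 0.5)
        counts = result.counts()
        assert sum(counts.values()) == len(result.records)

    def test_threshold_must_be_positive(self, resource_toy):
        with pytest.raises(ValueError):
            classify_records([], 0.0, resource_toy, resource_toy)

    def test_genuine_perturbation_survives_retest(self, resource_toy):
        result = simulate_knockout(resource_toy, "G1", 0.5)
        branch = {r.reaction_id: r for r in result.records}["BRANCH"]
        assert branch.classification == AFFECTED
        assert branch.delta_range == pytest.approx(5.0, abs=1e-6)


class TestSyntheticGroundTruth:
    def test_affected_set_recovered_exactly(self):
        model, truth = generate(SyntheticSpec(seed=21))
        result = simulate_knockout(model, truth.gene, 0.5)
        assert result.affected_reaction_ids == truth.expected_affected
        assert result.disabled_reactions == truth.gated_reactions

    def test_catabolic_knockout_leaves_growth_unchanged(self):
        model, truth = generate(SyntheticSpec(seed=22))
        result = simulate_knockout(model, truth.gene, 0.9)
        assert result.wt_biomass == pytest.approx(truth.expected_biomass, abs=1e-7)
        assert result.ko_biomass == pytest.approx(result.wt_biomass, abs=1e-7)
        assert result.relative_growth_change == pytest.approx(0.0, abs=1e-9)

    def test_affected_confined_to_branch_component(self):
        """Affected reactions stay inside the metabolite-reaction graph
        component reachable from the disabled steps without crossing the
        shared resource."""
        model, truth = generate(SyntheticSpec(seed=23))
        result = simulate_knockout(model, truth.gene, 0.5)
        component = reachable_reactions(
            model, truth.gated_reactions, barrier_metabolites=["res_c"]
        )
        assert result.affected_reaction_ids <= component

    def test_subsystem_distribution_matches_branch(self):
        model, truth = generate(SyntheticSpec(seed=24))
        result = simulate_knockout(model, truth.gene, 0.5)
        dist = subsystem_distribution(result.records)
        assert dist == {
            "degradation": len(truth.chain_reactions),
            "exchange/demand": 1,  # the silenced polymer source
        }
        assert sum(dist.values()) == len(result.affected)


class TestWorkedValues:
    def test_capacity_loss_from_printed_ranges(self):
        wt = _rng("MAR07517", 0.0, 140.0)
        ko = _rng("MAR07517", 0.0, 0.0)
        assert capacity_loss_percent(wt, ko) == pytest.approx(100.0)

    def test_affected_fraction_of_network(self):
        from gemko import affected_fraction_percent

        assert affected_fraction_percent(40, 12971) == pytest.approx(0.31)
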