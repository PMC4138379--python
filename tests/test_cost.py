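"""Cost model, pattern probabilities and the world-enumeration oracle."""

import math

import pytest

from gmopanel import (
    CapacityError,
    CostModel,
    GMEvent,
    GMOMatrix,
    GeneticElement,
    Outcome,
    PRUNED,
    Presence,
    brute_force_expected_cost,
    candidate_count,
    coverage,
    enumerate_patterns,
    evaluate_strategy,
    expected_total_cost,
    run_cost,
    standalone_negative_prob,
)
from conftest import random_small_matrix


def single_element_matrix(priors, element="P35S", covered=None):
    """Events all (or a subset) carrying one shared element."""
    covered = range(len(priors)) if covered is None else covered
    events = [
        GMEvent(
            name=f"E{i}",
            species="maize",
            prior=p,
            elements={element: Presence.PRESENT} if i in set(covered) else {},
            es_assay_id=f"es-{i}",
        )
        for i, p in enumerate(priors)
    ]
    return GMOMatrix(events=events, elements=[GeneticElement(element)])


class TestRunCost:
    @pytest.mark.parametrize(
        "n, expected",
        [(1, 113.00), (20, 515.42), (22, 557.78), (55, 1256.72), (76, 1701.50)],
    )
    def test_linear_cost(self, n, expected):
        assert run_cost(n) == pytest.approx(expected, abs=1e-9)

    def test_zero_assays_means_no_run(self):
        assert run_cost(0) == 0.0
        assert run_cost(0, CostModel(zero_assay_run_cost=5.0)) == 5.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            run_cost(-1)

    def test_cost_model_validation(self):
        with pytest.raises(ValueError):
            CostModel(slope=0)
        with pytest.raises(ValueError):
            CostModel(intercept=-1)


class TestStandaloneNegativeProb:
    def test_no_detected_events_gives_one(self):
        m = single_element_matrix([0.3, 0.2], covered=[])
        assert standalone_negative_prob(m, "P35S") == 1.0

    def test_single_event(self):
        m = single_element_matrix([0.3], covered=[0])
        assert standalone_negative_prob(m, "P35S") == pytest.approx(0.7)

    def test_two_half_priors_enumerates_to_quarter(self):
        # enumerate the 4 presence worlds: only (absent, absent) => 0.25
        m = single_element_matrix([0.5, 0.5])
        assert standalone_negative_prob(m, "P35S") == pytest.approx(0.25)

    def test_unknown_cell_not_credited(self, toy):
        # E2's T-nos cell flipped to UNKNOWN must drop it from the product
        toy.event("E2").elements["T-nos"] = Presence.UNKNOWN
        assert standalone_negative_prob(toy, "T-nos") == 1.0


class TestCandidateCount:
    def test_empty_set_counts_all_distinct_es(self, toy):
        assert candidate_count(toy, [], {}) == 3

    def test_all_covered_negative_gives_zero(self):
        m = single_element_matrix([0.5, 0.5])
        assert candidate_count(m, ["P35S"], {"P35S": Outcome.NEGATIVE}) == 0

    def test_mixed_pattern_from_worked_example(self, toy):
        # P35S positive keeps E1; T-nos negative excludes E2; E3 uncovered
        n = candidate_count(
            toy,
            ["P35S", "T-nos"],
            {"P35S": Outcome.POSITIVE, "T-nos": Outcome.NEGATIVE},
        )
        assert n == 2

    def test_shared_es_assay_counted_once(self):
        m = single_element_matrix([0.5, 0.5], covered=[])
        for ev in m.events:
            ev.es_assay_id = "es-shared"
        assert candidate_count(m, [], {}) == 1


class TestExpectedTotalCost:
    def test_empty_combination_is_baseline(self):
        m = single_element_matrix([0.01] * 20)
        assert expected_total_cost(m, []) == pytest.approx(515.42, abs=1e-9)

    def test_sure_negative_assay_costs_one_run(self):
        m = single_element_matrix([0.0, 0.0])
        assert expected_total_cost(m, ["P35S"]) == pytest.approx(113.00)

    def test_two_event_worked_example(self):
        # 113.00 + 0.75 * 134.18, verified by world enumeration
        m = single_element_matrix([0.5, 0.5])
        expected = expected_total_cost(m, ["P35S"])
        assert expected == pytest.approx(213.635, abs=1e-9)
        assert brute_force_expected_cost(m, ["P35S"]) == pytest.approx(
            expected, abs=1e-9
        )

    def test_deterministic_world_single_event(self):
        m = single_element_matrix([1.0])
        assert brute_force_expected_cost(m, ["P35S"]) == pytest.approx(226.00)
        assert expected_total_cost(m, ["P35S"]) == pytest.approx(226.00)

    def test_bound_above_true_value_is_no_op(self):
        m = single_element_matrix([0.5, 0.5])
        assert expected_total_cost(m, ["P35S"], bound=1e9) == pytest.approx(
            213.635
        )

    def test_bound_below_true_value_returns_pruned(self):
        m = single_element_matrix([0.5, 0.5])
        assert expected_total_cost(m, ["P35S"], bound=200.0) is PRUNED
        assert expected_total_cost(m, [], bound=10.0) is PRUNED

    def test_pattern_cap_enforced(self):
        m = random_small_matrix(0, max_events=5, max_elements=6)
        with pytest.raises(CapacityError):
            expected_total_cost(m, m.assays, pattern_cap=len(m.assays) - 1)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_world_enumeration_oracle(self, seed):
        m = random_small_matrix(seed, max_events=8, max_elements=5)
        exact = expected_total_cost(m, m.assays)
        oracle = brute_force_expected_cost(m, m.assays)
        assert exact == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_event_specific_portion(self, seed):
        # adding an assay never enlarges any world's candidate set
        m = random_small_matrix(seed, max_events=8, max_elements=6)
        cm = CostModel()
        ordered = sorted(m.assays, key=lambda a: a.name)
        prev_es = math.inf
        for k in range(len(ordered) + 1):
            sub = ordered[:k]
            total = expected_total_cost(m, sub, cm)
            es_part = total - run_cost(len(sub), cm)
            assert es_part <= prev_es + 1e-9
            prev_es = es_part


class TestEventSpecificLowerBound:
    def test_closed_form_on_toy(self, toy):
        from gmopanel import expected_es_lower_bound

        # groups present with prob 0.5, 0.5, 0.1:
        # slope*(0.5+0.5+0.1) + intercept*(1 - 0.5*0.5*0.9)
        expected = 21.18 * 1.1 + 91.82 * (1 - 0.225)
        assert expected_es_lower_bound(toy) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(15))
    def test_bounds_every_strategy_from_below(self, seed):
        from gmopanel import expected_es_lower_bound

        m = random_small_matrix(seed, max_events=8, max_elements=6)
        cm = CostModel()
        floor_ = expected_es_lower_bound(m, cm)
        assays = sorted(m.assays, key=lambda a: a.name)
        for k in range(len(assays) + 1):
            total = expected_total_cost(m, assays[:k], cm)
            es = total - run_cost(k, cm)
            assert es >= floor_ - 1e-9


class TestPatterns:
    @pytest.mark.parametrize("seed", range(10))
    def test_pattern_probabilities_sum_to_one(self, seed):
        m = random_small_matrix(seed, max_events=10, max_elements=6)
        patterns = enumerate_patterns(m, m.assays)
        assert len(patterns) == 2 ** len(m.assays)
        assert sum(p.probability for p in patterns) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_pattern_candidate_counts_match_public_op(self, toy):
        for p in enumerate_patterns(toy, toy.assays):
            assert p.candidate_count == candidate_count(
                toy, toy.assays, p.outcomes
            )


class TestCoverageAndStrategy:
    def test_coverage_values(self, toy):
        assert coverage(toy, [])[0] == 0.0
        pct, covered, total = coverage(toy, ["P35S"])
        assert (pct, covered, total) == (pytest.approx(100 * 2 / 3), 2, 3)
        assert coverage(toy, toy.assays)[0] == pytest.approx(100 * 2 / 3)

    def test_evaluate_strategy_fields_consistent(self, toy):
        s = evaluate_strategy(toy, ["P35S"])
        assert s.total_expected_cost == pytest.approx(
            s.screening_cost + s.expected_es_cost
        )
        assert s.savings == pytest.approx(s.baseline_cost - s.total_expected_cost)
        assert s.baseline_cost == pytest.approx(run_cost(3))

    def test_empty_strategy_zero_savings_zero_coverage(self, toy):
        s = evaluate_strategy(toy, [])
        assert s.savings == pytest.approx(0.0)
        assert s.coverage_pct == 0.0

    def test_baseline_counts_distinct_es_assays(self):
        m = single_element_matrix([0.1, 0.1, 0.1])
        for ev in m.events[:2]:
            ev.es_assay_id = "es-shared"
        s = evaluate_strategy(m, [])
        assert s.baseline_cost == pytest.approx(run_cost(2))
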