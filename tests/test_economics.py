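"""Discounting, accumulation and cost-utility comparison arithmetic."""

import numpy as np
import pytest

from smokefree import (RELEASED_STATES, CohortTrace, LifeTable, ParameterSet,
                       compare_scenarios, discount_factor)
from smokefree.economics import DOMINANT, DOMINATED, accumulate
from smokefree.engine import StateSpace


def _constant_trace(space, occupancy, cycles, start_age=40):
    rows = np.tile(np.asarray(occupancy, dtype=float), (cycles + 1, 1))
    return CohortTrace(space, rows, start_age)


def _plain_params(**kwargs) -> ParameterSet:
    base = dict(
        life_table=LifeTable.flat(0.0, age_min=0, age_max=120), max_age=120,
        cost_age_bands=[[0, 1.0]], utility_age_bands=[[0, 1.0]],
        discount_rate_costs=0.0, discount_rate_outcomes=0.0,
    )
    base.update(kwargs)
    return ParameterSet(**base)


class TestDiscounting:
    def test_zero_rate_gives_unit_factor(self):
        assert discount_factor(0.0, 17) == 1.0

    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0.035, 0) == 1.0

    def test_closed_form_two_cycles(self):
        assert discount_factor(0.035, 2) == pytest.approx(1 / 1.035**2, rel=1e-9)
        assert discount_factor(0.035, 2) == pytest.approx(0.93351, abs=5e-6)

    def test_negative_cycle_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.035, -1)


class TestAccumulation:
    def test_pure_smoker_undiscounted_personal_cost(self):
        p = _plain_params(cost_personal_smoking=100.0)
        trace = _constant_trace(RELEASED_STATES, [0, 1, 0, 0, 0, 0], cycles=3)
        out = accumulate(trace, p)
        assert out.costs.personal_smoking == pytest.approx(300.0)
        assert out.costs.personal_vaping == 0.0

    def test_pure_smoker_discounted_geometric_sum(self):
        p = _plain_params(cost_personal_smoking=100.0, discount_rate_costs=0.035)
        trace = _constant_trace(RELEASED_STATES, [0, 1, 0, 0, 0, 0], cycles=3)
        out = accumulate(trace, p)
        expected = 100 * (1 + 1 / 1.035 + 1 / 1.035**2)  # ≈ 289.97
        assert out.costs.personal_smoking == pytest.approx(expected, rel=1e-12)
        assert out.costs.personal_smoking == pytest.approx(289.97, abs=0.005)

    def test_dead_state_contributes_nothing(self):
        p = _plain_params(cost_personal_smoking=100.0)
        trace = _constant_trace(RELEASED_STATES, [0, 0, 0, 0, 0, 1], cycles=5)
        out = accumulate(trace, p)
        assert out.total_cost == 0.0
        assert out.life_years == 0.0

    def test_full_health_life_years_equal_qalys(self):
        p = _plain_params(utility_by_state={s: 1.0 for s in
                                            RELEASED_STATES.living})
        trace = _constant_trace(RELEASED_STATES, [1, 0, 0, 0, 0, 0], cycles=10)
        out = accumulate(trace, p)
        assert out.life_years == pytest.approx(10.0)
        assert out.qalys == pytest.approx(10.0)

    def test_zero_utility_gives_zero_qalys_only(self):
        p = _plain_params(utility_by_state={s: 0.0 for s in
                                            RELEASED_STATES.living})
        trace = _constant_trace(RELEASED_STATES, [1, 0, 0, 0, 0, 0], cycles=10)
        out = accumulate(trace, p)
        assert out.qalys == 0.0
        assert out.life_years == pytest.approx(10.0)

    def test_qaly_is_utility_weighted_mean(self):
        p = _plain_params(utility_by_state={"neither": 0.9, "smoker": 0.7,
                                            "former_smoker": 0.9, "vaper": 0.9,
                                            "former_vaper": 0.9})
        trace = _constant_trace(RELEASED_STATES, [0.5, 0.5, 0, 0, 0, 0], cycles=1)
        out = accumulate(trace, p)
        assert out.qalys == pytest.approx(0.8)

    def test_total_is_sum_of_components(self, params):
        from smokefree import ReleasedCohortModel
        out = ReleasedCohortModel(params, 3).run().outcome
        assert out.total_cost == pytest.approx(
            out.costs.healthcare + out.costs.personal + out.costs.intervention,
            abs=0.5)

    def test_qalys_never_exceed_life_years(self, params):
        from smokefree import ReleasedCohortModel
        for s in (1, 2, 3, 4):
            out = ReleasedCohortModel(params, s).run().outcome
            assert out.qalys <= out.life_years

    def test_discounting_reduces_totals(self):
        trace = _constant_trace(RELEASED_STATES, [0, 1, 0, 0, 0, 0], cycles=20)
        undisc = accumulate(trace, _plain_params(cost_personal_smoking=100.0))
        disc = accumulate(trace, _plain_params(cost_personal_smoking=100.0,
                                               discount_rate_costs=0.035,
                                               discount_rate_outcomes=0.035))
        assert disc.total_cost < undisc.total_cost
        assert disc.qalys < undisc.qalys

    def test_half_cycle_correction_averages_adjacent_cycles(self):
        p = _plain_params(cost_personal_smoking=100.0)
        space = StateSpace(("smoker", "dead"))
        rows = np.array([[1.0, 0.0], [0.5, 0.5]])
        trace = CohortTrace(space, rows, 40)
        assert accumulate(trace, p).costs.personal_smoking == pytest.approx(100.0)
        assert accumulate(trace, p, half_cycle=True).costs.personal_smoking \
            == pytest.approx(75.0)

    def test_missing_state_cost_entry_is_configuration_error(self):
        from smokefree.parameters import ConfigurationError
        p = _plain_params(cost_healthcare_by_state={"neither": 1.0})
        trace = _constant_trace(RELEASED_STATES, [0, 1, 0, 0, 0, 0], cycles=1)
        with pytest.raises(ConfigurationError, match="smoker"):
            accumulate(trace, p)


class TestComparison:
    def test_more_costly_less_effective_is_dominated(self):
        r = compare_scenarios(3764.0, None, 20000.0, delta_qalys=-0.252)
        assert r.label == DOMINATED
        assert r.icer is None
        assert r.inmb == pytest.approx(20000 * -0.252 - 3764)  # −8804

    def test_cheaper_more_effective_is_dominant(self):
        r = compare_scenarios(-100.0, None, 20000.0, delta_qalys=0.01)
        assert r.label == DOMINANT
        assert r.inmb == pytest.approx(300.0)

    def test_no_difference_case(self):
        r = compare_scenarios(0.0, None, 20000.0, delta_qalys=0.0)
        assert r.inmb == 0.0
        assert r.label == "no difference"

    def test_cost_difference_only_when_qalys_tie(self):
        r = compare_scenarios(50.0, None, 20000.0, delta_qalys=0.0)
        assert r.icer is None
        assert r.label == "cost difference only"

    def test_icer_reported_when_tradeoff_exists(self):
        r = compare_scenarios(1000.0, None, 20000.0, delta_qalys=0.1)
        assert r.icer == pytest.approx(10000.0)
        assert r.label is None

    def test_self_comparison_is_null(self, params):
        from smokefree import ReleasedCohortModel
        out = ReleasedCohortModel(params, 1).run().outcome
        r = compare_scenarios(out, out, params.wtp_threshold)
        assert (r.delta_cost, r.delta_qalys, r.inmb) == (0.0, 0.0, 0.0)

    def test_inmb_identity_to_machine_precision(self, params):
        from smokefree import COMPARISONS, ReleasedCohortModel
        outcomes = {s: ReleasedCohortModel(params, s).run().outcome
                    for s in (1, 2, 3, 4)}
        for a, b in COMPARISONS.values():
            r = compare_scenarios(outcomes[a], outcomes[b], params.wtp_threshold)
            assert r.inmb == pytest.approx(
                params.wtp_threshold * r.delta_qalys - r.delta_cost, abs=1e-9)

    def test_base_case_matches_published_signs_and_labels(self, params):
        """All three pairwise comparisons: first-listed scenario more costly,
        less effective, hence dominated, with negative net benefit."""
        from smokefree import COMPARISONS, ReleasedCohortModel
        outcomes = {s: ReleasedCohortModel(params, s).run().outcome
                    for s in (1, 2, 3, 4)}
        for a, b in COMPARISONS.values():
            r = compare_scenarios(outcomes[a], outcomes[b], params.wtp_threshold)
            assert r.delta_cost > 0 and r.delta_qalys < 0
            assert r.label == DOMINATED
            assert r.inmb < 0
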