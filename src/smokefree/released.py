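"""Lifetime model for people released from a smoke-free prison.

Four policy scenarios, crossing two factors:

====  ================  =====================
 id   vaping permitted  intervention offered
====  ================  =====================
 1    yes               no
 2    no                no
 3    yes               yes
 4    no                yes
====  ================  =====================

Release status is assigned at cycle 0.  Where vaping is permitted,
people who vaped in prison either relapse to smoking or carry on vaping;
everyone else leaves nicotine-free.  Where vaping is not permitted,
people who smoked before prison either relapse to smoking or leave
nicotine-free.  A cessation intervention, where offered, acts in the
first post-release year only: engagers incur its unit cost and a
fraction of them quit (smokers become former smokers, vapers former
vapers).  No benefit of vaping as a cessation aid is modelled, and
neither reimprisonment nor dual use enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import economics
from .engine import RELEASED_STATES, CohortTrace, run_cohort
from .parameters import ParameterSet

__all__ = [
    "ScenarioSpec",
    "SCENARIOS",
    "initial_distribution",
    "apply_intervention",
    "released_rr_by_state",
    "ReleasedCohortModel",
    "ReleasedResults",
    "run_released_scenario",
]

_SCENARIO_FACTORS = {1: (True, False), 2: (False, False),
                     3: (True, True), 4: (False, True)}


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four policy scenarios."""

    scenario: int

    def __post_init__(self):
        if self.scenario not in _SCENARIO_FACTORS:
            raise ValueError(f"scenario must be 1-4, got {self.scenario}")

    @property
    def vaping_permitted(self) -> bool:
        return _SCENARIO_FACTORS[self.scenario][0]

    @property
    def intervention_offered(self) -> bool:
        return _SCENARIO_FACTORS[self.scenario][1]

    def describe(self) -> str:
        return (f"Scenario {self.scenario}: "
                f"{'vaping permitted' if self.vaping_permitted else 'no vaping permitted'}, "
                f"{'intervention offered' if self.intervention_offered else 'no intervention'}")


SCENARIOS = {i: ScenarioSpec(i) for i in _SCENARIO_FACTORS}


def initial_distribution(spec: ScenarioSpec, p: ParameterSet) -> np.ndarray:
    """Occupancy at release (cycle 0) over the released-person states.

    Vaping permitted: in-prison vapers split into post-release smokers
    (relapse share) and continuing vapers; non-vapers are nicotine-free.
    No vaping: pre-prison smokers relapse to smoking or leave
    nicotine-free; never-smokers are nicotine-free.
    """
    dist = np.zeros(len(RELEASED_STATES))
    i = RELEASED_STATES.index
    if spec.vaping_permitted:
        v, r = p.p_vape_in_prison, p.p_relapse_vaper
        dist[i("smoker")] = v * r
        dist[i("vaper")] = v * (1.0 - r)
        dist[i("neither")] = 1.0 - v
    else:
        s, r = p.p_smoke_preprison, p.p_relapse_postrelease
        dist[i("smoker")] = s * r
        dist[i("neither")] = 1.0 - s * r
    return dist


def apply_intervention(
    dist: np.ndarray, spec: ScenarioSpec, p: ParameterSet
) -> tuple[np.ndarray, float]:
    """First-year cessation intervention overlay.

    The offer goes to in-prison vapers (vaping permitted) or pre-prison
    smokers (no vaping); a fraction engage, and engagers quit with the
    intervention's absolute quit probability.  The per-person cost is
    ``unit_cost × offered × engagement`` — always at most the unit cost.
    Returns the adjusted cycle-0 distribution and the per-person cost.
    """
    if not spec.intervention_offered:
        return dist.copy(), 0.0
    offered = p.p_vape_in_prison if spec.vaping_permitted else p.p_smoke_preprison
    engagement, quit = p.intervention_engagement, p.intervention_quit_effect
    cost = p.intervention_unit_cost * offered * engagement
    out = dist.copy()
    i = RELEASED_STATES.index
    moves = [("smoker", "former_smoker")]
    if spec.vaping_permitted:
        moves.append(("vaper", "former_vaper"))
    for src, dst in moves:
        moved = out[i(src)] * engagement * quit
        if moved > out[i(src)] + 1e-12:
            raise economics.ConfigurationError(
                f"intervention would move more mass than state {src!r} holds")
        out[i(src)] -= moved
        out[i(dst)] += moved
    return out, cost


def released_rr_by_state(p: ParameterSet) -> dict:
    """Mortality relative risks for released people.

    Everyone released carries the post-release excess; current smokers
    additionally carry the smoking excess.  Former smokers/vapers revert
    to background risk (a documented provisional assumption).
    """
    rr = {s: p.rr_mort_postrelease for s in RELEASED_STATES.living}
    rr["smoker"] = p.rr_mort_postrelease * p.rr_mort_smoker
    return rr


@dataclass
class ReleasedResults:
    """Trace plus economics for one released-person scenario."""

    spec: ScenarioSpec
    trace: CohortTrace
    outcome: economics.EconomicOutcome
    intervention_cost_per_person: float

    def summary(self) -> str:
        s = self.outcome.to_series()
        lines = [self.spec.describe(), "-" * 58]
        lines += [
            f"Healthcare cost (discounted)   £{s['healthcare']:>10,.0f}",
            f"Personal cost (discounted)     £{s['personal']:>10,.0f}"
            f"  ({s['personal_vaping'] / s['personal']:.0%} vape)"
            if s["personal"] else
            f"Personal cost (discounted)     £{s['personal']:>10,.0f}",
            f"Intervention cost              £{s['intervention']:>10,.0f}",
            f"Total cost (discounted)        £{s['total']:>10,.0f}",
            f"Life-years (discounted)        {s['life_years']:>11.2f}",
            f"QALYs (discounted)             {s['qalys']:>11.2f}",
            "Prevalence at release:",
        ]
        for state, share in self.outcome.prevalence_initial.items():
            if state != "dead":
                lines.append(f"  {state:<22s} {share:>6.1%}")
        return "\n".join(lines)


class ReleasedCohortModel:
    """Markov cohort model of one released-person scenario.

    Parameters
    ----------
    params : ParameterSet
        Full model input set.
    scenario : int or ScenarioSpec
        Which of the four policy scenarios to run.

    ``run()`` composes the release-status split, the first-year
    intervention overlay, the lifetime cohort run and the economic
    accumulation, returning :class:`ReleasedResults`.
    """

    def __init__(self, params: ParameterSet, scenario: int | ScenarioSpec):
        self.params = params
        self.spec = scenario if isinstance(scenario, ScenarioSpec) else ScenarioSpec(scenario)

    def run(self, half_cycle: bool = False) -> ReleasedResults:
        p = self.params
        dist = initial_distribution(self.spec, p)
        dist, cost = apply_intervention(dist, self.spec, p)
        trace = run_cohort(
            dist, p, RELEASED_STATES,
            start_age=p.start_age_released,
            sex=p.sex_released,
            rr_by_state=released_rr_by_state(p),
        )
        outcome = economics.accumulate(trace, p, first_cycle_intervention_cost=cost,
                                       half_cycle=half_cycle)
        return ReleasedResults(self.spec, trace, outcome, cost)


def run_released_scenario(
    spec: ScenarioSpec | int, p: ParameterSet, half_cycle: bool = False
) -> tuple[CohortTrace, economics.EconomicOutcome]:
    """Functional wrapper over :class:`ReleasedCohortModel`."""
    res = ReleasedCohortModel(p, spec).run(half_cycle=half_cycle)
    return res.trace, res.outcome
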