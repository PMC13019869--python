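"""Lifetime models for partners and children of released people.

Three household scenarios — the released person smokes, vapes, or does
neither — are run separately for each household member.  Partner status
is the member's own (general-population rates for women in the most
deprived neighbourhoods) and is not influenced by the released person;
the knock-on effect for partners is second-hand smoke (SHS): partners
who neither smoke nor vape occupy a distinct SHS-exposed state when the
released person smokes, which carries a small utility decrement, excess
healthcare cost and excess mortality.  Children (entering at age 15)
take up smoking/vaping with probabilities conditional on the released
person's status; no SHS state is applied to children.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import economics
from .engine import PARTNER_STATES, RELEASED_STATES, CohortTrace, run_cohort
from .parameters import ParameterSet

__all__ = [
    "RELEASED_STATUSES",
    "HouseholdScenario",
    "partner_initial_distribution",
    "child_initial_distribution",
    "HouseholdCohortModel",
    "HouseholdResults",
    "run_household_scenario",
]

RELEASED_STATUSES = ("smokes", "vapes", "neither")
MEMBERS = ("partner", "child")


@dataclass(frozen=True)
class HouseholdScenario:
    """Household member × released-person status."""

    member: str
    released_status: str

    def __post_init__(self):
        if self.member not in MEMBERS:
            raise ValueError(f"member must be one of {MEMBERS}")
        if self.released_status not in RELEASED_STATUSES:
            raise ValueError(f"released_status must be one of {RELEASED_STATUSES}")


def partner_initial_distribution(p: ParameterSet,
                                 scenario: HouseholdScenario) -> np.ndarray:
    """Partner occupancy at entry.

    Smoking/vaping by the partner's own rates, independent of the
    released person; the non-nicotine remainder sits in the SHS-exposed
    state if and only if the released person smokes.
    """
    if p.partner_p_smoke + p.partner_p_vape > 1.0:
        raise ValueError("partner smoking + vaping rates sum above 1")
    dist = np.zeros(len(PARTNER_STATES))
    i = PARTNER_STATES.index
    dist[i("smoker")] = p.partner_p_smoke
    dist[i("vaper")] = p.partner_p_vape
    rest = 1.0 - p.partner_p_smoke - p.partner_p_vape
    if scenario.released_status == "smokes":
        dist[i("neither_shs")] = rest
    else:
        dist[i("neither")] = rest
    return dist


def child_initial_distribution(p: ParameterSet,
                               scenario: HouseholdScenario) -> np.ndarray:
    """Child occupancy at entry (age 15), conditional on the released
    person's status via the uptake relative risks."""
    ps, pv = p.child_uptake(scenario.released_status)
    if ps + pv > 1.0:
        raise ValueError("child uptake probabilities sum above 1")
    dist = np.zeros(len(RELEASED_STATES))
    i = RELEASED_STATES.index
    dist[i("smoker")] = ps
    dist[i("vaper")] = pv
    dist[i("neither")] = 1.0 - ps - pv
    return dist


def _partner_rr(p: ParameterSet) -> dict:
    return {"smoker": p.rr_mort_smoker, "neither_shs": p.rr_mort_shs}


def _child_rr(p: ParameterSet) -> dict:
    return {"smoker": p.rr_mort_smoker}


@dataclass
class HouseholdResults:
    """Trace plus economics for one household member scenario."""

    scenario: HouseholdScenario
    trace: CohortTrace
    outcome: economics.EconomicOutcome

    def summary(self) -> str:
        s = self.outcome.to_series()
        head = (f"{self.scenario.member.capitalize()} living with a released "
                f"person who {'smokes' if self.scenario.released_status == 'smokes' else ('vapes' if self.scenario.released_status == 'vapes' else 'neither smokes nor vapes')}")
        lines = [head, "-" * len(head)]
        lines += [
            f"Healthcare cost (discounted)   £{s['healthcare']:>10,.0f}",
            f"Personal cost (discounted)     £{s['personal']:>10,.0f}",
            f"Total cost (discounted)        £{s['total']:>10,.0f}",
            f"Life-years (discounted)        {s['life_years']:>11.2f}",
            f"QALYs (discounted)             {s['qalys']:>11.2f}",
        ]
        return "\n".join(lines)


class HouseholdCohortModel:
    """Markov cohort model for a partner or child of a released person.

    Parameters
    ----------
    params : ParameterSet
    member : {"partner", "child"}
    released_status : {"smokes", "vapes", "neither"}
    """

    def __init__(self, params: ParameterSet, member: str, released_status: str):
        self.params = params
        self.scenario = HouseholdScenario(member, released_status)

    def run(self, half_cycle: bool = False) -> HouseholdResults:
        p = self.params
        if self.scenario.member == "partner":
            dist = partner_initial_distribution(p, self.scenario)
            trace = run_cohort(dist, p, PARTNER_STATES,
                               start_age=p.start_age_partner,
                               sex=p.sex_partner, rr_by_state=_partner_rr(p))
        else:
            dist = child_initial_distribution(p, self.scenario)
            trace = run_cohort(dist, p, RELEASED_STATES,
                               start_age=p.start_age_child,
                               sex=p.sex_child, rr_by_state=_child_rr(p))
        outcome = economics.accumulate(trace, p, half_cycle=half_cycle)
        return HouseholdResults(self.scenario, trace, outcome)


def run_household_scenario(
    scenario: HouseholdScenario, p: ParameterSet, half_cycle: bool = False
) -> tuple[CohortTrace, economics.EconomicOutcome]:
    """Functional wrapper over :class:`HouseholdCohortModel`."""
    res = HouseholdCohortModel(p, scenario.member, scenario.released_status).run(
        half_cycle=half_cycle)
    return res.trace, res.outcome
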