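"""Discounting, cost/QALY accumulation and cost-utility comparison.

Costs and utilities are attributed at cycle start (no half-cycle
correction by default, but ``half_cycle=True`` averages adjacent cycle
occupancies so its effect can be inspected).  Discounting uses the
standard ``1/(1+r)^t`` factor with year zero undiscounted.

A comparison between two scenarios reports the incremental cost ΔC,
incremental QALYs ΔQ, the ICER (ΔC/ΔQ) or a dominance label, and the
incremental net monetary benefit iNMB = λ·ΔQ − ΔC at willingness-to-pay
λ (here £20,000/QALY); iNMB > 0 indicates cost-effectiveness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CohortTrace, StateSpace
from .parameters import ConfigurationError, ParameterSet, age_band_value

__all__ = [
    "discount_factor",
    "CostBreakdown",
    "EconomicOutcome",
    "ComparisonResult",
    "accumulate_costs",
    "accumulate_outcomes",
    "accumulate",
    "compare_scenarios",
    "DOMINATED",
    "DOMINANT",
]

DOMINATED = "dominated (more costly and less effective)"
DOMINANT = "dominant (less costly and more effective)"


def discount_factor(rate: float, cycle: int):
    """``1/(1+rate)^cycle``; vectorised over ``cycle``; cycle 0 → 1."""
    cycle_arr = np.asarray(cycle)
    if np.any(cycle_arr < 0):
        raise ValueError("cycle must be non-negative")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    out = (1.0 + rate) ** -cycle_arr.astype(float)
    return float(out) if np.isscalar(cycle) else out


@dataclass
class CostBreakdown:
    """Discounted lifetime costs, split the way the published tables are."""

    healthcare: float = 0.0
    personal_smoking: float = 0.0
    personal_vaping: float = 0.0
    intervention: float = 0.0

    @property
    def personal(self) -> float:
        return self.personal_smoking + self.personal_vaping

    @property
    def total(self) -> float:
        return self.healthcare + self.personal + self.intervention


@dataclass
class EconomicOutcome:
    """Discounted costs, life-years and QALYs for one scenario run."""

    costs: CostBreakdown
    life_years: float
    qalys: float
    prevalence_initial: dict = field(default_factory=dict)
    prevalence_final: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return self.costs.total

    def to_series(self) -> pd.Series:
        return pd.Series({
            "healthcare": self.costs.healthcare,
            "personal_smoking": self.costs.personal_smoking,
            "personal_vaping": self.costs.personal_vaping,
            "personal": self.costs.personal,
            "intervention": self.costs.intervention,
            "total": self.total_cost,
            "life_years": self.life_years,
            "qalys": self.qalys,
        })


# --------------------------------------------------------------------------
# Per-state annual rates
# --------------------------------------------------------------------------


def _state_cost_vectors(p: ParameterSet, space: StateSpace, age: float):
    """(healthcare, smoking-spend, vaping-spend) £/year per state at ``age``."""
    mult = age_band_value(p.cost_age_bands, age)
    hc = np.zeros(len(space))
    smoke = np.zeros(len(space))
    vape = np.zeros(len(space))
    for i, s in enumerate(space.labels):
        if s == space.death_state:
            continue
        base = "neither" if s == "neither_shs" else s
        try:
            hc[i] = p.cost_healthcare_by_state[base] * mult
        except KeyError:
            raise ConfigurationError(f"no healthcare cost entry for state {base!r}")
        if s == "neither_shs":
            hc[i] += p.cost_healthcare_shs_excess * mult
        if s == "smoker":
            smoke[i] = p.cost_personal_smoking
        if s == "vaper":
            vape[i] = p.cost_personal_vaping
    return hc, smoke, vape


def _state_utility_vector(p: ParameterSet, space: StateSpace, age: float):
    mult = age_band_value(p.utility_age_bands, age)
    u = np.zeros(len(space))
    for i, s in enumerate(space.labels):
        if s == space.death_state:
            continue
        base = "neither" if s == "neither_shs" else s
        try:
            value = p.utility_by_state[base]
        except KeyError:
            raise ConfigurationError(f"no utility entry for living state {base!r}")
        if s == "neither_shs":
            value = max(0.0, value - p.utility_decrement_shs)
        u[i] = value * mult
    return u


def _cycle_occupancies(trace: CohortTrace, half_cycle: bool) -> np.ndarray:
    """Occupancy attributed to each lived cycle (rows 0..n_cycles-1)."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


# --------------------------------------------------------------------------
# Accumulation
# --------------------------------------------------------------------------


def accumulate_costs(
    trace: CohortTrace,
    p: ParameterSet,
    first_cycle_intervention_cost: float = 0.0,
    half_cycle: bool = False,
) -> CostBreakdown:
    """Discounted lifetime cost breakdown over a trace.

    Each cycle contributes ``Σ_state occupancy × annual cost × discount``;
    the intervention cost is a one-off added at cycle 0 (undiscounted).
    """
    occ = _cycle_occupancies(trace, half_cycle)
    cycles = np.arange(occ.shape[0])
    df = discount_factor(p.discount_rate_costs, cycles)
    out = CostBreakdown(intervention=float(first_cycle_intervention_cost))
    for t in range(occ.shape[0]):
        hc, smoke, vape = _state_cost_vectors(p, trace.space, trace.ages[t])
        out.healthcare += df[t] * float(occ[t] @ hc)
        out.personal_smoking += df[t] * float(occ[t] @ smoke)
        out.personal_vaping += df[t] * float(occ[t] @ vape)
    return out


def accumulate_outcomes(
    trace: CohortTrace,
    p: ParameterSet,
    half_cycle: bool = False,
) -> tuple[float, float]:
    """Discounted (life-years, QALYs) over a trace; QALYs ≤ life-years."""
    occ = _cycle_occupancies(trace, half_cycle)
    cycles = np.arange(occ.shape[0])
    df = discount_factor(p.discount_rate_outcomes, cycles)
    death = trace.space.death_index
    ly = float(np.sum(df * (1.0 - occ[:, death])))
    qaly = 0.0
    for t in range(occ.shape[0]):
        u = _state_utility_vector(p, trace.space, trace.ages[t])
        qaly += df[t] * float(occ[t] @ u)
    return ly, qaly


def accumulate(
    trace: CohortTrace,
    p: ParameterSet,
    first_cycle_intervention_cost: float = 0.0,
    half_cycle: bool = False,
) -> EconomicOutcome:
    """Full economic accumulation for one cohort trace."""
    costs = accumulate_costs(trace, p, first_cycle_intervention_cost, half_cycle)
    ly, qaly = accumulate_outcomes(trace, p, half_cycle)
    labels = trace.space.labels
    return EconomicOutcome(
        costs=costs,
        life_years=ly,
        qalys=qaly,
        prevalence_initial=dict(zip(labels, trace.occupancy[0])),
        prevalence_final=dict(zip(labels, trace.occupancy[-1])),
    )


# --------------------------------------------------------------------------
# Comparison
# --------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """Cost-utility comparison of scenario ``a`` minus scenario ``b``.

    ``label`` carries the dominance verdict where an ICER is not
    meaningful; dominance attaches to the first-listed scenario, matching
    the published table's direction.
    """

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str | None
    inmb: float
    wtp: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "icer_or_label": self.label if self.icer is None else self.icer,
            "inmb": self.inmb,
        })


def compare_scenarios(a: EconomicOutcome | float, b: EconomicOutcome | float,
                      wtp: float, *, delta_qalys: float | None = None) -> ComparisonResult:
    """Incremental comparison ``a − b`` at willingness-to-pay ``wtp``.

    Accepts either two :class:`EconomicOutcome` objects, or raw
    increments (``a`` = ΔC with ``delta_qalys`` = ΔQ) so the identity can
    be applied to externally reported numbers too.
    """
    if delta_qalys is None:
        dc = a.total_cost - b.total_cost
        dq = a.qalys - b.qalys
    else:
        dc, dq = float(a), float(delta_qalys)
    icer: float | None = None
    label: str | None = None
    if dc > 0 and dq < 0:
        label = DOMINATED
    elif dc < 0 and dq > 0:
        label = DOMINANT
    elif dq == 0.0:
        label = "cost difference only" if dc != 0.0 else "no difference"
    else:
        icer = dc / dq
    inmb = wtp * dq - dc
    return ComparisonResult(dc, dq, icer, label, inmb, wtp)
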