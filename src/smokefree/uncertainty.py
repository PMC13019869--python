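"""Probabilistic and deterministic sensitivity analysis.

The PSA draws one parameter set per iteration and evaluates *all*
scenarios on that shared draw (common random parameters across arms), so
the per-draw increments isolate scenario effects from parameter noise —
a requirement for a coherent cost-effectiveness plane.  Confidence
intervals are simple 2.5/97.5 percentiles of the draws.

The deterministic analyses mirror the published ones: a one-way
(tornado) analysis over the released-person parameters and a best/base/
worst-case sweep of child smoking/vaping uptake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .economics import ComparisonResult, compare_scenarios
from .household import HouseholdCohortModel, RELEASED_STATUSES
from .parameters import ConfigurationError, ParameterSet, sample_psa_draw
from .released import ReleasedCohortModel

__all__ = [
    "COMPARISONS",
    "PSAResult",
    "run_psa",
    "run_household_psa",
    "TornadoEntry",
    "one_way_sensitivity",
    "default_variations",
    "child_uptake_scenarios",
]

#: Published comparison pairs (first-listed minus second): 1 — vaping
#: permitted vs not, no intervention; 2 — no intervention vs intervention,
#: vaping permitted; 3 — no intervention vs intervention, no vaping.
COMPARISONS = {1: (1, 2), 2: (1, 3), 3: (2, 4)}

_FIELDS = ("healthcare", "personal_smoking", "personal_vaping",
           "intervention", "total", "life_years", "qalys")


def _outcome_row(outcome) -> tuple:
    c = outcome.costs
    return (c.healthcare, c.personal_smoking, c.personal_vaping,
            c.intervention, c.total, outcome.life_years, outcome.qalys)


@dataclass
class PSAResult:
    """Per-draw outcomes for the four released-person scenarios."""

    draws: dict            # scenario id -> DataFrame (n_draws × _FIELDS)
    wtp: float
    seed: int
    comparisons: dict = field(default_factory=lambda: dict(COMPARISONS))

    @property
    def n_draws(self) -> int:
        return len(next(iter(self.draws.values())))

    # -- summaries ---------------------------------------------------------

    def _column(self, scenario: int, column: str) -> pd.Series:
        frame = self.draws[scenario]
        if column == "personal":
            return frame["personal_smoking"] + frame["personal_vaping"]
        return frame[column]

    def mean(self, scenario: int, column: str) -> float:
        return float(self._column(scenario, column).mean())

    def ci(self, scenario: int, column: str, level: float = 95.0) -> tuple:
        lo, hi = np.percentile(self._column(scenario, column),
                               [(100 - level) / 2, 100 - (100 - level) / 2])
        return float(lo), float(hi)

    def delta(self, comparison: int, column: str) -> np.ndarray:
        a, b = self.comparisons[comparison]
        return (self._column(a, column) - self._column(b, column)).to_numpy()

    def inmb_draws(self, comparison: int) -> np.ndarray:
        return self.wtp * self.delta(comparison, "qalys") - self.delta(comparison, "total")

    def comparison_result(self, comparison: int) -> ComparisonResult:
        """Comparison built from the PSA mean increments."""
        dc = float(self.delta(comparison, "total").mean())
        dq = float(self.delta(comparison, "qalys").mean())
        return compare_scenarios(dc, None, self.wtp, delta_qalys=dq)

    def ce_plane(self) -> pd.DataFrame:
        """Cost-effectiveness plane points: one row per draw × comparison."""
        frames = []
        for comp in self.comparisons:
            frames.append(pd.DataFrame({
                "draw": np.arange(self.n_draws),
                "comparison": comp,
                "dQ": self.delta(comp, "qalys"),
                "dC": self.delta(comp, "total"),
            }))
        return pd.concat(frames, ignore_index=True)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for scen, frame in self.draws.items():
            for col in _FIELDS:
                lo, hi = self.ci(scen, col)
                rows.append({"scenario": scen, "quantity": col,
                             "mean": self.mean(scen, col), "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"PSA over {self.n_draws} draws (seed {self.seed}), "
                 f"WTP £{self.wtp:,.0f}/QALY"]
        for comp in self.comparisons:
            r = self.comparison_result(comp)
            lines.append(
                f"  Comparison {comp}: dC £{r.delta_cost:,.0f}, "
                f"dQ {r.delta_qalys:+.3f}, "
                f"{r.label if r.icer is None else f'ICER £{r.icer:,.0f}/QALY'}, "
                f"iNMB £{r.inmb:,.0f}")
        return "\n".join(lines)


def _draw_seeds(seed: int, n_draws: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_draws)


def run_psa(params: ParameterSet, n_draws: int, seed: int,
            scenarios=(1, 2, 3, 4)) -> PSAResult:
    """Probabilistic sensitivity analysis of the released-person model.

    Each draw samples one parameter set (seeded reproducibly from
    ``seed``) and evaluates every scenario on it.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    seeds = _draw_seeds(seed, n_draws)
    records = {s: [] for s in scenarios}
    for ds in seeds:
        draw = sample_psa_draw(params, int(ds))
        for s in scenarios:
            res = ReleasedCohortModel(draw, s).run()
            records[s].append(_outcome_row(res.outcome))
    draws = {s: pd.DataFrame(records[s], columns=_FIELDS) for s in scenarios}
    return PSAResult(draws=draws, wtp=params.wtp_threshold, seed=seed)


def run_household_psa(params: ParameterSet, n_draws: int, seed: int) -> pd.DataFrame:
    """PSA means and percentile CIs for every household member × status."""
    seeds = _draw_seeds(seed, n_draws)
    cells = [(m, st) for m in ("partner", "child") for st in RELEASED_STATUSES]
    records = {cell: [] for cell in cells}
    for ds in seeds:
        draw = sample_psa_draw(params, int(ds))
        for member, status in cells:
            res = HouseholdCohortModel(draw, member, status).run()
            records[(member, status)].append(_outcome_row(res.outcome))
    rows = []
    for (member, status), rec in records.items():
        frame = pd.DataFrame(rec, columns=_FIELDS)
        for col in _FIELDS:
            lo, hi = np.percentile(frame[col], [2.5, 97.5])
            rows.append({"member": member, "released_status": status,
                         "quantity": col, "mean": float(frame[col].mean()),
                         "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Deterministic sensitivity
# --------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    """iNMB per comparison for one parameter variation."""

    parameter: str
    value: object
    inmb: dict            # comparison id -> iNMB
    label: str = ""

    def shift(self, base: "TornadoEntry", comparison: int) -> float:
        return self.inmb[comparison] - base.inmb[comparison]


def _evaluate_inmb(p: ParameterSet) -> dict:
    outcomes = {s: ReleasedCohortModel(p, s).run().outcome for s in (1, 2, 3, 4)}
    return {
        comp: compare_scenarios(outcomes[a], outcomes[b], p.wtp_threshold).inmb
        for comp, (a, b) in COMPARISONS.items()
    }


def _apply_variation(p: ParameterSet, parameter: str, value) -> ParameterSet:
    out = p.copy()
    if parameter == "intervention_level":
        level = p.intervention_levels[value]
        out.intervention_unit_cost = level["unit_cost"]
        out.intervention_quit_effect = level["quit_effect"]
        return out
    try:
        out.set(parameter, value)
    except ConfigurationError:
        raise ConfigurationError(f"unknown parameter {parameter!r} in variation")
    return out


def default_variations(p: ParameterSet) -> list:
    """The published one-way variations: vaping prevalence in prison,
    relapse on release (vaping-permitted arms), vaping harms, intervention
    engagement, and intervention intensity."""
    return [
        ("p_vape_in_prison", 0.60),
        ("p_relapse_vaper", 0.50),
        ("cost_healthcare_by_state.vaper", 2 * p.cost_healthcare_by_state["vaper"]),
        ("utility_by_state.vaper", max(0.0, p.utility_by_state["vaper"] - 0.02)),
        ("intervention_engagement", 0.66),
        ("intervention_level", "low"),
        ("intervention_level", "high"),
    ]


def one_way_sensitivity(p: ParameterSet, variations=None) -> list:
    """Re-run the three comparisons once per variation, all else at base.

    Returns a list of :class:`TornadoEntry` with the base case first;
    entries sort naturally by absolute iNMB shift for tornado layout.
    """
    if variations is None:
        variations = default_variations(p)
    entries = [TornadoEntry("base", None, _evaluate_inmb(p), label="base case")]
    for parameter, value in variations:
        varied = _apply_variation(p, parameter, value)
        entries.append(TornadoEntry(parameter, value, _evaluate_inmb(varied),
                                    label=f"{parameter}={value}"))
    return entries


def tornado_frame(entries: list) -> pd.DataFrame:
    """Flat export: ``parameter, value, comparison, inmb``."""
    rows = []
    for e in entries:
        for comp, inmb in e.inmb.items():
            rows.append({"parameter": e.parameter, "value": e.value,
                         "comparison": comp, "inmb": inmb})
    return pd.DataFrame(rows)


#: Published best / base / worst child uptake baselines.
CHILD_UPTAKE_CASES = {"best": 0.076, "base": 0.152, "worst": 0.228}


def child_uptake_scenarios(p: ParameterSet, cases=None) -> pd.DataFrame:
    """Child-with-smoking-parent outcomes under best/base/worst uptake.

    The case value replaces the baseline ever-uptake rate (both smoking
    and vaping), scaled as usual by the parental-status relative risks.
    """
    cases = dict(CHILD_UPTAKE_CASES if cases is None else cases)
    rows = []
    for name, uptake in cases.items():
        varied = p.evolve(child_uptake_base_smoke=uptake,
                          child_uptake_base_vape=uptake)
        res = HouseholdCohortModel(varied, "child", "smokes").run()
        s = res.outcome.to_series()
        rows.append({"case": name, "uptake": uptake,
                     "healthcare": s["healthcare"], "personal": s["personal"],
                     "total": s["total"], "life_years": s["life_years"],
                     "qalys": s["qalys"]})
    return pd.DataFrame(rows).set_index("case")
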