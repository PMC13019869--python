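"""Result tables mirroring the published layout.

Currency is rendered to the nearest pound and QALYs/life-years to two
decimals; everything is held at full precision internally and only
rounded at the rendering edge.
"""

from __future__ import annotations

import pandas as pd

from .economics import ComparisonResult
from .household import HouseholdResults
from .released import ReleasedResults
from .uncertainty import COMPARISONS, PSAResult

__all__ = [
    "released_table",
    "comparison_table",
    "household_table",
    "render_tables",
]

_PREVALENCE_LABELS = {
    "neither": "Non-nicotine",
    "neither_shs": "Non-nicotine (exposed to SHS)",
    "smoker": "Person who smokes",
    "former_smoker": "Person who used to smoke",
    "vaper": "Person who vapes",
    "former_vaper": "Person who used to vape",
}


def _outcome_column(outcome, psa: PSAResult | None = None,
                    scenario: int | None = None) -> dict:
    s = outcome.to_series()

    def cell(key: str, money: bool) -> str:
        point = f"£{s[key]:,.0f}" if money else f"{s[key]:.2f}"
        if psa is not None and scenario is not None:
            lo, hi = psa.ci(scenario, "total" if key == "total" else key)
            band = (f" (95% CI £{lo:,.0f} to £{hi:,.0f})" if money
                    else f" (95% CI {lo:.2f} to {hi:.2f})")
            return point + band
        return point

    col = {
        "Healthcare £": cell("healthcare", True),
        "Personal £": cell("personal", True),
        "Intervention £": cell("intervention", True),
        "Total £": cell("total", True),
        "Life-years (discounted)": cell("life_years", False),
        "QALYs (discounted)": cell("qalys", False),
    }
    for state, label in _PREVALENCE_LABELS.items():
        if state in outcome.prevalence_initial:
            col[label] = f"{outcome.prevalence_initial[state]:.0%}"
    return col


def released_table(results: list[ReleasedResults],
                   psa: PSAResult | None = None) -> pd.DataFrame:
    """Four-scenario released-person table (rows: cost components,
    outcomes, prevalence)."""
    data = {}
    for res in results:
        name = f"Scenario {res.spec.scenario}"
        data[name] = _outcome_column(res.outcome, psa, res.spec.scenario)
    return pd.DataFrame(data)


def comparison_table(comparisons: dict[int, ComparisonResult]) -> pd.DataFrame:
    """Three pairwise cost-utility comparisons."""
    data = {}
    for comp, r in comparisons.items():
        a, b = COMPARISONS[comp]
        data[f"Comparison {comp} (S{a} v S{b})"] = {
            "Incremental cost £": f"£{r.delta_cost:,.0f}",
            "Incremental QALYs": f"{r.delta_qalys:.3f}",
            "Cost per QALY": (r.label if r.icer is None
                              else f"£{r.icer:,.0f}"),
            "iNMB £": f"£{r.inmb:,.0f}",
        }
    return pd.DataFrame(data)


def household_table(results: list[HouseholdResults]) -> pd.DataFrame:
    """Partner/child table across the three household scenarios."""
    status_label = {
        "neither": "lives with person who does not smoke or vape",
        "smokes": "lives with person who smokes",
        "vapes": "lives with person who vapes",
    }
    data = {}
    for res in results:
        name = f"{res.scenario.member}: {status_label[res.scenario.released_status]}"
        data[name] = _outcome_column(res.outcome)
    return pd.DataFrame(data)


def render_tables(bundle: dict) -> str:
    """Plain-text report from a result bundle.

    ``bundle`` maps section names to DataFrames (missing sections are
    listed rather than silently dropped).
    """
    expected = ("released", "comparisons", "household")
    missing = [k for k in expected if k not in bundle]
    lines = []
    for name, frame in bundle.items():
        lines.append(name.upper())
        lines.append("=" * len(name))
        lines.append(frame.to_string())
        lines.append("")
    if missing:
        lines.append(f"missing sections: {', '.join(missing)}")
    return "\n".join(lines)
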