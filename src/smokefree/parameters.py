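"""Parameter space for the smoke-free prison release models.

Everything numeric that drives the models lives in a single
:class:`ParameterSet`: initial smoking/vaping prevalences, post-release
relapse probabilities, annual behavioural transition probabilities,
life-table mortality with relative risks, per-state annual costs and
utilities, intervention characteristics, discount rates, the
willingness-to-pay threshold, and a probabilistic-sensitivity-analysis
(PSA) distribution specification per uncertain parameter.

Parameter files are human-editable YAML (see ``ParameterSet.save``) with
an optional flat table overlay (one row per scalar parameter:
``name,base_value,dist,arg1,arg2,source``).  Every value carries a
provenance tag (``printed`` for values anchored to the published
results, ``derived`` for values implied algebraically by published
tables, ``provisional`` for documented plausible-range choices, and
``file``/``sampled`` for values that arrived at run time).
"""

from __future__ import annotations

import copy
import dataclasses
import io
import math
import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

SCHEMA_VERSION = 1

__all__ = [
    "SchemaError",
    "ConfigurationError",
    "ParameterError",
    "PsaSpec",
    "LifeTable",
    "ParameterSet",
    "ValidationReport",
    "load_parameter_set",
    "validate_parameters",
    "sample_psa_draw",
    "load_parameter_table",
    "save_parameter_table",
]


class SchemaError(ValueError):
    """A parameter file does not conform to the documented schema."""


class ConfigurationError(ValueError):
    """A parameter set is internally inconsistent (e.g. unknown PSA family)."""


class ParameterError(ValueError):
    """A named parameter violates its invariant."""


# --------------------------------------------------------------------------
# PSA distribution specifications
# --------------------------------------------------------------------------

_PSA_FAMILIES = ("beta", "gamma", "lognormal", "lognormal1p")


@dataclass
class PsaSpec:
    """Uncertainty distribution for one parameter, in mean/sd form.

    Families follow standard health-economics practice: ``beta`` for
    probabilities and utilities, ``gamma`` for costs, ``lognormal`` for
    strictly positive ratios, and ``lognormal1p`` (1 + lognormal excess)
    for relative risks constrained to be at least 1.  Hyperparameters
    are recovered from the mean and standard deviation by method of
    moments, so a draw's expectation equals the base-case value.
    """

    dist: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.dist not in _PSA_FAMILIES:
            raise ConfigurationError(
                f"unsupported PSA distribution family {self.dist!r}; "
                f"expected one of {_PSA_FAMILIES}"
            )

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution (scalar unless ``size`` given)."""
        m, s = float(self.mean), float(self.sd)
        if s == 0.0:
            return m if size is None else np.full(size, m)
        if self.dist == "beta":
            if not 0.0 < m < 1.0:
                raise ConfigurationError(f"beta mean {m} outside (0, 1)")
            nu = m * (1.0 - m) / (s * s) - 1.0
            if nu <= 0:
                raise ConfigurationError(
                    f"beta sd {s} too large for mean {m} (variance exceeds m(1-m))"
                )
            return rng.beta(m * nu, (1.0 - m) * nu, size=size)
        if self.dist == "gamma":
            shape = (m / s) ** 2
            scale = s * s / m
            return rng.gamma(shape, scale, size=size)
        if self.dist in ("lognormal", "lognormal1p"):
            shift = 1.0 if self.dist == "lognormal1p" else 0.0
            me = m - shift
            if me <= 0:
                raise ConfigurationError(
                    f"{self.dist} mean {m} must exceed {shift}"
                )
            sigma2 = math.log(1.0 + (s / me) ** 2)
            mu = math.log(me) - sigma2 / 2.0
            return shift + rng.lognormal(mu, math.sqrt(sigma2), size=size)
        raise ConfigurationError(self.dist)  # pragma: no cover

    def to_dict(self) -> dict:
        return {"dist": self.dist, "mean": float(self.mean), "sd": float(self.sd)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PsaSpec":
        try:
            return cls(str(d["dist"]), float(d["mean"]), float(d["sd"]))
        except KeyError as exc:  # pragma: no cover - defensive
            raise SchemaError(f"PSA spec missing key {exc}") from exc


# --------------------------------------------------------------------------
# Life table
# --------------------------------------------------------------------------


class LifeTable:
    """Annual probability of death by age and sex.

    Built either from explicit rows (``from_frame``) or from
    Gompertz–Makeham coefficients ``q(a) = A + B·exp(C·a)``
    (``from_gompertz``).  Ages beyond the last tabulated row reuse the
    last row; ages below the first row reuse the first row.
    """

    def __init__(self, ages: np.ndarray, rates: dict[str, np.ndarray], spec: dict):
        self.ages = np.asarray(ages, dtype=int)
        self.rates = {k: np.asarray(v, dtype=float) for k, v in rates.items()}
        self.spec = spec
        for sex, q in self.rates.items():
            if q.shape != self.ages.shape:
                raise SchemaError(f"life table column {sex!r} length mismatch")
            if np.any((q < 0) | (q > 1)):
                raise ParameterError(f"life_table.{sex}: mortality outside [0, 1]")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_gompertz(
        cls,
        coefficients: Mapping[str, Mapping[str, float]],
        age_min: int = 0,
        age_max: int = 100,
    ) -> "LifeTable":
        ages = np.arange(age_min, age_max + 1)
        rates = {}
        for sex, c in coefficients.items():
            q = c["a"] + c["b"] * np.exp(c["c"] * ages)
            rates[sex] = np.clip(q, 0.0, 1.0)
        spec = {
            "kind": "gompertz_makeham",
            "coefficients": {s: dict(c) for s, c in coefficients.items()},
            "age_min": int(age_min),
            "age_max": int(age_max),
        }
        return cls(ages, rates, spec)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        if "age" not in frame.columns:
            raise SchemaError("life table frame requires an 'age' column")
        frame = frame.sort_values("age").reset_index(drop=True)
        ages = frame["age"].to_numpy(dtype=int)
        rates = {c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "age"}
        if not rates:
            raise SchemaError("life table frame has no sex columns")
        spec = {
            "kind": "table",
            "rows": [
                {"age": int(a), **{s: float(rates[s][i]) for s in rates}}
                for i, a in enumerate(ages)
            ],
        }
        return cls(ages, rates, spec)

    @classmethod
    def flat(cls, rate: float, sexes: Iterable[str] = ("male", "female"),
             age_min: int = 0, age_max: int = 100) -> "LifeTable":
        """Constant mortality at every age — handy for toy fixtures."""
        ages = np.arange(age_min, age_max + 1)
        rates = {s: np.full(ages.shape, float(rate)) for s in sexes}
        spec = {"kind": "flat", "rate": float(rate), "sexes": list(sexes),
                "age_min": int(age_min), "age_max": int(age_max)}
        return cls(ages, rates, spec)

    # -- queries -----------------------------------------------------------

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_mortality(self, age, sex: str):
        """q(age, sex); vectorised over ``age``, clamped to table range."""
        if sex not in self.rates:
            raise ParameterError(f"life table has no column for sex {sex!r}")
        idx = np.clip(np.asarray(age, dtype=int) - self.min_age, 0, len(self.ages) - 1)
        out = self.rates[sex][idx]
        return float(out) if np.isscalar(age) else out

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return copy.deepcopy(self.spec)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LifeTable":
        kind = d.get("kind")
        if kind == "gompertz_makeham":
            return cls.from_gompertz(d["coefficients"], d.get("age_min", 0),
                                     d.get("age_max", 100))
        if kind == "flat":
            return cls.flat(d["rate"], d.get("sexes", ("male", "female")),
                            d.get("age_min", 0), d.get("age_max", 100))
        if kind == "table":
            return cls.from_frame(pd.DataFrame(d["rows"]))
        raise SchemaError(f"unknown life table kind {kind!r}")

    def __eq__(self, other) -> bool:
        return isinstance(other, LifeTable) and self.spec == other.spec

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"LifeTable(kind={self.spec.get('kind')!r}, "
                f"ages {self.min_age}-{self.max_age}, sexes {sorted(self.rates)})")


# --------------------------------------------------------------------------
# The parameter set
# --------------------------------------------------------------------------

# Age-band schedules are lists of [age_from, value]; the value applying at an
# age is the one from the last band whose age_from does not exceed it.
AgeBands = list


def age_band_value(bands: AgeBands, age: float) -> float:
    value = bands[0][1]
    for age_from, v in bands:
        if age >= age_from:
            value = v
    return value


@dataclass
class ParameterSet:
    """Complete model input set (the shape of the published model's
    supplementary parameter table).

    Probabilities are annual unless stated otherwise; costs are GBP per
    year (2022 prices); utilities are on the 0–1 QALY scale where 0 is
    death and 1 is full health.
    """

    # demographics / horizon
    start_age_released: int = 35
    start_age_partner: int = 35
    start_age_child: int = 15
    max_age: int = 100
    sex_released: str = "male"
    sex_partner: str = "female"
    sex_child: str = "male"

    # release-status prevalences and relapse
    p_smoke_preprison: float = 0.70
    p_vape_in_prison: float = 0.76
    p_relapse_postrelease: float = 0.90   # pre-prison smokers, no-vaping policy
    p_relapse_vaper: float = 0.921        # in-prison vapers, vaping-permitted policy

    # annual behavioural transition probabilities (base case: status fixed)
    annual_quit_smoking: float = 0.0
    annual_relapse_former: float = 0.0
    annual_quit_vaping: float = 0.0
    annual_switch_vape_to_smoke: float = 0.0

    # household members
    partner_p_smoke: float = 0.21
    partner_p_vape: float = 0.10
    child_uptake_base_smoke: float = 0.152
    child_uptake_base_vape: float = 0.152
    child_rr_smoke_parent_smokes: float = 2.566
    child_rr_vape_parent_smokes: float = 1.776
    child_rr_smoke_parent_vapes: float = 1.974
    child_rr_vape_parent_vapes: float = 1.447

    # mortality
    life_table: LifeTable = field(default_factory=lambda: _DEFAULT_LIFE_TABLE())
    rr_mort_smoker: float = 2.0
    rr_mort_shs: float = 1.05
    rr_mort_postrelease: float = 1.5

    # costs (GBP/year at the reference age band)
    cost_healthcare_by_state: dict = field(default_factory=lambda: {
        "neither": 100.0, "smoker": 500.0, "former_smoker": 200.0,
        "vaper": 200.0, "former_vaper": 150.0,
    })
    cost_healthcare_shs_excess: float = 25.0
    cost_age_bands: AgeBands = field(default_factory=lambda: [
        [0, 0.5], [45, 1.0], [65, 1.8],
    ])
    cost_personal_smoking: float = 2000.0
    cost_personal_vaping: float = 600.0

    # intervention (first post-release year only)
    intervention_unit_cost: float = 112.0
    intervention_engagement: float = 0.505
    intervention_quit_effect: float = 0.052
    intervention_levels: dict = field(default_factory=lambda: {
        "low": {"unit_cost": 55.0, "quit_effect": 0.026},
        "medium": {"unit_cost": 112.0, "quit_effect": 0.052},
        "high": {"unit_cost": 225.0, "quit_effect": 0.104},
    })

    # utilities
    utility_by_state: dict = field(default_factory=lambda: {
        "neither": 0.88, "smoker": 0.79, "former_smoker": 0.85,
        "vaper": 0.84, "former_vaper": 0.85,
    })
    utility_decrement_shs: float = 0.02
    utility_age_bands: AgeBands = field(default_factory=lambda: [
        [0, 1.0], [45, 0.915], [65, 0.85], [75, 0.78],
    ])

    # economics
    discount_rate_costs: float = 0.035
    discount_rate_outcomes: float = 0.035
    wtp_threshold: float = 20000.0

    # PSA specification: dotted parameter path -> PsaSpec
    psa: dict = field(default_factory=dict)

    # provenance: dotted parameter path -> tag
    provenance: dict = field(default_factory=dict)

    # ---------------------------------------------------------------- paths

    def get(self, path: str):
        """Fetch a (possibly nested) parameter by dotted path."""
        obj: Any = self
        for part in path.split("."):
            if isinstance(obj, Mapping):
                if part not in obj:
                    raise ConfigurationError(f"unknown parameter {path!r}")
                obj = obj[part]
            else:
                if not hasattr(obj, part):
                    raise ConfigurationError(f"unknown parameter {path!r}")
                obj = getattr(obj, part)
        return obj

    def set(self, path: str, value) -> None:
        parts = path.split(".")
        obj: Any = self
        for part in parts[:-1]:
            obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
        last = parts[-1]
        if isinstance(obj, Mapping):
            if last not in obj:
                raise ConfigurationError(f"unknown parameter {path!r}")
            obj[last] = value
        else:
            if not hasattr(obj, last):
                raise ConfigurationError(f"unknown parameter {path!r}")
            setattr(obj, last, value)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def evolve(self, **changes) -> "ParameterSet":
        """Copy with dotted-path overrides, e.g. ``evolve(**{"utility_by_state.smoker": 0.8})``."""
        out = self.copy()
        for path, value in changes.items():
            out.set(path, value)
        return out

    # ------------------------------------------------------------- children

    def child_uptake(self, released_status: str) -> tuple[float, float]:
        """(smoking, vaping) uptake probabilities for a 15-year-old, by the
        released person's status."""
        rr = {
            "smokes": (self.child_rr_smoke_parent_smokes, self.child_rr_vape_parent_smokes),
            "vapes": (self.child_rr_smoke_parent_vapes, self.child_rr_vape_parent_vapes),
            "neither": (1.0, 1.0),
        }
        if released_status not in rr:
            raise ConfigurationError(f"unknown released-person status {released_status!r}")
        rs, rv = rr[released_status]
        return self.child_uptake_base_smoke * rs, self.child_uptake_base_vape * rv

    # spec-facing accessors (single-number view of the conditional uptakes)
    @property
    def child_uptake_given_parent_smokes(self) -> float:
        return self.child_uptake("smokes")[0]

    @property
    def child_uptake_given_parent_vapes(self) -> float:
        return self.child_uptake("vapes")[0]

    @property
    def child_uptake_given_parent_neither(self) -> float:
        return self.child_uptake("neither")[0]

    # --------------------------------------------------------- serialisation

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for f in dataclasses.fields(self):
            name = f.name
            value = getattr(self, name)
            if name == "life_table":
                d[name] = value.to_dict()
            elif name == "psa":
                d[name] = {k: v.to_dict() for k, v in sorted(value.items())}
            elif isinstance(value, dict):
                d[name] = copy.deepcopy(value)
            elif isinstance(value, list):
                d[name] = copy.deepcopy(value)
            else:
                d[name] = value
        return d

    @classmethod
    def from_dict(cls, d: Mapping, provenance_tag: str = "file") -> "ParameterSet":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema_version {version}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown parameter field(s): {sorted(unknown)}")
        base = cls()
        kwargs: dict[str, Any] = {}
        provenance = dict(base.provenance)
        file_provenance = dict(d.pop("provenance", {}))
        for name, value in d.items():
            if name == "life_table":
                kwargs[name] = LifeTable.from_dict(value)
            elif name == "psa":
                kwargs[name] = {k: PsaSpec.from_dict(v) for k, v in value.items()}
            else:
                kwargs[name] = copy.deepcopy(value)
            provenance[name] = provenance_tag
        for f in dataclasses.fields(cls):
            if f.name not in ("provenance", "psa"):
                provenance.setdefault(f.name, "default")
        # tags recorded in the file itself take precedence over the
        # generic load-time tag
        provenance.update(file_provenance)
        kwargs["provenance"] = provenance
        return dataclasses.replace(base, **kwargs)

    def save(self, path_or_stream) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=None)
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(text)
        else:
            with open(path_or_stream, "w") as fh:
                fh.write(text)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        a, b = self.to_dict(), other.to_dict()
        a.pop("provenance"), b.pop("provenance")
        return a == b

    # ------------------------------------------------------------ validation

    def validate(self) -> "ValidationReport":
        return validate_parameters(self)


def _DEFAULT_LIFE_TABLE() -> LifeTable:
    """UK-style national mortality approximated by Gompertz–Makeham fits."""
    return LifeTable.from_gompertz({
        "male": {"a": 6.0e-4, "b": 3.5e-5, "c": 0.092},
        "female": {"a": 4.0e-4, "b": 1.9e-5, "c": 0.094},
    })


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_PROBABILITY_FIELDS = (
    "p_smoke_preprison", "p_vape_in_prison", "p_relapse_postrelease",
    "p_relapse_vaper", "annual_quit_smoking", "annual_relapse_former",
    "annual_quit_vaping", "annual_switch_vape_to_smoke",
    "partner_p_smoke", "partner_p_vape",
    "child_uptake_base_smoke", "child_uptake_base_vape",
    "intervention_engagement", "intervention_quit_effect",
)

_RATIO_FIELDS = (
    "rr_mort_smoker", "rr_mort_shs", "rr_mort_postrelease",
    "child_rr_smoke_parent_smokes", "child_rr_vape_parent_smokes",
    "child_rr_smoke_parent_vapes", "child_rr_vape_parent_vapes",
)

_RATIO_GE1_FIELDS = ("rr_mort_smoker", "rr_mort_shs")

_COST_FIELDS = (
    "cost_personal_smoking", "cost_personal_vaping",
    "intervention_unit_cost", "cost_healthcare_shs_excess",
)


@dataclass
class ValidationReport:
    """List of invariant violations; empty iff the parameter set is valid."""

    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, field_name: str, message: str) -> None:
        self.violations.append((field_name, message))

    def raise_for_violations(self) -> None:
        if self.violations:
            lines = "; ".join(f"{f}: {m}" for f, m in self.violations)
            raise ParameterError(lines)

    def __str__(self) -> str:
        if self.ok:
            return "ValidationReport: all invariants hold"
        return "ValidationReport:\n" + "\n".join(
            f"  - {f}: {m}" for f, m in self.violations
        )


def validate_parameters(p: ParameterSet) -> ValidationReport:
    """Check every documented invariant; report rather than raise."""
    report = ValidationReport()
    for name in _PROBABILITY_FIELDS:
        v = p.get(name)
        if not 0.0 <= v <= 1.0:
            report.add(name, f"probability {v} outside [0, 1]")
    for name in _RATIO_FIELDS:
        v = p.get(name)
        if v < 0:
            report.add(name, f"ratio {v} is negative")
    for name in _RATIO_GE1_FIELDS:
        v = p.get(name)
        if v < 1.0:
            report.add(name, f"relative risk {v} below 1")
    for name in _COST_FIELDS:
        v = p.get(name)
        if v < 0:
            report.add(name, f"cost {v} is negative")
    for state, cost in p.cost_healthcare_by_state.items():
        if cost < 0:
            report.add(f"cost_healthcare_by_state.{state}", f"cost {cost} is negative")
    for state, u in p.utility_by_state.items():
        if not 0.0 <= u <= 1.0:
            report.add(f"utility_by_state.{state}", f"utility {u} outside [0, 1]")
    if not 0.0 <= p.utility_decrement_shs <= 1.0:
        report.add("utility_decrement_shs",
                   f"decrement {p.utility_decrement_shs} outside [0, 1]")
    if p.wtp_threshold <= 0:
        report.add("wtp_threshold", f"threshold {p.wtp_threshold} not positive")
    for name in ("discount_rate_costs", "discount_rate_outcomes"):
        v = p.get(name)
        if not 0.0 <= v <= 0.1:
            report.add(name, f"discount rate {v} outside [0, 0.1]")
    if p.partner_p_smoke + p.partner_p_vape > 1.0:
        report.add("partner_p_smoke", "partner smoking + vaping rates exceed 1")
    for status in ("smokes", "vapes", "neither"):
        ps, pv = p.child_uptake(status)
        if ps + pv > 1.0:
            report.add("child_uptake_base_smoke",
                       f"child uptake probabilities for status {status!r} sum above 1")
    min_start = min(p.start_age_released, p.start_age_partner, p.start_age_child)
    if p.life_table.min_age > min_start:
        report.add("life_table",
                   f"life table starts at age {p.life_table.min_age}, above the "
                   f"youngest cohort start age {min_start}")
    if p.max_age <= min_start:
        report.add("max_age", "horizon cap does not exceed the youngest start age")
    for band_field in ("cost_age_bands", "utility_age_bands"):
        bands = p.get(band_field)
        if not bands:
            report.add(band_field, "empty age-band schedule")
        elif any(b[1] < 0 for b in bands):
            report.add(band_field, "negative multiplier")
    for path, spec in p.psa.items():
        try:
            p.get(path)
        except ConfigurationError:
            report.add(f"psa.{path}", "PSA spec refers to an unknown parameter")
        if spec.sd < 0:
            report.add(f"psa.{path}", "negative standard deviation")
    return report


# --------------------------------------------------------------------------
# Loading / saving
# --------------------------------------------------------------------------


def load_parameter_set(source) -> ParameterSet:
    """Load a parameter file (YAML path, text, or stream).

    Missing entries are filled with the packaged defaults (provenance keeps
    track of which values came from the file).  A value violating its
    invariant raises :class:`ParameterError` naming the field; a file that
    does not parse raises :class:`SchemaError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise SchemaError(f"parameter file is not valid YAML: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise SchemaError("parameter file must be a mapping at the top level")
    params = ParameterSet.from_dict(data)
    params.validate().raise_for_violations()
    return params


def sample_psa_draw(p: ParameterSet, seed: int) -> ParameterSet:
    """One probabilistic-sensitivity-analysis draw.

    Every parameter with a PSA spec is replaced by a draw from its
    distribution; everything else is untouched.  Identical seeds give
    identical draws.  Parameters are sampled independently (the published
    analysis gives no correlation structure).
    """
    rng = np.random.default_rng(seed)
    out = p.copy()
    for path in sorted(p.psa):
        value = p.psa[path].sample(rng)
        out.set(path, float(value))
        out.provenance[path] = "sampled"
    return out


# --------------------------------------------------------------------------
# Flat table (one row per scalar parameter)
# --------------------------------------------------------------------------

_TABLE_COLUMNS = ["name", "base_value", "dist", "arg1", "arg2", "source"]


def save_parameter_table(p: ParameterSet, path_or_stream) -> None:
    """Export scalar parameters (and their PSA specs) as a flat CSV table."""
    rows = []
    for f in dataclasses.fields(p):
        name = f.name
        if name in ("life_table", "psa", "provenance", "intervention_levels",
                    "cost_age_bands", "utility_age_bands"):
            continue
        value = getattr(p, name)
        if isinstance(value, dict):
            items = [(f"{name}.{k}", v) for k, v in value.items()]
        else:
            items = [(name, value)]
        for path, v in items:
            if isinstance(v, str):
                continue
            spec = p.psa.get(path)
            rows.append({
                "name": path,
                "base_value": v,
                "dist": spec.dist if spec else "",
                "arg1": spec.mean if spec else "",
                "arg2": spec.sd if spec else "",
                "source": p.provenance.get(path, ""),
            })
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path_or_stream, index=False)


def load_parameter_table(path_or_stream, base: ParameterSet | None = None) -> ParameterSet:
    """Overlay a flat parameter table onto ``base`` (defaults if omitted)."""
    frame = pd.read_csv(path_or_stream)
    missing = set(_TABLE_COLUMNS[:2]) - set(frame.columns)
    if missing:
        raise SchemaError(f"parameter table missing column(s) {sorted(missing)}")
    if base is None:
        from .synthetic import default_parameters
        base = default_parameters()
    out = base.copy()
    for _, row in frame.iterrows():
        path = str(row["name"])
        try:
            out.set(path, float(row["base_value"]))
        except ConfigurationError:
            raise SchemaError(f"parameter table names unknown parameter {path!r}")
        out.provenance[path] = "file"
        dist = row.get("dist", "")
        if isinstance(dist, str) and dist:
            out.psa[path] = PsaSpec(dist, float(row["arg1"]), float(row["arg2"]))
    out.validate().raise_for_violations()
    return out
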