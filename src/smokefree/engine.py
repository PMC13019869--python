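"""Yearly-cycle cohort state-transition engine.

The engine advances a cohort's state-occupancy fractions through annual
cycles along an age axis.  Within a cycle mortality acts first (the
age- and sex-specific life-table probability times a per-state relative
risk product, capped at 1), then behavioural transitions (quitting,
relapse, switching) redistribute the survivors.  ``dead`` is absorbing.

A per-individual microsimulation (`microsim_oracle`) samples the same
transition matrices categorically; it exists as an independent oracle
for testing the matrix arithmetic, not as a modelling feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet

log = logging.getLogger(__name__)

LIVING_EXTINCTION = 1e-9  # stop cycling once this little of the cohort is alive

__all__ = [
    "StateSpace",
    "RELEASED_STATES",
    "PARTNER_STATES",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "microsim_oracle",
]


@dataclass(frozen=True)
class StateSpace:
    """Ordered state labels with a single absorbing death state."""

    labels: tuple
    death_state: str = "dead"

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("state labels must be unique")
        if self.labels.count(self.death_state) != 1:
            raise ValueError(f"exactly one {self.death_state!r} state required")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def death_index(self) -> int:
        return self.labels.index(self.death_state)

    @property
    def living(self) -> tuple:
        return tuple(s for s in self.labels if s != self.death_state)


RELEASED_STATES = StateSpace(
    ("neither", "smoker", "former_smoker", "vaper", "former_vaper", "dead"))

#: Partners gain a distinct non-nicotine state carrying second-hand-smoke
#: exposure; it is populated only when the released person smokes.
PARTNER_STATES = StateSpace(
    ("neither", "neither_shs", "smoker", "former_smoker", "vaper",
     "former_vaper", "dead"))


@dataclass
class CohortTrace:
    """State occupancy per cycle, with the cohort's age at each cycle.

    Row ``t`` of ``occupancy`` is the distribution at the *start* of cycle
    ``t``; row 0 is the initial distribution.
    """

    space: StateSpace
    occupancy: np.ndarray          # shape (n_cycles + 1, n_states)
    start_age: int
    ages: np.ndarray = field(init=False)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.ages = self.start_age + np.arange(self.occupancy.shape[0])

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.space.index(label)]

    def living(self) -> np.ndarray:
        return 1.0 - self.state(self.space.death_state)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per ``cycle, age, state, occupancy``."""
        t, s = self.occupancy.shape
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(t), s),
            "age": np.repeat(self.ages, s),
            "state": list(self.space.labels) * t,
            "occupancy": self.occupancy.ravel(),
        })


# --------------------------------------------------------------------------
# Transition matrices
# --------------------------------------------------------------------------


def _behavioural_matrix(space: StateSpace, p: ParameterSet) -> np.ndarray:
    """Annual transitions among survivors (rows sum to 1)."""
    n = len(space)
    B = np.eye(n)

    def move(src: str, dst: str, prob: float) -> None:
        i, j = space.index(src), space.index(dst)
        B[i, i] -= prob
        B[i, j] += prob

    if "smoker" in space.labels:
        move("smoker", "former_smoker", p.annual_quit_smoking)
        move("former_smoker", "smoker", p.annual_relapse_former)
    if "vaper" in space.labels:
        move("vaper", "former_vaper", p.annual_quit_vaping)
        move("vaper", "smoker", p.annual_switch_vape_to_smoke)
    if np.any(B < -1e-12):
        raise ValueError("behavioural transition probabilities sum above 1 "
                         "for at least one source state")
    return np.clip(B, 0.0, 1.0)


def build_transition_matrix(
    space: StateSpace,
    p: ParameterSet,
    age: int,
    sex: str = "male",
    rr_by_state: dict | None = None,
) -> np.ndarray:
    """Annual transition matrix at one age.

    Death probability from state ``s`` is ``q(age, sex) × rr_by_state[s]``
    capped at 1 (a warning is logged when the cap bites); the remaining
    mass follows the behavioural transitions.  The death row is identity.
    """
    if age < p.life_table.min_age:
        raise ValueError(f"age {age} below the life table range")
    rr_by_state = rr_by_state or {}
    q = p.life_table.annual_mortality(age, sex)
    B = _behavioural_matrix(space, p)
    d = np.array([q * rr_by_state.get(s, 1.0) for s in space.labels])
    if np.any(d > 1.0):
        log.warning("death probability capped at 1 at age %s (RR product)", age)
        d = np.minimum(d, 1.0)
    k = space.death_index
    M = B * (1.0 - d)[:, None]
    M[:, k] += d
    M[k, :] = 0.0
    M[k, k] = 1.0
    return M


def _mortality_vector(space: StateSpace, p: ParameterSet, ages: np.ndarray,
                      sex: str, rr_by_state: dict | None) -> np.ndarray:
    """Per-age, per-state death probabilities (cycles × states), capped."""
    rr_by_state = rr_by_state or {}
    q = p.life_table.annual_mortality(ages, sex)
    rr = np.array([rr_by_state.get(s, 1.0) for s in space.labels])
    rr[space.death_index] = 0.0
    d = np.minimum(np.outer(q, rr), 1.0)
    return d


# --------------------------------------------------------------------------
# Cohort runs
# --------------------------------------------------------------------------


def _check_initial(initial: np.ndarray, space: StateSpace) -> np.ndarray:
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (len(space),):
        raise ValueError(f"initial occupancy must have {len(space)} entries")
    if np.any(initial < 0) or abs(initial.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must be non-negative and sum to 1")
    return initial


def run_cohort(
    initial,
    p: ParameterSet,
    space: StateSpace = RELEASED_STATES,
    start_age: int = 35,
    horizon: int | None = None,
    sex: str = "male",
    rr_by_state: dict | None = None,
) -> CohortTrace:
    """Deterministic cohort run over yearly cycles.

    ``horizon`` defaults to a lifetime: cycles continue until ``max_age``
    or until living occupancy falls below ``LIVING_EXTINCTION``, whichever
    comes first.
    """
    initial = _check_initial(initial, space)
    if horizon is None:
        horizon = max(1, p.max_age - start_age)
    if horizon < 1:
        raise ValueError("horizon must be at least one cycle")
    ages = start_age + np.arange(horizon)
    d = _mortality_vector(space, p, ages, sex, rr_by_state)
    B = _behavioural_matrix(space, p)
    k = space.death_index
    rows = [initial]
    occ = initial
    for t in range(horizon):
        M = B * (1.0 - d[t])[:, None]
        M[:, k] += d[t]
        M[k, :] = 0.0
        M[k, k] = 1.0
        occ = occ @ M
        rows.append(occ)
        if 1.0 - occ[k] < LIVING_EXTINCTION:
            break
    return CohortTrace(space, np.array(rows), start_age)


def microsim_oracle(
    initial,
    p: ParameterSet,
    space: StateSpace = RELEASED_STATES,
    start_age: int = 35,
    horizon: int | None = None,
    n: int = 10_000,
    seed: int = 0,
    sex: str = "male",
    rr_by_state: dict | None = None,
) -> CohortTrace:
    """Individual-level simulation through the same transition matrices.

    Returns the empirical occupancy trace of ``n`` simulated people;
    identical seeds give identical traces.  Used as an independent check
    on :func:`run_cohort` (they agree within Monte-Carlo error).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    initial = _check_initial(initial, space)
    if horizon is None:
        horizon = max(1, p.max_age - start_age)
    rng = np.random.default_rng(seed)
    ages = start_age + np.arange(horizon)
    d = _mortality_vector(space, p, ages, sex, rr_by_state)
    B = _behavioural_matrix(space, p)
    k = space.death_index
    states = rng.choice(len(space), size=n, p=initial)
    counts = [np.bincount(states, minlength=len(space)) / n]
    for t in range(horizon):
        M = B * (1.0 - d[t])[:, None]
        M[:, k] += d[t]
        M[k, :] = 0.0
        M[k, k] = 1.0
        cum = np.cumsum(M, axis=1)
        u = rng.random(n)
        states = (u[:, None] > cum[states]).sum(axis=1)
        counts.append(np.bincount(states, minlength=len(space)) / n)
        if np.all(states == k):
            break
    return CohortTrace(space, np.array(counts), start_age)
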