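"""8-state Markov disease model in 30-day cycles.

States: the four index therapies (chemotherapy, immunotherapy,
chemo + immuno, targeted), a one-cycle interim-therapy bridge, disease
progression, next-line treatment, and death (absorbing).  One cohort enters
at the start of each model year, initialized across therapy states by the
decision tree's allocation; transition probabilities derive from 1-year
survival under a constant-hazard assumption, with progression and death as
competing risks (the per-cycle PFS-event probability minus the per-cycle
death probability, floored at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ScenarioParams, ParameterError, THERAPIES
from .testing_pathway import PathwayAllocation

__all__ = [
    "STATES",
    "STATE_INDEX",
    "annual_prob_to_cycle",
    "period_event_to_cycle",
    "competing_split",
    "build_transition_matrix",
    "run_cohorts",
    "pct_on_targeted",
    "CohortTrace",
]

STATES = (
    "chemo",
    "immuno",
    "chemo_immuno",
    "interim",
    "targeted",
    "progression",
    "next_line",
    "dead",
)
STATE_INDEX = {name: i for i, name in enumerate(STATES)}
DEAD = STATE_INDEX["dead"]


def annual_prob_to_cycle(
    survival_1yr: float, cycle_days: float = 30.0, days_per_year: float = 365.25
) -> float:
    """Per-cycle event probability from a 1-year survival, constant hazard.

    ``1 - s^(cycle_days/days_per_year)``; compounding over a full year of
    cycles recovers ``1 - s``.
    """
    if not (0.0 < survival_1yr <= 1.0):
        raise ValueError(f"survival_1yr must be in (0, 1], got {survival_1yr}")
    if cycle_days <= 0 or days_per_year <= 0:
        raise ValueError("cycle_days and days_per_year must be > 0")
    return 1.0 - survival_1yr ** (cycle_days / days_per_year)


def period_event_to_cycle(
    p_event: float, period_days: float, cycle_days: float = 30.0
) -> float:
    """Convert an event probability over ``period_days`` to a per-cycle one."""
    if not (0.0 <= p_event < 1.0):
        raise ValueError(f"p_event must be in [0, 1), got {p_event}")
    if period_days <= 0 or cycle_days <= 0:
        raise ValueError("period_days and cycle_days must be > 0")
    return 1.0 - (1.0 - p_event) ** (cycle_days / period_days)


def competing_split(
    pfs_1yr: float,
    os_1yr: float,
    cycle_days: float = 30.0,
    days_per_year: float = 365.25,
) -> tuple[float, float]:
    """Per-cycle (progression, death) probabilities from 1-year PFS and OS.

    PFS events include deaths, so the progression probability is the excess
    of the PFS-event probability over the death probability, floored at 0.
    """
    if pfs_1yr > os_1yr + 1e-12:
        raise ParameterError(
            f"PFS {pfs_1yr} exceeds OS {os_1yr}: PFS events include deaths"
        )
    p_death = annual_prob_to_cycle(os_1yr, cycle_days, days_per_year)
    p_event = annual_prob_to_cycle(pfs_1yr, cycle_days, days_per_year)
    return max(0.0, p_event - p_death), p_death


def build_transition_matrix(
    p: ModelParameters, alloc: PathwayAllocation | None = None
) -> np.ndarray:
    """Row-stochastic 8x8 per-cycle transition matrix.

    * therapy rows: stay / progress / die via :func:`competing_split`;
    * interim: exactly one cycle, then ``p_interim_switch`` of the survivors
      move to targeted therapy and the rest to progression; the interim
      death probability is the nontargeted-split-weighted average of the
      three nontargeted therapies' death probabilities;
    * progression and next-line exchange mass via the 3-month probabilities
      and die at the post-progression rate (chemotherapy OS unless
      overridden);
    * dead is absorbing.

    ``alloc`` is accepted for signature symmetry with the cohort runner but
    the matrix depends only on the parameters.
    """
    g = p.gaps
    cd, dpy = g.cycle_days, g.days_per_year
    n = len(STATES)
    M = np.zeros((n, n))

    p_death: dict[str, float] = {}
    for therapy in THERAPIES:
        pp, pd_ = competing_split(p.clinical.pfs_1yr[therapy], p.clinical.os_1yr[therapy], cd, dpy)
        p_death[therapy] = pd_
        i = STATE_INDEX[therapy]
        M[i, STATE_INDEX["progression"]] = pp
        M[i, DEAD] = pd_
        M[i, i] = 1.0 - pp - pd_

    # interim: one-cycle bridge on a nontargeted therapy mix
    s = p.splits
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 0:
        pd_interim = (
            s.p_chemo_nontargeted * p_death["chemo"]
            + s.p_immuno_nontargeted * p_death["immuno"]
            + s.p_chemoimmuno_nontargeted * p_death["chemo_immuno"]
        ) / triple
    else:
        pd_interim = p_death["chemo"]
    i = STATE_INDEX["interim"]
    M[i, DEAD] = pd_interim
    M[i, STATE_INDEX["targeted"]] = s.p_interim_switch * (1.0 - pd_interim)
    M[i, STATE_INDEX["progression"]] = (1.0 - s.p_interim_switch) * (1.0 - pd_interim)

    os_post = p.clinical.os_1yr_postprogression
    if os_post is None:
        os_post = p.clinical.os_1yr["chemo"]
    pd_post = annual_prob_to_cycle(os_post, cd, dpy)
    quarter = dpy / 4.0

    i = STATE_INDEX["progression"]
    p_next = period_event_to_cycle(p.clinical.p_prog_to_nextline_3mo, quarter, cd)
    M[i, DEAD] = pd_post
    M[i, STATE_INDEX["next_line"]] = (1.0 - pd_post) * p_next
    M[i, i] = 1.0 - pd_post - M[i, STATE_INDEX["next_line"]]

    i = STATE_INDEX["next_line"]
    p_back = period_event_to_cycle(p.clinical.p_nextline_to_prog_3mo, quarter, cd)
    M[i, DEAD] = pd_post
    M[i, STATE_INDEX["progression"]] = (1.0 - pd_post) * p_back
    M[i, i] = 1.0 - pd_post - M[i, STATE_INDEX["progression"]]

    M[DEAD, DEAD] = 1.0

    if (M < -1e-15).any():
        bad = np.argwhere(M < -1e-15)[0]
        raise ParameterError(
            f"negative transition probability from {STATES[bad[0]]} to {STATES[bad[1]]}"
        )
    M = np.clip(M, 0.0, None)
    rows = M.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ParameterError("transition matrix rows do not sum to 1")
    return M


@dataclass
class CohortTrace:
    """Expected state occupancy per entry cohort and 30-day cycle.

    ``occupancy[c, t, s]`` is the expected patient count of cohort ``c`` in
    state ``s`` at the start of cycle ``t`` (zero before the cohort enters).
    Lost-to-second-opinion patients never enter the Markov model and are
    carried separately.
    """

    occupancy: np.ndarray  # (n_cohorts, n_cycles + 1, 8)
    entry_cycles: np.ndarray  # (n_cohorts,)
    lost_per_cohort: np.ndarray  # (n_cohorts,)
    cohort_size: float
    cycles_per_year: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[1] - 1

    @property
    def n_cohorts(self) -> int:
        return self.occupancy.shape[0]

    @property
    def total_entered(self) -> float:
        return self.cohort_size * self.n_cohorts

    def total_occupancy(self, cycle: int) -> np.ndarray:
        """State totals over all cohorts that have entered by ``cycle``."""
        self._check_cycle(cycle)
        return self.occupancy[:, cycle, :].sum(axis=0)

    def alive(self, cycle: int) -> float:
        """Patients in any non-dead state at ``cycle`` (lost excluded)."""
        totals = self.total_occupancy(cycle)
        return float(totals.sum() - totals[DEAD])

    def entered_by(self, cycle: int) -> float:
        self._check_cycle(cycle)
        return float(self.cohort_size * (self.entry_cycles <= cycle).sum())

    def _check_cycle(self, cycle: int) -> None:
        if not (0 <= cycle <= self.n_cycles):
            raise IndexError(f"cycle {cycle} outside horizon [0, {self.n_cycles}]")

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cohort, cycle, state, count) table."""
        c, t, s = self.occupancy.shape
        idx = pd.MultiIndex.from_product(
            [range(c), range(t), STATES], names=["cohort", "cycle", "state"]
        )
        return pd.DataFrame({"count": self.occupancy.reshape(-1)}, index=idx).reset_index()


def run_cohorts(
    p: ModelParameters, scenario: ScenarioParams, alloc: PathwayAllocation
) -> CohortTrace:
    """Propagate one entering cohort per model year to the horizon end.

    Cohorts enter at the cycle boundary nearest past each year start
    (ceil of ``year x cycles/year``); each is initialized across therapy
    states per the allocation (lost patients excluded) and propagated with
    the time-homogeneous transition matrix to the end of the horizon.
    """
    if scenario.horizon_years < 1:
        raise ParameterError("scenario.horizon_years must be >= 1")
    g = p.gaps
    cpy = g.days_per_year / g.cycle_days
    horizon = int(scenario.horizon_years)
    n_cycles = math.ceil(horizon * cpy - 1e-9)
    entry_cycles = np.array([math.ceil(y * cpy - 1e-9) for y in range(horizon)])

    size = scenario.patients_per_year
    entry = np.zeros(len(STATES))
    entry[STATE_INDEX["chemo"]] = size * alloc.mass_chemo
    entry[STATE_INDEX["immuno"]] = size * alloc.mass_immuno
    entry[STATE_INDEX["chemo_immuno"]] = size * alloc.mass_chemoimmuno
    entry[STATE_INDEX["interim"]] = size * alloc.mass_interim
    entry[STATE_INDEX["targeted"]] = size * alloc.mass_targeted_direct

    M = build_transition_matrix(p, alloc)
    occ = np.zeros((horizon, n_cycles + 1, len(STATES)))
    for c, t0 in enumerate(entry_cycles):
        occ[c, t0] = entry
        for t in range(t0, n_cycles):
            occ[c, t + 1] = occ[c, t] @ M
    return CohortTrace(
        occupancy=occ,
        entry_cycles=entry_cycles,
        lost_per_cohort=np.full(horizon, size * alloc.mass_lost_second_opinion),
        cohort_size=size,
        cycles_per_year=cpy,
    )


def pct_on_targeted(
    trace: CohortTrace, at: int | None = None, denominator: str = "alive"
) -> float:
    """Percentage of patients in the targeted state at a cycle.

    ``denominator="alive"`` (default) divides by patients alive and retained
    at the cycle -- the share of the hospital's ongoing caseload on targeted
    therapy; ``"entered"`` divides by all patients entered by that cycle.
    """
    if at is None:
        at = trace.n_cycles
    totals = trace.total_occupancy(at)
    targeted = totals[STATE_INDEX["targeted"]]
    if denominator == "alive":
        denom = trace.alive(at)
    elif denominator == "entered":
        denom = trace.entered_by(at)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return 100.0 * targeted / denom
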