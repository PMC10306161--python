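"""Cost, revenue, ROI and payback accounting.

Costs are testing fees (per billed test) plus the one-off machine
acquisition at time 0 in any scenario that uses in-house testing.  Revenue
is test reimbursement (in-house tests only; send-out tests are billed by
the external laboratory) plus hospital-visit revenue for every 30-day cycle
a retained patient is alive.  Yearly flows are discounted end-of-year at
the annual rate; the time-0 acquisition is undiscounted.  ROI is the
incremental (revenue - cost) of the proposed scenario versus the current
one; the payback period is found on a monthly grid with each year's flows
spread uniformly across its 12 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ScenarioParams, ParameterError
from .testing_pathway import pathway_distribution, mean_turnaround, PathwayAllocation
from .disease_model import run_cohorts, pct_on_targeted, CohortTrace, DEAD

__all__ = [
    "BudgetLedger",
    "RoiResult",
    "discount_factor",
    "testing_costs",
    "revenues",
    "build_ledger",
    "roi_timeline",
    "payback_period",
    "run_analysis",
]

#: Sentinel returned when the cumulative net stream never reaches zero.
BEYOND_HORIZON = None


def discount_factor(year_index: int, rate: float) -> float:
    """End-of-year discount factor ``(1 + rate)^-year_index``.

    ``year_index`` counts from 1 for the first model year; time-0 outlays
    (machine acquisition) are not discounted.
    """
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    return (1.0 + rate) ** (-year_index)


@dataclass
class BudgetLedger:
    """Per-year cost and revenue streams for one scenario.

    Yearly arrays are undiscounted; discounted variants apply end-of-year
    factors.  The acquisition outlay sits at time 0 and is included in cost
    totals undiscounted.
    """

    horizon_years: int
    rate: float
    testing_cost: np.ndarray = field(default=None)  # (H,)
    acquisition_cost_t0: float = 0.0
    reimbursement: np.ndarray = field(default=None)  # (H,)
    visit_revenue: np.ndarray = field(default=None)  # (H,)

    def __post_init__(self) -> None:
        H = self.horizon_years
        for name in ("testing_cost", "reimbursement", "visit_revenue"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(H))
            else:
                arr = np.asarray(getattr(self, name), dtype=float)
                if arr.shape != (H,):
                    raise ParameterError(f"{name} must have one entry per year")
                setattr(self, name, arr)

    @property
    def factors(self) -> np.ndarray:
        return np.array(
            [discount_factor(y, self.rate) for y in range(1, self.horizon_years + 1)]
        )

    def discounted(self, stream: str) -> np.ndarray:
        return getattr(self, stream) * self.factors

    @property
    def cost_yearly(self) -> np.ndarray:
        return self.testing_cost

    @property
    def revenue_yearly(self) -> np.ndarray:
        return self.reimbursement + self.visit_revenue

    @property
    def cost_total_discounted(self) -> float:
        return float(self.acquisition_cost_t0 + self.discounted("testing_cost").sum())

    @property
    def cost_total_undiscounted(self) -> float:
        return float(self.acquisition_cost_t0 + self.testing_cost.sum())

    @property
    def revenue_total_discounted(self) -> float:
        return float((self.revenue_yearly * self.factors).sum())

    @property
    def revenue_total_undiscounted(self) -> float:
        return float(self.revenue_yearly.sum())

    def merge(self, other: "BudgetLedger") -> "BudgetLedger":
        """Combine two partial ledgers (e.g. cost-only and revenue-only)."""
        if (self.horizon_years, self.rate) != (other.horizon_years, other.rate):
            raise ParameterError("cannot merge ledgers with different horizon/rate")
        return BudgetLedger(
            horizon_years=self.horizon_years,
            rate=self.rate,
            testing_cost=self.testing_cost + other.testing_cost,
            acquisition_cost_t0=self.acquisition_cost_t0 + other.acquisition_cost_t0,
            reimbursement=self.reimbursement + other.reimbursement,
            visit_revenue=self.visit_revenue + other.visit_revenue,
        )

    def to_frame(self) -> pd.DataFrame:
        f = self.factors
        return pd.DataFrame(
            {
                "year": np.arange(1, self.horizon_years + 1),
                "testing_cost": self.testing_cost,
                "testing_cost_discounted": self.testing_cost * f,
                "reimbursement": self.reimbursement,
                "reimbursement_discounted": self.reimbursement * f,
                "visit_revenue": self.visit_revenue,
                "visit_revenue_discounted": self.visit_revenue * f,
            }
        )


@dataclass
class RoiResult:
    """Incremental results of proposed vs current scenario."""

    yearly_roi: np.ndarray  # discounted, acquisition attributed to year 1
    yearly_roi_undiscounted: np.ndarray
    cumulative_roi_discounted: float
    cumulative_roi_undiscounted: float
    payback_months: int | None


def testing_costs(
    p: ModelParameters, scenario: ScenarioParams, tests: dict[str, float]
) -> BudgetLedger:
    """Cost-side ledger: per-year billed testing fees plus acquisition.

    Any scenario with a positive in-house fraction carries the machine
    acquisition cost once at time 0.
    """
    m = p.money
    per_patient = (
        tests.get("inhouse", 0.0) * m.cost_inhouse_test
        + tests.get("sendout", 0.0) * m.cost_sendout_test
        + tests.get("singlegene", 0.0) * m.cost_singlegene_test
    )
    yearly = np.full(scenario.horizon_years, scenario.patients_per_year * per_patient)
    acquisition = m.cost_machine_acquisition if scenario.frac_inhouse > 0 else 0.0
    return BudgetLedger(
        horizon_years=scenario.horizon_years,
        rate=scenario.discount_rate_annual,
        testing_cost=yearly,
        acquisition_cost_t0=acquisition,
    )


def revenues(
    p: ModelParameters,
    scenario: ScenarioParams,
    trace: CohortTrace,
    tests: dict[str, float],
) -> BudgetLedger:
    """Revenue-side ledger: in-house test reimbursement plus visit revenue.

    Visit revenue accrues for every cycle a retained patient is alive
    (``visits_per_cycle`` visits at the per-visit price), assigned to the
    calendar year containing the cycle; patients lost to second opinion
    leave before any visit.
    """
    H = scenario.horizon_years
    m = p.money
    reimb = np.full(
        H, scenario.patients_per_year * tests.get("inhouse", 0.0) * m.reimb_inhouse_test
    )
    visit = np.zeros(H)
    per_cycle_value = m.visits_per_cycle * m.revenue_hospital_visit
    for t in range(trace.n_cycles):
        year = min(int(t / trace.cycles_per_year), H - 1)
        visit[year] += trace.alive(t) * per_cycle_value
    return BudgetLedger(
        horizon_years=H,
        rate=scenario.discount_rate_annual,
        reimbursement=reimb,
        visit_revenue=visit,
    )


def build_ledger(
    p: ModelParameters, scenario: ScenarioParams
) -> tuple[BudgetLedger, PathwayAllocation, CohortTrace]:
    """Full ledger for one scenario, with the intermediates it used."""
    alloc = pathway_distribution(p, scenario)
    tests = {
        "inhouse": alloc.tests_inhouse,
        "sendout": alloc.tests_sendout,
        "singlegene": alloc.tests_singlegene,
    }
    trace = run_cohorts(p, scenario, alloc)
    ledger = testing_costs(p, scenario, tests).merge(revenues(p, scenario, trace, tests))
    return ledger, alloc, trace


def roi_timeline(current: BudgetLedger, proposed: BudgetLedger) -> RoiResult:
    """Incremental (revenue - cost) streams, yearly and cumulative.

    The acquisition-cost difference is attributed to the first model year in
    the yearly view and to month 0 on the monthly payback grid.
    """
    if (current.horizon_years, ) != (proposed.horizon_years, ):
        raise ParameterError("ledgers cover different horizons")
    if current.rate != proposed.rate:
        raise ParameterError("ledgers use different discount rates")
    d_rev_u = proposed.revenue_yearly - current.revenue_yearly
    d_cost_u = proposed.cost_yearly - current.cost_yearly
    d_acq = proposed.acquisition_cost_t0 - current.acquisition_cost_t0
    f = current.factors

    yearly_u = d_rev_u - d_cost_u
    yearly_u[0] -= d_acq
    yearly_d = (d_rev_u - d_cost_u) * f
    yearly_d[0] -= d_acq  # time-0 outlay, undiscounted

    monthly = np.repeat((d_rev_u - d_cost_u) / 12.0, 12)
    cumulative_monthly = np.concatenate(([-d_acq], -d_acq + np.cumsum(monthly)))
    return RoiResult(
        yearly_roi=yearly_d,
        yearly_roi_undiscounted=yearly_u,
        cumulative_roi_discounted=float(yearly_d.sum()),
        cumulative_roi_undiscounted=float(yearly_u.sum()),
        payback_months=payback_period(cumulative_monthly),
    )


def payback_period(cumulative_monthly_net: np.ndarray) -> int | None:
    """First whole month at which the cumulative net stream reaches zero.

    The input is the cumulative incremental net cash position at month
    0, 1, 2, ...; crossings are located by linear interpolation and rounded
    to whole months.  Returns ``None`` when break-even is never reached
    within the stream ("beyond horizon").
    """
    cum = np.asarray(cumulative_monthly_net, dtype=float)
    if cum.size == 0:
        raise ParameterError("empty cumulative stream")
    if cum[0] >= 0:
        return 0
    above = np.nonzero(cum >= 0)[0]
    if above.size == 0:
        return BEYOND_HORIZON
    i = int(above[0])
    frac = (0.0 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return int(round((i - 1) + frac))


def run_analysis(p: ModelParameters, pct_denominator: str = "alive") -> dict:
    """Run both scenarios end to end and summarize the headline outcomes."""
    cur, alloc_cur, trace_cur = build_ledger(p, p.scenario_current)
    pro, alloc_pro, trace_pro = build_ledger(p, p.scenario_proposed)
    roi = roi_timeline(cur, pro)
    H = p.scenario_current.horizon_years
    lost_cur = float(trace_cur.lost_per_cohort.sum())
    lost_pro = float(trace_pro.lost_per_cohort.sum())
    pct_cur = pct_on_targeted(trace_cur, denominator=pct_denominator)
    pct_pro = pct_on_targeted(trace_pro, denominator=pct_denominator)
    return {
        "testing_cost_current": cur.cost_total_discounted,
        "testing_cost_proposed": pro.cost_total_discounted,
        "testing_cost_difference": pro.cost_total_discounted - cur.cost_total_discounted,
        "revenue_current": cur.revenue_total_discounted,
        "revenue_proposed": pro.revenue_total_discounted,
        "revenue_difference": pro.revenue_total_discounted - cur.revenue_total_discounted,
        "roi_discounted": roi.cumulative_roi_discounted,
        "roi_undiscounted": roi.cumulative_roi_undiscounted,
        "yearly_roi": roi.yearly_roi,
        "payback_months": roi.payback_months,
        "tat_current": mean_turnaround(p, p.scenario_current),
        "tat_proposed": mean_turnaround(p, p.scenario_proposed),
        "tat_reduction": (
            mean_turnaround(p, p.scenario_current) - mean_turnaround(p, p.scenario_proposed)
        ),
        "pct_targeted_current": pct_cur,
        "pct_targeted_proposed": pct_pro,
        "pct_targeted_difference": pct_pro - pct_cur,
        "patients_lost_current": lost_cur,
        "patients_lost_proposed": lost_pro,
        "patients_retained_gain": lost_cur - lost_pro,
    }
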