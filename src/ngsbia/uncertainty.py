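"""Probabilistic, one-way and scenario sensitivity analyses, plus calibration.

The PSA re-runs the full pipeline for both scenarios with every uncertain
parameter drawn independently: Beta for probabilities and Gamma for costs
and durations, moment-matched so that the mean equals the point value and
the standard deviation is (high - low)/3.92, i.e. the range is read as an
approximate 95% interval; parameters without a published range carry the
default 10% band.  The one-way analysis additionally sweeps the in-house
testing proportion over its full operational range [0, 1] -- it is a
structural lever rather than a sampled uncertainty, so it appears in the
tornado but not in the PSA draws.

Calibration fits the gap parameters to the published base-case outputs with
a deterministic grid-plus-bisection coordinate search; the base-case ladder
fits, in order, the retest multiplier (current testing cost), the two
second-opinion probabilities (patients lost in each scenario), and the
visits-per-cycle factor (current revenue), each step holding earlier fits
fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ModelParameters,
    ParameterError,
    get_value,
    set_value,
    validate_parameters,
)
from .budget_engine import run_analysis

__all__ = [
    "PsaResult",
    "TornadoResult",
    "CalibrationSpec",
    "CalibrationTarget",
    "run_psa",
    "one_way_sa",
    "scenario_sweep",
    "calibrate",
    "calibrate_basecase",
    "BASECASE_TARGETS",
]

#: Published base-case outputs used as calibration targets (5-year horizon,
#: 500 patients/year, 3.5% discount): discounted current-scenario testing
#: cost and revenue, and patients lost to second opinion per scenario.
BASECASE_TARGETS = {
    "testing_cost_current": 680_080.0,
    "patients_lost_current": 173.0,
    "patients_lost_proposed": 64.0,
    "revenue_current": 11_741_432.0,
}

#: Outcomes recorded per PSA draw.
_PSA_OUTCOMES = (
    "roi",
    "roi_undiscounted",
    "payback_months",
    "tat_reduction_days",
    "pct_targeted_diff",
)

from .parameters import is_probability_path as _is_probability


def _draw_parameter(rng: np.random.Generator, path: str, point: float, lo: float, hi: float) -> float:
    """One PSA draw for a parameter: Beta for probabilities, Gamma otherwise."""
    sd = (hi - lo) / 3.92
    if sd <= 0:
        return point
    if _is_probability(path):
        var = sd * sd
        cap = point * (1.0 - point)
        if point <= 0.0 or point >= 1.0 or var >= cap:
            return point
        nu = cap / var - 1.0
        return float(rng.beta(point * nu, (1.0 - point) * nu))
    if point <= 0:
        return point
    shape = (point / sd) ** 2
    scale = sd * sd / point
    return float(rng.gamma(shape, scale))


def sample_parameters(p: ModelParameters, rng: np.random.Generator) -> ModelParameters:
    """Draw a full parameter set from the uncertainty distributions.

    Complement pairs are maintained by :func:`~ngsbia.parameters.set_value`;
    draws that would break a structural constraint (nontargeted split
    summing above 1, PFS above OS, inverted turnaround range) are repaired
    by rescaling/clipping so every draw is a valid model input.
    """
    q = p.copy()
    for path in sorted(p.uncertainty):
        lo, hi = p.uncertainty[path]
        point = get_value(p, path)
        set_value(q, path, _draw_parameter(rng, path, point, lo, hi))
    s = q.splits
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 1.0:
        scale = 1.0 / triple
        s.p_immuno_nontargeted *= scale
        s.p_chemo_nontargeted *= scale
        s.p_chemoimmuno_nontargeted *= scale
        residual = 1.0 - (
            s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
        )
        if residual < 0.0:  # round-off guard
            s.p_chemoimmuno_nontargeted += residual
    for therapy, os_1yr in q.clinical.os_1yr.items():
        if q.clinical.pfs_1yr[therapy] > os_1yr:
            q.clinical.pfs_1yr[therapy] = os_1yr
    if q.tat.tat_sendout_low > q.tat.tat_sendout_high:
        q.tat.tat_sendout_low, q.tat.tat_sendout_high = (
            q.tat.tat_sendout_high,
            q.tat.tat_sendout_low,
        )
    # the drawn set is itself a valid model input: re-bracket its ranges
    q.uncertainty = {path: _bracket(path, get_value(q, path)) for path in q.uncertainty}
    return q


def _bracket(path: str, x: float) -> tuple[float, float]:
    hi = 1.1 * x
    if _is_probability(path):
        hi = min(hi, 1.0)
    return (0.9 * x, hi)


@dataclass
class PsaResult:
    """Draw table plus percentile summaries of a probabilistic SA."""

    draws: pd.DataFrame
    summaries: dict[str, tuple[float, float, float]]  # outcome -> (median, lo2.5, hi97.5)
    seed: int
    n_draws: int

    @staticmethod
    def summarize(draws: pd.DataFrame) -> dict[str, tuple[float, float, float]]:
        out = {}
        for col in draws.columns:
            x = draws[col].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                out[col] = (math.nan, math.nan, math.nan)
                continue
            lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
            out[col] = (float(med), float(lo), float(hi))
        return out


def run_psa(p: ModelParameters, n_draws: int, seed: int) -> PsaResult:
    """Probabilistic sensitivity analysis over ``n_draws`` pipeline re-runs.

    Each draw samples every uncertain parameter, re-runs both scenarios and
    records the incremental outcomes.  Fully reproducible from ``seed``;
    payback periods beyond the horizon are recorded as NaN.
    """
    if n_draws < 2:
        raise ParameterError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_draws, len(_PSA_OUTCOMES)))
    for i in range(n_draws):
        q = sample_parameters(p, rng)
        res = run_analysis(q)
        payback = res["payback_months"]
        rows[i] = (
            res["roi_discounted"],
            res["roi_undiscounted"],
            math.nan if payback is None else payback,
            res["tat_reduction"],
            res["pct_targeted_difference"],
        )
    draws = pd.DataFrame(rows, columns=_PSA_OUTCOMES)
    return PsaResult(
        draws=draws,
        summaries=PsaResult.summarize(draws),
        seed=seed,
        n_draws=n_draws,
    )


@dataclass
class TornadoResult:
    """One-way sensitivity spans ranked by magnitude (ties alphabetical)."""

    entries: list[tuple[str, float, float, float]]  # (name, at_low, at_high, span)

    @property
    def top_driver(self) -> str:
        return self.entries[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["parameter", "outcome_at_low", "outcome_at_high", "span"]
        )


#: Structural lever added to the one-way analysis with its full range.
_TORNADO_EXTRA = ("scenario_proposed.frac_inhouse", (0.0, 1.0))


def one_way_sa(p: ModelParameters, outcome: str = "roi") -> TornadoResult:
    """One-way sensitivity analysis of ROI (or payback) per parameter.

    Each uncertain parameter is set to its low then high bound with all
    others at base case; the proposed-scenario in-house proportion is swept
    over [0, 1] as a structural lever.
    """
    if outcome not in ("roi", "payback"):
        raise ParameterError("outcome must be 'roi' or 'payback'")
    key = "roi_discounted" if outcome == "roi" else "payback_months"
    horizon_months = 12 * p.scenario_current.horizon_years

    def evaluate(path: str, value: float) -> float:
        q = p.copy()
        set_value(q, path, value)
        res = run_analysis(q)
        out = res[key]
        if out is None:  # payback beyond horizon
            out = float(horizon_months)
        return float(out)

    ranges = dict(p.uncertainty)
    ranges[_TORNADO_EXTRA[0]] = _TORNADO_EXTRA[1]
    entries = []
    for path in sorted(ranges):
        lo, hi = ranges[path]
        at_low = evaluate(path, lo)
        at_high = evaluate(path, hi)
        entries.append((path, at_low, at_high, abs(at_high - at_low)))
    entries.sort(key=lambda e: (-e[3], e[0]))
    return TornadoResult(entries=entries)


def scenario_sweep(
    p: ModelParameters, axis: str, grid: Sequence[float] | None = None
) -> pd.DataFrame:
    """Re-run the analysis over a grid of alternative hospital strategies.

    ``axis``:
      * ``"inhouse_pct"``: proposed-scenario in-house testing share, grid in
        percent (0-100);
      * ``"patient_volume"``: annual patient count, both scenarios;
      * ``"single_gene_comparator"``: the current scenario uses single-gene
        testing instead of send-out NGS (grid ignored; a single row).
    """
    if axis == "single_gene_comparator":
        q = p.copy()
        q.scenario_current.comparator_mode = "single_gene"
        res = run_analysis(q)
        rows = [("single_gene", res["roi_discounted"], res["payback_months"])]
        return pd.DataFrame(rows, columns=["setting", "roi", "payback_months"])
    if grid is None:
        raise ParameterError(f"axis {axis!r} requires a grid")
    rows = []
    for setting in sorted(grid):
        q = p.copy()
        if axis == "inhouse_pct":
            if not (0.0 <= setting <= 100.0):
                raise ParameterError("inhouse_pct grid values must lie in [0, 100]")
            set_value(q, "scenario_proposed.frac_inhouse", setting / 100.0)
        elif axis == "patient_volume":
            if setting < 0:
                raise ParameterError("patient_volume grid values must be >= 0")
            q.scenario_current.patients_per_year = float(setting)
            q.scenario_proposed.patients_per_year = float(setting)
        else:
            raise ParameterError(f"unknown sweep axis {axis!r}")
        res = run_analysis(q)
        rows.append((setting, res["roi_discounted"], res["payback_months"]))
    return pd.DataFrame(rows, columns=["setting", "roi", "payback_months"])


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationTarget:
    """One published output to reproduce: observable name, value, weight."""

    observable: str
    printed_value: float
    weight: float = 1.0


@dataclass
class CalibrationSpec:
    """Free parameters (dotted path, bounds) and targets for a fit."""

    free_parameters: list[tuple[str, float, float]]
    targets: list[CalibrationTarget]
    tolerance: float = 1e-3  # relative residual triggering a report warning
    grid_points: int = 17
    refine_iters: int = 60
    max_passes: int = 12  # coordinate-descent passes (early stop on stall)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ParameterError("calibration needs at least one target")
        for path, lo, hi in self.free_parameters:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
                raise ParameterError(f"free parameter {path}: bounds must be finite")


def _objective(p: ModelParameters, spec: CalibrationSpec) -> tuple[float, dict[str, float]]:
    res = run_analysis(p)
    total = 0.0
    achieved = {}
    for t in spec.targets:
        value = res[t.observable]
        value = float(value) if value is not None else math.inf
        achieved[t.observable] = value
        denom = abs(t.printed_value) if t.printed_value != 0 else 1.0
        total += t.weight * ((value - t.printed_value) / denom) ** 2
    return total, achieved


def calibrate(
    p: ModelParameters, spec: CalibrationSpec
) -> tuple[ModelParameters, pd.DataFrame]:
    """Deterministic coordinate search minimizing squared relative error.

    Each pass scans a uniform grid per free parameter and refines around the
    best grid point by interval bisection (golden-section); two passes are
    enough for the near-separable base-case ladder.  Returns the fitted
    parameters and a report listing the residual per target (with a
    ``warning`` flag where the residual exceeds the spec tolerance -- a
    warning, never an exception).
    """
    q = p.copy()
    if not spec.free_parameters:
        _, achieved = _objective(q, spec)
        return q, _report(spec, achieved)

    def assign(path: str, x: float) -> None:
        set_value(q, path, x)
        # keep the uncertainty range bracketing the trial value
        if path in q.uncertainty:
            hi_cap = 1.0 if _is_probability(path) else math.inf
            q.uncertainty[path] = (0.9 * x, min(1.1 * x, hi_cap))

    def f(path: str, x: float) -> float:
        assign(path, x)
        total, _ = _objective(q, spec)
        return total

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    previous = math.inf
    for _ in range(spec.max_passes):
        for path, lo, hi in spec.free_parameters:
            grid = np.linspace(lo, hi, spec.grid_points)
            vals = [f(path, x) for x in grid]
            best = int(np.argmin(vals))
            a = grid[max(0, best - 1)]
            b = grid[min(len(grid) - 1, best + 1)]
            c, d = b - invphi * (b - a), a + invphi * (b - a)
            fc, fd = f(path, c), f(path, d)
            for _ in range(spec.refine_iters):
                if b - a < 1e-12 * max(1.0, abs(b)):
                    break
                if fc < fd:
                    b, d, fd = d, c, fc
                    c = b - invphi * (b - a)
                    fc = f(path, c)
                else:
                    a, c, fc = c, d, fd
                    d = a + invphi * (b - a)
                    fd = f(path, d)
            assign(path, (a + b) / 2.0)
        total, _ = _objective(q, spec)
        if previous - total < 1e-16:
            break
        previous = total
    _, achieved = _objective(q, spec)
    return q, _report(spec, achieved)


def _report(spec: CalibrationSpec, achieved: dict[str, float]) -> pd.DataFrame:
    rows = []
    for t in spec.targets:
        value = achieved[t.observable]
        denom = abs(t.printed_value) if t.printed_value != 0 else 1.0
        residual = (value - t.printed_value) / denom
        rows.append(
            (t.observable, t.printed_value, value, residual, abs(residual) > spec.tolerance)
        )
    return pd.DataFrame(
        rows, columns=["target", "printed", "achieved", "relative_residual", "warning"]
    )


def calibrate_basecase(
    p: ModelParameters | None = None,
) -> tuple[ModelParameters, pd.DataFrame]:
    """Run the base-case calibration ladder against the published outputs.

    Order matters: (1) retest multiplier vs current testing cost, (2)
    send-out second-opinion probability vs current patients lost, (3)
    in-house second-opinion probability vs proposed patients lost, (4)
    visits per cycle vs current revenue.  Each step holds earlier fits
    fixed; each observable is driven almost exclusively by its paired
    parameter, which keeps the ladder near-separable.
    """
    from .parameters import default_parameters

    q = p.copy() if p is not None else default_parameters()
    ladder = [
        ("money.retest_multiplier", 1.0, 1.01, "testing_cost_current"),
        ("gaps.p_second_opinion_sendout", 0.0, 1.0, "patients_lost_current"),
        ("gaps.p_second_opinion_inhouse", 0.0, 1.0, "patients_lost_proposed"),
        ("money.visits_per_cycle", 0.0, 10.0, "revenue_current"),
    ]
    reports = []
    for path, lo, hi, observable in ladder:
        spec = CalibrationSpec(
            free_parameters=[(path, lo, hi)],
            targets=[CalibrationTarget(observable, BASECASE_TARGETS[observable])],
        )
        q, report = calibrate(q, spec)
        report.insert(0, "fitted_parameter", path)
        report["fitted_value"] = get_value(q, path)
        reports.append(report)
    violations = validate_parameters(q)
    if violations:  # pragma: no cover - calibration stays inside legal bounds
        raise ParameterError("; ".join(str(v) for v in violations))
    return q, pd.concat(reports, ignore_index=True)
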