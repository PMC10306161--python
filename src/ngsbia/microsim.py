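"""Patient-level microsimulation: independent oracle for the cohort model.

Simulates individual patients through the identical decision tree
(Bernoulli draws at each node) and Markov chain (categorical draws per
30-day cycle), on the same cycle grid as the cohort model, then checks the
aggregate against the cohort trace cell by cell.  Also provides the random
valid parameter sets used by the property tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    ModelParameters,
    ScenarioParams,
    ParameterError,
    default_parameters,
    get_value,
    set_value,
    validate_parameters,
)
from .testing_pathway import arm_masses, effective_interim_fraction
from .disease_model import (
    STATES,
    STATE_INDEX,
    DEAD,
    build_transition_matrix,
    CohortTrace,
)

__all__ = [
    "MicrosimAggregate",
    "DiscrepancyReport",
    "simulate_patients",
    "compare_with_cohort",
    "random_parameter_set",
]

_LOST = len(STATES)  # pseudo-state index for lost-to-second-opinion patients


@dataclass
class MicrosimAggregate:
    """Per-(cycle, state) occupancy fractions with binomial standard errors."""

    occupancy_fraction: np.ndarray  # (n_cycles + 1, 8), fraction of entered
    standard_error: np.ndarray  # same shape
    lost_fraction: float
    tests_per_patient: dict[str, float]
    n: int
    n_per_cohort: int
    seed: int
    entry_cycles: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy_fraction.shape[0] - 1


@dataclass
class DiscrepancyReport:
    """Cell-wise z-scores between microsim and cohort expectations."""

    z: np.ndarray  # (n_cycles + 1, 8)
    flagged: np.ndarray  # bool, |z| > threshold
    threshold: float
    flagged_fraction: float
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        t, s = self.z.shape
        idx = pd.MultiIndex.from_product([range(t), STATES], names=["cycle", "state"])
        return pd.DataFrame(
            {"z": self.z.reshape(-1), "flagged": self.flagged.reshape(-1)}, index=idx
        ).reset_index()


def _simulate_tree(
    p: ModelParameters,
    scenario: ScenarioParams,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, float]]:
    """Initial state (therapy index or lost) and billed tests per patient."""
    t, g = p.testing, p.gaps
    inhouse = rng.random(n) < scenario.frac_inhouse
    tissue = rng.random(n) < t.frac_tissue

    insufficient = tissue & (rng.random(n) < t.p_insufficient_tissue)
    # in-house arm: one tissue re-acquisition attempt
    retry = insufficient & inhouse
    insufficient_final = np.where(
        retry, rng.random(n) < t.p_insufficient_tissue, insufficient
    )
    insufficient_blood = ~tissue & (rng.random(n) < t.p_insufficient_blood)
    no_sample = insufficient_final | insufficient_blood

    p_fail = np.where(tissue, t.p_fail_tissue, t.p_fail_blood)
    failed = ~no_sample & (rng.random(n) < p_fail)
    conclusive = ~no_sample & ~failed
    p_act = np.where(tissue, t.p_actionable_tissue, t.p_actionable_blood)
    actionable = conclusive & (rng.random(n) < p_act)

    state = np.full(n, -1, dtype=np.int64)

    f_int_ih = effective_interim_fraction(p, "inhouse")
    f_int_so = effective_interim_fraction(p, "sendout")
    f_interim = np.where(inhouse, f_int_ih, f_int_so)
    interim = actionable & (rng.random(n) < f_interim)
    state[actionable & ~interim] = STATE_INDEX["targeted"]
    state[interim] = STATE_INDEX["interim"]

    nontargeted = ~actionable
    p_so = np.where(inhouse, g.p_second_opinion_inhouse, g.p_second_opinion_sendout)
    lost = nontargeted & (rng.random(n) < p_so)
    state[lost] = _LOST
    staying = nontargeted & ~lost
    s = p.splits
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 0:
        cut1 = s.p_chemo_nontargeted / triple
        cut2 = cut1 + s.p_immuno_nontargeted / triple
        u = rng.random(n)
        state[staying & (u < cut1)] = STATE_INDEX["chemo"]
        state[staying & (u >= cut1) & (u < cut2)] = STATE_INDEX["immuno"]
        state[staying & (u >= cut2)] = STATE_INDEX["chemo_immuno"]
    else:
        state[staying] = STATE_INDEX["chemo_immuno"]

    # billed tests: one per patient, plus a repeat with prob (multiplier - 1)
    m = p.money.retest_multiplier
    billed = 1.0 + (rng.random(n) < (m - 1.0)).astype(float)
    single_gene_mode = scenario.comparator_mode == "single_gene"
    tests = {
        "inhouse": float(billed[inhouse].sum()) / n,
        "sendout": 0.0 if single_gene_mode else float(billed[~inhouse].sum()) / n,
        "singlegene": (
            float(billed[~inhouse].sum()) / n * g.singlegene_tests_per_patient
            if single_gene_mode
            else 0.0
        ),
    }
    return state, tests


def simulate_patients(
    p: ModelParameters,
    scenario: ScenarioParams,
    n: int,
    seed: int,
    return_histories: bool = False,
) -> MicrosimAggregate | tuple[MicrosimAggregate, pd.DataFrame]:
    """Simulate ``n`` patients through the pathway and the Markov chain.

    Patients are split evenly across the entering cohorts (``n`` is rounded
    down to a multiple of the horizon); each traverses the decision tree and
    is then propagated cycle by cycle with categorical draws from the same
    transition matrix as the cohort engine.  Fully reproducible from
    ``seed``.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("; ".join(str(v) for v in violations))
    rng = np.random.default_rng(seed)

    g = p.gaps
    cpy = g.days_per_year / g.cycle_days
    horizon = int(scenario.horizon_years)
    n_cycles = math.ceil(horizon * cpy - 1e-9)
    entry_cycles = np.array([math.ceil(y * cpy - 1e-9) for y in range(horizon)])
    n_per = max(1, n // horizon)
    n_eff = n_per * horizon

    state0, tests = _simulate_tree(p, scenario, n_eff, rng)
    patient_entry = np.repeat(entry_cycles, n_per)

    M = build_transition_matrix(p)
    cumM = np.cumsum(M, axis=1)

    counts = np.zeros((n_cycles + 1, len(STATES)))
    state = state0.copy()
    histories = np.full((n_eff, n_cycles + 1), -1, dtype=np.int8) if return_histories else None
    for t in range(n_cycles + 1):
        active = (patient_entry <= t) & (state != _LOST)
        if active.any():
            np.add.at(counts[t], state[active], 1.0)
        if histories is not None:
            histories[:, t] = np.where(active, state, -1)
        if t == n_cycles:
            break
        moving = active & (state != DEAD)
        idx = np.nonzero(moving)[0]
        if idx.size:
            u = rng.random(idx.size)
            state[idx] = (u[:, None] > cumM[state[idx]]).sum(axis=1)

    frac = counts / n_eff
    se = np.sqrt(frac * (1.0 - frac) / n_eff)
    agg = MicrosimAggregate(
        occupancy_fraction=frac,
        standard_error=se,
        lost_fraction=float((state0 == _LOST).sum()) / n_eff,
        tests_per_patient=tests,
        n=n_eff,
        n_per_cohort=n_per,
        seed=seed,
        entry_cycles=entry_cycles,
    )
    if return_histories:
        hist = pd.DataFrame(
            histories, columns=[f"cycle_{t}" for t in range(n_cycles + 1)]
        )
        hist.insert(0, "entry_cycle", patient_entry)
        return agg, hist
    return agg


def compare_with_cohort(
    micro: MicrosimAggregate, trace: CohortTrace, threshold: float = 3.0
) -> DiscrepancyReport:
    """Cell-wise z-scores of microsim occupancy against cohort expectations.

    The cohort expectation per (cycle, state) is the expected fraction of
    all entered patients; the standard error is binomial at that expectation
    with the microsim's sample size.  Cells with zero expectation must be
    exactly empty in the microsimulation (both engines share the same
    support), and count as agreeing.  Comparison is restricted to cycles
    where at least one cohort has entered.
    """
    if micro.n_cycles != trace.n_cycles or len(micro.entry_cycles) != trace.n_cohorts:
        raise ParameterError("microsim and cohort trace shapes do not match")
    expected = np.stack(
        [trace.total_occupancy(t) / trace.total_entered for t in range(trace.n_cycles + 1)]
    )
    se = np.sqrt(expected * (1.0 - expected) / micro.n)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (micro.occupancy_fraction - expected) / se
    z = np.where(se > 0, z, np.where(micro.occupancy_fraction == expected, 0.0, np.inf))
    flagged = np.abs(z) > threshold
    frac = float(flagged.mean())
    return DiscrepancyReport(
        z=z,
        flagged=flagged,
        threshold=threshold,
        flagged_fraction=frac,
        passed=frac <= 0.01,
    )


# ---------------------------------------------------------------------------
# Random valid parameter sets for property tests
# ---------------------------------------------------------------------------

#: Paths varied by random_parameter_set: uniform within +/-50% of the
#: default, clipped to the legal range.
_RANDOMIZED_PROB_PATHS = (
    "testing.frac_tissue",
    "testing.p_insufficient_tissue",
    "testing.p_insufficient_blood",
    "testing.p_fail_tissue",
    "testing.p_fail_blood",
    "testing.p_actionable_tissue",
    "testing.p_actionable_blood",
    "splits.p_interim",
    "splits.p_interim_switch",
    "clinical.p_prog_to_nextline_3mo",
    "clinical.p_nextline_to_prog_3mo",
    "gaps.p_second_opinion_sendout",
    "gaps.p_second_opinion_inhouse",
)
_RANDOMIZED_MONEY_PATHS = (
    "money.cost_inhouse_test",
    "money.cost_sendout_test",
    "money.cost_singlegene_test",
    "money.cost_machine_acquisition",
    "money.reimb_inhouse_test",
    "money.revenue_hospital_visit",
    "money.visits_per_cycle",
)


def random_parameter_set(seed: int) -> ModelParameters:
    """A valid random parameter set, uniform within +/-50% of the defaults.

    All invariants hold by construction: complements are maintained, the
    nontargeted split triple is rescaled to keep a nonnegative residual,
    PFS is clipped below OS, and every probability stays in [0, 1].
    """
    rng = np.random.default_rng(seed)
    p = default_parameters()

    def jitter(x: float, lo: float = 0.0, hi: float = math.inf) -> float:
        return float(np.clip(x * rng.uniform(0.5, 1.5), lo, hi))

    for path in _RANDOMIZED_PROB_PATHS:
        set_value(p, path, jitter(get_value(p, path), 0.0, 1.0))
    for path in _RANDOMIZED_MONEY_PATHS:
        set_value(p, path, jitter(get_value(p, path)))
    p.money.retest_multiplier = float(rng.uniform(1.0, 1.01))

    s = p.splits
    for name in ("p_immuno_nontargeted", "p_chemo_nontargeted", "p_chemoimmuno_nontargeted"):
        setattr(s, name, jitter(getattr(s, name), 0.0, 1.0))
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 1.0:
        for name in ("p_immuno_nontargeted", "p_chemo_nontargeted", "p_chemoimmuno_nontargeted"):
            setattr(s, name, getattr(s, name) / triple)
        # guard the residual against round-off going negative
        if s.nontargeted_residual < 0.0:
            s.p_chemoimmuno_nontargeted += s.nontargeted_residual

    for therapy in p.clinical.os_1yr:
        os_1yr = float(np.clip(p.clinical.os_1yr[therapy] * rng.uniform(0.5, 1.5), 0.01, 1.0))
        pfs_1yr = float(
            np.clip(p.clinical.pfs_1yr[therapy] * rng.uniform(0.5, 1.5), 0.01, os_1yr)
        )
        p.clinical.os_1yr[therapy] = os_1yr
        p.clinical.pfs_1yr[therapy] = pfs_1yr

    lo = float(np.clip(p.tat.tat_sendout_low * rng.uniform(0.5, 1.5), 0.0, math.inf))
    hi = float(np.clip(p.tat.tat_sendout_high * rng.uniform(0.5, 1.5), lo, math.inf))
    p.tat.tat_sendout_low, p.tat.tat_sendout_high = lo, hi
    p.tat.tat_inhouse = jitter(p.tat.tat_inhouse)

    mix = float(rng.uniform(0.0, 1.0))
    set_value(p, "scenario_proposed.frac_inhouse", mix)

    # uncertainty ranges must keep bracketing the randomized points
    p.uncertainty = {
        path: (0.9 * get_value(p, path), min(1.1 * get_value(p, path), 1.0))
        if _is_prob_path(path)
        else (0.9 * get_value(p, path), 1.1 * get_value(p, path))
        for path in p.uncertainty
    }
    return p


def _is_prob_path(path: str) -> bool:
    from .uncertainty import _is_probability

    return _is_probability(path)
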