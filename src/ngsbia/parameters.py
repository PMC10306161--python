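"""Model inputs for the in-house NGS budget-impact analysis.

Every quantity the model consumes lives in :class:`ModelParameters`: the
testing-pathway probabilities, therapy-split fractions, unit costs and
reimbursements, turnaround times, 1-year survival inputs, the two hospital
scenarios (current = all send-out NGS, proposed = 75% in-house), and a small
set of gap parameters (second-opinion probabilities, retest multiplier,
visits per cycle) that the analysis needs but that published base cases
typically leave implicit.  Parameters round-trip losslessly through a
human-editable YAML file; validation reports violations as data rather than
raising, so a partially invalid file can be diagnosed in one pass.
"""

from __future__ import annotations

import copy
import importlib.resources
import math
from dataclasses import dataclass, field, fields, asdict
from typing import Any, Iterator

import yaml

__all__ = [
    "THERAPIES",
    "ParameterError",
    "Violation",
    "TestingParams",
    "TherapySplitParams",
    "CostRevenueParams",
    "TurnaroundParams",
    "ClinicalParams",
    "ScenarioParams",
    "GapParams",
    "ModelParameters",
    "default_parameters",
    "default_uncertainty",
    "load_parameters",
    "loads_parameters",
    "save_parameters",
    "dumps_parameters",
    "validate_parameters",
    "get_value",
    "set_value",
    "packaged_basecase_path",
]

#: Therapy labels, in the order used throughout the package.
THERAPIES = ("chemo", "immuno", "chemo_immuno", "targeted")

_COMPARATOR_MODES = ("sendout_ngs", "single_gene")
_TAT_CONVENTIONS = ("high", "midpoint")


class ParameterError(ValueError):
    """Raised when a configuration cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class Violation:
    """A single invariant breach, named after the offending field."""

    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.message}"


# ---------------------------------------------------------------------------
# Component parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class TestingParams:
    """Sample mix and per-sample test outcome probabilities."""

    frac_tissue: float = 0.60
    frac_blood: float = 0.40
    p_insufficient_tissue: float = 0.05
    p_insufficient_blood: float = 0.003
    p_fail_tissue: float = 0.012
    p_fail_blood: float = 0.005
    p_actionable_tissue: float = 0.23
    p_actionable_blood: float = 0.24


@dataclass
class TherapySplitParams:
    """Therapy assignment fractions at the decision-tree terminal nodes.

    The three nontargeted fractions are conditional on reaching the
    nontargeted node; their residual mass (0.10 in the base case) is the
    unallocated share interpreted as the default second-opinion probability.
    ``p_direct_targeted`` and ``p_interim`` split the actionable node.
    """

    p_immuno_nontargeted: float = 0.25
    p_chemo_nontargeted: float = 0.29
    p_chemoimmuno_nontargeted: float = 0.36
    p_direct_targeted: float = 0.73
    p_interim: float = 0.27
    p_interim_switch: float = 0.34

    @property
    def nontargeted_residual(self) -> float:
        """Unallocated mass at the nontargeted node (second-opinion share)."""
        return 1.0 - (
            self.p_immuno_nontargeted
            + self.p_chemo_nontargeted
            + self.p_chemoimmuno_nontargeted
        )


@dataclass
class CostRevenueParams:
    """Unit costs and revenues, 2021 USD.

    ``retest_multiplier`` scales billed tests per patient to account for
    repeat testing; it is a single scalar shared by both scenarios and is
    normally calibrated once against the current-scenario testing cost.
    ``visits_per_cycle`` prices hospital visits per 30-day cycle alive and is
    calibrated against the current-scenario revenue.
    """

    cost_inhouse_test: float = 600.0
    cost_sendout_test: float = 300.0
    cost_singlegene_test: float = 141.0
    cost_machine_acquisition: float = 200_000.0
    reimb_inhouse_test: float = 580.0
    revenue_hospital_visit: float = 124.0
    retest_multiplier: float = 1.0
    visits_per_cycle: float = 1.0


@dataclass
class TurnaroundParams:
    """Turnaround times in days; the send-out value is a published range."""

    tat_sendout_low: float = 10.32
    tat_sendout_high: float = 27.80
    tat_inhouse: float = 3.0

    @property
    def tat_sendout_midpoint(self) -> float:
        return 0.5 * (self.tat_sendout_low + self.tat_sendout_high)


@dataclass
class ClinicalParams:
    """1-year survival inputs per therapy and 3-month progression dynamics."""

    pfs_1yr: dict[str, float] = field(
        default_factory=lambda: {
            "chemo": 0.173,
            "immuno": 0.279,
            "chemo_immuno": 0.341,
            "targeted": 0.40,
        }
    )
    os_1yr: dict[str, float] = field(
        default_factory=lambda: {
            "chemo": 0.494,
            "immuno": 0.673,
            "chemo_immuno": 0.692,
            "targeted": 0.86,
        }
    )
    p_prog_to_nextline_3mo: float = 0.48
    p_nextline_to_prog_3mo: float = 0.50
    #: Optional override for the 1-year OS used in the progression and
    #: next-line states; ``None`` falls back to the chemotherapy OS, the most
    #: conservative printed therapy.
    os_1yr_postprogression: float | None = None


@dataclass
class ScenarioParams:
    """One hospital scenario: horizon, discounting, volume and testing mix."""

    horizon_years: int = 5
    discount_rate_annual: float = 0.035
    patients_per_year: float = 500.0
    frac_inhouse: float = 0.0
    frac_sendout: float = 1.0
    comparator_mode: str = "sendout_ngs"


@dataclass
class GapParams:
    """Quantities the analysis needs but the published base case never prints.

    * second-opinion probabilities are arm-specific (patients facing slow
      send-out results leave more often than patients with 3-day in-house
      results) and are normally calibrated to the printed lost-patient counts;
    * ``interim_tat_scaling`` scales the interim-therapy fraction of the
      in-house arm by ``tat_inhouse / reference`` (faster results mean fewer
      patients need bridging therapy); the reference defaults to the send-out
      midpoint when ``interim_tat_reference_days`` is ``None``;
    * ``mixed_sendout_tat`` selects which send-out turnaround applies to the
      residual send-out tests of a mixed scenario: ``"high"`` (top of the
      printed range -- the tests still sent out are the complex ones) or
      ``"midpoint"``;
    * ``singlegene_tests_per_patient`` is the number of single-gene assays
      replacing one NGS panel in the single-gene comparator (one per major
      NSCLC driver gene).
    """

    p_second_opinion_sendout: float = 0.10
    p_second_opinion_inhouse: float = 0.05
    interim_tat_scaling: bool = True
    interim_tat_reference_days: float | None = None
    cycle_days: float = 30.0
    days_per_year: float = 365.25
    mixed_sendout_tat: str = "high"
    singlegene_tests_per_patient: float = 5.0


@dataclass
class ModelParameters:
    """The complete, validated input set for one analysis."""

    testing: TestingParams = field(default_factory=TestingParams)
    splits: TherapySplitParams = field(default_factory=TherapySplitParams)
    money: CostRevenueParams = field(default_factory=CostRevenueParams)
    tat: TurnaroundParams = field(default_factory=TurnaroundParams)
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    scenario_current: ScenarioParams = field(default_factory=ScenarioParams)
    scenario_proposed: ScenarioParams = field(
        default_factory=lambda: ScenarioParams(frac_inhouse=0.75, frac_sendout=0.25)
    )
    gaps: GapParams = field(default_factory=GapParams)
    #: Uncertainty ranges keyed by dotted parameter path, e.g.
    #: ``"money.cost_inhouse_test"`` or ``"clinical.os_1yr.targeted"``.
    uncertainty: dict[str, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------


def _pm10(x: float, cap: float | None = None) -> tuple[float, float]:
    lo, hi = 0.9 * x, 1.1 * x
    if cap is not None:
        hi = min(hi, cap)
    return (lo, hi)


def default_uncertainty() -> dict[str, tuple[float, float]]:
    """Uncertainty ranges for the base case.

    Printed ranges are used verbatim; every other parameter gets the default
    10% band around its point value (probabilities capped at 1).
    """
    u: dict[str, tuple[float, float]] = {
        # costs and revenues with printed ranges
        "money.cost_inhouse_test": (578.0, 908.0),
        "money.cost_sendout_test": (270.0, 330.0),
        "money.cost_singlegene_test": _pm10(141.0),
        "money.cost_machine_acquisition": _pm10(200_000.0),
        "money.reimb_inhouse_test": (522.0, 638.0),
        "money.revenue_hospital_visit": (112.0, 136.0),
        # turnaround
        "tat.tat_sendout_low": _pm10(10.32),
        "tat.tat_sendout_high": _pm10(27.80),
        "tat.tat_inhouse": _pm10(3.0),
        # testing pathway probabilities
        "testing.frac_tissue": _pm10(0.60, cap=1.0),
        "testing.p_insufficient_tissue": _pm10(0.05, cap=1.0),
        "testing.p_insufficient_blood": _pm10(0.003, cap=1.0),
        "testing.p_fail_tissue": _pm10(0.012, cap=1.0),
        "testing.p_fail_blood": _pm10(0.005, cap=1.0),
        "testing.p_actionable_tissue": _pm10(0.23, cap=1.0),
        "testing.p_actionable_blood": _pm10(0.24, cap=1.0),
        # therapy splits
        "splits.p_immuno_nontargeted": _pm10(0.25, cap=1.0),
        "splits.p_chemo_nontargeted": _pm10(0.29, cap=1.0),
        "splits.p_chemoimmuno_nontargeted": _pm10(0.36, cap=1.0),
        "splits.p_interim": _pm10(0.27, cap=1.0),
        "splits.p_interim_switch": _pm10(0.34, cap=1.0),
        # clinical: printed 95% CIs where available, 10% otherwise
        "clinical.pfs_1yr.chemo": (0.120, 0.235),
        "clinical.pfs_1yr.immuno": _pm10(0.279, cap=1.0),
        "clinical.pfs_1yr.chemo_immuno": (0.288, 0.395),
        "clinical.pfs_1yr.targeted": (0.28, 0.52),
        "clinical.os_1yr.chemo": (0.421, 0.562),
        "clinical.os_1yr.immuno": _pm10(0.673, cap=1.0),
        "clinical.os_1yr.chemo_immuno": (0.641, 0.738),
        "clinical.os_1yr.targeted": (0.807, 0.899),
        "clinical.p_prog_to_nextline_3mo": _pm10(0.48, cap=1.0),
        "clinical.p_nextline_to_prog_3mo": _pm10(0.50, cap=1.0),
        # gap parameters
        "gaps.p_second_opinion_sendout": _pm10(0.10, cap=1.0),
        "gaps.p_second_opinion_inhouse": _pm10(0.05, cap=1.0),
    }
    return u


def default_parameters() -> ModelParameters:
    """The printed base case plus default gap parameters and uncertainty."""
    return ModelParameters(uncertainty=default_uncertainty())


# ---------------------------------------------------------------------------
# Dotted-path access (used by PSA, tornado and calibration)
# ---------------------------------------------------------------------------


def _walk(p: ModelParameters, path: str) -> tuple[Any, str]:
    parts = path.split(".")
    obj: Any = p
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            obj = getattr(obj, part)
    return obj, parts[-1]


_PROBABILITY_PREFIXES = ("testing.", "splits.", "clinical.", "gaps.p_second_opinion")


def is_probability_path(path: str) -> bool:
    """Whether a dotted parameter path denotes a probability in [0, 1]."""
    if path.startswith("clinical.") and path.endswith("_3mo"):
        return True
    return any(path.startswith(pre) for pre in _PROBABILITY_PREFIXES)


def get_value(p: ModelParameters, path: str) -> float:
    """Read a scalar by dotted path, e.g. ``"clinical.os_1yr.targeted"``."""
    obj, leaf = _walk(p, path)
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def set_value(p: ModelParameters, path: str, value: float) -> None:
    """Set a scalar by dotted path, maintaining complement pairs.

    Setting ``testing.frac_tissue`` updates ``frac_blood`` (and vice versa);
    likewise for the scenario in-house/send-out mix and for the
    direct-targeted/interim split at the actionable node.
    """
    obj, leaf = _walk(p, path)
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        setattr(obj, leaf, value)
    complements = {
        "frac_tissue": "frac_blood",
        "frac_blood": "frac_tissue",
        "frac_inhouse": "frac_sendout",
        "frac_sendout": "frac_inhouse",
        "p_direct_targeted": "p_interim",
        "p_interim": "p_direct_targeted",
    }
    other = complements.get(leaf)
    if other is not None and not isinstance(obj, dict) and hasattr(obj, other):
        setattr(obj, other, 1.0 - value)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_prob(out: list[Violation], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(name, f"probability {value!r} outside [0, 1]"))


def validate_parameters(p: ModelParameters) -> list[Violation]:
    """Return every invariant breach; an empty list means valid."""
    v: list[Violation] = []
    t = p.testing
    if abs(t.frac_tissue + t.frac_blood - 1.0) > 1e-9:
        v.append(Violation("testing.frac_tissue", "frac_tissue + frac_blood != 1"))
    for f in fields(t):
        _check_prob(v, f"testing.{f.name}", getattr(t, f.name))

    s = p.splits
    for f in fields(s):
        _check_prob(v, f"splits.{f.name}", getattr(s, f.name))
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 1.0 + 1e-9:
        v.append(
            Violation(
                "splits.p_immuno_nontargeted",
                f"nontargeted therapy fractions sum to {triple:.4f} > 1",
            )
        )
    if abs(s.p_direct_targeted + s.p_interim - 1.0) > 1e-9:
        v.append(Violation("splits.p_interim", "p_direct_targeted + p_interim != 1"))

    m = p.money
    for name in (
        "cost_inhouse_test",
        "cost_sendout_test",
        "cost_singlegene_test",
        "cost_machine_acquisition",
        "reimb_inhouse_test",
        "revenue_hospital_visit",
    ):
        if getattr(m, name) < 0:
            v.append(Violation(f"money.{name}", "monetary value must be >= 0"))
    if not (1.0 <= m.retest_multiplier <= 1.1):
        v.append(Violation("money.retest_multiplier", "must lie in [1.0, 1.1]"))
    if m.visits_per_cycle < 0:
        v.append(Violation("money.visits_per_cycle", "must be >= 0"))

    tt = p.tat
    if tt.tat_sendout_low > tt.tat_sendout_high:
        v.append(Violation("tat.tat_sendout_low", "send-out range low > high"))
    for f in fields(tt):
        if getattr(tt, f.name) < 0:
            v.append(Violation(f"tat.{f.name}", "turnaround must be >= 0"))

    c = p.clinical
    for therapy in THERAPIES:
        if therapy not in c.pfs_1yr or therapy not in c.os_1yr:
            v.append(Violation(f"clinical.pfs_1yr.{therapy}", "missing therapy entry"))
            continue
        _check_prob(v, f"clinical.pfs_1yr.{therapy}", c.pfs_1yr[therapy])
        _check_prob(v, f"clinical.os_1yr.{therapy}", c.os_1yr[therapy])
        if c.os_1yr[therapy] < c.pfs_1yr[therapy] - 1e-12:
            v.append(
                Violation(
                    f"clinical.os_1yr.{therapy}",
                    "1-year OS below 1-year PFS (PFS events include deaths)",
                )
            )
    _check_prob(v, "clinical.p_prog_to_nextline_3mo", c.p_prog_to_nextline_3mo)
    _check_prob(v, "clinical.p_nextline_to_prog_3mo", c.p_nextline_to_prog_3mo)
    if c.os_1yr_postprogression is not None:
        _check_prob(v, "clinical.os_1yr_postprogression", c.os_1yr_postprogression)

    for label in ("scenario_current", "scenario_proposed"):
        sc: ScenarioParams = getattr(p, label)
        if abs(sc.frac_inhouse + sc.frac_sendout - 1.0) > 1e-9:
            v.append(Violation(f"{label}.frac_inhouse", "frac_inhouse + frac_sendout != 1"))
        _check_prob(v, f"{label}.frac_inhouse", sc.frac_inhouse)
        if sc.horizon_years < 1:
            v.append(Violation(f"{label}.horizon_years", "horizon must be >= 1 year"))
        if sc.patients_per_year < 0:
            v.append(Violation(f"{label}.patients_per_year", "must be >= 0"))
        if sc.discount_rate_annual < 0:
            v.append(Violation(f"{label}.discount_rate_annual", "must be >= 0"))
        if sc.comparator_mode not in _COMPARATOR_MODES:
            v.append(
                Violation(
                    f"{label}.comparator_mode",
                    f"must be one of {_COMPARATOR_MODES}",
                )
            )

    g = p.gaps
    _check_prob(v, "gaps.p_second_opinion_sendout", g.p_second_opinion_sendout)
    _check_prob(v, "gaps.p_second_opinion_inhouse", g.p_second_opinion_inhouse)
    if g.cycle_days <= 0:
        v.append(Violation("gaps.cycle_days", "must be > 0"))
    if g.days_per_year <= 0:
        v.append(Violation("gaps.days_per_year", "must be > 0"))
    if g.mixed_sendout_tat not in _TAT_CONVENTIONS:
        v.append(Violation("gaps.mixed_sendout_tat", f"must be one of {_TAT_CONVENTIONS}"))
    if g.singlegene_tests_per_patient < 0:
        v.append(Violation("gaps.singlegene_tests_per_patient", "must be >= 0"))
    if g.interim_tat_reference_days is not None and g.interim_tat_reference_days <= 0:
        v.append(Violation("gaps.interim_tat_reference_days", "must be > 0"))

    for path, bounds in p.uncertainty.items():
        try:
            lo, hi = float(bounds[0]), float(bounds[1])
        except (TypeError, ValueError, IndexError):
            v.append(Violation(f"uncertainty.{path}", "range must be a (low, high) pair"))
            continue
        try:
            point = get_value(p, path)
        except (AttributeError, KeyError):
            v.append(Violation(f"uncertainty.{path}", "unknown parameter path"))
            continue
        if not (lo <= point <= hi):
            v.append(
                Violation(
                    f"uncertainty.{path}",
                    f"range ({lo}, {hi}) does not bracket the point value {point}",
                )
            )
    return v


# ---------------------------------------------------------------------------
# Serialization (canonical YAML)
# ---------------------------------------------------------------------------


def _to_dict(p: ModelParameters) -> dict[str, Any]:
    d = asdict(p)
    d["uncertainty"] = {k: [float(lo), float(hi)] for k, (lo, hi) in p.uncertainty.items()}
    return d


def dumps_parameters(p: ModelParameters) -> str:
    """Canonical YAML serialization (sorted keys, block style)."""
    return yaml.safe_dump(_to_dict(p), sort_keys=True, default_flow_style=False)


def save_parameters(p: ModelParameters, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_parameters(p))


_COMPLEMENTS = {
    ("testing", "frac_tissue"): "frac_blood",
    ("testing", "frac_blood"): "frac_tissue",
    ("scenario_current", "frac_inhouse"): "frac_sendout",
    ("scenario_current", "frac_sendout"): "frac_inhouse",
    ("scenario_proposed", "frac_inhouse"): "frac_sendout",
    ("scenario_proposed", "frac_sendout"): "frac_inhouse",
    ("splits", "p_direct_targeted"): "p_interim",
    ("splits", "p_interim"): "p_direct_targeted",
}


def _merge_block(target: Any, block_name: str, data: dict[str, Any]) -> None:
    known = {f.name for f in fields(target)}
    for key, value in data.items():
        if key not in known:
            raise ParameterError(f"{block_name}.{key}: unknown parameter")
        current = getattr(target, key)
        if isinstance(current, dict) and isinstance(value, dict):
            unknown = set(value) - set(current)
            if unknown:
                raise ParameterError(
                    f"{block_name}.{key}.{sorted(unknown)[0]}: unknown parameter"
                )
            current.update(value)
        else:
            setattr(target, key, value)
        partner = _COMPLEMENTS.get((block_name, key))
        if partner is not None and partner not in data:
            setattr(target, partner, 1.0 - float(value))


def loads_parameters(text: str) -> ModelParameters:
    """Parse a YAML config; unspecified fields fall back to defaults."""
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError("top level of the config must be a mapping")
    p = default_parameters()
    block_names = {f.name for f in fields(p)}
    for block_name, data in raw.items():
        if block_name not in block_names:
            raise ParameterError(f"{block_name}: unknown section")
        if block_name == "uncertainty":
            p.uncertainty = {
                str(k): (float(v[0]), float(v[1])) for k, v in (data or {}).items()
            }
            continue
        if not isinstance(data, dict):
            raise ParameterError(f"{block_name}: section must be a mapping")
        _merge_block(getattr(p, block_name), block_name, data)
    if "uncertainty" not in raw:
        # default ranges follow overridden points: keep printed ranges where
        # they still bracket, else fall back to the 10% band around the new value
        for path, (lo, hi) in list(p.uncertainty.items()):
            point = get_value(p, path)
            if not (lo <= point <= hi):
                cap = 1.0 if is_probability_path(path) else math.inf
                p.uncertainty[path] = (0.9 * point, min(1.1 * point, cap))
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("; ".join(str(x) for x in violations))
    return p


def load_parameters(path: str) -> ModelParameters:
    """Load and validate a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_parameters(fh.read())


def packaged_basecase_path():
    """Path-like handle to the packaged base-case config."""
    return importlib.resources.files("ngsbia") / "data" / "basecase.yaml"
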