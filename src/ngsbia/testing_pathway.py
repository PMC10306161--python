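"""Decision-tree testing pathway: from sample to therapy decision.

Each annual cohort moves through sample collection (tissue or blood),
sufficiency, test success, and actionability, ending at a therapy
assignment, an interim-therapy bridge, or loss to second opinion.  The two
arms differ in turnaround time and in the in-house arm's ability to
re-acquire tissue once after an insufficient first sample.  Everything here
is a closed-form expectation over the tree; the patient-level counterpart
lives in :mod:`ngsbia.microsim`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParameters, ScenarioParams, validate_parameters, ParameterError

__all__ = [
    "PathwayAllocation",
    "arm_masses",
    "effective_interim_fraction",
    "pathway_distribution",
    "mean_turnaround",
    "second_opinion_loss",
    "tests_performed",
]


@dataclass(frozen=True)
class PathwayAllocation:
    """Expected per-patient mass at each terminal node plus test counts."""

    mass_targeted_direct: float
    mass_interim: float
    mass_chemo: float
    mass_immuno: float
    mass_chemoimmuno: float
    mass_lost_second_opinion: float
    tests_inhouse: float
    tests_sendout: float
    tests_singlegene: float
    mean_tat: float

    @property
    def total_mass(self) -> float:
        return (
            self.mass_targeted_direct
            + self.mass_interim
            + self.mass_chemo
            + self.mass_immuno
            + self.mass_chemoimmuno
            + self.mass_lost_second_opinion
        )

    @property
    def mass_actionable(self) -> float:
        return self.mass_targeted_direct + self.mass_interim


def _require_valid(p: ModelParameters) -> None:
    violations = validate_parameters(p)
    if violations:
        raise ParameterError("; ".join(str(v) for v in violations))


def effective_interim_fraction(p: ModelParameters, arm: str) -> float:
    """Interim share of the actionable node for one arm.

    The send-out arm uses the printed fraction directly.  With
    ``gaps.interim_tat_scaling`` on, the in-house arm scales it by the ratio
    of in-house turnaround to a reference turnaround (default: the send-out
    midpoint): near-immediate results leave few patients needing a bridge
    therapy.
    """
    s = p.splits
    if arm != "inhouse" or not p.gaps.interim_tat_scaling:
        return s.p_interim
    ref = p.gaps.interim_tat_reference_days
    if ref is None:
        ref = p.tat.tat_sendout_midpoint
    if ref <= 0:
        return s.p_interim
    return min(1.0, s.p_interim * p.tat.tat_inhouse / ref)


def arm_masses(p: ModelParameters, arm: str) -> dict[str, float]:
    """Terminal-node masses for a single pure arm (``inhouse``/``sendout``).

    The single-gene comparator shares the send-out arm's tree: only test
    pricing differs (mutation-type-specific detection is out of scope).
    """
    if arm not in ("inhouse", "sendout"):
        raise ValueError(f"unknown arm {arm!r}")
    t, s, g = p.testing, p.splits, p.gaps
    ft, fb = t.frac_tissue, t.frac_blood
    pit, pib = t.p_insufficient_tissue, t.p_insufficient_blood
    pft, pfb = t.p_fail_tissue, t.p_fail_blood

    if arm == "inhouse":
        # one re-acquisition attempt after an insufficient first tissue sample
        tissue_tested = ft * ((1.0 - pit) + pit * (1.0 - pit))
        tissue_insufficient = ft * pit * pit
        retest_fraction = ft * pit
    else:
        tissue_tested = ft * (1.0 - pit)
        tissue_insufficient = ft * pit
        retest_fraction = 0.0

    tissue_conclusive = tissue_tested * (1.0 - pft)
    blood_tested = fb * (1.0 - pib)
    blood_conclusive = blood_tested * (1.0 - pfb)
    inconclusive = (
        tissue_insufficient
        + tissue_tested * pft
        + fb * pib
        + blood_tested * pfb
    )

    actionable = tissue_conclusive * t.p_actionable_tissue + blood_conclusive * t.p_actionable_blood
    nontargeted_node = inconclusive + (
        tissue_conclusive * (1.0 - t.p_actionable_tissue)
        + blood_conclusive * (1.0 - t.p_actionable_blood)
    )

    p_so = g.p_second_opinion_inhouse if arm == "inhouse" else g.p_second_opinion_sendout
    lost = nontargeted_node * p_so
    staying = nontargeted_node - lost
    triple = s.p_immuno_nontargeted + s.p_chemo_nontargeted + s.p_chemoimmuno_nontargeted
    if triple > 0:
        immuno = staying * s.p_immuno_nontargeted / triple
        chemo = staying * s.p_chemo_nontargeted / triple
        chemoimmuno = staying * s.p_chemoimmuno_nontargeted / triple
    else:  # degenerate: no nontargeted therapies configured
        immuno = chemo = 0.0
        chemoimmuno = staying

    f_interim = effective_interim_fraction(p, arm)
    return {
        "targeted_direct": actionable * (1.0 - f_interim),
        "interim": actionable * f_interim,
        "chemo": chemo,
        "immuno": immuno,
        "chemo_immuno": chemoimmuno,
        "lost": lost,
        "conclusive_tissue": tissue_conclusive,
        "conclusive_blood": blood_conclusive,
        "actionable": actionable,
        "nontargeted_node": nontargeted_node,
        "retest_fraction": retest_fraction,
    }


def _scenario_weights(scenario: ScenarioParams) -> tuple[float, float]:
    if abs(scenario.frac_inhouse + scenario.frac_sendout - 1.0) > 1e-9:
        raise ParameterError("scenario frac_inhouse + frac_sendout must equal 1")
    return scenario.frac_inhouse, scenario.frac_sendout


def _scenario_sendout_tat(p: ModelParameters, scenario: ScenarioParams) -> float:
    """Send-out turnaround applicable to a scenario's send-out tests.

    A pure send-out hospital sees the midpoint of the published range.  In a
    mixed scenario the residual send-out tests are, under the default
    ``"high"`` convention, the complex cases at the top of the range.
    """
    mid = p.tat.tat_sendout_midpoint
    if scenario.frac_inhouse > 0 and p.gaps.mixed_sendout_tat == "high":
        return p.tat.tat_sendout_high
    return mid


def mean_turnaround(
    p: ModelParameters,
    scenario: ScenarioParams,
    include_retests: bool = True,
) -> float:
    """Patient-weighted mean days from test dispatch to result.

    With ``include_retests`` the in-house arm adds the re-acquisition delay
    (``tat_inhouse`` extra days for the fraction of patients whose first
    tissue sample was insufficient).
    """
    w_ih, w_so = _scenario_weights(scenario)
    t_so = _scenario_sendout_tat(p, scenario)
    t_ih = p.tat.tat_inhouse
    if include_retests:
        t_ih = t_ih + p.testing.frac_tissue * p.testing.p_insufficient_tissue * p.tat.tat_inhouse
    return w_ih * t_ih + w_so * t_so


def pathway_distribution(p: ModelParameters, scenario: ScenarioParams) -> PathwayAllocation:
    """Mix the two pure arms by the scenario's testing proportions."""
    _require_valid(p)
    w_ih, w_so = _scenario_weights(scenario)
    ih = arm_masses(p, "inhouse")
    so = arm_masses(p, "sendout")

    def mix(key: str) -> float:
        return w_ih * ih[key] + w_so * so[key]

    m = p.money.retest_multiplier
    if scenario.comparator_mode == "single_gene":
        tests_sendout = 0.0
        tests_singlegene = w_so * m * p.gaps.singlegene_tests_per_patient
    else:
        tests_sendout = w_so * m
        tests_singlegene = 0.0

    return PathwayAllocation(
        mass_targeted_direct=mix("targeted_direct"),
        mass_interim=mix("interim"),
        mass_chemo=mix("chemo"),
        mass_immuno=mix("immuno"),
        mass_chemoimmuno=mix("chemo_immuno"),
        mass_lost_second_opinion=mix("lost"),
        tests_inhouse=w_ih * m,
        tests_sendout=tests_sendout,
        tests_singlegene=tests_singlegene,
        mean_tat=mean_turnaround(p, scenario),
    )


def second_opinion_loss(
    p: ModelParameters, scenario: ScenarioParams, cohort_size: float
) -> float:
    """Expected patients lost to second opinion per entering cohort."""
    alloc = pathway_distribution(p, scenario)
    return cohort_size * alloc.mass_lost_second_opinion


def tests_performed(p: ModelParameters, scenario: ScenarioParams) -> dict[str, float]:
    """Expected billed tests per patient by type.

    Billed counts are one test per patient scaled by the repeat-testing
    multiplier; the in-house re-acquisition re-run is part of the same billed
    test.  The single-gene comparator replaces each send-out NGS panel with
    ``gaps.singlegene_tests_per_patient`` single-gene assays.
    """
    alloc = pathway_distribution(p, scenario)
    return {
        "inhouse": alloc.tests_inhouse,
        "sendout": alloc.tests_sendout,
        "singlegene": alloc.tests_singlegene,
    }
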