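"""End-to-end triage pipeline over a population and funnel accounting.

The screening instrument is a multistep funnel: a large screened
population answers the primary questionnaire; eligible women are invited
to a Spoke centre for risk assessment; high-risk (profile 3) women and
women with a direct criterion reach a Hub centre; Hub-eligible families
undergo BRCA1/2 testing; positive results enter carrier surveillance.
Each step loses women to non-attendance, which the pipeline models as
independent Bernoulli draws with configurable acceptance probabilities
(all 1.0 by default, making the funnel deterministic).

Stage counts and the derived one-decimal percentages reproduce the
reporting style of such programmes: percentages are computed by exact
rational arithmetic and rounded half-up at one decimal.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import surveillance
from .grid_score import total_score
from .pedigree_io import Pedigree
from .referral_rules import (
    GeneticTestResult,
    Pathway,
    ReferralDecision,
    Route,
    VariantClass,
    classify_result,
    hub_test_eligibility,
    route,
    select_index_case,
)
from .risk_profile import (
    Covariates,
    DEFAULT_POPULATION_LIFETIME_RISK,
    RiskAssessment,
    RiskModel,
    assess,
)


class Source(str, enum.Enum):
    GP = "gp"
    SPECIALIST = "specialist"
    SCREENING_PROGRAM = "screening_program"


#: Age bands used when stratifying Spoke arrivals.
SPOKE_AGE_BANDS = ["<35", "35-39", "40-44", "45-49", "50-54", "55-59",
                   "60-64", "65-69", "70-74"]
#: Finer bands used for the tested cohort.
FINE_AGE_BANDS = ["<25", "25-29", "30-34", "35-39", "40-44", "45-49",
                  "50-54", "55-59", "60-64", "65-69", "70-74"]


def age_band(age: int, scheme: str = "spoke") -> str:
    """Assign an age to a reporting band (``spoke`` or ``fine`` scheme)."""
    bands = SPOKE_AGE_BANDS if scheme == "spoke" else FINE_AGE_BANDS
    for label in bands:
        if label.startswith("<"):
            if age < int(label[1:]):
                return label
        else:
            lo, hi = (int(x) for x in label.split("-"))
            if lo <= age <= hi:
                return label
    return bands[-1]


class UndefinedPercentage(ZeroDivisionError):
    pass


def percent(numerator: int, denominator: int) -> float:
    """One-decimal percentage with half-up rounding (exact arithmetic).

    ``percent(5615, 22289) == 25.2``. Raises on a zero denominator.
    """
    if denominator == 0:
        raise UndefinedPercentage(f"percentage {numerator}/0 is undefined")
    q = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass
class ScreeningRecord:
    """One woman entering the programme: her pedigree plus pipeline inputs."""

    pedigree: Pedigree
    covariates: Covariates = Covariates()
    source: Source = Source.SCREENING_PROGRAM
    lifetime_risk_ratio: Optional[float] = None
    test_result: Optional[GeneticTestResult] = None
    true_genotypes: Optional[dict[str, bool]] = None  # simulator truth, if any

    @property
    def proband_age(self) -> Optional[int]:
        return self.pedigree.proband.age


@dataclass
class PipelineParams:
    """Step acceptance probabilities and shared model settings.

    With every probability at 1 the pipeline is fully deterministic.
    """

    p_attend_spoke: float = 1.0     # invited -> phones/attends the Spoke
    p_complete_spoke: float = 1.0   # arrived -> completes the assessment
    p_attend_hub: float = 1.0       # referred -> evaluated at the Hub
    p_accept_test: float = 1.0      # eligible -> test performed
    seed: int = 0
    population_lifetime_risk: float = DEFAULT_POPULATION_LIFETIME_RISK
    risk_model: Optional[RiskModel] = None  # None: the toy model inside assess()


@dataclass
class RecordDecision:
    """Everything decided for one record along the funnel."""

    grid_total: int
    referral: ReferralDecision
    source: Source
    proband_age: Optional[int]
    attended_spoke: bool = False
    evaluated: bool = False
    assessment: Optional[RiskAssessment] = None
    hub_referred: bool = False
    hub_evaluated: bool = False
    test_eligible: bool = False
    index_case: Optional[str] = None
    tested: bool = False
    test_result: Optional[GeneticTestResult] = None
    pathway: Optional[Pathway] = None
    surveillance_basis: Optional[surveillance.PlanBasis] = None


@dataclass
class FunnelStats:
    stages: list[tuple[str, int]]
    derived: list[tuple[str, str, str, float]] = field(default_factory=list)
    strata: dict[str, pd.DataFrame] = field(default_factory=dict)

    def stage(self, name: str) -> int:
        for n, c in self.stages:
            if n == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count"])


STAGE_ORDER = [
    "records", "no_referral", "spoke_invited", "hub_direct",
    "spoke_attended", "spoke_refused_assessment", "spoke_evaluated",
    "profile_LR", "profile_IR", "profile_HR",
    "hub_referred", "hub_evaluated", "test_eligible", "tested", "carriers",
]


def _simulated_result(rec: ScreeningRecord, index_case: Optional[str]) -> Optional[GeneticTestResult]:
    """Derive a deterministic test result from simulator genotype truth."""
    if rec.true_genotypes is None:
        return None
    subject = index_case if index_case is not None else rec.pedigree.proband_id
    carrier = rec.true_genotypes.get(subject, False)
    return GeneticTestResult(
        variant_class=VariantClass.C5 if carrier else VariantClass.C1
    )


def run_pipeline(
    population: Sequence[ScreeningRecord],
    params: PipelineParams | None = None,
) -> tuple[list[RecordDecision], FunnelStats]:
    """Run every record through grid -> routing -> risk profile -> Hub ->
    testing -> surveillance, and aggregate stage counts."""
    params = params or PipelineParams()
    rng = np.random.default_rng(params.seed)
    decisions: list[RecordDecision] = []

    for rec in population:
        if not isinstance(rec.source, Source):
            rec.source = Source(rec.source)
        gs = total_score(rec.pedigree)
        ref = route(rec.pedigree, gs)
        dec = RecordDecision(
            grid_total=gs.total,
            referral=ref,
            source=rec.source,
            proband_age=rec.proband_age,
        )
        decisions.append(dec)
        if ref.route is Route.NONE:
            continue

        if ref.route is Route.SPOKE:
            if rng.random() >= params.p_attend_spoke:
                continue
            dec.attended_spoke = True
            if rng.random() >= params.p_complete_spoke:
                continue
            dec.evaluated = True
            dec.assessment = assess(
                rec.pedigree,
                rec.covariates,
                model=params.risk_model,
                population_lifetime_risk=params.population_lifetime_risk,
                lifetime_risk_ratio=rec.lifetime_risk_ratio,
            )
            if not dec.assessment.hub_referable:
                dec.surveillance_basis = (
                    surveillance.PlanBasis.PROFILE1
                    if dec.assessment.profile == 1
                    else surveillance.PlanBasis.PROFILE2
                )
                continue
            dec.hub_referred = True
        else:  # direct criterion: straight to the Hub
            dec.hub_referred = True

        if rng.random() >= params.p_attend_hub:
            continue
        dec.hub_evaluated = True
        eligible, _criteria = hub_test_eligibility(rec.pedigree)
        dec.test_eligible = eligible
        if not eligible:
            dec.surveillance_basis = surveillance.PlanBasis.PROFILE3_NO_MUTATION
            continue
        dec.index_case = select_index_case(rec.pedigree)
        result = rec.test_result or _simulated_result(rec, dec.index_case)
        if dec.index_case is None or result is None or rng.random() >= params.p_accept_test:
            dec.surveillance_basis = surveillance.PlanBasis.PROFILE3_NO_MUTATION
            continue
        dec.tested = True
        dec.test_result = result
        dec.pathway = classify_result(result, dec.assessment)
        if dec.pathway is Pathway.CARRIER_SURVEILLANCE:
            dec.surveillance_basis = surveillance.PlanBasis.PROFILE3_MUTATION
        else:
            profile = dec.assessment.profile if dec.assessment else 3
            dec.surveillance_basis = {
                1: surveillance.PlanBasis.PROFILE1,
                2: surveillance.PlanBasis.PROFILE2,
                3: surveillance.PlanBasis.PROFILE3_NO_MUTATION,
            }[profile]

    return decisions, summarize(decisions)


def summarize(decisions: Sequence[RecordDecision]) -> FunnelStats:
    """Aggregate per-record decisions into ordered stage counts."""
    c = {name: 0 for name in STAGE_ORDER}
    c["records"] = len(decisions)
    for d in decisions:
        r = d.referral.route
        if r is Route.NONE:
            c["no_referral"] += 1
        elif r is Route.SPOKE:
            c["spoke_invited"] += 1
        else:
            c["hub_direct"] += 1
        c["spoke_attended"] += d.attended_spoke
        c["spoke_refused_assessment"] += d.attended_spoke and not d.evaluated
        c["spoke_evaluated"] += d.evaluated
        if d.assessment is not None:
            c[f"profile_{('LR', 'IR', 'HR')[d.assessment.profile - 1]}"] += 1
        c["hub_referred"] += d.hub_referred
        c["hub_evaluated"] += d.hub_evaluated
        c["test_eligible"] += d.test_eligible
        c["tested"] += d.tested
        c["carriers"] += bool(d.test_result and d.test_result.carrier and d.tested)
    stages = [(name, c[name]) for name in STAGE_ORDER]
    derived = []
    for label, num, den in [
        ("spoke_attendance", "spoke_attended", "spoke_invited"),
        ("high_risk_fraction", "profile_HR", "spoke_evaluated"),
        ("hub_attendance", "hub_evaluated", "hub_referred"),
        ("test_rate", "tested", "hub_evaluated"),
        ("carrier_yield", "carriers", "tested"),
    ]:
        if c[den] > 0:
            derived.append((label, num, den, percent(c[num], c[den])))
    return FunnelStats(stages=stages, derived=derived)


def funnel_from_counts(
    stages: Sequence[tuple[str, int]],
    derived: Sequence[tuple[str, str, str]] = (),
) -> FunnelStats:
    """Build funnel statistics from externally supplied stage counts.

    ``derived`` lists (label, numerator stage, denominator stage) triples;
    each percentage is computed with :func:`percent`.
    """
    stages = [(str(n), int(c)) for n, c in stages]
    lookup = dict(stages)
    out = []
    for label, num, den in derived:
        out.append((label, num, den, percent(lookup[num], lookup[den])))
    return FunnelStats(stages=stages, derived=out)


def published_counts() -> dict:
    """The published five-year stage counts of the Emilia-Romagna programme,
    shipped as package data (inputs for funnel reporting, not outputs)."""
    import importlib.resources as res
    import json

    with res.files("hboc_triage").joinpath("data/reported_counts.json").open() as fh:
        return json.load(fh)


def published_funnel() -> FunnelStats:
    """Funnel statistics recomputed from the published stage counts."""
    data = published_counts()
    return funnel_from_counts(data["stages"], data["derived"])


def tabulate(
    decisions: Sequence[RecordDecision],
    by: tuple[str, ...] = ("age_band", "source"),
    scheme: str = "spoke",
) -> pd.DataFrame:
    """Cross-tabulate decisions by age band and/or referral source,
    with row/column totals."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "age_band": age_band(d.proband_age, scheme) if d.proband_age is not None else "unknown",
                "source": d.source.value,
                "route": d.referral.route.value,
            }
        )
    df = pd.DataFrame(rows)
    if not len(df):
        return pd.DataFrame()
    if len(by) == 2:
        out = pd.crosstab(df[by[0]], df[by[1]], margins=True, margins_name="Total")
    else:
        out = df[by[0]].value_counts().to_frame("count")
        out.loc["Total"] = out["count"].sum()
    return out
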