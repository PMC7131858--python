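"""Lifetime-risk profiles behind a pluggable risk-model contract.

The screening programme stratifies women by the ratio of their lifetime
breast-cancer risk to the general-population lifetime risk, as produced by
an external risk calculator (the programme used Tyrer-Cuzick). Only the
calculator's *outputs* are modelled here: any callable returning a 10-year
risk and a lifetime risk satisfies the contract, and externally computed
ratios can be injected per record.

Profile bands on the ratio scale: profile 1 (low) for ratio < 2, profile 2
(intermediate) for 2 <= ratio <= 3, profile 3 (high) for ratio > 3. The
low/intermediate boundary is a documented convention: the programme's
verbal description ("at most 1 time more", "between two and three times
more") does not pin down the (1x, 2x) interval, and this package assigns
it to profile 1. Profile-3 women are referred to the Hub tier.

A deliberately simple multiplicative relative-risk model
(:func:`toy_risk_model`) ships for exercising the pipeline end to end; it
is a documented toy, not a reimplementation of any published calculator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from .pedigree_io import Pedigree, Relation, Site, relation_to_proband

#: Default general-population lifetime breast-cancer risk (~1 in 10).
DEFAULT_POPULATION_LIFETIME_RISK = 0.10

#: Profile band edges on the ratio scale.
INTERMEDIATE_MIN = 2.0
HIGH_MIN = 3.0  # exclusive


@dataclass(frozen=True)
class Covariates:
    """Personal covariates an external risk calculator would collect."""

    age: Optional[int] = None
    age_at_menarche: Optional[int] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    parity: Optional[int] = None
    previous_breast_lesions: bool = False
    menopausal: Optional[bool] = None


@dataclass(frozen=True)
class RiskAssessment:
    ten_year_risk: float
    lifetime_risk: float
    population_lifetime_risk: float
    ratio: float
    profile: int

    @property
    def hub_referable(self) -> bool:
        return self.profile == 3


RiskModel = Callable[[Pedigree, Covariates], tuple[float, float]]


def classify_profile(
    ratio: float,
    intermediate_min: float = INTERMEDIATE_MIN,
    high_min: float = HIGH_MIN,
) -> int:
    """Profile from a lifetime-risk ratio: [0, 2) -> 1, [2, 3] -> 2, (3, inf) -> 3."""
    if ratio < 0:
        raise ValueError(f"negative risk ratio: {ratio}")
    if ratio > high_min:
        return 3
    if ratio >= intermediate_min:
        return 2
    return 1


_FIRST_DEGREE = {Relation.MOTHER, Relation.SISTER, Relation.DAUGHTER}
_SECOND_DEGREE = {
    Relation.PATERNAL_GRANDMOTHER,
    Relation.MATERNAL_GRANDMOTHER,
    Relation.PATERNAL_AUNT,
    Relation.MATERNAL_AUNT,
    Relation.NIECE,
}

#: Relative-risk factors for the toy model, keyed by (degree, site, early onset).
#: Early onset means breast cancer before 40. Values are conventional
#: order-of-magnitude familial relative risks chosen so that two young-onset
#: first-degree breast cancers exceed the high-risk (3x) threshold.
TOY_RR_TABLE: dict[tuple[str, str, bool], float] = {
    ("first", "breast", True): 2.0,
    ("first", "breast", False): 1.5,
    ("second", "breast", True): 1.5,
    ("second", "breast", False): 1.2,
    ("first", "ovary", False): 1.8,
    ("second", "ovary", False): 1.3,
}


def toy_risk_model(
    ped: Pedigree,
    covariates: Covariates = Covariates(),
    baseline: float = DEFAULT_POPULATION_LIFETIME_RISK,
    rr_table: dict[tuple[str, str, bool], float] | None = None,
) -> tuple[float, float]:
    """Multiplicative family-history relative-risk model (pipeline exercise only).

    Lifetime risk = baseline x product of one factor per affected first- or
    second-degree relative's diagnosis, capped at 1. The 10-year risk is
    derived from the lifetime risk assuming a uniform hazard over a 55-year
    adult horizon. Deterministic; monotone in family history.
    """
    table = TOY_RR_TABLE if rr_table is None else rr_table
    product = 1.0
    for iid in sorted(ped.individuals):
        if iid == ped.proband_id:
            continue
        rel = relation_to_proband(ped, iid)
        if rel in _FIRST_DEGREE:
            degree = "first"
        elif rel in _SECOND_DEGREE:
            degree = "second"
        else:
            continue
        for dx in ped[iid].diagnoses:
            early = (
                dx.site is Site.BREAST
                and dx.age_at_onset is not None
                and dx.age_at_onset < 40
            )
            key = (degree, dx.site.value, early if dx.site is Site.BREAST else False)
            product *= table.get(key, 1.0)
    lifetime = min(1.0, baseline * product)
    ten_year = 1.0 - (1.0 - lifetime) ** (10.0 / 55.0)
    return ten_year, lifetime


def assess(
    ped: Pedigree,
    covariates: Covariates = Covariates(),
    model: RiskModel | None = None,
    population_lifetime_risk: float = DEFAULT_POPULATION_LIFETIME_RISK,
    lifetime_risk_ratio: Optional[float] = None,
) -> RiskAssessment:
    """Run a risk model (or accept an external ratio) and classify the profile.

    ``lifetime_risk_ratio``, when given, bypasses the model entirely — this
    is how externally computed Tyrer-Cuzick outputs are injected.
    """
    if not 0 < population_lifetime_risk <= 1:
        raise ValueError("population_lifetime_risk must be in (0, 1]")
    if lifetime_risk_ratio is not None:
        lifetime = lifetime_risk_ratio * population_lifetime_risk
        ten_year = float("nan")
        ratio = lifetime_risk_ratio
    else:
        fn = model if model is not None else toy_risk_model
        ten_year, lifetime = fn(ped, covariates)
        name = getattr(fn, "__name__", repr(fn))
        for label, value in (("ten_year_risk", ten_year), ("lifetime_risk", lifetime)):
            if not 0 <= value <= 1:
                raise ValueError(f"risk model {name!r} returned {label}={value} outside [0, 1]")
        ratio = lifetime / population_lifetime_risk
    return RiskAssessment(
        ten_year_risk=ten_year,
        lifetime_risk=lifetime,
        population_lifetime_risk=population_lifetime_risk,
        ratio=ratio,
        profile=classify_profile(ratio),
    )
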