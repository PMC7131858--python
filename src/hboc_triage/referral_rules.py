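"""Direct Hub criteria, Spoke/Hub routing, test eligibility and result routing.

Seven family-history features send a woman straight to the Hub (genetic
counselling) tier, bypassing the Spoke risk assessment:

* male breast cancer anywhere in the family;
* breast AND ovarian cancer in the same patient or across the family;
* early-onset breast cancer (<=35 years);
* bilateral breast cancer at <=50 years;
* ovarian cancer that is neither mucinous nor borderline;
* two first-degree-related relatives with breast cancer, one of whom was
  diagnosed at <=40 years or bilaterally;
* triple-negative breast cancer at <=60 years.

The same feature set defines eligibility for BRCA1/2 testing at the Hub.
Without a direct criterion, routing falls back on the questionnaire grid
(total >=2) or on the proband's own breast cancer at 36–40 years, both of
which trigger the Spoke referral.

All criteria are evaluated over blood relatives of the proband (including
the proband); a relative by marriage present as a link node never counts.
Unknown onset ages never satisfy an age-thresholded criterion.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .pedigree_io import (
    Pedigree,
    Site,
    Trilean,
    first_degree_pairs,
)

Evidence = tuple[str, int]  # (individual_id, diagnosis_index)


class CriterionCode(str, enum.Enum):
    MALE_BC = "MALE_BC"
    BC_AND_OC = "BC_AND_OC"
    EARLY_ONSET_BC = "EARLY_ONSET_BC"
    BILATERAL_BC_LE50 = "BILATERAL_BC_LE50"
    NONMUC_NONBORD_OC = "NONMUC_NONBORD_OC"
    TWO_FDR_BC = "TWO_FDR_BC"
    TNBC_LE60 = "TNBC_LE60"


class Route(str, enum.Enum):
    NONE = "none"
    SPOKE = "spoke"
    HUB_DIRECT = "hub_direct"


#: Non-criterion routing reasons.
GRID_GE2 = "GRID_GE2"
BC_36_40 = "BC_36_40"


@dataclass(frozen=True)
class Criterion:
    code: CriterionCode
    evidence: tuple[Evidence, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError(f"criterion {self.code} reported satisfied without evidence")


@dataclass
class ReferralDecision:
    route: Route
    reasons: list[str] = field(default_factory=list)
    criteria: list[Criterion] = field(default_factory=list)


class VariantClass(str, enum.Enum):
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    C5 = "C5"
    NOT_TESTED = "not_tested"


class Gene(str, enum.Enum):
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"
    NONE = "none"


@dataclass(frozen=True)
class GeneticTestResult:
    """Outcome of BRCA1/2 analysis, classified into pathogenicity tiers C1–C5.

    C4 (likely pathogenic) and C5 (pathogenic) are positive results: the
    woman is a carrier. C1–C3 (benign through uncertain) are managed by
    risk profile instead.
    """

    gene: Gene = Gene.NONE
    variant_class: VariantClass = VariantClass.NOT_TESTED

    @property
    def carrier(self) -> bool:
        return self.variant_class in (VariantClass.C4, VariantClass.C5)


class Pathway(str, enum.Enum):
    CARRIER_SURVEILLANCE = "carrier_surveillance"
    PROFILE_BASED = "profile_based"


EARLY_ONSET_AGE = 35
BILATERAL_AGE = 50
TNBC_AGE = 60
FDR_YOUNG_AGE = 40


def _dx_items(ped: Pedigree, blood: set[str]):
    for iid in sorted(blood):
        for k, dx in enumerate(ped[iid].diagnoses):
            yield iid, k, ped[iid], dx


def direct_hub_criteria(ped: Pedigree) -> list[Criterion]:
    """Evaluate the seven direct-referral criteria, with evidence."""
    blood = ped.blood_relatives()
    found: list[Criterion] = []

    def add(code: CriterionCode, ev: list[Evidence]) -> None:
        if ev:
            found.append(Criterion(code=code, evidence=tuple(ev)))

    male_bc = [
        (iid, k)
        for iid, k, ind, dx in _dx_items(ped, blood)
        if ind.sex.value == "male" and dx.site is Site.BREAST
    ]
    add(CriterionCode.MALE_BC, male_bc)

    # BC and OC in the same patient, or both sites across the family
    bc = [(iid, k) for iid, k, _, dx in _dx_items(ped, blood) if dx.site is Site.BREAST]
    oc = [(iid, k) for iid, k, _, dx in _dx_items(ped, blood) if dx.site is Site.OVARY]
    if bc and oc:
        same = {iid for iid, _ in bc} & {iid for iid, _ in oc}
        if same:
            ev = [e for e in bc + oc if e[0] in same]
        else:
            ev = bc + oc
        add(CriterionCode.BC_AND_OC, sorted(ev))

    add(
        CriterionCode.EARLY_ONSET_BC,
        [
            (iid, k)
            for iid, k, _, dx in _dx_items(ped, blood)
            if dx.site is Site.BREAST
            and dx.age_at_onset is not None
            and dx.age_at_onset <= EARLY_ONSET_AGE
        ],
    )
    add(
        CriterionCode.BILATERAL_BC_LE50,
        [
            (iid, k)
            for iid, k, _, dx in _dx_items(ped, blood)
            if dx.is_bilateral
            and dx.age_at_onset is not None
            and dx.age_at_onset <= BILATERAL_AGE
        ],
    )
    add(
        CriterionCode.NONMUC_NONBORD_OC,
        [
            (iid, k)
            for iid, k, _, dx in _dx_items(ped, blood)
            if dx.site is Site.OVARY
            and dx.mucinous is Trilean.NO
            and dx.borderline is Trilean.NO
        ],
    )

    # Two first-degree-related BC cases, one <=40 or bilateral. The proband
    # counts as one of the two.
    bc_ids = {iid for iid, _ in bc}
    qualifying: set[Evidence] = set()
    for pair in first_degree_pairs(ped, bc_ids):
        a, b = sorted(pair)
        pair_dx = [(iid, k) for iid, k in bc if iid in (a, b)]
        if any(
            (dx := ped[iid].diagnoses[k]).is_bilateral
            or (dx.age_at_onset is not None and dx.age_at_onset <= FDR_YOUNG_AGE)
            for iid, k in pair_dx
        ):
            qualifying.update(pair_dx)
    add(CriterionCode.TWO_FDR_BC, sorted(qualifying))

    add(
        CriterionCode.TNBC_LE60,
        [
            (iid, k)
            for iid, k, _, dx in _dx_items(ped, blood)
            if dx.site is Site.BREAST
            and dx.triple_negative is Trilean.YES
            and dx.age_at_onset is not None
            and dx.age_at_onset <= TNBC_AGE
        ],
    )
    return found


def _proband_bc_36_40(ped: Pedigree) -> bool:
    return any(
        dx.site is Site.BREAST
        and dx.age_at_onset is not None
        and 36 <= dx.age_at_onset <= 40
        for dx in ped.proband.diagnoses
    )


def route(ped: Pedigree, gs) -> ReferralDecision:
    """Route a screened woman: direct Hub, Spoke, or no referral.

    A direct criterion wins; otherwise grid total >=2 or the proband's own
    breast cancer at 36–40 years triggers the Spoke referral. All triggers
    are listed in ``reasons``.
    """
    criteria = direct_hub_criteria(ped)
    reasons: list[str] = [c.code.value for c in criteria]
    if gs.spoke_eligible:
        reasons.append(GRID_GE2)
    if _proband_bc_36_40(ped):
        reasons.append(BC_36_40)
    if criteria:
        return ReferralDecision(route=Route.HUB_DIRECT, reasons=reasons, criteria=criteria)
    if gs.spoke_eligible or BC_36_40 in reasons:
        return ReferralDecision(route=Route.SPOKE, reasons=reasons)
    return ReferralDecision(route=Route.NONE, reasons=[])


def hub_test_eligibility(ped: Pedigree) -> tuple[bool, list[Criterion]]:
    """Eligibility for BRCA1/2 testing at the Hub.

    The Hub eligibility list restates the direct-referral features, so the
    same predicate set is evaluated. A woman referred on risk profile alone
    with no criterion is not test-eligible; she is followed under the
    profile-3 surveillance protocol instead.
    """
    criteria = direct_hub_criteria(ped)
    return bool(criteria), criteria


_NO_BC_AGE = 10**6


def _index_rank(ped: Pedigree, iid: str) -> tuple:
    ind = ped[iid]
    sites = {dx.site for dx in ind.diagnoses}
    both = Site.BREAST in sites and Site.OVARY in sites
    nmnb_oc = any(
        dx.site is Site.OVARY and dx.mucinous is Trilean.NO and dx.borderline is Trilean.NO
        for dx in ind.diagnoses
    )
    bc_ages = [
        dx.age_at_onset
        for dx in ind.diagnoses
        if dx.site is Site.BREAST and dx.age_at_onset is not None
    ]
    bilateral = any(dx.is_bilateral for dx in ind.diagnoses)
    return (
        0 if both else 1,
        0 if nmnb_oc else 1,
        min(bc_ages) if bc_ages else _NO_BC_AGE,
        0 if bilateral else 1,
        0 if iid == ped.proband_id else 1,
        iid,
    )


def select_index_case(ped: Pedigree) -> Optional[str]:
    """Pick the most indicative alive affected family member for testing.

    Ranking (documented heuristic): both breast and ovarian cancer, then
    non-mucinous non-borderline ovarian cancer, then earliest breast-cancer
    onset, then bilateral disease, with the proband preferred on ties.
    Returns None when no affected family member is alive.
    """
    candidates = [
        iid
        for iid in ped.blood_relatives()
        if ped[iid].affected and ped[iid].alive is Trilean.YES
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda iid: _index_rank(ped, iid))


def classify_result(res: GeneticTestResult, ra) -> Pathway:
    """Route a released test result: carriers (C4/C5) to carrier
    surveillance, C1–C3 to the risk-profile-based schedule."""
    if res.variant_class is VariantClass.NOT_TESTED:
        raise ValueError("cannot classify an untested result")
    if res.carrier:
        return Pathway.CARRIER_SURVEILLANCE
    if ra is None:
        warnings.warn("no risk assessment supplied for a non-carrier result")
    return Pathway.PROFILE_BASED
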