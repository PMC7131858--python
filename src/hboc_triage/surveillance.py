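"""Surveillance schedule generation per risk profile and mutation status.

Schedules are emitted as lists of :class:`ScheduleItem` — modality, age
window, interval — reproducing the programme's surveillance table:

* profile 1: the population screening programme (annual mammography
  45–50, biennial 51–74);
* profile 2: programme entry at 25 (if a relative had early-onset breast
  cancer) or 36; annual mammography 40–50, biennial 51–74; ultrasound
  above 41 only with high breast density; MRI per EUSOMA guidelines;
* profile 3 without a detected mutation: six-monthly ultrasound 25–60,
  annual mammography 35–69, biennial 70–74, MRI per EUSOMA guidelines;
* proven BRCA1/2 carriers: six-monthly breast ultrasound from mutation
  detection (never before 18) to 69, annual breast MRI 25–74, annual
  mammography 35–69 and biennial 70–74, plus six-monthly transvaginal
  ultrasound with Ca.125 for ovarian surveillance.

Modifiers: after bilateral mastectomy only six-monthly ultrasound remains
among the breast modalities; after a prior ovarian cancer the ovarian
surveillance reduces to six-monthly Ca.125 alone.

MRI "per EUSOMA guidelines" is an opaque marker item — the external
guideline's age/interval rules are not reproduced here.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Optional


class Modality(str, enum.Enum):
    US = "US"
    MMG = "MMG"
    MRI = "MRI"
    TVUS_CA125 = "TVUS_CA125"
    CA125_ONLY = "CA125_ONLY"
    POPULATION_SCREENING = "POPULATION_SCREENING"
    MRI_PER_EUSOMA = "MRI_PER_EUSOMA"


class PlanBasis(str, enum.Enum):
    PROFILE1 = "profile1"
    PROFILE2 = "profile2"
    PROFILE3_NO_MUTATION = "profile3_no_mutation"
    PROFILE3_MUTATION = "profile3_mutation"


class Modifier(str, enum.Enum):
    POST_MASTECTOMY = "post_mastectomy"
    PRIOR_OC = "prior_OC"
    RELATIVE_EOBC = "relative_EOBC"
    HIGH_DENSITY = "high_density"


BREAST_MODALITIES = {Modality.US, Modality.MMG, Modality.MRI, Modality.MRI_PER_EUSOMA}
OVARIAN_MODALITIES = {Modality.TVUS_CA125, Modality.CA125_ONLY}

#: Ovarian surveillance is not offered before this age (it targets adult
#: carriers who decline or are too young for risk-reducing surgery).
OVARIAN_SURVEILLANCE_MIN_AGE = 30


@dataclass(frozen=True)
class ScheduleItem:
    modality: Modality
    start_age: int
    end_age: int
    interval_months: int
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start_age > self.end_age:
            raise ValueError(f"start_age {self.start_age} > end_age {self.end_age}")
        if self.interval_months not in (6, 12, 24):
            raise ValueError(f"interval_months must be 6, 12 or 24, got {self.interval_months}")


@dataclass
class SurveillancePlan:
    basis: PlanBasis
    items: list[ScheduleItem]
    modifiers: frozenset[Modifier] = frozenset()
    start_age: Optional[int] = None  # programme entry age, where defined


def _annual_biennial_mmg(annual: tuple[int, int], biennial: tuple[int, int],
                         condition: str | None = None) -> list[ScheduleItem]:
    return [
        ScheduleItem(Modality.MMG, *annual, interval_months=12, condition=condition),
        ScheduleItem(Modality.MMG, *biennial, interval_months=24, condition=condition),
    ]


def build_plan(
    profile: int,
    carrier: bool,
    current_age: int,
    modifiers: Iterable[Modifier] = (),
) -> SurveillancePlan:
    """Build the surveillance plan for one woman.

    A proven carrier is always managed under the mutation protocol (a
    carrier with profile < 3 is normalized with a warning). ``current_age``
    stands in for the mutation-detection age when setting the carrier
    ultrasound start.
    """
    mods = frozenset(Modifier(m) for m in modifiers)
    if carrier and profile != 3:
        warnings.warn(f"carrier with profile {profile}: managed as profile3_mutation")
        profile = 3

    if carrier:
        basis = PlanBasis.PROFILE3_MUTATION
        us_start = max(18, current_age)
        items = [
            ScheduleItem(Modality.US, us_start, 69, 6),
            ScheduleItem(Modality.MRI, 25, 74, 12),
            *_annual_biennial_mmg((35, 69), (70, 74)),
            ScheduleItem(
                Modality.TVUS_CA125,
                max(OVARIAN_SURVEILLANCE_MIN_AGE, current_age),
                74,
                6,
            ),
        ]
        plan = SurveillancePlan(basis=basis, items=items, modifiers=mods,
                                start_age=us_start)
    elif profile == 3:
        items = [
            ScheduleItem(Modality.US, 25, 60, 6),
            *_annual_biennial_mmg((35, 69), (70, 74)),
            ScheduleItem(Modality.MRI_PER_EUSOMA, 25, 74, 12,
                         condition="per EUSOMA guidelines"),
        ]
        plan = SurveillancePlan(basis=PlanBasis.PROFILE3_NO_MUTATION, items=items,
                                modifiers=mods, start_age=25)
    elif profile == 2:
        start = 25 if Modifier.RELATIVE_EOBC in mods else 36
        items = _annual_biennial_mmg((40, 50), (51, 74))
        if Modifier.HIGH_DENSITY in mods:
            items.append(ScheduleItem(Modality.US, 42, 74, 12,
                                      condition="if high breast density"))
        items.append(ScheduleItem(Modality.MRI_PER_EUSOMA, start, 74, 12,
                                  condition="per EUSOMA guidelines"))
        plan = SurveillancePlan(basis=PlanBasis.PROFILE2, items=items,
                                modifiers=mods, start_age=start)
    elif profile == 1:
        items = _annual_biennial_mmg((45, 50), (51, 74), condition="population screening")
        plan = SurveillancePlan(basis=PlanBasis.PROFILE1, items=items,
                                modifiers=mods, start_age=45)
    else:
        raise ValueError(f"profile must be 1, 2 or 3, got {profile}")

    return _apply_modifiers(plan)


def _apply_modifiers(plan: SurveillancePlan) -> SurveillancePlan:
    items = list(plan.items)
    if Modifier.POST_MASTECTOMY in plan.modifiers:
        # After bilateral mastectomy the residual breast-cancer risk is low
        # (~4-5%): keep only six-monthly ultrasound among breast modalities.
        breast = [i for i in items if i.modality in BREAST_MODALITIES]
        other = [i for i in items if i.modality not in BREAST_MODALITIES]
        us = [i for i in breast if i.modality is Modality.US]
        if us:
            items = [replace(i, interval_months=6) for i in us] + other
        else:
            start = plan.start_age if plan.start_age is not None else 18
            items = [ScheduleItem(Modality.US, max(18, start), 69, 6)] + other
    if Modifier.PRIOR_OC in plan.modifiers:
        items = [
            replace(i, modality=Modality.CA125_ONLY)
            if i.modality is Modality.TVUS_CA125
            else i
            for i in items
        ]
    return SurveillancePlan(basis=plan.basis, items=items,
                            modifiers=plan.modifiers, start_age=plan.start_age)


#: Marker items carry no concrete schedule and are excluded from counting.
_OPAQUE = {Modality.MRI_PER_EUSOMA, Modality.POPULATION_SCREENING}


def appointments_in_window(
    plan: SurveillancePlan, from_age: float, to_age: float
) -> dict[Modality, int]:
    """Count scheduled events per modality in the half-open window [from, to).

    Events for an item fall at ``start_age``, ``start_age + interval``, ...
    while not exceeding ``end_age``. Exact rational arithmetic is used so
    six-monthly grids never suffer float drift. Opaque guideline markers
    are not counted.
    """
    if from_age > to_age:
        raise ValueError("from_age must be <= to_age")
    counts: dict[Modality, int] = {}
    lo, hi = Fraction(from_age), Fraction(to_age)
    for item in plan.items:
        if item.modality in _OPAQUE:
            continue
        step = Fraction(item.interval_months, 12)
        start, end = Fraction(item.start_age), Fraction(item.end_age)
        n = 0
        # first event index k with start + k*step >= lo
        k = max(0, -((lo - start) // -step)) if lo > start else 0
        t = start + k * step
        while t < hi and t <= end:
            n += 1
            t += step
        if n:
            counts[item.modality] = counts.get(item.modality, 0) + n
    return counts
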