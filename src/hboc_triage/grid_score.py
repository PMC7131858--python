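"""Primary-questionnaire scoring grid and the Spoke-referral threshold.

Each breast/ovarian cancer diagnosis in the family contributes 0, 1 or 2
points depending on the relative's kinship row and, for breast cancer, on
an age-at-onset band (<40; 40–49 split by laterality; 50–59; >=60).
Ovarian cancer has a single column per row. Male breast cancer is scored
by a dedicated row worth 2 points at any age and any kinship. A total of
>=2 points makes the woman eligible for the Spoke (risk-counselling)
referral.

Conventions where the printed grid is silent:

* bilateral disease is one diagnosis; laterality only splits the 40–49
  band, so a bilateral cancer at <40 or >=50 scores under its age column;
* unknown laterality in 40–49 scores as monolateral (the lower cell) with
  a warning;
* an unknown age at onset contributes 0 points with a warning — the
  direct referral criteria are evaluated separately and are not affected.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

from .pedigree_io import (
    CancerDiagnosis,
    Laterality,
    Pedigree,
    Relation,
    Sex,
    Site,
    relation_to_proband,
)

SPOKE_THRESHOLD = 2


class AgeBand(str, enum.Enum):
    UNDER_40 = "<40"
    B40_49_BILATERAL = "40-49 bilateral"
    B40_49_MONOLATERAL = "40-49 monolateral"
    B50_59 = "50-59"
    GE_60 = ">=60"
    OC = "OC"


_BC_BANDS = [
    AgeBand.UNDER_40,
    AgeBand.B40_49_BILATERAL,
    AgeBand.B40_49_MONOLATERAL,
    AgeBand.B50_59,
    AgeBand.GE_60,
]

# Questionnaire rows: points per breast-cancer band, then the single OC cell.
_GRID: dict[Relation, tuple[tuple[int, int, int, int, int], int]] = {
    Relation.SELF: ((2, 2, 1, 1, 0), 2),
    Relation.MOTHER: ((2, 2, 1, 1, 0), 1),
    Relation.SISTER: ((2, 2, 1, 1, 0), 1),
    Relation.DAUGHTER: ((2, 2, 1, 1, 0), 1),
    Relation.PATERNAL_GRANDMOTHER: ((2, 2, 1, 1, 0), 1),
    Relation.PATERNAL_AUNT: ((2, 2, 1, 1, 0), 1),
    Relation.MATERNAL_GRANDMOTHER: ((1, 1, 1, 0, 0), 1),
    Relation.MATERNAL_AUNT: ((1, 1, 1, 0, 0), 1),
    Relation.PATERNAL_COUSIN: ((1, 0, 0, 0, 0), 1),
    Relation.NIECE: ((1, 1, 1, 0, 0), 1),
    Relation.OTHER: ((0, 0, 0, 0, 0), 0),
}

# Male breast cancer: its own row, 2 points in every age band, no OC cell.
_MBC_POINTS = 2


@dataclass(frozen=True)
class ScoreContribution:
    individual_id: str
    relation: Relation
    diagnosis_index: int
    band: AgeBand | None  # None: breast cancer with unknown onset age
    points: int


@dataclass
class GridScore:
    contributions: list[ScoreContribution] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(c.points for c in self.contributions)

    @property
    def spoke_eligible(self) -> bool:
        return self.total >= SPOKE_THRESHOLD


def _bc_band(dx: CancerDiagnosis) -> AgeBand:
    age = dx.age_at_onset
    assert age is not None
    if age < 40:
        return AgeBand.UNDER_40
    if age < 50:
        if dx.laterality is Laterality.BILATERAL:
            return AgeBand.B40_49_BILATERAL
        if dx.laterality is Laterality.UNKNOWN:
            warnings.warn(
                "unknown laterality in the 40-49 band scored as monolateral",
                stacklevel=3,
            )
        return AgeBand.B40_49_MONOLATERAL
    if age < 60:
        return AgeBand.B50_59
    return AgeBand.GE_60


def diagnosis_band(dx: CancerDiagnosis) -> AgeBand | None:
    """The grid column a diagnosis falls in; None for unknown-age BC."""
    if dx.site is Site.OVARY:
        return AgeBand.OC
    if dx.age_at_onset is None:
        return None
    return _bc_band(dx)


def score_diagnosis(relation: Relation, dx: CancerDiagnosis, is_male: bool = False) -> int:
    """Points for one diagnosis under the questionnaire grid.

    ``is_male`` routes any breast cancer onto the male-BC row (2 points at
    every age, regardless of the kinship label). Ovarian cancer in a male
    is a contract violation blocked by pedigree validation.
    """
    relation = Relation(relation)
    if is_male:
        if dx.site is Site.OVARY:
            raise ValueError("male individual cannot have an ovary diagnosis")
        return _MBC_POINTS
    band = diagnosis_band(dx)
    if band is None:
        warnings.warn(
            "breast diagnosis with unknown age at onset contributes 0 grid points",
            stacklevel=2,
        )
        return 0
    bc_row, oc_cell = _GRID[relation]
    if band is AgeBand.OC:
        return oc_cell
    return bc_row[_BC_BANDS.index(band)]


def total_score(ped: Pedigree) -> GridScore:
    """Score every diagnosis of every family member and sum.

    Contributions are ordered by (individual id, diagnosis index) so the
    result is deterministic regardless of input enumeration order.
    """
    contributions: list[ScoreContribution] = []
    for iid in sorted(ped.individuals):
        ind = ped[iid]
        relation = relation_to_proband(ped, iid)
        for k, dx in enumerate(ind.diagnoses):
            pts = score_diagnosis(relation, dx, is_male=ind.sex is Sex.MALE)
            contributions.append(
                ScoreContribution(
                    individual_id=iid,
                    relation=relation,
                    diagnosis_index=k,
                    band=diagnosis_band(dx),
                    points=pts,
                )
            )
    return GridScore(contributions=contributions)
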