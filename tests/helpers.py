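"""Shared builders and independent oracles for the test suite.

The oracles here re-derive expected values along a different code path
from the implementation: the questionnaire grid is re-typed as a literal
table, criteria are re-coded as direct predicates over the raw diagnosis
lists, and percentages are recomputed with Fraction arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

from hboc_triage.pedigree_io import (
    CancerDiagnosis,
    Individual,
    Pedigree,
    relation_to_proband,
)


def bc(age=None, lat="unilateral", tn="unknown"):
    return CancerDiagnosis(site="breast", age_at_onset=age, laterality=lat,
                           triple_negative=tn)


def oc(age=None, mucinous="unknown", borderline="unknown"):
    return CancerDiagnosis(site="ovary", age_at_onset=age, mucinous=mucinous,
                           borderline=borderline)


def person(iid, sex="female", age=None, alive="yes", mother=None, father=None, dx=()):
    return Individual(id=iid, sex=sex, age=age, alive=alive,
                      mother_id=mother, father_id=father, diagnoses=list(dx))


def build(*individuals, proband="P"):
    return Pedigree(proband_id=proband, individuals={i.id: i for i in individuals})


def nuclear(proband_dx=(), mother_dx=(), proband_age=46, mother_age=75):
    """Proband + both parents; the standard three-person fixture."""
    return build(
        person("P", age=proband_age, mother="M", father="F", dx=proband_dx),
        person("M", age=mother_age, dx=mother_dx),
        person("F", sex="male", age=78),
    )


def three_generations():
    """8-person, 3-generation fixture: proband, parents, both grandmother
    lines, a paternal aunt and a sister."""
    return build(
        person("P", age=46, mother="M", father="F"),
        person("M", age=72, mother="MGM"),
        person("F", sex="male", age=74, mother="PGM", father="PGF"),
        person("MGM", age=95, alive="no"),
        person("PGM", age=90, alive="no"),
        person("PGF", sex="male", age=88, alive="no"),
        person("AUNT", age=70, mother="PGM", father="PGF"),
        person("SIS", age=44, mother="M", father="F"),
    )


# --- independent grid oracle ----------------------------------------------

# Re-typed questionnaire cells: relation -> (<40, 40-49 bil, 40-49 mono,
# 50-59, >=60, OC).
ORACLE_TABLE = {
    "self":                 (2, 2, 1, 1, 0, 2),
    "mother":               (2, 2, 1, 1, 0, 1),
    "sister":               (2, 2, 1, 1, 0, 1),
    "daughter":             (2, 2, 1, 1, 0, 1),
    "paternal_grandmother": (2, 2, 1, 1, 0, 1),
    "paternal_aunt":        (2, 2, 1, 1, 0, 1),
    "maternal_grandmother": (1, 1, 1, 0, 0, 1),
    "maternal_aunt":        (1, 1, 1, 0, 0, 1),
    "paternal_cousin":      (1, 0, 0, 0, 0, 1),
    "niece":                (1, 1, 1, 0, 0, 1),
    "other":                (0, 0, 0, 0, 0, 0),
}


#: (age, laterality) probe for each breast column of the grid, by index.
BAND_PROBES_ACCEPT = [
    (38, "unilateral"),
    (45, "bilateral"),
    (45, "unilateral"),
    (55, "unilateral"),
    (72, "unilateral"),
]


def oracle_points(relation: str, dx: CancerDiagnosis, is_male: bool) -> int:
    if is_male:
        return 2  # male-BC row: 2 at every age
    row = ORACLE_TABLE[relation]
    if dx.site.value == "ovary":
        return row[5]
    a = dx.age_at_onset
    if a is None:
        return 0
    if a < 40:
        return row[0]
    if a < 50:
        return row[1] if dx.laterality.value == "bilateral" else row[2]
    if a < 60:
        return row[3]
    return row[4]


def oracle_total(ped: Pedigree) -> int:
    total = 0
    for ind in ped:
        rel = relation_to_proband(ped, ind.id).value
        for dx in ind.diagnoses:
            total += oracle_points(rel, dx, ind.sex.value == "male")
    return total


# --- independent criterion predicates --------------------------------------

def _blood_dx(ped: Pedigree):
    blood = ped.blood_relatives()
    for iid in blood:
        for dx in ped[iid].diagnoses:
            yield ped[iid], dx


def pred_male_bc(ped):
    return any(i.sex.value == "male" and d.site.value == "breast"
               for i, d in _blood_dx(ped))


def pred_bc_and_oc(ped):
    sites = {d.site.value for _, d in _blood_dx(ped)}
    return sites == {"breast", "ovary"}


def pred_early_onset(ped):
    return any(d.site.value == "breast" and d.age_at_onset is not None
               and d.age_at_onset <= 35 for _, d in _blood_dx(ped))


def pred_bilateral_le50(ped):
    return any(d.site.value == "breast" and d.laterality.value == "bilateral"
               and d.age_at_onset is not None and d.age_at_onset <= 50
               for _, d in _blood_dx(ped))


def pred_nonmuc_nonbord_oc(ped):
    return any(d.site.value == "ovary" and d.mucinous.value == "no"
               and d.borderline.value == "no" for _, d in _blood_dx(ped))


def pred_tnbc_le60(ped):
    return any(d.site.value == "breast" and d.triple_negative.value == "yes"
               and d.age_at_onset is not None and d.age_at_onset <= 60
               for _, d in _blood_dx(ped))


def pred_two_fdr_bc(ped):
    blood = ped.blood_relatives()
    affected = [iid for iid in blood if any(d.site.value == "breast"
                                            for d in ped[iid].diagnoses)]

    def first_degree(a, b):
        pa = {p for p in (ped[a].mother_id, ped[a].father_id) if p}
        pb = {p for p in (ped[b].mother_id, ped[b].father_id) if p}
        return a in pb or b in pa or (len(pa) == 2 and pa == pb)

    def young_or_bilateral(iid):
        return any(
            d.site.value == "breast"
            and ((d.age_at_onset is not None and d.age_at_onset <= 40)
                 or d.laterality.value == "bilateral")
            for d in ped[iid].diagnoses
        )

    for a in affected:
        for b in affected:
            if a < b and first_degree(a, b):
                if young_or_bilateral(a) or young_or_bilateral(b):
                    return True
    return False


CRITERION_PREDICATES = {
    "MALE_BC": pred_male_bc,
    "BC_AND_OC": pred_bc_and_oc,
    "EARLY_ONSET_BC": pred_early_onset,
    "BILATERAL_BC_LE50": pred_bilateral_le50,
    "NONMUC_NONBORD_OC": pred_nonmuc_nonbord_oc,
    "TWO_FDR_BC": pred_two_fdr_bc,
    "TNBC_LE60": pred_tnbc_le60,
}


def oracle_percent(n: int, d: int) -> float:
    """Half-up one-decimal percentage via pure Fraction arithmetic."""
    x = Fraction(100 * n, d) * 10
    return (x.numerator // x.denominator
            + (1 if 2 * (x.numerator % x.denominator) >= x.denominator else 0)) / 10


def dense_synth_config(n: int, seed: int):
    """A generator config with elevated background incidence so random
    pedigrees carry plenty of diagnoses for oracle-equivalence checks."""
    from hboc_triage.synthpop import SynthConfig

    return SynthConfig(
        n_probands=n,
        seed=seed,
        carrier_freq=0.05,
        bc_hazard={
            "carrier": [0.0, 0.0, 0.06, 0.12, 0.15, 0.15, 0.12, 0.10, 0.05],
            "non_carrier": [0.0, 0.0, 0.01, 0.03, 0.05, 0.06, 0.06, 0.05, 0.04],
        },
        oc_hazard={
            "carrier": [0.0, 0.0, 0.01, 0.03, 0.05, 0.06, 0.05, 0.03, 0.02],
            "non_carrier": [0.0, 0.0, 0.002, 0.005, 0.01, 0.012, 0.012, 0.01, 0.008],
        },
        male_bc_factor=0.1,
    )
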