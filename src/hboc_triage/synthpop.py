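"""Synthetic screening populations with Mendelian carrier transmission.

Every pipeline stage is testable without patient data: the generator
builds three-generation family templates around a screened proband, seeds
a rare autosomal-dominant susceptibility allele in the founders, transmits
it to descendants with probability 1/2, and samples breast/ovarian cancer
onsets from genotype-specific piecewise-constant hazards by decade of
age. Tumour features (laterality, triple-negative status, ovarian
histology) are drawn per diagnosis.

The defaults emulate the structure of a mammography-screening population
(probands aged 45–74, a low-frequency high-penetrance allele, sporadic
background incidence) at desk scale: roughly 2–5% of probands end up
Spoke-eligible and carriers are strongly enriched among test-eligible
families. No claim of demographic realism for any specific region is
made, and absolute cohort sizes are not a simulation target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .funnel import ScreeningRecord, Source
from .pedigree_io import (
    CancerDiagnosis,
    Individual,
    Laterality,
    Pedigree,
    Sex,
    Site,
    Trilean,
)
from .risk_profile import Covariates


class ConfigError(ValueError):
    pass


#: Per-decade probability of breast-cancer onset (decade d covers ages
#: [10*d, 10*d+10)). Carriers face a lifetime risk around 60-70%; the
#: non-carrier curve gives the usual ~10% lifetime figure.
DEFAULT_BC_HAZARD = {
    "carrier":     [0.0, 0.0, 0.02, 0.10, 0.14, 0.14, 0.12, 0.10, 0.05],
    "non_carrier": [0.0, 0.0, 0.0005, 0.003, 0.009, 0.014, 0.018, 0.018, 0.012],
}
#: Per-decade probability of ovarian-cancer onset (females only).
DEFAULT_OC_HAZARD = {
    "carrier":     [0.0, 0.0, 0.0, 0.01, 0.04, 0.06, 0.05, 0.03, 0.02],
    "non_carrier": [0.0, 0.0, 0.0, 0.0002, 0.001, 0.002, 0.003, 0.003, 0.002],
}
#: Male breast-cancer hazards are this fraction of the female curve.
DEFAULT_MALE_BC_FACTOR = 0.02

#: Relative slots built around the proband: (count, presence probability).
DEFAULT_FAMILY_TEMPLATE: dict[str, tuple[int, float]] = {
    "sisters": (2, 0.4),
    "daughters": (2, 0.4),
    "paternal_aunts": (2, 0.4),
    "maternal_aunts": (2, 0.4),
    "paternal_uncles": (1, 0.4),
    "paternal_cousins": (1, 0.5),
    "nieces": (1, 0.4),
}


@dataclass(frozen=True)
class SynthConfig:
    n_probands: int = 100
    seed: int = 0
    carrier_freq: float = 0.004          # founder allele carrier frequency
    bc_hazard: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BC_HAZARD.items()})
    oc_hazard: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_OC_HAZARD.items()})
    male_bc_factor: float = DEFAULT_MALE_BC_FACTOR
    bilateral_prob: float = 0.12
    tnbc_prob: float = 0.15
    mucinous_prob: float = 0.10
    borderline_prob: float = 0.10
    family_template: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_TEMPLATE))
    proband_age_range: tuple[int, int] = (45, 74)

    def validate(self) -> None:
        bad = []
        for name in ("carrier_freq", "bilateral_prob", "tnbc_prob",
                     "mucinous_prob", "borderline_prob", "male_bc_factor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                bad.append(name)
        for site, table in (("bc_hazard", self.bc_hazard), ("oc_hazard", self.oc_hazard)):
            for geno in ("carrier", "non_carrier"):
                if geno not in table or any(h < 0 for h in table[geno]):
                    bad.append(f"{site}[{geno}]")
            if f"{site}[carrier]" not in bad and f"{site}[non_carrier]" not in bad:
                car, non = table["carrier"], table["non_carrier"]
                if len(car) != len(non) or any(c < n for c, n in zip(car, non)):
                    bad.append(f"{site}: carrier penetrance must dominate non-carrier")
        if self.n_probands < 0:
            bad.append("n_probands")
        lo, hi = self.proband_age_range
        if not (0 <= lo <= hi):
            bad.append("proband_age_range")
        if bad:
            raise ConfigError(f"invalid config fields: {bad}")


class _Builder:
    """Builds one family: individuals, genotypes, diagnoses.

    Ids are unqualified inside the builder; the family tag prefix is added
    when the Pedigree is assembled.
    """

    def __init__(self, cfg: SynthConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.individuals: dict[str, Individual] = {}
        self.genotypes: dict[str, bool] = {}

    def founder(self, iid: str, sex: Sex, age: int) -> str:
        self.genotypes[iid] = bool(self.rng.random() < self.cfg.carrier_freq)
        return self._add(iid, sex, age, None, None)

    def child(self, iid: str, sex: Sex, age: int,
              mother: Optional[str], father: Optional[str],
              force_alive: bool = False) -> str:
        carrier = False
        for parent in (mother, father):
            if parent is not None:
                transmits = self.genotypes[parent]
            else:
                # a parent absent from the pedigree may still carry the allele
                transmits = self.rng.random() < self.cfg.carrier_freq
            if transmits and self.rng.random() < 0.5:
                carrier = True
        self.genotypes[iid] = carrier
        return self._add(iid, sex, age, mother, father, force_alive)

    def _add(self, iid: str, sex: Sex, age: int,
             mother: Optional[str], father: Optional[str],
             force_alive: bool = False) -> str:
        lifespan = int(self.rng.normal(82, 8))
        if age >= lifespan and not force_alive:
            alive, final_age = Trilean.NO, max(1, lifespan)
        else:
            alive, final_age = Trilean.YES, age
        ind = Individual(
            id=iid, sex=sex, age=final_age, alive=alive,
            mother_id=mother, father_id=father,
            diagnoses=[],
        )
        ind.diagnoses = self._sample_diagnoses(ind, self.genotypes[iid])
        ind.__post_init__()  # re-check the onset <= age invariant
        self.individuals[iid] = ind
        return iid

    def assemble(self, tag: str, proband: str) -> tuple[Pedigree, dict[str, bool]]:
        q = lambda x: f"{tag}:{x}" if x is not None else None
        individuals = {
            q(ind.id): Individual(
                id=q(ind.id), sex=ind.sex, age=ind.age, alive=ind.alive,
                mother_id=q(ind.mother_id), father_id=q(ind.father_id),
                diagnoses=list(ind.diagnoses),
            )
            for ind in self.individuals.values()
        }
        ped = Pedigree(proband_id=q(proband), individuals=individuals)
        return ped, {q(k): v for k, v in self.genotypes.items()}

    def _onset_age(self, hazards: list[float], scale: float, current_age: int) -> Optional[int]:
        for d, h in enumerate(hazards):
            lo = 10 * d
            if lo > current_age:
                break
            frac = min(1.0, (current_age + 1 - lo) / 10.0)
            if self.rng.random() < h * scale * frac:
                return int(min(current_age, lo + self.rng.integers(0, 10)))
        return None

    def _sample_diagnoses(self, ind: Individual, carrier: bool) -> list[CancerDiagnosis]:
        geno = "carrier" if carrier else "non_carrier"
        scale_bc = self.cfg.male_bc_factor if ind.sex is Sex.MALE else 1.0
        out: list[CancerDiagnosis] = []
        age_bc = self._onset_age(self.cfg.bc_hazard[geno], scale_bc, ind.age)
        if age_bc is not None:
            bilateral = self.rng.random() < self.cfg.bilateral_prob
            out.append(
                CancerDiagnosis(
                    site=Site.BREAST,
                    age_at_onset=age_bc,
                    laterality=Laterality.BILATERAL if bilateral else Laterality.UNILATERAL,
                    triple_negative=Trilean.YES if self.rng.random() < self.cfg.tnbc_prob else Trilean.NO,
                )
            )
        if ind.sex is Sex.FEMALE:
            age_oc = self._onset_age(self.cfg.oc_hazard[geno], 1.0, ind.age)
            if age_oc is not None:
                out.append(
                    CancerDiagnosis(
                        site=Site.OVARY,
                        age_at_onset=age_oc,
                        mucinous=Trilean.YES if self.rng.random() < self.cfg.mucinous_prob else Trilean.NO,
                        borderline=Trilean.YES if self.rng.random() < self.cfg.borderline_prob else Trilean.NO,
                    )
                )
        return out


def _draw_source(rng: np.random.Generator, age: int) -> Source:
    """Age-dependent referral source; the screening programme never refers
    women under 45 (it only covers 45–74)."""
    if age < 45:
        return Source.GP if rng.random() < 0.4 else Source.SPECIALIST
    u = rng.random()
    if u < 0.60:
        return Source.SCREENING_PROGRAM
    if u < 0.75:
        return Source.GP
    return Source.SPECIALIST


def _draw_covariates(rng: np.random.Generator, age: int) -> Covariates:
    return Covariates(
        age=age,
        age_at_menarche=int(rng.integers(11, 16)),
        height_cm=float(np.round(rng.normal(163, 6), 1)),
        weight_kg=float(np.round(rng.normal(65, 10), 1)),
        parity=int(rng.integers(0, 4)),
        previous_breast_lesions=bool(rng.random() < 0.05),
        menopausal=age >= 51,
    )


def generate_family(cfg: SynthConfig, rng: np.random.Generator, tag: str) -> tuple[Pedigree, dict[str, bool]]:
    """Build one proband-rooted three-generation family."""
    b = _Builder(cfg, rng)
    lo, hi = cfg.proband_age_range
    p_age = int(rng.integers(lo, hi + 1))
    gen_gap = lambda: int(rng.integers(20, 36))

    m_age = p_age + gen_gap()
    f_age = p_age + gen_gap()
    b.founder("mgm", Sex.FEMALE, m_age + gen_gap())
    b.founder("mgf", Sex.MALE, m_age + gen_gap())
    b.founder("pgm", Sex.FEMALE, f_age + gen_gap())
    b.founder("pgf", Sex.MALE, f_age + gen_gap())
    b.child("mother", Sex.FEMALE, m_age, "mgm", "mgf")
    b.child("father", Sex.MALE, f_age, "pgm", "pgf")
    b.child("proband", Sex.FEMALE, p_age, "mother", "father", force_alive=True)

    def slots(key: str):
        count, p = cfg.family_template.get(key, (0, 0.0))
        return [i for i in range(count) if rng.random() < p]

    sisters = [
        b.child(f"sister{i}", Sex.FEMALE,
                max(18, p_age + int(rng.integers(-8, 9))), "mother", "father")
        for i in slots("sisters")
    ]
    if p_age >= 40:
        for i in slots("daughters"):
            b.child(f"daughter{i}", Sex.FEMALE, max(1, p_age - gen_gap()), "proband", None)
    for i in slots("paternal_aunts"):
        b.child(f"paunt{i}", Sex.FEMALE, f_age + int(rng.integers(-8, 9)), "pgm", "pgf")
    for i in slots("maternal_aunts"):
        b.child(f"maunt{i}", Sex.FEMALE, m_age + int(rng.integers(-8, 9)), "mgm", "mgf")
    uncles = [
        b.child(f"puncle{i}", Sex.MALE, f_age + int(rng.integers(-8, 9)), "pgm", "pgf")
        for i in slots("paternal_uncles")
    ]
    if uncles:
        for i in slots("paternal_cousins"):
            b.child(f"pcousin{i}", Sex.FEMALE,
                    max(18, p_age + int(rng.integers(-10, 11))), None, uncles[0])
    if sisters:
        for i in slots("nieces"):
            b.child(f"niece{i}", Sex.FEMALE, max(1, p_age - gen_gap()), sisters[0], None)

    return b.assemble(tag, "proband")


def generate_population(cfg: SynthConfig) -> list[ScreeningRecord]:
    """Generate ``cfg.n_probands`` screening records (deterministic per seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records: list[ScreeningRecord] = []
    for i in range(cfg.n_probands):
        ped, genotypes = generate_family(cfg, rng, tag=f"F{i:05d}")
        age = ped.proband.age
        records.append(
            ScreeningRecord(
                pedigree=ped,
                covariates=_draw_covariates(rng, age),
                source=_draw_source(rng, age),
                true_genotypes=genotypes,
            )
        )
    return records


def enrichment_check(
    records: list[ScreeningRecord], decisions
) -> tuple[float, float]:
    """(carrier fraction among test-eligible families, overall carrier fraction).

    The family's carrier status is read off the selected index case when one
    exists, else the proband — mirroring who would actually be tested.
    """
    from .referral_rules import select_index_case

    def fam_carrier(rec: ScreeningRecord) -> bool:
        idx = select_index_case(rec.pedigree) or rec.pedigree.proband_id
        return rec.true_genotypes.get(idx, False) if rec.true_genotypes else False

    flags = [fam_carrier(r) for r in records]
    eligible_flags = [f for f, d in zip(flags, decisions) if d.test_eligible]
    overall = float(np.mean(flags)) if flags else 0.0
    eligible = float(np.mean(eligible_flags)) if eligible_flags else 0.0
    return eligible, overall
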