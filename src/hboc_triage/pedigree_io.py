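"""Family-history data model, kinship inference and pedigree I/O.

The screening instrument operates on small proband-rooted pedigrees: the
woman being screened (the proband, always female) plus the blood relatives
whose breast/ovarian cancer history the primary questionnaire asks about.
Individuals are linked by ``mother_id``/``father_id`` references; the
parent links must form a DAG and every referenced parent must exist.

Two on-disk forms are supported and round-trip losslessly:

* JSON (canonical) — one object per pedigree; schema shipped in
  ``schemas/pedigree.schema.json`` (version 1.0).
* CSV — one row per individual, UTF-8, comma-separated, header mandatory;
  an individual with k > 1 diagnoses is encoded as k rows sharing the same
  ``id`` (the non-diagnosis columns must agree across those rows).

Unknown values (age, laterality, receptor/histology flags) are explicit
``None`` / ``"unknown"`` and are preserved by both writers.
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import pandas as pd

SCHEMA_FORMAT = "hboc-pedigree"
SCHEMA_VERSION = "1.0"


class PedigreeError(ValueError):
    """Raised when a pedigree (or its serialized form) violates an invariant."""


class Site(str, enum.Enum):
    BREAST = "breast"
    OVARY = "ovary"


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class Trilean(str, enum.Enum):
    """Three-valued flag used for vital status and tumor features."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class Laterality(str, enum.Enum):
    UNILATERAL = "unilateral"
    BILATERAL = "bilateral"
    UNKNOWN = "unknown"


class Relation(str, enum.Enum):
    """Kinship labels recognized by the scoring grid.

    The ten named patterns are the questionnaire rows; every other kinship
    path (including all male relatives) maps to ``OTHER`` and scores zero,
    except that male breast cancer is scored by a dedicated row regardless
    of kinship.
    """

    SELF = "self"
    MOTHER = "mother"
    SISTER = "sister"
    DAUGHTER = "daughter"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    PATERNAL_AUNT = "paternal_aunt"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"
    MATERNAL_AUNT = "maternal_aunt"
    PATERNAL_COUSIN = "paternal_cousin"
    NIECE = "niece"
    OTHER = "other"


@dataclass(frozen=True)
class CancerDiagnosis:
    """One tumor event.

    Breast diagnoses carry ``laterality`` and ``triple_negative``; ovarian
    diagnoses carry ``mucinous`` and ``borderline``. Fields that do not
    apply to the site must be None and are rejected otherwise. A bilateral
    breast cancer is ONE diagnosis.
    """

    site: Site
    age_at_onset: Optional[int] = None
    laterality: Optional[Laterality] = None
    triple_negative: Optional[Trilean] = None
    mucinous: Optional[Trilean] = None
    borderline: Optional[Trilean] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "site", Site(self.site))
        if self.age_at_onset is not None and self.age_at_onset < 0:
            raise PedigreeError(f"negative age_at_onset: {self.age_at_onset}")
        if self.site is Site.BREAST:
            if self.mucinous is not None or self.borderline is not None:
                raise PedigreeError("breast diagnosis cannot carry mucinous/borderline")
            object.__setattr__(
                self,
                "laterality",
                Laterality(self.laterality) if self.laterality is not None else Laterality.UNKNOWN,
            )
            object.__setattr__(
                self,
                "triple_negative",
                Trilean(self.triple_negative) if self.triple_negative is not None else Trilean.UNKNOWN,
            )
        else:
            if self.laterality is not None or self.triple_negative is not None:
                raise PedigreeError("ovary diagnosis cannot carry laterality/triple_negative")
            object.__setattr__(
                self,
                "mucinous",
                Trilean(self.mucinous) if self.mucinous is not None else Trilean.UNKNOWN,
            )
            object.__setattr__(
                self,
                "borderline",
                Trilean(self.borderline) if self.borderline is not None else Trilean.UNKNOWN,
            )

    @property
    def is_bilateral(self) -> bool:
        return self.site is Site.BREAST and self.laterality is Laterality.BILATERAL


@dataclass
class Individual:
    id: str
    sex: Sex
    age: Optional[int] = None
    alive: Trilean = Trilean.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    diagnoses: list[CancerDiagnosis] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sex = Sex(self.sex)
        self.alive = Trilean(self.alive)
        if self.age is not None and self.age < 0:
            raise PedigreeError(f"negative age for {self.id!r}")
        if self.sex is Sex.MALE:
            for dx in self.diagnoses:
                if dx.site is Site.OVARY:
                    raise PedigreeError(f"male individual {self.id!r} with ovary diagnosis")
        for dx in self.diagnoses:
            if dx.age_at_onset is not None and self.age is not None and dx.age_at_onset > self.age:
                raise PedigreeError(
                    f"diagnosis at age {dx.age_at_onset} exceeds current/death age "
                    f"{self.age} for {self.id!r}"
                )

    @property
    def affected(self) -> bool:
        return bool(self.diagnoses)


@dataclass
class Pedigree:
    """Proband-rooted family graph keyed by individual id."""

    proband_id: str
    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.proband_id not in self.individuals:
            raise PedigreeError(f"missing proband {self.proband_id!r}")
        if self.proband.sex is not Sex.FEMALE:
            raise PedigreeError("proband must be female (the screened population is women)")
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self.individuals.values():
            for pid, expected_sex, role in (
                (ind.mother_id, Sex.FEMALE, "mother"),
                (ind.father_id, Sex.MALE, "father"),
            ):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise PedigreeError(f"unknown {role} id {pid!r} referenced by {ind.id!r}")
                if self.individuals[pid].sex is not expected_sex:
                    raise PedigreeError(
                        f"{pid!r} referenced as {role} of {ind.id!r} but is not {expected_sex.value}"
                    )
                g.add_edge(pid, ind.id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise PedigreeError(f"cycle in parent links: {path}")

    @property
    def proband(self) -> Individual:
        return self.individuals[self.proband_id]

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self.individuals[individual_id]
        except KeyError:
            raise KeyError(f"no individual {individual_id!r} in pedigree") from None

    def __iter__(self):
        return iter(self.individuals.values())

    def __len__(self) -> int:
        return len(self.individuals)

    # -- kinship -----------------------------------------------------------

    def parents_of(self, individual_id: str) -> set[str]:
        ind = self[individual_id]
        return {p for p in (ind.mother_id, ind.father_id) if p is not None}

    def _shares_parent(self, a: str, b: str) -> bool:
        return a != b and bool(self.parents_of(a) & self.parents_of(b))

    def _full_siblings(self, a: str, b: str) -> bool:
        pa, pb = self.parents_of(a), self.parents_of(b)
        return a != b and len(pa) == 2 and pa == pb

    def ancestors_of(self, individual_id: str) -> set[str]:
        """Ancestor ids of an individual, including the individual itself."""
        seen = {individual_id}
        stack = [individual_id]
        while stack:
            for p in self.parents_of(stack.pop()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return seen

    def blood_relatives(self) -> set[str]:
        """Ids sharing an ancestor (or a line of descent) with the proband.

        Relatives by marriage present only as link nodes (e.g. an uncle's
        unnamed partner) share no ancestor with the proband and are excluded.
        """
        proband_anc = self.ancestors_of(self.proband_id)
        return {
            iid for iid in self.individuals
            if self.ancestors_of(iid) & proband_anc
        }


def relation_to_proband(ped: Pedigree, individual_id: str) -> Relation:
    """Map an individual onto the questionnaire's kinship rows.

    Matches the path from the proband against the ten named patterns
    (self; mother; sister sharing >=1 parent; daughter; father's mother;
    father's sister; mother's mother; mother's sister; father's brother's
    daughter; sibling's daughter). Anything else — including every male
    relative and granddaughters — is ``OTHER``.
    """
    ind = ped[individual_id]
    pb = ped.proband
    if individual_id == ped.proband_id:
        return Relation.SELF
    if individual_id == pb.mother_id:
        return Relation.MOTHER
    if ind.sex is not Sex.FEMALE:
        return Relation.OTHER
    if ped._shares_parent(individual_id, ped.proband_id):
        return Relation.SISTER
    if ped.proband_id in ped.parents_of(individual_id):
        return Relation.DAUGHTER
    father, mother = pb.father_id, pb.mother_id
    if father is not None:
        if individual_id == ped[father].mother_id:
            return Relation.PATERNAL_GRANDMOTHER
        if ped._shares_parent(individual_id, father):
            return Relation.PATERNAL_AUNT
        # daughter of father's brother
        for par in ped.parents_of(individual_id):
            if ped[par].sex is Sex.MALE and ped._shares_parent(par, father):
                return Relation.PATERNAL_COUSIN
    if mother is not None:
        if individual_id == ped[mother].mother_id:
            return Relation.MATERNAL_GRANDMOTHER
        if ped._shares_parent(individual_id, mother):
            return Relation.MATERNAL_AUNT
    for par in ped.parents_of(individual_id):
        if ped._shares_parent(par, ped.proband_id):
            return Relation.NIECE
    return Relation.OTHER


def first_degree_pairs(ped: Pedigree, ids: Iterable[str]) -> set[frozenset[str]]:
    """Unordered pairs within ``ids`` related as parent–child or full siblings."""
    ids = set(ids)
    for iid in ids:
        ped[iid]  # raises KeyError on dangling ids
    pairs: set[frozenset[str]] = set()
    for a, b in combinations(sorted(ids), 2):
        if (
            a in ped.parents_of(b)
            or b in ped.parents_of(a)
            or ped._full_siblings(a, b)
        ):
            pairs.add(frozenset((a, b)))
    return pairs


# ---------------------------------------------------------------------------
# JSON form (canonical)
# ---------------------------------------------------------------------------

def _dx_to_dict(dx: CancerDiagnosis) -> dict:
    d: dict = {"site": dx.site.value}
    if dx.age_at_onset is not None:
        d["age_at_onset"] = dx.age_at_onset
    if dx.site is Site.BREAST:
        d["laterality"] = dx.laterality.value
        d["triple_negative"] = dx.triple_negative.value
    else:
        d["mucinous"] = dx.mucinous.value
        d["borderline"] = dx.borderline.value
    return d


def _dx_from_dict(d: dict) -> CancerDiagnosis:
    known = {"site", "age_at_onset", "laterality", "triple_negative", "mucinous", "borderline"}
    bad = set(d) - known
    if bad:
        raise PedigreeError(f"unknown diagnosis fields: {sorted(bad)}")
    return CancerDiagnosis(
        site=Site(d["site"]),
        age_at_onset=d.get("age_at_onset"),
        laterality=d.get("laterality"),
        triple_negative=d.get("triple_negative"),
        mucinous=d.get("mucinous"),
        borderline=d.get("borderline"),
    )


def pedigree_to_dict(ped: Pedigree) -> dict:
    return {
        "format": SCHEMA_FORMAT,
        "version": SCHEMA_VERSION,
        "proband_id": ped.proband_id,
        "individuals": [
            {
                "id": ind.id,
                "sex": ind.sex.value,
                **({"age": ind.age} if ind.age is not None else {}),
                "alive": ind.alive.value,
                **({"mother_id": ind.mother_id} if ind.mother_id else {}),
                **({"father_id": ind.father_id} if ind.father_id else {}),
                "diagnoses": [_dx_to_dict(dx) for dx in ind.diagnoses],
            }
            for ind in ped.individuals.values()
        ],
    }


def pedigree_from_dict(data: dict) -> Pedigree:
    if not isinstance(data, dict) or "individuals" not in data:
        raise PedigreeError("not a pedigree record (missing 'individuals')")
    if data.get("format", SCHEMA_FORMAT) != SCHEMA_FORMAT:
        raise PedigreeError(f"unsupported format {data.get('format')!r}")
    if "proband_id" not in data:
        raise PedigreeError("missing proband_id")
    individuals: dict[str, Individual] = {}
    for rec in data["individuals"]:
        iid = str(rec["id"])
        if iid in individuals:
            raise PedigreeError(f"duplicate individual id {iid!r}")
        individuals[iid] = Individual(
            id=iid,
            sex=Sex(rec["sex"]),
            age=rec.get("age"),
            alive=Trilean(rec.get("alive", "unknown")),
            mother_id=rec.get("mother_id"),
            father_id=rec.get("father_id"),
            diagnoses=[_dx_from_dict(d) for d in rec.get("diagnoses", [])],
        )
    return Pedigree(proband_id=str(data["proband_id"]), individuals=individuals)


# ---------------------------------------------------------------------------
# CSV form
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "id", "proband", "sex", "age", "alive", "mother_id", "father_id",
    "site", "age_at_onset", "laterality", "triple_negative", "mucinous", "borderline",
]


def pedigree_to_csv(ped: Pedigree) -> str:
    rows = []
    for ind in ped.individuals.values():
        base = {
            "id": ind.id,
            "proband": 1 if ind.id == ped.proband_id else 0,
            "sex": ind.sex.value,
            "age": ind.age,
            "alive": ind.alive.value,
            "mother_id": ind.mother_id,
            "father_id": ind.father_id,
        }
        if not ind.diagnoses:
            rows.append(base)
        else:
            for dx in ind.diagnoses:
                d = _dx_to_dict(dx)
                rows.append({**base, **d})
    # string cells throughout: keeps integer ages from floating to "48.0"
    # when a column mixes known and unknown values
    clean = [
        {col: ("" if row.get(col) is None else str(row.get(col, "")))
         for col in CSV_COLUMNS}
        for row in rows
    ]
    df = pd.DataFrame(clean, columns=CSV_COLUMNS)
    return df.to_csv(index=False)


def pedigree_from_csv(text: str) -> Pedigree:
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    missing = {"id", "proband", "sex"} - set(df.columns)
    if missing:
        raise PedigreeError(f"CSV missing required columns: {sorted(missing)}")

    def val(row, col):
        v = row.get(col, "")
        return None if v in ("", None) else v

    individuals: dict[str, Individual] = {}
    proband_id: Optional[str] = None
    order: list[str] = []
    per_id_rows: dict[str, list] = {}
    for _, row in df.iterrows():
        iid = row["id"]
        if iid not in per_id_rows:
            per_id_rows[iid] = []
            order.append(iid)
        per_id_rows[iid].append(row)
        if str(row["proband"]).strip() in ("1", "true", "True", "yes"):
            proband_id = iid
    if proband_id is None:
        raise PedigreeError("missing proband (no row with proband=1)")
    for iid in order:
        rows = per_id_rows[iid]
        head = rows[0]
        for r in rows[1:]:
            for col in ("sex", "age", "alive", "mother_id", "father_id"):
                if val(r, col) != val(head, col):
                    raise PedigreeError(f"inconsistent {col!r} across rows for id {iid!r}")
        diagnoses = []
        for r in rows:
            site = val(r, "site")
            if site is None:
                continue
            age = val(r, "age_at_onset")
            diagnoses.append(
                CancerDiagnosis(
                    site=Site(site),
                    age_at_onset=int(age) if age is not None else None,
                    laterality=val(r, "laterality"),
                    triple_negative=val(r, "triple_negative"),
                    mucinous=val(r, "mucinous"),
                    borderline=val(r, "borderline"),
                )
            )
        age = val(head, "age")
        individuals[iid] = Individual(
            id=iid,
            sex=Sex(head["sex"]),
            age=int(age) if age is not None else None,
            alive=Trilean(val(head, "alive") or "unknown"),
            mother_id=val(head, "mother_id"),
            father_id=val(head, "father_id"),
            diagnoses=diagnoses,
        )
    return Pedigree(proband_id=proband_id, individuals=individuals)


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def parse_pedigree(source: Union[str, Path, dict]) -> Pedigree:
    """Parse a pedigree from JSON text, CSV text, a dict, or a file path.

    Format detection: dicts are taken as the JSON form; strings/paths are
    sniffed (leading ``{`` means JSON, otherwise CSV; ``.json``/``.csv``
    extensions decide for paths).
    """
    if isinstance(source, dict):
        return pedigree_from_dict(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".csv":
            return pedigree_from_csv(text)
        return pedigree_from_dict(json.loads(text))
    text = str(source)
    if text.lstrip().startswith("{"):
        return pedigree_from_dict(json.loads(text))
    return pedigree_from_csv(text)


def write_pedigree(ped: Pedigree, fmt: str = "json") -> str:
    """Serialize a pedigree; ``parse_pedigree(write_pedigree(p))`` == ``p``."""
    if fmt == "json":
        return json.dumps(pedigree_to_dict(ped), indent=2)
    if fmt == "csv":
        return pedigree_to_csv(ped)
    raise ValueError(f"unknown format {fmt!r}")


def load_population(path: Union[str, Path]) -> list[Pedigree]:
    """Load a JSON file holding either one pedigree or a list of pedigrees."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, list):
        return [pedigree_from_dict(d) for d in data]
    return [pedigree_from_dict(data)]
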