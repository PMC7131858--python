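"""Pedigree data model, validation, kinship inference and round-tripping."""

import json

import pytest

from hboc_triage.pedigree_io import (
    PedigreeError,
    Relation,
    first_degree_pairs,
    parse_pedigree,
    pedigree_to_dict,
    relation_to_proband,
    write_pedigree,
)

from helpers import bc, build, nuclear, oc, person, three_generations


class TestValidation:
    def test_minimal_proband_only(self):
        ped = parse_pedigree(json.dumps({
            "proband_id": "P",
            "individuals": [{"id": "P", "sex": "female"}],
        }))
        assert len(ped) == 1 and ped.proband.id == "P"

    def test_self_parent_cycle_named_in_error(self):
        with pytest.raises(PedigreeError, match="cycle.*A"):
            build(person("A", mother="A"), proband="A")

    def test_longer_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            build(
                person("P", mother="M"),
                person("M", mother="G"),
                person("G", mother="M"),
            )

    def test_unknown_parent_id(self):
        with pytest.raises(PedigreeError, match="ghost"):
            build(person("P", mother="ghost"))

    def test_father_must_be_male(self):
        with pytest.raises(PedigreeError):
            build(person("P", father="X"), person("X", sex="female"))

    def test_male_proband_rejected(self):
        with pytest.raises(PedigreeError, match="female"):
            build(person("P", sex="male"), proband="P")

    def test_male_with_ovary_diagnosis_rejected(self):
        with pytest.raises(PedigreeError, match="ovary"):
            person("X", sex="male", dx=[oc(60)])

    def test_missing_proband(self):
        with pytest.raises(PedigreeError, match="proband"):
            build(person("A"), proband="P")

    def test_onset_after_current_age_rejected(self):
        with pytest.raises(PedigreeError, match="exceeds"):
            person("A", age=40, dx=[bc(50)])

    def test_site_specific_fields_enforced(self):
        with pytest.raises(PedigreeError):
            bc(50).__class__(site="ovary", laterality="bilateral")
        with pytest.raises(PedigreeError):
            bc(50).__class__(site="breast", mucinous="yes")


class TestRelations:
    def test_named_kinship_paths(self):
        ped = three_generations()
        expected = {
            "P": Relation.SELF,
            "M": Relation.MOTHER,
            "SIS": Relation.SISTER,
            "MGM": Relation.MATERNAL_GRANDMOTHER,
            "PGM": Relation.PATERNAL_GRANDMOTHER,
            "AUNT": Relation.PATERNAL_AUNT,
            "F": Relation.OTHER,
            "PGF": Relation.OTHER,
        }
        assert {iid: relation_to_proband(ped, iid) for iid in expected} == expected

    def test_paternal_cousin_is_daughter_of_fathers_brother(self):
        ped = build(
            person("P", father="F", mother="M"),
            person("M"),
            person("F", sex="male", mother="PGM"),
            person("PGM"),
            person("UNCLE", sex="male", mother="PGM"),
            person("COUSIN", father="UNCLE"),
        )
        assert relation_to_proband(ped, "COUSIN") is Relation.PATERNAL_COUSIN

    def test_maternal_cousin_is_other(self):
        ped = build(
            person("P", mother="M"),
            person("M", mother="MGM"),
            person("MGM"),
            person("MUNCLE", sex="male", mother="MGM"),
            person("MCOUSIN", father="MUNCLE"),
        )
        assert relation_to_proband(ped, "MCOUSIN") is Relation.OTHER

    def test_niece_and_granddaughter(self):
        ped = build(
            person("P", mother="M"),
            person("M"),
            person("SIS", mother="M"),
            person("NIECE", mother="SIS"),
            person("DAU", mother="P"),
            person("GRANDDAU", mother="DAU"),
        )
        assert relation_to_proband(ped, "NIECE") is Relation.NIECE
        assert relation_to_proband(ped, "DAU") is Relation.DAUGHTER
        # granddaughters are not a questionnaire row
        assert relation_to_proband(ped, "GRANDDAU") is Relation.OTHER

    def test_half_sister_counts_as_sister(self):
        ped = build(
            person("P", mother="M"),
            person("M"),
            person("HALF", mother="M"),
        )
        assert relation_to_proband(ped, "HALF") is Relation.SISTER

    def test_dangling_id_raises_lookup_error(self):
        with pytest.raises(KeyError):
            relation_to_proband(nuclear(), "nobody")

    def test_label_depends_only_on_kinship_path(self, synth_records):
        """Permuting unrelated individuals never changes a relation label."""
        ped = synth_records[0].pedigree
        baseline = {iid: relation_to_proband(ped, iid) for iid in ped.individuals}
        shuffled = build(*reversed(list(ped)), proband=ped.proband_id)
        assert {iid: relation_to_proband(shuffled, iid) for iid in shuffled.individuals} == baseline


class TestFirstDegree:
    def test_parent_child_pair(self):
        ped = three_generations()
        assert first_degree_pairs(ped, {"M", "MGM"}) == {frozenset({"M", "MGM"})}

    def test_unrelated_pair_empty(self):
        ped = three_generations()
        assert first_degree_pairs(ped, {"M", "AUNT"}) == set()

    def test_two_sisters_and_mother_three_pairs(self):
        ped = build(
            person("P", mother="M", father="F"),
            person("S1", mother="M", father="F"),
            person("M"),
            person("F", sex="male"),
        )
        assert first_degree_pairs(ped, {"P", "S1", "M"}) == {
            frozenset({"P", "S1"}), frozenset({"P", "M"}), frozenset({"S1", "M"}),
        }

    def test_half_sisters_are_not_first_degree(self):
        ped = build(person("P", mother="M"), person("M"), person("H", mother="M"))
        assert first_degree_pairs(ped, {"P", "H"}) == set()

    def test_whole_fixture_enumeration(self):
        ped = three_generations()
        got = first_degree_pairs(ped, set(ped.individuals))
        expected = {
            frozenset({"P", "M"}), frozenset({"P", "F"}),
            frozenset({"SIS", "M"}), frozenset({"SIS", "F"}),
            frozenset({"P", "SIS"}),          # full siblings
            frozenset({"M", "MGM"}),
            frozenset({"F", "PGM"}), frozenset({"F", "PGF"}),
            frozenset({"AUNT", "PGM"}), frozenset({"AUNT", "PGF"}),
            frozenset({"F", "AUNT"}),         # full siblings
        }
        assert got == expected


class TestRoundTrip:
    def test_three_person_json(self):
        ped = nuclear(mother_dx=[bc(38)])
        again = parse_pedigree(write_pedigree(ped, "json"))
        assert pedigree_to_dict(again) == pedigree_to_dict(ped)
        assert sum(len(i.diagnoses) for i in again) == 1

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_fixture_round_trips(self, fmt):
        ped = three_generations()
        again = parse_pedigree(write_pedigree(ped, fmt))
        assert pedigree_to_dict(again) == pedigree_to_dict(ped)

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_unknowns_preserved(self, fmt):
        ped = build(
            person("P", age=None, alive="unknown", dx=[bc(None, lat="unknown")]),
        )
        again = parse_pedigree(write_pedigree(ped, fmt))
        p = again.proband
        assert p.age is None and p.alive.value == "unknown"
        assert p.diagnoses[0].age_at_onset is None
        assert p.diagnoses[0].laterality.value == "unknown"

    @pytest.mark.parametrize("fmt", ["json", "csv"])
    def test_generated_population_round_trips(self, synth_records, fmt):
        for rec in synth_records[:60]:
            ped = rec.pedigree
            again = parse_pedigree(write_pedigree(ped, fmt))
            assert pedigree_to_dict(again) == pedigree_to_dict(ped)

    def test_multiple_diagnoses_csv_rows(self):
        ped = build(person("P", age=62, dx=[bc(45, lat="bilateral"), oc(58)]))
        text = write_pedigree(ped, "csv")
        assert text.count("\n") == 3  # header + one row per diagnosis
        again = parse_pedigree(text)
        assert len(again.proband.diagnoses) == 2
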