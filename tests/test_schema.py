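import re

import pytest

from oudharmony import schema
from oudharmony.schema import (HarmonizedDatabase, emit_codebook,
                               parse_codebook, register_schema,
                               validate_database)


@pytest.fixture(scope="module")
def registry():
    return register_schema()


class TestRegistry:
    def test_counts(self, registry):
        patient = [s for s in registry.values() if not s.is_meta]
        meta = [s for s in registry.values() if s.is_meta]
        assert len(patient) == 23
        assert len(meta) == 3

    def test_expected_tables_present(self, registry):
        for name in ("demographics", "all_drugs", "tlfb", "uds", "uds_temp",
                     "withdrawal", "withdrawal_pre_post", "meta_study_length"):
            assert name in registry

    def test_snake_case_names(self, registry):
        pat = re.compile(r"^[a-z][a-z0-9_]*$")
        for s in registry.values():
            assert pat.match(s.name)
            for v in s.variables:
                assert pat.match(v.name), (s.name, v.name)

    def test_no_day_column_families(self, registry):
        for s in registry.values():
            stems = [m.group("stem") for v in s.variables
                     if (m := schema.DAY_SUFFIX_RE.match(v.name))]
            assert len(stems) == len(set(stems))

    def test_flag01_variables_binary(self, registry):
        for s in registry.values():
            for v in s.variables:
                if v.value_type == "flag01":
                    assert set(v.permitted_values) == {0, 1}
                    assert v.name.split("_")[0] in ("is", "was", "has",
                                                    "sud")  # verb-style prefix

    def test_patient_tables_lead_with_who(self, registry):
        for s in registry.values():
            if not s.is_meta:
                assert s.variables[0].name == "who"

    def test_project_lives_only_in_enrollment(self, registry):
        for s in registry.values():
            if s.is_meta or s.name == "enrollment":
                continue
            assert "project" not in s.variable_names


class TestCodebook:
    def test_round_trip_identity(self, clean_run):
        db = clean_run["db"]
        doc = emit_codebook(db)
        assert parse_codebook(doc) == db.registry

    def test_every_variable_documented_once(self, clean_run):
        doc = emit_codebook(clean_run["db"])
        for name, s in clean_run["db"].registry.items():
            entries = [v["name"] for v in doc[name]["variables"]]
            assert entries == list(s.variable_names)

    def test_is_male_permitted_values(self, registry):
        v = registry["demographics"].variable("is_male")
        assert set(v.permitted_values) == {0, 1}

    def test_race_levels(self, registry):
        v = registry["demographics"].variable("race")
        assert set(v.permitted_values) == {"White", "Black",
                                           "Refused/Missing", "Other"}

    def test_empty_database_empty_codebook(self):
        db = HarmonizedDatabase()
        db.tables = {}
        assert emit_codebook(db) == {}

    def test_rendered_codebook_mentions_each_table(self, clean_run):
        text = schema.render_codebook(emit_codebook(clean_run["db"]))
        for name in clean_run["db"].registry:
            assert f"## {name}" in text


class TestValidation:
    def test_valid_synthetic_db_is_clean(self, clean_run):
        assert validate_database(clean_run["db"]) == []

    def test_orphan_who_is_referential_violation(self, clean_run):
        db = clean_run["db"]
        broken = HarmonizedDatabase(registry=db.registry)
        broken.tables = {k: v.copy() for k, v in db.tables.items()}
        enrol = broken.tables["enrollment"]
        victim = broken.tables["treatment_dose"]["who"].iloc[0]
        broken.tables["enrollment"] = enrol[enrol["who"] != victim]
        report = validate_database(broken)
        refs = [v for v in report if v.rule == "ref.who_not_enrolled"]
        assert refs and all(v.who == victim for v in refs)

    def test_raw_style_sex_coding_rejected(self, clean_run):
        db = clean_run["db"]
        broken = HarmonizedDatabase(registry=db.registry)
        broken.tables = {k: v.copy() for k, v in db.tables.items()}
        demo = broken.tables["demographics"].copy()
        demo.loc[demo.index[0], "is_male"] = 2  # the raw 1/2 anti-pattern
        broken.tables["demographics"] = demo
        report = validate_database(broken)
        assert any(v.rule == "value.not_permitted" and "is_male" in v.message
                   for v in report)

    def test_missing_who_column_is_structural(self, clean_run):
        db = clean_run["db"]
        broken = HarmonizedDatabase(registry=db.registry)
        broken.tables = {k: v.copy() for k, v in db.tables.items()}
        broken.tables["pain"] = broken.tables["pain"].drop(columns=["who"])
        report = validate_database(broken)
        assert any(v.rule == "structure.no_who" and v.table == "pain"
                   for v in report)

    def test_duplicate_key_detected(self, clean_run):
        import pandas as pd
        db = clean_run["db"]
        broken = HarmonizedDatabase(registry=db.registry)
        broken.tables = {k: v.copy() for k, v in db.tables.items()}
        uds = broken.tables["uds"]
        broken.tables["uds"] = pd.concat([uds, uds.iloc[[0]]], ignore_index=True)
        report = validate_database(broken)
        assert any(v.rule == "key.duplicate" and v.table == "uds"
                   for v in report)
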