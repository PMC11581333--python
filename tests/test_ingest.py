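import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oudharmony.dialects import ctn0027_dialect, ctn0030_dialect
from oudharmony.ingest import (DialectError, RawBundle, RecodeError,
                               drop_exact_duplicates, melt_wide_daily,
                               recode_categoricals, resolve_subject_ids)


def bundle_with(table_columns, project="CTN-0027", dialect=None):
    dialect = dialect or ctn0027_dialect()
    tables = {name: pd.DataFrame(rows) for name, rows in table_columns.items()}
    return RawBundle(project, tables, dialect)


class TestSubjectIds:
    def test_alias_columns_unified_to_who(self):
        b = bundle_with({
            "screening": [{"PATNUM": "27-1"}, {"PATNUM": "27-2"}],
            "uds": [{"tcPATNUM": "27-2"}, {"tcPATNUM": "27-1"}],
        })
        out, id_map, nxt = resolve_subject_ids(b)
        assert list(out.tables["screening"]["who"]) == [1, 2]
        assert list(out.tables["uds"]["who"]) == [2, 1]
        assert nxt == 3
        assert set(id_map["raw_id"]) == {"27-1", "27-2"}

    def test_each_dialect_alias_recognized(self):
        b = bundle_with({"screening": [{"patientnumber": "5101"}]},
                        dialect=__import__("oudharmony.dialects",
                                           fromlist=["x"]).ctn0051_dialect())
        out, _, _ = resolve_subject_ids(b)
        assert list(out.tables["screening"]["who"]) == [1]

    def test_two_alias_columns_is_an_error_naming_both(self):
        b = bundle_with({"screening": [{"ID": "a", "PROJID": "b"}]},
                        dialect=ctn0030_dialect())
        with pytest.raises(DialectError) as err:
            resolve_subject_ids(b)
        assert "ID" in str(err.value) and "PROJID" in str(err.value)

    def test_no_alias_column_is_an_error(self):
        b = bundle_with({"screening": [{"subject": "x"}]})
        with pytest.raises(DialectError):
            resolve_subject_ids(b)

    def test_injective_per_project(self):
        rows = [{"PATNUM": f"27-{i}"} for i in range(20)]
        out, id_map, _ = resolve_subject_ids(bundle_with({"screening": rows}))
        assert id_map["who"].is_unique and id_map["raw_id"].is_unique


class TestRecode:
    def test_parole_codes_harmonized_across_dialects(self):
        # same answer coded "2" under variable L2 in one dialect and "1"
        # under ALPROBAT in another
        b30 = bundle_with({"asi": [{"ID": "a", "L2": "2"}]},
                          dialect=ctn0030_dialect())
        out, _ = recode_categoricals(b30)
        assert out.tables["asi"]["L2"].iloc[0] == "yes"

        d51 = __import__("oudharmony.dialects", fromlist=["x"]).ctn0051_dialect()
        b51 = bundle_with({"asi": [{"patientnumber": "b", "ALPROBAT": "1"}]},
                          dialect=d51)
        out, _ = recode_categoricals(b51)
        assert out.tables["asi"]["ALPROBAT"].iloc[0] == "yes"

    def test_direct_sex_map(self):
        b = bundle_with({"screening": [{"PATNUM": "27-1", "sex": "1"}]})
        out, _ = recode_categoricals(b)
        assert out.tables["screening"]["sex"].iloc[0] == "male"

    def test_unmapped_code_raises_with_context(self):
        b = bundle_with({"screening": [{"PATNUM": "27-1", "sex": "9"}]})
        with pytest.raises(RecodeError) as err:
            recode_categoricals(b)
        assert "sex" in str(err.value) and "9" in str(err.value)

    def test_output_codes_within_harmonized_set(self):
        b = bundle_with({"screening": [{"PATNUM": "1", "sex": "1"},
                                       {"PATNUM": "2", "sex": "2"},
                                       {"PATNUM": "3", "sex": ""}]})
        out, _ = recode_categoricals(b)
        assert set(out.tables["screening"]["sex"].dropna()) <= {"male", "female"}

    def test_exact_duplicates_dropped_with_audit(self):
        b = bundle_with({"screening": [{"PATNUM": "27-1", "sex": "1"},
                                       {"PATNUM": "27-1", "sex": "1"}]})
        out, corr = drop_exact_duplicates(b)
        assert len(out.tables["screening"]) == 1
        assert corr[0].rule_id == "ingest.exact_duplicate_row"


class TestMeltWideDaily:
    def test_hand_computed_offsets(self):
        row = {"heroin_d1": "1", "heroin_d2": "0", "heroin_d3": "1"}
        assert melt_wide_daily(row, 14) == [(14, "heroin"), (16, "heroin")]

    def test_all_zero_row_emits_nothing(self):
        assert melt_wide_daily({"heroin_d1": "0", "thc_d2": "0"}, 0) == []

    def test_two_substances_same_day_two_records(self):
        row = {"cocaine_d1": "1", "crack_d1": "1"}
        assert melt_wide_daily(row, 5) == [(5, "cocaine"), (5, "crack")]

    def test_non_day_columns_ignored(self):
        assert melt_wide_daily({"who": "3", "note": "x", "thc_d2": "1"}, 0) == \
            [(1, "thc")]

    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=7,
                    max_size=7),
           st.lists(st.integers(min_value=0, max_value=1), min_size=7,
                    max_size=7))
    @settings(deadline=None, derandomize=True)
    def test_melting_conserves_positives(self, heroin, thc):
        row = {f"heroin_d{i+1}": str(v) for i, v in enumerate(heroin)}
        row.update({f"thc_d{i+1}": str(v) for i, v in enumerate(thc)})
        events = melt_wide_daily(row, 0)
        assert len(events) == sum(heroin) + sum(thc)
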