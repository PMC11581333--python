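from datetime import date

import pytest

from oudharmony import uds
from oudharmony.uds import (PanelRow, binarize_result, exclude_treatment_drug,
                            merge_opiate_thresholds, resolve_duplicates,
                            temperature_flag)

WINDOW = (date(2009, 1, 1), date(2009, 12, 31))


class TestBinarize:
    @pytest.mark.parametrize("raw, flag", [
        ("positive", 1), ("negative", 0), ("unclear", 0),
        ("invalid", 0), ("not_assessed", 0),
    ])
    def test_negative_default_rule(self, raw, flag):
        assert binarize_result(raw) == flag

    def test_total_over_raw_enum(self):
        assert {binarize_result(r) for r in uds.RAW_RESULTS} <= {0, 1}

    def test_unknown_raw_value(self):
        with pytest.raises(ValueError):
            binarize_result("maybe")


class TestThresholdMerge:
    def test_any_positive_wins(self):
        assert merge_opiate_thresholds({300: "positive", 2000: "negative"}) == 1

    def test_all_negative(self):
        assert merge_opiate_thresholds({300: "negative", 2000: "negative"}) == 0

    def test_single_threshold(self):
        assert merge_opiate_thresholds({2000: "positive"}) == 1

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            merge_opiate_thresholds({})


def panel(who=1, d=date(2009, 6, 10), results=None, ts=None, week=None,
          note=None):
    return PanelRow(who=who, date=d, results=results or [("cocaine", "positive")],
                    entry_timestamp=ts, visit_week=week, note=note)


class TestResolveDuplicates:
    def test_note_keeps_both(self):
        rows = [panel(note="second sample, clinician suspicion"), panel()]
        kept, corr = resolve_duplicates(rows, WINDOW)
        assert len(kept) == 2 and corr == []

    def test_timestamp_identifies_date_typo(self):
        true_date = date(2009, 6, 3)
        rows = [panel(results=[("thc", "positive")], ts=true_date),
                panel(results=[("cocaine", "positive")],
                      ts=date(2009, 6, 10))]
        kept, corr = resolve_duplicates(rows, WINDOW)
        assert kept[0].date == true_date
        assert [c.rule_id for c in corr] == ["uds.date_from_timestamp"]

    def test_end_of_study_copy_collapsed_and_flagged(self):
        rows = [panel(), panel()]
        kept, corr = resolve_duplicates(rows, WINDOW)
        assert len(kept) == 1
        assert kept[0].is_end_of_study == 1
        assert corr and corr[0].rule_id == "uds.end_of_study_duplicate"

    def test_contradictory_rows_kept_with_flag(self):
        rows = [panel(results=[("cocaine", "positive")]),
                panel(results=[("cocaine", "negative")])]
        kept, corr = resolve_duplicates(rows, WINDOW)
        assert len(kept) == 2
        assert all(r.flag == "uds.duplicate_ambiguous" for r in kept)

    def test_group_never_emptied(self):
        for rows in ([panel()], [panel(), panel()],
                     [panel(), panel(results=[("thc", "negative")])]):
            kept, _ = resolve_duplicates(rows, WINDOW)
            assert len(kept) >= 1


class TestTreatmentDrugExclusion:
    POS = [(10, "Methadone"), (10, "Cocaine"), (17, "Buprenorphine")]

    def test_methadone_arm_drops_methadone_only(self):
        kept, excluded = exclude_treatment_drug(self.POS, "methadone")
        assert (10, "Methadone") not in kept
        assert (10, "Methadone") in excluded
        assert (10, "Cocaine") in kept and (17, "Buprenorphine") in kept

    def test_bup_arm_keeps_methadone(self):
        kept, excluded = exclude_treatment_drug(self.POS, "buprenorphine")
        assert (10, "Methadone") in kept
        assert excluded == [(17, "Buprenorphine")]

    def test_unrandomized_and_xr_ntx_exclude_nothing(self):
        for assignment in (None, "xr_ntx"):
            kept, excluded = exclude_treatment_drug(self.POS, assignment)
            assert kept == self.POS and excluded == []

    def test_union_is_identity(self):
        kept, excluded = exclude_treatment_drug(self.POS, "methadone")
        assert sorted(kept + excluded) == sorted(self.POS)


class TestTemperature:
    MAP = {"1": "Yes", "0": "No"}

    def test_in_range(self):
        assert temperature_flag("1", self.MAP) == "Yes"

    def test_out_of_range(self):
        assert temperature_flag("0", self.MAP) == "No"

    def test_absent_field_missing(self):
        assert temperature_flag(None, self.MAP) == "Missing"
        assert temperature_flag("", self.MAP) == "Missing"

    def test_unmapped_code(self):
        with pytest.raises(ValueError):
            temperature_flag("7", self.MAP)
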