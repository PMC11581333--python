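from datetime import date

import pytest
from hypothesis import given, settings, strategies as st

from oudharmony import temporal
from oudharmony.temporal import (assign_week, derive_baseline_window,
                                 derive_use_weeks, detect_relapse, repair_date)


class TestAssignWeek:
    @pytest.mark.parametrize("d, week", [(0, 1), (6, 1), (7, 2), (13, 2), (14, 3)])
    def test_boundaries(self, d, week):
        assert assign_week(d) == week

    def test_negative_offset_is_baseline_not_a_week(self):
        with pytest.raises(ValueError):
            assign_week(-1)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, derandomize=True)
    def test_partitions_nonnegative_days(self, d):
        w = assign_week(d)
        assert 7 * (w - 1) <= d <= 7 * w - 1


class TestBaselineWindow:
    def test_gap_arithmetic(self):
        end, gap = derive_baseline_window([(-35, -6)], 4)
        assert end == -6 and gap == 10

    def test_block_ending_at_randomization(self):
        end, gap = derive_baseline_window([(-30, 4)], 4)
        assert gap == 0

    def test_no_pre_engagement_block(self):
        assert derive_baseline_window([(2, 9)], 4) == (None, None)

    def test_earliest_block_wins(self):
        end, gap = derive_baseline_window([(-10, -4), (-40, -11)], 0)
        assert end == -11 and gap == 11


class TestRepairDate:
    WINDOW = (date(2009, 1, 1), date(2009, 12, 31))

    def test_year_typo_against_anchor(self):
        res = repair_date(date(2007, 3, 1), self.WINDOW, anchor=date(2009, 3, 1))
        assert res.changed and res.rule == "repair.year"
        assert res.date == date(2009, 3, 1)

    def test_off_by_one_against_anchor(self):
        res = repair_date(date(2009, 3, 1), self.WINDOW, anchor=date(2009, 3, 2))
        assert res.rule == "repair.offby1" and res.date == date(2009, 3, 2)

    def test_backfill_gap_left_alone(self):
        # survey dated days after the recall period ends: normal pattern
        res = repair_date(date(2009, 3, 6), self.WINDOW, anchor=date(2009, 3, 1))
        assert not res.changed and res.rule is None

    def test_in_window_untouched(self):
        res = repair_date(date(2009, 6, 1), self.WINDOW)
        assert not res.changed and res.rule is None

    def test_unique_year_shift_repaired(self):
        res = repair_date(date(2007, 6, 1), self.WINDOW)
        assert res.rule == "repair.year" and res.date == date(2009, 6, 1)

    def test_transposition_repaired_with_week_context(self):
        origin = date(2009, 6, 1)
        window = (date(2009, 5, 1), date(2009, 12, 1))
        # true date 2009-06-03 (week 1) mistyped as 2009-06-30
        res = repair_date(date(2009, 6, 30), window, expected_week=1,
                          week_origin=origin)
        assert res.rule == "repair.transpose" and res.date == date(2009, 6, 3)

    def test_two_candidates_flag_ambiguous(self):
        # a window spanning several years admits two year-shift repairs
        window = (date(2007, 1, 1), date(2010, 12, 31))
        res = repair_date(date(2005, 5, 3), window)
        assert res.rule == "flag.ambiguous"
        assert res.date == date(2005, 5, 3)  # never guessed

    def test_unrepairable_flagged(self):
        res = repair_date(date(1999, 6, 15), self.WINDOW)
        assert res.rule == "flag.unrepairable" and not res.changed


def brute_force_relapse(weeks, run=4, min_week=4):
    last = max(weeks) if weeks else 0
    for w in range(min_week, last + 1):
        if all(weeks.get(w + i, 0) for i in range(run)):
            return w + run - 1
    return None


class TestRelapse:
    @pytest.mark.parametrize("used, expected", [
        ({4, 5, 6, 7}, 7),
        ({1, 2, 3, 4}, None),          # run must start at week >= 4
        ({4, 5, 7, 8, 9, 10}, 10),     # first qualifying run is 7-10
        ({3, 4, 5, 6}, None),
        (set(), None),
        (set(range(1, 25)), 7),
    ])
    def test_examples(self, used, expected):
        weeks = {w: int(w in used) for w in range(1, 25)}
        assert detect_relapse(weeks) == expected

    def test_alternative_end_anchor_reading(self):
        weeks = {w: int(w in {1, 2, 3, 4}) for w in range(1, 25)}
        assert detect_relapse(weeks, anchor="end") == 4

    @given(st.lists(st.integers(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_matches_brute_force(self, flags):
        weeks = {i + 1: f for i, f in enumerate(flags)}
        assert detect_relapse(weeks) == brute_force_relapse(weeks)


class TestUseWeeks:
    def test_flags_only_marked_weeks(self):
        series = derive_use_weeks(1, [(25, "Heroin"), (32, "Opioid")],
                                  randomization_when=4, follow_up_weeks=8)
        assert series.weeks == {1: 0, 2: 0, 3: 0, 4: 1, 5: 1, 6: 0, 7: 0, 8: 0}

    def test_multiple_visits_same_week_both_count(self):
        series = derive_use_weeks(1, [(18, "Heroin"), (20, "Heroin")],
                                  randomization_when=4, follow_up_weeks=4)
        assert series.weeks[3] == 1

    def test_non_opioid_positives_do_not_count(self):
        series = derive_use_weeks(1, [(10, "Cocaine")],
                                  randomization_when=4, follow_up_weeks=4)
        assert all(v == 0 for v in series.weeks.values())

    def test_tlfb_only_counts_when_enabled(self):
        args = dict(randomization_when=0, follow_up_weeks=4,
                    tlfb_positives=[(7, "Heroin")])
        assert derive_use_weeks(1, [], **args).weeks[2] == 0
        assert derive_use_weeks(1, [], include_tlfb=True, **args).weeks[2] == 1
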