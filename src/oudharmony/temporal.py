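"""Study timelines: week assignment, baseline windows, date repair, relapse.

Two temporal anchors coexist: ``when`` counts days relative to consent
(day 0 = consent), while study weeks are anchored on the randomization
date — 0-6 days after randomization is Week 1, 7-13 days Week 2, and so
on.  A "use week" is a follow-up week containing any positive
non-prescribed-opioid urine toxicology; "relapse" is four consecutive use
weeks on or after Week 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional, Sequence

RULE_YEAR = "repair.year"
RULE_OFFBY1 = "repair.offby1"
RULE_TRANSPOSE = "repair.transpose"
RULE_MONTHSWAP = "repair.monthswap"
FLAG_AMBIGUOUS = "flag.ambiguous"
FLAG_UNREPAIRABLE = "flag.unrepairable"

#: context window half-widths for plausible dates: consent - 60 days up to
#: last scheduled visit + 30 days
WINDOW_BEFORE_CONSENT = 60
WINDOW_AFTER_LAST_VISIT = 30


@dataclass
class StudyTimeline:
    who: int
    consent_when: int = 0
    screening_when: int = 0
    randomization_when: Optional[int] = None
    randomization2_when: Optional[int] = None
    detox_admission_when: Optional[int] = None
    baseline_end_when: Optional[int] = None
    days_baseline_to_randomization: Optional[int] = None


@dataclass
class UseWeekSeries:
    who: int
    weeks: dict = field(default_factory=dict)  # week index >= 1 -> 0/1
    relapse_week: Optional[int] = None


def assign_week(days_after_randomization: int) -> int:
    """Calendar-week index from a day offset: week = floor(d/7) + 1."""
    d = int(days_after_randomization)
    if d < 0:
        raise ValueError(f"negative day offset {d}: pre-randomization days "
                         "belong to the baseline window, not a study week")
    return d // 7 + 1


def derive_baseline_window(blocks: Iterable[tuple], randomization_when: int):
    """Locate the end of the baseline drug-use survey.

    ``blocks`` are TLFB coverage intervals ``(start_when, end_when)`` per
    survey administration.  The baseline block is the earliest block whose
    recall began before consent (start_when < 0); its last covered day is
    the End of Baseline Survey, and the gap to randomization is
    ``randomization_when - baseline_end_when`` days.  Returns
    ``(baseline_end_when, gap)`` or ``(None, None)`` when no
    pre-engagement block exists.
    """
    candidates = [b for b in blocks if b[0] < 0]
    if not candidates:
        return None, None
    start, end = min(candidates, key=lambda b: (b[0], b[1]))
    return end, int(randomization_when) - int(end)


# ---------------------------------------------------------------------------
# date repair

@dataclass
class DateRepair:
    date: date
    rule: Optional[str] = None  # repair.* when changed, flag.* when not
    original: Optional[date] = None

    @property
    def changed(self) -> bool:
        return self.rule is not None and self.rule.startswith("repair.")


def _transpose_day(d: date):
    swapped = int(f"{d.day:02d}"[::-1])
    try:
        return d.replace(day=swapped)
    except ValueError:
        return None


def _swap_month_day(d: date):
    if d.day > 12:
        return None
    try:
        return d.replace(month=d.day, day=d.month)
    except ValueError:
        return None


def repair_date(d: date, window: tuple,
                expected_week: Optional[int] = None,
                week_origin: Optional[date] = None,
                anchor: Optional[date] = None) -> DateRepair:
    """Conservative single-date repair against its context.

    Applied in order: (a) year-typo repair when a year shift aligns the
    date with its anchor or uniquely with the context window; (b)
    off-by-one repair against the anchor (survey date moved to the last
    TLFB day); (c) digit-transposition and month/day-swap candidates,
    accepted only when exactly one lands in the context (window plus
    expected study week).  Unrepairable or ambiguous dates are returned
    unchanged with a flag — never guessed.
    """
    lo, hi = window

    def week_of(c: date):
        if week_origin is None:
            return None
        offset = (c - week_origin).days
        return None if offset < 0 else offset // 7 + 1

    def fits(c: date) -> bool:
        if not (lo <= c <= hi):
            return False
        if expected_week is not None and week_origin is not None:
            return week_of(c) == expected_week
        return True

    if anchor is not None:
        if d == anchor:
            return DateRepair(d)
        for k in range(-3, 4):
            if k and _shift_year(d, k) == anchor:
                return DateRepair(anchor, RULE_YEAR, d)
        if abs((d - anchor).days) == 1:
            return DateRepair(anchor, RULE_OFFBY1, d)
        return DateRepair(d)  # normal recall gap; not an error pattern

    if fits(d):
        return DateRepair(d)

    candidates = []
    for k in (1, -1, 2, -2, 3, -3):
        c = _shift_year(d, k)
        if c is not None and fits(c):
            candidates.append((RULE_YEAR, c))
    for maker, rule in ((_transpose_day, RULE_TRANSPOSE), (_swap_month_day, RULE_MONTHSWAP)):
        c = maker(d)
        if c is not None and c != d and fits(c):
            candidates.append((rule, c))
    distinct = sorted({c for _, c in candidates})
    if len(distinct) == 1:
        rule = next(r for r, c in candidates if c == distinct[0])
        return DateRepair(distinct[0], rule, d)
    if len(distinct) > 1:
        return DateRepair(d, FLAG_AMBIGUOUS)
    return DateRepair(d, FLAG_UNREPAIRABLE)


def _shift_year(d: date, k: int):
    try:
        return d.replace(year=d.year + k)
    except ValueError:  # Feb 29
        return None


# ---------------------------------------------------------------------------
# use weeks and relapse

#: categories that can set a use-week flag; the uds table has the
#: prescribed treatment drug already excluded, so any remaining positive
#: in these categories is non-prescribed opioid use
OPIOID_CATEGORIES = frozenset({"Heroin", "Opioid", "Methadone", "Buprenorphine"})


def derive_use_weeks(who: int, uds_positives: Iterable[tuple],
                     randomization_when: int, follow_up_weeks: int,
                     tlfb_positives: Iterable[tuple] = (),
                     include_tlfb: bool = False,
                     opioid_categories: frozenset = OPIOID_CATEGORIES) -> UseWeekSeries:
    """Flag each follow-up week with any qualifying opioid positive.

    ``uds_positives`` (and optionally ``tlfb_positives``) are ``(when,
    category)`` pairs with ``when`` relative to consent.  Multiple visits
    in one week all contribute.  Self-report contributes only when
    ``include_tlfb`` is set; the default follows the urine-toxicology
    definition.
    """
    weeks = {w: 0 for w in range(1, int(follow_up_weeks) + 1)}
    streams = [uds_positives] + ([tlfb_positives] if include_tlfb else [])
    for stream in streams:
        for when, category in stream:
            if category not in opioid_categories:
                continue
            offset = int(when) - int(randomization_when)
            if offset < 0:
                continue
            w = assign_week(offset)
            if w in weeks:
                weeks[w] = 1
    series = UseWeekSeries(who=who, weeks=weeks)
    series.relapse_week = detect_relapse(weeks)
    return series


def detect_relapse(weeks: Mapping[int, int], run_length: int = 4,
                   min_week: int = 4, anchor: str = "start") -> Optional[int]:
    """End week of the first run of four consecutive use weeks at/after Week 4.

    ``anchor="start"`` (default) requires the run's first week >= 4, so the
    earliest possible relapse run is weeks 4-7; ``anchor="end"`` is the
    alternative reading requiring only the run's last week >= 4.
    """
    if anchor not in ("start", "end"):
        raise ValueError("anchor must be 'start' or 'end'")
    if not weeks:
        return None
    last = max(weeks)
    lo = min_week if anchor == "start" else 1
    for w in range(lo, last - run_length + 2):
        if all(weeks.get(w + i, 0) for i in range(run_length)):
            end = w + run_length - 1
            if anchor == "end" and end < min_week:
                continue
            return end
    return None
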