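"""Concept crosswalks between instrument-specific values and harmonized levels.

Covers: opioid withdrawal severity (COWS/SOWS onto a shared four-level
ordinal), baseline pain (SF-36 bodily-pain item and EuroQoL pain item onto
three levels), risky-behavior frequency categories onto days-per-30,
demographic harmonization (age, race, education, marital, employment,
living arrangement), FTND nicotine-dependence scoring, and binary medical /
psychiatric / substance-use-disorder flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Optional

from .schema import (EDUCATION_LEVELS, EMPLOYMENT_LEVELS, MARITAL_LEVELS,
                     PAIN_LEVELS, RACE_LEVELS, SEVERITY_LEVELS)

# --------------------------------------------------------------------------
# withdrawal

#: published instrument ranges: COWS has 11 items (max 48), SOWS 16 items
#: (each 0-4, max 64)
INSTRUMENT_MAX = {"COWS": 48, "SOWS": 64}

#: ordered severity rules: first match wins, swept severe -> none
_SEVERITY_RULES = (
    ("severe", {"COWS": 25, "SOWS": 21}),
    ("moderate", {"COWS": 13, "SOWS": 11}),
    ("mild", {"COWS": 5, "SOWS": 1}),
)


def withdrawal_severity(instrument: str, score: int) -> str:
    """Four-level harmonized withdrawal severity from a raw scale score.

    Rules are applied in order severe (COWS >= 25, SOWS >= 21), moderate
    (COWS >= 13, SOWS >= 11), mild (COWS >= 5, SOWS >= 1), else none.
    """
    if instrument not in INSTRUMENT_MAX:
        raise KeyError(f"unknown withdrawal instrument {instrument!r}")
    score = int(score)
    if score < 0 or score > INSTRUMENT_MAX[instrument]:
        raise ValueError(f"{instrument} score {score} outside 0..{INSTRUMENT_MAX[instrument]}")
    for level, cut in _SEVERITY_RULES:
        if score >= cut[instrument]:
            return level
    return "none"


def select_pre_post(measurements: Iterable[tuple], induction_when: int):
    """Closest withdrawal measurements around first treatment induction.

    ``measurements`` is an iterable of ``(when, value)``; pre is the latest
    strictly before ``induction_when``, post the earliest at or after it.
    Either side may be absent.  Returns ``(pre, post)`` as (when, value)
    tuples or None.
    """
    pre = post = None
    for when, value in measurements:
        if when < induction_when:
            if pre is None or when > pre[0]:
                pre = (when, value)
        else:
            if post is None or when < post[0]:
                post = (when, value)
    return pre, post


# --------------------------------------------------------------------------
# pain

_SF36_PAIN = {
    "None": "No Pain",
    "Very Mild": "Very Mild to Moderate Pain",
    "Mild": "Very Mild to Moderate Pain",
    "Moderate": "Very Mild to Moderate Pain",
    "Severe": "Severe Pain",
    "Very Severe": "Severe Pain",
}
_EUROQOL_PAIN = {
    "I have no pain or discomfort": "No Pain",
    "I have moderate pain or discomfort": "Very Mild to Moderate Pain",
    "I have extreme pain or discomfort": "Severe Pain",
}
PAIN_MAPS = {"SF36": _SF36_PAIN, "EuroQoL": _EUROQOL_PAIN}


def pain_category(instrument: str, response: str) -> str:
    """Map an SF-36 or EuroQoL pain response onto the three shared levels."""
    try:
        levels = PAIN_MAPS[instrument]
    except KeyError:
        raise KeyError(f"unknown pain instrument {instrument!r}") from None
    try:
        return levels[response]
    except KeyError:
        raise KeyError(f"unknown {instrument} pain response {response!r}") from None


# --------------------------------------------------------------------------
# risky behaviors

RAB_DAYS = {
    "not at all": 0,
    "a few times": 5,
    "a few times each week": 15,
    "every day": 30,
}


def rab_days(category: str) -> int:
    """Days of use per 30 for a categorical frequency response."""
    try:
        return RAB_DAYS[category]
    except KeyError:
        raise KeyError(f"unknown frequency category {category!r}") from None


def derive_iv_summaries(days_by_drug: Mapping[str, int],
                        events_by_drug: Mapping[str, int]) -> dict:
    """Per-subject IV-use summaries from per-drug days and events/day.

    ``iv_max_days`` is the maximum days of use across IV drugs,
    ``iv_max_events`` the maximum events per day, and ``iv_monthly`` the
    monthly exposure (days x events/day) of the most-used drug.  No IV use
    yields all zeros.
    """
    days = {k: int(v) for k, v in days_by_drug.items() if v}
    if not days:
        return {"iv_max_days": 0, "iv_max_events": 0, "iv_monthly": 0}
    top = max(sorted(days), key=lambda k: days[k])
    events = {k: int(v) for k, v in events_by_drug.items() if v}
    return {
        "iv_max_days": max(days.values()),
        "iv_max_events": max(events.values(), default=1),
        "iv_monthly": days[top] * events.get(top, 1),
    }


# --------------------------------------------------------------------------
# demographics

def age_at_screening(dob: date, screening: date) -> int:
    """Integer portion of the year difference between DOB and screening."""
    if dob > screening:
        raise ValueError(f"date of birth {dob} after screening date {screening}")
    years = screening.year - dob.year
    if (screening.month, screening.day) < (dob.month, dob.day):
        years -= 1
    return years


def collapse_race(raw: str) -> str:
    """Four census-style categories: White, Black, Refused/Missing, Other."""
    if raw is None or str(raw).strip() == "":
        return "Refused/Missing"
    text = str(raw).strip().lower()
    if text == "white":
        return "White"
    if text in ("black", "black or african american"):
        return "Black"
    if text in ("participant chooses not to answer", "refused", "unknown", "missing"):
        return "Refused/Missing"
    return "Other"


#: direct-survey education code 13 means "high school graduate"; the ASI
#: codes the same attainment as 12 years
HS_DIRECT_SURVEY_CODE = 13


def education_category(asi_years: Optional[float],
                       direct_survey_code: Optional[float] = None) -> str:
    """Bin years of education, backfilling missing ASI values from the
    direct survey (the direct code 13 = HS graduate normalizes to 12)."""
    years = asi_years
    if years is None and direct_survey_code is not None:
        years = direct_survey_code
        if years == HS_DIRECT_SURVEY_CODE:
            years = 12
    if years is None:
        return "Missing/Refused"
    years = float(years)
    if years < 12:
        return "Less than High School"
    if years == 12:
        return "High School/GED"
    return "More than High School"


@dataclass
class DemographicsRow:
    age: int
    is_male: Optional[int]
    is_hispanic: Optional[int]
    race: str
    education: str
    marital: str
    is_living_stable: Optional[int]
    job: str


def harmonize_demographics(dob: date, screening: date, sex: Optional[str],
                           hispanic: Optional[str], race_raw: str,
                           asi_education_years: Optional[float],
                           direct_education_code: Optional[float],
                           marital: str, living_stable: Optional[str],
                           usual_employment: str) -> DemographicsRow:
    """Assemble one harmonized demographics row from dialect-recoded inputs.

    ``sex``/``hispanic``/``living_stable`` arrive as recoded values
    ("male"/"female", "yes"/"no", "stable"/"unstable") or None for missing.
    """
    tri = {"male": 1, "female": 0, "yes": 1, "no": 0,
           "stable": 1, "unstable": 0, None: None}
    if marital not in MARITAL_LEVELS:
        raise KeyError(f"unknown marital level {marital!r}")
    if usual_employment not in EMPLOYMENT_LEVELS:
        raise KeyError(f"unknown employment level {usual_employment!r}")
    return DemographicsRow(
        age=age_at_screening(dob, screening),
        is_male=tri[sex],
        is_hispanic=tri[hispanic],
        race=collapse_race(race_raw),
        education=education_category(asi_education_years, direct_education_code),
        marital=marital,
        is_living_stable=tri[living_stable],
        job=usual_employment,
    )


# --------------------------------------------------------------------------
# nicotine

#: standard FTND item maxima: time-to-first-cigarette 0-3, forbidden-places
#: 0-1, cigarette-hate-to-give-up 0-1, cigarettes-per-day 0-3,
#: morning-smoking 0-1, smoke-when-ill 0-1; total 0-10
FTND_ITEM_MAX = (3, 1, 1, 3, 1, 1)


def score_ftnd(items: Iterable[Optional[int]], is_smoker: bool = True) -> Optional[int]:
    """Fagerstrom Test for Nicotine Dependence total (0-10); nonsmokers
    score missing rather than zero."""
    if not is_smoker:
        return None
    items = list(items)
    if len(items) != 6:
        raise ValueError(f"FTND requires 6 item responses, got {len(items)}")
    total = 0
    for value, hi in zip(items, FTND_ITEM_MAX):
        value = int(value)
        if not 0 <= value <= hi:
            raise ValueError(f"FTND item response {value} outside 0..{hi}")
        total += value
    return total


# --------------------------------------------------------------------------
# diagnoses

def sud_flag(dsm4_abuse: Optional[int], dsm4_dependence: Optional[int],
             dsm5_disorder: Optional[int]) -> Optional[int]:
    """Single binary: DSM-IV abuse OR dependence OR DSM-5 use disorder.

    Missing on every source stays missing; any positive source wins.
    """
    sources = [dsm4_abuse, dsm4_dependence, dsm5_disorder]
    known = [int(s) for s in sources if s is not None]
    if not known:
        return None
    return 1 if any(known) else 0


def derive_diagnosis_flags(history: Mapping[str, Optional[int]],
                           checklist: Mapping[str, Optional[int]],
                           asi: Mapping[str, Optional[int]]) -> dict:
    """Keep medical-history, checklist and ASI flags as separate variables.

    Agreement between sources is only modest, so the harmonized database
    retains each source rather than merging them.
    """
    out = {}
    for key, value in history.items():
        out[f"history_{key}"] = None if value is None else int(value)
    for key, value in checklist.items():
        out[f"checklist_{key}"] = None if value is None else int(value)
    for key, value in asi.items():
        out[f"asi_{key}"] = None if value is None else int(value)
    return out
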