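"""Urine-drug-screen harmonization.

Panels arrive as per-substance rows with raw result codes, optional entry
timestamps and (for opiate assays) a detection threshold of 300 or 2000
ng/mL.  Harmonization binarizes results (anything that is not clearly
positive — unclear, invalid, not assessed — counts negative), merges the
two opiate thresholds into "any positive for morphine metabolite",
resolves duplicate same-date samples through a deterministic cascade, and
drops the prescribed treatment drug from the ``uds`` table while keeping
it in ``all_drugs``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Optional, Sequence

from .schema import CorrectionEntry

RAW_RESULTS = ("positive", "negative", "unclear", "invalid", "not_assessed")

RULE_EOS = "uds.end_of_study_duplicate"
RULE_TIMESTAMP = "uds.date_from_timestamp"
FLAG_DUP_AMBIGUOUS = "uds.duplicate_ambiguous"

#: treatment drug detected on the panel for each randomized medication;
#: XR-NTX is not an assay target, so nothing is excluded for that arm
ASSIGNED_PANEL_DRUG = {
    "methadone": "methadone",
    "buprenorphine": "buprenorphine",
    "xr_ntx": None,
}


def binarize_result(raw_result: str) -> int:
    """1 for positive; negative/unclear/invalid/not_assessed all code 0."""
    if raw_result not in RAW_RESULTS:
        raise ValueError(f"unknown UDS raw result {raw_result!r}")
    return 1 if raw_result == "positive" else 0


def merge_opiate_thresholds(results_by_threshold: Mapping[int, str]) -> int:
    """Any-positive across the 300 and 2000 ng/mL opiate assays."""
    if not results_by_threshold:
        raise ValueError("no opiate assay present for this visit")
    return int(any(binarize_result(r) for r in results_by_threshold.values()))


def temperature_flag(raw_value: Optional[str], dialect_map: Mapping[str, str]) -> str:
    """Yes / No / Missing for the sample-temperature-in-range concept."""
    if raw_value is None or str(raw_value).strip() == "":
        return "Missing"
    try:
        return dialect_map[str(raw_value)]
    except KeyError:
        raise ValueError(f"unmapped temperature code {raw_value!r}") from None


@dataclass
class PanelRow:
    """One same-visit panel: who, sample date, per-substance results."""

    who: int
    date: date
    results: dict  # substance -> raw result code
    entry_timestamp: Optional[date] = None
    visit_week: Optional[int] = None
    note: Optional[str] = None
    is_end_of_study: int = 0
    flag: Optional[str] = None
    temp: Optional[str] = None


def resolve_duplicates(rows: Sequence[PanelRow], window: tuple,
                       week_origin: Optional[date] = None):
    """Deterministic cascade for multiple panels sharing one (who, date).

    In order: a justification note keeps all rows; an entry timestamp or
    expected-week context that identifies one row as date-typo'd repairs
    that row's date; an identical-result copy collapses to one row flagged
    end-of-study; anything else is kept with an ambiguity flag.  Never
    reduces a group to zero rows and never breaks ties randomly.
    """
    corrections: list[CorrectionEntry] = []
    if len(rows) < 2:
        return list(rows), corrections
    if any(r.note for r in rows):
        return list(rows), corrections

    group_date = rows[0].date
    out = list(rows)
    moved = False
    for r in out:
        if (r.entry_timestamp is not None and r.entry_timestamp != r.date
                and window[0] <= r.entry_timestamp <= window[1]):
            # the data-entry timestamp carries the true sample date; the
            # recorded date was typo'd into another visit's date
            corrections.append(CorrectionEntry(
                r.who, "uds", "date", r.date, r.entry_timestamp,
                RULE_TIMESTAMP, "duplicate date resolved from entry timestamp"))
            r.date = r.entry_timestamp
            moved = True
    if moved:
        # keep cascading on whatever still shares the original date
        remaining = [r for r in out if r.date == group_date]
        if len(remaining) >= 2:
            kept, more = resolve_duplicates(remaining, window, week_origin)
            corrections.extend(more)
            out = [r for r in out if r.date != group_date] + kept
        return out, corrections

    # end-of-study copy: identical results duplicated when someone left early
    survivors: list[PanelRow] = []
    for r in out:
        twin = next((s for s in survivors if s.results == r.results), None)
        if twin is not None:
            twin.is_end_of_study = 1
            corrections.append(CorrectionEntry(
                r.who, "uds", "row", "duplicate panel", "dropped",
                RULE_EOS, "identical same-date panel kept once, flagged end of study"))
        else:
            survivors.append(r)
    if len(survivors) < len(out):
        return survivors, corrections

    for r in out:
        r.flag = FLAG_DUP_AMBIGUOUS
    return out, corrections


def exclude_treatment_drug(positives: Iterable[tuple],
                           assignment_drug: Optional[str]):
    """Split UDS positives into the uds table and the excluded assigned drug.

    ``positives`` are ``(when, substance_category)`` pairs.  Rows matching
    the subject's randomized medication are omitted from ``uds`` (they
    stay in ``all_drugs``); unrandomized subjects keep everything.
    Returns ``(kept, excluded)``.
    """
    excluded_cat = None
    if assignment_drug is not None:
        panel = ASSIGNED_PANEL_DRUG.get(assignment_drug)
        if panel == "methadone":
            excluded_cat = "Methadone"
        elif panel == "buprenorphine":
            excluded_cat = "Buprenorphine"
    kept, excluded = [], []
    for when, category in positives:
        (excluded if category == excluded_cat else kept).append((when, category))
    return kept, excluded
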