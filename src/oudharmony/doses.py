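"""Dose-log harmonization: one prescribed dose per dosed day.

Raw logs mix daily rows, weekly rows (one stated daily dose covering
seven days), same-day split rows (in-clinic plus take-home), and one row
per injection for extended-release naltrexone.  Normalization expands
weekly rows, sums same-day entries, relabels isolated single-day
"other drug" entries to the randomized assignment, and computes
per-subject treatment summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .schema import CorrectionEntry
from .temporal import assign_week

RULE_OTHER_DRUG = "dose.other_drug_relabel"
FLAG_OTHER_RUN = "dose.other_drug_run"
RULE_SAME_DAY_SUM = "dose.same_day_sum"


@dataclass
class DoseRecord:
    who: int
    when: int
    drug: str  # methadone | buprenorphine | xr_ntx
    dose: float
    was_corrected: int = 0
    flag: Optional[str] = None


@dataclass
class RawDoseEntry:
    """A raw log line: either one day or a week span at a daily dose."""

    who: int
    when: int               # first covered day
    drug: str
    dose: float             # daily dose in mg (or 1 per injection)
    span_days: int = 1      # 7 for weekly logs


def normalize_dose_log(entries: Iterable[RawDoseEntry]):
    """Expand week spans and sum same-day entries into daily DoseRecords."""
    corrections: list[CorrectionEntry] = []
    per_day: dict[tuple, DoseRecord] = {}
    multi: set[tuple] = set()
    for e in entries:
        for offset in range(int(e.span_days)):
            key = (e.who, e.when + offset, e.drug)
            if key in per_day:
                per_day[key].dose += float(e.dose)
                multi.add(key)
            else:
                per_day[key] = DoseRecord(e.who, e.when + offset, e.drug, float(e.dose))
    for who, when, drug in sorted(multi):
        rec = per_day[(who, when, drug)]
        corrections.append(CorrectionEntry(
            who, "treatment_dose", "dose", None, rec.dose, RULE_SAME_DAY_SUM,
            "multiple same-day logs summed (in-clinic + take-home)"))
    return sorted(per_day.values(), key=lambda r: (r.who, r.when, r.drug)), corrections


def correct_other_drug(records: Sequence[DoseRecord], assigned_drug: str):
    """Relabel isolated single-day other-drug doses to the assignment.

    A lone other-drug day flanked by assigned-drug dosing is a data-entry
    error (the dose itself corresponds to the assigned drug); runs of two
    or more other-drug days fall outside that documented pattern and are
    only flagged.  Drug labels change; dose values and dates never do.
    """
    corrections: list[CorrectionEntry] = []
    recs = sorted(records, key=lambda r: r.when)
    i = 0
    while i < len(recs):
        if recs[i].drug == assigned_drug:
            i += 1
            continue
        j = i
        while j < len(recs) and recs[j].drug != assigned_drug:
            j += 1
        run = recs[i:j]
        if len(run) == 1:
            r = run[0]
            corrections.append(CorrectionEntry(
                r.who, "treatment_dose", "what", r.drug, assigned_drug,
                RULE_OTHER_DRUG, "single other-drug dose amid assigned treatment"))
            r.drug = assigned_drug
            r.was_corrected = 1
        else:
            for r in run:
                r.flag = FLAG_OTHER_RUN
        i = j
    return recs, corrections


@dataclass
class TreatmentSummary:
    who: int
    n_doses: Optional[int] = None
    length_days: Optional[int] = None
    avg_dose: Optional[float] = None
    max_dose: Optional[float] = None
    first_week_n_doses: Optional[int] = None
    first_week_avg_dose: Optional[float] = None
    first_week_max_dose: Optional[float] = None


def summarize_treatment(who: int, records: Sequence[DoseRecord]) -> TreatmentSummary:
    """Per-subject dose summaries; the first week anchors on the first dose.

    Recorded zero doses (skipped days) stay in the log but are excluded
    from counts and averages; injections count one dose each.
    """
    dosed = sorted((r for r in records if r.dose > 0), key=lambda r: r.when)
    if not dosed:
        return TreatmentSummary(who)
    first = dosed[0].when
    doses = [r.dose for r in dosed]
    week1 = [r.dose for r in dosed if assign_week(r.when - first) == 1]
    return TreatmentSummary(
        who=who,
        n_doses=len(dosed),
        length_days=dosed[-1].when - first + 1,
        avg_dose=sum(doses) / len(doses),
        max_dose=max(doses),
        first_week_n_doses=len(week1),
        first_week_avg_dose=sum(week1) / len(week1),
        first_week_max_dose=max(week1),
    )
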