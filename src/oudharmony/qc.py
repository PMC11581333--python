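"""Quality control: database diffing, logic checks, summaries, recovery scoring.

``compare_databases`` implements the "double helix" check — two
independently produced databases are diffed row-by-row and cell-by-cell
after key-sorting and dtype normalization, so independent implementations
can be verified against each other.  ``logic_check`` runs the
recommended data-collection sanity rules (dates in window, week labels
consistent with calendar weeks, no unexplained duplicate samples, no
runaway free text).  ``score_recovery`` grades a rebuilt database against
an injected-error ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import temporal
from .schema import HarmonizedDatabase

#: audit rules that represent repairs of errors (as opposed to routine
#: harmonization such as dialect recoding or same-day dose summing)
CORRECTION_RULES = (
    "repair.year", "repair.offby1", "repair.transpose", "repair.monthswap",
    "uds.date_from_timestamp", "uds.end_of_study_duplicate",
    "dose.other_drug_relabel", "ingest.exact_duplicate_row",
    "impute.drink_amount",
)


def correction_entries(db: HarmonizedDatabase) -> list:
    return [e for e in db.audit_log if e.rule_id in CORRECTION_RULES]


# ---------------------------------------------------------------------------
# database comparison

def _normalize(df: pd.DataFrame, key: tuple) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().sum() == series.notna().sum():
            out[col] = numeric.astype(float)
        else:
            out[col] = series.astype(object).where(series.notna(), None)
            out[col] = out[col].map(lambda v: None if v is None else str(v))
    keycols = [k for k in key if k in out.columns] or list(out.columns)
    return out.sort_values(keycols, kind="mergesort").reset_index(drop=True)


@dataclass
class DiscrepancyReport:
    missing_tables: list = field(default_factory=list)
    row_diffs: dict = field(default_factory=dict)   # table -> (only_a, only_b)
    cell_diffs: dict = field(default_factory=dict)  # table -> list of dicts

    @property
    def empty(self) -> bool:
        return not (self.missing_tables or self.row_diffs or self.cell_diffs)

    def summary(self) -> str:
        if self.empty:
            return "databases identical"
        parts = []
        for t in self.missing_tables:
            parts.append(f"{t}: present in only one database")
        for t, (a, b) in self.row_diffs.items():
            parts.append(f"{t}: {a} rows only in A, {b} only in B")
        for t, cells in self.cell_diffs.items():
            parts.append(f"{t}: {len(cells)} differing cells")
        return "; ".join(parts)


def compare_databases(db_a: HarmonizedDatabase,
                      db_b: HarmonizedDatabase) -> DiscrepancyReport:
    """Keyed row-level and cell-level diff; identical inputs -> empty report."""
    report = DiscrepancyReport()
    names = set(db_a.tables) | set(db_b.tables)
    for name in sorted(names):
        if name not in db_a.tables or name not in db_b.tables:
            report.missing_tables.append(name)
            continue
        schema = db_a.registry.get(name) or db_b.registry.get(name)
        key = schema.key if schema else tuple(db_a.tables[name].columns)
        a = _normalize(db_a.tables[name], key)
        b = _normalize(db_b.tables[name], key)
        if list(a.columns) != list(b.columns):
            report.missing_tables.append(name)
            continue
        keycols = [k for k in key if k in a.columns] or list(a.columns)
        ka = a.set_index(keycols, drop=False)
        kb = b.set_index(keycols, drop=False)
        only_a = ka.index.difference(kb.index)
        only_b = kb.index.difference(ka.index)
        if len(only_a) or len(only_b):
            report.row_diffs[name] = (len(only_a), len(only_b))
        shared = ka.index.intersection(kb.index)
        if len(shared):
            xa = ka.loc[shared]
            xb = kb.loc[shared]
            cells = []
            for col in a.columns:
                va, vb = xa[col].to_numpy(), xb[col].to_numpy()
                if va.dtype.kind == "f" and vb.dtype.kind == "f":
                    neq = ~(np.isclose(va, vb, equal_nan=True))
                else:
                    neq = va != vb
                for pos in np.nonzero(neq)[0]:
                    cells.append({"key": shared[pos], "column": col,
                                  "a": va[pos], "b": vb[pos]})
            if cells:
                report.cell_diffs[name] = cells
    return report


# ---------------------------------------------------------------------------
# logic checks (data-collection sanity rules)

@dataclass
class LogicViolation:
    who: object
    table: str
    field: str
    rule_id: str
    message: str


FREE_TEXT_THRESHOLD = 20


def logic_check(db: HarmonizedDatabase,
                follow_up_weeks: int = 24) -> list:
    """Table-driven sanity rules on a harmonized database.

    Flags: event days far outside the study window (date.future /
    date.before_study), visit week labels that disagree with the
    calendar-week rule (week.mismatch), duplicate same-day samples
    (uds.duplicate_date), and text variables with runaway distinct values
    (free.text).
    """
    out: list[LogicViolation] = []
    rand = db.tables.get("randomization")
    if rand is not None and len(rand):
        rand1 = rand[rand["which"].astype(str) == "1"].set_index("who")["when"]
        # the study window extends from the latest randomization event, so
        # phase-2 treatment in re-randomized designs is in-window
        rand_last = rand.groupby("who")["when"].max()
    else:
        rand1 = pd.Series(dtype=float)
        rand_last = pd.Series(dtype=float)
    hi_default = 7 * follow_up_weeks + temporal.WINDOW_AFTER_LAST_VISIT

    for name in ("uds_temp", "visits", "treatment_dose", "withdrawal", "tlfb"):
        df = db.tables.get(name)
        if df is None or not len(df):
            continue
        for _, r in df.iterrows():
            who, when = r["who"], r["when"]
            hi = rand_last.get(who, 0) + hi_default
            if when > hi:
                out.append(LogicViolation(who, name, "when", "date.future",
                                          f"day {when} beyond study window"))
            elif when < -temporal.WINDOW_BEFORE_CONSENT - 30:
                out.append(LogicViolation(who, name, "when", "date.before_study",
                                          f"day {when} before study window"))

    visits = db.tables.get("visits")
    if visits is not None and len(visits):
        for _, r in visits.iterrows():
            who = r["who"]
            if who not in rand1.index:
                continue
            offset = int(r["when"]) - int(rand1[who])
            if offset >= 0 and temporal.assign_week(offset) != int(r["visit_week"]):
                out.append(LogicViolation(
                    who, "visits", "visit_week", "week.mismatch",
                    f"label week {r['visit_week']} but calendar week "
                    f"{temporal.assign_week(offset)}"))

    uds_temp = db.tables.get("uds_temp")
    if uds_temp is not None and len(uds_temp):
        dup = uds_temp.duplicated(subset=["who", "when"], keep=False)
        for _, r in uds_temp[dup].iterrows():
            out.append(LogicViolation(r["who"], "uds_temp", "when",
                                      "uds.duplicate_date",
                                      f"multiple samples on day {r['when']}"))

    for name, schema in db.registry.items():
        df = db.tables.get(name)
        if df is None or not len(df):
            continue
        for v in schema.variables:
            if v.value_type == "text" and v.name not in ("raw_id", "label",
                                                         "table", "variable"):
                distinct = df[v.name].nunique()
                if distinct > FREE_TEXT_THRESHOLD and name not in ("all_drugs",):
                    out.append(LogicViolation(
                        None, name, v.name, "free.text",
                        f"{distinct} distinct values in a text field"))
    return out


# ---------------------------------------------------------------------------
# summaries

def _quartiles(values) -> tuple:
    """Median-of-halves quartiles: (q1, median, q3); None for empty input."""
    xs = sorted(float(v) for v in values if v is not None and not pd.isna(v))
    if not xs:
        return None, None, None

    def med(seq):
        n = len(seq)
        m = n // 2
        return seq[m] if n % 2 else (seq[m - 1] + seq[m]) / 2.0

    n = len(xs)
    half = n // 2
    lower = xs[:half]
    upper = xs[half + (n % 2):]
    return (med(lower) if lower else xs[0], med(xs), med(upper) if upper else xs[-1])


def summarize_tables(db: HarmonizedDatabase) -> dict:
    """Per-project counts, percentages and median (Q1-Q3) summaries.

    Covers demographics, urine screens per person, positive screens by
    category, withdrawal severity pre/post, and the treatment-dose
    summary block.  Machine-readable nested dict.
    """
    enrollment = db.tables["enrollment"]
    project_of = dict(zip(enrollment["who"], enrollment["project"]))
    projects = sorted(enrollment["project"].unique())
    out: dict = {"n_subjects": {p: int((enrollment["project"] == p).sum())
                                for p in projects}}

    demo = db.tables["demographics"].copy()
    demo["project"] = demo["who"].map(project_of)
    dblock = {}
    for p in projects:
        sub = demo[demo["project"] == p]
        n = len(sub)
        dblock[p] = {
            "n": n,
            "age_median_q1_q3": _quartiles(sub["age"]),
            "pct_male": round(100.0 * sub["is_male"].mean(), 1) if n else None,
            "race": {k: int(v) for k, v in sub["race"].value_counts().items()},
        }
    out["demographics"] = dblock

    uds_temp = db.tables["uds_temp"].copy()
    uds_temp["project"] = uds_temp["who"].map(project_of)
    block = {}
    for p in projects:
        counts = uds_temp[uds_temp["project"] == p].groupby("who")["when"].count()
        randomized = db.tables["randomization"]
        p_who = [w for w in randomized["who"].unique() if project_of.get(w) == p]
        per_person = [int(counts.get(w, 0)) for w in p_who]
        block[p] = {"median_q1_q3": _quartiles(per_person)}
    out["uds_per_person"] = block

    uds = db.tables["uds"].copy()
    uds["project"] = uds["who"].map(project_of)
    pos = {}
    for p in projects:
        sub = uds[uds["project"] == p]
        n_samples = int((uds_temp["project"] == p).sum())
        freq = sub["what"].value_counts()
        pos[p] = {cat: {"n": int(freq[cat]),
                        "pct": round(100.0 * freq[cat] / n_samples, 1)
                        if n_samples else None}
                  for cat in freq.index}
    out["uds_positive"] = pos

    wpp = db.tables["withdrawal_pre_post"].copy()
    wpp["project"] = wpp["who"].map(project_of)
    wd = {}
    for p in projects:
        sub = wpp[wpp["project"] == p]
        wd[p] = {
            "pre": {k: int(v) for k, v in sub["severity_pre"].value_counts().items()},
            "post": {k: int(v) for k, v in sub["severity_post"].value_counts().items()},
        }
    out["withdrawal_pre_post"] = wd

    from .doses import DoseRecord, summarize_treatment
    doses = db.tables["treatment_dose"].copy()
    doses["project"] = doses["who"].map(project_of)
    tblock = {}
    for (p, drug), sub in doses.groupby(["project", "what"]):
        summaries = []
        for who, g in sub.groupby("who"):
            recs = [DoseRecord(who, int(r["when"]), drug, float(r["dose"]))
                    for _, r in g.iterrows()]
            summaries.append(summarize_treatment(who, recs))
        tblock[f"{p}:{drug}"] = {
            "n": len(summaries),
            "n_doses_median_q1_q3": _quartiles([s.n_doses for s in summaries]),
            "length_days_median_q1_q3": _quartiles([s.length_days for s in summaries]),
            "avg_dose_median_q1_q3": _quartiles([s.avg_dose for s in summaries]),
            "max_dose_median_q1_q3": _quartiles([s.max_dose for s in summaries]),
            "first_week_avg_median_q1_q3": _quartiles(
                [s.first_week_avg_dose for s in summaries]),
            "first_week_max_median_q1_q3": _quartiles(
                [s.first_week_max_dose for s in summaries]),
        }
    out["treatment_dose"] = tblock
    return out


# ---------------------------------------------------------------------------
# recovery scoring against an injected-error ledger

def score_recovery(rebuilt: HarmonizedDatabase, ledger: pd.DataFrame) -> dict:
    """Per-rule recovery rates: fraction of ledgered corruptions that were
    repaired back to the ledgered truth by the pipeline."""
    out: dict = {}
    if not len(ledger):
        return out
    uds_keys = set(zip(rebuilt.tables["uds_temp"]["who"].astype(int),
                       rebuilt.tables["uds_temp"]["when"].astype(int)))
    uds_counts = rebuilt.tables["uds_temp"].groupby(["who", "when"]).size()
    all_drugs = rebuilt.tables["all_drugs"]
    tlfb_keys = set(zip(all_drugs["who"].astype(int),
                        all_drugs["when"].astype(int), all_drugs["what"]))
    dose = rebuilt.tables["treatment_dose"]
    dose_drug = {(int(r["who"]), int(r["when"])): r["what"]
                 for _, r in dose.iterrows()}
    repairs = [(e.rule_id, e.who, e.corrected_value) for e in rebuilt.audit_log
               if str(e.rule_id).startswith("repair.")]

    for rule, entries in ledger.groupby("rule_id"):
        hits = 0
        for _, e in entries.iterrows():
            who = int(e["who"])
            if rule in ("date_year_typo", "date_transpose", "duplicate_uds"):
                if e["table"] == "uds":
                    true_when, bad_when = int(e["true_value"]), int(e["corrupted_value"])
                    ok = (who, true_when) in uds_keys
                    if rule != "duplicate_uds":
                        ok = ok and (who, bad_when) not in uds_keys
                    hits += ok
                else:  # survey-date repair, visible only in the audit trail
                    hits += any(r[1] == who and str(r[2]) == str(e["true_value"])
                                for r in repairs)
            elif rule == "date_offby1":
                hits += any(r[1] == who and str(r[2]) == str(e["true_value"])
                            for r in repairs)
            elif rule == "eos_duplicate":
                hits += uds_counts.get((who, int(e["true_value"])), 0) == 1
            elif rule in ("drug_misspelling", "multi_drug_string"):
                tokens = str(e["true_value"]).split("|")
                hits += all((who, int(e["locator"]), tok) in tlfb_keys
                            for tok in tokens)
            elif rule == "dose_other_drug":
                hits += dose_drug.get((who, int(e["locator"]))) == e["true_value"]
            elif rule == "drink_amount_missing":
                tl = rebuilt.tables["tlfb"]
                m = tl[(tl["who"].astype(int) == who)
                       & (tl["when"].astype(int) == int(e["locator"]))
                       & (tl["what"] == "Alcohol")]
                hits += bool(len(m)) and bool((m["is_imputed"] == 1).any())
            else:
                continue
        out[rule] = {"n": int(len(entries)), "recovered": int(hits),
                     "rate": hits / len(entries)}
    return out
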