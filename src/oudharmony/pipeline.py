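"""End-to-end harmonization: raw dialect bundles -> harmonized database.

Bundles are processed in sorted project order so that ``who`` assignment
is deterministic.  Every mutation a cleaning rule makes (date repairs,
duplicate resolution, drug-label corrections, imputations) is appended to
the audit log as a :class:`~oudharmony.schema.CorrectionEntry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Optional

import pandas as pd

from . import crosswalks, dialects, temporal, uds as udsmod
from .doses import RawDoseEntry, correct_other_drug, normalize_dose_log
from .ingest import (RawBundle, drop_exact_duplicates, melt_wide_daily,
                     read_bundle, recode_categoricals, resolve_subject_ids)
from .schema import (CorrectionEntry, HarmonizedDatabase, codebook_frame,
                     register_schema, validate_database)
from .textnorm import (canonicalize_drug, default_lexicon,
                       impute_missing_drink_amount, parse_standard_drinks)

RULE_IMPUTE_DRINKS = "impute.drink_amount"


class PipelineError(RuntimeError):
    pass


def _f(v) -> Optional[float]:
    if v is None or str(v).strip() == "":
        return None
    return float(v)


def _i(v) -> Optional[int]:
    f = _f(v)
    return None if f is None else int(f)


def _yes(v) -> Optional[int]:
    return None if v is None else {"yes": 1, "no": 0}[v]


@dataclass
class _SubjectContext:
    who: int
    raw_id: str
    consent: date
    rand: Optional[date] = None
    rand2: Optional[date] = None
    arm: Optional[str] = None
    arm2: Optional[str] = None
    drug: Optional[str] = None
    induction_when: Optional[int] = None

    def when(self, d: date) -> int:
        return (d - self.consent).days

    @property
    def window(self):
        lo = self.consent - timedelta(days=temporal.WINDOW_BEFORE_CONSENT)
        if self.rand is not None:
            hi = self.rand + timedelta(days=7 * 24 + temporal.WINDOW_AFTER_LAST_VISIT)
        else:
            hi = self.consent + timedelta(days=temporal.WINDOW_AFTER_LAST_VISIT)
        return lo, hi


def run_pipeline(bundles, strict: bool = True) -> HarmonizedDatabase:
    """Harmonize raw bundles (mapping project -> RawBundle, or a directory
    of per-project bundle folders) into the 23+3-table database."""
    if isinstance(bundles, (str, Path)):
        root = Path(bundles)
        dirs = sorted(p for p in root.iterdir() if (p / "dialect.json").exists())
        if not dirs:
            raise PipelineError(f"no bundles found under {root}")
        bundles = {}
        for p in dirs:
            b = read_bundle(p)
            bundles[b.project] = b

    registry = register_schema()
    rows = {name: [] for name in registry}
    audit: list[CorrectionEntry] = []
    arm_drug = dict(zip(dialects.meta_arms_frame()["arm"],
                        dialects.meta_arms_frame()["drug"]))

    who_start = 1
    for project in sorted(bundles):
        bundle = bundles[project]
        if "screening" not in bundle.tables:
            raise PipelineError(f"{project}: bundle is missing its screening table")
        bundle, id_map, who_start = resolve_subject_ids(bundle, who_start)
        bundle, dup_corr = drop_exact_duplicates(bundle)
        audit.extend(dup_corr)
        bundle, recode_corr = recode_categoricals(bundle)
        audit.extend(recode_corr)
        _process_bundle(bundle, arm_drug, rows, audit)

    db = HarmonizedDatabase(registry=registry)
    for name in registry:
        schema = registry[name]
        db.tables[name] = pd.DataFrame(rows[name], columns=list(schema.variable_names))
    db.tables["meta_study_length"] = dialects.meta_study_length_frame()
    db.tables["meta_arms"] = dialects.meta_arms_frame()
    db.tables["meta_codebook"] = codebook_frame(registry)
    db.audit_log = audit

    if strict:
        report = validate_database(db)
        if report:
            lines = "; ".join(f"{v.table}:{v.rule}:{v.message}" for v in report[:10])
            raise PipelineError(f"harmonized database failed validation: {lines}")
    return db


# ---------------------------------------------------------------------------

def _process_bundle(bundle: RawBundle, arm_drug: dict, rows: dict, audit: list):
    dialect = bundle.dialect
    t = bundle.tables
    lex = default_lexicon()

    # subject contexts
    contexts: dict[int, _SubjectContext] = {}
    for _, r in t["screening"].iterrows():
        ctx = _SubjectContext(int(r["who"]), r["raw_id"],
                              dialect.parse_date(r["consent_date"]))
        contexts[ctx.who] = ctx
    if "randomization" in t and len(t["randomization"]):
        for _, r in t["randomization"].iterrows():
            ctx = contexts[int(r["who"])]
            d = dialect.parse_date(r["date"])
            if r.get("phase") == "2":
                ctx.rand2, ctx.arm2 = d, r["arm"]
            else:
                ctx.rand, ctx.arm = d, r["arm"]
                ctx.drug = arm_drug.get(r["arm"])

    _do_screening(bundle, contexts, rows)
    _do_flat_tables(bundle, contexts, rows)
    _do_doses(bundle, contexts, rows, audit)
    _do_randomization_visits(bundle, contexts, rows)
    _do_withdrawal(bundle, contexts, rows)
    _do_tlfb(bundle, contexts, rows, audit, lex)
    _do_uds(bundle, contexts, rows, audit, lex)


def _do_screening(bundle, contexts, rows):
    dialect = bundle.dialect
    t = bundle.tables
    asi = {int(r["who"]): r for _, r in t["asi"].iterrows()} if "asi" in t else {}
    for _, r in t["screening"].iterrows():
        who = int(r["who"])
        ctx = contexts[who]
        rows["enrollment"].append({"who": who, "project": bundle.project,
                                   "raw_id": r["raw_id"]})
        a = asi.get(who)
        edu_years = _f(a["education_years"]) if a is not None else None
        direct = _f(r["education"]) if "education" in r.index else None
        demo = crosswalks.harmonize_demographics(
            dialect.parse_date(r["dob"]), ctx.consent,
            r["sex"] if r["sex"] in ("male", "female") else None,
            r["hispanic"], r["race"], edu_years, direct,
            r["marital"] or "Missing",
            a["living"] if a is not None else None,
            (a["employment"] or "Missing") if a is not None else "Missing")
        rows["demographics"].append({
            "who": who, "age": demo.age, "is_male": demo.is_male,
            "is_hispanic": demo.is_hispanic, "race": demo.race,
            "education": demo.education, "marital": demo.marital,
            "is_living_stable": demo.is_living_stable, "job": demo.job})
        if a is not None:
            parole_col = "ALPROBAT" if "ALPROBAT" in a.index else "L2"
            rows["asi_employment"].append({
                "who": who, "education_years": edu_years,
                "usual_employment": a["employment"]})
            rows["asi_legal"].append({"who": who,
                                      "is_on_parole": _yes(a[parole_col])})
            rows["asi_psychiatric"].append({
                "who": who, "has_depression": _yes(a["dep"]),
                "has_anxiety": _yes(a["anx"]),
                "has_hallucinations": _yes(a["hall"])})


def _do_flat_tables(bundle, contexts, rows):
    dialect = bundle.dialect
    t = bundle.tables

    if "medical" in t:
        for _, r in t["medical"].iterrows():
            who = int(r["who"])
            rows["medical_history"].append({
                "who": who, "has_schizophrenia": _yes(r["schiz"]),
                "has_major_depression": _yes(r["depress"]),
                "has_bipolar": _yes(r["bipolar"]),
                "has_anxiety": _yes(r["anxiety"]),
                "has_epilepsy": _yes(r["epilepsy"]),
                "has_neuro_damage": _yes(r["neuro"])})
            rows["psychiatric_diagnoses"].append({
                "who": who, "has_schizophrenia": _yes(r["ck_schiz"]),
                "has_major_depression": _yes(r["ck_depress"]),
                "has_bipolar": _yes(r["ck_bipolar"]),
                "has_anxiety": _yes(r["ck_anx"])})
            for sub in ("alcohol", "amphetamine", "cannabis", "cocaine",
                        "sedatives", "opioid"):
                if f"{sub}_dx" in r.index:
                    flag = crosswalks.sud_flag(None, None, _yes(r[f"{sub}_dx"]))
                else:
                    flag = crosswalks.sud_flag(_yes(r[f"{sub}_abuse"]),
                                               _yes(r[f"{sub}_dep"]), None)
                rows["sud_diagnoses"].append({"who": who, "substance": sub,
                                              "sud_diagnosis": flag})

    if "pain" in t:
        for _, r in t["pain"].iterrows():
            resp = r["response"]
            rows["pain"].append({
                "who": int(r["who"]),
                "pain": (crosswalks.pain_category(dialect.pain_instrument, resp)
                         if resp is not None else "Missing")})

    if "nicotine" in t:
        for _, r in t["nicotine"].iterrows():
            smoker = _yes(r["smoker"])
            ftnd = None
            if smoker:
                items = [_i(r[f"q{j}"]) for j in range(1, 7)]
                ftnd = crosswalks.score_ftnd(items, True)
            rows["nicotine"].append({"who": int(r["who"]),
                                     "is_smoker": smoker, "ftnd": ftnd})

    if "rbs" in t:
        for _, r in t["rbs"].iterrows():
            who = int(r["who"])
            for sub in ("cocaine", "heroin", "speedball", "opioid", "amphetamine"):
                if f"{sub}_freq" in r.index:
                    days = crosswalks.rab_days(r[f"{sub}_freq"])
                else:
                    days = _i(r[f"{sub}_days"])
                rows["rbs_drug"].append({"who": who, "substance": sub,
                                         "days_use": days})
            iv_days = {sub: _i(r.get(f"{sub}_iv_days"))
                       for sub in ("heroin", "cocaine")
                       if _i(r.get(f"{sub}_iv_days"))}
            iv_events = {sub: _i(r.get(f"{sub}_iv_events"))
                         for sub in ("heroin", "cocaine")
                         if _i(r.get(f"{sub}_iv_events"))}
            iv = crosswalks.derive_iv_summaries(iv_days, iv_events)
            rows["rbs_iv"].append({"who": who, **iv,
                                   "is_needle_sharing": _yes(r["needle"])})
            rows["rbs_sex"].append({"who": who, "n_partners": _i(r["partners"]),
                                    "is_unprotected_sex": _yes(r["unprotected"])})


def _do_randomization_visits(bundle, contexts, rows):
    dialect = bundle.dialect
    t = bundle.tables
    for ctx in contexts.values():
        if ctx.rand is None:
            continue
        rows["randomization"].append({"who": ctx.who, "when": ctx.when(ctx.rand),
                                      "which": 1, "treatment": ctx.arm})
        # single-randomization designs store the same event twice so that
        # every randomized subject has exactly two records
        rand2 = ctx.rand2 if ctx.rand2 is not None else ctx.rand
        arm2 = ctx.arm2 if ctx.arm2 is not None else ctx.arm
        rows["randomization"].append({"who": ctx.who, "when": ctx.when(rand2),
                                      "which": 2, "treatment": arm2})
    if "visits" in t and len(t["visits"]):
        for _, r in t["visits"].iterrows():
            ctx = contexts[int(r["who"])]
            rows["visits"].append({"who": ctx.who,
                                   "when": ctx.when(dialect.parse_date(r["date"])),
                                   "visit_week": _i(r["week"])})
    if "missed_visits" in t and len(t["missed_visits"]):
        for _, r in t["missed_visits"].iterrows():
            ctx = contexts[int(r["who"])]
            rows["missed_visits"].append({
                "who": ctx.who, "when": ctx.when(dialect.parse_date(r["date"])),
                "reason": r["reason"] or "Unknown"})


def _do_withdrawal(bundle, contexts, rows):
    dialect = bundle.dialect
    t = bundle.tables
    if "withdrawal" not in t or not len(t["withdrawal"]):
        return
    series: dict[int, list] = {}
    for _, r in t["withdrawal"].iterrows():
        ctx = contexts[int(r["who"])]
        when = ctx.when(dialect.parse_date(r["date"]))
        score = _i(r["score"])
        sev = crosswalks.withdrawal_severity(dialect.withdrawal_instrument, score)
        rows["withdrawal"].append({"who": ctx.who, "when": when,
                                   "instrument": dialect.withdrawal_instrument,
                                   "score": score, "severity": sev})
        series.setdefault(ctx.who, []).append((when, sev))
    for who, measures in series.items():
        ctx = contexts[who]
        induction = ctx.induction_when
        if induction is None:
            induction = ctx.when(ctx.rand) if ctx.rand else 0
        pre, post = crosswalks.select_pre_post(measures, induction)
        rows["withdrawal_pre_post"].append({
            "who": who,
            "when_pre": pre[0] if pre else None,
            "severity_pre": pre[1] if pre else None,
            "when_post": post[0] if post else None,
            "severity_post": post[1] if post else None})


def _do_doses(bundle, contexts, rows, audit):
    dialect = bundle.dialect
    t = bundle.tables
    dose_by_who: dict[int, list] = {}
    if "dose" not in t or not len(t["dose"]):
        return dose_by_who
    entries: dict[int, list] = {}
    for _, r in t["dose"].iterrows():
        ctx = contexts[int(r["who"])]
        start = ctx.when(dialect.parse_date(r["date"]))
        end = r["end_date"]
        span = 1
        if end:
            span = ctx.when(dialect.parse_date(end)) - start + 1
        entries.setdefault(ctx.who, []).append(
            RawDoseEntry(ctx.who, start, r["drug"], float(r["dose"]), span))
    for who in sorted(entries):
        ctx = contexts[who]
        records, corr = normalize_dose_log(entries[who])
        audit.extend(corr)
        if ctx.drug in ("methadone", "buprenorphine"):
            records, corr = correct_other_drug(records, ctx.drug)
            audit.extend(corr)
        records = sorted(records, key=lambda x: (x.when, x.drug))
        dose_by_who[who] = records
        ctx.induction_when = min((x.when for x in records if x.dose > 0),
                                 default=None)
        for rec in records:
            rows["treatment_dose"].append({"who": who, "when": rec.when,
                                           "what": rec.drug, "dose": rec.dose,
                                           "was_corrected": rec.was_corrected})
    return dose_by_who


# ---------------------------------------------------------------------------
# timeline follow-back

def _do_tlfb(bundle, contexts, rows, audit, lex):
    dialect = bundle.dialect
    t = bundle.tables
    if "tlfb" not in t or not len(t["tlfb"]):
        return
    # per-subject accumulators: day -> tokens / categories / alcohol amount
    day_cats: dict[int, dict] = {}
    day_tokens: dict[int, dict] = {}
    alcohol: dict[int, dict] = {}

    def add(who, when, token, amount=None, has_amount=False):
        cat = lex.categories[token]
        day_cats.setdefault(who, {}).setdefault(when, [])
        if cat not in day_cats[who][when]:
            day_cats[who][when].append(cat)
        day_tokens.setdefault(who, {}).setdefault(when, set()).add(token)
        if token == "alcohol" and has_amount:
            alcohol.setdefault(who, {})[when] = amount

    if dialect.layouts.get("tlfb") == "long":
        _tlfb_long(bundle, contexts, audit, add)
    else:
        _tlfb_wide(bundle, contexts, add)

    if "tlfb_other" in t and len(t["tlfb_other"]):
        for _, r in t["tlfb_other"].iterrows():
            ctx = contexts[int(r["who"])]
            when = ctx.when(dialect.parse_date(r["date"]))
            for token in canonicalize_drug(r["text"], lex):
                add(ctx.who, when, token)

    # drink-amount imputation from the subject's usual pattern
    for who, days in alcohol.items():
        missing = [w for w, v in days.items() if v is None]
        if not missing:
            continue
        known = [v for v in days.values() if v is not None]
        for w in missing:
            imp = impute_missing_drink_amount(known)
            if imp.imputed:
                days[w] = imp.value
                audit.append(CorrectionEntry(
                    who, "tlfb", "amount", None, imp.value, RULE_IMPUTE_DRINKS,
                    "missing drink amount imputed from consistent pattern"))
            alcohol[who][w] = (imp.value, 1) if imp.imputed else (None, None)

    for who in sorted(day_cats):
        for when in sorted(day_cats[who]):
            for cat in day_cats[who][when]:
                amount = imputed = None
                if cat == "Alcohol":
                    v = alcohol.get(who, {}).get(when)
                    if isinstance(v, tuple):
                        amount, imputed = v
                    elif v is not None:
                        amount, imputed = v, 0
                rows["tlfb"].append({"who": who, "when": when, "what": cat,
                                     "amount": amount, "is_imputed": imputed})
            for token in sorted(day_tokens[who][when]):
                rows["all_drugs"].append({"who": who, "when": when,
                                          "what": token, "source": "TLFB"})


def _tlfb_long(bundle, contexts, audit, add):
    dialect = bundle.dialect
    df = bundle.tables["tlfb"]
    for (who, survey_str, period_str), group in df.groupby(
            ["who", "survey_date", "period_end"], sort=False):
        ctx = contexts[int(who)]
        survey = dialect.parse_date(survey_str)
        period_end = dialect.parse_date(period_str)
        repair = temporal.repair_date(survey, ctx.window, anchor=period_end)
        if repair.changed:
            audit.append(CorrectionEntry(
                ctx.who, "tlfb", "survey_date", repair.original, repair.date,
                repair.rule, "survey date aligned with last day of recall period"))
        for _, r in group.iterrows():
            when = ctx.when(dialect.parse_date(r["entry_date"]))
            item, value = r["item"], r["value"]
            if item == "ALCOHOL":
                drinks = parse_standard_drinks(value)
                add(ctx.who, when, "alcohol", drinks.value, has_amount=True)
            elif item == "OTHER":
                for token in canonicalize_drug(value):
                    add(ctx.who, when, token)
            else:
                add(ctx.who, when, dialect.tlfb_columns[item])


def _tlfb_wide(bundle, contexts, add):
    dialect = bundle.dialect
    df = bundle.tables["tlfb"]
    id_cols = {"who", "raw_id", "survey_date"}
    for _, r in df.iterrows():
        ctx = contexts[int(r["who"])]
        survey = dialect.parse_date(r["survey_date"])
        start_when = ctx.when(survey) - 6
        cells = {c: r[c] for c in df.columns if c not in id_cols}
        for when, stem in melt_wide_daily(cells, start_when):
            token = dialect.tlfb_columns[stem]
            if token == "alcohol" and dialect.alcohol_mode == "count":
                k = when - start_when + 1
                add(ctx.who, when, token, float(r[f"{stem}_d{k}"]), has_amount=True)
            else:
                add(ctx.who, when, token)


# ---------------------------------------------------------------------------
# urine drug screens

def _do_uds(bundle, contexts, rows, audit, lex):
    dialect = bundle.dialect
    t = bundle.tables
    if "uds" not in t or not len(t["uds"]):
        return
    df = t["uds"]
    panels_by_who: dict[int, list] = {}
    for (who, date_str, ts_str, week), group in df.groupby(
            ["who", "date", "timestamp", "week"], sort=False):
        ctx = contexts[int(who)]
        ts = (datetime.strptime(ts_str[:10], "%Y-%m-%d").date()
              if ts_str else None)
        week_label = int(week) if str(week).isdigit() else None
        panel = udsmod.PanelRow(
            who=ctx.who, date=dialect.parse_date(date_str),
            results=[(r["substance"], r["result"]) for _, r in group.iterrows()],
            entry_timestamp=ts,
            visit_week=week_label if week_label and week_label >= 1 else None)
        panel.temp = group.iloc[0]["temp"]
        panels_by_who.setdefault(ctx.who, []).append(panel)

    for who in sorted(panels_by_who):
        ctx = contexts[who]
        window = ctx.window
        week_origin = ctx.rand
        panels = panels_by_who[who]
        by_date: dict[date, list] = {}
        for p in panels:
            by_date.setdefault(p.date, []).append(p)
        resolved: list = []
        for d in sorted(by_date):
            kept, corr = udsmod.resolve_duplicates(by_date[d], window, week_origin)
            audit.extend(corr)
            resolved.extend(kept)
        for p in resolved:
            if (p.entry_timestamp is not None and p.entry_timestamp != p.date
                    and window[0] <= p.entry_timestamp <= window[1]):
                audit.append(CorrectionEntry(
                    who, "uds", "date", p.date, p.entry_timestamp,
                    udsmod.RULE_TIMESTAMP, "date aligned with entry timestamp"))
                p.date = p.entry_timestamp
            elif p.visit_week is not None and week_origin is not None:
                repair = temporal.repair_date(p.date, window,
                                              expected_week=p.visit_week,
                                              week_origin=week_origin)
                if repair.changed:
                    audit.append(CorrectionEntry(
                        who, "uds", "date", repair.original, repair.date,
                        repair.rule, "date repaired against study-week context"))
                    p.date = repair.date
                elif repair.rule is not None:
                    audit.append(CorrectionEntry(
                        who, "uds", "date", p.date, p.date, repair.rule,
                        "date inconsistent with study-week context"))
            _emit_panel(ctx, p, dialect, lex, rows)


def _emit_panel(ctx, panel, dialect, lex, rows):
    when = ctx.when(panel.date)
    opiate_results = [res for sub, res in panel.results if sub == "opiates"]
    tokens = sorted({sub for sub, res in panel.results
                     if sub != "opiates" and udsmod.binarize_result(res)})
    if opiate_results:
        merged = udsmod.merge_opiate_thresholds(
            dict(zip(dialect.opiate_thresholds, opiate_results)))
        if merged:
            tokens.append("opiates")
    for token in sorted(tokens):
        rows["all_drugs"].append({"who": ctx.who, "when": when,
                                  "what": token, "source": "UDS"})
    cats = sorted({lex.categories[tok] for tok in tokens})
    kept, _excluded = udsmod.exclude_treatment_drug(
        [(when, c) for c in cats], ctx.drug)
    for _, cat in kept:
        rows["uds"].append({"who": ctx.who, "when": when, "what": cat})
    rows["uds_temp"].append({"who": ctx.who, "when": when,
                             "in_range": panel.temp if panel.temp else "Missing"})
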