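"""Synthetic three-dialect trial bundles with ledgered error injection.

The generator emulates three study formats (methadone-vs-buprenorphine
outpatient, two-phase prescription-opioid buprenorphine, and inpatient
XR-NTX-vs-buprenorphine) at a structural level: wide or long daily
drug-use grids, dialect-specific urine panels and categorical codings,
COWS or SOWS withdrawal scores, weekly/daily/injection dose logs,
two-phase re-randomization, and screened-but-never-randomized subjects.

It emits raw bundles plus the harmonized database a perfect pipeline
should produce, and can corrupt the bundles with the documented error
taxonomy (date typos, duplicate urine panels, drug misspellings,
mislabeled doses, missing drink amounts), recording every corruption in a
ground-truth ledger so recovery can be scored.  Everything is fully
determined by the seed.

The generator targets structural fidelity, not epidemiological fidelity:
marginal distributions are plausible but are configuration, not claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from . import crosswalks, dialects
from .ingest import DialectSpec, RawBundle
from .schema import HarmonizedDatabase, register_schema, codebook_frame
from .textnorm import collapse_daily, default_lexicon

PROJECT_ORDER = ("CTN-0027", "CTN-0030", "CTN-0051")

DEFAULT_ERROR_RATES = {
    "date_year_typo": 0.03,
    "date_offby1": 0.05,
    "date_transpose": 0.02,
    "duplicate_uds": 0.02,
    "eos_duplicate": 0.10,
    "drug_misspelling": 0.30,
    "multi_drug_string": 0.15,
    "dose_other_drug": 0.10,
    "drink_amount_missing": 0.05,
}


@dataclass
class GeneratorConfig:
    n_subjects: int = 50                 # per project
    follow_up_weeks: int = 24
    seed: int = 0
    error_rates: dict = dc_field(default_factory=lambda: dict(DEFAULT_ERROR_RATES))
    screened_only_frac: float = 0.2
    rerandomized_frac: float = 0.35      # two-phase dialect only
    visit_attendance: float = 0.85
    completer_frac: float = 0.6

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for rule, p in self.error_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"error rate {rule} = {p} outside [0, 1]")


# ---------------------------------------------------------------------------
# latent subject state (concept space: harmonized values, integer 'when')

_RACES = ("White", "Black or African American", "Asian",
          "Native Hawaiian or Pacific Islander",
          "American Indian or Alaska Native", "Other",
          "Participant Chooses Not to Answer")
_RACE_P = (0.62, 0.14, 0.03, 0.01, 0.02, 0.17, 0.01)

#: weekly probability a drug-category latent state is active, by project;
#: keys are the dialect's structured TLFB column stems
_USE_PROFILES = {
    "CTN-0027": {"OPIATES": 0.85, "OXYCODONE": 0.30, "COCAINE": 0.40,
                 "METHAMPHETAMINE": 0.10, "AMPHETAMINE": 0.05,
                 "BENZODIAZEPINE": 0.20, "THC": 0.30, "PROPOXYPHENE": 0.02},
    "CTN-0030": {"oxycodone": 0.80, "hydrocodone": 0.50, "heroin_opium": 0.10,
                 "morphine": 0.10, "codeine": 0.05, "hydromorphone": 0.05,
                 "other_opiates": 0.10, "methadone": 0.20, "sedatives": 0.05,
                 "benzodiazepine": 0.25, "thc": 0.30, "cocaine": 0.15,
                 "amphetamine": 0.05, "methamphetamine": 0.03, "propoxyphene": 0.02},
    "CTN-0051": {"heroin": 0.80, "crack": 0.30, "cocaine": 0.25,
                 "opioid_analgesics": 0.30, "ecstasy": 0.05, "barbiturates": 0.03,
                 "benzodiazepine": 0.20, "thc": 0.30, "amphetamine": 0.10,
                 "methadone": 0.10, "inhalants": 0.01, "buprenorphine": 0.10},
}
_OPIOID_STEMS = {"OPIATES", "OXYCODONE", "oxycodone", "hydrocodone", "heroin_opium",
                 "morphine", "codeine", "hydromorphone", "other_opiates",
                 "heroin", "opioid_analgesics"}
_DAILY_P = {"default": 0.5, "OPIATES": 0.85, "heroin": 0.8, "oxycodone": 0.8,
            "hydrocodone": 0.6}

#: urine-panel positive probabilities while using / not using
_UDS_POS = {"AMP": 0.05, "BZO": 0.18, "MTD": 0.05, "OXY": 0.10, "COC": 0.25,
            "MAMP": 0.05, "OPI300": 0.45, "OPI2000": 0.30, "THC": 0.25,
            "PPX": 0.01, "BUP": 0.05, "BAR": 0.03, "MDMA": 0.005}

#: free-text "other drug" pools (canonical spellings the lexicon covers)
_OTHER_POOLS = {
    "CTN-0027": ("ecstasy", "vicodin", "percocet", "adderall", "tramadol",
                 "morphine", "fentanyl", "xanax", "mushrooms"),
    "CTN-0051": ("kratom", "spice", "percocet", "adderall", "mushrooms",
                 "whippits", "fentanyl"),
}

#: alcohol free-text templates: (string, standard-drinks value)
_LIGHT_TEMPLATES = (
    ("1/2 12oz beer", 0.5), ("1/2 beer", 0.5), ("1/2 of a beer", 0.5),
    ("1 beer", 1.0), ("2 beers", 2.0), ("3 beers", 3.0),
    ("1 glass of wine", 1.0), ("2 glasses of wine", 2.0),
    ("1 1/2 glasses of wine", 1.5), ("2 shots of vodka", 2.0),
    ("a beer", 1.0), ("1 shot of whiskey", 1.0),
)
_HEAVY_TEMPLATES = (
    ("5 beers", 5.0), ("6 beers", 6.0), ("8 beers", 8.0),
    ("6pk beer", 6.0), ("12 beers", 12.0),
    ("6pk beer & 2 shots of whiskey", 8.0),
    ("many glasses of wine", 5.0),
    ("6pk beer & 1/2 gal. rum", 49.0),
)


@dataclass
class _Subject:
    who: int
    project: str
    raw_id: str
    consent: date
    screened_only: bool
    # design
    arm: Optional[str] = None
    drug: Optional[str] = None           # methadone | buprenorphine | xr_ntx
    r_when: Optional[int] = None
    r2_when: Optional[int] = None
    arm2: Optional[str] = None
    induction_when: Optional[int] = None
    dropout_week: Optional[int] = None
    # demographics / surveys (harmonized concept values)
    dob: Optional[date] = None
    sex: str = "male"
    hispanic: str = "no"
    race_raw: str = "White"
    marital: Optional[str] = None
    direct_edu: Optional[int] = None
    edu_years: Optional[int] = None
    employment: str = "Full Time"
    parole: str = "no"
    asi_dep: str = "no"
    asi_anx: str = "no"
    asi_hall: str = "no"
    living: str = "stable"
    medical: dict = dc_field(default_factory=dict)
    checklist: dict = dc_field(default_factory=dict)
    sud: dict = dc_field(default_factory=dict)      # substance -> dict of raw flags
    pain_resp: Optional[str] = None
    smoker: bool = True
    ftnd_items: Optional[list] = None
    rbs_days: dict = dc_field(default_factory=dict)
    iv_days: dict = dc_field(default_factory=dict)
    iv_events: dict = dc_field(default_factory=dict)
    needle: str = "no"
    partners: int = 0
    unprotected: str = "no"
    # longitudinal
    tlfb: list = dc_field(default_factory=list)       # (when, stem, value)
    other_drugs: list = dc_field(default_factory=list)  # (when, text, token)
    uds_panels: list = dc_field(default_factory=list)
    withdrawal: list = dc_field(default_factory=list)  # (when, score)
    doses: list = dc_field(default_factory=list)       # (when, end_when|None, drug, dose)
    visits: list = dc_field(default_factory=list)      # (when, week)
    missed: list = dc_field(default_factory=list)      # (when, week, reason_text)


@dataclass
class _Panel:
    when: int
    week: str                      # "0", "1".."24"
    has_ts: bool
    results: list                  # [(raw_code, concept_result)]
    temp: Optional[str]            # Yes | No | None(missing)


def _pick(rng, seq):
    return seq[int(rng.integers(len(seq)))]


def _simulate_subject(rng: np.random.Generator, who: int, project: str,
                      raw_id: str, cfg: GeneratorConfig) -> _Subject:
    consent = date(2008, 1, 1) + timedelta(int(rng.integers(0, 720)))
    s = _Subject(who, project, raw_id, consent,
                 screened_only=bool(rng.random() < cfg.screened_only_frac))

    # demographics
    age = int(rng.integers(18, 60))
    s.dob = consent - timedelta(days=age * 365 + int(rng.integers(0, 365)))
    s.sex = "male" if rng.random() < 0.67 else "female"
    s.hispanic = "yes" if rng.random() < 0.14 else "no"
    s.race_raw = str(rng.choice(_RACES, p=_RACE_P))
    s.marital = _pick(rng, ("Married or Partnered", "Separated/Divorced/Widowed",
                            "Single", "Single", "Single"))
    s.edu_years = int(rng.integers(8, 17)) if rng.random() > 0.08 else None
    if project == "CTN-0051":
        s.direct_edu = 13 if (s.edu_years or 12) >= 12 else 10
    s.employment = str(rng.choice(["Full Time", "Part Time", "Student",
                                   "Unemployed", "Other"],
                                  p=[0.5, 0.2, 0.03, 0.24, 0.03]))
    s.parole = "yes" if rng.random() < 0.15 else "no"
    s.asi_dep = "yes" if rng.random() < 0.35 else "no"
    s.asi_anx = "yes" if rng.random() < 0.40 else "no"
    s.asi_hall = "yes" if rng.random() < 0.05 else "no"
    s.living = "stable" if rng.random() < 0.95 else "unstable"
    for key, p in (("schiz", 0.02), ("depress", 0.30), ("bipolar", 0.11),
                   ("anxiety", 0.34), ("epilepsy", 0.045), ("neuro", 0.12)):
        s.medical[key] = int(rng.random() < p)
    for key, p in (("ck_schiz", 0.02), ("ck_depress", 0.28),
                   ("ck_bipolar", 0.09), ("ck_anx", 0.30)):
        s.checklist[key] = int(rng.random() < p)
    for sub, p in (("alcohol", 0.2), ("amphetamine", 0.1), ("cannabis", 0.2),
                   ("cocaine", 0.28), ("sedatives", 0.15), ("opioid", 0.95)):
        if project == "CTN-0051":
            s.sud[sub] = {"dx": int(rng.random() < p)}
        else:
            dep = int(rng.random() < p)
            s.sud[sub] = {"abuse": int(rng.random() < p * 0.4), "dep": dep}
    if project == "CTN-0051":
        s.pain_resp = _pick(rng, ("I have no pain or discomfort",) * 4
                            + ("I have moderate pain or discomfort",) * 5
                            + ("I have extreme pain or discomfort",))
    else:
        s.pain_resp = _pick(rng, ("None", "Very Mild", "Mild", "Moderate",
                                  "Moderate", "Severe", "Very Severe"))
    s.smoker = rng.random() < 0.85
    if s.smoker:
        s.ftnd_items = [int(rng.integers(0, hi + 1)) for hi in crosswalks.FTND_ITEM_MAX]

    # risky behaviors
    for sub, p_any, hi in (("cocaine", 0.4, 20), ("heroin", 0.7, 30),
                           ("speedball", 0.12, 15), ("opioid", 0.5, 30),
                           ("amphetamine", 0.2, 15)):
        if project == "CTN-0051":
            cat = _pick(rng, ("not at all",) * 3 + ("a few times", "a few times each week",
                                                    "every day")) if rng.random() < p_any else "not at all"
            s.rbs_days[sub] = cat  # category; days derived via the crosswalk
        else:
            s.rbs_days[sub] = int(rng.integers(1, hi + 1)) if rng.random() < p_any else 0
    if rng.random() < 0.55 and project != "CTN-0030":
        for sub in ("heroin", "cocaine"):
            if rng.random() < 0.8:
                s.iv_days[sub] = int(rng.integers(1, 31))
                s.iv_events[sub] = int(rng.integers(1, 4))
    s.needle = "yes" if (s.iv_days and rng.random() < 0.2) else "no"
    s.partners = int(rng.integers(0, 5))
    s.unprotected = "yes" if rng.random() < 0.4 else "no"

    # design events
    if not s.screened_only:
        s.r_when = int(rng.integers(3, 11))
        if project == "CTN-0027":
            s.arm = _pick(rng, ("Methadone", "Outpatient BUP"))
            s.drug = "methadone" if s.arm == "Methadone" else "buprenorphine"
        elif project == "CTN-0030":
            s.arm = _pick(rng, ("Outpatient BUP + Standard Medical Management",
                                "Outpatient BUP + Enhanced Medical Management"))
            s.drug = "buprenorphine"
            if rng.random() < cfg.rerandomized_frac:
                s.r2_when = s.r_when + 84 + int(rng.integers(0, 6))
                s.arm2 = _pick(rng, ("Outpatient BUP + Standard Medical Management",
                                     "Outpatient BUP + Enhanced Medical Management"))
        else:
            s.arm = _pick(rng, ("Inpatient XR-NTX", "Inpatient BUP"))
            s.drug = "xr_ntx" if s.arm == "Inpatient XR-NTX" else "buprenorphine"
        s.induction_when = s.r_when + int(rng.integers(0, 3))
        s.dropout_week = (cfg.follow_up_weeks if rng.random() < cfg.completer_frac
                          else int(rng.integers(2, cfg.follow_up_weeks)))

    _simulate_drug_use(rng, s, cfg)
    if not s.screened_only:
        _simulate_visits_uds(rng, s, cfg)
        _simulate_withdrawal(rng, s)
        _simulate_doses(rng, s, cfg)
    return s


def _alcohol_value(rng, heavy: bool):
    template, value = _pick(rng, _HEAVY_TEMPLATES if heavy else _LIGHT_TEMPLATES)
    return template, value


def _simulate_drug_use(rng: np.random.Generator, s: _Subject, cfg: GeneratorConfig):
    """Daily TLFB events: a 28-day baseline block plus weekly follow-up."""
    profile = _USE_PROFILES[s.project]
    drinker = rng.random() < 0.5
    heavy_drinker = drinker and rng.random() < 0.3
    other_pool = _OTHER_POOLS.get(s.project, ())
    uses_other = other_pool and rng.random() < 0.35
    other_choices = (list(rng.choice(other_pool, size=2, replace=False))
                     if uses_other else [])

    # week blocks: baseline covers when -28..-1; follow-up weeks are anchored
    # on randomization and only exist for attended visit weeks
    blocks = [(-28 + 7 * i, None) for i in range(4)]
    if not s.screened_only:
        for w in range(1, cfg.follow_up_weeks + 1):
            if w <= s.dropout_week:
                blocks.append((s.r_when + 7 * (w - 1), w))

    for start, week in blocks:
        post = week is not None
        for stem, p_week in profile.items():
            p = p_week * (0.4 if (post and stem in _OPIOID_STEMS) else 1.0)
            if rng.random() >= p:
                continue
            p_day = _DAILY_P.get(stem, _DAILY_P["default"])
            for k in range(7):
                if rng.random() < p_day:
                    s.tlfb.append((start + k, stem, "1"))
        if drinker and rng.random() < 0.8:
            for k in range(7):
                if rng.random() < 0.18:
                    text, value = _alcohol_value(rng, heavy_drinker)
                    s.tlfb.append((start + k, "__alcohol__", (text, value)))
        if other_choices and rng.random() < 0.4:
            day = start + int(rng.integers(0, 7))
            for token_text in other_choices if rng.random() < 0.3 else other_choices[:1]:
                s.other_drugs.append((day, token_text))


def _simulate_visits_uds(rng: np.random.Generator, s: _Subject, cfg: GeneratorConfig):
    dialect = dialects.builtin_dialects()[s.project]
    on_drug_weeks = _dosed_weeks(s, cfg)

    def panel(when: int, week_label: str, visit_week: Optional[int]):
        results = []
        for code in dialect.uds_substances:
            if code == "BUP" and s.project == "CTN-0030" and visit_week not in (10, 12, 22, 24):
                continue
            p = _UDS_POS[code]
            if code in ("OPI300", "OPI2000"):
                p = 0.75 if visit_week is None else 0.35
            if code == "MTD" and s.drug == "methadone" and visit_week in on_drug_weeks:
                p = 0.98
            if code == "BUP" and s.drug == "buprenorphine" and visit_week in on_drug_weeks:
                p = 0.95
            positive = rng.random() < p
            concept = "positive" if positive else "negative"
            if not positive and rng.random() < 0.002:
                concept = ("invalid" if s.project == "CTN-0051"
                           else _pick(rng, ("unclear", "not_assessed")))
            results.append((code, concept))
        # a positive at the 2000 ng/mL opiate threshold implies 300 ng/mL
        if ("OPI2000", "positive") in results:
            results = [(c, "positive" if c == "OPI300" else r) for c, r in results]
        if s.project != "CTN-0051" and rng.random() < 0.01:
            temp = None
        else:
            temp = "No" if rng.random() < 0.002 else "Yes"
        s.uds_panels.append(_Panel(when, week_label, bool(rng.random() < 0.3),
                                   results, temp))

    panel(s.r_when - 2, "0", None)  # baseline sample before randomization
    for w in range(1, cfg.follow_up_weeks + 1):
        if w > s.dropout_week:
            break
        scheduled = s.r_when + 7 * (w - 1)
        if rng.random() < cfg.visit_attendance:
            when = scheduled + int(rng.integers(0, 7))
            s.visits.append((when, w))
            panel(when, str(w), w)
        else:
            reason = _pick(rng, ("jail", "prison", "incarcerated", "sick",
                                 "hospitalized", "out of town", "vacation",
                                 "no show", "unknown"))
            s.missed.append((scheduled, w, reason))


def _simulate_withdrawal(rng: np.random.Generator, s: _Subject):
    hi_pre, hi_post = (40, 15) if s.project == "CTN-0051" else (35, 12)
    s.withdrawal.append((s.r_when - 1, int(rng.integers(1, hi_pre + 1))))
    s.withdrawal.append((s.induction_when + 1, int(rng.integers(0, hi_post + 1))))
    if rng.random() < 0.7:
        s.withdrawal.append((s.r_when + 21 + int(rng.integers(0, 4)),
                             int(rng.integers(0, hi_post + 1))))


def _dosed_weeks(s: _Subject, cfg: GeneratorConfig) -> set:
    if s.project == "CTN-0030":
        weeks = set(range(1, min(4, s.dropout_week) + 1))
        if s.r2_when is not None:
            w2 = (s.r2_when - s.r_when) // 7 + 1
            weeks |= set(range(w2, min(w2 + 16, cfg.follow_up_weeks) + 1))
        return weeks
    return set(range(1, s.dropout_week + 1))


def _simulate_doses(rng: np.random.Generator, s: _Subject, cfg: GeneratorConfig):
    if s.drug == "xr_ntx":
        n_inj = max(1, min(6, s.dropout_week * 7 // 28 + 1))
        for k in range(n_inj):
            s.doses.append((s.induction_when + 28 * k, None, "xr_ntx", 1.0))
        return
    weekly_logger = s.project == "CTN-0027" and rng.random() < 0.4
    if s.project == "CTN-0030":
        spans = [(s.r_when, min(s.r_when + 27, s.r_when + 7 * s.dropout_week - 1))]
        if s.r2_when is not None:
            spans.append((s.r2_when, s.r2_when + 16 * 7 - 1))
    else:
        spans = [(s.induction_when, s.r_when + 7 * s.dropout_week - 1)]
    base = float(rng.integers(6, 13)) if s.drug == "buprenorphine" else float(rng.integers(30, 61))
    top = (base + float(rng.integers(4, 13)) if s.drug == "buprenorphine"
           else base + float(rng.integers(20, 51)))
    for start, end in spans:
        day = start
        while day <= end:
            dose = base if day - start < 7 else top
            if weekly_logger and day - start >= 14 and day + 6 <= end:
                s.doses.append((day, day + 6, s.drug, dose))
                day += 7
                continue
            if rng.random() < 0.05:  # skipped day
                day += 1
                continue
            if day - start < 3 and rng.random() < 0.3 and dose > 4:
                # split same-day logs: in-clinic plus take-home/add-on
                # (unequal parts: identical rows would be indistinguishable
                # from accidental duplicates)
                part = float(int(dose // 2))
                if part * 2 == dose:
                    part -= 1
                s.doses.append((day, None, s.drug, part))
                s.doses.append((day, None, s.drug, dose - part))
            else:
                s.doses.append((day, None, s.drug, dose))
            day += 1


# ---------------------------------------------------------------------------
# generation entry points

def _make_subjects(cfg: GeneratorConfig) -> list:
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    who = 1
    for project in PROJECT_ORDER:
        for i in range(cfg.n_subjects):
            raw_id = {"CTN-0027": f"27-{i + 1:04d}",
                      "CTN-0030": f"P{i + 1:04d}",
                      "CTN-0051": f"{5101 + i}"}[project]
            subjects.append(_simulate_subject(rng, who, project, raw_id, cfg))
            who += 1
    return subjects


def generate_clean_bundle(cfg: GeneratorConfig):
    """Three raw bundles plus the ground-truth harmonized database."""
    subjects = _make_subjects(cfg)
    bundles = {p: _render_bundle([s for s in subjects if s.project == p],
                                 dialects.builtin_dialects()[p])
               for p in PROJECT_ORDER}
    truth = _build_truth(subjects, cfg)
    return bundles, truth


def generate(cfg: GeneratorConfig):
    """Convenience: clean bundles, truth, corrupted bundles and ledger."""
    bundles, truth = generate_clean_bundle(cfg)
    corrupted, ledger = inject_errors(bundles, cfg)
    return bundles, corrupted, truth, ledger


# ---------------------------------------------------------------------------
# rendering to raw dialect tables

def _inv(mapping: dict) -> dict:
    """harmonized -> raw code (first raw code in sorted order wins)."""
    out = {}
    for raw in sorted(mapping):
        out.setdefault(mapping[raw], raw)
    return out


def _render_bundle(subjects: list, dialect: DialectSpec) -> RawBundle:
    project = dialect.project
    fmt = dialect.format_date
    inv = {key: _inv(m) for key, m in dialect.recodes.items()}
    id_screen = dialect.id_aliases[0]
    id_uds = dialect.id_aliases[1] if len(dialect.id_aliases) > 1 else id_screen
    id_tlfb = dialect.id_aliases[2] if len(dialect.id_aliases) > 2 else id_screen

    def D(s, when):
        return fmt(s.consent + timedelta(int(when)))

    screening, asi, rand_rows = [], [], []
    visits_rows, missed_rows, tlfb_rows, other_rows = [], [], [], []
    uds_rows, wd_rows, nic_rows, med_rows, pain_rows, rbs_rows, dose_rows = (
        [], [], [], [], [], [], [])

    for s in subjects:
        row = {id_screen: s.raw_id, "consent_date": D(s, 0), "dob": fmt(s.dob),
               "sex": inv["screening.sex"][s.sex],
               "hispanic": inv["screening.hispanic"][s.hispanic],
               "race": s.race_raw,
               "marital": inv["screening.marital"][s.marital]}
        if project == "CTN-0051":
            row["education"] = "" if s.direct_edu is None else str(s.direct_edu)
        screening.append(row)

        arow = {id_screen: s.raw_id,
                "education_years": "" if s.edu_years is None else str(s.edu_years),
                "employment": inv["asi.employment"][s.employment],
                "dep": inv["asi.dep"][s.asi_dep],
                "anx": inv["asi.anx"][s.asi_anx],
                "hall": inv["asi.hall"][s.asi_hall],
                "living": inv["asi.living"][s.living]}
        parole_col = "ALPROBAT" if project == "CTN-0051" else "L2"
        arow[parole_col] = inv[f"asi.{parole_col}"][s.parole]
        asi.append(arow)

        mrow = {id_screen: s.raw_id}
        yes = inv["medical.schiz"]["yes"]
        no = inv["medical.schiz"]["no"]
        for key, val in {**s.medical, **s.checklist}.items():
            mrow[key] = yes if val else no
        for sub, flags in s.sud.items():
            for suf, val in flags.items():
                mrow[f"{sub}_{suf}"] = yes if val else no
        med_rows.append(mrow)

        pain_rows.append({id_screen: s.raw_id,
                          "response": inv["pain.response"][s.pain_resp]})

        nrow = {id_screen: s.raw_id,
                "smoker": inv["nicotine.smoker"]["yes" if s.smoker else "no"]}
        for j in range(6):
            nrow[f"q{j + 1}"] = str(s.ftnd_items[j]) if s.smoker else ""
        nic_rows.append(nrow)

        rrow = {id_screen: s.raw_id}
        for sub, val in s.rbs_days.items():
            if project == "CTN-0051":
                rrow[f"{sub}_freq"] = inv[f"rbs.{sub}_freq"][val]
            else:
                rrow[f"{sub}_days"] = str(val)
        for sub in ("heroin", "cocaine"):
            rrow[f"{sub}_iv_days"] = str(s.iv_days.get(sub, ""))
            rrow[f"{sub}_iv_events"] = str(s.iv_events.get(sub, ""))
        rrow["needle"] = inv["rbs.needle"][s.needle]
        rrow["partners"] = str(s.partners)
        rrow["unprotected"] = inv["rbs.unprotected"][s.unprotected]
        rbs_rows.append(rrow)

        if s.screened_only:
            pass
        else:
            rand_rows.append({id_screen: s.raw_id, "date": D(s, s.r_when),
                              "phase": "1", "arm": inv["randomization.arm"][s.arm]})
            if s.r2_when is not None:
                rand_rows.append({id_screen: s.raw_id, "date": D(s, s.r2_when),
                                  "phase": "2",
                                  "arm": inv["randomization.arm"][s.arm2]})
            for when, w in s.visits:
                visits_rows.append({id_screen: s.raw_id, "date": D(s, when),
                                    "week": str(w)})
            for when, w, reason in s.missed:
                missed_rows.append({id_screen: s.raw_id, "date": D(s, when),
                                    "reason": reason})
            for when, score in s.withdrawal:
                wd_rows.append({id_screen: s.raw_id, "date": D(s, when),
                                "score": str(score)})
            for when, end_when, drug, dose in s.doses:
                dose_rows.append({id_screen: s.raw_id, "date": D(s, when),
                                  "end_date": "" if end_when is None else D(s, end_when),
                                  "drug": inv["dose.drug"][drug],
                                  "dose": f"{dose:g}"})
            for p in s.uds_panels:
                ts = (s.consent + timedelta(p.when)).isoformat() + " 10:30" if p.has_ts else ""
                temp_code = "" if p.temp is None else inv["uds.temp"][p.temp]
                for code, concept in p.results:
                    uds_rows.append({id_uds: s.raw_id, "date": D(s, p.when),
                                     "timestamp": ts, "week": p.week,
                                     "substance": code,
                                     "result": inv["uds.result"][concept],
                                     "temp": temp_code})

        tlfb_rows.extend(_render_tlfb(s, dialect, id_tlfb, other_rows, id_screen))

    tables = {
        "screening": pd.DataFrame(screening),
        "asi": pd.DataFrame(asi),
        "medical": pd.DataFrame(med_rows),
        "pain": pd.DataFrame(pain_rows),
        "nicotine": pd.DataFrame(nic_rows),
        "rbs": pd.DataFrame(rbs_rows),
        "randomization": pd.DataFrame(rand_rows),
        "visits": pd.DataFrame(visits_rows),
        "missed_visits": pd.DataFrame(missed_rows),
        "withdrawal": pd.DataFrame(wd_rows),
        "dose": pd.DataFrame(dose_rows),
        "uds": pd.DataFrame(uds_rows),
        "tlfb": pd.DataFrame(tlfb_rows),
    }
    if other_rows:
        tables["tlfb_other"] = pd.DataFrame(other_rows)
    tables = {k: v.astype(str) if len(v) else v for k, v in tables.items()}
    return RawBundle(project, tables, dialect)


def _tlfb_block_starts(s: _Subject, cfg_weeks: int) -> list:
    starts = [(-28 + 7 * i, None) for i in range(4)]
    if not s.screened_only:
        for w in range(1, cfg_weeks + 1):
            if w <= s.dropout_week:
                starts.append((s.r_when + 7 * (w - 1), w))
    return starts


def _render_tlfb(s: _Subject, dialect: DialectSpec, id_tlfb: str,
                 other_rows: list, id_screen: str) -> list:
    fmt = dialect.format_date

    def D(when):
        return fmt(s.consent + timedelta(int(when)))

    by_day = {}
    for when, stem, value in s.tlfb:
        by_day.setdefault(when, {})[stem] = value
    rows = []
    baseline_survey_when = 2 + (s.who % 6)  # administered a few days post-consent

    if dialect.layouts.get("tlfb") == "long":
        def anchor_dates(when):
            # forms record both the administration date and the last day of
            # the recall period; post-randomization forms are filled on the
            # period's last day, baseline forms a few days after consent
            if when < 0:
                return D(baseline_survey_when), D(-1)
            week_end = s.r_when + ((when - s.r_when) // 7) * 7 + 6
            return D(week_end), D(week_end)

        for when in sorted(by_day):
            survey, period_end = anchor_dates(when)
            for stem, value in sorted(by_day[when].items()):
                text = value[0] if stem == "__alcohol__" else "1"
                item = "ALCOHOL" if stem == "__alcohol__" else stem
                rows.append({id_tlfb: s.raw_id, "survey_date": survey,
                             "period_end": period_end, "entry_date": D(when),
                             "item": item, "value": text})
        for when, text in s.other_drugs:
            survey, period_end = anchor_dates(when)
            rows.append({id_tlfb: s.raw_id, "survey_date": survey,
                         "period_end": period_end, "entry_date": D(when),
                         "item": "OTHER", "value": text})
        return rows

    # wide weekly grids: one row per 7-day block ending at survey_date
    block_starts = sorted({(-28 + 7 * i) for i in range(4)}
                          | {s.r_when + 7 * (w - 1)
                             for w in range(1, (s.dropout_week or 0) + 1)
                             if not s.screened_only})
    stems = list(dialect.tlfb_columns)
    for start in block_starts:
        block_days = {d: by_day.get(start + d, {}) for d in range(7)}
        if not any(block_days.values()):
            continue
        row = {id_tlfb: s.raw_id, "survey_date": D(start + 6)}
        for stem in stems:
            for d in range(7):
                if stem == "drinks":
                    value = block_days[d].get("__alcohol__")
                    row[f"{stem}_d{d + 1}"] = f"{value[1]:g}" if value else "0"
                elif stem == "alcohol" and dialect.alcohol_mode == "binary":
                    row[f"{stem}_d{d + 1}"] = "1" if "__alcohol__" in block_days[d] else "0"
                else:
                    row[f"{stem}_d{d + 1}"] = "1" if stem in block_days[d] else "0"
        rows.append(row)
    for when, text in s.other_drugs:
        other_rows.append({id_screen: s.raw_id, "date": D(when),
                           "slot": "1", "text": text})
    return rows


# ---------------------------------------------------------------------------
# ground truth database

def _build_truth(subjects: list, cfg: GeneratorConfig) -> HarmonizedDatabase:
    lex = default_lexicon()
    dial = dialects.builtin_dialects()
    T = {name: [] for name in register_schema()}

    for s in subjects:
        dialect = dial[s.project]
        T["enrollment"].append({"who": s.who, "project": s.project, "raw_id": s.raw_id})
        demo = crosswalks.harmonize_demographics(
            s.dob, s.consent, s.sex, s.hispanic, s.race_raw,
            s.edu_years, s.direct_edu, s.marital, s.living, s.employment)
        T["demographics"].append({"who": s.who, "age": demo.age,
                                  "is_male": demo.is_male,
                                  "is_hispanic": demo.is_hispanic,
                                  "race": demo.race, "education": demo.education,
                                  "marital": demo.marital,
                                  "is_living_stable": demo.is_living_stable,
                                  "job": demo.job})
        T["asi_employment"].append({"who": s.who, "education_years": s.edu_years,
                                    "usual_employment": s.employment})
        T["asi_legal"].append({"who": s.who, "is_on_parole": int(s.parole == "yes")})
        T["asi_psychiatric"].append({"who": s.who,
                                     "has_depression": int(s.asi_dep == "yes"),
                                     "has_anxiety": int(s.asi_anx == "yes"),
                                     "has_hallucinations": int(s.asi_hall == "yes")})
        T["medical_history"].append({"who": s.who,
                                     "has_schizophrenia": s.medical["schiz"],
                                     "has_major_depression": s.medical["depress"],
                                     "has_bipolar": s.medical["bipolar"],
                                     "has_anxiety": s.medical["anxiety"],
                                     "has_epilepsy": s.medical["epilepsy"],
                                     "has_neuro_damage": s.medical["neuro"]})
        T["psychiatric_diagnoses"].append({"who": s.who,
                                           "has_schizophrenia": s.checklist["ck_schiz"],
                                           "has_major_depression": s.checklist["ck_depress"],
                                           "has_bipolar": s.checklist["ck_bipolar"],
                                           "has_anxiety": s.checklist["ck_anx"]})
        for sub, flags in s.sud.items():
            T["sud_diagnoses"].append({"who": s.who, "substance": sub,
                                       "sud_diagnosis": crosswalks.sud_flag(
                                           flags.get("abuse"), flags.get("dep"),
                                           flags.get("dx"))})
        T["pain"].append({"who": s.who,
                          "pain": crosswalks.pain_category(
                              dialect.pain_instrument, s.pain_resp)})
        T["nicotine"].append({"who": s.who, "is_smoker": int(s.smoker),
                              "ftnd": crosswalks.score_ftnd(s.ftnd_items, s.smoker)
                              if s.smoker else None})
        for sub, val in s.rbs_days.items():
            days = crosswalks.rab_days(val) if isinstance(val, str) else val
            T["rbs_drug"].append({"who": s.who, "substance": sub, "days_use": days})
        iv = crosswalks.derive_iv_summaries(s.iv_days, s.iv_events)
        T["rbs_iv"].append({"who": s.who, **iv,
                            "is_needle_sharing": int(s.needle == "yes")})
        T["rbs_sex"].append({"who": s.who, "n_partners": s.partners,
                             "is_unprotected_sex": int(s.unprotected == "yes")})

        _truth_tlfb(s, dialect, lex, T)

        if s.screened_only:
            continue

        T["randomization"].append({"who": s.who, "when": s.r_when, "which": 1,
                                   "treatment": s.arm})
        T["randomization"].append({"who": s.who,
                                   "when": s.r2_when if s.r2_when is not None else s.r_when,
                                   "which": 2,
                                   "treatment": s.arm2 if s.arm2 is not None else s.arm})
        for when, w in s.visits:
            T["visits"].append({"who": s.who, "when": when, "visit_week": w})
        for when, w, reason in s.missed:
            T["missed_visits"].append({"who": s.who, "when": when,
                                       "reason": dial[s.project].recodes[
                                           "missed_visits.reason"][reason]})
        for when, score in sorted(s.withdrawal):
            sev = crosswalks.withdrawal_severity(dialect.withdrawal_instrument, score)
            T["withdrawal"].append({"who": s.who, "when": when,
                                    "instrument": dialect.withdrawal_instrument,
                                    "score": score, "severity": sev})
        first_dose = min((w for w, _, _, _ in s.doses), default=s.induction_when)
        pre, post = crosswalks.select_pre_post(
            [(w, crosswalks.withdrawal_severity(dialect.withdrawal_instrument, sc))
             for w, sc in s.withdrawal], first_dose)
        T["withdrawal_pre_post"].append({
            "who": s.who,
            "when_pre": pre[0] if pre else None,
            "severity_pre": pre[1] if pre else None,
            "when_post": post[0] if post else None,
            "severity_post": post[1] if post else None})

        _truth_uds(s, dialect, lex, T)
        _truth_doses(s, T)

    db = HarmonizedDatabase()
    registry = db.registry
    for name, rows in T.items():
        schema = registry[name]
        df = pd.DataFrame(rows, columns=list(schema.variable_names))
        T[name] = df
    T["meta_study_length"] = dialects.meta_study_length_frame()
    T["meta_arms"] = dialects.meta_arms_frame()
    T["meta_codebook"] = codebook_frame(registry)
    db.tables = T
    return db


def _truth_tlfb(s: _Subject, dialect: DialectSpec, lex, T: dict):
    day_categories = {}
    day_tokens = {}
    day_alcohol = {}
    for when, stem, value in s.tlfb:
        if stem == "__alcohol__":
            amount = value[1] if dialect.alcohol_mode != "binary" else None
            day_alcohol[when] = amount
            day_categories.setdefault(when, []).append("Alcohol")
            day_tokens.setdefault(when, set()).add("alcohol")
        else:
            token = dialect.tlfb_columns[stem]
            day_categories.setdefault(when, []).append(lex.categories[token])
            day_tokens.setdefault(when, set()).add(token)
    for when, text in s.other_drugs:
        token = lex.variants[text]
        day_categories.setdefault(when, []).append(lex.categories[token])
        day_tokens.setdefault(when, set()).add(token)
    for when in sorted(day_categories):
        for _, _, cat in collapse_daily((s.who, when, c)
                                        for c in day_categories[when]):
            T["tlfb"].append({"who": s.who, "when": when, "what": cat,
                              "amount": day_alcohol.get(when) if cat == "Alcohol" else None,
                              "is_imputed": 0 if (cat == "Alcohol" and
                                                  day_alcohol.get(when) is not None)
                              else None})
        for token in sorted(day_tokens[when]):
            T["all_drugs"].append({"who": s.who, "when": when, "what": token,
                                   "source": "TLFB"})


def _truth_uds(s: _Subject, dialect: DialectSpec, lex, T: dict):
    from .uds import ASSIGNED_PANEL_DRUG
    excluded_cat = {"methadone": "Methadone", "buprenorphine": "Buprenorphine",
                    None: None}[ASSIGNED_PANEL_DRUG.get(s.drug)]
    code_map = dialect.recodes["uds.substance"]
    for p in s.uds_panels:
        tokens = sorted({code_map[code] for code, concept in p.results
                         if concept == "positive"})
        for token in tokens:
            T["all_drugs"].append({"who": s.who, "when": p.when, "what": token,
                                   "source": "UDS"})
        cats = sorted({lex.categories[t] for t in tokens})
        for cat in cats:
            if cat == excluded_cat:
                continue
            T["uds"].append({"who": s.who, "when": p.when, "what": cat})
        T["uds_temp"].append({"who": s.who, "when": p.when,
                              "in_range": p.temp if p.temp is not None else "Missing"})


def _truth_doses(s: _Subject, T: dict):
    per_day = {}
    for when, end_when, drug, dose in s.doses:
        span = 1 if end_when is None else end_when - when + 1
        for k in range(span):
            key = (when + k, drug)
            per_day[key] = per_day.get(key, 0.0) + dose
    for (when, drug), dose in sorted(per_day.items()):
        T["treatment_dose"].append({"who": s.who, "when": when, "what": drug,
                                    "dose": dose, "was_corrected": 0})


# ---------------------------------------------------------------------------
# error injection

def who_map(bundles: dict) -> dict:
    """(project, raw_id) -> who, replicating first-seen assignment order."""
    out = {}
    counter = 1
    for project in PROJECT_ORDER:
        if project not in bundles:
            continue
        bundle = bundles[project]
        idc = bundle.dialect.id_aliases[0]
        for raw in bundle.tables["screening"][idc]:
            if (project, raw) not in out:
                out[(project, raw)] = counter
                counter += 1
    return out


def inject_errors(bundles: dict, cfg: GeneratorConfig):
    """Corrupt clean bundles per the documented error taxonomy.

    Returns ``(corrupted_bundles, ledger)`` where the ledger is one row per
    injected corruption: project, raw_id, who, table, field, rule_id,
    locator (the affected ``when``), true_value and corrupted_value.
    All-zero rates return bundles identical to the input and an empty
    ledger.  Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed + 99991)
    rates = {**{k: 0.0 for k in DEFAULT_ERROR_RATES}, **cfg.error_rates}
    whos = who_map(bundles)
    lex = default_lexicon()
    ledger_rows = []
    out = {}

    for project in PROJECT_ORDER:
        if project not in bundles:
            continue
        bundle = bundles[project]
        dialect = bundle.dialect
        tables = {k: v.copy() for k, v in bundle.tables.items()}
        idc = dialect.id_aliases[0]
        consent = {r[idc]: dialect.parse_date(r["consent_date"])
                   for _, r in tables["screening"].iterrows()}

        def log(raw_id, table, field, rule, locator, true, corrupted):
            ledger_rows.append({
                "project": project, "raw_id": raw_id,
                "who": whos[(project, raw_id)], "table": table, "field": field,
                "rule_id": rule, "locator": locator,
                "true_value": true, "corrupted_value": corrupted})

        _corrupt_uds(rng, tables, dialect, rates, consent, log)
        if dialect.layouts.get("tlfb") == "long":
            _corrupt_tlfb_long(rng, tables, dialect, rates, consent, lex, log)
        if "tlfb_other" in tables and len(tables["tlfb_other"]):
            _corrupt_other_table(rng, tables, dialect, rates, consent, lex, log)
        if project == "CTN-0027":
            _corrupt_doses(rng, tables, dialect, rates, consent, log)
        out[project] = RawBundle(project, tables, dialect)

    ledger = pd.DataFrame(ledger_rows, columns=[
        "project", "raw_id", "who", "table", "field", "rule_id",
        "locator", "true_value", "corrupted_value"])
    return out, ledger


def _corrupt_uds(rng, tables, dialect, rates, consent, log):
    uds = tables["uds"]
    if not len(uds):
        return
    idc = next(c for c in uds.columns if c in dialect.id_aliases)
    fmt, parse = dialect.format_date, dialect.parse_date
    # panel bookkeeping: (raw_id, date_str) -> row indices, in frame order
    panels = {}
    for idx, r in uds.iterrows():
        panels.setdefault((r[idc], r["date"]), []).append(idx)
    dates_by_id = {}
    for raw_id, date_str in panels:
        dates_by_id.setdefault(raw_id, set()).add(date_str)
    corrupted = set()

    for (raw_id, date_str), indices in list(panels.items()):
        first = uds.loc[indices[0]]
        week, ts = first["week"], first["timestamp"]
        d = parse(date_str)
        when = (d - consent[raw_id]).days
        if not str(week).isdigit() or int(week) < 1:
            continue
        u = rng.random()
        if ts == "":
            new = None
            rule = None
            if u < rates["date_year_typo"]:
                shift = -int(rng.integers(1, 3))
                try:
                    new = d.replace(year=d.year + shift)
                except ValueError:
                    new = None
                rule = "date_year_typo"
            elif u < rates["date_year_typo"] + rates["date_transpose"]:
                if 2 <= d.day <= 9:
                    try:
                        new = d.replace(day=d.day * 10)
                    except ValueError:
                        new = None
                rule = "date_transpose"
            if new is not None and fmt(new) not in dates_by_id[raw_id]:
                uds.loc[indices, "date"] = fmt(new)
                dates_by_id[raw_id].add(fmt(new))
                corrupted.add((raw_id, date_str))
                log(raw_id, "uds", "date", rule, when, when,
                    (new - consent[raw_id]).days)
        else:
            if u < rates["duplicate_uds"]:
                others = [k for k in panels
                          if k[0] == raw_id and k[1] != date_str
                          and k not in corrupted
                          and str(uds.loc[panels[k][0], "week"]).isdigit()]
                if others:
                    target = others[int(rng.integers(len(others)))]
                    uds.loc[indices, "date"] = target[1]
                    corrupted.add((raw_id, date_str))
                    log(raw_id, "uds", "date", "duplicate_uds", when, when,
                        (parse(target[1]) - consent[raw_id]).days)

    # end-of-study copies of each subject's last panel
    extra = []
    for raw_id, dates in sorted(dates_by_id.items()):
        if rng.random() >= rates["eos_duplicate"]:
            continue
        last = max(dates, key=parse)
        if (raw_id, last) in corrupted:
            continue
        rows = uds.loc[panels[(raw_id, last)]].copy()
        rows["week"] = "EOS"
        rows["timestamp"] = ""
        extra.append(rows)
        when = (parse(last) - consent[raw_id]).days
        log(raw_id, "uds", "row", "eos_duplicate", when, when, when)
    if extra:
        tables["uds"] = pd.concat([uds] + extra, ignore_index=True)


def _corrupt_tlfb_long(rng, tables, dialect, rates, consent, lex, log):
    tlfb = tables["tlfb"]
    if not len(tlfb):
        return
    idc = next(c for c in tlfb.columns if c in dialect.id_aliases)
    fmt, parse = dialect.format_date, dialect.parse_date

    # survey-date typos on follow-up administrations (survey == period end)
    for (raw_id, survey), idx in tlfb.groupby([idc, "survey_date"],
                                              sort=False).groups.items():
        period = tlfb.loc[idx[0], "period_end"]
        if survey != period:
            continue
        d = parse(survey)
        when = (d - consent[raw_id]).days
        u = rng.random()
        if u < rates["date_offby1"]:
            new = d + timedelta(int(rng.choice([-1, 1])))
            tlfb.loc[idx, "survey_date"] = fmt(new)
            log(raw_id, "tlfb_survey", "survey_date", "date_offby1",
                when, d.isoformat(), new.isoformat())
        elif u < rates["date_offby1"] + rates["date_year_typo"]:
            try:
                new = d.replace(year=d.year - 2)
            except ValueError:
                continue
            tlfb.loc[idx, "survey_date"] = fmt(new)
            log(raw_id, "tlfb_survey", "survey_date", "date_year_typo",
                when, d.isoformat(), new.isoformat())

    # free-text drug corruption on OTHER entries
    other_idx = [i for i in tlfb.index if tlfb.loc[i, "item"] == "OTHER"]
    _misspell(rng, tlfb, other_idx, "value", idc, "entry_date",
              dialect, rates, consent, lex, log)
    # merge same-day multi-drug entries into one compound string
    drop = []
    by_day = {}
    for i in other_idx:
        if i in drop:
            continue
        by_day.setdefault((tlfb.loc[i, idc], tlfb.loc[i, "entry_date"]), []).append(i)
    for (raw_id, date_str), idxs in by_day.items():
        idxs = [i for i in idxs if i not in drop]
        if len(idxs) >= 2 and rng.random() < rates["multi_drug_string"]:
            a, b = tlfb.loc[idxs[0], "value"], tlfb.loc[idxs[1], "value"]
            joiner = "/" if rng.random() < 0.5 else " and "
            tlfb.loc[idxs[0], "value"] = f"{a}{joiner}{b}"
            drop.append(idxs[1])
            when = (parse(date_str) - consent[raw_id]).days
            log(raw_id, "all_drugs", "what", "multi_drug_string", when,
                f"{lex.variants[a]}|{lex.variants[b]}", f"{a}{joiner}{b}")
    if drop:
        tables["tlfb"] = tlfb.drop(index=drop).reset_index(drop=True)
        tlfb = tables["tlfb"]

    # blank drink amounts for subjects with several drinking days
    alco = [i for i in tlfb.index if tlfb.loc[i, "item"] == "ALCOHOL"]
    by_id = {}
    for i in alco:
        by_id.setdefault(tlfb.loc[i, idc], []).append(i)
    for raw_id, idxs in by_id.items():
        if len(idxs) < 3:
            continue
        for i in idxs:
            if rng.random() < rates["drink_amount_missing"] and tlfb.loc[i, "value"]:
                when = (parse(tlfb.loc[i, "entry_date"]) - consent[raw_id]).days
                log(raw_id, "tlfb", "amount", "drink_amount_missing", when,
                    tlfb.loc[i, "value"], "")
                tlfb.loc[i, "value"] = ""


def _corrupt_other_table(rng, tables, dialect, rates, consent, lex, log):
    other = tables["tlfb_other"]
    idc = next(c for c in other.columns if c in dialect.id_aliases)
    _misspell(rng, other, list(other.index), "text", idc, "date",
              dialect, rates, consent, lex, log)
    drop = []
    by_day = {}
    for i in other.index:
        by_day.setdefault((other.loc[i, idc], other.loc[i, "date"]), []).append(i)
    for (raw_id, date_str), idxs in by_day.items():
        if len(idxs) >= 2 and rng.random() < rates["multi_drug_string"]:
            a, b = other.loc[idxs[0], "text"], other.loc[idxs[1], "text"]
            other.loc[idxs[0], "text"] = f"{a}/{b}"
            drop.append(idxs[1])
            when = (dialect.parse_date(date_str) - consent[raw_id]).days
            log(raw_id, "all_drugs", "what", "multi_drug_string", when,
                f"{lex.variants[a]}|{lex.variants[b]}", f"{a}/{b}")
    if drop:
        tables["tlfb_other"] = other.drop(index=drop).reset_index(drop=True)


def _misspell(rng, df, indices, text_col, idc, date_col,
              dialect, rates, consent, lex, log):
    variants_of = {}
    for variant, canonical in lex.variants.items():
        variants_of.setdefault(canonical, []).append(variant)
    for i in indices:
        text = df.loc[i, text_col]
        if rng.random() >= rates["drug_misspelling"]:
            continue
        token = lex.variants.get(text)
        if token is None:
            continue
        alts = [v for v in variants_of[token] if v != text]
        if not alts:
            continue
        raw_id = df.loc[i, idc]
        when = (dialect.parse_date(df.loc[i, date_col]) - consent[raw_id]).days
        new = alts[int(rng.integers(len(alts)))]
        log(raw_id, "all_drugs", "what", "drug_misspelling", when, token, new)
        df.loc[i, text_col] = new


def _corrupt_doses(rng, tables, dialect, rates, consent, log):
    dose = tables["dose"]
    if not len(dose):
        return
    idc = next(c for c in dose.columns if c in dialect.id_aliases)
    flip = {"M": "B", "B": "M"}
    token = {"M": "methadone", "B": "buprenorphine"}
    for raw_id, idx in dose.groupby(idc, sort=False).groups.items():
        if rng.random() >= rates["dose_other_drug"]:
            continue
        daily = [i for i in idx if dose.loc[i, "end_date"] == ""]
        # only days with a single log line, strictly inside the series
        counts = {}
        for i in daily:
            counts[dose.loc[i, "date"]] = counts.get(dose.loc[i, "date"], 0) + 1
        dates = sorted({dose.loc[i, "date"] for i in daily},
                       key=dialect.parse_date)
        inner = [i for i in daily
                 if counts[dose.loc[i, "date"]] == 1
                 and dose.loc[i, "date"] not in (dates[0], dates[-1])]
        if not inner:
            continue
        i = inner[int(rng.integers(len(inner)))]
        old = dose.loc[i, "drug"]
        dose.loc[i, "drug"] = flip[old]
        when = (dialect.parse_date(dose.loc[i, "date"]) - consent[raw_id]).days
        log(raw_id, "treatment_dose", "what", "dose_other_drug", when,
            token[old], token[flip[old]])
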