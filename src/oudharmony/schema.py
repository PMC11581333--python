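"""Harmonized relational schema: table registry, codebook, validation.

The harmonized database follows a tidy "who / when / what" design: every
patient-level table carries a ``who`` subject key, event tables carry an
integer ``when`` (days relative to consent, day 0 = consent), and drug or
concept values live in a single ``what`` column rather than per-day column
families.  Binary indicators are verb-prefixed and coded 0/1; categorical
variables enumerate every permitted level including missing-style levels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pandas as pd

PROJECTS = ("CTN-0027", "CTN-0030", "CTN-0051")

#: The seven subject-identifier spellings observed across raw study bundles.
ID_ALIASES = (
    "tcPATNUM", "txtPInumber", "PATNUM", "ID", "PROJID", "patientnumber", "PATID",
)

SNAKE_RE = re.compile(r"^[a-z][a-z0-9_]*$")
# column families like heroin_d1 / heroin_d2 or use_w3 violate tidy shape
DAY_SUFFIX_RE = re.compile(r"^(?P<stem>.*)_(?:d|day|w|wk|week)(?P<idx>\d+)$")

TREATMENT_ARMS = (
    "Methadone",
    "Outpatient BUP",
    "Outpatient BUP + Standard Medical Management",
    "Outpatient BUP + Enhanced Medical Management",
    "Inpatient BUP",
    "Inpatient XR-NTX",
)

DRUG_CATEGORIES = (
    "Alcohol", "Amphetamine", "Barbiturate", "Benzodiazepine", "Buprenorphine",
    "Cocaine", "Hallucinogen", "Heroin", "Inhalant", "K2", "Kratom", "MDMA",
    "Methadone", "Opioid", "Sedatives", "THC", "Unknown",
)

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")
PAIN_LEVELS = ("No Pain", "Very Mild to Moderate Pain", "Severe Pain", "Missing")
RACE_LEVELS = ("White", "Black", "Refused/Missing", "Other")
EDUCATION_LEVELS = (
    "Missing/Refused", "Less than High School", "High School/GED",
    "More than High School",
)
MARITAL_LEVELS = (
    "Separated/Divorced/Widowed", "Married or Partnered", "Single",
    "Not Asked", "Missing",
)
EMPLOYMENT_LEVELS = ("Full Time", "Part Time", "Student", "Unemployed", "Other", "Missing")
MISSED_REASONS = ("In Jail", "Illness", "Travel", "Unknown")
RBS_SUBSTANCES = ("cocaine", "heroin", "speedball", "opioid", "amphetamine")
SUD_SUBSTANCES = ("alcohol", "amphetamine", "cannabis", "cocaine", "sedatives", "opioid")
TREATMENT_DRUGS = ("methadone", "buprenorphine", "xr_ntx")
STUDY_STAGES = ("stabilization", "taper", "follow_up")


@dataclass(frozen=True)
class VariableSpec:
    """One variable in the codebook."""

    name: str
    value_type: str  # integer | real | category | text | flag01
    label: str
    permitted_values: tuple = ()
    reference_level: Optional[str] = None

    def __post_init__(self):
        if self.value_type not in ("integer", "real", "category", "text", "flag01"):
            raise ValueError(f"unknown value_type {self.value_type!r}")
        if self.value_type == "category" and not self.permitted_values:
            raise ValueError(f"category variable {self.name!r} must enumerate values")


@dataclass(frozen=True)
class TableSchema:
    name: str
    variables: tuple
    key: tuple  # uniqueness key columns
    is_meta: bool = False

    @property
    def variable_names(self) -> tuple:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)


def _v(name, value_type, label, permitted=(), ref=None):
    if value_type == "flag01":
        permitted = (0, 1)
    return VariableSpec(name, value_type, label, tuple(permitted), ref)


WHO = _v("who", "integer", "Subject key, unique across the merged database")
WHEN = _v("when", "integer", "Days relative to consent (day 0 = consent)")


def register_schema() -> dict:
    """Return the fixed registry of 23 patient tables and 3 meta tables.

    The registry is the single source of truth for table names, variables,
    permitted values and uniqueness keys.
    """
    t = {}

    def table(name, variables, key, is_meta=False):
        t[name] = TableSchema(name, tuple(variables), tuple(key), is_meta)

    table("enrollment", [
        WHO,
        _v("project", "category", "Source trial", PROJECTS, "CTN-0027"),
        _v("raw_id", "text", "Original subject identifier from the raw bundle"),
    ], ["who"])

    table("demographics", [
        WHO,
        _v("age", "integer", "Age in whole years at screening (floor of DOB-to-screening difference)"),
        _v("is_male", "flag01", "1 if sex assigned at birth is male"),
        _v("is_hispanic", "flag01", "1 if of Hispanic/Latino ethnicity"),
        _v("race", "category", "Race collapsed to four census-style categories", RACE_LEVELS, "White"),
        _v("education", "category", "Educational attainment", EDUCATION_LEVELS, "High School/GED"),
        _v("marital", "category", "Relationship status", MARITAL_LEVELS, "Single"),
        _v("is_living_stable", "flag01", "1 if usual living arrangement is stable"),
        _v("job", "category", "Usual employment status (majority of past 3 years)", EMPLOYMENT_LEVELS, "Full Time"),
    ], ["who"])

    table("randomization", [
        WHO, WHEN,
        _v("which", "category", "Randomization event index (re-randomized subjects have two distinct events)", (1, 2), 1),
        _v("treatment", "category", "Assigned treatment arm", TREATMENT_ARMS),
    ], ["who", "which"])

    table("treatment_dose", [
        WHO, WHEN,
        _v("what", "category", "Treatment drug", TREATMENT_DRUGS),
        _v("dose", "real", "Total daily dose in mg, or 1 per injection for XR-NTX"),
        _v("was_corrected", "flag01", "1 if the drug label was repaired to the randomized assignment"),
    ], ["who", "when", "what"])

    table("visits", [
        WHO, WHEN,
        _v("visit_week", "integer", "Study-week label recorded on the visit form"),
    ], ["who", "when"])

    table("missed_visits", [
        WHO, WHEN,
        _v("reason", "category", "Harmonized reason for the missed visit", MISSED_REASONS, "Unknown"),
    ], ["who", "when"])

    table("tlfb", [
        WHO, WHEN,
        _v("what", "category", "Harmonized drug category (one record per category per day)", DRUG_CATEGORIES),
        _v("amount", "real", "Standard drinks for Alcohol records; missing otherwise"),
        _v("is_imputed", "flag01", "1 if the drink amount was imputed from the subject's usual pattern"),
    ], ["who", "when", "what"])

    table("all_drugs", [
        WHO, WHEN,
        _v("what", "text", "Canonical drug token (typos fixed, compounds split, doses stripped)"),
        _v("source", "category", "How the drug was identified", ("TLFB", "UDS"), "TLFB"),
    ], ["who", "when", "what", "source"])

    table("uds", [
        WHO, WHEN,
        _v("what", "category", "Drug category with a positive screen (prescribed treatment drug excluded)",
           DRUG_CATEGORIES),
    ], ["who", "when", "what"])

    table("uds_temp", [
        WHO, WHEN,
        _v("in_range", "category", "Urine sample temperature in acceptable range", ("Yes", "No", "Missing"), "Yes"),
    ], ["who", "when"])

    table("withdrawal", [
        WHO, WHEN,
        _v("instrument", "category", "Withdrawal scale used", ("COWS", "SOWS"), "COWS"),
        _v("score", "integer", "Raw total score (COWS 0-48, SOWS 0-64)"),
        _v("severity", "category", "Harmonized opioid withdrawal severity", SEVERITY_LEVELS, "none"),
    ], ["who", "when", "instrument"])

    table("withdrawal_pre_post", [
        WHO,
        _v("when_pre", "integer", "Day of the closest measurement strictly before first dose"),
        _v("severity_pre", "category", "Severity at the pre-induction measurement", SEVERITY_LEVELS),
        _v("when_post", "integer", "Day of the closest measurement at/after first dose"),
        _v("severity_post", "category", "Severity at the post-induction measurement", SEVERITY_LEVELS),
    ], ["who"])

    table("nicotine", [
        WHO,
        _v("is_smoker", "flag01", "1 if a current smoker"),
        _v("ftnd", "integer", "Fagerstrom Test for Nicotine Dependence score 0-10; missing for nonsmokers"),
    ], ["who"])

    table("asi_employment", [
        WHO,
        _v("education_years", "integer", "Years of education completed (ASI-Lite)"),
        _v("usual_employment", "category", "Usual employment status (ASI-Lite)", EMPLOYMENT_LEVELS, "Full Time"),
    ], ["who"])

    table("asi_legal", [
        WHO,
        _v("is_on_parole", "flag01", "1 if on parole or probation (ASI-Lite L2)"),
    ], ["who"])

    table("asi_psychiatric", [
        WHO,
        _v("has_depression", "flag01", "Serious depression not caused by drug use (ASI-Lite)"),
        _v("has_anxiety", "flag01", "Serious anxiety/tension not caused by drug use (ASI-Lite)"),
        _v("has_hallucinations", "flag01", "Experienced hallucinations not caused by drug use (ASI-Lite)"),
    ], ["who"])

    table("medical_history", [
        WHO,
        _v("has_schizophrenia", "flag01", "History of schizophrenia or other psychotic disorder (medical exam)"),
        _v("has_major_depression", "flag01", "History of major depressive disorder (medical exam)"),
        _v("has_bipolar", "flag01", "History of bipolar disorder (medical exam)"),
        _v("has_anxiety", "flag01", "History of anxiety disorder (medical exam)"),
        _v("has_epilepsy", "flag01", "History of epilepsy (medical exam)"),
        _v("has_neuro_damage", "flag01", "History of clinically significant neurological damage (medical exam)"),
    ], ["who"])

    table("psychiatric_diagnoses", [
        WHO,
        _v("has_schizophrenia", "flag01", "Schizophrenia/psychotic disorder on the diagnostic checklist"),
        _v("has_major_depression", "flag01", "Major depressive disorder on the diagnostic checklist"),
        _v("has_bipolar", "flag01", "Bipolar disorder on the diagnostic checklist"),
        _v("has_anxiety", "flag01", "Anxiety disorder on the diagnostic checklist"),
    ], ["who"])

    table("sud_diagnoses", [
        WHO,
        _v("substance", "category", "Substance class", SUD_SUBSTANCES),
        _v("sud_diagnosis", "flag01",
           "1 if DSM-IV abuse or dependence, or DSM-5 use disorder, for this substance"),
    ], ["who", "substance"])

    table("pain", [
        WHO,
        _v("pain", "category", "Baseline bodily pain harmonized to three levels", PAIN_LEVELS, "No Pain"),
    ], ["who"])

    table("rbs_drug", [
        WHO,
        _v("substance", "category", "Substance class on the risky-behavior survey", RBS_SUBSTANCES),
        _v("days_use", "integer", "Estimated days of use in the last 30 days"),
    ], ["who", "substance"])

    table("rbs_iv", [
        WHO,
        _v("iv_max_days", "integer", "Maximum days of use across all IV drugs (last 30 days)"),
        _v("iv_max_events", "integer", "Maximum drug-use events per day across IV drugs"),
        _v("iv_monthly", "integer", "Monthly exposure (days x events/day) for the most-used IV drug"),
        _v("is_needle_sharing", "flag01", "1 if needles were shared"),
    ], ["who"])

    table("rbs_sex", [
        WHO,
        _v("n_partners", "integer", "Number of sexual partners reported"),
        _v("is_unprotected_sex", "flag01", "1 if unprotected sex reported"),
    ], ["who"])

    # --- meta tables ---
    table("meta_study_length", [
        _v("project", "category", "Source trial", PROJECTS, "CTN-0027"),
        _v("arm", "category", "Treatment arm", TREATMENT_ARMS),
        _v("phase", "integer", "Study phase (two-phase adaptive designs use 1 and 2)"),
        _v("stage", "category", "Treatment stage", STUDY_STAGES, "stabilization"),
        _v("weeks", "integer", "Duration of the stage in weeks"),
    ], ["project", "arm", "phase", "stage"], is_meta=True)

    table("meta_arms", [
        _v("project", "category", "Source trial", PROJECTS, "CTN-0027"),
        _v("arm", "category", "Treatment arm", TREATMENT_ARMS),
        _v("drug", "category", "Treatment drug delivered in this arm", TREATMENT_DRUGS),
    ], ["project", "arm"], is_meta=True)

    table("meta_codebook", [
        _v("table", "text", "Table name"),
        _v("variable", "text", "Variable name"),
        _v("value_type", "text", "Variable type"),
        _v("label", "text", "Short description"),
    ], ["table", "variable"], is_meta=True)

    _check_registry(t)
    return t


def patient_tables(registry: dict | None = None) -> list:
    registry = registry or register_schema()
    return [s.name for s in registry.values() if not s.is_meta]


def meta_tables(registry: dict | None = None) -> list:
    registry = registry or register_schema()
    return [s.name for s in registry.values() if s.is_meta]


def _check_registry(registry: dict) -> None:
    n_patient = sum(1 for s in registry.values() if not s.is_meta)
    n_meta = sum(1 for s in registry.values() if s.is_meta)
    assert n_patient == 23 and n_meta == 3, (n_patient, n_meta)
    for schema in registry.values():
        if not SNAKE_RE.match(schema.name):
            raise ValueError(f"table name not snake_case: {schema.name}")
        seen_stems = set()
        for v in schema.variables:
            if not SNAKE_RE.match(v.name):
                raise ValueError(f"variable name not snake_case: {schema.name}.{v.name}")
            m = DAY_SUFFIX_RE.match(v.name)
            if m:
                stem = m.group("stem")
                if stem in seen_stems:
                    raise ValueError(f"repeated day/week column family: {schema.name}.{v.name}")
                seen_stems.add(stem)
        if not schema.is_meta and schema.variables[0].name != "who":
            raise ValueError(f"patient table {schema.name} must lead with who")


@dataclass
class CorrectionEntry:
    """Audit-trail record for one mutation made by a cleaning rule."""

    who: object
    table: str
    field: str
    original_value: object
    corrected_value: object
    rule_id: str
    rationale: str = ""


@dataclass
class HarmonizedDatabase:
    """Named collection of tidy tables plus codebook and audit log."""

    tables: dict = field(default_factory=dict)
    audit_log: list = field(default_factory=list)
    registry: dict = field(default_factory=register_schema)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


# ---------------------------------------------------------------------------
# validation

@dataclass
class Violation:
    table: str
    rule: str
    message: str
    who: object = None


def validate_database(db: HarmonizedDatabase) -> list:
    """Check referential integrity, permitted values, keys and tidy shape.

    Returns a list of :class:`Violation`; an empty list means the database
    is valid.  A structurally malformed table (missing ``who``) yields a
    single structural violation naming the table.
    """
    registry = db.registry
    out: list[Violation] = []

    for name, schema in registry.items():
        if name not in db.tables:
            out.append(Violation(name, "structure.missing_table", f"table {name} absent"))
    if out:
        return out

    enrollment = db.tables["enrollment"]
    if "who" not in enrollment.columns:
        return [Violation("enrollment", "structure.no_who", "enrollment lacks a who column")]
    known_who = set(enrollment["who"])
    if len(known_who) != len(enrollment):
        out.append(Violation("enrollment", "key.duplicate", "duplicate who in enrollment"))

    for name, schema in registry.items():
        df = db.tables[name]
        if not schema.is_meta:
            if "who" not in df.columns:
                out.append(Violation(name, "structure.no_who", f"table {name} lacks a who column"))
                continue
            if name != "enrollment":
                orphans = sorted(set(df["who"]) - known_who)
                for w in orphans:
                    out.append(Violation(name, "ref.who_not_enrolled",
                                         f"who {w} not present in enrollment", who=w))
        # tidy shape over actual columns
        stems = {}
        for col in df.columns:
            m = DAY_SUFFIX_RE.match(str(col))
            if m:
                stems.setdefault(m.group("stem"), []).append(col)
        for stem, cols in stems.items():
            if len(cols) >= 2:
                out.append(Violation(name, "tidy.column_family",
                                     f"repeated day/week columns {cols}"))
        # schema conformance
        for v in schema.variables:
            if v.name not in df.columns:
                out.append(Violation(name, "structure.missing_variable",
                                     f"variable {v.name} absent from {name}"))
                continue
            col = df[v.name].dropna()
            if v.value_type in ("category", "flag01") and len(col):
                permitted = set(v.permitted_values)
                permitted |= {str(p) for p in v.permitted_values}
                bad = set(col.unique()) - permitted
                # numeric flags may arrive as floats from CSV round-trips
                bad = {b for b in bad
                       if not (isinstance(b, float) and b in {float(p) for p in v.permitted_values
                                                              if isinstance(p, (int, float))})}
                for b in sorted(map(str, bad)):
                    out.append(Violation(name, "value.not_permitted",
                                         f"{v.name} value {b!r} not permitted"))
        # uniqueness key
        keycols = [k for k in schema.key if k in df.columns]
        if keycols and len(df) and df.duplicated(subset=keycols).any():
            ndup = int(df.duplicated(subset=keycols).sum())
            out.append(Violation(name, "key.duplicate",
                                 f"{ndup} duplicate rows on key {keycols}"))
    return out


# ---------------------------------------------------------------------------
# codebook

def emit_codebook(db: HarmonizedDatabase) -> dict:
    """Machine-readable codebook: one entry per variable per table."""
    doc = {}
    for name, schema in db.registry.items():
        if name not in db.tables:
            continue
        doc[name] = {
            "is_meta": schema.is_meta,
            "key": list(schema.key),
            "variables": [
                {
                    "name": v.name,
                    "value_type": v.value_type,
                    "label": v.label,
                    "permitted_values": list(v.permitted_values),
                    "reference_level": v.reference_level,
                }
                for v in schema.variables
            ],
        }
    return doc


def parse_codebook(doc: dict) -> dict:
    """Inverse of :func:`emit_codebook`; ``parse(emit(db)) == db.registry``."""
    registry = {}
    for name, entry in doc.items():
        variables = tuple(
            VariableSpec(
                v["name"], v["value_type"], v["label"],
                tuple(v["permitted_values"]), v["reference_level"],
            )
            for v in entry["variables"]
        )
        registry[name] = TableSchema(name, variables, tuple(entry["key"]), entry["is_meta"])
    return registry


def render_codebook(doc: dict) -> str:
    """Human-readable rendering of the codebook."""
    lines = []
    for name, entry in doc.items():
        kind = "meta table" if entry["is_meta"] else "patient table"
        lines.append(f"## {name} ({kind}; key: {', '.join(entry['key'])})")
        for v in entry["variables"]:
            perm = ""
            if v["permitted_values"]:
                perm = " {" + ", ".join(map(str, v["permitted_values"])) + "}"
            ref = f" [ref: {v['reference_level']}]" if v["reference_level"] is not None else ""
            lines.append(f"  - {v['name']} <{v['value_type']}>{perm}{ref}: {v['label']}")
        lines.append("")
    return "\n".join(lines)


def codebook_frame(registry: dict | None = None) -> pd.DataFrame:
    """The meta_codebook table content, derived from the registry."""
    registry = registry or register_schema()
    rows = []
    for name, schema in registry.items():
        if name == "meta_codebook":
            continue
        for v in schema.variables:
            rows.append({"table": name, "variable": v.name,
                         "value_type": v.value_type, "label": v.label})
    return pd.DataFrame(rows, columns=["table", "variable", "value_type", "label"])
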