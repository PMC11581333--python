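"""Built-in dialect descriptors for the three emulated study formats.

The three source-style dialects differ in subject-ID column names, date
formats, categorical codings, withdrawal instrument (clinician-rated COWS
vs self-rated SOWS), pain instrument (SF-36 item vs EuroQoL item), urine
panel composition (opiate thresholds of 300 and/or 2000 ng/mL; barbiturate
and MDMA assays in one dialect only), and timeline-followback layout
(dated long entries vs wide weekly day grids).
"""

from __future__ import annotations

import pandas as pd

from .ingest import DialectSpec

_YES_NO_01 = {"1": "yes", "0": "no"}
_YES_NO_YN = {"Y": "yes", "N": "no"}

_MISSED_REASONS = {
    "prison": "In Jail", "jail": "In Jail", "incarcerated": "In Jail",
    "sick": "Illness", "hospitalized": "Illness", "flu": "Illness",
    "out of town": "Travel", "vacation": "Travel",
    "no show": "Unknown", "unknown": "Unknown",
}

_SF36_PAIN_CODES = {
    "1": "None", "2": "Very Mild", "3": "Mild",
    "4": "Moderate", "5": "Severe", "6": "Very Severe",
}
_EUROQOL_PAIN_CODES = {
    "1": "I have no pain or discomfort",
    "2": "I have moderate pain or discomfort",
    "3": "I have extreme pain or discomfort",
}

_UDS_SUBSTANCE_CODES = {
    "AMP": "amphetamine", "BZO": "benzodiazepine", "MTD": "methadone",
    "OXY": "oxycodone", "COC": "cocaine", "MAMP": "methamphetamine",
    "OPI300": "opiates", "OPI2000": "opiates", "THC": "thc",
    "PPX": "propoxyphene", "BUP": "buprenorphine", "BAR": "barbiturate",
    "MDMA": "mdma",
}

_RAB_FREQ = {"0": "not at all", "1": "a few times",
             "2": "a few times each week", "3": "every day"}


def _medical_recodes(codes: dict) -> dict:
    cols = ["schiz", "depress", "bipolar", "anxiety", "epilepsy", "neuro",
            "ck_schiz", "ck_depress", "ck_bipolar", "ck_anx"]
    return {f"medical.{c}": dict(codes) for c in cols}


def _sud_recodes(substances, suffixes, codes) -> dict:
    out = {}
    for sub in substances:
        for suf in suffixes:
            out[f"medical.{sub}_{suf}"] = dict(codes)
    return out


_SUD_SUBSTANCES = ("alcohol", "amphetamine", "cannabis", "cocaine", "sedatives", "opioid")


def ctn0027_dialect() -> DialectSpec:
    recodes = {
        "screening.sex": {"1": "male", "2": "female"},
        "screening.hispanic": {"1": "yes", "2": "no"},
        "screening.marital": {"1": "Married or Partnered",
                              "2": "Separated/Divorced/Widowed", "3": "Single"},
        "asi.employment": {"1": "Full Time", "2": "Part Time", "3": "Student",
                           "4": "Unemployed", "5": "Other"},
        "asi.L2": {"0": "no", "2": "yes"},
        "asi.dep": _YES_NO_01, "asi.anx": _YES_NO_01, "asi.hall": _YES_NO_01,
        "asi.living": {"1": "stable", "2": "unstable"},
        "uds.result": {"P": "positive", "N": "negative", "U": "unclear",
                       "NA": "not_assessed"},
        "uds.temp": {"1": "Yes", "0": "No"},
        "uds.substance": dict(_UDS_SUBSTANCE_CODES),
        "pain.response": dict(_SF36_PAIN_CODES),
        "randomization.arm": {"1": "Methadone", "2": "Outpatient BUP"},
        "dose.drug": {"M": "methadone", "B": "buprenorphine"},
        "nicotine.smoker": _YES_NO_01,
        "missed_visits.reason": dict(_MISSED_REASONS),
        "rbs.needle": _YES_NO_01, "rbs.unprotected": _YES_NO_01,
    }
    recodes.update(_medical_recodes(_YES_NO_01))
    recodes.update(_sud_recodes(_SUD_SUBSTANCES, ("abuse", "dep"), _YES_NO_01))
    return DialectSpec(
        project="CTN-0027",
        id_aliases=["PATNUM", "tcPATNUM"],
        recodes=recodes,
        layouts={"tlfb": "long"},
        date_format="%m/%d/%Y",
        withdrawal_instrument="COWS",
        pain_instrument="SF36",
        opiate_thresholds=[300, 2000],
        alcohol_mode="text",
        uds_substances=["AMP", "BZO", "MTD", "OXY", "COC", "MAMP",
                        "OPI300", "OPI2000", "THC", "PPX"],
        tlfb_columns={
            "ALCOHOL": "alcohol", "AMPHETAMINE": "amphetamine",
            "BENZODIAZEPINE": "benzodiazepine", "THC": "thc",
            "COCAINE": "cocaine", "METHAMPHETAMINE": "methamphetamine",
            "OPIATES": "opiates", "OXYCODONE": "oxycodone",
            "PROPOXYPHENE": "propoxyphene",
        },
    )


def ctn0030_dialect() -> DialectSpec:
    recodes = {
        "screening.sex": {"1": "male", "2": "female"},
        "screening.hispanic": {"1": "yes", "2": "no"},
        "screening.marital": {"1": "Married or Partnered",
                              "2": "Separated/Divorced/Widowed", "3": "Single"},
        "asi.employment": {"1": "Full Time", "2": "Part Time", "3": "Student",
                           "4": "Unemployed", "5": "Other"},
        "asi.L2": {"0": "no", "2": "yes"},
        "asi.dep": _YES_NO_01, "asi.anx": _YES_NO_01, "asi.hall": _YES_NO_01,
        "asi.living": {"1": "stable", "2": "unstable"},
        "uds.result": {"1": "positive", "0": "negative", "U": "unclear",
                       "NA": "not_assessed"},
        "uds.temp": {"1": "Yes", "0": "No"},
        "uds.substance": dict(_UDS_SUBSTANCE_CODES),
        "pain.response": dict(_SF36_PAIN_CODES),
        "randomization.arm": {
            "SMM": "Outpatient BUP + Standard Medical Management",
            "EMM": "Outpatient BUP + Enhanced Medical Management"},
        "dose.drug": {"BUP": "buprenorphine"},
        "nicotine.smoker": _YES_NO_01,
        "missed_visits.reason": dict(_MISSED_REASONS),
        "rbs.needle": _YES_NO_01, "rbs.unprotected": _YES_NO_01,
    }
    recodes.update(_medical_recodes(_YES_NO_01))
    recodes.update(_sud_recodes(_SUD_SUBSTANCES, ("abuse", "dep"), _YES_NO_01))
    return DialectSpec(
        project="CTN-0030",
        id_aliases=["ID", "PROJID", "txtPInumber"],
        recodes=recodes,
        layouts={"tlfb": "wide_daily"},
        date_format="%Y-%m-%d",
        withdrawal_instrument="COWS",
        pain_instrument="SF36",
        opiate_thresholds=[2000],
        alcohol_mode="binary",
        uds_substances=["AMP", "BZO", "MTD", "OXY", "COC", "MAMP",
                        "OPI2000", "THC", "PPX", "BUP"],
        tlfb_columns={
            "alcohol": "alcohol", "heroin_opium": "heroin",
            "morphine": "morphine", "hydromorphone": "hydromorphone",
            "codeine": "codeine", "oxycodone": "oxycodone",
            "hydrocodone": "hydrocodone", "propoxyphene": "propoxyphene",
            "other_opiates": "opioid_analgesic", "sedatives": "sedative",
            "benzodiazepine": "benzodiazepine", "thc": "thc",
            "cocaine": "cocaine", "amphetamine": "amphetamine",
            "methamphetamine": "methamphetamine", "methadone": "methadone",
        },
    )


def ctn0051_dialect() -> DialectSpec:
    recodes = {
        "screening.sex": {"1": "male", "2": "female", "8": "refused", "9": "refused"},
        "screening.hispanic": {"1": "yes", "0": "no"},
        "screening.marital": {"1": "Married or Partnered",
                              "2": "Separated/Divorced/Widowed", "3": "Single"},
        "asi.employment": {"1": "Full Time", "2": "Part Time", "3": "Student",
                           "4": "Unemployed", "5": "Other"},
        "asi.ALPROBAT": {"0": "no", "1": "yes"},
        "asi.dep": _YES_NO_YN, "asi.anx": _YES_NO_YN, "asi.hall": _YES_NO_YN,
        "asi.living": {"Y": "stable", "N": "unstable"},
        "uds.result": {"POS": "positive", "NEG": "negative", "INV": "invalid"},
        "uds.temp": {"Y": "Yes", "N": "No"},
        "uds.substance": dict(_UDS_SUBSTANCE_CODES),
        "pain.response": dict(_EUROQOL_PAIN_CODES),
        "randomization.arm": {"1": "Inpatient XR-NTX", "2": "Inpatient BUP"},
        "dose.drug": {"XR": "xr_ntx", "BUP": "buprenorphine"},
        "nicotine.smoker": _YES_NO_YN,
        "missed_visits.reason": dict(_MISSED_REASONS),
        "rbs.needle": _YES_NO_YN, "rbs.unprotected": _YES_NO_YN,
        "rbs.cocaine_freq": dict(_RAB_FREQ), "rbs.heroin_freq": dict(_RAB_FREQ),
        "rbs.speedball_freq": dict(_RAB_FREQ), "rbs.opioid_freq": dict(_RAB_FREQ),
        "rbs.amphetamine_freq": dict(_RAB_FREQ),
    }
    recodes.update(_medical_recodes(_YES_NO_YN))
    recodes.update(_sud_recodes(_SUD_SUBSTANCES, ("dx",), _YES_NO_YN))
    return DialectSpec(
        project="CTN-0051",
        id_aliases=["patientnumber", "PATID"],
        recodes=recodes,
        layouts={"tlfb": "wide_daily", "tlfb_other": "long"},
        date_format="%d%b%Y",
        withdrawal_instrument="SOWS",
        pain_instrument="EuroQoL",
        opiate_thresholds=[300],
        alcohol_mode="count",
        uds_substances=["AMP", "BZO", "MTD", "OXY", "COC", "MAMP",
                        "OPI300", "THC", "PPX", "BUP", "BAR", "MDMA"],
        tlfb_columns={
            "drinks": "alcohol", "heroin": "heroin",
            "opioid_analgesics": "opioid_analgesic",
            "buprenorphine": "buprenorphine", "ecstasy": "mdma",
            "barbiturates": "barbiturate", "benzodiazepine": "benzodiazepine",
            "thc": "thc", "cocaine": "cocaine", "crack": "crack",
            "inhalants": "inhalant", "methadone": "methadone",
            "amphetamine": "amphetamine",
        },
    )


def builtin_dialects() -> dict:
    return {
        "CTN-0027": ctn0027_dialect(),
        "CTN-0030": ctn0030_dialect(),
        "CTN-0051": ctn0051_dialect(),
    }


def meta_study_length_frame() -> pd.DataFrame:
    """Static per-arm timeline metadata (phase, stage, duration in weeks)."""
    rows = [
        ("CTN-0027", "Methadone", 1, "stabilization", 24),
        ("CTN-0027", "Outpatient BUP", 1, "stabilization", 24),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 1, "stabilization", 2),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 1, "taper", 2),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 1, "follow_up", 8),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 1, "stabilization", 2),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 1, "taper", 2),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 1, "follow_up", 8),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 2, "stabilization", 12),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 2, "taper", 4),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", 2, "follow_up", 8),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 2, "stabilization", 12),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 2, "taper", 4),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", 2, "follow_up", 8),
        ("CTN-0051", "Inpatient XR-NTX", 1, "stabilization", 24),
        ("CTN-0051", "Inpatient BUP", 1, "stabilization", 24),
    ]
    return pd.DataFrame(rows, columns=["project", "arm", "phase", "stage", "weeks"])


def meta_arms_frame() -> pd.DataFrame:
    """Treatment drug delivered in each randomization arm."""
    rows = [
        ("CTN-0027", "Methadone", "methadone"),
        ("CTN-0027", "Outpatient BUP", "buprenorphine"),
        ("CTN-0030", "Outpatient BUP + Standard Medical Management", "buprenorphine"),
        ("CTN-0030", "Outpatient BUP + Enhanced Medical Management", "buprenorphine"),
        ("CTN-0051", "Inpatient BUP", "buprenorphine"),
        ("CTN-0051", "Inpatient XR-NTX", "xr_ntx"),
    ]
    return pd.DataFrame(rows, columns=["project", "arm", "drug"])
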