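"""Free-text normalization: drug mentions and alcohol quantities.

Raw timeline-followback bundles contain free-text drug entries with typos
("extacy"), compound entries ("Vicodin/Percocet"), and superfluous dose
text ("adderall 5 mg").  This module canonicalizes those strings against a
shipped lexicon, maps canonical drugs onto harmonized categories, and
parses free-text daily alcohol quantities into standard drinks
(12 oz beer = 5 oz wine = 1.5 oz spirits = 1 drink).

The lexicon and the drink-equivalence table are data files shipped with
the package, not code: the hand-curated fixes they encode are content.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

_OZ_PER_DRINK = {"beer": 12.0, "wine": 5.0, "spirits": 1.5, "generic": None}
_GALLON_OZ = 128.0

_WORD_NUMBERS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "couple": 2, "couple of": 2,
}
#: quantity words that mean "a lot, unquantified"; coded as five drinks
_AMBIGUOUS_WORDS = ("many", "several", "lots of", "lots", "a lot of", "a lot",
                    "bunch of", "a bunch of", "some", "a few", "few")
AMBIGUOUS_DRINKS = 5.0

_DOSE_RE = re.compile(
    r"[-–—]*\s*\d+(?:\.\d+)?\s*(?:mg|mgs|mcg|ug|ml|milligrams?|grams?|g)\b"
    r"|[-–—]*\s*\d+\s*(?:tabs?|tablets?|pills?|caps?|capsules?|doses?)\b",
    re.IGNORECASE,
)
_SPLIT_RE = re.compile(r"\s*(?:/|,|;|&|\+|\band\b|\bwith\b)\s*", re.IGNORECASE)


def _load_pairs(name: str) -> dict:
    out = {}
    with resources.files("oudharmony.data").joinpath(name).open() as fh:
        for row in csv.DictReader(fh):
            vals = list(row.values())
            out[vals[0]] = tuple(vals[1:]) if len(vals) > 2 else vals[1]
    return out


class DrugLexicon:
    """Spelling variants, canonical tokens and category grouping."""

    def __init__(self, variants: dict | None = None, categories: dict | None = None):
        self.variants = variants or _load_pairs("drug_lexicon.csv")
        self.categories = categories or _load_pairs("drug_categories.csv")
        missing = set(self.variants.values()) - set(self.categories)
        if missing:
            raise ValueError(f"canonical tokens without a category: {sorted(missing)}")

    def canonical_tokens(self) -> set:
        return set(self.variants.values())


_DEFAULT_LEXICON: Optional[DrugLexicon] = None


def default_lexicon() -> DrugLexicon:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = DrugLexicon()
    return _DEFAULT_LEXICON


def canonicalize_drug(raw_text: str, lexicon: DrugLexicon | None = None) -> list:
    """Map a raw free-text drug entry to a list of canonical tokens.

    Compound entries split into one token per drug; dose/unit text is
    stripped; spelling variants resolve through the lexicon; anything left
    unrecognized yields the token ``"unknown"``.  Total function: never
    raises on string input.
    """
    lexicon = lexicon or default_lexicon()
    if raw_text is None:
        return []
    text = str(raw_text).strip().lower()
    if not text:
        return []
    tokens = []
    for piece in _SPLIT_RE.split(text):
        piece = _DOSE_RE.sub("", piece).strip(" .-–—\t")
        piece = re.sub(r"\s+", " ", piece)
        if not piece:
            continue
        hit = lexicon.variants.get(piece)
        if hit is None:
            # drop trailing plural 's' and leftover digits before giving up
            alt = re.sub(r"\d+", "", piece).strip()
            hit = lexicon.variants.get(alt) or lexicon.variants.get(alt.rstrip("s"))
        tokens.append(hit if hit is not None else "unknown")
    return tokens


def categorize_drug(token: str, lexicon: DrugLexicon | None = None) -> str:
    """Harmonized drug category for a canonical token."""
    lexicon = lexicon or default_lexicon()
    try:
        return lexicon.categories[token]
    except KeyError:
        raise KeyError(f"not a canonical drug token: {token!r}") from None


def collapse_daily(mentions: Iterable[tuple]) -> list:
    """Collapse same-day drug mentions into one record per category.

    ``mentions`` is an iterable of ``(who, when, category)`` triples sharing
    the same who and when (e.g. crack and powder cocaine on one day, or the
    same day surveyed at two visits).  Order of first appearance is kept.
    """
    seen, out = set(), []
    for who, when, category in mentions:
        key = (who, when, category)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


# ---------------------------------------------------------------------------
# alcohol quantities

@dataclass
class StandardDrinks:
    value: Optional[float]  # standard drinks for the day; None if unknown
    imputed: int = 0
    flag: Optional[str] = None  # 'missing' | 'unparseable' | 'ambiguous' | 'pattern-inconsistent'


class DrinkTable:
    """Beverage keywords and their per-unit standard-drink values."""

    def __init__(self, rows: dict | None = None):
        self.rows = rows or _load_pairs("drink_equivalents.csv")
        # longest keyword first so 'glass of wine' wins over 'wine'
        self.keywords = sorted(self.rows, key=len, reverse=True)

    def lookup(self, text: str):
        for kw in self.keywords:
            if re.search(rf"\b{re.escape(kw)}\b", text):
                beverage, per_unit = self.rows[kw]
                return kw, beverage, float(per_unit)
        return None


_DEFAULT_DRINKS: Optional[DrinkTable] = None


def default_drink_table() -> DrinkTable:
    global _DEFAULT_DRINKS
    if _DEFAULT_DRINKS is None:
        _DEFAULT_DRINKS = DrinkTable()
    return _DEFAULT_DRINKS


_FRACTION_RE = re.compile(r"(?:(\d+)\s+)?(\d+)\s*[/⁄]\s*(\d+)")
_PACK_RE = re.compile(r"(\d+)\s*[- ]?\s*(?:pk|pack|packs)\b")
_OZ_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(?:oz|ounce|ounces)\b")
_NUM_RE = re.compile(r"\d+(?:\.\d+)?")


def _leading_quantity(text: str):
    """Quantity at the start of a segment: fraction, decimal, int or word."""
    m = _FRACTION_RE.match(text)
    if m:
        whole = int(m.group(1)) if m.group(1) else 0
        return whole + int(m.group(2)) / int(m.group(3)), text[m.end():]
    m = re.match(r"\d+(?:\.\d+)?", text)
    if m:
        return float(m.group(0)), text[m.end():]
    for word in sorted(_AMBIGUOUS_WORDS, key=len, reverse=True):
        if text.startswith(word + " "):
            return "ambiguous", text[len(word):]
    for word, n in sorted(_WORD_NUMBERS.items(), key=lambda kv: -len(kv[0])):
        if text.startswith(word + " "):
            return float(n), text[len(word):]
    return None, text


def _segment_drinks(segment: str, table: DrinkTable):
    seg = segment.strip()
    if not seg:
        return None
    qty, rest = _leading_quantity(seg)
    rest = rest.strip()

    pack = _PACK_RE.search(seg)
    hit = table.lookup(seg)

    if qty == "ambiguous":
        return ("ambiguous", AMBIGUOUS_DRINKS) if hit else ("ambiguous", AMBIGUOUS_DRINKS)

    # gallon containers are spirits-sized: "1/2 gal. rum" = 64 oz of spirits
    gal = re.search(r"\bgal(?:lon|lons)?\b\.?|\bgal\.", seg)
    if gal is None:
        gal = re.search(r"\bgal\b", seg)
    if hit:
        kw, beverage, per_unit = hit
        if gal and beverage == "spirits":
            per_unit = _GALLON_OZ / _OZ_PER_DRINK["spirits"]
            return ("ok", (qty if qty is not None else 1.0) * per_unit)
        if beverage == "beer":
            oz = _OZ_RE.search(seg)
            if oz:
                per_unit = float(oz.group(1)) / _OZ_PER_DRINK["beer"]
            elif re.search(r"\bpints?\b", seg):
                per_unit = 16.0 / _OZ_PER_DRINK["beer"]
        if beverage == "wine" and re.search(r"\bbottle\b", seg):
            per_unit = 25.0 / _OZ_PER_DRINK["wine"]  # 750 ml bottle ~ 5 glasses
        if pack:
            n = float(pack.group(1))
            mult = qty if (qty is not None and qty != n) else 1.0
            return ("ok", mult * n * per_unit)
        return ("ok", (qty if qty is not None else 1.0) * per_unit)
    if qty is not None and re.search(r"\bpints?\b", seg):
        return ("ok", qty * 16.0 / _OZ_PER_DRINK["beer"])
    return None


def _round_drinks(total: float) -> float:
    """Round to the nearest integer when >= 10, else the nearest half drink."""
    if total >= 10:
        return float(int(total + 0.5))
    return int(total * 2 + 0.5) / 2.0


def parse_standard_drinks(raw_text: str, table: DrinkTable | None = None) -> StandardDrinks:
    """Deterministically convert a day's free-text drinking report to drinks.

    Fractions, counts, pack sizes, container sizes and conjunctions are
    parsed against the drink-equivalence table; ambiguous "many"-type
    phrases code to five standard drinks; unparseable non-empty text
    returns a missing value with a flag.  Totals round to the nearest
    integer at 10+ drinks and to the nearest half drink below that.
    """
    table = table or default_drink_table()
    if raw_text is None:
        return StandardDrinks(None, flag="missing")
    text = str(raw_text).strip().lower().replace("½", "1/2")
    if not text:
        return StandardDrinks(None, flag="missing")
    # keep numeric fractions intact through the conjunction split: "1/2" is
    # a quantity, not two clauses joined by "/"
    text = re.sub(r"(\d)\s*/\s*(\d)", r"\1⁄\2", text)
    total, ambiguous, parsed_any = 0.0, False, False
    for segment in _SPLIT_RE.split(text):
        res = _segment_drinks(segment, table)
        if res is None:
            continue
        status, value = res
        parsed_any = True
        total += value
        ambiguous = ambiguous or status == "ambiguous"
    if not parsed_any:
        # bare number means "N drinks" only when that is the whole string
        m = re.fullmatch(r"\d+(?:\.\d+)?", text)
        if m:
            return StandardDrinks(_round_drinks(float(m.group(0))))
        return StandardDrinks(None, flag="unparseable")
    return StandardDrinks(_round_drinks(total), flag="ambiguous" if ambiguous else None)


HEAVY_LIGHT_LINE = 4.0


def impute_missing_drink_amount(known_amounts: Iterable[float],
                                line: float = HEAVY_LIGHT_LINE) -> StandardDrinks:
    """Impute a missing drink amount from the subject's usual pattern.

    If every known amount falls on one side of the heavy/light line
    (consistently heavy: all > ``line``; consistently light: all <=
    ``line``), the subject's median known amount is imputed.  A mixed
    pattern, or no known amounts, stays missing with a flag.
    """
    amounts = sorted(float(a) for a in known_amounts if a is not None)
    if not amounts:
        return StandardDrinks(None, flag="missing")
    heavy = [a > line for a in amounts]
    if all(heavy) or not any(heavy):
        n = len(amounts)
        mid = n // 2
        median = amounts[mid] if n % 2 else (amounts[mid - 1] + amounts[mid]) / 2.0
        return StandardDrinks(median, imputed=1)
    return StandardDrinks(None, flag="pattern-inconsistent")
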