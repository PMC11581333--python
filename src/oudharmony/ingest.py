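"""Reading raw per-study bundles and standardizing identifiers and codes.

Each study speaks its own dialect: its own subject-ID column names (seven
spellings exist across the three studies), its own categorical codings
(the same parole answer is code "2" in one study and "1" in another), its
own date format, and its own table layouts (long rows vs wide daily
grids).  A :class:`DialectSpec` declares those conventions; ingestion
resolves them into provisional long-form records keyed by a synthetic
``who`` assigned in deterministic first-seen order.

Raw tables are read as strings; typing happens only after recoding, so
date typos and free text survive intact for the cleaning rules.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .schema import CorrectionEntry, ID_ALIASES

RULE_EXACT_DUP = "ingest.exact_duplicate_row"


class DialectError(ValueError):
    pass


class RecodeError(ValueError):
    pass


@dataclass
class DialectSpec:
    """Declarative description of one study's raw-data conventions."""

    project: str
    id_aliases: list
    recodes: dict = field(default_factory=dict)   # "table.column" -> {raw: harmonized}
    layouts: dict = field(default_factory=dict)   # table -> long | wide_daily
    date_format: str = "%Y-%m-%d"
    withdrawal_instrument: str = "COWS"
    pain_instrument: str = "SF36"
    opiate_thresholds: list = field(default_factory=lambda: [300, 2000])
    uds_substances: list = field(default_factory=list)
    tlfb_columns: dict = field(default_factory=dict)  # structured column -> canonical token
    #: how daily alcohol quantity is recorded: free "text", a numeric
    #: "count" of standard drinks, or a "binary" any-drinking indicator
    alcohol_mode: str = "binary"

    def __post_init__(self):
        if not self.id_aliases:
            raise DialectError("id_aliases must be non-empty")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DialectSpec":
        return cls(**json.loads(text))

    def parse_date(self, value: str) -> Optional[date]:
        if value is None or str(value).strip() == "":
            return None
        return datetime.strptime(str(value).strip(), self.date_format).date()

    def format_date(self, d: date) -> str:
        return d.strftime(self.date_format)


@dataclass
class RawBundle:
    """One study's raw tables (string-valued) plus its dialect."""

    project: str
    tables: dict
    dialect: DialectSpec


def read_bundle(directory: str | Path) -> RawBundle:
    directory = Path(directory)
    dialect = DialectSpec.from_json((directory / "dialect.json").read_text())
    tables = {}
    for path in sorted(directory.glob("*.csv")):
        tables[path.stem] = pd.read_csv(path, dtype=str, keep_default_na=False)
    return RawBundle(dialect.project, tables, dialect)


def write_bundle(bundle: RawBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "dialect.json").write_text(bundle.dialect.to_json())
    for name, df in bundle.tables.items():
        df.to_csv(directory / f"{name}.csv", index=False)


# ---------------------------------------------------------------------------
# subject identifiers

def find_id_column(df: pd.DataFrame, aliases: Iterable[str], table: str) -> str:
    """The single recognizable subject-ID column; ambiguity is an error."""
    hits = [c for c in df.columns if c in set(aliases)]
    if len(hits) != 1:
        raise DialectError(
            f"table {table!r} must carry exactly one subject-ID column; "
            f"found {hits or 'none'} among aliases {list(aliases)}")
    return hits[0]


def resolve_subject_ids(bundle: RawBundle, who_start: int = 1,
                        id_table: str = "screening"):
    """Key every table by a synthetic ``who``; return (bundle, id_map, next).

    ``who`` is assigned in first-appearance order of the raw IDs in the
    screening table (projects are processed in sorted order by the caller,
    so assignment is deterministic across the merged database).  Raw IDs
    are retained as ``raw_id``.
    """
    aliases = list(bundle.dialect.id_aliases) + list(ID_ALIASES)
    order: dict[str, int] = {}
    id_col = find_id_column(bundle.tables[id_table], aliases, id_table)
    for raw in bundle.tables[id_table][id_col]:
        if raw not in order:
            order[raw] = who_start + len(order)
    out_tables = {}
    for name, df in bundle.tables.items():
        col = find_id_column(df, aliases, name)
        df = df.rename(columns={col: "raw_id"})
        unknown = set(df["raw_id"]) - set(order)
        if unknown:
            raise DialectError(
                f"table {name!r} has raw IDs absent from {id_table}: {sorted(unknown)[:5]}")
        df.insert(0, "who", df["raw_id"].map(order))
        out_tables[name] = df
    id_map = pd.DataFrame(
        {"who": list(order.values()), "raw_id": list(order.keys())}
    ).sort_values("who", ignore_index=True)
    return RawBundle(bundle.project, out_tables, bundle.dialect), id_map, who_start + len(order)


# ---------------------------------------------------------------------------
# categorical recoding

def drop_exact_duplicates(bundle: RawBundle):
    """Exact duplicate raw rows carry no information; drop with an audit entry."""
    corrections = []
    tables = {}
    for name, df in bundle.tables.items():
        dup = df.duplicated()
        if dup.any():
            for _, row in df[dup].iterrows():
                corrections.append(CorrectionEntry(
                    row.get("who", row.get("raw_id")), name, "row",
                    "exact duplicate", "dropped", RULE_EXACT_DUP, ""))
            df = df[~dup].reset_index(drop=True)
        tables[name] = df
    return RawBundle(bundle.project, tables, bundle.dialect), corrections


def recode_categoricals(bundle: RawBundle):
    """Apply the dialect's recode maps so identical concepts carry identical
    codes across projects.  Observed codes missing from the map are an
    error — never guessed.  Returns (bundle, corrections).
    """
    corrections = []
    errors = []
    tables = dict(bundle.tables)
    for key, mapping in bundle.dialect.recodes.items():
        table, column = key.split(".", 1)
        if table not in tables or column not in tables[table].columns:
            continue
        df = tables[table].copy()
        observed = set(df[column].unique()) - {""}
        unmapped = observed - set(mapping)
        if unmapped:
            errors.append((bundle.project, table, column, sorted(unmapped)))
            continue
        df[column] = df[column].map(lambda v: mapping.get(v, None) if v != "" else None)
        for raw, harm in sorted(mapping.items()):
            if raw in observed and str(raw) != str(harm):
                corrections.append(CorrectionEntry(
                    None, table, column, raw, harm, "recode.dialect",
                    f"{bundle.project} dialect code harmonized"))
        tables[table] = df
    if errors:
        msgs = "; ".join(f"{p} {t}.{c}: unmapped codes {u}" for p, t, c, u in errors)
        raise RecodeError(msgs)
    return RawBundle(bundle.project, tables, bundle.dialect), corrections


# ---------------------------------------------------------------------------
# wide daily grids

_DAY_COL_RE = re.compile(r"^(?P<stem>.+)_d(?P<k>\d+)$")


def melt_wide_daily(row, start_when: int):
    """One event per positive day cell of a wide grid row.

    ``row`` maps column names to cell values; columns named ``<stem>_d<k>``
    hold day ``start_when + k - 1``.  Cells that are empty, zero or
    negative emit nothing.  Returns ``[(when, stem), ...]`` in column
    order.
    """
    events = []
    for col, value in row.items():
        m = _DAY_COL_RE.match(str(col))
        if not m:
            continue
        k = int(m.group("k"))
        if k < 1:
            raise DialectError(f"unparseable day column {col!r}")
        try:
            positive = float(value) > 0
        except (TypeError, ValueError):
            positive = str(value).strip() not in ("", "0")
        if positive:
            events.append((start_when + k - 1, m.group("stem")))
    return events
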