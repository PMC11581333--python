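"""Serialization: one CSV per table, codebook.json, and a manifest."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .schema import (HarmonizedDatabase, emit_codebook, parse_codebook,
                     register_schema)


def write_database(db: HarmonizedDatabase, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"tables": {}}
    for name, df in db.tables.items():
        df.to_csv(directory / f"{name}.csv", index=False)
        manifest["tables"][name] = {"rows": int(len(df)),
                                    "columns": list(df.columns)}
    (directory / "codebook.json").write_text(json.dumps(emit_codebook(db), indent=1))
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if db.audit_log:
        audit = pd.DataFrame([e.__dict__ for e in db.audit_log])
        audit.to_csv(directory / "audit_log.csv", index=False)


def read_database(directory) -> HarmonizedDatabase:
    directory = Path(directory)
    codebook_path = directory / "codebook.json"
    registry = (parse_codebook(json.loads(codebook_path.read_text()))
                if codebook_path.exists() else register_schema())
    db = HarmonizedDatabase(registry=registry)
    for name in registry:
        path = directory / f"{name}.csv"
        if path.exists():
            db.tables[name] = pd.read_csv(path)
    return db
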