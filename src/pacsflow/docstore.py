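"""Per-profile metadata collections on an embedded document store.

Each extraction profile maps to one collection; a document is the PHI-free
attribute map of one series.  Backed by SQLite (single file, transactional),
with the upsert keyed by (profile, series_uid) — re-writing a document after
a crash is harmless, which is what makes at-least-once extraction show
exactly-once effects.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path
from typing import Iterator


class DocumentStore:
    def __init__(self, path: Path | str = ":memory:"):
        self.path = str(path)
        if self.path != ":memory:":
            Path(self.path).parent.mkdir(parents=True, exist_ok=True)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute(
            """CREATE TABLE IF NOT EXISTS documents (
                   profile TEXT NOT NULL,
                   series_uid TEXT NOT NULL,
                   receipt_time TEXT,
                   values_json TEXT NOT NULL,
                   PRIMARY KEY (profile, series_uid)
               )"""
        )
        self._conn.commit()

    def upsert(self, profile: str, series_uid: str, values: dict,
               receipt_time: str | None = None) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO documents VALUES (?, ?, ?, ?)",
            (profile, series_uid, receipt_time,
             json.dumps(values, separators=(",", ":"))),
        )
        self._conn.commit()

    def get(self, profile: str, series_uid: str) -> dict | None:
        row = self._conn.execute(
            "SELECT values_json FROM documents WHERE profile=? AND series_uid=?",
            (profile, series_uid),
        ).fetchone()
        return json.loads(row[0]) if row else None

    def count(self, profile: str) -> int:
        (n,) = self._conn.execute(
            "SELECT COUNT(*) FROM documents WHERE profile=?", (profile,)
        ).fetchone()
        return n

    def iter_documents(self, profile: str) -> Iterator[tuple[str, dict, str | None]]:
        """Yield (series_uid, values, receipt_time) for one collection."""
        cursor = self._conn.execute(
            "SELECT series_uid, values_json, receipt_time FROM documents "
            "WHERE profile=? ORDER BY series_uid",
            (profile,),
        )
        for series_uid, values_json, receipt in cursor:
            yield series_uid, json.loads(values_json), receipt

    def distinct_series(self, profile: str) -> set[str]:
        cursor = self._conn.execute(
            "SELECT series_uid FROM documents WHERE profile=?", (profile,)
        )
        return {row[0] for row in cursor}

    def profiles(self) -> list[str]:
        cursor = self._conn.execute("SELECT DISTINCT profile FROM documents")
        return sorted(row[0] for row in cursor)

    def close(self) -> None:
        self._conn.close()
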