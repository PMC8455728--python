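"""Newline-delimited UID-set state files with atomic replace.

Shared by the metadata extractor and the storage cleaner: progress is a
handful of named sets of series UIDs, written whole and renamed into place
so a crash never leaves a torn file.
"""

from __future__ import annotations

import os
from pathlib import Path


class CorruptStateError(RuntimeError):
    """State file unreadable; rebuild from the document store."""


def write_uid_set(path: Path | str, uids: set[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text("".join(f"{u}\n" for u in sorted(uids)))
    os.replace(tmp, path)


def read_uid_set(path: Path | str) -> set[str]:
    """Load a set; a missing file is the empty state (cold start)."""
    path = Path(path)
    if not path.exists():
        return set()
    try:
        lines = path.read_text(encoding="utf-8").splitlines()
    except (UnicodeDecodeError, OSError) as exc:
        raise CorruptStateError(
            f"state file {path} is unreadable ({exc}); rebuild the extracted "
            "sets from the document store (series present in collections are "
            "re-marked extracted)"
        ) from exc
    uids = set()
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if any(ch in line for ch in "\x00") or not line.isprintable():
            raise CorruptStateError(
                f"state file {path} contains non-text content; rebuild from "
                "the document store"
            )
        uids.add(line)
    return uids
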