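"""Storage lifecycle: nightly cleanup with safety interlocks.

Research-store disk is a staging area, not an archive: once a series'
metadata sits in every active collection, its images can go.  The cleaner
deletes exactly the series that are (a) extracted for ALL active profiles,
(b) not registered in the holds file by a still-running consumer, and
(c) past a retention floor since receipt.  Deleted-series progress is a
durable UID set, so the nightly run is idempotent and crash-tolerant.
"""

from __future__ import annotations

import logging
import threading
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Callable, Iterable

from ._statefiles import CorruptStateError, read_uid_set, write_uid_set
from .ingestion import IngestionIndex
from .metadata import ExtractionState

log = logging.getLogger(__name__)

#: Default nightly cleanup time (local clock).
DEFAULT_CLEANUP_TIME = time(23, 59)

#: Minimum age since receipt before a series may be deleted.
DEFAULT_RETENTION = timedelta(days=1)

DELETED_STATE_FILE = "deleted.txt"


def persist_state(state: dict[str, set[str]], directory: Path | str) -> None:
    """Write named UID sets as newline-delimited files (atomic replace)."""
    for name, uids in state.items():
        write_uid_set(Path(directory) / f"{name}.txt", uids)


def load_state(directory: Path | str) -> dict[str, set[str]]:
    """Load every UID-set file; a missing directory is the empty state."""
    directory = Path(directory)
    if not directory.exists():
        return {}
    return {p.stem: read_uid_set(p) for p in sorted(directory.glob("*.txt"))}


@dataclass
class DeletionReport:
    deleted: list[str] = field(default_factory=list)
    kept_pending: int = 0
    kept_held: int = 0
    kept_recent: int = 0
    errors: list[str] = field(default_factory=list)

    @property
    def n_deleted(self) -> int:
        return len(self.deleted)


def clear_storage(
    now: datetime,
    extraction_state: ExtractionState,
    index: IngestionIndex,
    storage_root: Path | str,
    *,
    holds: frozenset[str] | set[str] = frozenset(),
    retention: timedelta = DEFAULT_RETENTION,
    state_dir: Path | str | None = None,
    active_profiles: Iterable[str] | None = None,
) -> DeletionReport:
    """Delete series whose metadata is fully extracted and safe to drop.

    A series survives if ANY active profile has not extracted it, if any
    consumer holds it, or if it is younger than the retention floor.  With
    no active profiles nothing is deleted — "extracted for all profiles"
    must never be vacuously true.  A failure on one series is logged and
    the rest proceed; progress is persisted so a re-run deletes nothing
    twice.  Empty parent directories are pruned.
    """
    storage_root = Path(storage_root)
    profiles = list(active_profiles if active_profiles is not None
                    else extraction_state.extracted)
    deleted_path = (Path(state_dir) / DELETED_STATE_FILE) if state_dir else None
    already_deleted = read_uid_set(deleted_path) if deleted_path else set()
    report = DeletionReport()
    if not profiles:
        log.warning("no active profiles; refusing to delete anything")
        return report
    for series_uid, records in sorted(index.by_series().items()):
        if series_uid in already_deleted:
            continue
        if not all(series_uid in extraction_state.extracted_for(p)
                   for p in profiles):
            report.kept_pending += 1
            continue
        if series_uid in holds:
            report.kept_held += 1
            continue
        latest_receipt = max(datetime.fromisoformat(r.receipt_time)
                             for r in records)
        if now - latest_receipt < retention:
            report.kept_recent += 1
            continue
        paths = [storage_root / r.path for r in records]
        if not any(p.exists() for p in paths):
            # files already gone (crash after delete, before persist)
            already_deleted.add(series_uid)
            continue
        try:
            for path in paths:
                path.unlink(missing_ok=True)
                _prune_empty_dirs(path.parent, storage_root)
        except OSError as exc:
            log.error("deletion failed for series %s: %s", series_uid, exc)
            report.errors.append(series_uid)
            continue
        already_deleted.add(series_uid)
        report.deleted.append(series_uid)
        if deleted_path:
            write_uid_set(deleted_path, already_deleted)
    if deleted_path:
        write_uid_set(deleted_path, already_deleted)
    return report


def _prune_empty_dirs(directory: Path, stop: Path) -> None:
    while directory != stop and directory.is_dir() and not any(directory.iterdir()):
        directory.rmdir()
        directory = directory.parent


def next_cleanup_instant(now: datetime, at: time = DEFAULT_CLEANUP_TIME) -> datetime:
    """The next occurrence of the nightly cleanup time after ``now``."""
    candidate = datetime.combine(now.date(), at)
    if candidate <= now:
        candidate += timedelta(days=1)
    return candidate


def run_periodic(
    task: Callable[[], object],
    interval_s: float,
    stop: threading.Event,
    *,
    run_immediately: bool = True,
) -> None:
    """Run ``task`` every ``interval_s`` seconds until ``stop`` is set.

    The interval clock starts when the task returns; errors are logged and
    the loop continues — one bad cycle must not kill the daemon.
    """
    if run_immediately:
        _run_once(task)
    while not stop.wait(interval_s):
        _run_once(task)


def _run_once(task: Callable[[], object]) -> None:
    try:
        task()
    except Exception:  # noqa: BLE001 - daemon loop survives bad cycles
        log.exception("periodic task failed; continuing")
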