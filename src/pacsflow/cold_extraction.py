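"""On-demand (cold) extraction: CSV query lists -> C-FIND/C-MOVE batches.

A researcher hands over a CSV of identifiers in one of four shapes —
a patient list (EMPI), patient+accession, accession only, or
patient+study-date — and the retriever expands each row into a STUDY-level
query against the PACS, one C-MOVE per matching study, with bounded
retries, a failures CSV, and per-query progress persisted so a halted run
resumes exactly where it stopped without re-sending completed queries.
"""

from __future__ import annotations

import csv
import logging
import os
import time as time_mod
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from pydicom import Dataset

from .dimse import STATUS_SUCCESS

log = logging.getLogger(__name__)


class QueryShape(str, Enum):
    EMPI = "EMPI"
    EMPI_ACCESSION = "EMPI_ACCESSION"
    ACCESSION = "ACCESSION"
    EMPI_STUDYDATE = "EMPI_STUDYDATE"


#: CSV header columns expected for each shape (matched case-insensitively).
SHAPE_COLUMNS: dict[QueryShape, tuple[str, ...]] = {
    QueryShape.EMPI: ("EMPI",),
    QueryShape.EMPI_ACCESSION: ("EMPI", "Accession"),
    QueryShape.ACCESSION: ("Accession",),
    QueryShape.EMPI_STUDYDATE: ("EMPI", "StudyDate"),
}


class QueryShapeError(ValueError):
    """CSV header does not match the declared query shape."""


@dataclass(frozen=True)
class QuerySpec:
    """One retrieval request; fields present iff the shape requires them."""

    shape: QueryShape
    empi: str | None = None
    accession: str | None = None
    study_date: str | None = None

    def __post_init__(self) -> None:
        needs = {
            QueryShape.EMPI: ("empi",),
            QueryShape.EMPI_ACCESSION: ("empi", "accession"),
            QueryShape.ACCESSION: ("accession",),
            QueryShape.EMPI_STUDYDATE: ("empi", "study_date"),
        }[self.shape]
        for name in ("empi", "accession", "study_date"):
            value = getattr(self, name)
            if name in needs and not value:
                raise ValueError(f"shape {self.shape.value} requires {name}")
            if name not in needs and value:
                raise ValueError(f"shape {self.shape.value} forbids {name}")

    @property
    def key(self) -> str:
        parts = [self.shape.value, self.empi or "", self.accession or "",
                 self.study_date or ""]
        return ":".join(parts)


def parse_query_csv(file: Path | str, declared_shape: QueryShape) -> list[QuerySpec]:
    """Parse a user query CSV into specs.

    The header row must match the declared shape's columns (any order is
    rejected — the shapes are positional contracts).  Duplicate rows
    collapse to one spec; malformed rows are logged with their 1-based row
    number and skipped.  An empty file yields an empty list.
    """
    path = Path(file)
    expected = SHAPE_COLUMNS[declared_shape]
    text = path.read_text()
    if not text.strip():
        return []
    rows = list(csv.reader(text.splitlines()))
    header = [c.strip() for c in rows[0]]
    if [c.lower() for c in header] != [c.lower() for c in expected]:
        raise QueryShapeError(
            f"header {header} does not match shape {declared_shape.value}; "
            f"expected columns {list(expected)}"
        )
    specs: dict[str, QuerySpec] = {}
    for row_no, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        values = [cell.strip() for cell in row]
        if len(values) != len(expected) or not all(values):
            log.warning("%s row %d malformed: %r", path.name, row_no, row)
            continue
        fields = dict(zip([c.lower() for c in expected], values))
        spec = QuerySpec(
            shape=declared_shape,
            empi=fields.get("empi"),
            accession=fields.get("accession"),
            study_date=fields.get("studydate"),
        )
        specs.setdefault(spec.key, spec)
    return list(specs.values())


def to_find_identifier(spec: QuerySpec) -> Dataset:
    """STUDY-level Study-Root identifier for a spec.

    EMPI maps to PatientID (matching all studies of the patient),
    accession to AccessionNumber, study date to an exact StudyDate;
    StudyInstanceUID is requested as a return key for the follow-up move.
    """
    identifier = Dataset()
    identifier.QueryRetrieveLevel = "STUDY"
    identifier.StudyInstanceUID = ""
    if spec.empi is not None:
        identifier.PatientID = spec.empi
    if spec.accession is not None:
        identifier.AccessionNumber = spec.accession
    if spec.study_date is not None:
        identifier.StudyDate = spec.study_date
    return identifier


class RetrievalProgress:
    """Durable per-query progress: completed keys and attempt counts.

    Stored as newline-delimited text files updated by atomic rename, so a
    crash at any point leaves a consistent snapshot.  Attempt counts are
    persisted *before* the query is issued: across any crash/restart
    sequence a spec reaches the PACS at most (1 + max_retries) times.
    """

    def __init__(self, directory: Path | str):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.completed: set[str] = set()
        self.attempts: dict[str, int] = {}
        self.last_status: dict[str, str] = {}
        self._load()

    def _file(self, name: str) -> Path:
        return self.directory / name

    def _load(self) -> None:
        done = self._file("completed.txt")
        if done.exists():
            self.completed = {ln for ln in done.read_text().splitlines() if ln}
        att = self._file("attempts.tsv")
        if att.exists():
            for line in att.read_text().splitlines():
                if line:
                    key, count, status = line.split("\t")
                    self.attempts[key] = int(count)
                    self.last_status[key] = status
    def persist(self) -> None:
        _atomic_write(self._file("completed.txt"),
                      "".join(f"{k}\n" for k in sorted(self.completed)))
        _atomic_write(self._file("attempts.tsv"),
                      "".join(f"{k}\t{n}\t{self.last_status.get(k, '')}\n"
                              for k, n in sorted(self.attempts.items())))

    def mark_attempt(self, key: str, status: str = "") -> int:
        self.attempts[key] = self.attempts.get(key, 0) + 1
        self.last_status[key] = status
        self.persist()
        return self.attempts[key]

    def mark_completed(self, key: str) -> None:
        self.completed.add(key)
        self.persist()


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


@dataclass
class RetrievalReport:
    n_completed: int = 0
    n_failed: int = 0
    n_no_match: int = 0
    n_skipped: int = 0
    n_studies_retrieved: int = 0
    no_match_keys: list[str] = field(default_factory=list)
    failed_keys: list[str] = field(default_factory=list)


def run_batch_retrieval(
    specs: Sequence[QuerySpec],
    pacs,
    dest_ae: str,
    progress: RetrievalProgress,
    *,
    max_retries: int = 2,
    inter_query_delay: float = 0.0,
    failures_csv: Path | str | None = None,
) -> RetrievalReport:
    """Run the C-FIND / C-MOVE batch for every spec not yet completed.

    For each pending spec: C-FIND enumerates matching studies, then one
    C-MOVE per study to ``dest_ae``.  Any move failure retries the whole
    spec (re-sent instances are idempotent at the listener) up to
    ``max_retries`` extra attempts; terminal failures go to the failures
    CSV.  A spec with zero C-FIND matches completes with a "no-match" flag
    — an empty result is not an error.  Queries run sequentially with an
    optional inter-query delay; PACS-side throttling is the server's job.
    """
    report = RetrievalReport()
    for spec in specs:
        key = spec.key
        if key in progress.completed:
            report.n_skipped += 1
            continue
        if progress.attempts.get(key, 0) >= 1 + max_retries:
            _record_failure(report, progress, key, failures_csv)
            continue
        identifier = to_find_identifier(spec)
        done = False
        while not done and progress.attempts.get(key, 0) < 1 + max_retries:
            progress.mark_attempt(key)
            studies = pacs.c_find(identifier)
            if not studies:
                progress.last_status[key] = "no-match"
                progress.mark_completed(key)
                report.n_completed += 1
                report.n_no_match += 1
                report.no_match_keys.append(key)
                done = True
                break
            all_ok = True
            for study in studies:
                move_id = Dataset()
                move_id.QueryRetrieveLevel = "STUDY"
                move_id.StudyInstanceUID = study.StudyInstanceUID
                result = pacs.c_move(move_id, dest_ae)
                if result.status != STATUS_SUCCESS:
                    all_ok = False
                    progress.last_status[key] = f"0x{result.status:04X}"
                    break
                report.n_studies_retrieved += 1
            if all_ok:
                progress.last_status[key] = "success"
                progress.mark_completed(key)
                report.n_completed += 1
                done = True
            else:
                progress.persist()
            if inter_query_delay:
                time_mod.sleep(inter_query_delay)
        if not done:
            _record_failure(report, progress, key, failures_csv)
    return report


def _record_failure(report: RetrievalReport, progress: RetrievalProgress,
                    key: str, failures_csv: Path | str | None) -> None:
    report.n_failed += 1
    report.failed_keys.append(key)
    if failures_csv is not None:
        path = Path(failures_csv)
        new = not path.exists()
        with open(path, "a", newline="") as fh:
            writer = csv.writer(fh)
            if new:
                writer.writerow(["key", "attempts", "last_status"])
            writer.writerow([key, progress.attempts.get(key, 0),
                             progress.last_status.get(key, "")])
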