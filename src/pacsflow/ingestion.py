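"""Real-time ingestion: storage listeners, hierarchical filing, durable index.

One listener per configured source accepts C-STORE, files each instance
into a patient/study/series hierarchy, and appends an :class:`InstanceRecord`
— identifiers, storage path, raw header timestamps and the receipt instant
assigned by the listener's own clock — to a newline-delimited JSON index.
The index, not filesystem mtimes, is the durable record of receipt times:
mtimes do not survive copies.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass, asdict, field
from datetime import datetime
from enum import Enum
from pathlib import Path, PurePosixPath
from typing import Callable, Iterable

from pydicom import Dataset, dcmread
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .dimse import DimseNetwork, STATUS_PROCESSING_FAILURE, STATUS_SUCCESS

log = logging.getLogger(__name__)

UNKNOWN_BUCKET = "UNKNOWN"

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9.\-]")


class FolderDepth(str, Enum):
    PATIENT = "patient"
    PATIENT_STUDY = "patient/study"
    PATIENT_STUDY_SERIES = "patient/study/series"


@dataclass(frozen=True)
class SourceConfig:
    """One configured image source (PACS feed) with its own port and root."""

    name: str
    ae_title: str
    port: int
    storage_root: Path
    folder_depth: FolderDepth = FolderDepth.PATIENT_STUDY_SERIES


@dataclass
class InstanceRecord:
    """Index entry for one stored instance.

    ``receipt_time`` is stamped by the listener at store time — never read
    from headers — so it reflects the research-cluster clock, the reference
    against which scanner clock skew is measured.  Header date/time fields
    are kept as raw DICOM DA/TM strings; parsing is the analytics layer's
    concern.
    """

    sop_uid: str
    series_uid: str
    study_uid: str
    patient_id: str
    accession: str
    path: str
    receipt_time: str  # ISO-8601
    acquisition_date: str = ""
    acquisition_time: str = ""
    series_date: str = ""
    series_time: str = ""
    content_date: str = ""
    content_time: str = ""
    station_name: str = ""
    device_serial: str = ""
    modality: str = ""
    body_part: str = ""
    instance_number: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), separators=(",", ":"))

    @classmethod
    def from_json(cls, line: str) -> "InstanceRecord":
        return cls(**json.loads(line))


def sanitize_component(value: str) -> str:
    """Filesystem-safe path component: anything outside [A-Za-z0-9.-] -> '_'."""
    return _SANITIZE_RE.sub("_", value)


def resolve_storage_path(
    patient_id: str,
    study_uid: str,
    series_uid: str,
    sop_uid: str,
    folder_depth: FolderDepth = FolderDepth.PATIENT_STUDY_SERIES,
) -> PurePosixPath:
    """Deterministic relative path for an instance at the configured depth.

    Missing patient/study/series identifiers fall into an ``UNKNOWN``
    bucket (real scanners emit incomplete headers); a missing SOP instance
    UID is an error — an unidentifiable instance cannot be filed.
    """
    sop = sanitize_component(sop_uid)
    if not sop:
        raise ValueError("sop_uid empty after sanitization; cannot file instance")
    parts = [sanitize_component(patient_id) or UNKNOWN_BUCKET]
    if folder_depth in (FolderDepth.PATIENT_STUDY, FolderDepth.PATIENT_STUDY_SERIES):
        parts.append(sanitize_component(study_uid) or UNKNOWN_BUCKET)
    if folder_depth is FolderDepth.PATIENT_STUDY_SERIES:
        parts.append(sanitize_component(series_uid) or UNKNOWN_BUCKET)
    return PurePosixPath(*parts, f"{sop}.dcm")


class IngestionIndex:
    """Append-only newline-delimited JSON index of stored instances.

    Appends are flushed and fsynced line-by-line; on load, later lines for
    the same SOP instance UID win (re-stores update, never duplicate)."""

    def __init__(self, path: Path | str):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def append(self, record: InstanceRecord) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(record.to_json() + "\n")
            fh.flush()
            os.fsync(fh.fileno())

    def load(self) -> list[InstanceRecord]:
        if not self.path.exists():
            return []
        records = []
        for line in self.path.read_text().splitlines():
            if line.strip():
                records.append(InstanceRecord.from_json(line))
        return records

    def by_sop(self) -> dict[str, InstanceRecord]:
        return {r.sop_uid: r for r in self.load()}

    def by_series(self) -> dict[str, list[InstanceRecord]]:
        grouped: dict[str, list[InstanceRecord]] = {}
        for record in self.by_sop().values():
            grouped.setdefault(record.series_uid, []).append(record)
        return grouped


def record_from_dataset(ds: Dataset, path: str, receipt_time: datetime) -> InstanceRecord:
    number = ds.get("InstanceNumber")
    return InstanceRecord(
        sop_uid=str(ds.SOPInstanceUID),
        series_uid=str(ds.get("SeriesInstanceUID", "")),
        study_uid=str(ds.get("StudyInstanceUID", "")),
        patient_id=str(ds.get("PatientID", "")),
        accession=str(ds.get("AccessionNumber", "")),
        path=path,
        receipt_time=receipt_time.isoformat(),
        acquisition_date=str(ds.get("AcquisitionDate", "")),
        acquisition_time=str(ds.get("AcquisitionTime", "")),
        series_date=str(ds.get("SeriesDate", "")),
        series_time=str(ds.get("SeriesTime", "")),
        content_date=str(ds.get("ContentDate", "")),
        content_time=str(ds.get("ContentTime", "")),
        station_name=str(ds.get("StationName", "")),
        device_serial=str(ds.get("DeviceSerialNumber", "")),
        modality=str(ds.get("Modality", "")),
        body_part=str(ds.get("BodyPartExamined", "")),
        instance_number=int(number) if number is not None else None,
    )


class StorageListener:
    """A storage service-class provider for one source.

    Every accepted C-STORE produces exactly one Part 10 file at the
    resolved path (written to a temp name, then atomically renamed — a
    crash mid-store leaves no partial file) and one index record.
    Re-storing the same SOP instance overwrites the file and appends an
    updated record; last-write-wins at load time keeps counts honest after
    C-MOVE retries.
    """

    def __init__(
        self,
        config: SourceConfig,
        network: DimseNetwork,
        clock: Callable[[], datetime] | None = None,
        index: IngestionIndex | None = None,
        on_store: Callable[[InstanceRecord], None] | None = None,
    ):
        self.config = config
        self.ae_title = config.ae_title
        self.network = network
        self._clock = clock or datetime.now
        # per-arrival trigger: extractors can react to each image instead of
        # (or in addition to) interval polling
        self._on_store = on_store
        self.storage_root = Path(config.storage_root)
        self.storage_root.mkdir(parents=True, exist_ok=True)
        self.index = index or IngestionIndex(self.storage_root / "ingestion_index.ndjson")
        network.register(self)

    def c_store(self, ds: Dataset) -> int:
        try:
            sop_uid = str(ds.SOPInstanceUID)
            rel = resolve_storage_path(
                str(ds.get("PatientID", "")),
                str(ds.get("StudyInstanceUID", "")),
                str(ds.get("SeriesInstanceUID", "")),
                sop_uid,
                self.config.folder_depth,
            )
        except (AttributeError, ValueError) as exc:
            log.error("rejecting malformed dataset: %s", exc)
            return STATUS_PROCESSING_FAILURE
        target = self.storage_root / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        tmp = target.with_suffix(".dcm.part")
        try:
            if not getattr(ds, "file_meta", None):
                ds.file_meta = _minimal_file_meta(ds)
            ds.save_as(tmp, enforce_file_format=True)
            os.replace(tmp, target)
        except Exception as exc:  # unwritable path, encoding failure
            log.error("store failed for %s: %s", sop_uid, exc)
            tmp.unlink(missing_ok=True)
            return STATUS_PROCESSING_FAILURE
        record = record_from_dataset(ds, str(rel), self._clock())
        self.index.append(record)
        if self._on_store is not None:
            self._on_store(record)
        return STATUS_SUCCESS

    def stop(self) -> None:
        self.network.unregister(self.ae_title)

    def reconcile(self) -> int:
        """Startup sweep: index any on-disk file the index does not know.

        Covers the crash window between file rename and index append; the
        re-created record gets a fresh receipt time (the true one was lost
        with the crash)."""
        known = set(self.index.by_sop())
        swept = 0
        for path in self.storage_root.rglob("*.dcm"):
            ds = dcmread(path, stop_before_pixels=True)
            if str(ds.SOPInstanceUID) not in known:
                rel = path.relative_to(self.storage_root)
                self.index.append(record_from_dataset(ds, str(rel), self._clock()))
                swept += 1
        return swept


def _minimal_file_meta(ds: Dataset) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def start_listener(
    config: SourceConfig,
    network: DimseNetwork,
    clock: Callable[[], datetime] | None = None,
) -> StorageListener:
    """Bring up the storage listener for one source and register its AE."""
    return StorageListener(config, network, clock=clock)


def validate_sources(configs: Iterable[SourceConfig]) -> None:
    """Ports (and AE titles) must be unique across configured sources."""
    ports: dict[int, str] = {}
    for cfg in configs:
        if cfg.port in ports:
            raise ValueError(
                f"port {cfg.port} used by both {ports[cfg.port]!r} and {cfg.name!r}"
            )
        ports[cfg.port] = cfg.name
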