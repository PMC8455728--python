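"""Synthetic multi-scanner DICOM fleet and embedded mock PACS.

Emulates the clinical side of the pipeline: a fleet of scanners, each with
its own (possibly miscalibrated) clock, performing non-overlapping exams
over a working day, producing multi-series multi-instance studies with tiny
pixel payloads. The generated archive can then be served through
:class:`MockPacs` so the ingestion, retrieval and analytics layers are
exercised end to end with no external PACS.

Key realism choices (all recorded in the schedule provenance / archive
manifest so tests can use them as ground truth):

* header timestamps (StudyDate/Time, SeriesDate/Time, AcquisitionDate/Time)
  equal the true instant **plus** the scanner's clock offset — a wrong
  timezone setting shows up as a constant ±N-hour shift, exactly the
  anomaly the clock-skew detector must recover;
* instance acquisition instants are spread evenly across the exam window
  so min/max over instances recover the window endpoints exactly;
* a scanner performs one exam at a time: intervals within one scanner's
  schedule are pairwise disjoint by construction.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from pydicom import Dataset, dcmread
from pydicom.dataset import FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

from .dimse import (
    DimseNetwork,
    STATUS_MOVE_DEST_UNKNOWN,
    STATUS_PROCESSING_FAILURE,
    STATUS_SUCCESS,
    UnknownAETitle,
)

#: Private-root prefix for all deterministically generated UIDs.
UID_ROOT = "1.2.826.0.1.3680043.10.873."

MANIFEST_NAME = "manifest.json"

#: Fixed network/processing delay between true acquisition and receipt at
#: the research store, in minutes.  Small against the 20-min skew threshold.
DEFAULT_NETWORK_DELAY_MIN = 2.0

BODY_PARTS = ["HEAD", "CHEST", "ABDOMEN", "PELVIS", "SPINE", "KNEE"]


class PackingError(ValueError):
    """A scanner's requested exams cannot fit inside the given day."""


@dataclass(frozen=True)
class ScannerSpec:
    """One scanner in the fleet.

    ``clock_offset_min`` is the scanner clock minus true time, in minutes;
    zero means a correctly calibrated scanner.  ``scanner_id`` maps to both
    StationName and DeviceSerialNumber in generated headers.
    """

    scanner_id: str
    modality: str = "MR"
    clock_offset_min: float = 0.0
    site_id: str = "SITE1"

    def __post_init__(self) -> None:
        if not np.isfinite(self.clock_offset_min):
            raise ValueError("clock_offset_min must be finite")


@dataclass(frozen=True)
class ExamSpec:
    """One exam (accession) on one scanner, in true (wall-clock) time."""

    accession: str
    empi: str
    scanner_id: str
    true_start: datetime
    true_end: datetime
    n_series: int
    instances_per_series: int
    body_part: str

    def __post_init__(self) -> None:
        if self.true_start >= self.true_end:
            raise ValueError("true_start must precede true_end")
        if self.n_series < 1 or self.instances_per_series < 1:
            raise ValueError("n_series and instances_per_series must be >= 1")


@dataclass
class FleetSchedule:
    """Exams for a fleet on one day plus the generation provenance.

    Iterating / indexing the schedule yields the :class:`ExamSpec` entries;
    ``provenance`` records the uniform draw bounds so oracle tests can check
    generated values against the stated ranges.
    """

    exams: list[ExamSpec]
    provenance: dict

    def __iter__(self) -> Iterator[ExamSpec]:
        return iter(self.exams)

    def __len__(self) -> int:
        return len(self.exams)

    def __getitem__(self, i):
        return self.exams[i]


@dataclass
class CorruptedSchedule:
    """Human-entered (CDW-style) rendition of a schedule.

    A fraction ``error_rate`` of the recorded start/end times is perturbed;
    unlike scanner-derived windows, the perturbed entries may overlap.
    """

    entries: list[tuple[str, datetime, datetime]]
    error_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")


def deterministic_uid(*parts: object) -> str:
    """A valid DICOM UID under the private root, a pure function of parts."""
    digest = hashlib.sha1("|".join(str(p) for p in parts).encode()).hexdigest()
    return UID_ROOT + str(1 + int(digest, 16) % 10**30)


def generate_fleet_schedule(
    scanners: Sequence[ScannerSpec],
    day: date,
    exams_per_scanner: int,
    seed: int,
    *,
    day_start_hour: int = 7,
    duration_bounds_min: tuple[float, float] = (15.0, 45.0),
    gap_bounds_min: tuple[float, float] = (5.0, 30.0),
    series_bounds: tuple[int, int] = (2, 3),
    instances_bounds: tuple[int, int] = (2, 4),
) -> FleetSchedule:
    """Draw a day of non-overlapping exams for every scanner.

    Durations and inter-exam gaps are uniform within the given bounds
    (minutes); series/instance counts uniform integers.  Scheduling is
    sequential from ``day_start_hour``, so disjointness within a scanner
    holds by construction; exams of different scanners may well overlap,
    as in a real fleet.  Raises :class:`PackingError` if an exam would run
    past midnight — never silently truncates.
    """
    if exams_per_scanner < 0:
        raise ValueError("exams_per_scanner must be >= 0")
    ids = [s.scanner_id for s in scanners]
    if len(set(ids)) != len(ids):
        raise ValueError("scanner_id values must be unique within a fleet")

    day_end = datetime.combine(day + timedelta(days=1), time.min)
    exams: list[ExamSpec] = []
    for scanner in scanners:
        rng = random.Random(f"{seed}:{scanner.scanner_id}:{day.isoformat()}")
        cursor = datetime.combine(day, time(hour=day_start_hour))
        for i in range(exams_per_scanner):
            duration = timedelta(minutes=rng.uniform(*duration_bounds_min))
            start, end = cursor, cursor + duration
            if end > day_end:
                raise PackingError(
                    f"scanner {scanner.scanner_id}: exam {i + 1}/"
                    f"{exams_per_scanner} would end {end}, past {day_end}"
                )
            exams.append(
                ExamSpec(
                    # accession stays within the 16-char SH limit: scanner id,
                    # day-of-year, exam ordinal
                    accession=f"A{scanner.scanner_id}{day:%j}{i:02d}",
                    empi=f"EMPI-{scanner.scanner_id}-{i:03d}",
                    scanner_id=scanner.scanner_id,
                    true_start=start,
                    true_end=end,
                    n_series=rng.randint(*series_bounds),
                    instances_per_series=rng.randint(*instances_bounds),
                    body_part=rng.choice(BODY_PARTS),
                )
            )
            cursor = end + timedelta(minutes=rng.uniform(*gap_bounds_min))
    provenance = {
        "seed": seed,
        "day": day.isoformat(),
        "exams_per_scanner": exams_per_scanner,
        "day_start_hour": day_start_hour,
        "duration_bounds_min": list(duration_bounds_min),
        "gap_bounds_min": list(gap_bounds_min),
        "series_bounds": list(series_bounds),
        "instances_bounds": list(instances_bounds),
    }
    return FleetSchedule(exams=exams, provenance=provenance)


def corrupt_schedule(
    exams: Iterable[ExamSpec],
    error_rate: float,
    seed: int,
    *,
    max_shift_min: float = 90.0,
) -> CorruptedSchedule:
    """Emulate a human-entered copy of the schedule.

    Each entry independently gets its recorded start and/or end shifted by a
    uniform ±``max_shift_min`` minutes with probability ``error_rate`` —
    large shifts readily produce the physically impossible exam overlaps
    that scanner-derived windows are free of.
    """
    rng = random.Random(f"corrupt:{seed}")
    entries: list[tuple[str, datetime, datetime]] = []
    for exam in exams:
        start, end = exam.true_start, exam.true_end
        if rng.random() < error_rate:
            start = start + timedelta(minutes=rng.uniform(-max_shift_min, max_shift_min))
            end = end + timedelta(minutes=rng.uniform(-max_shift_min, max_shift_min))
            if end <= start:  # keep entries well-formed; errors live in placement
                start, end = min(start, end), max(start, end) + timedelta(minutes=1)
        entries.append((exam.accession, start, end))
    return CorruptedSchedule(entries=entries, error_rate=error_rate)


def _exam_instance_times(exam: ExamSpec) -> list[datetime]:
    total = exam.n_series * exam.instances_per_series
    if total == 1:
        return [exam.true_start]
    dur = exam.true_end - exam.true_start
    return [exam.true_start + (dur * k) / (total - 1) for k in range(total)]


def _tm(dt: datetime) -> str:
    base = dt.strftime("%H%M%S")
    return f"{base}.{dt.microsecond:06d}" if dt.microsecond else base


def _build_instance(
    exam: ExamSpec,
    scanner: ScannerSpec,
    study_uid: str,
    series_uid: str,
    series_no: int,
    instance_no: int,
    header_time: datetime,
    series_header_time: datetime,
) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    sop_uid = deterministic_uid(exam.accession, "sop", series_no, instance_no)
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.PatientID = exam.empi
    ds.PatientName = f"Synth^{exam.empi}"  # synthetic PHI for stripping tests
    ds.PatientBirthDate = "19700101"
    ds.AccessionNumber = exam.accession
    ds.Modality = scanner.modality
    ds.BodyPartExamined = exam.body_part
    ds.StationName = scanner.scanner_id
    ds.DeviceSerialNumber = scanner.scanner_id
    ds.InstitutionName = scanner.site_id
    ds.SeriesNumber = series_no
    ds.InstanceNumber = instance_no
    ds.StudyDate = header_time.strftime("%Y%m%d")
    ds.StudyTime = _tm(header_time)
    ds.SeriesDate = series_header_time.strftime("%Y%m%d")
    ds.SeriesTime = _tm(series_header_time)
    ds.AcquisitionDate = header_time.strftime("%Y%m%d")
    ds.AcquisitionTime = _tm(header_time)
    ds.ContentDate = header_time.strftime("%Y%m%d")
    ds.ContentTime = _tm(header_time)
    # synthetic private tag: real-PACS streams carry vendor private data
    block = ds.private_block(0x0009, "PACSFLOW_SYNTH", create=True)
    block.add_new(0x01, "LO", "synthetic-private-payload")

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = 16
    ds.Columns = 16
    ds.BitsAllocated = 8
    ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.PixelData = np.arange(256, dtype=np.uint8).reshape(16, 16).tobytes()
    return ds


def materialize_instances(
    exams: Iterable[ExamSpec],
    scanners: Sequence[ScannerSpec],
    out_dir: Path | str,
    *,
    network_delay_min: float = DEFAULT_NETWORK_DELAY_MIN,
) -> list[Path]:
    """Write the fleet's DICOM Part 10 archive plus a ground-truth manifest.

    Header timestamps carry the scanner clock offset; the manifest records
    the true acquisition instant of every instance (the oracle for window
    and skew recovery) and the fleet's clock offsets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.scanner_id: s for s in scanners}
    paths: list[Path] = []
    manifest: dict = {
        "network_delay_min": network_delay_min,
        "scanners": {s.scanner_id: asdict(s) for s in scanners},
        "exams": [],
        "instances": {},
    }
    for exam in exams:
        scanner = by_id.get(exam.scanner_id)
        if scanner is None:
            raise KeyError(f"exam {exam.accession} references unknown scanner "
                           f"{exam.scanner_id!r}")
        offset = timedelta(minutes=scanner.clock_offset_min)
        study_uid = deterministic_uid(exam.accession, "study")
        true_times = _exam_instance_times(exam)
        manifest["exams"].append({**asdict(exam),
                                  "true_start": exam.true_start.isoformat(),
                                  "true_end": exam.true_end.isoformat(),
                                  "study_uid": study_uid})
        k = 0
        for s in range(1, exam.n_series + 1):
            series_uid = deterministic_uid(exam.accession, "series", s)
            series_true = true_times[k]
            for i in range(1, exam.instances_per_series + 1):
                true_t = true_times[k]
                ds = _build_instance(exam, scanner, study_uid, series_uid,
                                     s, i, true_t + offset, series_true + offset)
                path = out_dir / f"{ds.SOPInstanceUID}.dcm"
                ds.save_as(path, enforce_file_format=True)
                paths.append(path)
                manifest["instances"][ds.SOPInstanceUID] = {
                    "true_acquisition": true_t.isoformat(),
                    "scanner_id": scanner.scanner_id,
                    "accession": exam.accession,
                    "study_uid": study_uid,
                    "series_uid": series_uid,
                }
                k += 1
    (out_dir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return paths


def load_manifest(archive_dir: Path | str) -> dict:
    return json.loads((Path(archive_dir) / MANIFEST_NAME).read_text())


class SimulatedClock:
    """An injectable clock for listeners; the mock PACS advances it so each
    receipt timestamp lands at true acquisition + network delay."""

    def __init__(self, now: datetime):
        self.now = now

    def advance_to(self, instant: datetime) -> None:
        # a fleet's instances are replayed interleaved, not chronologically,
        # so each C-STORE sets the clock to that instance's arrival moment
        self.now = instant

    def __call__(self) -> datetime:
        return self.now


@dataclass
class MoveResult:
    status: int
    n_completed: int = 0
    n_failed: int = 0


_FIND_KEYS = ("PatientID", "AccessionNumber", "StudyDate", "StudyInstanceUID")


class MockPacs:
    """Study-Root query/retrieve test double over a materialized archive.

    Answers C-FIND at STUDY level on PatientID, AccessionNumber, StudyDate
    and StudyInstanceUID (empty/absent key = universal match) and C-MOVE by
    pushing matching instances via C-STORE to the named destination on the
    in-process network.  ``fail_every=k`` makes every k-th C-MOVE fail
    before sending anything, for retry tests.
    """

    def __init__(
        self,
        archive_dir: Path | str,
        network: DimseNetwork,
        *,
        ae_title: str = "MOCKPACS",
        fail_every: int | None = None,
        simulated_clock: SimulatedClock | None = None,
    ):
        self.archive_dir = Path(archive_dir)
        self.network = network
        self.ae_title = ae_title
        self.fail_every = fail_every
        self.simulated_clock = simulated_clock
        self._move_count = 0
        self._datasets = [dcmread(p) for p in sorted(self.archive_dir.glob("*.dcm"))]
        try:
            self._manifest = load_manifest(self.archive_dir)
        except FileNotFoundError:
            self._manifest = {"instances": {}, "network_delay_min": 0.0}

    # -- C-FIND -----------------------------------------------------------
    def c_find(self, identifier: Dataset) -> list[Dataset]:
        matches: dict[str, Dataset] = {}
        for ds in self._datasets:
            if all(self._key_matches(identifier, ds, key) for key in _FIND_KEYS):
                uid = ds.StudyInstanceUID
                if uid not in matches:
                    result = Dataset()
                    result.QueryRetrieveLevel = "STUDY"
                    result.StudyInstanceUID = uid
                    result.PatientID = ds.get("PatientID", "")
                    result.AccessionNumber = ds.get("AccessionNumber", "")
                    result.StudyDate = ds.get("StudyDate", "")
                    matches[uid] = result
        return list(matches.values())

    @staticmethod
    def _key_matches(identifier: Dataset, ds: Dataset, key: str) -> bool:
        wanted = identifier.get(key, "")
        if wanted in ("", None):
            return True
        return str(ds.get(key, "")) == str(wanted)

    # -- C-MOVE -----------------------------------------------------------
    def c_move(self, identifier: Dataset, dest_ae: str) -> MoveResult:
        self._move_count += 1
        if self.fail_every and self._move_count % self.fail_every == 0:
            return MoveResult(status=STATUS_PROCESSING_FAILURE)
        try:
            dest = self.network.resolve(dest_ae)
        except UnknownAETitle:
            return MoveResult(status=STATUS_MOVE_DEST_UNKNOWN)
        delay = timedelta(minutes=self._manifest.get("network_delay_min", 0.0))
        completed = failed = 0
        for ds in self._datasets:
            if all(self._key_matches(identifier, ds, key) for key in _FIND_KEYS):
                info = self._manifest["instances"].get(ds.SOPInstanceUID)
                if info and self.simulated_clock is not None:
                    true_t = datetime.fromisoformat(info["true_acquisition"])
                    self.simulated_clock.advance_to(true_t + delay)
                status = dest.c_store(ds)
                if status == STATUS_SUCCESS:
                    completed += 1
                else:
                    failed += 1
        status = STATUS_SUCCESS if failed == 0 else STATUS_PROCESSING_FAILURE
        return MoveResult(status=status, n_completed=completed, n_failed=failed)


def mock_pacs_serve(
    archive_dir: Path | str,
    network: DimseNetwork,
    **kwargs,
) -> MockPacs:
    """Bring up the mock PACS over an archive directory (service handle)."""
    return MockPacs(archive_dir, network, **kwargs)
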