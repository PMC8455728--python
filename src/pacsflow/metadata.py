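"""Profile-driven, PHI-free metadata extraction.

The extractor traverses stored instances (via the ingestion index), picks
one representative image per new series — header metadata is constant
within a series for the attributes of interest, so reading every slice
buys nothing — and writes one document per (series, profile) into the
profile's collection.  Profiles are plain text files, one DICOM attribute
keyword per line; dropping a new file into the profile folder adds a
collection on the next cycle without a restart.  Attributes on the PHI
exclusion list are stripped at profile-load time, so no document can ever
carry them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from pydicom import dcmread
from pydicom.datadict import tag_for_keyword
from pydicom.multival import MultiValue
from pydicom.valuerep import PersonName

from ._statefiles import read_uid_set, write_uid_set
from .docstore import DocumentStore
from .ingestion import IngestionIndex, InstanceRecord

log = logging.getLogger(__name__)

#: Default polling interval for the extraction loop, seconds (10 minutes).
DEFAULT_CYCLE_INTERVAL_S = 600.0

#: Directly identifying attributes stripped from every profile, modeled on
#: the DICOM basic confidentiality profile.  PatientID and AccessionNumber
#: are deliberately NOT listed by default — cohort workflows need them and
#: collection-level access control is the isolation boundary — but sites
#: sharing collections can extend this list in configuration.
DEFAULT_PHI_EXCLUSION: tuple[str, ...] = (
    "PatientName",
    "PatientBirthDate",
    "PatientBirthTime",
    "PatientAddress",
    "PatientTelephoneNumbers",
    "PatientMotherBirthName",
    "OtherPatientIDs",
    "OtherPatientNames",
    "ReferringPhysicianName",
    "ReferringPhysicianAddress",
    "ReferringPhysicianTelephoneNumbers",
    "PerformingPhysicianName",
    "PhysiciansOfRecord",
    "OperatorsName",
    "InstitutionAddress",
    "PersonName",
    "MilitaryRank",
)


@dataclass(frozen=True)
class ExtractionProfile:
    """A named attribute list; one profile feeds one collection."""

    name: str
    attributes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ValueError(f"profile {self.name!r} has no attributes")


@dataclass
class MetadataDocument:
    series_uid: str
    profile: str
    values: dict
    receipt_time: str | None = None


class RepresentativeMode(str, Enum):
    FIRST = "first"
    FIRST_MIDDLE_LAST = "first_middle_last"
    ALL = "all"


def load_profiles(
    directory: Path | str,
    phi_exclusion: Sequence[str] = DEFAULT_PHI_EXCLUSION,
) -> list[ExtractionProfile]:
    """Read every ``*.txt`` profile file in a folder.

    Filename stem is the profile (= collection) name; one attribute keyword
    per line, ``#`` comments and blank lines ignored.  PHI-listed keywords
    are removed with a warning.  Unknown keywords are kept with a warning —
    extraction simply yields no value for them — so a typo never takes the
    extractor down.
    """
    directory = Path(directory)
    excluded = {k.lower() for k in phi_exclusion}
    profiles = []
    for path in sorted(directory.glob("*.txt")):
        attributes: list[str] = []
        for line in path.read_text().splitlines():
            keyword = line.split("#", 1)[0].strip()
            if not keyword:
                continue
            if keyword.lower() in excluded:
                log.warning("profile %s: dropping PHI attribute %s",
                            path.stem, keyword)
                continue
            if tag_for_keyword(keyword) is None:
                log.warning("profile %s: unknown attribute keyword %s (kept)",
                            path.stem, keyword)
            attributes.append(keyword)
        if attributes:
            profiles.append(ExtractionProfile(path.stem, tuple(attributes)))
        else:
            log.warning("profile %s: no usable attributes, skipped", path.stem)
    return profiles


def select_representative(
    instances: Sequence[InstanceRecord],
    mode: RepresentativeMode = RepresentativeMode.FIRST,
) -> list[InstanceRecord]:
    """Pick the representative instance(s) of a series.

    Ordering is by InstanceNumber, with missing numbers sorted last and
    ties broken by SOP instance UID, so the choice is deterministic for
    any input order.
    """
    if not instances:
        raise ValueError("cannot select a representative from an empty series")
    ordered = sorted(
        instances,
        key=lambda r: (r.instance_number is None, r.instance_number or 0, r.sop_uid),
    )
    if mode is RepresentativeMode.ALL:
        return ordered
    if mode is RepresentativeMode.FIRST:
        return [ordered[0]]
    picks = [ordered[0], ordered[len(ordered) // 2], ordered[-1]]
    deduped: list[InstanceRecord] = []
    for record in picks:
        if record not in deduped:
            deduped.append(record)
    return deduped


def _plain(value):
    """Convert a pydicom element value to a JSON-able plain Python value.

    Numeric VRs come through as numbers, person names and UIDs as strings,
    multi-valued attributes as lists preserving order.
    """
    if isinstance(value, MultiValue) or isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, PersonName):
        return str(value)
    if isinstance(value, bool):
        return value
    if isinstance(value, int):
        return int(value)
    if isinstance(value, float):
        return float(value)
    if isinstance(value, bytes):
        return value.decode("ascii", "replace")
    return str(value)


def extract_document(
    instance_file: Path | str,
    record: InstanceRecord,
    profile: ExtractionProfile,
    phi_exclusion: Sequence[str] = DEFAULT_PHI_EXCLUSION,
) -> MetadataDocument:
    """Extract one series document from one instance file.

    Attributes absent from the header are omitted (not null-filled); the
    receipt time is copied from the ingestion record, never from headers.
    The PHI list is re-checked here as a belt-and-braces guard even though
    profiles are already stripped at load time.
    """
    ds = dcmread(instance_file, stop_before_pixels=True)
    excluded = {k.lower() for k in phi_exclusion}
    values = {}
    for keyword in profile.attributes:
        if keyword.lower() in excluded:
            continue
        if tag_for_keyword(keyword) is None:
            continue  # unknown keyword: profile load already warned
        if keyword in ds:
            element = ds.data_element(keyword)
            if element is not None and element.value not in (None, ""):
                values[keyword] = _plain(element.value)
    return MetadataDocument(
        series_uid=record.series_uid,
        profile=profile.name,
        values=values,
        receipt_time=record.receipt_time,
    )


def parse_dicom_datetime(da: str, tm: str) -> tuple[datetime, bool]:
    """Combine DICOM DA and TM strings into an instant.

    Returns ``(instant, full_precision)``; a missing time yields midnight
    with ``full_precision=False`` so downstream statistics can exclude
    date-only values.  Accepts the truncated TM dialects (HH, HHMM) and
    fractional seconds.
    """
    try:
        day = datetime.strptime(da.strip(), "%Y%m%d")
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"unparseable DICOM DA value {da!r}") from exc
    tm = (tm or "").strip()
    if not tm:
        return day, False
    base, _, frac = tm.partition(".")
    if len(base) not in (2, 4, 6) or not base.isdigit():
        raise ValueError(f"unparseable DICOM TM value {tm!r}")
    hour = int(base[0:2])
    minute = int(base[2:4]) if len(base) >= 4 else 0
    second = int(base[4:6]) if len(base) == 6 else 0
    micro = int(frac.ljust(6, "0")[:6]) if frac else 0
    try:
        return day.replace(hour=hour, minute=minute, second=second,
                           microsecond=micro), True
    except ValueError as exc:
        raise ValueError(f"unparseable DICOM TM value {tm!r}") from exc


@dataclass
class ExtractionState:
    """Per-profile sets of already-extracted series plus the cycle interval."""

    extracted: dict[str, set[str]] = field(default_factory=dict)
    cycle_interval_s: float = DEFAULT_CYCLE_INTERVAL_S

    def extracted_for(self, profile: str) -> set[str]:
        return self.extracted.setdefault(profile, set())

    def persist(self, state_dir: Path | str) -> None:
        for profile, uids in self.extracted.items():
            write_uid_set(Path(state_dir) / f"extracted_{profile}.txt", uids)

    @classmethod
    def load(cls, state_dir: Path | str,
             cycle_interval_s: float = DEFAULT_CYCLE_INTERVAL_S) -> "ExtractionState":
        state = cls(cycle_interval_s=cycle_interval_s)
        directory = Path(state_dir)
        if directory.exists():
            for path in sorted(directory.glob("extracted_*.txt")):
                profile = path.stem[len("extracted_"):]
                state.extracted[profile] = read_uid_set(path)
        return state

    @classmethod
    def rebuild_from_store(cls, store: DocumentStore,
                           cycle_interval_s: float = DEFAULT_CYCLE_INTERVAL_S
                           ) -> "ExtractionState":
        """Recover after state-file corruption: every series that already has
        a document in a collection is re-marked extracted for that profile."""
        state = cls(cycle_interval_s=cycle_interval_s)
        for profile in store.profiles():
            state.extracted[profile] = store.distinct_series(profile)
        return state


def run_extraction_cycle(
    state: ExtractionState,
    index: IngestionIndex,
    profiles: Iterable[ExtractionProfile],
    store: DocumentStore,
    storage_root: Path | str,
    *,
    mode: RepresentativeMode = RepresentativeMode.FIRST,
    state_dir: Path | str | None = None,
    phi_exclusion: Sequence[str] = DEFAULT_PHI_EXCLUSION,
    persist_every: int = 25,
) -> int:
    """One extraction pass: process every series not yet extracted per profile.

    Document writes land before the series is marked extracted, so a crash
    between the two re-extracts on restart and the (series, profile) upsert
    absorbs the duplicate — at-least-once work, exactly-once visible effect.
    Progress is checkpointed to ``state_dir`` every ``persist_every``
    documents and at the end of the cycle, bounding re-work after a crash.
    An unparseable instance leaves its series pending for retry next cycle.
    Returns the number of documents written; an immediate re-run is a no-op.
    """
    storage_root = Path(storage_root)
    by_series = index.by_series()
    written = 0
    for profile in profiles:
        done = state.extracted_for(profile.name)
        for series_uid, records in sorted(by_series.items()):
            if series_uid in done:
                continue
            representatives = select_representative(records, mode)
            values: dict = {}
            receipt = representatives[0].receipt_time
            failed = False
            for record in representatives:
                try:
                    doc = extract_document(storage_root / record.path, record,
                                           profile, phi_exclusion)
                except Exception as exc:
                    log.error("series %s left pending, unreadable instance "
                              "%s: %s", series_uid, record.path, exc)
                    failed = True
                    break
                for key, value in doc.values.items():
                    values.setdefault(key, value)
            if failed:
                continue
            store.upsert(profile.name, series_uid, values, receipt)
            written += 1
            done.add(series_uid)
            if state_dir is not None and written % persist_every == 0:
                state.persist(state_dir)
    if state_dir is not None:
        state.persist(state_dir)
    return written


def filter_cohort(
    store: DocumentStore,
    profile: ExtractionProfile,
    predicates: dict[str, object],
) -> list[str]:
    """Series UIDs whose documents satisfy ALL predicates (conjunction).

    String matches are case-insensitive (DICOM code strings); a predicate
    value that is a set/list/tuple means set membership.  Predicating on an
    attribute the profile does not extract is an error — it could only ever
    produce a silently empty cohort.
    """
    for attr in predicates:
        if attr not in profile.attributes:
            raise KeyError(
                f"predicate attribute {attr!r} is not in profile "
                f"{profile.name!r}; extracted attributes: {list(profile.attributes)}"
            )

    def norm(v):
        return v.lower() if isinstance(v, str) else v

    def matches(doc_value, wanted) -> bool:
        if isinstance(wanted, (set, frozenset, list, tuple)):
            return any(matches(doc_value, w) for w in wanted)
        if isinstance(doc_value, list):
            return any(matches(v, wanted) for v in doc_value)
        return norm(doc_value) == norm(wanted)

    cohort = []
    for series_uid, values, _receipt in store.iter_documents(profile.name):
        if all(attr in values and matches(values[attr], wanted)
               for attr, wanted in predicates.items()):
            cohort.append(series_uid)
    return cohort
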