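"""Operational analytics over extracted metadata, plus image export tools.

Three questions drive this layer:

* **Utilization** — how long did each exam run and how long did the
  scanner idle between exams?  Exam windows are the min/max acquisition
  instants over an exam's series documents; because header timestamps are
  machine-written at acquisition, windows derived from them cannot show
  the physically impossible exam overlaps that human-entered schedule
  records (CDW-style) regularly do.
* **Clock calibration** — the signed skew between receipt at the research
  store and the header acquisition instant should stay within network and
  processing delay.  A per-scanner median far outside that (default
  threshold 20 minutes) means a miscalibrated scanner clock, typically a
  wrong timezone.  The median is robust: one image stuck in a queue must
  not flag a scanner.
* **Downstream consumption** — pixel export to headerless PNG and
  whitelist-based DICOM de-identification with consistent UID remapping.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from pydicom import Dataset, dcmread
from pydicom.dataset import FileMetaDataset
from pydicom.multival import MultiValue

from .metadata import DEFAULT_PHI_EXCLUSION, MetadataDocument, parse_dicom_datetime
from .synthetic import UID_ROOT

#: Skew magnitude above which a scanner is flagged as miscalibrated.
DEFAULT_SKEW_THRESHOLD = timedelta(minutes=20)

#: Attribute set sufficient for the utilization and skew analyses.
OPS_PROFILE_ATTRIBUTES: tuple[str, ...] = (
    "Modality",
    "StationName",
    "DeviceSerialNumber",
    "AccessionNumber",
    "StudyInstanceUID",
    "BodyPartExamined",
    "AcquisitionDate",
    "AcquisitionTime",
    "SeriesDate",
    "SeriesTime",
    "ContentDate",
    "ContentTime",
)

#: (date, time) attribute pairs in precedence order for the acquisition
#: instant; the first parseable pair wins.
_TIMESTAMP_PRECEDENCE = (
    ("AcquisitionDate", "AcquisitionTime"),
    ("SeriesDate", "SeriesTime"),
    ("ContentDate", "ContentTime"),
)


@dataclass
class ExamWindow:
    scanner_id: str
    exam_key: str
    start: datetime
    end: datetime
    n_series: int = 0
    n_instances: int = 0

    @property
    def duration(self) -> timedelta:
        return self.end - self.start


@dataclass
class WindowsResult:
    windows: list[ExamWindow]
    n_excluded_no_timestamp: int = 0
    n_excluded_no_scanner: int = 0


def acquisition_instant(values: dict) -> tuple[datetime | None, bool]:
    """Best acquisition instant of a document under the precedence order.

    Returns (instant, full_precision); (None, False) when nothing parses.
    """
    for date_key, time_key in _TIMESTAMP_PRECEDENCE:
        da = values.get(date_key, "")
        if not da:
            continue
        try:
            return parse_dicom_datetime(str(da), str(values.get(time_key, "")))
        except ValueError:
            continue
    return None, False


def scanner_identity(values: dict) -> str | None:
    """StationName primary, DeviceSerialNumber fallback."""
    return values.get("StationName") or values.get("DeviceSerialNumber") or None


def compute_exam_windows(
    documents: Iterable[MetadataDocument],
    grouping: str = "accession",
) -> WindowsResult:
    """One window per (scanner, exam): min/max acquisition instant.

    ``grouping`` selects the exam key: AccessionNumber (default; one
    accession = one ordered exam) or StudyInstanceUID.  Either way the
    other serves as fallback when the primary is missing.  Documents with
    no parseable timestamp or no scanner identity are excluded and counted.
    """
    if grouping not in ("accession", "study"):
        raise ValueError(f"grouping must be 'accession' or 'study', got {grouping!r}")
    buckets: dict[tuple[str, str], list[datetime]] = {}
    result = WindowsResult(windows=[])
    for doc in documents:
        scanner = scanner_identity(doc.values)
        if scanner is None:
            result.n_excluded_no_scanner += 1
            continue
        instant, _full = acquisition_instant(doc.values)
        if instant is None:
            result.n_excluded_no_timestamp += 1
            continue
        primary = doc.values.get("AccessionNumber") if grouping == "accession" \
            else doc.values.get("StudyInstanceUID")
        fallback = doc.values.get("StudyInstanceUID") if grouping == "accession" \
            else doc.values.get("AccessionNumber")
        key = str(primary or fallback or doc.series_uid)
        buckets.setdefault((scanner, key), []).append(instant)
    for (scanner, key), instants in sorted(buckets.items()):
        result.windows.append(
            ExamWindow(
                scanner_id=scanner,
                exam_key=key,
                start=min(instants),
                end=max(instants),
                n_series=len(instants),
                n_instances=len(instants),
            )
        )
    return result


@dataclass
class UtilizationReport:
    day: date
    scanner_id: str
    windows: list[ExamWindow] = field(default_factory=list)
    exam_durations: list[timedelta] = field(default_factory=list)
    idle_gaps: list[timedelta] = field(default_factory=list)
    overlaps: list[tuple[ExamWindow, ExamWindow]] = field(default_factory=list)
    busy_fraction: float = 0.0

    @property
    def span(self) -> timedelta:
        if not self.windows:
            return timedelta(0)
        return self.windows[-1].end - self.windows[0].start


def detect_overlaps(windows: Sequence[ExamWindow]) -> list[tuple[ExamWindow, ExamWindow]]:
    """All pairs with positive-length intersection.

    Touching endpoints (one exam ends exactly when the next starts) are
    legal back-to-back scheduling, not overlap.
    """
    ordered = sorted(windows, key=lambda w: (w.start, w.end))
    pairs = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if b.start >= a.end:
                break
            pairs.append((a, b))
    return pairs


def utilization_report(windows: Sequence[ExamWindow], day: date) -> UtilizationReport:
    """Duration, idle-gap and busy-fraction metrics for one scanner-day.

    With no overlaps the identity Σ durations + Σ idle gaps = span
    (first start to last end) holds exactly.  An empty window list yields
    an empty report with zero metrics.
    """
    scanners = {w.scanner_id for w in windows}
    if len(scanners) > 1:
        raise ValueError(f"windows span multiple scanners: {sorted(scanners)}")
    ordered = sorted(windows, key=lambda w: (w.start, w.end))
    report = UtilizationReport(day=day, scanner_id=next(iter(scanners), ""),
                               windows=ordered)
    if not ordered:
        return report
    report.exam_durations = [w.duration for w in ordered]
    for prev, cur in zip(ordered, ordered[1:]):
        gap = cur.start - prev.end
        if gap > timedelta(0):
            report.idle_gaps.append(gap)
    report.overlaps = detect_overlaps(ordered)
    span = report.span
    busy = sum(report.exam_durations, timedelta(0))
    report.busy_fraction = busy / span if span > timedelta(0) else 1.0
    return report


def windows_from_entries(
    entries: Iterable[tuple[str, datetime, datetime]],
    scanner_id: str = "",
) -> list[ExamWindow]:
    """Adapt (exam key, start, end) schedule entries — e.g. a human-entered
    schedule record — into windows for overlap comparison."""
    return [ExamWindow(scanner_id=scanner_id, exam_key=key, start=start, end=end)
            for key, start, end in entries]


# ---------------------------------------------------------------------------
# clock skew
# ---------------------------------------------------------------------------

@dataclass
class ClockSkewReport:
    scanner_id: str
    threshold: timedelta
    n_documents: int = 0
    skews: list[timedelta] = field(default_factory=list)
    median_skew: timedelta | None = None
    flagged: bool = False
    assessable: bool = False
    n_exceeding: int = 0  # per-document count over threshold, for drill-down


def clock_skew_report(
    documents: Iterable[MetadataDocument],
    threshold: timedelta = DEFAULT_SKEW_THRESHOLD,
) -> dict[str, ClockSkewReport]:
    """Per-scanner receipt-minus-acquisition skew statistics.

    Sign convention: skew = receipt − acquisition; small positive values
    are ordinary network/processing delay, a large magnitude either way
    means the scanner clock is wrong (a clock N minutes ahead shows as a
    skew near −N).  Date-only (low-precision) timestamps are excluded.
    A scanner is flagged iff |median skew| exceeds the threshold; scanners
    with no usable timestamp are reported unassessable, never flagged.
    """
    reports: dict[str, ClockSkewReport] = {}
    for doc in documents:
        scanner = scanner_identity(doc.values)
        if scanner is None:
            continue
        report = reports.setdefault(
            scanner, ClockSkewReport(scanner_id=scanner, threshold=threshold))
        report.n_documents += 1
        if not doc.receipt_time:
            continue
        instant, full = acquisition_instant(doc.values)
        if instant is None or not full:
            continue
        skew = datetime.fromisoformat(doc.receipt_time) - instant
        report.skews.append(skew)
        if abs(skew) > threshold:
            report.n_exceeding += 1
    for report in reports.values():
        if report.skews:
            report.assessable = True
            report.median_skew = statistics.median(report.skews)
            report.flagged = abs(report.median_skew) > threshold
    return reports


def flagged_scanners(reports: dict[str, ClockSkewReport]) -> set[str]:
    return {sid for sid, r in reports.items() if r.flagged}


# ---------------------------------------------------------------------------
# CSV / plot export
# ---------------------------------------------------------------------------

def utilization_to_frame(reports: Iterable[UtilizationReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append({
            "day": rep.day.isoformat(),
            "scanner_id": rep.scanner_id,
            "n_exams": len(rep.windows),
            "total_exam_min": sum(rep.exam_durations, timedelta(0)).total_seconds() / 60,
            "total_idle_min": sum(rep.idle_gaps, timedelta(0)).total_seconds() / 60,
            "span_min": rep.span.total_seconds() / 60,
            "busy_fraction": rep.busy_fraction,
            "n_overlaps": len(rep.overlaps),
        })
    return pd.DataFrame(rows)


def skew_to_frame(reports: dict[str, ClockSkewReport]) -> pd.DataFrame:
    rows = []
    for sid, rep in sorted(reports.items()):
        rows.append({
            "scanner_id": sid,
            "n_documents": rep.n_documents,
            "n_skews": len(rep.skews),
            "median_skew_min": (rep.median_skew.total_seconds() / 60
                                if rep.median_skew is not None else np.nan),
            "threshold_min": rep.threshold.total_seconds() / 60,
            "assessable": rep.assessable,
            "flagged": rep.flagged,
            "n_exceeding": rep.n_exceeding,
        })
    return pd.DataFrame(rows)


def plot_timeline(windows: Sequence[ExamWindow], out: Path | str) -> None:
    """Per-scanner exam timeline: one horizontal bar per exam window."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scanners = sorted({w.scanner_id for w in windows})
    ypos = {sid: i for i, sid in enumerate(scanners)}
    fig, ax = plt.subplots(figsize=(10, 1 + 0.5 * len(scanners)))
    for w in windows:
        ax.barh(ypos[w.scanner_id],
                (w.end - w.start).total_seconds() / 3600,
                left=w.start.hour + w.start.minute / 60 + w.start.second / 3600,
                height=0.4)
    ax.set_yticks(range(len(scanners)), scanners)
    ax.set_xlabel("hour of day")
    ax.set_title("exam windows")
    fig.tight_layout()
    fig.savefig(out, dpi=80)
    plt.close(fig)


# ---------------------------------------------------------------------------
# PNG export
# ---------------------------------------------------------------------------

class PixelConversionError(ValueError):
    """Pixel data missing or undecodable for the file's transfer syntax."""


def _first_number(value) -> float:
    # WindowCenter/Width may be multi-valued (one per VOI LUT); use the first
    if isinstance(value, (MultiValue, list, tuple)):
        return float(value[0])
    return float(value)


def dicom_to_png(instance_file: Path | str, out: Path | str) -> Path:
    """Export pixel data as an 8-bit grayscale, headerless PNG.

    Window center/width is applied when present, otherwise min–max
    scaling; MONOCHROME1 is inverted so higher values always render
    brighter.  The PNG carries no DICOM header, which is what makes it a
    de-identified hand-off format for imaging pipelines (assuming no
    burned-in pixel text, which is out of scope here).
    """
    ds = dcmread(instance_file)
    syntax = getattr(getattr(ds, "file_meta", None), "TransferSyntaxUID", "unknown")
    if "PixelData" not in ds:
        raise PixelConversionError(
            f"{instance_file}: no pixel data (transfer syntax {syntax})")
    try:
        arr = ds.pixel_array.astype(np.float64)
    except Exception as exc:
        raise PixelConversionError(
            f"{instance_file}: cannot decode pixel data "
            f"(transfer syntax {syntax}): {exc}") from exc
    center, width = ds.get("WindowCenter"), ds.get("WindowWidth")
    if center is not None and width is not None:
        c, w = _first_number(center), _first_number(width)
        lo, hi = c - w / 2.0, c + w / 2.0
        scaled = np.clip((arr - lo) / max(hi - lo, 1e-12), 0.0, 1.0) * 255.0
    else:
        lo, hi = float(arr.min()), float(arr.max())
        scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255.0
    if str(ds.get("PhotometricInterpretation", "")).strip() == "MONOCHROME1":
        scaled = 255.0 - scaled
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.round(scaled).astype(np.uint8), mode="L").save(out)
    return out


# ---------------------------------------------------------------------------
# de-identification
# ---------------------------------------------------------------------------

#: Attributes always present in de-identified output: object identity and,
#: when pixel data exists, the image-pixel module needed to interpret it.
DEID_MANDATORY = ("SOPClassUID", "SOPInstanceUID", "StudyInstanceUID",
                  "SeriesInstanceUID")
_PIXEL_MODULE = ("SamplesPerPixel", "PhotometricInterpretation", "Rows",
                 "Columns", "BitsAllocated", "BitsStored", "HighBit",
                 "PixelRepresentation", "PlanarConfiguration", "PixelData")


class UidMap:
    """Persistent original→surrogate UID map.

    Surrogates are issued sequentially under a dedicated sub-root of the
    package's private UID root, and the map is saved as JSON so study and
    series linkage survives across runs and across files.
    """

    _SUB_ROOT = UID_ROOT + "99."

    def __init__(self, path: Path | str | None = None):
        self.path = Path(path) if path else None
        self._map: dict[str, str] = {}
        if self.path and self.path.exists():
            self._map = json.loads(self.path.read_text())

    def remap(self, uid: str) -> str:
        if uid not in self._map:
            self._map[uid] = f"{self._SUB_ROOT}{len(self._map) + 1}"
        return self._map[uid]

    def save(self) -> None:
        if self.path is None:
            return
        tmp = self.path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self._map, indent=0))
        tmp.replace(self.path)

    def __len__(self) -> int:
        return len(self._map)


def deidentify(
    instance_file: Path | str,
    keep: Sequence[str],
    uid_map: UidMap,
    out: Path | str,
    phi_exclusion: Sequence[str] = DEFAULT_PHI_EXCLUSION,
) -> Path:
    """Write a de-identified copy containing ONLY the whitelisted attributes.

    The output holds the kept attributes (those present in the source),
    remapped SOP/series/study UIDs (consistent through ``uid_map``, so
    multi-instance linkage survives), the image-pixel module, and the file
    meta required for a valid Part 10 file.  Pixel data is copied bit-exact.
    Asking to keep a PHI-listed attribute raises before anything is written.
    """
    if not keep:
        raise ValueError("keep list must be non-empty")
    banned = {k.lower() for k in phi_exclusion}
    offenders = [k for k in keep if k.lower() in banned]
    if offenders:
        raise ValueError(f"keep list contains PHI attributes: {offenders}")

    src = dcmread(instance_file)
    out_ds = Dataset()
    out_ds.SOPClassUID = src.SOPClassUID
    out_ds.SOPInstanceUID = uid_map.remap(str(src.SOPInstanceUID))
    out_ds.StudyInstanceUID = uid_map.remap(str(src.get("StudyInstanceUID", "")))
    out_ds.SeriesInstanceUID = uid_map.remap(str(src.get("SeriesInstanceUID", "")))
    for keyword in keep:
        if keyword in DEID_MANDATORY:
            continue
        if keyword in src:
            element = src.data_element(keyword)
            if element is not None:
                out_ds.add(element)
    if "PixelData" in src:
        for keyword in _PIXEL_MODULE:
            if keyword in src:
                out_ds.add(src.data_element(keyword))

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = out_ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = out_ds.SOPInstanceUID
    meta.TransferSyntaxUID = src.file_meta.TransferSyntaxUID
    out_ds.file_meta = meta
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out_ds.save_as(out, enforce_file_format=True)
    uid_map.save()
    return out
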