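"""Exam windows, utilization, clock skew, PNG export, de-identification."""

import hashlib
from datetime import date, datetime, timedelta

import numpy as np
import pytest
from PIL import Image
from pydicom import dcmread

import pacsflow as pf
from pacsflow.analytics import (
    ClockSkewReport,
    DEFAULT_SKEW_THRESHOLD,
    DEID_MANDATORY,
    ExamWindow,
    PixelConversionError,
    UidMap,
    clock_skew_report,
    compute_exam_windows,
    deidentify,
    detect_overlaps,
    dicom_to_png,
    flagged_scanners,
    utilization_report,
    windows_from_entries,
)
from pacsflow.metadata import MetadataDocument

from conftest import FLEET_DAY

DAY = date(2024, 1, 15)


def doc(scanner="S1", accession="A1", series="1.1", da="20240115",
        tm="080000", receipt=None):
    values = {"StationName": scanner, "AccessionNumber": accession,
              "StudyInstanceUID": f"study-{accession}",
              "AcquisitionDate": da, "AcquisitionTime": tm}
    return MetadataDocument(series_uid=series, profile="ops", values=values,
                            receipt_time=receipt)


def window(start_hm, end_hm, scanner="S1", key="A1"):
    return ExamWindow(scanner_id=scanner, exam_key=key,
                      start=datetime(2024, 1, 15, *start_hm),
                      end=datetime(2024, 1, 15, *end_hm))


class TestExamWindows:
    def test_window_is_min_max_over_documents(self):
        docs = [doc(series=f"1.{i}", tm=tm)
                for i, tm in enumerate(["080000", "081000", "082500"])]
        result = compute_exam_windows(docs)
        (w,) = result.windows
        assert (w.start, w.end) == (datetime(2024, 1, 15, 8, 0),
                                    datetime(2024, 1, 15, 8, 25))
        assert w.duration == timedelta(minutes=25)

    def test_single_document_yields_zero_length_window(self):
        (w,) = compute_exam_windows([doc()]).windows
        assert w.start == w.end

    def test_unparseable_and_scannerless_documents_counted(self):
        bad_time = doc(series="1.2")
        bad_time.values["AcquisitionDate"] = "not-a-date"
        del bad_time.values["AcquisitionTime"]
        no_scanner = doc(series="1.3")
        del no_scanner.values["StationName"]
        result = compute_exam_windows([doc(), bad_time, no_scanner])
        assert len(result.windows) == 1
        assert result.n_excluded_no_timestamp == 1
        assert result.n_excluded_no_scanner == 1

    def test_timestamp_precedence_falls_back_to_series_then_content(self):
        fallback = doc()
        del fallback.values["AcquisitionDate"]
        del fallback.values["AcquisitionTime"]
        fallback.values.update(SeriesDate="20240115", SeriesTime="091500")
        (w,) = compute_exam_windows([fallback]).windows
        assert w.start == datetime(2024, 1, 15, 9, 15)

    def test_study_grouping_exposed(self):
        docs = [doc(series="1.1"), doc(series="1.2", tm="090000")]
        for grouping in ("accession", "study"):
            (w,) = compute_exam_windows(docs, grouping=grouping).windows
            assert w.duration == timedelta(hours=1)
        with pytest.raises(ValueError):
            compute_exam_windows(docs, grouping="bogus")

    def test_fleet_windows_contained_in_true_intervals(self, nine_pipeline):
        """Each computed window sits inside the generator's true exam
        interval shifted by that scanner's clock offset."""
        pipe = nine_pipeline
        result = compute_exam_windows(pipe.documents())
        truth = {e.accession: e for e in pipe.fleet.schedule}
        offsets = {s.scanner_id: timedelta(minutes=s.clock_offset_min)
                   for s in pipe.fleet.scanners}
        assert len(result.windows) == len(truth)
        for w in result.windows:
            exam = truth[w.exam_key]
            shift = offsets[w.scanner_id]
            assert w.start == exam.true_start + shift  # first series starts the exam
            assert w.end <= exam.true_end + shift


class TestUtilization:
    def test_idle_gap_and_busy_fraction_arithmetic(self):
        report = utilization_report([window((8, 0), (8, 25)),
                                     window((9, 0), (9, 30), key="A2")], DAY)
        assert report.idle_gaps == [timedelta(minutes=35)]
        assert report.busy_fraction == pytest.approx((25 + 30) / 90)
        assert report.overlaps == []

    def test_single_window_fully_busy(self):
        report = utilization_report([window((8, 0), (8, 25))], DAY)
        assert report.idle_gaps == []
        assert report.busy_fraction == 1.0

    def test_empty_input_empty_report(self):
        report = utilization_report([], DAY)
        assert report.windows == [] and report.busy_fraction == 0.0

    def test_mixed_scanners_rejected(self):
        with pytest.raises(ValueError, match="multiple scanners"):
            utilization_report([window((8, 0), (9, 0)),
                                window((8, 0), (9, 0), scanner="S2")], DAY)

    def test_conservation_identity_on_fleet_fixture(self, nine_pipeline):
        """Sum of durations + sum of idle gaps == span, exactly, per scanner."""
        result = compute_exam_windows(nine_pipeline.documents())
        scanners = {w.scanner_id for w in result.windows}
        assert scanners  # non-vacuous
        for sid in scanners:
            windows = [w for w in result.windows if w.scanner_id == sid]
            report = utilization_report(windows, FLEET_DAY)
            assert report.overlaps == []
            total = sum(report.exam_durations, timedelta(0)) + \
                sum(report.idle_gaps, timedelta(0))
            assert total == report.span


class TestOverlaps:
    def test_scanner_derived_windows_never_overlap(self, nine_pipeline):
        result = compute_exam_windows(nine_pipeline.documents())
        for sid in {w.scanner_id for w in result.windows}:
            assert detect_overlaps(
                [w for w in result.windows if w.scanner_id == sid]) == []

    def test_forced_overlap_is_reported(self):
        a = window((8, 0), (8, 40))
        b = window((8, 30), (9, 0), key="A2")
        assert detect_overlaps([a, b]) == [(a, b)]

    def test_touching_endpoints_are_not_overlap(self):
        a = window((8, 0), (8, 30))
        b = window((8, 30), (9, 0), key="A2")
        assert detect_overlaps([a, b]) == []

    def test_corrupted_schedule_shows_overlaps_truth_does_not(self, nine_fleet):
        true_entries = [(e.accession, e.true_start, e.true_end)
                        for e in nine_fleet.schedule if e.scanner_id == "S1"]
        assert detect_overlaps(windows_from_entries(true_entries, "S1")) == []
        corrupted = pf.corrupt_schedule(
            [e for e in nine_fleet.schedule], 1.0, seed=5)
        by_scanner = {e.accession: e.scanner_id for e in nine_fleet.schedule}
        overlap_found = False
        for sid in {s.scanner_id for s in nine_fleet.scanners}:
            entries = [e for e in corrupted.entries if by_scanner[e[0]] == sid]
            if detect_overlaps(windows_from_entries(entries, sid)):
                overlap_found = True
        assert overlap_found


class TestClockSkew:
    def make_docs(self, offset_min, delay_min=2.0, n=5, scanner="S1"):
        docs = []
        for i in range(n):
            true_t = datetime(2024, 1, 15, 8, 0) + timedelta(minutes=10 * i)
            header = true_t + timedelta(minutes=offset_min)
            receipt = true_t + timedelta(minutes=delay_min)
            docs.append(doc(scanner=scanner, series=f"1.{i}",
                            da=header.strftime("%Y%m%d"),
                            tm=header.strftime("%H%M%S"),
                            receipt=receipt.isoformat()))
        return docs

    def test_calibrated_scanner_not_flagged(self):
        (report,) = clock_skew_report(self.make_docs(0.0)).values()
        assert report.median_skew == timedelta(minutes=2)
        assert not report.flagged

    def test_hour_ahead_scanner_flagged(self):
        (report,) = clock_skew_report(self.make_docs(60.0)).values()
        assert report.median_skew == timedelta(minutes=-58)
        assert report.flagged

    def test_median_robust_to_single_delayed_image(self):
        docs = self.make_docs(0.0)
        delayed = datetime.fromisoformat(docs[0].receipt_time) + timedelta(hours=5)
        docs[0].receipt_time = delayed.isoformat()
        (report,) = clock_skew_report(docs).values()
        assert not report.flagged
        assert report.n_exceeding == 1  # per-image exceedance still surfaced

    def test_date_only_timestamps_unassessable_not_flagged(self):
        docs = [doc(tm="", receipt="2024-01-15T08:02:00")]
        (report,) = clock_skew_report(docs).values()
        assert not report.assessable and not report.flagged
        assert report.median_skew is None

    def test_nine_fleet_parameter_recovery(self, nine_pipeline):
        """Flagged set == scanners with |offset| > 20 min, exactly."""
        reports = clock_skew_report(nine_pipeline.documents())
        offsets = {s.scanner_id: s.clock_offset_min
                   for s in nine_pipeline.fleet.scanners}
        expected = {sid for sid, off in offsets.items() if abs(off) > 20}
        assert flagged_scanners(reports) == expected
        delay = timedelta(minutes=2)
        for sid, report in reports.items():
            assert report.median_skew == delay - timedelta(minutes=offsets[sid])


class TestPngExport:
    def test_ramp_scales_to_full_8bit_range(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        out = dicom_to_png(src, tmp_path / "out.png")
        arr = np.asarray(Image.open(out))
        assert arr.shape == (16, 16)
        assert arr.min() == 0 and arr.max() == 255

    def test_monochrome1_inverts_against_twin(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        ds = dcmread(src)
        ds.PhotometricInterpretation = "MONOCHROME1"
        twin = tmp_path / "mono1.dcm"
        ds.save_as(twin, enforce_file_format=True)
        normal = np.asarray(Image.open(dicom_to_png(src, tmp_path / "a.png")))
        inverted = np.asarray(Image.open(dicom_to_png(twin, tmp_path / "b.png")))
        assert np.array_equal(inverted, 255 - normal)

    def test_window_center_width_applied(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        ds = dcmread(src)
        ds.WindowCenter, ds.WindowWidth = 64, 128  # clips everything >= 128
        windowed = tmp_path / "win.dcm"
        ds.save_as(windowed, enforce_file_format=True)
        arr = np.asarray(Image.open(dicom_to_png(windowed, tmp_path / "w.png")))
        assert arr.max() == 255 and (arr == 255).sum() > 1  # saturated tail

    def test_missing_pixel_data_error_names_transfer_syntax(
            self, small_fleet, tmp_path):
        ds = dcmread(sorted(small_fleet.archive.glob("*.dcm"))[0])
        del ds.PixelData
        bare = tmp_path / "bare.dcm"
        ds.save_as(bare, enforce_file_format=True)
        with pytest.raises(PixelConversionError, match="1.2.840.10008.1.2.1"):
            dicom_to_png(bare, tmp_path / "x.png")


class TestDeidentify:
    KEEP = ["Modality", "BodyPartExamined"]

    def test_output_attributes_within_whitelist_plus_mandatory(
            self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        out = deidentify(src, self.KEEP, UidMap(), tmp_path / "deid.dcm")
        ds = dcmread(out)
        pixel_module = {"SamplesPerPixel", "PhotometricInterpretation", "Rows",
                        "Columns", "BitsAllocated", "BitsStored", "HighBit",
                        "PixelRepresentation", "PlanarConfiguration", "PixelData"}
        allowed = set(self.KEEP) | set(DEID_MANDATORY) | pixel_module
        present = {elem.keyword for elem in ds if elem.keyword}
        assert present <= allowed
        assert "PatientName" not in ds and "PatientID" not in ds
        # private vendor tags are gone too
        assert all(not elem.tag.is_private for elem in ds)

    def test_pixel_data_preserved_bit_exact(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        out = deidentify(src, self.KEEP, UidMap(), tmp_path / "deid.dcm")
        digest = lambda p: hashlib.sha256(dcmread(p).PixelData).hexdigest()
        assert digest(src) == digest(out)

    def test_uid_linkage_survives_remapping(self, small_fleet, tmp_path):
        uid_map = UidMap(tmp_path / "map.json")
        paths = sorted(small_fleet.archive.glob("*.dcm"))
        by_series = {}
        for path in paths[:6]:
            ds = dcmread(path)
            by_series.setdefault(str(ds.SeriesInstanceUID), []).append(path)
        series_files = next(files for files in by_series.values() if len(files) > 1)
        outs = [dcmread(deidentify(p, self.KEEP, UidMap(tmp_path / "map.json"),
                                   tmp_path / f"d{i}.dcm"))
                for i, p in enumerate(series_files)]
        remapped_series = {str(ds.SeriesInstanceUID) for ds in outs}
        remapped_sops = {str(ds.SOPInstanceUID) for ds in outs}
        assert len(remapped_series) == 1  # same series stays one series
        assert len(remapped_sops) == len(outs)  # instances stay distinct
        originals = {str(dcmread(p).SOPInstanceUID) for p in series_files}
        assert not remapped_sops & originals

    def test_keeping_phi_is_rejected_before_any_write(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        target = tmp_path / "never.dcm"
        with pytest.raises(ValueError, match="PHI"):
            deidentify(src, ["Modality", "PatientName"], UidMap(), target)
        assert not target.exists()

    def test_empty_keep_list_rejected(self, small_fleet, tmp_path):
        src = sorted(small_fleet.archive.glob("*.dcm"))[0]
        with pytest.raises(ValueError, match="non-empty"):
            deidentify(src, [], UidMap(), tmp_path / "never.dcm")


def test_default_threshold_is_twenty_minutes():
    assert DEFAULT_SKEW_THRESHOLD == timedelta(minutes=20)
    report = ClockSkewReport(scanner_id="S", threshold=DEFAULT_SKEW_THRESHOLD)
    assert report.threshold.total_seconds() == 1200
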