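"""Shared fixtures: synthetic fleets, archives and a full pipeline harness."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pytest

import pacsflow as pf

#: Clock offsets (minutes) of the nine-scanner calibration fleet; exactly
#: five exceed the 20-minute threshold in magnitude.
NINE_OFFSETS = (0.0, 5.0, 25.0, -60.0, 300.0, 12.0, -1440.0, 18.0, 45.0)

FLEET_DAY = date(2024, 1, 15)


def make_scanners(offsets, prefix="S"):
    return [pf.ScannerSpec(scanner_id=f"{prefix}{i}", clock_offset_min=off)
            for i, off in enumerate(offsets, start=1)]


@dataclass
class Fleet:
    scanners: list
    schedule: pf.FleetSchedule
    archive: Path

    @property
    def sop_uids(self) -> set[str]:
        return {p.stem for p in self.archive.glob("*.dcm")}

    @property
    def manifest(self) -> dict:
        return pf.synthetic.load_manifest(self.archive)


def build_fleet(tmp: Path, offsets, exams_per_scanner=2, seed=1) -> Fleet:
    scanners = make_scanners(offsets)
    schedule = pf.generate_fleet_schedule(scanners, FLEET_DAY,
                                          exams_per_scanner, seed)
    archive = tmp / "archive"
    pf.materialize_instances(schedule.exams, scanners, archive)
    return Fleet(scanners=scanners, schedule=schedule, archive=archive)


@pytest.fixture(scope="session")
def nine_fleet(tmp_path_factory) -> Fleet:
    """Nine scanners spanning calibrated, mildly-off and wildly-off clocks."""
    return build_fleet(tmp_path_factory.mktemp("nine"), NINE_OFFSETS)


@pytest.fixture(scope="session")
def small_fleet(tmp_path_factory) -> Fleet:
    """Two scanners: one calibrated, one a full hour ahead."""
    return build_fleet(tmp_path_factory.mktemp("small"), (0.0, 60.0))


@dataclass
class Pipeline:
    """A wired-up research store fed from a fleet archive via the mock PACS."""

    fleet: Fleet
    root: Path
    network: pf.DimseNetwork
    clock: pf.SimulatedClock
    listener: pf.StorageListener
    pacs: pf.MockPacs
    store: pf.DocumentStore = None
    state: pf.ExtractionState = None
    profiles: list = field(default_factory=list)

    @property
    def storage_root(self) -> Path:
        return self.root / "store"

    @property
    def state_dir(self) -> Path:
        return self.root / "state"

    def retrieve_all(self, max_retries: int = 2,
                     pacs=None) -> pf.cold_extraction.RetrievalReport:
        csv_path = self.root / "accessions.csv"
        accessions = sorted({e.accession for e in self.fleet.schedule})
        csv_path.write_text("Accession\n" + "\n".join(accessions) + "\n")
        specs = pf.parse_query_csv(csv_path, pf.QueryShape.ACCESSION)
        progress = pf.RetrievalProgress(self.root / "progress")
        return pf.run_batch_retrieval(specs, pacs or self.pacs, "RESEARCH",
                                      progress, max_retries=max_retries)

    def extract(self, profile_attrs=pf.OPS_PROFILE_ATTRIBUTES,
                profile_name="ops") -> int:
        profile_dir = self.root / "profiles"
        profile_dir.mkdir(exist_ok=True)
        (profile_dir / f"{profile_name}.txt").write_text(
            "\n".join(profile_attrs) + "\n")
        self.profiles = pf.load_profiles(profile_dir)
        if self.store is None:
            self.store = pf.DocumentStore(self.root / "docs.sqlite")
        if self.state is None:
            self.state = pf.ExtractionState.load(self.state_dir)
        return pf.run_extraction_cycle(self.state, self.listener.index,
                                       self.profiles, self.store,
                                       self.storage_root,
                                       state_dir=self.state_dir)

    def documents(self, profile_name="ops") -> list[pf.MetadataDocument]:
        return [pf.MetadataDocument(series_uid=s, profile=profile_name,
                                    values=v, receipt_time=r)
                for s, v, r in self.store.iter_documents(profile_name)]


def build_pipeline(fleet: Fleet, root: Path, **pacs_kwargs) -> Pipeline:
    root.mkdir(parents=True, exist_ok=True)
    network = pf.DimseNetwork()
    clock = pf.SimulatedClock(datetime.combine(FLEET_DAY, datetime.min.time()))
    listener = pf.start_listener(
        pf.SourceConfig(name="research", ae_title="RESEARCH", port=11112,
                        storage_root=root / "store"),
        network, clock=clock)
    pacs = pf.mock_pacs_serve(fleet.archive, network,
                              simulated_clock=clock, **pacs_kwargs)
    return Pipeline(fleet=fleet, root=root, network=network, clock=clock,
                    listener=listener, pacs=pacs)


@pytest.fixture
def pipeline(small_fleet, tmp_path) -> Pipeline:
    return build_pipeline(small_fleet, tmp_path / "pipe")


@pytest.fixture(scope="session")
def nine_pipeline(nine_fleet, tmp_path_factory) -> Pipeline:
    """Fully-run pipeline over the nine-scanner fleet (retrieve + extract)."""
    pipe = build_pipeline(nine_fleet, tmp_path_factory.mktemp("ninepipe"))
    report = pipe.retrieve_all()
    assert report.n_failed == 0
    pipe.extract()
    return pipe
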