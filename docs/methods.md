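# Methods

## Scope and model

`pacsflow` models a hospital-to-research-cluster imaging pipeline as five
cooperating components: a synthetic scanner fleet with an embedded mock
PACS, real-time ingestion, on-demand (cold) retrieval, profile-driven
metadata extraction, and storage lifecycle management, with an analytics
layer on top. The unit of clinical work is the *exam* (one accession on one
scanner), which produces one study of several series, each of several
instances.

## Transport model

The DIMSE services (C-STORE, C-FIND, C-MOVE) are carried by an in-process
message layer (`pacsflow.dimse`): an AE-title registry resolves C-MOVE
destinations, services return DICOM status codes (0x0000 success, 0xA801
unknown move destination, 0xC000 processing failure), and a C-MOVE is
executed as a sequence of C-STORE sub-operations to the resolved
destination. Everything above the wire — query matching semantics, status
handling, retry and resume behaviour, idempotent re-stores — behaves as the
DICOM services define; PDU encoding and association negotiation are out of
scope. This keeps the full pipeline runnable and deterministic inside one
process, which is what the test suite and the acceptance script rely on.

## Synthetic fleet

The generator emulates the facts of scanner operation that the analytics
depend on, and nothing more:

* **Schedules.** Per scanner and day, exams are laid out sequentially from
  a 07:00 start: duration ~ U(15, 45) min, inter-exam gap ~ U(5, 30) min
  (bounds are parameters and are recorded in the schedule provenance).
  Disjointness within a scanner therefore holds by construction — a scanner
  runs one exam at a time — while different scanners overlap freely, as in
  a real fleet. If a requested exam would run past midnight the generator
  raises rather than silently truncating.
* **Clocks.** Each scanner has a signed clock offset in minutes. Every
  header timestamp (Study/Series/Acquisition/Content Date and Time) equals
  the true instant *plus* the offset, which is exactly how a wrong timezone
  manifests. Instance acquisition instants are spread evenly across the
  exam window with the first and last instants hitting the window
  endpoints, so min/max over instances recovers the (offset-shifted)
  window exactly.
* **Instances.** Secondary-capture objects with a 16×16 8-bit ramp payload
  (0..255) — enough to exercise PNG scaling and bit-exact pixel
  preservation while keeping fixtures kilobyte-scale. A synthetic
  PatientName/BirthDate and one private vendor tag are included so
  PHI-stripping and de-identification are testable. Transfer syntax is
  Explicit VR Little Endian.
* **Determinism.** All randomness derives from string-seeded generators
  keyed on (seed, scanner, day); UIDs are SHA-1-derived under a private
  root, a pure function of the exam identifiers. Identical inputs produce
  byte-stable schedules and UID sets.
* **Receipt times.** A fixed network/processing delay (default 2 min,
  recorded in the archive manifest) separates true acquisition from
  arrival. The mock PACS replays each instance by setting an injectable
  simulated clock to `true acquisition + delay` immediately before the
  C-STORE, and the listener stamps receipt from that clock — receipt time
  is always assigned by the listener, never read from headers, while skew
  experiments remain exact.

What the generator does **not** emulate: realistic pixel content, modality
physics, compressed transfer syntaxes, header incompleteness and vendor
quirks, PACS-side throttling, or out-of-order/duplicated network delivery
beyond what the fault-injection hook produces. Passing tests therefore
demonstrate the pipeline's logic — filing, resume, exactly-once effects,
parameter recovery — not robustness to the full diversity of clinical
headers.

## Ingestion

Each accepted C-STORE is written to a temp name and atomically renamed
(no partial files survive a crash), then appended — flushed and fsynced —
to a newline-delimited JSON index. Re-storing a SOP instance overwrites the
file and appends an updated record; loads are last-write-wins, so C-MOVE
retries never inflate counts. A startup `reconcile()` sweep indexes any
orphan file from the crash window between rename and append. Storage paths
are sanitized (`[^A-Za-z0-9.-]` → `_`) at a configurable depth (patient /
patient-study / patient-study-series, the last being default); a missing
patient or study falls into an `UNKNOWN` bucket rather than rejecting the
instance, because real scanners do emit incomplete headers; a missing SOP
instance UID is the one unfixable case and is rejected.

## Cold retrieval

Progress is per query (C-MOVE is atomic per study from the client's view):
completed keys and attempt counts live in newline-delimited files replaced
atomically. The attempt counter is persisted *before* the query is issued,
which bounds PACS-side work to `1 + max_retries` attempts per query across
any crash/restart sequence. A failed move retries the whole query —
re-sent instances are idempotent at the listener. Zero C-FIND matches is a
completed query flagged "no-match", not an error. Queries run sequentially
(an optional inter-query delay is available); study-date queries take one
exact date — ranges are out of scope.

## Metadata extraction

One representative instance per series (default: lowest InstanceNumber,
missing numbers ordered last, ties broken by SOP UID) feeds one document
per (series, profile). The cycle marks a series extracted only after its
document upsert commits, and the upsert key (profile, series) makes
duplicate writes harmless — at-least-once work with exactly-once visible
effect. Progress checkpoints every 25 documents (configurable) and at cycle
end, bounding re-work after a kill. Numeric VRs are stored as numbers,
multi-valued attributes as ordered lists, everything else as strings.
An unparseable file leaves its series pending for the next cycle.

The default PHI exclusion list covers directly identifying attributes
(names, birth dates, addresses, phone numbers, physician and operator
names, institution address). PatientID and AccessionNumber are retained by
default because cohort workflows require them; collection-level access
control is the intended isolation boundary, and the list is configurable
for sites that share collections. PHI stripping happens at profile load
*and* again at extraction, so a hand-built profile cannot leak.

Two trigger modes exist: interval polling (default 600 s) and per-arrival
events via the listener's `on_store` callback.

## Lifecycle

The cleaner deletes a series only when it is extracted for **all** active
profiles, is not held by a registered consumer, and is older than the
retention floor (default 1 day since receipt). With zero active profiles it
refuses to delete anything — the all-profiles condition must never be
vacuously true. "Still processing" detection is an explicit holds file that
consumers register series into; lock-file sniffing was rejected as
unportable. Deleted-series progress is a durable UID set, making the
nightly run (default 23:59) idempotent; a series whose files are already
gone is absorbed silently, covering the crash window between unlink and
persist. State files are newline-delimited UID sets written via atomic
rename; a corrupt file raises with an instruction to rebuild, and
`ExtractionState.rebuild_from_store` reconstructs the extracted sets from
the document collections.

## Analytics

* **Windows.** Timestamp precedence is Acquisition → Series → Content
  (date/time pairs); the first parseable pair wins. Exam identity is
  AccessionNumber with StudyInstanceUID fallback (study grouping is also
  exposed); scanner identity is StationName with DeviceSerialNumber
  fallback. A window is min/max over the exam's documents; single-document
  exams give zero-length windows; documents without a usable timestamp or
  scanner are excluded and counted. A window belongs to the day containing
  its start; midnight-spanning windows are legal.
* **Utilization.** Windows sorted by start; idle gaps are the positive
  gaps between consecutive windows; busy fraction is Σ durations over the
  first-start→last-end span (degenerate zero span ⇒ 1.0). When no windows
  overlap, Σ durations + Σ gaps equals the span exactly (timedelta
  arithmetic, no floats). Overlap is positive-length intersection;
  touching endpoints are legal back-to-back scheduling.
* **Skew.** skew = receipt − acquisition; positive means delay or a
  scanner clock running behind, negative a clock running ahead. Date-only
  (low-precision) instants are excluded. The per-scanner decision statistic
  is the median — chosen over per-image flagging so one image stuck in a
  send queue cannot flag a scanner — with the per-image exceedance count
  still reported for drill-down. The default threshold is 20 minutes,
  sized to dominate ordinary network and processing delay. A scanner with
  no usable timestamps is reported unassessable, never flagged.
* **PNG export.** Window center/width applied when present, else min–max
  scaling to 8-bit; MONOCHROME1 inverted; output carries no DICOM header.
* **De-identification.** Whitelist semantics: output contains only the
  kept attributes, remapped UIDs (sequential surrogates under a dedicated
  private sub-root, persisted as JSON so linkage survives across runs),
  and the image-pixel module copied bit-exact. A keep list that names a
  PHI attribute fails before any write.

## Problem sizes

Tests and the acceptance script use a nine-scanner fleet (clock offsets
0, +5, +25, −60, +300, +12, −1440, +18, +45 min), two exams per scanner
per day, 2–3 series per exam and 2–4 instances per series — about 150
instances end to end. These sizes exercise every code path (multi-study
queries, retries, partial cycles, cleanup interlocks) while keeping the
whole suite in the seconds range; all structural results (flag sets,
conservation identities, completeness fractions) are invariant to scaling
the fleet up.

## Known limitations

* No wire-level DIMSE: the transport is in-process, so interoperability
  with real PACS implementations is untested by design.
* Compressed transfer syntaxes (e.g. JPEG Lossless) are not generated or
  decoded; the pixel path is uncompressed only.
* No SERIES/IMAGE-level or patient-root query models; no C-GET.
* Pixel-level PHI (burned-in annotations) is out of scope for both PNG
  export and de-identification.
* Storage encryption at rest is treated as a deployment concern.
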