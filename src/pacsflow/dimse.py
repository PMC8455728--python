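"""In-process DIMSE-semantics message layer.

The framework's moving parts — the mock PACS, the storage listeners, the
batch retriever — talk to each other through the C-STORE / C-FIND / C-MOVE
service semantics: status codes, an AE-title registry, and move-destination
resolution. This module carries those semantics as direct Python calls so a
whole fleet-to-research-store pipeline runs inside one process. The wire
encoding (PDUs, association negotiation) is out of scope; everything above
it — who may receive, what a query matches, how a move failure surfaces —
behaves as the DICOM services define.
"""

from __future__ import annotations

from typing import Protocol

from pydicom import Dataset

# DIMSE status codes (subset used by the framework)
STATUS_SUCCESS = 0x0000
STATUS_PENDING = 0xFF00
STATUS_MOVE_DEST_UNKNOWN = 0xA801
STATUS_PROCESSING_FAILURE = 0xC000


class StoreSCP(Protocol):
    """Anything that can accept a C-STORE: a storage listener, a test probe."""

    ae_title: str

    def c_store(self, ds: Dataset) -> int: ...


class UnknownAETitle(KeyError):
    """Raised when a destination AE title is not registered on the network."""


class DimseNetwork:
    """Registry of application entities reachable for C-STORE sub-operations.

    Plays the role of the DICOM network fabric: a C-MOVE names a destination
    AE title, and the serving PACS resolves it here before pushing instances.
    """

    def __init__(self) -> None:
        self._entities: dict[str, StoreSCP] = {}

    def register(self, scp: StoreSCP) -> None:
        if scp.ae_title in self._entities:
            raise ValueError(f"AE title already registered: {scp.ae_title}")
        self._entities[scp.ae_title] = scp

    def unregister(self, ae_title: str) -> None:
        self._entities.pop(ae_title, None)

    def resolve(self, ae_title: str) -> StoreSCP:
        try:
            return self._entities[ae_title]
        except KeyError:
            raise UnknownAETitle(ae_title) from None

    def ae_titles(self) -> list[str]:
        return sorted(self._entities)


def is_success(status: int) -> bool:
    return status == STATUS_SUCCESS


def is_failure(status: int) -> bool:
    return status not in (STATUS_SUCCESS, STATUS_PENDING)
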