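"""Anchor-based parsing of cassette reads into element identities.

Each read is scanned for fixed vector anchors (CACCG before the SpCas9
spacer, a tracr-derived fragment before barcode 1, an overlap-extension
fragment before barcode 2, and CTTAAAC before the reverse-complemented
SaCas9 spacer); the fixed-length substring immediately following each
anchor is looked up in the reference library. Because the sequencing
primer is separated from the cassette by a variable-length stagger,
anchors are searched over the whole read (leftmost occurrence) rather
than at fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO

from .library_design import (
    BARCODE_LEN,
    ELEMENT_ANCHOR,
    ELEMENT_ORDER,
    SA_SPACER_LEN,
    SP_SPACER_LEN,
    CassetteLayout,
    LibraryDesign,
    hamming,
    revcomp,
)

#: sentinel: the element's sequence did not match the reference
UNMAPPED = "UNMAPPED"
#: sentinel: the element's anchor was not found in the read
ANCHOR_NOT_FOUND = "ANCHOR_NOT_FOUND"
SENTINELS = (UNMAPPED, ANCHOR_NOT_FOUND)

ELEMENT_LENGTHS = {
    "sp_spacer": SP_SPACER_LEN,
    "sp_barcode": BARCODE_LEN,
    "sa_barcode": BARCODE_LEN,
    "sa_spacer_rc": SA_SPACER_LEN,
}


def find_anchor(read: str, anchor: str, window: tuple[int, int] | None = None):
    """Leftmost 0-based position of ``anchor`` within ``window``, or None.

    ``window`` is a 0-based half-open interval on the read; None means the
    whole read. A missing anchor is a value (None), not an error.
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    start, end = window if window is not None else (0, len(read))
    pos = read.find(anchor, start, end)
    return pos if pos >= 0 and pos + len(anchor) <= end else None


@dataclass(frozen=True)
class ExtractedElements:
    """Raw element substrings pulled from one read (None when absent)."""

    sp_spacer: str | None
    sp_barcode: str | None
    sa_barcode: str | None
    sa_spacer_rc: str | None

    def get(self, name: str) -> str | None:
        return getattr(self, name)


def extract_elements(read: str, layout: CassetteLayout) -> ExtractedElements:
    """Pull the four fixed-length elements out of a read via anchor search.

    Each element is the substring immediately following the leftmost
    occurrence of its anchor. A missing anchor, or a read that ends before
    the element is complete, leaves that element (and only that element)
    absent.
    """
    out: dict[str, str | None] = {}
    for element in ELEMENT_ORDER:
        anchor = getattr(layout.anchors, ELEMENT_ANCHOR[element])
        pos = find_anchor(read, anchor)
        if pos is None:
            out[element] = None
            continue
        start = pos + len(anchor)
        end = start + ELEMENT_LENGTHS[element]
        out[element] = read[start:end] if end <= len(read) else None
    return ExtractedElements(**out)


@dataclass(frozen=True)
class ReferenceLibrary:
    """Sequence -> construct-id lookups for all four elements.

    The SaCas9 spacer map is keyed by the spacer's reverse complement, as
    that is the orientation in which it appears on the sequenced strand.
    All mappings are injective by construction (library sequences unique).
    """

    sp_spacer: dict[str, str]
    sp_barcode: dict[str, str]
    sa_barcode: dict[str, str]
    sa_spacer_rc: dict[str, str]
    expected_pairs: dict[str, str]

    @classmethod
    def from_design(cls, design: LibraryDesign) -> "ReferenceLibrary":
        return cls(
            sp_spacer={c.sp_spacer: c.id for c in design.constructs},
            sp_barcode={c.sp_barcode.seq: c.id for c in design.constructs},
            sa_barcode={c.sa_barcode.seq: c.id for c in design.constructs},
            sa_spacer_rc={revcomp(c.sa_spacer): c.id for c in design.constructs},
            expected_pairs=design.expected_pairs,
        )

    @property
    def construct_ids(self) -> list[str]:
        return list(self.expected_pairs)

    def mapping_for(self, element: str) -> dict[str, str]:
        return getattr(self, element)


def map_element(seq: str, reference: dict[str, str], max_mismatch: int = 0) -> str:
    """Look up an element sequence in a reference mapping.

    With ``max_mismatch=0`` this is an exact lookup. With ``max_mismatch=1``
    the unique reference sequence within one substitution is returned;
    ties or distance > 1 give UNMAPPED. For a barcode code at Hamming
    distance >= 2, a 1-mismatch lookup can never miscall: the true barcode
    is the only candidate within distance 1 of any of its single mutants.
    """
    hit = reference.get(seq)
    if hit is not None or max_mismatch == 0:
        return hit if hit is not None else UNMAPPED
    best_id, best_d, ties = None, max_mismatch + 1, 0
    for ref_seq, ref_id in reference.items():
        if len(ref_seq) != len(seq):
            continue
        d = hamming(seq, ref_seq)
        if d < best_d:
            best_id, best_d, ties = ref_id, d, 1
        elif d == best_d:
            ties += 1
    if best_d <= max_mismatch and ties == 1:
        return best_id
    return UNMAPPED


@dataclass(frozen=True)
class ReadAssignment:
    """Mapped identity (or sentinel) of each cassette element in one read."""

    read_id: str
    sp_id: str
    sp_bc_id: str
    sa_bc_id: str
    sa_id: str

    _ATTR = {
        "sp_spacer": "sp_id",
        "sp_barcode": "sp_bc_id",
        "sa_barcode": "sa_bc_id",
        "sa_spacer_rc": "sa_id",
    }

    def get(self, element: str) -> str:
        return getattr(self, self._ATTR[element])

    @property
    def fully_assigned(self) -> bool:
        return all(self.get(e) not in SENTINELS for e in ELEMENT_ORDER)


@dataclass
class ParseSummary:
    """Per-slot mapping tallies for a parsed read set."""

    total_reads: int = 0
    fully_assigned: int = 0
    mapped: dict[str, int] = field(
        default_factory=lambda: {e: 0 for e in ELEMENT_ORDER}
    )
    unmapped: dict[str, int] = field(
        default_factory=lambda: {e: 0 for e in ELEMENT_ORDER}
    )
    anchor_missing: dict[str, int] = field(
        default_factory=lambda: {e: 0 for e in ELEMENT_ORDER}
    )

    def add(self, assignment: ReadAssignment) -> None:
        self.total_reads += 1
        if assignment.fully_assigned:
            self.fully_assigned += 1
        for element in ELEMENT_ORDER:
            value = assignment.get(element)
            if value == ANCHOR_NOT_FOUND:
                self.anchor_missing[element] += 1
            elif value == UNMAPPED:
                self.unmapped[element] += 1
            else:
                self.mapped[element] += 1

    def check(self) -> None:
        for element in ELEMENT_ORDER:
            total = (
                self.mapped[element]
                + self.unmapped[element]
                + self.anchor_missing[element]
            )
            assert total == self.total_reads, f"slot tally mismatch for {element}"


@dataclass(frozen=True)
class ParseOptions:
    """Knobs for read assignment.

    ``barcode_max_mismatch`` enables 1-mismatch rescue for barcodes only
    (safe under a distance-2 code); spacers are always matched exactly.
    ``try_revcomp`` retries the reverse-complemented read when the forward
    strand yields no assignable element at all (anchors missing or only
    spurious matches).
    """

    barcode_max_mismatch: int = 0
    try_revcomp: bool = False


def _parse_strand(
    seq: str,
    refs: ReferenceLibrary,
    layout: CassetteLayout,
    options: ParseOptions,
) -> dict[str, str]:
    extracted = extract_elements(seq, layout)
    values: dict[str, str] = {}
    for element in ELEMENT_ORDER:
        raw = extracted.get(element)
        if raw is None:
            values[element] = ANCHOR_NOT_FOUND
            continue
        mm = options.barcode_max_mismatch if element.endswith("barcode") else 0
        values[element] = map_element(raw, refs.mapping_for(element), mm)
    return values


def assign_read(
    read_id: str,
    seq: str,
    refs: ReferenceLibrary,
    layout: CassetteLayout,
    options: ParseOptions = ParseOptions(),
) -> ReadAssignment:
    """Assign a single read's four elements."""
    values = _parse_strand(seq, refs, layout, options)
    if options.try_revcomp and all(v in SENTINELS for v in values.values()):
        values = _parse_strand(revcomp(seq), refs, layout, options)
    return ReadAssignment(
        read_id=read_id,
        sp_id=values["sp_spacer"],
        sp_bc_id=values["sp_barcode"],
        sa_bc_id=values["sa_barcode"],
        sa_id=values["sa_spacer_rc"],
    )


def _iter_fastq(source) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path/handle, with record context."""
    record_no = 0
    try:
        for rec in SeqIO.parse(source, "fastq"):
            record_no += 1
            yield rec.id, str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {record_no + 1}: {exc}") from exc


def assign_reads(
    fastq: str | Path | TextIO | Iterable[tuple[str, str]],
    refs: ReferenceLibrary,
    layout: CassetteLayout,
    options: ParseOptions = ParseOptions(),
) -> tuple[list[ReadAssignment], ParseSummary]:
    """Parse a FASTQ stream into per-read assignments plus a summary.

    ``fastq`` may be a path, an open text handle, or an already-materialised
    iterable of (read_id, sequence) pairs. Quality values are ignored.
    """
    if isinstance(fastq, (str, Path)) or hasattr(fastq, "read"):
        pairs: Iterable[tuple[str, str]] = _iter_fastq(fastq)
    else:
        pairs = fastq
    assignments: list[ReadAssignment] = []
    summary = ParseSummary()
    for read_id, seq in pairs:
        a = assign_read(read_id, seq, refs, layout, options)
        assignments.append(a)
        summary.add(a)
    summary.check()
    return assignments, summary


def assignments_frame(assignments: Iterable[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.read_id, a.sp_id, a.sp_bc_id, a.sa_bc_id, a.sa_id)
            for a in assignments
        ],
        columns=["read_id", "sp_id", "sp_bc_id", "sa_bc_id", "sa_id"],
    )


def write_assignments_tsv(assignments: Iterable[ReadAssignment], path) -> None:
    assignments_frame(assignments).to_csv(path, sep="\t", index=False)
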