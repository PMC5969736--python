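"""Barcode sets, construct definitions and cassette geometry.

A dual-guide ("Big Papi"-style) cassette carries, on the sequenced strand:

    [upstream]-CACCG-[SpCas9 spacer, 20 nt]-[gap 82 nt, ending in a
    tracr-derived anchor]-[barcode 1, 6 nt]-[gap 17 nt, ending in an
    overlap-extension anchor]-[barcode 2, 6 nt]-[gap 82 nt, ending in
    CTTAAAC]-[SaCas9 spacer reverse complement, 21 nt]-[downstream]

Inter-element distances are counted as intervening nucleotides, exclusive
on both ends; this is the only convention under which the gap arithmetic
82 + 6 + 17 + 6 + 82 = 193 (spacer-to-spacer) holds and the two barcodes
are readable with a single 29-nt read. All coordinates are 0-based,
half-open.

The hexamer barcodes form a code with pairwise Hamming distance >= 2, so a
single substitution introduced by the polymerase or the sequencer can never
turn one valid barcode into another -- it is flagged and dropped instead.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"

SP_SPACER_LEN = 20  # SpCas9, U6-driven
SA_SPACER_LEN = 21  # SaCas9, H1-driven
BARCODE_LEN = 6

_HOMOPOLYMER_RE = re.compile(r"(.)\1{4}")  # run of >= 5 identical bases


class LengthMismatchError(ValueError):
    """Sequences of unequal length where equal length is required."""


class BarcodeCapacityError(ValueError):
    """The requested barcode set size is not achievable."""


class GeometryError(ValueError):
    """Stuffers or anchors violate the cassette distance constraints."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise LengthMismatchError(
            f"hamming requires equal lengths, got {len(a)} and {len(b)}"
        )
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Barcode:
    """A short synthetic tag uniquely identifying its linked spacer."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq or set(self.seq) - set(DNA_ALPHABET):
            raise ValueError(f"barcode {self.id!r}: invalid sequence {self.seq!r}")


@dataclass(frozen=True)
class BarcodeSet:
    """An ordered barcode collection with a guaranteed minimum pairwise distance.

    The invariants (unique ids, unique sequences, uniform length, all
    pairwise Hamming distances >= ``min_hamming``) are audited exhaustively
    on construction.
    """

    barcodes: tuple[Barcode, ...]
    min_hamming: int = 2

    def __post_init__(self) -> None:
        seqs = [b.seq for b in self.barcodes]
        ids = [b.id for b in self.barcodes]
        if len(set(ids)) != len(ids):
            raise ValueError("barcode ids are not unique")
        if len(set(seqs)) != len(seqs):
            raise ValueError("barcode sequences are not unique")
        if len({len(s) for s in seqs}) > 1:
            raise LengthMismatchError("barcodes have mixed lengths")
        for x, y in itertools.combinations(seqs, 2):
            if hamming(x, y) < self.min_hamming:
                raise ValueError(
                    f"barcodes {x} and {y} are closer than Hamming {self.min_hamming}"
                )

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def length(self) -> int:
        return len(self.barcodes[0].seq)


def design_barcodes(
    n: int,
    length: int = BARCODE_LEN,
    min_hamming: int = 2,
    seed: int | np.random.Generator = 0,
    id_prefix: str = "BC",
    max_restarts: int = 50,
) -> BarcodeSet:
    """Greedy random search for ``n`` barcodes with pairwise Hamming >= ``min_hamming``.

    Homopolymer candidates (a run of five or more identical bases) are
    rejected for synthesis and sequencing robustness. Deterministic for a
    given seed. Raises :class:`BarcodeCapacityError` when the greedy search
    (with restarts) cannot place ``n`` codes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if 4 ** length <= 4 ** 10:
        candidates = [
            "".join(t) for t in itertools.product(DNA_ALPHABET, repeat=length)
        ]
    else:  # pragma: no cover - very long codes; sample instead of enumerating
        candidates = [
            "".join(rng.choice(list(DNA_ALPHABET), size=length))
            for _ in range(200_000)
        ]
    candidates = [c for c in candidates if not _HOMOPOLYMER_RE.search(c)]

    for _ in range(max_restarts):
        order = rng.permutation(len(candidates))
        chosen: list[str] = []
        for i in order:
            cand = candidates[i]
            if all(hamming(cand, c) >= min_hamming for c in chosen):
                chosen.append(cand)
                if len(chosen) == n:
                    width = max(2, len(str(n)))
                    return BarcodeSet(
                        tuple(
                            Barcode(f"{id_prefix}{j + 1:0{width}d}", s)
                            for j, s in enumerate(chosen)
                        ),
                        min_hamming=min_hamming,
                    )
    raise BarcodeCapacityError(
        f"cannot design {n} barcodes of length {length} at Hamming >= {min_hamming}"
    )


# ---------------------------------------------------------------------------
# Cassette geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteGeometry:
    """Intervening distances (nt, exclusive on both ends) between elements."""

    d_sg1_bc1: int = 82
    d_bc1_bc2: int = 17
    d_bc2_sg2: int = 82
    barcode_len: int = BARCODE_LEN

    @property
    def d_sg1_sg2(self) -> int:
        """Spacer-to-spacer distance implied by the gaps and barcode lengths."""
        return (
            self.d_sg1_bc1
            + self.barcode_len
            + self.d_bc1_bc2
            + self.barcode_len
            + self.d_bc2_sg2
        )


@dataclass(frozen=True)
class Anchors:
    """Fixed vector substrings searched for during read parsing.

    ``sp_spacer_anchor`` (CACCG) and ``sa_spacer_anchor`` (CTTAAAC) are the
    published vector-derived search strings; the two barcode anchors stand in
    for the tracr-derived and overlap-extension-derived fragments and are
    configurable.
    """

    sp_spacer_anchor: str = "CACCG"
    sp_bc_anchor: str = "GTCGGTG"
    sa_bc_anchor: str = "CTGCAGG"
    sa_spacer_anchor: str = "CTTAAAC"


@dataclass(frozen=True)
class VectorStuffers:
    """Fixed vector sequence between the variable elements.

    Each gap consists of a free stuffer followed by that gap's anchor, so
    ``len(gap1_free) + len(sp_bc_anchor)`` must equal the sgRNA-1 to
    barcode-1 distance, and so on.
    """

    upstream: str
    gap1_free: str
    gap2_free: str
    gap3_free: str
    downstream: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=n)) if n else ""


def _contains_any(seq: str, anchors: Anchors) -> bool:
    strings = [a for a in (
        anchors.sp_spacer_anchor,
        anchors.sp_bc_anchor,
        anchors.sa_bc_anchor,
        anchors.sa_spacer_anchor,
    ) if a]
    return any(s in seq for s in strings)


def random_sequence_avoiding(
    rng: np.random.Generator, n: int, anchors: Anchors, max_tries: int = 1000
) -> str:
    """A random DNA string of length ``n`` containing no anchor substring."""
    for _ in range(max_tries):
        s = _random_dna(rng, n)
        if not _contains_any(s, anchors):
            return s
    raise RuntimeError(f"could not draw an anchor-free sequence of length {n}")


def default_stuffers(
    geometry: CassetteGeometry = CassetteGeometry(),
    anchors: Anchors = Anchors(),
    seed: int = 20180525,
    upstream_len: int = 20,
    downstream_len: int = 30,
) -> VectorStuffers:
    """Deterministic synthetic stuffers satisfying the distance constraints.

    The published vector sequence between elements is not modelled; these
    stuffers are synthetic, generated once from a fixed seed, and verified
    anchor-free so that leftmost anchor search is unambiguous.
    """
    for name, gap, anchor in (
        ("gap1", geometry.d_sg1_bc1, anchors.sp_bc_anchor),
        ("gap2", geometry.d_bc1_bc2, anchors.sa_bc_anchor),
        ("gap3", geometry.d_bc2_sg2, anchors.sa_spacer_anchor),
    ):
        if gap < len(anchor):
            raise GeometryError(
                f"{name} distance {gap} nt cannot contain its {len(anchor)}-nt anchor"
            )
    rng = np.random.default_rng(seed)
    return VectorStuffers(
        upstream=random_sequence_avoiding(rng, upstream_len, anchors),
        gap1_free=random_sequence_avoiding(
            rng, geometry.d_sg1_bc1 - len(anchors.sp_bc_anchor), anchors
        ),
        gap2_free=random_sequence_avoiding(
            rng, geometry.d_bc1_bc2 - len(anchors.sa_bc_anchor), anchors
        ),
        gap3_free=random_sequence_avoiding(
            rng, geometry.d_bc2_sg2 - len(anchors.sa_spacer_anchor), anchors
        ),
        downstream=random_sequence_avoiding(rng, downstream_len, anchors),
    )


@dataclass(frozen=True)
class CassetteLayout:
    """A concrete cassette template with element and anchor intervals.

    ``elements`` maps 'sp_spacer' / 'sp_barcode' / 'sa_barcode' /
    'sa_spacer_rc' to 0-based half-open intervals on ``template``;
    ``anchor_intervals`` does the same for the four anchor strings.
    """

    template: str
    elements: dict[str, tuple[int, int]]
    anchor_intervals: dict[str, tuple[int, int]]
    anchors: Anchors
    geometry: CassetteGeometry

    def distance(self, upstream: str, downstream: str) -> int:
        """Intervening nucleotides between two elements (exclusive both ends)."""
        return self.elements[downstream][0] - self.elements[upstream][1]

    def element_seq(self, name: str) -> str:
        s, e = self.elements[name]
        return self.template[s:e]


ELEMENT_ORDER = ("sp_spacer", "sp_barcode", "sa_barcode", "sa_spacer_rc")

#: anchor searched for ahead of each element, in read order
ELEMENT_ANCHOR = {
    "sp_spacer": "sp_spacer_anchor",
    "sp_barcode": "sp_bc_anchor",
    "sa_barcode": "sa_bc_anchor",
    "sa_spacer_rc": "sa_spacer_anchor",
}


def build_layout(
    sp_spacer: str,
    sp_barcode: Barcode | str,
    sa_spacer: str,
    sa_barcode: Barcode | str,
    stuffers: VectorStuffers,
    anchors: Anchors = Anchors(),
    geometry: CassetteGeometry = CassetteGeometry(),
) -> CassetteLayout:
    """Assemble a cassette template and validate its geometry.

    The SaCas9 spacer is placed reverse-complemented on the read strand
    (H1-driven, opposite orientation), immediately after CTTAAAC. Raises
    :class:`GeometryError` when the stuffers do not reproduce the configured
    distances or when an anchor's leftmost occurrence in the template is not
    at its intended position (which would derail leftmost anchor search).
    """
    bc1 = sp_barcode.seq if isinstance(sp_barcode, Barcode) else sp_barcode
    bc2 = sa_barcode.seq if isinstance(sa_barcode, Barcode) else sa_barcode
    if len(sp_spacer) != SP_SPACER_LEN:
        raise ValueError(f"SpCas9 spacer must be {SP_SPACER_LEN} nt, got {len(sp_spacer)}")
    if len(sa_spacer) != SA_SPACER_LEN:
        raise ValueError(f"SaCas9 spacer must be {SA_SPACER_LEN} nt, got {len(sa_spacer)}")

    gaps = {
        "sgRNA-1 to barcode-1": (
            len(stuffers.gap1_free) + len(anchors.sp_bc_anchor),
            geometry.d_sg1_bc1,
        ),
        "barcode-1 to barcode-2": (
            len(stuffers.gap2_free) + len(anchors.sa_bc_anchor),
            geometry.d_bc1_bc2,
        ),
        "barcode-2 to sgRNA-2": (
            len(stuffers.gap3_free) + len(anchors.sa_spacer_anchor),
            geometry.d_bc2_sg2,
        ),
    }
    for name, (got, want) in gaps.items():
        if got != want:
            raise GeometryError(f"{name} span is {got} nt, expected {want} nt")

    parts: list[str] = []
    elements: dict[str, tuple[int, int]] = {}
    anchor_intervals: dict[str, tuple[int, int]] = {}
    pos = 0

    def _add(s: str, element: str | None = None, anchor: str | None = None) -> None:
        nonlocal pos
        parts.append(s)
        if element is not None:
            elements[element] = (pos, pos + len(s))
        if anchor is not None:
            anchor_intervals[anchor] = (pos, pos + len(s))
        pos += len(s)

    _add(stuffers.upstream)
    _add(anchors.sp_spacer_anchor, anchor="sp_spacer_anchor")
    _add(sp_spacer, element="sp_spacer")
    _add(stuffers.gap1_free)
    _add(anchors.sp_bc_anchor, anchor="sp_bc_anchor")
    _add(bc1, element="sp_barcode")
    _add(stuffers.gap2_free)
    _add(anchors.sa_bc_anchor, anchor="sa_bc_anchor")
    _add(bc2, element="sa_barcode")
    _add(stuffers.gap3_free)
    _add(anchors.sa_spacer_anchor, anchor="sa_spacer_anchor")
    _add(revcomp(sa_spacer), element="sa_spacer_rc")
    _add(stuffers.downstream)

    template = "".join(parts)
    for anchor_name, (start, _end) in anchor_intervals.items():
        s = getattr(anchors, anchor_name)
        if s and template.find(s) != start:
            raise GeometryError(
                f"anchor {anchor_name} ({s}) first occurs at "
                f"{template.find(s)}, expected {start}; leftmost search would misfire"
            )
    return CassetteLayout(
        template=template,
        elements=elements,
        anchor_intervals=anchor_intervals,
        anchors=anchors,
        geometry=geometry,
    )


def required_read_length(layout: CassetteLayout, mode: str = "barcode_only") -> int:
    """Minimal single-read span for the chosen detection mode.

    ``barcode_only``: first base of barcode-1 through last base of barcode-2
    (29 nt for the 17-nt gap design). ``full``: first base of the SpCas9
    spacer through the last base of the reverse-complemented SaCas9 spacer.
    """
    if mode == "barcode_only":
        return layout.elements["sa_barcode"][1] - layout.elements["sp_barcode"][0]
    if mode == "full":
        return layout.elements["sa_spacer_rc"][1] - layout.elements["sp_spacer"][0]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Library design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Construct:
    """One library member: paired spacers and their paired barcodes."""

    id: str
    sp_spacer: str
    sp_barcode: Barcode
    sa_spacer: str
    sa_barcode: Barcode

    def __post_init__(self) -> None:
        if len(self.sp_spacer) != SP_SPACER_LEN:
            raise ValueError(
                f"{self.id}: SpCas9 spacer must be {SP_SPACER_LEN} nt"
            )
        if len(self.sa_spacer) != SA_SPACER_LEN:
            raise ValueError(
                f"{self.id}: SaCas9 spacer must be {SA_SPACER_LEN} nt"
            )


@dataclass(frozen=True)
class LibraryDesign:
    """A set of constructs sharing one cassette geometry.

    Only matched wells are paired: a library of n constructs occupies n of
    the n x n combinatorial space (57 of 3,249 for the 57-well design), so
    any unintended combination observed in reads is evidence of uncoupling.
    """

    constructs: tuple[Construct, ...]
    stuffers: VectorStuffers
    anchors: Anchors = Anchors()
    geometry: CassetteGeometry = CassetteGeometry()
    _layout_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.constructs]
        if len(set(ids)) != len(ids):
            raise ValueError("construct ids are not unique")
        for attr in ("sp_spacer", "sa_spacer"):
            seqs = [getattr(c, attr) for c in self.constructs]
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"{attr} sequences are not unique across constructs")

    def __len__(self) -> int:
        return len(self.constructs)

    @property
    def expected_pairs(self) -> dict[str, str]:
        """Expected SpCas9-construct -> SaCas9-construct pairing (identity here)."""
        return {c.id: c.id for c in self.constructs}

    def layout_for(self, construct: Construct) -> CassetteLayout:
        return build_layout(
            construct.sp_spacer,
            construct.sp_barcode,
            construct.sa_spacer,
            construct.sa_barcode,
            self.stuffers,
            anchors=self.anchors,
            geometry=self.geometry,
        )

    @property
    def layout(self) -> CassetteLayout:
        """Canonical layout (element lengths are fixed, so intervals are shared)."""
        return self.layout_for(self.constructs[0])

    def assemble(self, sp_id: str, bc1_id: str, bc2_id: str, sa_id: str) -> str:
        """Cassette template for an arbitrary (possibly chimeric) genotype."""
        key = (sp_id, bc1_id, bc2_id, sa_id)
        if key not in self._layout_cache:
            by_id = {c.id: c for c in self.constructs}
            layout = build_layout(
                by_id[sp_id].sp_spacer,
                by_id[bc1_id].sp_barcode,
                by_id[sa_id].sa_spacer,
                by_id[bc2_id].sa_barcode,
                self.stuffers,
                anchors=self.anchors,
                geometry=self.geometry,
            )
            self._layout_cache[key] = layout.template
        return self._layout_cache[key]


def _well_ids(n: int) -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)][:n]


def design_library(
    n_constructs: int = 57,
    seed: int = 0,
    geometry: CassetteGeometry = CassetteGeometry(),
    anchors: Anchors = Anchors(),
    stuffers: VectorStuffers | None = None,
    min_hamming: int = 2,
) -> LibraryDesign:
    """Generate a complete synthetic library (spacers, barcodes, stuffers).

    Spacers are random and anchor-free; each Cas9's barcode set has pairwise
    Hamming distance >= ``min_hamming``. Each construct's cassette is built
    once to validate anchor uniqueness; offending spacers are redrawn.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if stuffers is None:
        stuffers = default_stuffers(geometry, anchors, seed=20180525)
    sp_bcs = design_barcodes(n_constructs, geometry.barcode_len, min_hamming, rng, "SPBC")
    sa_bcs = design_barcodes(n_constructs, geometry.barcode_len, min_hamming, rng, "SABC")

    ids = _well_ids(n_constructs)
    if len(ids) < n_constructs:
        ids = [f"C{i + 1:03d}" for i in range(n_constructs)]
    constructs: list[Construct] = []
    seen_sp: set[str] = set()
    seen_sa: set[str] = set()
    for i in range(n_constructs):
        for _ in range(100):
            sp = random_sequence_avoiding(rng, SP_SPACER_LEN, anchors)
            sa = random_sequence_avoiding(rng, SA_SPACER_LEN, anchors)
            if sp in seen_sp or sa in seen_sa:
                continue
            try:
                build_layout(
                    sp, sp_bcs.barcodes[i], sa, sa_bcs.barcodes[i],
                    stuffers, anchors=anchors, geometry=geometry,
                )
            except GeometryError:
                continue  # junction-spanning anchor collision; redraw
            break
        else:  # pragma: no cover
            raise RuntimeError("could not draw anchor-compatible spacers")
        seen_sp.add(sp)
        seen_sa.add(sa)
        constructs.append(
            Construct(ids[i], sp, sp_bcs.barcodes[i], sa, sa_bcs.barcodes[i])
        )
    return LibraryDesign(
        constructs=tuple(constructs),
        stuffers=stuffers,
        anchors=anchors,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

REFERENCE_COLUMNS = ["construct_id", "sp_spacer", "sp_barcode", "sa_spacer", "sa_barcode"]


def reference_table(design: LibraryDesign) -> pd.DataFrame:
    """Reference table (one row per construct) as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "construct_id": c.id,
                "sp_spacer": c.sp_spacer,
                "sp_barcode": c.sp_barcode.seq,
                "sa_spacer": c.sa_spacer,
                "sa_barcode": c.sa_barcode.seq,
            }
            for c in design.constructs
        ],
        columns=REFERENCE_COLUMNS,
    )


def write_reference_tsv(design: LibraryDesign, path) -> None:
    reference_table(design).to_csv(path, sep="\t", index=False)


def read_reference_tsv(
    path,
    stuffers: VectorStuffers | None = None,
    anchors: Anchors = Anchors(),
    geometry: CassetteGeometry = CassetteGeometry(),
) -> LibraryDesign:
    """Load a library from a reference TSV (construct_id + four sequences)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    constructs = tuple(
        Construct(
            row.construct_id,
            row.sp_spacer,
            Barcode(f"SPBC_{row.construct_id}", row.sp_barcode),
            row.sa_spacer,
            Barcode(f"SABC_{row.construct_id}", row.sa_barcode),
        )
        for row in df.itertuples(index=False)
    )
    if stuffers is None:
        stuffers = default_stuffers(geometry, anchors)
    return LibraryDesign(constructs, stuffers, anchors, geometry)


def write_cassettes_fasta(design: LibraryDesign, path) -> None:
    """One FASTA record per construct's full cassette template."""
    records = [
        SeqRecord(
            Seq(design.assemble(c.id, c.id, c.id, c.id)),
            id=c.id,
            description="dual-sgRNA cassette",
        )
        for c in design.constructs
    ]
    SeqIO.write(records, path, "fasta")
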