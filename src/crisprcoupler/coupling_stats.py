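"""Coupling-fraction statistics and template-molecule arithmetic.

For a pairing (A, B) of cassette elements, the per-construct coupling
fraction is

    f_i = #{reads: A maps to construct i and B maps to i's expected mate}
          ---------------------------------------------------------------
          #{reads: A maps to construct i and B maps to any library member}

so a read whose B element is unmapped (sequencing error, truncation) does
not count against coupling by default; a flag switches the denominator to
condition on A alone, folding dropout into uncoupling. Per-pairing results
are summarised box-plot style: median, 25th/75th percentiles, 10th/90th
percentiles (linear-interpolation percentile definition).

Template arithmetic converts DNA mass to template-molecule counts: one
genome copy of human gDNA is taken as 6.6 pg, and one 12.3-kb plasmid
(7.5e6 g/mol) as 1.24e-5 pg (the molar mass over Avogadro's number,
truncated to the three-figure value used in the field's calculation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_parser import ReadAssignment, ReferenceLibrary, SENTINELS

#: pg of genomic DNA per template (one diploid human genome copy)
GDNA_PG_PER_TEMPLATE = 6.6
#: molar mass (g/mol) of a 12.3-kb plasmid
PLASMID_G_PER_MOL = 7.5e6
#: pg per plasmid molecule: 7.5e6 / N_A, printed three-figure intermediate
PLASMID_PG_PER_TEMPLATE = 1.24e-5

_ROLE_ELEMENT = {
    "sp_sgRNA": "sp_spacer",
    "sa_sgRNA": "sa_spacer_rc",
    "sp_barcode": "sp_barcode",
    "sa_barcode": "sa_barcode",
}
ROLES = tuple(_ROLE_ELEMENT)


class PairingConfigError(ValueError):
    """The requested pairing cannot be evaluated on these assignments."""


@dataclass(frozen=True)
class Pairing:
    """Two element roles and the expected-mate mapping between their ids."""

    a_role: str
    b_role: str
    mate: Mapping[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if self.a_role == self.b_role:
            raise PairingConfigError("pairing roles must differ")
        for role in (self.a_role, self.b_role):
            if role not in _ROLE_ELEMENT:
                raise PairingConfigError(f"unknown role {role!r}")

    @property
    def a_element(self) -> str:
        return _ROLE_ELEMENT[self.a_role]

    @property
    def b_element(self) -> str:
        return _ROLE_ELEMENT[self.b_role]


def sgrna_sgrna_pairing(refs: ReferenceLibrary, condition_on: str = "sp") -> Pairing:
    """SpCas9 sgRNA vs SaCas9 sgRNA (default conditioned on the SpCas9 guide)."""
    mate = dict(refs.expected_pairs)
    if condition_on == "sp":
        return Pairing("sp_sgRNA", "sa_sgRNA", mate, "sgRNA-sgRNA (Sp-conditioned)")
    return Pairing(
        "sa_sgRNA", "sp_sgRNA", {v: k for k, v in mate.items()},
        "sgRNA-sgRNA (Sa-conditioned)",
    )


def sgrna_barcode_pairing(refs: ReferenceLibrary, cas9: str = "sp") -> Pairing:
    """Each Cas9's sgRNA vs its own barcode."""
    mate = {cid: cid for cid in refs.construct_ids}
    if cas9 == "sp":
        return Pairing("sp_sgRNA", "sp_barcode", mate, "sgRNA-barcode (SpCas9)")
    return Pairing("sa_sgRNA", "sa_barcode", mate, "sgRNA-barcode (SaCas9)")


def barcode_barcode_pairing(refs: ReferenceLibrary) -> Pairing:
    return Pairing(
        "sp_barcode", "sa_barcode",
        {cid: cid for cid in refs.construct_ids},
        "barcode-barcode",
    )


@dataclass(frozen=True)
class CouplingSummary:
    """Box-plot summary across constructs: median plus quartiles and deciles."""

    median: float
    q25: float
    q75: float
    p10: float
    p90: float

    def __post_init__(self) -> None:
        ordered = (self.p10, self.q25, self.median, self.q75, self.p90)
        assert all(x <= y + 1e-12 for x, y in zip(ordered, ordered[1:]))


def summarize(fractions: Sequence[float]) -> CouplingSummary:
    """Median, quartiles and 10th/90th percentiles (linear interpolation)."""
    arr = np.asarray(list(fractions), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty fraction collection")
    p10, q25, med, q75, p90 = np.percentile(arr, [10, 25, 50, 75, 90])
    return CouplingSummary(median=med, q25=q25, q75=q75, p10=p10, p90=p90)


@dataclass(frozen=True)
class CouplingReport:
    """Per-construct coupling fractions for one pairing, plus their summary."""

    pairing: Pairing
    per_construct: pd.DataFrame  # construct_id, numerator, denominator, fraction
    summary: CouplingSummary
    missing_constructs: tuple[str, ...]
    denominator: str  # 'both-mapped' or 'a-mapped'

    @property
    def fractions(self) -> pd.Series:
        return self.per_construct.set_index("construct_id")["fraction"]

    @property
    def pooled_fraction(self) -> float:
        """All-reads fraction: total correct mates over total denominator."""
        num = self.per_construct["numerator"].sum()
        den = self.per_construct["denominator"].sum()
        return num / den if den else float("nan")


def coupling_fractions(
    assignments: Iterable[ReadAssignment],
    pairing: Pairing,
    refs: ReferenceLibrary,
    denominator: str = "both-mapped",
) -> CouplingReport:
    """Per-construct coupling fractions from parsed read assignments.

    Denominator conventions: ``both-mapped`` (default) counts only reads
    where both elements map to library members, isolating uncoupling from
    dropout; ``a-mapped`` counts every read whose A element maps, so
    unmapped partners also reduce coupling.
    """
    if denominator not in ("both-mapped", "a-mapped"):
        raise ValueError(f"unknown denominator convention {denominator!r}")
    a_ids = list(pairing.mate)
    num = {i: 0 for i in a_ids}
    den = {i: 0 for i in a_ids}
    a_el, b_el = pairing.a_element, pairing.b_element
    for read in assignments:
        a = read.get(a_el)
        if a in SENTINELS or a not in den:
            continue
        b = read.get(b_el)
        b_mapped = b not in SENTINELS
        if denominator == "both-mapped" and not b_mapped:
            continue
        den[a] += 1
        if b_mapped and b == pairing.mate[a]:
            num[a] += 1
    return _build_report(num, den, pairing, denominator)


def _build_report(
    num: Mapping[str, int],
    den: Mapping[str, int],
    pairing: Pairing,
    denominator: str,
) -> CouplingReport:
    rows, missing = [], []
    for cid in pairing.mate:
        d = den[cid]
        if d == 0:
            missing.append(cid)
            continue
        n = num[cid]
        assert n <= d
        rows.append((cid, n, d, n / d))
    df = pd.DataFrame(
        rows, columns=["construct_id", "numerator", "denominator", "fraction"]
    )
    if df.empty:
        raise ValueError("no construct had a non-zero denominator")
    return CouplingReport(
        pairing=pairing,
        per_construct=df,
        summary=summarize(df["fraction"]),
        missing_constructs=tuple(missing),
        denominator=denominator,
    )


def coupling_fractions_from_counts(
    counts: pd.DataFrame,
    mate: Mapping[str, str],
    name: str = "from-counts",
) -> CouplingReport:
    """Coupling fractions from a raw read-count matrix.

    ``counts`` is a wide table: rows indexed by A-element construct id,
    columns by B-element construct id, entries the number of reads
    carrying that (A, B) combination -- the shape of a supplementary
    raw-count table. The denominator for construct i is its row sum
    (reads whose partner mapped somewhere in the library).
    """
    counts = counts.astype(float)
    unknown = set(mate) - set(counts.index)
    if unknown:
        raise ValueError(f"count matrix missing rows for: {sorted(unknown)[:5]}")
    num = {i: float(counts.at[i, mate[i]]) if mate[i] in counts.columns else 0.0
           for i in mate}
    den = {i: float(counts.loc[i].sum()) for i in mate}
    pairing = Pairing("sp_sgRNA", "sa_sgRNA", dict(mate), name)
    return _build_report(num, den, pairing, "both-mapped")


def read_count_table(path, sheet=0) -> pd.DataFrame:
    """Load a wide count matrix from TSV/CSV or XLSX (first column = row ids)."""
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        return pd.read_excel(path, sheet_name=sheet, index_col=0)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


# ---------------------------------------------------------------------------
# Template-molecule arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateInput:
    """A PCR input: sample kind plus mass in picograms."""

    kind: str  # 'gDNA' or 'pDNA'
    mass_pg: float

    def __post_init__(self) -> None:
        if self.kind not in ("gDNA", "pDNA"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if not self.mass_pg > 0:
            raise ValueError("mass must be positive")


UG_TO_PG = 1e6
NG_TO_PG = 1e3


def template_molecules(template: TemplateInput) -> float:
    """Number of template molecules in a DNA input.

    gDNA: one template per genome copy at 6.6 pg each; pDNA: one template
    per plasmid at 1.24e-5 pg each (12.3-kb plasmid, 7.5e6 g/mol).
    """
    per_template = (
        GDNA_PG_PER_TEMPLATE if template.kind == "gDNA" else PLASMID_PG_PER_TEMPLATE
    )
    return template.mass_pg / per_template


def equivalent_pdna_mass(gdna_mass_ug: float) -> float:
    """pDNA mass (pg) holding as many templates as ``gdna_mass_ug`` μg of gDNA.

    10 μg of human gDNA (~1.5e6 genome copies) corresponds to ~19 pg of a
    12.3-kb plasmid library -- roughly the "20 pg" rule of thumb for
    matching template counts between plasmid and genomic samples.
    """
    n = template_molecules(TemplateInput("gDNA", gdna_mass_ug * UG_TO_PG))
    return n * PLASMID_PG_PER_TEMPLATE


def combinatorial_space(
    n_sp: int, n_sa: int, n_intended: int
) -> tuple[int, float]:
    """Total combinatorial space and the fraction of it that is intended.

    A 57-well paired library occupies 57 of 57 x 57 = 3,249 possible
    guide combinations (1.7%), which is what makes unintended pairings
    detectable at all.
    """
    if n_sp < 1 or n_sa < 1 or n_intended < 1:
        raise ValueError("counts must be positive")
    total = n_sp * n_sa
    if n_intended > total:
        raise ValueError(f"{n_intended} intended pairs exceed the space of {total}")
    return total, n_intended / total


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def write_coupling_tsv(report: CouplingReport, path) -> None:
    report.per_construct.to_csv(path, sep="\t", index=False)


def summary_frame(reports: Iterable[CouplingReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        s = r.summary
        rows.append(
            {
                "pairing": r.pairing.name,
                "denominator": r.denominator,
                "n_constructs": len(r.per_construct),
                "median": s.median,
                "q25": s.q25,
                "q75": s.q75,
                "p10": s.p10,
                "p90": s.p90,
                "pooled_fraction": r.pooled_fraction,
            }
        )
    return pd.DataFrame(rows)
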