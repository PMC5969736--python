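"""Generative model of uncoupling: lentiviral recombination, PCR template
switching, and sequencing-error FASTQ emission.

The mechanism modelled is the abortive-product/template-jumping one: during
each PCR cycle a nascent copy may terminate prematurely and, in a later
cycle, re-prime on common vector sequence of a *different* template
molecule, splicing the upstream elements of one genotype onto the
downstream elements of another. The hazard of such an event is taken as
per-nucleotide, per-replication: a copy over a cassette of length L
switches with probability 1 - (1 - lambda_c)^L, with the breakpoint uniform
along the cassette and the partner drawn abundance-weighted from the pool.
Because longer intervening distance means more nucleotides at risk between
two elements, uncoupling is ordered by distance (17 < 82 < 193 nt), and it
grows with cycle number and -- through an optional resource-depletion
term -- with template input:

    lambda_c = lambda * (1 + alpha * S_c / (S_c + K))

where S_c is the cumulative number of synthesized copies and K a
half-depletion constant, a saturating stand-in for dNTP/primer exhaustion.

Pools are tracked at genotype resolution (sp, bc1, bc2, sa construct ids),
not base resolution; a breakpoint landing inside an element is rounded to
the nearest element boundary, so the at-risk span between two elements runs
midpoint-to-midpoint. Lentiviral recombination (gDNA samples only) is a
single distance-dependent crossover per integration, modelled the same way
with its own rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_design import (
    DNA_ALPHABET,
    ELEMENT_ANCHOR,
    ELEMENT_ORDER,
    CassetteLayout,
    LibraryDesign,
    required_read_length,
)

Genotype = tuple[str, str, str, str]  # (sp, bc1, bc2, sa) construct ids


@dataclass(frozen=True)
class SimulationParams:
    """Tunable conditions of one simulated experiment.

    ``n_templates``: molecules entering PCR (1.5e6 mimics 10 μg gDNA,
    8.1e8 mimics 10 ng pDNA). ``switch_rate``: per-nucleotide,
    per-replication template-switch hazard. ``resource_coupling`` (alpha)
    scales the hazard as synthesis depletes resources, with
    ``resource_capacity`` (K) the half-depletion copy count.
    ``lenti_switch_rate`` (rho) is the per-nucleotide, per-integration
    crossover rate applied only to gDNA-like samples. ``efficiency`` is the
    per-cycle copy probability; ``seq_error_rate`` the per-base
    substitution rate at read emission.
    """

    n_templates: int = 100_000
    cycles: int = 22
    switch_rate: float = 0.0
    resource_coupling: float = 0.0
    resource_capacity: float = 1e6
    lenti_switch_rate: float = 0.0
    seq_error_rate: float = 0.0
    efficiency: float = 1.0
    read_length: int = 300
    stagger_range: tuple[int, int] = (1, 8)
    seed: int = 0
    mode: str = "stochastic"  # or 'expected'
    stochastic_pool_cap: float = 1e15

    def __post_init__(self) -> None:
        for name in ("switch_rate", "lenti_switch_rate", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.efficiency <= 1.0:
            raise ValueError("efficiency must be in (0, 1]")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        if self.mode not in ("stochastic", "expected"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class MoleculePool:
    """Genotype -> abundance, plus a cumulative synthesized-copy counter."""

    counts: dict[Genotype, float] = field(default_factory=dict)
    synthesized: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def probabilities(self) -> tuple[list[Genotype], np.ndarray]:
        genotypes = list(self.counts)
        arr = np.array([self.counts[g] for g in genotypes], dtype=float)
        return genotypes, arr / arr.sum()

    def copy(self) -> "MoleculePool":
        return MoleculePool(dict(self.counts), self.synthesized)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def seed_pool(
    design: LibraryDesign,
    n_templates: int,
    weights=None,
    seed: int | np.random.Generator = 0,
    expected: bool = False,
) -> MoleculePool:
    """Draw the starting template pool over *intended* genotypes only.

    ``weights`` are per-construct relative abundances (uniform by default).
    Stochastic mode draws a multinomial; ``expected`` mode assigns the
    real-valued expected counts, for template regimes (e.g. 8.1e8
    molecules) where individual sampling noise is irrelevant.
    """
    rng = _as_rng(seed)
    intended: list[Genotype] = [(c.id, c.id, c.id, c.id) for c in design.constructs]
    if weights is None:
        w = np.full(len(intended), 1.0 / len(intended))
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(intended):
            raise ValueError("weights must match the construct count")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        w = w / w.sum()
    if expected:
        counts = {g: n_templates * p for g, p in zip(intended, w) if p > 0}
    else:
        draws = rng.multinomial(n_templates, w)
        counts = {g: int(k) for g, k in zip(intended, draws) if k > 0}
    return MoleculePool(counts=counts)


# ---------------------------------------------------------------------------
# Crossover geometry
# ---------------------------------------------------------------------------

def cassette_length(layout: CassetteLayout) -> int:
    return len(layout.template)


def _element_midpoints(layout: CassetteLayout) -> list[float]:
    return [
        (layout.elements[e][0] + layout.elements[e][1]) / 2.0
        for e in ELEMENT_ORDER
    ]


def category_probs(layout: CassetteLayout) -> np.ndarray:
    """P(breakpoint category k), k = number of leading elements kept from
    the aborted source molecule (0..4), for a uniform breakpoint.

    A breakpoint inside an element is rounded to the nearest boundary, so
    category thresholds sit at element midpoints.
    """
    L = cassette_length(layout)
    mids = _element_midpoints(layout)
    bounds = [0.0] + mids + [float(L)]
    widths = np.diff(bounds)
    return widths / L


def splice(source: Genotype, partner: Genotype, category: int) -> Genotype:
    """Genotype of a chimeric product keeping ``category`` leading elements
    of the source and taking the rest from the partner."""
    return tuple(source[:category]) + tuple(partner[category:])


def pair_at_risk_probability(
    layout: CassetteLayout, a_element: str, b_element: str
) -> float:
    """P(a uniform breakpoint separates elements A and B | a switch occurred).

    Equals the midpoint-to-midpoint span over the cassette length, i.e.
    (intervening distance + half of each element's length) / L, so it is
    strictly increasing in the distance between the elements.
    """
    mids = dict(zip(ELEMENT_ORDER, _element_midpoints(layout)))
    return abs(mids[b_element] - mids[a_element]) / cassette_length(layout)


def switch_probability(rate: float, length: int) -> float:
    """P(at least one switch event over ``length`` nucleotides)."""
    return 1.0 - (1.0 - rate) ** length


# ---------------------------------------------------------------------------
# Recombination / PCR
# ---------------------------------------------------------------------------

def _split_categories(
    rng: np.random.Generator,
    source: Genotype,
    n_events: int,
    cat_p: np.ndarray,
    prefix_events: list[dict[tuple[str, ...], int]],
    out: dict[Genotype, float],
) -> None:
    """Assign ``n_events`` crossovers on ``source`` to breakpoint categories.

    Category 4 (breakpoint downstream of every element) reproduces the
    source; categories 0-3 keep the first ``k`` elements of the source and
    are accumulated per source prefix so that partner sampling can be done
    in aggregate by :func:`_place_crossovers`.
    """
    cats = rng.multinomial(n_events, cat_p)
    if cats[4]:
        out[source] = out.get(source, 0) + int(cats[4])
    for k in range(4):
        if cats[k]:
            prefix = source[:k]
            bucket = prefix_events[k]
            bucket[prefix] = bucket.get(prefix, 0) + int(cats[k])


def _suffix_distribution(
    genotypes: list[Genotype], pool_p: np.ndarray, k: int
) -> tuple[list[tuple[str, ...]], np.ndarray]:
    """Abundance-weighted distribution of the last ``4 - k`` elements."""
    agg: dict[tuple[str, ...], float] = {}
    for g, p in zip(genotypes, pool_p):
        suffix = g[k:]
        agg[suffix] = agg.get(suffix, 0.0) + p
    suffixes = list(agg)
    probs = np.array([agg[s] for s in suffixes])
    return suffixes, probs / probs.sum()


def _place_crossovers(
    rng: np.random.Generator,
    prefix_events: list[dict[tuple[str, ...], int]],
    genotypes: list[Genotype],
    pool_p: np.ndarray,
    out: dict[Genotype, float],
) -> None:
    """Sample abundance-weighted partners for every accumulated crossover.

    The spliced product only depends on the partner's downstream elements,
    so partners are drawn from the suffix marginal in one multinomial per
    (category, source-prefix) pair rather than per source molecule.
    """
    for k in range(4):
        if not prefix_events[k]:
            continue
        suffixes, suffix_p = _suffix_distribution(genotypes, pool_p, k)
        for prefix, m in prefix_events[k].items():
            draws = rng.multinomial(m, suffix_p)
            for j in np.nonzero(draws)[0]:
                g = prefix + suffixes[j]
                out[g] = out.get(g, 0) + int(draws[j])


def apply_lentiviral_recombination(
    pool: MoleculePool,
    layout: CassetteLayout,
    lenti_switch_rate: float,
    seed: int | np.random.Generator = 0,
) -> MoleculePool:
    """One distance-dependent crossover opportunity per integrated molecule.

    Each molecule recombines with probability 1 - (1 - rho)^L; the
    crossover position is uniform and the downstream partner is sampled
    abundance-weighted from the pre-recombination pool. Molecule count is
    conserved. A zero rate returns the pool unchanged.
    """
    if lenti_switch_rate == 0.0 or not pool.counts:
        return pool.copy()
    rng = _as_rng(seed)
    p_rec = switch_probability(lenti_switch_rate, cassette_length(layout))
    cat_p = category_probs(layout)
    genotypes, pool_p = pool.probabilities()
    out: dict[Genotype, float] = {}
    prefix_events: list[dict[tuple[str, ...], int]] = [{} for _ in range(4)]
    for g, n in pool.counts.items():
        n_rec = rng.binomial(int(n), p_rec)
        if n - n_rec > 0:
            out[g] = out.get(g, 0) + (n - n_rec)
        if n_rec:
            _split_categories(rng, g, n_rec, cat_p, prefix_events, out)
    _place_crossovers(rng, prefix_events, genotypes, pool_p, out)
    return MoleculePool(counts=out, synthesized=pool.synthesized)


def _cycle_switch_rate(params: SimulationParams, synthesized: float) -> float:
    depletion = synthesized / (synthesized + params.resource_capacity)
    return min(1.0, params.switch_rate * (1.0 + params.resource_coupling * depletion))


def simulate_pcr(
    pool: MoleculePool,
    layout: CassetteLayout,
    params: SimulationParams,
    seed: int | np.random.Generator | None = None,
) -> MoleculePool:
    """Amplify a pool for ``params.cycles`` cycles with template switching.

    Per cycle, every molecule is copied with probability ``efficiency``;
    each new copy switches templates with probability
    1 - (1 - lambda_c)^L, where lambda_c includes the resource-depletion
    term, splicing in the downstream elements of an abundance-weighted
    partner (pool composition snapshotted at cycle start). ``expected``
    mode propagates real-valued expected counts deterministically, for
    pools too large to sample molecule-by-molecule.
    """
    rng = _as_rng(params.seed if seed is None else seed)
    L = cassette_length(layout)
    cat_p = category_probs(layout)
    current = pool.copy()
    for _ in range(params.cycles):
        lam = _cycle_switch_rate(params, current.synthesized)
        p_switch = switch_probability(lam, L)
        genotypes, pool_p = current.probabilities()
        new: dict[Genotype, float] = dict(current.counts)
        made = 0.0
        if params.mode == "stochastic":
            if current.total > params.stochastic_pool_cap:
                raise RuntimeError(
                    f"stochastic pool exceeds {params.stochastic_pool_cap:.0e} "
                    "molecules; use expected-count mode (mode='expected')"
                )
            prefix_events: list[dict[tuple[str, ...], int]] = [
                {} for _ in range(4)
            ]
            for g, n in current.counts.items():
                copies = rng.binomial(int(n), params.efficiency)
                made += copies
                switched = rng.binomial(copies, p_switch) if p_switch else 0
                if copies - switched:
                    new[g] = new.get(g, 0) + (copies - switched)
                if switched:
                    _split_categories(rng, g, switched, cat_p, prefix_events, new)
            _place_crossovers(rng, prefix_events, genotypes, pool_p, new)
        else:
            new = _expected_cycle(current, params.efficiency, p_switch, cat_p,
                                  genotypes, pool_p)
            made = current.total * params.efficiency
        current = MoleculePool(counts=new, synthesized=current.synthesized + made)
        if params.mode == "expected":
            _prune(current)
    return current


def _expected_cycle(
    current: MoleculePool,
    efficiency: float,
    p_switch: float,
    cat_p: np.ndarray,
    genotypes: list[Genotype],
    pool_p: np.ndarray,
) -> dict[Genotype, float]:
    """Deterministic expected-count update for one cycle.

    Chimeric mass for category k factorises into a source-prefix marginal
    times the pool's suffix marginal, keeping the update far below the
    naive genotype-squared cost.
    """
    new: dict[Genotype, float] = dict(current.counts)
    for g, n in current.counts.items():
        intact = n * efficiency * (1.0 - p_switch) + n * efficiency * p_switch * cat_p[4]
        if intact:
            new[g] = new.get(g, 0.0) + intact
    switched_total = {g: n * efficiency * p_switch for g, n in current.counts.items()}
    suffix_probs = dict(zip(genotypes, pool_p))
    for category in range(4):
        mass_k = cat_p[category]
        if mass_k == 0:
            continue
        prefix_mass: dict[tuple, float] = {}
        for g, m in switched_total.items():
            key = g[:category]
            prefix_mass[key] = prefix_mass.get(key, 0.0) + m * mass_k
        suffix_mass: dict[tuple, float] = {}
        for g, p in suffix_probs.items():
            key = g[category:]
            suffix_mass[key] = suffix_mass.get(key, 0.0) + p
        for pre, pm in prefix_mass.items():
            for suf, sp in suffix_mass.items():
                if pm * sp > 0:
                    g = pre + suf
                    new[g] = new.get(g, 0.0) + pm * sp
    return new


def _prune(pool: MoleculePool, min_fraction: float = 1e-12) -> None:
    threshold = pool.total * min_fraction
    for g in [g for g, n in pool.counts.items() if n < threshold]:
        del pool.counts[g]


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASE_IDX = {b: i for i, b in enumerate(DNA_ALPHABET)}


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0.0:
        return seq
    mask = rng.random(len(seq)) < error_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.nonzero(mask)[0]:
        alternatives = [b for b in DNA_ALPHABET if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _anchor_positions(layout: CassetteLayout) -> list[tuple[str, int]]:
    return [
        (getattr(layout.anchors, ELEMENT_ANCHOR[e]),
         layout.anchor_intervals[ELEMENT_ANCHOR[e]][0])
        for e in ELEMENT_ORDER
        if getattr(layout.anchors, ELEMENT_ANCHOR[e])
    ]


def _draw_stagger(
    rng: np.random.Generator,
    stagger_range: tuple[int, int],
    template: str,
    anchor_pos: list[tuple[str, int]],
    max_tries: int = 50,
) -> str:
    """A random stagger prefix that does not create a spurious upstream anchor."""
    lo, hi = stagger_range
    for _ in range(max_tries):
        k = int(rng.integers(lo, hi + 1))
        stagger = "".join(rng.choice(list(DNA_ALPHABET), size=k)) if k else ""
        read = stagger + template
        if all(read.find(a) == k + pos for a, pos in anchor_pos):
            return stagger
    raise RuntimeError("could not draw an anchor-free stagger prefix")


def emit_reads(
    pool: MoleculePool,
    design: LibraryDesign,
    n_reads: int,
    read_length: int = 300,
    error_rate: float = 0.0,
    stagger_range: tuple[int, int] = (1, 8),
    seed: int | np.random.Generator = 0,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Sample sequencing reads from a molecule pool.

    Each read is a random 1-8 nt stagger prefix plus the genotype's
    assembled cassette, truncated to ``read_length``, with independent
    per-base substitution errors and a constant quality string. Returns the
    records and a ground-truth table (read_id -> source genotype and
    stagger length); optionally writes FASTQ and truth TSV.
    """
    layout = design.layout
    min_len = required_read_length(layout, "barcode_only")
    if read_length < min_len:
        raise ValueError(
            f"read_length {read_length} is below the {min_len}-nt barcode span"
        )
    rng = _as_rng(seed)
    records: list[SeqRecord] = []
    truth_rows: list[dict] = []
    if n_reads > 0:
        if not pool.counts:
            raise ValueError("cannot sample reads from an empty pool")
        genotypes, probs = pool.probabilities()
        anchor_pos = _anchor_positions(layout)
        per_genotype = rng.multinomial(n_reads, probs)
        templates = {g: design.assemble(*g) for g, k in zip(genotypes, per_genotype) if k}
        idx = 0
        for g, k in zip(genotypes, per_genotype):
            for _ in range(int(k)):
                idx += 1
                read_id = f"read{idx:07d}"
                stagger = _draw_stagger(rng, stagger_range, templates[g], anchor_pos)
                seq = (stagger + templates[g])[:read_length]
                seq = _apply_errors(seq, error_rate, rng)
                rec = SeqRecord(Seq(seq), id=read_id, description="")
                rec.letter_annotations["phred_quality"] = [40] * len(seq)
                records.append(rec)
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "sp_id": g[0],
                        "sp_bc_id": g[1],
                        "sa_bc_id": g[2],
                        "sa_id": g[3],
                        "stagger_len": len(stagger),
                    }
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sp_id", "sp_bc_id", "sa_bc_id", "sa_id", "stagger_len"],
    )
    if fastq_path is not None:
        SeqIO.write(records, str(fastq_path), "fastq")
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


def simulate_reads(
    design: LibraryDesign,
    params: SimulationParams,
    n_reads: int,
    fastq_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame, MoleculePool]:
    """End-to-end: seed pool -> (lentiviral recombination) -> PCR -> reads.

    All stages draw from independent streams spawned from ``params.seed``,
    so the whole run is reproducible from the parameter set alone.
    """
    root = np.random.default_rng(params.seed)
    rng_pool, rng_lenti, rng_pcr, rng_reads = root.spawn(4)
    layout = design.layout
    pool = seed_pool(
        design, params.n_templates, seed=rng_pool,
        expected=(params.mode == "expected"),
    )
    if params.lenti_switch_rate > 0:
        pool = apply_lentiviral_recombination(
            pool, layout, params.lenti_switch_rate, seed=rng_lenti
        )
    pool = simulate_pcr(pool, layout, params, seed=rng_pcr)
    records, truth = emit_reads(
        pool,
        design,
        n_reads,
        read_length=params.read_length,
        error_rate=params.seq_error_rate,
        stagger_range=params.stagger_range,
        seed=rng_reads,
        fastq_path=fastq_path,
        truth_path=truth_path,
    )
    return records, truth, pool


ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENT_ORDER)}


def pool_coupling_fraction(
    pool: MoleculePool,
    a_element: str,
    b_element: str,
    mate: dict[str, str] | None = None,
) -> float:
    """Abundance-weighted fraction of molecules whose B element carries the
    expected mate of their A element (identity mate map by default).

    This is the molecule-level analogue of the read-level coupling
    fraction, free of sequencing-sampling noise.
    """
    ia, ib = ELEMENT_INDEX[a_element], ELEMENT_INDEX[b_element]
    good = total = 0.0
    for g, n in pool.counts.items():
        expected = mate[g[ia]] if mate is not None else g[ia]
        if g[ib] == expected:
            good += n
        total += n
    if total == 0:
        raise ValueError("empty pool")
    return good / total


# ---------------------------------------------------------------------------
# Closed-form expectations and rate estimation
# ---------------------------------------------------------------------------

def expected_uncoupled_fraction_single_cycle(
    switch_rate: float,
    layout: CassetteLayout,
    a_element: str,
    b_element: str,
    n_constructs: int,
    efficiency: float = 1.0,
) -> float:
    """Expected uncoupled read fraction after ONE cycle on a uniform pool.

    New copies make up e/(1+e) of the molecules; a copy switches with
    probability 1-(1-lambda)^L; the breakpoint separates the pair with the
    midpoint-span probability; and the partner carries a different mate
    with probability 1 - 1/G for a uniform pool of G intended genotypes.
    """
    w_new = efficiency / (1.0 + efficiency)
    q = switch_probability(switch_rate, cassette_length(layout))
    span = pair_at_risk_probability(layout, a_element, b_element)
    return w_new * q * span * (1.0 - 1.0 / n_constructs)


def estimate_switch_rate(
    uncoupled_fraction: float,
    layout: CassetteLayout,
    a_element: str,
    b_element: str,
    n_constructs: int,
    efficiency: float = 1.0,
) -> float:
    """Invert the single-cycle expectation to recover the per-nt switch rate.

    Intended for reads generated by a one-cycle amplification of a uniform
    pool; returns the lambda whose expected uncoupled fraction matches the
    observed one.
    """
    w_new = efficiency / (1.0 + efficiency)
    span = pair_at_risk_probability(layout, a_element, b_element)
    denom = w_new * span * (1.0 - 1.0 / n_constructs)
    q = uncoupled_fraction / denom
    if not 0.0 <= q < 1.0:
        raise ValueError(
            f"observed uncoupling {uncoupled_fraction} outside the invertible range"
        )
    L = cassette_length(layout)
    return 1.0 - (1.0 - q) ** (1.0 / L)


# ---------------------------------------------------------------------------
# Synthetic supplementary-shaped count tables
# ---------------------------------------------------------------------------

def synthetic_count_table(
    median_coupling: float,
    construct_ids: list[str],
    mean_reads: int = 2000,
    concentration: float = 200.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """SYNTHETIC stand-in for a raw read-count matrix (one row and column per
    construct, entries = reads observed with that element combination).

    The study's raw count tables are not deposited in machine-readable
    form, so this generator produces tables of the same shape whose true
    per-construct coupling probabilities are Beta-distributed around
    ``median_coupling`` (spread set by ``concentration``), with uncoupled
    reads spread uniformly over the other constructs. It exists to exercise
    the count -> fraction -> median path on supplementary-shaped input.
    """
    if not 0.0 < median_coupling < 1.0:
        raise ValueError("median_coupling must be in (0, 1)")
    rng = _as_rng(seed)
    n = len(construct_ids)
    mat = np.zeros((n, n), dtype=int)
    a = median_coupling * concentration
    b = (1.0 - median_coupling) * concentration
    for i in range(n):
        p_i = rng.beta(a, b)
        reads = rng.poisson(mean_reads)
        correct = rng.binomial(reads, p_i)
        mat[i, i] = correct
        wrong = reads - correct
        if wrong and n > 1:
            others = [j for j in range(n) if j != i]
            spread = rng.multinomial(wrong, np.full(n - 1, 1.0 / (n - 1)))
            for j, k in zip(others, spread):
                mat[i, j] += k
    return pd.DataFrame(mat, index=construct_ids, columns=construct_ids)
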