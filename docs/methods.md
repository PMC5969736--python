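# Methods

## Cassette geometry

Every construct is assembled on the read strand as

```
[upstream 20 nt] CACCG [Sp spacer, 20 nt]
  [gap, 82 nt, ending in GTCGGTG] [barcode 1, 6 nt]
  [gap, 17 nt, ending in CTGCAGG] [barcode 2, 6 nt]
  [gap, 82 nt, ending in CTTAAAC] [revcomp(Sa spacer), 21 nt]
[downstream 30 nt]
```

Distances are exclusive of both flanking elements, so the Sp→Sa spacer
distance closes at 82 + 6 + 17 + 6 + 82 = 193 nt and the default
assembled template is 289 nt. The minimal read covering both barcodes is
6 + 17 + 6 = 29 nt from the first barcode base; a read covering every
element needs 234 nt from the first spacer base.

Each element is located by a fixed anchor that immediately precedes it.
The three internal anchors (`GTCGGTG`, `CTGCAGG`, `CTTAAAC`) are
synthetic 7-mers standing in for the scaffold junctions a real vector
would provide (tracrRNA 3' end, overlap-extension junction, Sa scaffold
boundary); they were chosen so that no anchor contains, or is created by
juxtaposition with, another anchor. `build_layout` validates that the
*leftmost* occurrence of every anchor in the assembled template is its
intended position and raises `GeometryError` otherwise; `design_library`
redraws any spacer that violates this. Because chimeras only exchange
whole elements between validated parents, every junction context in a
chimeric molecule also exists in a validated layout, so chimeras are
anchor-safe by construction.

## Barcode design

Hexamer barcode sets are grown greedily from a shuffled enumeration of
all 4^6 candidates, rejecting candidates with homopolymer runs ≥ 5 or
pairwise Hamming distance < 2 to any accepted barcode, with up to 50
restarts. `BarcodeSet` re-audits all pairs on construction. A
minimum-distance-2 code gives the mapping guarantee tested exhaustively
in the suite: any single-base mutant of a barcode maps to the true
barcode or to `UNMAPPED`, never to a different barcode.

## Read parsing

`assign_read` searches the whole read for each anchor (leftmost match),
extracts the fixed-length element after it, and maps the element against
the reference (exact by default; `barcode_max_mismatch=1` allows a
*unique* 1-mismatch neighbour). Slots report `ANCHOR_NOT_FOUND` when the
anchor is absent or the element is truncated, `UNMAPPED` when the
sequence matches no reference entry. With `try_revcomp=True` a read
whose four slots are all sentinels is retried on the reverse complement.

## Coupling statistics

For a pairing (element A conditioned on element B's construct),

```
f_i = #(A -> i and B -> i) / #(A -> i and B mapped)        ["both-mapped"]
```

with an alternative `"a-mapped"` denominator that also counts reads
whose B slot is unmapped. Summaries are the 10/25/50/75/90th percentiles
of `{f_i}` computed with `numpy.percentile` (linear interpolation), plus
the read-weighted `pooled_fraction`. The same machinery consumes raw
construct-by-construct count tables (TSV/CSV/XLSX) via
`coupling_fractions_from_counts`.

Template arithmetic uses 6.6 pg of human gDNA per haploid template and
1.24e-5 pg per 7.5-MDa plasmid. The plasmid figure is the conventional
truncated intermediate (7.5e6 g/mol / 6.022e23 /mol = 1.245e-11 g);
keeping 1.24e-5 pg reproduces the headline 8.1e8 templates per 10 ng,
whereas the fully rounded 1.25e-5 would not.

## PCR model

The simulator tracks molecule counts per *genotype* — the 4-tuple of
construct ids for (Sp spacer, barcode 1, barcode 2, Sa spacer). Each
cycle, every molecule is copied with probability `efficiency`; each copy
template-switches with probability

```
p_switch = 1 - (1 - lambda_c)^L ,
lambda_c = switch_rate * (1 + resource_coupling * S / (S + resource_capacity))
```

where `L` is the template length and `S` the cumulative number of
strands synthesized so far — a saturating resource-depletion term that
makes late cycles and large template pools more chimera-prone without
letting the per-base rate diverge.

A switching copy draws a uniform breakpoint on the template, rounded to
the nearest element boundary by the midpoint rule: the breakpoint
category is chosen with probabilities proportional to the spans between
consecutive element midpoints (ends of the template for the outer
categories). Category *k* keeps the first *k* elements from the source
and takes the remainder from a partner drawn abundance-weighted from the
pool snapshot at cycle start. Under the midpoint rule the probability
that a switch falls between elements A and B is
`(gap + (len_A + len_B)/2) / L` — e.g. 23/289 for the barcode pair
versus 213.5/289 for the spacer pair, which is what drives the
barcode advantage.

Because the spliced product depends on the partner only through its
downstream elements, partner draws are aggregated: switch events are
binned by (category, source prefix) and one multinomial over the
*suffix marginal* of the pool places each bin. This is statistically
identical to per-molecule partner sampling and keeps each cycle linear
in the number of genotype prefixes × suffixes rather than quadratic in
genotypes.

Two propagation modes share this machinery:

- `stochastic` — integer counts, binomial/multinomial sampling,
  guarded by `stochastic_pool_cap` (default 1e15 molecules).
- `expected` — deterministic real-valued expected counts via the same
  prefix × suffix factorization, pruning genotypes below 1e-12 of the
  pool.

Lentiviral recombination (`apply_lentiviral_recombination`) gives each
molecule one crossover opportunity with probability
`1 - (1 - lenti_switch_rate)^L`, reusing the category machinery;
molecule count is conserved.

## Read emission

`emit_reads` samples genotypes abundance-weighted, assembles each
template, prepends a random 1–8-nt stagger prefix (rejection-resampled
if it would create a spurious earlier anchor occurrence), truncates to
`read_length`, applies per-base substitution errors, and writes FASTQ
(constant Phred 40) plus a ground-truth TSV. All randomness flows
through `numpy.random.default_rng(seed).spawn(...)`, so outputs are
byte-identical for a given seed.

## Single-cycle closed form and estimator

For one cycle at efficiency *e*, the expected uncoupled fraction for an
element pair spanning `span` of the at-risk template is

```
u = e/(1+e) * (1 - (1-lambda)^L) * span/L * (1 - 1/G)
```

(`G` = number of equally abundant constructs; the last factor removes
switches that land back on the same genotype). `estimate_switch_rate`
inverts this for `lambda` given an observed `u`, which the test suite
exercises end-to-end: reads simulated at `lambda = 1e-3` through one
cycle are parsed and quantified, and the inversion recovers the rate
within 20%.

## Synthetic count tables

`synthetic_count_table(median, ids, ...)` emulates a per-condition raw
count matrix: each construct's coupling probability is drawn from
`Beta(median*kappa, (1-median)*kappa)` (kappa = 200), its read total
from Poisson(mean_reads), and off-diagonal reads are spread uniformly.
The generative truth *is* the target median, so the count → fraction →
median pipeline is validated against known ground truth. These tables
are clearly labelled synthetic; they model the shape of real screen
count tables, not any particular dataset.

## Problem sizes and limits

Genotype-resolved simulation scales with the number of *distinct*
genotypes, which saturates at n^4 for an n-construct design once
chimeras are abundant. Multi-cycle, chimera-rich simulations are
therefore run at 6–12 construct scale (12^4 ≈ 2.1e4 genotypes; seconds
per run), in either mode. Full 57-construct designs (57^4 ≈ 1.1e7
potential genotypes) are practical for single-cycle runs (as in the
switch-rate recovery test) and for zero/low-chimera regimes, but not
for 28-cycle high-switching simulation; condition-level analyses at
that scale should work from count tables instead. Other deliberate
numerical choices: percentiles use linear interpolation; expected-mode
pruning at 1e-12 of pool size; breakpoint rounding by the midpoint
rule; stagger resampling capped at 50 attempts.

## Limitations

The model exchanges whole elements (no intra-element chimeras), treats
switching as a single event per copy, ignores amplification bias between
genotypes beyond resource depletion, uses substitution-only sequencing
errors at constant quality, and assumes equimolar library
representation unless explicit weights are supplied.
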