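# crisprcoupler

Tools for quantifying — and simulating — the uncoupling of paired genetic
elements during PCR amplification of combinatorial CRISPR screening
libraries.

## The problem

Combinatorial CRISPR screens place two programmed elements on one vector:
a *S. pyogenes* (Sp) sgRNA spacer and a *S. aureus* (Sa) sgRNA spacer,
each tagged with a short barcode. Readout requires that elements observed
together on one sequencing read truly came from the same vector. Two
processes break that assumption:

1. **Template switching during PCR.** A nascent strand dissociates from
   its template and re-anneals to a different template molecule, creating
   a chimera that carries element A from one vector and element B from
   another. The probability grows with the number of bases the polymerase
   must traverse between the elements, with cycle number, and with
   template excess under late-cycle resource depletion.
2. **Lentiviral template switching.** Reverse transcriptase switches
   between the two co-packaged genomic RNAs, recombining elements before
   integration.

For a construct *i*, the **coupling fraction** is

```
f_i = (reads where element A and element B both map to construct i)
      / (reads where A maps to i and B maps to some construct)
```

and a condition is summarized by the box-plot statistics (median,
quartiles, 10th/90th percentiles) of `{f_i}` over constructs, plus a
read-weighted pooled fraction.

Because the two 6-nt barcodes sit only 17 nt apart (versus 193 nt between
the two spacers), barcode–barcode pairs survive amplification far better
than spacer–spacer pairs — and both barcodes fit in a single **29-nt**
read.

## What the package provides

- `library_design` — dual-guide cassette geometry (82 / 17 / 82-nt gaps),
  Hamming-distance-≥2 hexamer barcode design, full template assembly with
  anchor-placement validation, reference tables (TSV/FASTA).
- `read_parser` — anchor-based element extraction from reads, exact or
  1-mismatch barcode mapping with `UNMAPPED` / `ANCHOR_NOT_FOUND`
  sentinels, FASTQ ingestion, per-element assignment summaries.
- `coupling_stats` — coupling fractions from read assignments or from raw
  count tables (TSV/CSV/XLSX), box-plot summaries, template-molecule
  arithmetic (6.6 pg gDNA per template; 1.24e-5 pg plasmid per template),
  combinatorial-space accounting.
- `pcr_simulator` — genotype-resolved stochastic and expected-count PCR
  models with distance-dependent template switching, resource-depletion
  coupling, lentiviral recombination, FASTQ read emission with ground
  truth, a single-cycle closed form, and a switch-rate estimator.
- `cli` — `crisprcoupler design | simulate | quantify | report |
  compare-designs`, a YAML-configured end-to-end pipeline with seeded,
  byte-reproducible outputs and provenance headers.

## Worked example

Design a 12-construct paired library, amplify it under harsh conditions
(28 cycles, large template pool, resource-coupled switching), sequence it
with errors, and quantify coupling:

```python
from crisprcoupler import (
    design_library, ReferenceLibrary, SimulationParams, simulate_reads,
    assign_reads, coupling_fractions, sgrna_sgrna_pairing,
    barcode_barcode_pairing,
)

design = design_library(12, seed=1)
refs = ReferenceLibrary.from_design(design)

params = SimulationParams(
    n_templates=50_000, cycles=28, switch_rate=2e-4,
    resource_coupling=3.0, resource_capacity=1e5,
    seq_error_rate=1e-3, seed=1,
)
records, truth, pool = simulate_reads(design, params, 20_000)
assignments, summary = assign_reads(
    [(r.id, str(r.seq)) for r in records], refs, design.layout
)
gg = coupling_fractions(assignments, sgrna_sgrna_pairing(refs), refs)
bb = coupling_fractions(assignments, barcode_barcode_pairing(refs), refs)
print(summary.fully_assigned, summary.total_reads)   # 18510 20000
print(round(gg.summary.median, 3))                   # 0.206
print(round(bb.summary.median, 3))                   # 0.829
```

The spacer–spacer pairing (193 nt apart) is heavily uncoupled while the
barcode–barcode pairing (17 nt apart) largely survives — the ordering the
cassette geometry is designed to exploit. The deterministic
expected-count mode reproduces the template-excess effect: under the same
conditions, seeding with 800,000 templates yields a spacer–spacer
coupling of 0.190 versus 0.229 from 1,500 templates.

The same pipeline is available from the shell:

```bash
crisprcoupler design --n 12 --seed 1 --out-dir lib/
crisprcoupler simulate --reference lib/reference.tsv --reads 20000 \
    --templates 50000 --cycles 28 --switch-rate 2e-4 \
    --resource-coupling 3.0 --seed 1 --out-fastq reads.fastq
crisprcoupler quantify --fastq reads.fastq --reference lib/reference.tsv \
    --pairing all --out-dir quant/
crisprcoupler compare-designs
```

`compare-designs` tabulates published dual-guide vector geometries
against this design, with the expected relative uncoupling implied by
each inter-element distance.

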