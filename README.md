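# htkit — haplotagging linked-read toolkit

Haplotagging is a linked-read library method: long DNA molecules are
captured on barcoded beads, so the short paired-end reads sequenced from
one molecule all carry the same combinatorial barcode. The barcode is
composed of four nucleotide segments (letters **A**, **C**, **B**, **D**),
each translated through a lookup table to an integer alias in `[1, 99]`,
giving the canonical 12-character form `AxxCxxBxxDxx` (e.g.
`A01C54B23D09`); a `00` segment means its nucleotides matched no table
entry, and a barcode is *valid* only when all four segments are nonzero.

`htkit` implements the bespoke computations this data model needs, for
population-genomics groups working with haplotagging (or other linked-read)
libraries:

- **demux** — split pooled paired-end FASTQ by a sample–barcode schema,
  translating inline barcode nucleotides to the ACBD alias, trimming them
  from the sequence, and writing SAM-style `BX:Z:<barcode>` and
  `VX:i:{0|1}` (barcode-validity) tags into the read headers.
- **tags** — move barcode information losslessly between FASTQ header
  comments and SAM/BAM tags, and normalize technology-specific barcodes
  into the standardized `BX:Z` + `VX:i` convention.
- **deconvolve** — assign alignments to unique molecules of origin:
  alignments with the same barcode on the same contig belong to one
  molecule while consecutive end-to-start gaps stay within a distance
  threshold *d* (default 100 kbp); a larger gap, or a different contig,
  starts a new molecule. Molecule ids are written as `MI:i` tags.
- **markdups** — duplicate marking with the barcode as part of the
  duplicate key, so reads at identical coordinates from different
  molecules are never co-flagged.
- **stats** — linked-read QC metrics (molecule span N50, reads per
  molecule, molecules per barcode, valid-barcode fraction) as JSON plus a
  self-contained HTML report.
- **sim** — a linked-read simulator (long molecules sampled from a
  reference, one valid barcode per molecule, short read pairs with inline
  barcode nucleotides, full per-pair truth tables) and a variant simulator
  (SNPs, indels, inversions, deletions, tandem duplications with a truth
  table), so the entire toolkit is testable without external data.

## Worked example

```python
import htkit
from htkit.simulate import (LinkedReadSimParams, random_reference,
                            simulate_linked_reads, read_truth,
                            truth_to_pseudo_alignments)
from htkit.demux import demultiplex
from htkit.deconvolve import assign_molecule_intervals, DeconvolutionParams
from htkit.linkstats import compute_stats

lookups = htkit.default_lookup_tables()   # 6-nt segments, 64 values/letter
layout = htkit.default_layout()           # A,C,B,D inline at the 5' of R2
schema = htkit.SampleSchema(id_segment="C",
                            assignments={1: "fishA", 2: "fishB"})

reference = random_reference({"chr1": 1_000_000, "chr2": 800_000}, seed=11)
params = LinkedReadSimParams(n_samples=2, barcodes_per_sample=15,
                             molecules_per_barcode=1.5,
                             molecule_len_mean=30_000, error_rate=0.001,
                             seed=11, min_same_barcode_gap=120_000)
sim = simulate_linked_reads(reference, params, layout, lookups, schema, "sim_out")
print(f"simulated {sim.n_pairs} read pairs from {sim.n_molecules} molecules")

summary = demultiplex(r1=sim.r1, r2=sim.r2, layout=layout, lookups=lookups,
                      schema=schema, outdir="demux_out")
print(summary.to_text())

alignments = truth_to_pseudo_alignments(read_truth(sim.truth), params.read_len)
mi, molecules = assign_molecule_intervals(alignments,
                                          DeconvolutionParams(d=100_000))
stats = compute_stats(molecules)
print(f"molecules inferred: {stats.n_molecules} (truth: {sim.n_molecules})")
print(f"molecule span N50:  {stats.molecule_span.n50:.0f} bp")
```

prints

```
simulated 1058 read pairs from 45 molecules
total pairs:            1058
unassigned pairs:       0
invalid-barcode pairs:  0
invalid segments:       A=0 B=0 C=0 D=0
pairs per sample:
  fishA	693
  fishB	365

molecules inferred: 45 (truth: 45)
molecule span N50:  32770 bp
```

Every simulated pair was routed to its true sample with its true barcode
(`unassigned 0`, `invalid 0` at a 0.1% base error rate thanks to
single-mismatch segment rescue), and because the simulation placed
same-barcode molecules more than the 100 kbp threshold apart, distance
deconvolution recovers the true molecule count exactly. The N50 is the
molecule span S such that molecules spanning ≥ S account for at least
half of the total summed span.

The same operations are exposed as a CLI:

```bash
htkit sim reads --reference ref.fa --schema schema.tsv --seed 1 --outdir sim/
htkit demux --r1 sim/reads.R1.fq.gz --r2 sim/reads.R2.fq.gz \
            --schema schema.tsv --outdir demux/
htkit deconvolve --bam sample.bam --dist 100000 --out tagged.bam \
                 --molecules molecules.tsv
htkit markdups --bam tagged.bam --out dedup.bam
htkit stats --bam dedup.bam --molecules molecules.tsv --out-prefix qc
htkit sim variants --reference ref.fa --snp-rate 0.001 --inversions 2 \
                   --seed 1 --outdir variants/
```

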