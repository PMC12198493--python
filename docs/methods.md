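# Methods

## Barcode model

A haplotag barcode is four integer segment values (letters A, C, B, D),
each in `[0, 99]`, rendered as the zero-padded 12-character string
`AxxCxxBxxDxx`. Zero is reserved: it is never a lookup-table value and
marks a segment whose nucleotides could not be translated. A barcode is
valid (`VX:i:1`) iff all four segments are nonzero; parsing and formatting
are exact inverses on this domain.

Segment translation uses per-letter lookup tables mapping fixed-length
ACGT strings to values in `[1, 99]` (injective per table; any table size
up to 99 is accepted rather than hard-coding a bead count). An exact key
match always wins. With `max_mismatch=1` (the default) an unmatched query
is rescued when exactly one key lies at Hamming distance 1; two or more
tying keys, or none, return 0 — ambiguity must never mis-assign. `N`
matches no base and counts as a mismatch at its position.

**Built-in tables.** The shipped default tables use 6-nt segments with 64
values per letter, constructed as the lexicographic greedy code with
minimum pairwise Hamming distance 4 (64 is the Singleton-bound maximum for
a length-6 quaternary code at that distance; all four letters share the
codeword set, as real haplotagging bead segments do). Distance 4 makes
every single-base error uniquely correctable and makes it impossible for a
two-error segment to be rescued into a *different* value, so the expected
invalid-segment fraction under an i.i.d. per-base substitution rate ε has
the closed form

    P(invalid) = 1 − [(1−ε)^L + L·ε·(1−ε)^(L−1)·u],   L = 6,

where `u` is the fraction of single-base mutants that rescue uniquely back
to their own value (`u = 1` for the built-in tables; it is computed by
enumeration, not assumed, wherever the formula is checked). Terms of order
ε² and beyond all land in the "invalid" outcome, and ε³-order
mis-rescues are negligible at the error rates considered (ε ≤ 0.01).

## Demultiplexing

The read layout — which read (R1/R2/I1/I2) holds each segment, at which
offset and length, and whether barcode bases are trimmed — is fully
configurable because barcode placement varies across haplotagging library
generations. The shipped default places the four 6-nt segments
contiguously at the 5′ start of R2 in A, C, B, D order and trims them
(with the matching quality positions), giving the simulator and the
demultiplexer a shared convention.

Tags are appended to the FASTQ header after the first whitespace as
`BX:Z:<canonical> VX:i:{0|1}`, preserving any pre-existing comment. SAM
convention forbids spaces inside a tag, so the emitted form is always
`BX:Z:`/`VX:i:`. Input that already carries BX/VX is rejected rather than
double-tagged. Samples are identified by a single schema-designated
segment letter (full-barcode schemas would be a straightforward
extension); pairs whose identifying segment is 0 or unmapped go to an
`unassigned` output, never dropped, so `total = assigned + unassigned`
holds on every run. Outputs are gzip (level 4, zeroed mtime) so identical
inputs give byte-identical files.

## Tag transfer and standardization

Aligners differ in whether they carry FASTQ comments into the alignment
record. Two cases are detected per record: tags already present
(bwa-mem `-C` style; VX is derived from the barcode when missing), or the
raw comment text held in a `CO:Z` tag, from which `BX:Z:`/`VX:i:` are
promoted to real tags. A record whose existing BX conflicts with its
comment aborts the run, since that indicates upstream corruption.
Standardization styles for non-haplotag technologies: `nucleotide` sets
`VX:i:0` iff the barcode contains a non-ACGT character; `generic` accepts
any nonempty string as valid. These are deliberately minimal readings of
"barcode validity" outside the ACBD system.

## Molecule deconvolution

Within each (barcode, contig) group, alignments sorted by position are
chained: a new molecule starts whenever the gap to the previous member
exceeds the threshold *d* (default 100,000 bp). The gap is end-to-start,
clamped at zero — `max(0, next.start − previous.end)` — because
start-to-start spacing would conflate read length with molecule spacing;
`gap_mode="start"` is available as a one-line alternative. Chaining is
transitive, so a molecule's total span may exceed *d*; that is intended.
Both mates of a proper pair always share a molecule (chains are merged by
read name via union–find if chaining ever separates them). Unmapped,
secondary, supplementary, barcode-less and invalid-barcode (`VX:i:0`)
records receive no `MI` tag but are passed through, preserving record
counts. Molecule ids are assigned in ascending (contig index, molecule
start, barcode) order, making outputs diffable.

## Duplicate marking

Fragments (read pairs, or single primary records) are grouped by both
ends' (contig, unclipped 5′ start, orientation) plus the barcode;
identical coordinates with different barcodes are distinct molecules and
never co-flagged. Within a group the fragment with the highest summed base
quality is kept (ties broken by lexicographically smallest read name, for
determinism); all records of the other fragments are flagged. Existing
duplicate flags are cleared first, making the operation idempotent, and at
least one member of every group always remains unflagged.

## QC statistics

The metric set is the minimal linked-read QC canon the deconvolution
output makes computable: molecule span N50 (the span S such that molecules
with span ≥ S cover at least half the summed span), reads per molecule,
molecules per barcode, valid-barcode fraction, and singleton-molecule
fraction. An empty molecule set yields zero counts with distribution
fields marked undefined, not an error. The HTML report is a single
self-contained static file; its table cells are rendered from the same
dictionary that is embedded verbatim as JSON, so the two can never
disagree. "Interactive" dashboards are out of scope here by design —
report fidelity is not the method.

## Simulators

**Linked reads.** Molecule counts per barcode are Poisson; molecule
lengths are lognormal (default mean 40 kb, σ_log 0.35) truncated to
[1 kb, 500 kb]; placement is uniform over contigs weighted by length,
rejecting overhangs; read pairs per molecule are Poisson with mean
`length × coverage / (2 × read_len)` (default per-molecule coverage 0.2,
read length 150 bp, i.e. ~20 pairs for a 30 kb molecule — haplotagging
molecules are sparsely covered); inserts are normal (mean 500, sd 50,
floored); substitution errors are i.i.d. per base, barcode bases included;
base qualities are constant. Each molecule receives a unique valid barcode
whose identifying segment matches its sample's schema entry, and the
inline barcode nucleotides are the inverse of the same lookup tables the
demultiplexer uses, guaranteeing internal consistency. An optional
`min_same_barcode_gap` forces same-barcode molecules on one contig to sit
at least that far apart, which makes the true molecule count exactly
recoverable by distance deconvolution — used by the recovery checks.
These distribution choices are the simplest that give the other modules a
truthful test surface; no numeric agreement with any external read
simulator is claimed. Features of real data the generator does not model:
PCR chimeras, barcode collisions as a process (they can be induced via
configuration), position-dependent quality and error profiles, GC bias,
and indel sequencing errors — so passing tests demonstrate algorithmic
correctness of the toolkit, not robustness to every artifact of real
libraries.

**Variants.** SVs (inversion, deletion, tandem duplication — the classes
linked-read SV callers target) are placed first, uniformly with bounded
retries, never overlapping each other; SNPs and indels (insertion or
deletion 50/50, geometric sizes) are then placed only outside SV
intervals. The truth table records contig, 1-based position/end, type,
ref and alt, ordered so that a naive editor applying it position-descending
(or ascending with offsets) reproduces the mutated FASTA exactly; the
length identity `new = old + Σ(len(alt) − len(ref))` is asserted on every
run. Inversions preserve length by construction.

## Determinism and numerical choices

All randomness flows from a single `numpy` generator per simulation,
seeded explicitly; gzip streams are written with zeroed mtime and no
filename so equal content is byte-equal. Coordinate-sort order is enforced
on alignment input, with the first out-of-order record named in the
error. Problem sizes in the test and acceptance runs (~10⁴ read pairs,
10³ alignments in oracle comparisons, 10–100 kb references) were chosen
as the smallest scales at which the statistical checks (binomial 3σ
bands, lognormal moments) are meaningful.

## Known limitations

- Sample assignment uses one identifying segment letter, not the full
  barcode combination.
- The distance threshold is a hard cutoff; no probabilistic model of
  molecule spacing is attempted (alignments from distinct molecules closer
  than *d* with the same barcode are merged, and sparse molecules with an
  internal gap beyond *d* are split — inherent to any threshold rule).
- Duplicate marking considers primary alignments only and requires mates
  to share a barcode tag.
- VX semantics for non-haplotag chemistries are a minimal reading
  (character-set validity), not a technology-specific validation.
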