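"""Synthetic haplotagging linked-read and genomic-variant simulation.

The linked-read generator emulates a haplotagging library: long DNA
molecules are sampled uniformly over a reference (rejecting contig
overhangs), each molecule carries one valid ACBD barcode whose
identifying segment matches its sample's schema entry, short paired reads
are drawn from normal-insert fragments inside each molecule, and the
barcode nucleotides (the inverse of the demultiplexing lookup tables) are
placed inline per the read layout. Substitution errors are applied i.i.d.
at a per-base rate to every base, barcode bases included. Every read pair
is recorded in a truth table, so demultiplexing, tag transfer and
molecule deconvolution can all be scored exactly.

Model choices (Poisson molecule counts, lognormal molecule lengths
truncated to [1 kb, 500 kb], normal inserts, uniform placement, constant
base quality) are the simplest that give the downstream modules a
truthful test surface; no agreement with any external simulator is
claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pysam

from .barcodes import SEGMENT_ORDER, HaplotagBarcode, SegmentLookup, format_bx
from .layout import ReadLayout
from .schema import SampleSchema
from ._io import xopen_write

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _wrap_fasta(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{_wrap_fasta(seq)}\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    contigs: Dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fx:
        for rec in fx:
            contigs[rec.name] = rec.sequence.upper()
    return contigs


def random_reference(
    contig_lengths: Mapping[str, int], seed: int, gc: float = 0.45
) -> Dict[str, str]:
    """Random nucleotide reference with the given contig lengths."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        name: rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")
        for name, length in contig_lengths.items()
    }


# ---------------------------------------------------------------------------
# Linked-read simulation
# ---------------------------------------------------------------------------

@dataclass
class LinkedReadSimParams:
    """Knobs of the linked-read generator.

    ``molecule_coverage`` sets the Poisson mean of read pairs per molecule
    as ``length * coverage / (2 * read_len)`` — i.e. mean short-read
    coverage of each molecule, typically well below 1x for haplotagging.
    ``min_same_barcode_gap`` optionally forces molecules sharing a barcode
    on one contig to sit at least that many bp apart (useful to make the
    molecule count exactly recoverable by distance deconvolution).
    """

    n_samples: int = 4
    barcodes_per_sample: int = 50
    molecules_per_barcode: float = 2.0  # Poisson mean
    molecule_len_mean: float = 40_000.0  # lognormal mean, bp
    molecule_len_sigma: float = 0.35  # sigma of log length
    molecule_len_min: int = 1_000
    molecule_len_max: int = 500_000
    molecule_coverage: float = 0.2
    read_len: int = 150
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    insert_min: int = 320
    error_rate: float = 0.0
    min_same_barcode_gap: Optional[int] = None
    base_quality: int = 37
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.barcodes_per_sample < 1:
            raise ValueError("n_samples and barcodes_per_sample must be >= 1")
        for name in ("molecules_per_barcode", "molecule_coverage", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        # a fragment must hold at least one read
        self.insert_min = max(self.insert_min, self.read_len)


@dataclass
class SimTruthRow:
    read_id: str
    sample: str
    bx: str
    molecule_id: int
    contig: str
    mol_start: int
    mol_end: int
    frag_start: int
    frag_end: int
    strand: str


TRUTH_COLUMNS = [
    "read_id",
    "sample",
    "bx",
    "molecule_id",
    "contig",
    "mol_start",
    "mol_end",
    "frag_start",
    "frag_end",
    "strand",
]


def write_truth(rows: Iterable[SimTruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    str(getattr(r, c)) for c in TRUTH_COLUMNS
                )
                + "\n"
            )


def read_truth(path: str | Path) -> List[SimTruthRow]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == TRUTH_COLUMNS, f"unexpected truth columns {header}"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            d = dict(zip(TRUTH_COLUMNS, f))
            rows.append(
                SimTruthRow(
                    read_id=d["read_id"],
                    sample=d["sample"],
                    bx=d["bx"],
                    molecule_id=int(d["molecule_id"]),
                    contig=d["contig"],
                    mol_start=int(d["mol_start"]),
                    mol_end=int(d["mol_end"]),
                    frag_start=int(d["frag_start"]),
                    frag_end=int(d["frag_end"]),
                    strand=d["strand"],
                )
            )
    return rows


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alternatives = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([alternatives[rng.integers(3)]])
    return arr.tobytes().decode("ascii")


def _embed_barcode(
    genomic: str,
    source: str,
    layout: ReadLayout,
    segment_nt: Mapping[str, str],
) -> str:
    """Insert barcode nucleotides into a read, the inverse of demux trimming."""
    placements = sorted(
        ((seg.offset, seg.end, letter) for letter, seg in layout.segments.items() if seg.source == source),
    )
    if not placements:
        return genomic
    out: List[str] = []
    pos = 0  # position in the assembled read
    g = 0  # cursor in the genomic bases
    for offset, end, letter in placements:
        n_genomic = offset - pos
        if n_genomic < 0:
            raise ValueError("overlapping segment placements")
        out.append(genomic[g : g + n_genomic])
        g += n_genomic
        out.append(segment_nt[letter])
        pos = end
    out.append(genomic[g:])
    return "".join(out)


def _assign_barcodes(
    samples: Sequence[Tuple[str, int]],
    schema: SampleSchema,
    lookups: Mapping[str, SegmentLookup],
    barcodes_per_sample: int,
    rng: np.random.Generator,
) -> List[Tuple[str, HaplotagBarcode]]:
    """One unique valid barcode per (sample, bead), id segment fixed per sample."""
    free_letters = [l for l in SEGMENT_ORDER if l != schema.id_segment]
    values = {l: sorted(lookups[l].inverse) for l in free_letters}
    seen = set()
    out: List[Tuple[str, HaplotagBarcode]] = []
    for sample, id_value in samples:
        for _ in range(barcodes_per_sample):
            for _attempt in range(10_000):
                segs = {schema.id_segment: id_value}
                for l in free_letters:
                    segs[l] = int(values[l][rng.integers(len(values[l]))])
                key = tuple(segs[l] for l in SEGMENT_ORDER)
                if key not in seen:
                    seen.add(key)
                    break
            else:
                raise RuntimeError(
                    "could not draw a unique barcode; barcode space exhausted"
                )
            out.append((sample, HaplotagBarcode(*key)))
    return out


@dataclass
class LinkedReadSimResult:
    r1: Path
    r2: Path
    truth: Path
    params_json: Path
    n_pairs: int
    n_molecules: int


def simulate_linked_reads(
    reference: str | Path | Mapping[str, str],
    params: LinkedReadSimParams,
    layout: ReadLayout,
    lookups: Mapping[str, SegmentLookup],
    schema: SampleSchema,
    out: str | Path,
) -> LinkedReadSimResult:
    """Simulate a haplotagging run: R1/R2 FASTQ plus a per-pair truth table."""
    contigs = reference if isinstance(reference, Mapping) else read_fasta(reference)
    if not contigs:
        raise ValueError("reference has no contigs")
    min_contig = min(len(s) for s in contigs.values())
    if min_contig < params.molecule_len_min:
        raise ValueError(
            f"shortest contig ({min_contig} bp) is below the minimum molecule "
            f"length ({params.molecule_len_min} bp)"
        )
    schema_samples = schema.samples
    if len(schema_samples) < params.n_samples:
        raise ValueError(
            f"schema provides {len(schema_samples)} samples but n_samples="
            f"{params.n_samples}"
        )
    samples = []
    value_of = {name: v for v, name in schema.assignments.items()}
    for name in schema_samples[: params.n_samples]:
        samples.append((name, value_of[name]))

    rng = np.random.default_rng(params.seed)
    names = list(contigs)
    lengths = np.array([len(contigs[n]) for n in names], dtype=float)
    contig_p = lengths / lengths.sum()

    barcodes = _assign_barcodes(
        samples, schema, lookups, params.barcodes_per_sample, rng
    )

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    r1_path, r2_path = out / "reads.R1.fq.gz", out / "reads.R2.fq.gz"
    truth_path, params_path = out / "truth.tsv", out / "sim_params.json"
    qual_char = chr(params.base_quality + 33)

    truth_rows: List[SimTruthRow] = []
    n_pairs = 0
    molecule_id = 0
    placed: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}

    with xopen_write(r1_path) as w1, xopen_write(r2_path) as w2:
        for sample, barcode in barcodes:
            bx = format_bx(barcode)
            segment_nt = {
                l: lookups[l].inverse[getattr(barcode, l.lower())]
                for l in SEGMENT_ORDER
            }
            n_mol = int(rng.poisson(params.molecules_per_barcode))
            for _ in range(n_mol):
                # sample a truncated-lognormal molecule length and place it
                for _attempt in range(1_000):
                    length = int(
                        rng.lognormal(
                            np.log(params.molecule_len_mean), params.molecule_len_sigma
                        )
                    )
                    if not params.molecule_len_min <= length <= params.molecule_len_max:
                        continue
                    ci = int(rng.choice(len(names), p=contig_p))
                    contig = names[ci]
                    room = len(contigs[contig]) - length
                    if room < 0:
                        continue
                    start = int(rng.integers(room + 1))
                    end = start + length
                    if params.min_same_barcode_gap is not None:
                        gap = params.min_same_barcode_gap
                        clashes = any(
                            start < e + gap and s < end + gap
                            for s, e in placed.get((bx, contig), [])
                        )
                        if clashes:
                            continue
                    break
                else:
                    raise RuntimeError(
                        "could not place a molecule after 1000 attempts; "
                        "loosen placement constraints or enlarge the reference"
                    )
                molecule_id += 1
                placed.setdefault((bx, contig), []).append((start, end))
                mean_pairs = length * params.molecule_coverage / (2 * params.read_len)
                k = int(rng.poisson(mean_pairs))
                k = max(k, 1)  # a molecule with no reads is unobservable
                for _ in range(k):
                    insert = int(
                        round(rng.normal(params.insert_mean, params.insert_sd))
                    )
                    insert = min(max(insert, params.insert_min, params.read_len), length)
                    fs = start + int(rng.integers(length - insert + 1))
                    fe = fs + insert
                    strand = "+" if rng.random() < 0.5 else "-"
                    fwd = contigs[contig][fs : fs + params.read_len]
                    rev = revcomp(contigs[contig][fe - params.read_len : fe])
                    if strand == "+":
                        g1, g2 = fwd, rev
                    else:
                        g1, g2 = rev, fwd
                    read_id = f"sim_{n_pairs:08d}"
                    s1 = _embed_barcode(g1, "R1", layout, segment_nt)
                    s2 = _embed_barcode(g2, "R2", layout, segment_nt)
                    s1 = _apply_errors(s1, params.error_rate, rng)
                    s2 = _apply_errors(s2, params.error_rate, rng)
                    w1.write(f"@{read_id}\n{s1}\n+\n{qual_char * len(s1)}\n")
                    w2.write(f"@{read_id}\n{s2}\n+\n{qual_char * len(s2)}\n")
                    truth_rows.append(
                        SimTruthRow(
                            read_id=read_id,
                            sample=sample,
                            bx=bx,
                            molecule_id=molecule_id,
                            contig=contig,
                            mol_start=start,
                            mol_end=end,
                            frag_start=fs,
                            frag_end=fe,
                            strand=strand,
                        )
                    )
                    n_pairs += 1

    write_truth(truth_rows, truth_path)
    with open(params_path, "w") as fh:
        json.dump(asdict(params), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return LinkedReadSimResult(
        r1=r1_path,
        r2=r2_path,
        truth=truth_path,
        params_json=params_path,
        n_pairs=n_pairs,
        n_molecules=molecule_id,
    )


def truth_to_pseudo_alignments(rows: Sequence[SimTruthRow], read_len: int):
    """Turn truth fragment coordinates into coordinate-sorted pseudo-alignments.

    Each read pair yields two alignments (one per fragment end), letting the
    deconvolution chain be evaluated without running an aligner.
    """
    from .deconvolve import PseudoAlignment

    alns = []
    for r in rows:
        alns.append(
            PseudoAlignment(
                name=r.read_id,
                contig=r.contig,
                start=r.frag_start,
                end=min(r.frag_start + read_len, r.frag_end),
                bx=r.bx,
                proper_pair=True,
            )
        )
        alns.append(
            PseudoAlignment(
                name=r.read_id,
                contig=r.contig,
                start=max(r.frag_end - read_len, r.frag_start),
                end=r.frag_end,
                bx=r.bx,
                proper_pair=True,
            )
        )
    alns.sort(key=lambda a: (a.contig, a.start, a.end, a.name))
    return alns


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

@dataclass
class VariantSimParams:
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_size_p: float = 0.5  # geometric success prob; mean size 1/p
    sv_counts: Dict[str, int] = field(
        default_factory=lambda: {"inversion": 0, "deletion": 0, "duplication": 0}
    )
    sv_size_min: int = 1_000
    sv_size_max: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snp_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0 < self.indel_size_p <= 1:
            raise ValueError("indel_size_p must be in (0, 1]")
        unknown = set(self.sv_counts) - {"inversion", "deletion", "duplication"}
        if unknown:
            raise ValueError(f"unknown SV classes: {sorted(unknown)}")
        if self.sv_size_min < 2 or self.sv_size_max < self.sv_size_min:
            raise ValueError("invalid SV size range")


@dataclass
class VariantRecord:
    contig: str
    pos: int  # 1-based; for INS, the base after which insertion occurs
    end: int  # 1-based inclusive; == pos for SNP/INS
    type: str  # SNP / INS / DEL / INV / DUP
    ref: str
    alt: str


VARIANT_COLUMNS = ["contig", "pos", "end", "type", "ref", "alt"]


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_COLUMNS) + "\n")
        for v in variants:
            fh.write(f"{v.contig}\t{v.pos}\t{v.end}\t{v.type}\t{v.ref}\t{v.alt}\n")


def read_variant_table(path: str | Path) -> List[VariantRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == VARIANT_COLUMNS
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                VariantRecord(
                    contig=f[0], pos=int(f[1]), end=int(f[2]), type=f[3],
                    ref=f[4] if f[4] != "." else "", alt=f[5] if f[5] != "." else "",
                )
            )
    return out


def apply_variants(contigs: Mapping[str, str], variants: Sequence[VariantRecord]) -> Dict[str, str]:
    """Apply a truth table to a reference (descending position per contig)."""
    mutated = dict(contigs)
    by_contig: Dict[str, List[VariantRecord]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for contig, vs in by_contig.items():
        seq = mutated[contig]
        for v in sorted(vs, key=lambda v: v.pos, reverse=True):
            i, j = v.pos - 1, v.end  # python slice [i, j)
            if v.type == "SNP":
                assert seq[i] == v.ref, f"{contig}:{v.pos} ref mismatch"
                seq = seq[:i] + v.alt + seq[i + 1 :]
            elif v.type == "INS":
                seq = seq[: v.pos] + v.alt + seq[v.pos :]
            elif v.type == "DEL":
                assert seq[i:j] == v.ref
                seq = seq[:i] + seq[j:]
            elif v.type == "INV":
                assert seq[i:j] == v.ref
                seq = seq[:i] + v.alt + seq[j:]
            elif v.type == "DUP":
                assert seq[i:j] == v.ref
                seq = seq[:i] + v.alt + seq[j:]
            else:
                raise ValueError(f"unknown variant type {v.type}")
        mutated[contig] = seq
    return mutated


def _blocked(intervals: List[Tuple[int, int]], start: int, end: int) -> bool:
    return any(start < e and s < end for s, e in intervals)


def simulate_variants(
    reference: str | Path | Mapping[str, str],
    params: VariantSimParams,
    out: str | Path,
) -> Tuple[Path, Path]:
    """Inject SNPs, small indels and SVs into a reference.

    SVs (inversion, deletion, tandem duplication) are placed first and never
    overlap each other; SNPs and indels are never placed inside SV intervals.
    Returns (mutated FASTA path, truth table path).
    """
    contigs = reference if isinstance(reference, Mapping) else read_fasta(reference)
    rng = np.random.default_rng(params.seed)
    names = list(contigs)
    lengths = np.array([len(contigs[n]) for n in names], dtype=float)
    contig_p = lengths / lengths.sum()

    variants: List[VariantRecord] = []
    blocked: Dict[str, List[Tuple[int, int]]] = {n: [] for n in names}

    sv_type_map = {"inversion": "INV", "deletion": "DEL", "duplication": "DUP"}
    for sv_class in ("inversion", "deletion", "duplication"):
        for _ in range(params.sv_counts.get(sv_class, 0)):
            for _attempt in range(1_000):
                size = int(rng.integers(params.sv_size_min, params.sv_size_max + 1))
                ci = int(rng.choice(len(names), p=contig_p))
                contig = names[ci]
                if len(contigs[contig]) <= size:
                    continue
                start = int(rng.integers(len(contigs[contig]) - size))
                if _blocked(blocked[contig], start, start + size):
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not place a {sv_class} of size within "
                    f"[{params.sv_size_min}, {params.sv_size_max}] after 1000 attempts"
                )
            blocked[contig].append((start, start + size))
            segment = contigs[contig][start : start + size]
            if sv_class == "inversion":
                alt = revcomp(segment)
            elif sv_class == "deletion":
                alt = ""
            else:  # tandem duplication
                alt = segment + segment
            variants.append(
                VariantRecord(
                    contig=contig,
                    pos=start + 1,
                    end=start + size,
                    type=sv_type_map[sv_class],
                    ref=segment,
                    alt=alt,
                )
            )

    for contig in names:
        seq = contigs[contig]
        L = len(seq)
        taken: set[int] = set()

        def free(pos0: int, span: int = 1) -> bool:
            if pos0 + span > L:
                return False
            if _blocked(blocked[contig], pos0, pos0 + span):
                return False
            return not any(p in taken for p in range(pos0, pos0 + span))

        n_snp = int(rng.binomial(L, params.snp_rate)) if params.snp_rate > 0 else 0
        placed_snp = 0
        attempts = 0
        while placed_snp < n_snp and attempts < 50 * n_snp + 1_000:
            attempts += 1
            pos0 = int(rng.integers(L))
            if not free(pos0):
                continue
            ref = seq[pos0]
            if ref not in "ACGT":
                continue
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            taken.add(pos0)
            variants.append(
                VariantRecord(contig=contig, pos=pos0 + 1, end=pos0 + 1,
                              type="SNP", ref=ref, alt=alt)
            )
            placed_snp += 1

        n_indel = int(rng.binomial(L, params.indel_rate)) if params.indel_rate > 0 else 0
        placed_indel = 0
        attempts = 0
        while placed_indel < n_indel and attempts < 50 * n_indel + 1_000:
            attempts += 1
            size = int(rng.geometric(params.indel_size_p))
            is_ins = rng.random() < 0.5
            if is_ins:
                pos0 = int(rng.integers(1, L))  # insert after this 0-based base
                if not free(pos0):
                    continue
                alt = "".join("ACGT"[int(b)] for b in rng.integers(4, size=size))
                taken.add(pos0)
                variants.append(
                    VariantRecord(contig=contig, pos=pos0 + 1, end=pos0 + 1,
                                  type="INS", ref="", alt=alt)
                )
            else:
                pos0 = int(rng.integers(L - size)) if L > size else None
                if pos0 is None or not free(pos0, size):
                    continue
                taken.update(range(pos0, pos0 + size))
                variants.append(
                    VariantRecord(contig=contig, pos=pos0 + 1, end=pos0 + size,
                                  type="DEL", ref=seq[pos0 : pos0 + size], alt="")
                )
            placed_indel += 1

    order = {n: i for i, n in enumerate(names)}
    variants.sort(key=lambda v: (order[v.contig], v.pos, v.type))

    mutated = apply_variants(contigs, variants)
    expected_delta = sum(len(v.alt) - len(v.ref) for v in variants)
    assert sum(map(len, mutated.values())) == sum(map(len, contigs.values())) + expected_delta

    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = out / "mutated.fasta"
    table_path = out / "variants.tsv"
    write_fasta(mutated, fasta_path)
    write_variant_table(variants, table_path)
    return fasta_path, table_path
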