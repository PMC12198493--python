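"""Distance-based molecule deconvolution and barcode-aware duplicate marking.

Linked-read barcodes are reused across many input molecules, so alignments
sharing a barcode must be resolved into molecules of origin. The rule:
alignments with the same barcode on the same contig belong to the same
molecule when, walking them in position order, the gap between consecutive
members stays within a distance threshold ``d`` (default 100 kbp); a gap
beyond ``d``, or a different contig, starts a new molecule. The gap is
measured end-to-start (clamped at zero) so read length is not conflated
with molecule spacing; ``gap_mode="start"`` switches to start-to-start.
Both mates of a proper pair always share a molecule. Inferred molecules
are written as ``MI:i`` tags, numbered in ascending (contig, start,
barcode) order.

Duplicate marking augments the usual coordinate key with the barcode:
records that share position, orientation and mate coordinates but carry
different barcodes originate from different molecules and are never
co-flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam


@dataclass(frozen=True)
class PseudoAlignment:
    """Minimal alignment view the chaining algorithm needs."""

    name: str
    contig: str
    start: int  # 0-based leftmost
    end: int  # 0-based exclusive
    bx: str
    proper_pair: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end {self.end} <= start {self.start}")


@dataclass
class MoleculeInterval:
    molecule_id: int
    contig: str
    start: int
    end: int
    bx: str
    n_reads: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class DeconvolutionParams:
    d: int = 100_000
    gap_mode: str = "end"  # "end": next.start - prev.end; "start": start-to-start

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"distance threshold d must be > 0, got {self.d}")
        if self.gap_mode not in ("end", "start"):
            raise ValueError(f"gap_mode must be 'end' or 'start', got {self.gap_mode!r}")


class UnsortedInputError(RuntimeError):
    """Input alignments are not coordinate-sorted."""


def _find(parent: List[int], i: int) -> int:
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return i


def _union(parent: List[int], a: int, b: int) -> None:
    ra, rb = _find(parent, a), _find(parent, b)
    if ra != rb:
        parent[max(ra, rb)] = min(ra, rb)


def assign_molecule_intervals(
    alignments: Sequence[PseudoAlignment],
    params: DeconvolutionParams | None = None,
    contig_order: Sequence[str] | None = None,
) -> Tuple[List[Optional[int]], List[MoleculeInterval]]:
    """Chain coordinate-sorted alignments into molecules.

    Returns (molecule id per input alignment, molecule interval list).
    Input must be sorted by (contig, start) with contigs in ``contig_order``
    (order of first appearance when omitted). Proper pairs (same read name,
    ``proper_pair`` set) are merged into one molecule even if chaining
    split them.
    """
    params = params or DeconvolutionParams()
    if contig_order is None:
        contig_order = []
        seen = set()
        for a in alignments:
            if a.contig not in seen:
                seen.add(a.contig)
                contig_order.append(a.contig)
    contig_rank = {c: i for i, c in enumerate(contig_order)}

    prev_key: Tuple[int, int] | None = None
    # per (bx, contig): (chain index, prev member start, prev member end)
    active: Dict[Tuple[str, str], Tuple[int, int, int]] = {}
    chain_of: List[int] = []
    chains: List[List[int]] = []  # chain index -> member alignment indices

    for idx, aln in enumerate(alignments):
        if aln.contig not in contig_rank:
            raise ValueError(f"alignment {aln.name!r}: contig {aln.contig!r} not in contig order")
        key = (contig_rank[aln.contig], aln.start)
        if prev_key is not None and key < prev_key:
            raise UnsortedInputError(
                f"alignment {idx} ({aln.name!r} at {aln.contig}:{aln.start}) is out of order"
            )
        prev_key = key
        gkey = (aln.bx, aln.contig)
        state = active.get(gkey)
        if state is None:
            new_chain = True
        else:
            chain_idx, prev_start, prev_end = state
            if params.gap_mode == "end":
                gap = max(0, aln.start - prev_end)
            else:
                gap = aln.start - prev_start
            new_chain = gap > params.d
        if new_chain:
            chain_idx = len(chains)
            chains.append([])
        chains[chain_idx].append(idx)
        chain_of.append(chain_idx)
        active[gkey] = (chain_idx, aln.start, aln.end)

    # merge chains holding both mates of a proper pair
    parent = list(range(len(chains)))
    pair_chain: Dict[Tuple[str, str], int] = {}
    for idx, aln in enumerate(alignments):
        if not aln.proper_pair:
            continue
        pkey = (aln.name, aln.bx)
        other = pair_chain.get(pkey)
        if other is None:
            pair_chain[pkey] = chain_of[idx]
        else:
            _union(parent, other, chain_of[idx])

    components: Dict[int, List[int]] = {}
    for chain_idx, members in enumerate(chains):
        root = _find(parent, chain_idx)
        components.setdefault(root, []).extend(members)

    raw: List[Tuple[Tuple[int, int, str], List[int]]] = []
    for members in components.values():
        first = alignments[members[0]]
        start = min(alignments[i].start for i in members)
        end = max(alignments[i].end for i in members)
        raw.append(((contig_rank[first.contig], start, first.bx), members))
    raw.sort(key=lambda item: item[0])

    mi_per_alignment: List[Optional[int]] = [None] * len(alignments)
    molecules: List[MoleculeInterval] = []
    for mol_id, ((_, start, bx), members) in enumerate(raw, start=1):
        contig = alignments[members[0]].contig
        end = max(alignments[i].end for i in members)
        molecules.append(
            MoleculeInterval(
                molecule_id=mol_id,
                contig=contig,
                start=start,
                end=end,
                bx=bx,
                n_reads=len(members),
            )
        )
        for i in members:
            mi_per_alignment[i] = mol_id
    return mi_per_alignment, molecules


# ---------------------------------------------------------------------------
# BAM-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionCounts:
    total_records: int = 0
    eligible: int = 0
    no_barcode: int = 0
    invalid_barcode: int = 0
    skipped: int = 0  # unmapped / secondary / supplementary
    n_molecules: int = 0


def _record_vx(record: pysam.AlignedSegment) -> Optional[int]:
    if record.has_tag("VX"):
        return int(record.get_tag("VX"))
    if record.has_tag("BX"):
        from .barcodes import BarcodeFormatError, barcode_validity, parse_bx

        try:
            return barcode_validity(parse_bx(str(record.get_tag("BX"))))
        except BarcodeFormatError:
            return 1  # non-haplotag barcode with no VX: assume usable
    return None


def _is_eligible(record: pysam.AlignedSegment) -> bool:
    return not (
        record.is_unmapped or record.is_secondary or record.is_supplementary
    )


def assign_molecules(
    bam_in: str | Path,
    bam_out: str | Path,
    params: DeconvolutionParams | None = None,
) -> Tuple[DeconvolutionCounts, List[MoleculeInterval]]:
    """Assign MI tags to a coordinate-sorted, BX-tagged alignment file.

    Two passes: the first collects eligible primary alignments and chains
    them; the second rewrites the file adding ``MI:i`` tags. Ineligible
    records (unmapped, secondary, supplementary, VX==0, or barcode-less)
    pass through unchanged.
    """
    params = params or DeconvolutionParams()
    counts = DeconvolutionCounts()
    pseudo: List[PseudoAlignment] = []
    keys: List[Tuple[str, int, int, str]] = []  # to map back in pass 2

    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        contig_order = list(src.references)
        prev = None
        for record in src:
            counts.total_records += 1
            if not _is_eligible(record):
                counts.skipped += 1
                continue
            here = (record.reference_id, record.reference_start)
            if prev is not None and here < prev:
                raise UnsortedInputError(
                    f"record {record.query_name!r} at "
                    f"{record.reference_name}:{record.reference_start} is out of order; "
                    "input must be coordinate-sorted"
                )
            prev = here
            if not record.has_tag("BX"):
                counts.no_barcode += 1
                continue
            vx = _record_vx(record)
            if vx == 0:
                counts.invalid_barcode += 1
                continue
            counts.eligible += 1
            pseudo.append(
                PseudoAlignment(
                    name=record.query_name,
                    contig=record.reference_name,
                    start=record.reference_start,
                    end=record.reference_end,
                    bx=str(record.get_tag("BX")),
                    proper_pair=record.is_proper_pair,
                )
            )

    mi, molecules = assign_molecule_intervals(pseudo, params, contig_order=contig_order)
    counts.n_molecules = len(molecules)
    mi_by_key: Dict[Tuple[str, str, int, str], int] = {}
    for aln, mol in zip(pseudo, mi):
        mi_by_key[(aln.name, aln.contig, aln.start, aln.bx)] = mol

    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        mode = "wb" if str(bam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(bam_out), mode, template=src) as dst:
            for record in src:
                if (
                    _is_eligible(record)
                    and record.has_tag("BX")
                    and _record_vx(record) != 0
                ):
                    key = (
                        record.query_name,
                        record.reference_name,
                        record.reference_start,
                        str(record.get_tag("BX")),
                    )
                    record.set_tag("MI", mi_by_key[key], value_type="i")
                dst.write(record)
    return counts, molecules


def write_molecule_table(molecules: Iterable[MoleculeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tcontig\tstart\tend\tspan\tbx\tn_reads\n")
        for m in molecules:
            fh.write(
                f"{m.molecule_id}\t{m.contig}\t{m.start}\t{m.end}\t{m.span}\t{m.bx}\t{m.n_reads}\n"
            )


def read_molecule_table(path: str | Path) -> List[MoleculeInterval]:
    molecules = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            molecules.append(
                MoleculeInterval(
                    molecule_id=int(f[idx["molecule_id"]]),
                    contig=f[idx["contig"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    bx=f[idx["bx"]],
                    n_reads=int(f[idx["n_reads"]]),
                )
            )
    return molecules


# ---------------------------------------------------------------------------
# Barcode-aware duplicate marking
# ---------------------------------------------------------------------------

@dataclass
class DuplicateCounts:
    total_records: int = 0
    fragments: int = 0
    duplicate_fragments: int = 0
    records_flagged: int = 0


def _unclipped_start(record: pysam.AlignedSegment) -> int:
    """5' unclipped reference coordinate (orientation-aware)."""
    cig = record.cigartuples or []
    if record.is_reverse:
        tail = 0
        for op, length in reversed(cig):
            if op in (4, 5):  # soft / hard clip
                tail += length
            else:
                break
        return record.reference_end + tail
    head = 0
    for op, length in cig:
        if op in (4, 5):
            head += length
        else:
            break
    return record.reference_start - head


def _end_key(record: pysam.AlignedSegment) -> Tuple:
    return (record.reference_id, _unclipped_start(record), record.is_reverse)


def mark_duplicates_bx(bam_in: str | Path, bam_out: str | Path) -> DuplicateCounts:
    """Flag PCR/optical duplicates using the barcode as part of the key.

    Fragments (read pairs, or single primary records) are duplicates when
    they share both ends' (contig, unclipped 5' start, orientation) and the
    BX barcode; identical coordinates with different barcodes are distinct
    molecules and never co-flagged. Within a duplicate set the fragment with
    the highest summed base quality (ties: lexicographically smallest name)
    is kept; all records of the other fragments are flagged. Existing
    duplicate flags are cleared first, so the operation is idempotent.
    """
    counts = DuplicateCounts()
    frag_ends: Dict[str, List[Tuple]] = {}
    frag_qual: Dict[str, int] = {}
    frag_bx: Dict[str, Optional[str]] = {}

    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        prev = None
        for record in src:
            counts.total_records += 1
            if not _is_eligible(record):
                continue
            here = (record.reference_id, record.reference_start)
            if prev is not None and here < prev:
                raise UnsortedInputError(
                    f"record {record.query_name!r} is out of order; "
                    "input must be coordinate-sorted"
                )
            prev = here
            name = record.query_name
            frag_ends.setdefault(name, []).append(_end_key(record))
            qual = sum(record.query_qualities or [])
            frag_qual[name] = frag_qual.get(name, 0) + qual
            bx = str(record.get_tag("BX")) if record.has_tag("BX") else None
            if name in frag_bx and frag_bx[name] != bx:
                raise ValueError(f"fragment {name!r}: mates carry different BX tags")
            frag_bx[name] = bx

    groups: Dict[Tuple, List[str]] = {}
    for name, ends in frag_ends.items():
        key = (tuple(sorted(ends)), frag_bx[name])
        groups.setdefault(key, []).append(name)
    counts.fragments = len(frag_ends)

    dup_names = set()
    for names in groups.values():
        if len(names) < 2:
            continue
        keeper = min(names, key=lambda n: (-frag_qual[n], n))
        for n in names:
            if n != keeper:
                dup_names.add(n)
    counts.duplicate_fragments = len(dup_names)

    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        mode = "wb" if str(bam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(bam_out), mode, template=src) as dst:
            for record in src:
                record.is_duplicate = record.query_name in dup_names
                if record.is_duplicate:
                    counts.records_flagged += 1
                dst.write(record)
    return counts
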