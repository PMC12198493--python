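"""Distance-threshold molecule assignment and barcode-aware duplicate marking."""

import numpy as np
import pysam
import pytest

from htkit.deconvolve import (
    DeconvolutionParams,
    PseudoAlignment,
    UnsortedInputError,
    assign_molecule_intervals,
    assign_molecules,
    mark_duplicates_bx,
    read_molecule_table,
    write_molecule_table,
)

from conftest import SAM_HEADER, make_record, write_sam

D = 100_000


def _partition(alignments, mi):
    """Group alignment indices by molecule id, as frozensets, for comparison."""
    groups = {}
    for i, m in enumerate(mi):
        groups.setdefault(m, set()).add(i)
    return {frozenset(v) for v in groups.values()}


def _oracle_partition(alignments, d):
    """Brute force: link position-adjacent same-(bx, contig) members with
    gap <= d, take connected components (independent union-find)."""
    parent = list(range(len(alignments)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    groups = {}
    for i, a in enumerate(alignments):
        groups.setdefault((a.bx, a.contig), []).append(i)
    for members in groups.values():
        members = sorted(members, key=lambda i: (alignments[i].start, alignments[i].end))
        for i, j in zip(members, members[1:]):
            gap = max(0, alignments[j].start - alignments[i].end)
            if gap <= d:
                union(i, j)
    comps = {}
    for i in range(len(alignments)):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


class TestChaining:
    def test_two_reads_within_threshold_one_molecule(self):
        alns = [
            PseudoAlignment("r1", "chr1", 1000, 1100, "A01C01B01D01"),
            PseudoAlignment("r2", "chr1", 50_000, 50_100, "A01C01B01D01"),
        ]
        mi, mols = assign_molecule_intervals(alns, DeconvolutionParams(d=D))
        assert len(mols) == 1
        assert mols[0].n_reads == 2
        assert (mols[0].start, mols[0].end) == (1000, 50_100)

    def test_two_reads_beyond_threshold_two_molecules(self):
        alns = [
            PseudoAlignment("r1", "chr1", 1000, 1100, "A01C01B01D01"),
            PseudoAlignment("r2", "chr1", 201_200, 201_300, "A01C01B01D01"),
        ]
        mi, mols = assign_molecule_intervals(alns, DeconvolutionParams(d=D))
        assert len(mols) == 2
        assert mi == [1, 2]

    def test_same_barcode_different_contigs_never_joined(self):
        alns = [
            PseudoAlignment("r1", "chr1", 1000, 1100, "A01C01B01D01"),
            PseudoAlignment("r2", "chr2", 1000, 1100, "A01C01B01D01"),
        ]
        mi, mols = assign_molecule_intervals(alns, DeconvolutionParams(d=D))
        assert len(mols) == 2

    def test_single_alignment_single_molecule(self):
        alns = [PseudoAlignment("r1", "chr1", 500, 650, "A01C01B01D01")]
        mi, mols = assign_molecule_intervals(alns)
        assert mi == [1]
        assert mols[0].n_reads == 1
        assert mols[0].span == 150

    def test_gap_is_end_to_start_not_start_to_start(self):
        # long first read: starts 150 kb apart but end-to-start gap is 10 kb
        alns = [
            PseudoAlignment("r1", "chr1", 0, 140_000, "A01C01B01D01"),
            PseudoAlignment("r2", "chr1", 150_000, 150_100, "A01C01B01D01"),
        ]
        _, mols_end = assign_molecule_intervals(alns, DeconvolutionParams(d=D, gap_mode="end"))
        _, mols_start = assign_molecule_intervals(alns, DeconvolutionParams(d=D, gap_mode="start"))
        assert len(mols_end) == 1
        assert len(mols_start) == 2

    def test_chaining_can_exceed_threshold_in_total_span(self):
        step = 90_000
        alns = [
            PseudoAlignment(f"r{i}", "chr1", i * step, i * step + 100, "A01C01B01D01")
            for i in range(5)
        ]
        _, mols = assign_molecule_intervals(alns, DeconvolutionParams(d=D))
        assert len(mols) == 1
        assert mols[0].span > D

    def test_unsorted_input_rejected(self):
        alns = [
            PseudoAlignment("r1", "chr1", 5000, 5100, "A01C01B01D01"),
            PseudoAlignment("r2", "chr1", 100, 200, "A01C01B01D01"),
        ]
        with pytest.raises(UnsortedInputError):
            assign_molecule_intervals(alns)

    def test_molecule_ids_ordered_by_contig_start_barcode(self):
        alns = sorted(
            [
                PseudoAlignment("r1", "chr1", 10_000, 10_100, "A02C02B02D02"),
                PseudoAlignment("r2", "chr1", 500, 600, "A01C01B01D01"),
                PseudoAlignment("r3", "chr2", 100, 200, "A01C01B01D01"),
            ],
            key=lambda a: (a.contig, a.start),
        )
        _, mols = assign_molecule_intervals(alns)
        keys = [(m.contig, m.start, m.bx) for m in mols]
        assert [m.molecule_id for m in mols] == [1, 2, 3]
        assert keys == sorted(keys)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        barcodes = [f"A{i:02d}C01B01D01" for i in range(1, 51)]
        contigs = ["chr1", "chr2", "chr3"]
        alns = []
        for i in range(1000):
            contig = contigs[rng.integers(3)]
            start = int(rng.integers(2_000_000))
            alns.append(
                PseudoAlignment(
                    name=f"r{i}",
                    contig=contig,
                    start=start,
                    end=start + int(rng.integers(50, 30_000)),
                    bx=barcodes[rng.integers(len(barcodes))],
                )
            )
        alns.sort(key=lambda a: (a.contig, a.start, a.end, a.name))
        mi, mols = assign_molecule_intervals(alns, DeconvolutionParams(d=D))
        assert _partition(alns, mi) == _oracle_partition(alns, D)
        # partition property: member counts sum to the alignment count
        assert sum(m.n_reads for m in mols) == len(alns)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DeconvolutionParams(d=0)
        with pytest.raises(ValueError):
            DeconvolutionParams(d=100, gap_mode="middle")


class TestBamAssignment:
    def test_mi_tags_and_passthrough(self, tmp_path, sam_header):
        bx = "A01C54B23D09"
        records = [
            make_record(sam_header, "p1", "chr1", 1000, bx=bx, vx=1),
            make_record(sam_header, "p2", "chr1", 20_000, bx=bx, vx=1),
            make_record(sam_header, "bad", "chr1", 30_000, bx="A00C54B23D09", vx=0),
            make_record(sam_header, "untagged", "chr1", 40_000),
            make_record(sam_header, "sec", "chr1", 50_000, bx=bx, vx=1, flag=256),
            make_record(sam_header, "p3", "chr1", 400_000, bx=bx, vx=1),
        ]
        sam = write_sam(tmp_path / "in.sam", records)
        counts, mols = assign_molecules(sam, tmp_path / "out.sam")
        assert counts.total_records == 6
        assert counts.eligible == 3
        assert counts.invalid_barcode == 1
        assert counts.no_barcode == 1
        assert counts.skipped == 1
        assert len(mols) == 2
        with pysam.AlignmentFile(str(tmp_path / "out.sam")) as f:
            got = {r.query_name: (r.get_tag("MI") if r.has_tag("MI") else None) for r in f}
        assert got == {"p1": 1, "p2": 1, "bad": None, "untagged": None, "sec": None, "p3": 2}

    def test_unsorted_bam_aborts(self, tmp_path, sam_header):
        records = [
            make_record(sam_header, "r1", "chr1", 5000, bx="A01C01B01D01", vx=1),
            make_record(sam_header, "r2", "chr1", 100, bx="A01C01B01D01", vx=1),
        ]
        sam = write_sam(tmp_path / "unsorted.sam", records)
        with pytest.raises(UnsortedInputError):
            assign_molecules(sam, tmp_path / "out.sam")

    def test_molecule_table_roundtrip(self, tmp_path):
        alns = [
            PseudoAlignment("r1", "chr1", 100, 250, "A01C01B01D01"),
            PseudoAlignment("r2", "chr1", 300, 450, "A01C01B01D01"),
        ]
        _, mols = assign_molecule_intervals(alns)
        path = tmp_path / "molecules.tsv"
        write_molecule_table(mols, path)
        assert read_molecule_table(path) == mols


def _dup_oracle(fragments):
    """fragments: name -> (ends_key, bx, qual). Returns set of duplicate names."""
    groups = {}
    for name, (ends, bx, qual) in fragments.items():
        groups.setdefault((ends, bx), []).append(name)
    dups = set()
    for names in groups.values():
        if len(names) > 1:
            keeper = sorted(names, key=lambda n: (-fragments[n][2], n))[0]
            dups.update(n for n in names if n != keeper)
    return dups


def _pair(header, name, pos1, pos2, bx, qual=30):
    # proper FR pair on chr1
    r1 = make_record(header, name, "chr1", pos1, bx=bx, vx=1, flag=0x63, qual=qual,
                     mate_pos=pos2)
    r2 = make_record(header, name, "chr1", pos2, bx=bx, vx=1, flag=0x93, qual=qual,
                     mate_pos=pos1)
    return [r1, r2]


class TestDuplicateMarking:
    def test_identical_pairs_same_bx_one_flagged(self, tmp_path, sam_header):
        records = _pair(sam_header, "a", 1000, 1400, "A01C01B01D01", qual=35)
        records += _pair(sam_header, "b", 1000, 1400, "A01C01B01D01", qual=20)
        records.sort(key=lambda r: r.reference_start)
        sam = write_sam(tmp_path / "in.sam", records)
        counts = mark_duplicates_bx(sam, tmp_path / "out.sam")
        assert counts.duplicate_fragments == 1
        with pysam.AlignmentFile(str(tmp_path / "out.sam")) as f:
            flags = {r.query_name for r in f if r.is_duplicate}
        assert flags == {"b"}  # lower quality pair flagged

    def test_identical_coordinates_different_bx_never_coflagged(self, tmp_path, sam_header):
        records = _pair(sam_header, "a", 1000, 1400, "A01C01B01D01")
        records += _pair(sam_header, "b", 1000, 1400, "A02C01B01D01")
        records.sort(key=lambda r: r.reference_start)
        sam = write_sam(tmp_path / "in.sam", records)
        counts = mark_duplicates_bx(sam, tmp_path / "out.sam")
        assert counts.duplicate_fragments == 0
        with pysam.AlignmentFile(str(tmp_path / "out.sam")) as f:
            assert not any(r.is_duplicate for r in f)

    def test_idempotent_and_never_flags_whole_set(self, tmp_path, sam_header):
        records = []
        for i, q in enumerate((30, 30, 30)):
            records += _pair(sam_header, f"n{i}", 2000, 2600, "A03C01B01D01", qual=q)
        records.sort(key=lambda r: r.reference_start)
        sam = write_sam(tmp_path / "in.sam", records)
        mark_duplicates_bx(sam, tmp_path / "out1.sam")
        counts2 = mark_duplicates_bx(tmp_path / "out1.sam", tmp_path / "out2.sam")
        assert counts2.duplicate_fragments == 2  # one fragment always kept
        t1 = (tmp_path / "out1.sam").read_text()
        t2 = (tmp_path / "out2.sam").read_text()
        assert t1 == t2

    def test_matches_grouping_oracle_on_random_instance(self, tmp_path, sam_header):
        rng = np.random.default_rng(23)
        positions = [1000, 1000, 5000, 5000, 9000]
        barcodes = ["A01C01B01D01", "A02C01B01D01"]
        records = []
        fragments = {}
        for i in range(40):
            pos1 = int(positions[rng.integers(len(positions))])
            pos2 = pos1 + 400
            bx = barcodes[rng.integers(2)]
            qual = int(rng.integers(20, 40))
            name = f"frag{i:02d}"
            records += _pair(sam_header, name, pos1, pos2, bx, qual=qual)
            ends = (("chr1", pos1, False), ("chr1", pos2 + 100, True))
            fragments[name] = (tuple(sorted(ends)), bx, qual * 200)
        records.sort(key=lambda r: (r.reference_start, r.query_name))
        sam = write_sam(tmp_path / "in.sam", records)
        mark_duplicates_bx(sam, tmp_path / "out.sam")
        with pysam.AlignmentFile(str(tmp_path / "out.sam")) as f:
            flagged = {r.query_name for r in f if r.is_duplicate}
        assert flagged == _dup_oracle(fragments)

    def test_soft_clips_do_not_split_duplicates(self, tmp_path, sam_header):
        # same unclipped start, one record soft-clipped at the 5' end
        r1 = make_record(sam_header, "a", "chr1", 1000, bx="A01C01B01D01", vx=1, qual=35)
        r2 = make_record(
            sam_header, "b", "chr1", 1005, bx="A01C01B01D01", vx=1, qual=20,
            cigar=[(4, 5), (0, 95)],
        )
        sam = write_sam(tmp_path / "in.sam", [r1, r2])
        counts = mark_duplicates_bx(sam, tmp_path / "out.sam")
        assert counts.duplicate_fragments == 1
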