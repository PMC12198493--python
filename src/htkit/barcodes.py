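"""Haplotag ACBD barcode model.

Haplotagging encodes a combinatorial bead barcode as four nucleotide
segments (letters A, C, B, D), each mapped through a lookup table to an
integer alias in [1, 99]. The human-readable canonical form is the
12-character string ``AxxCxxBxxDxx`` (zero-padded two-digit values); a
value of ``00`` marks a segment whose nucleotides matched no table entry,
and a barcode is *valid* only when all four segments are nonzero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Tuple

SEGMENT_ORDER: Tuple[str, str, str, str] = ("A", "C", "B", "D")
_BASES = "ACGT"


class BarcodeFormatError(ValueError):
    """A barcode string does not follow the canonical AxxCxxBxxDxx form."""


@dataclass(frozen=True)
class HaplotagBarcode:
    """Four integer segment values, each in [0, 99]; 0 means invalid."""

    a: int
    c: int
    b: int
    d: int

    def __post_init__(self) -> None:
        for letter, value in zip(SEGMENT_ORDER, self.segments):
            if not isinstance(value, int) or not 0 <= value <= 99:
                raise ValueError(
                    f"segment {letter} value {value!r} outside [0, 99]"
                )

    @property
    def segments(self) -> Tuple[int, int, int, int]:
        return (self.a, self.c, self.b, self.d)

    @property
    def valid(self) -> bool:
        return all(v != 0 for v in self.segments)


@dataclass(frozen=True)
class TagPair:
    """A BX:Z barcode string together with its VX:i validity flag."""

    bx: str
    vx: int

    def __post_init__(self) -> None:
        if self.vx not in (0, 1):
            raise ValueError(f"vx must be 0 or 1, got {self.vx}")


def parse_bx(text: str) -> HaplotagBarcode:
    """Parse a canonical 12-character ACBD barcode string.

    Raises :class:`BarcodeFormatError` naming the offending position for
    wrong length, wrong or misordered segment letters, or non-digit
    characters.
    """
    if not isinstance(text, str) or len(text) != 12:
        raise BarcodeFormatError(
            f"barcode {text!r} must be exactly 12 characters, got "
            f"{len(text) if isinstance(text, str) else type(text).__name__}"
        )
    values = []
    for i, letter in enumerate(SEGMENT_ORDER):
        pos = i * 3
        if text[pos] != letter:
            raise BarcodeFormatError(
                f"barcode {text!r}: expected segment letter {letter!r} at "
                f"position {pos}, found {text[pos]!r}"
            )
        digits = text[pos + 1 : pos + 3]
        if not digits.isdigit():
            raise BarcodeFormatError(
                f"barcode {text!r}: non-digit segment value {digits!r} at "
                f"position {pos + 1}"
            )
        values.append(int(digits))
    return HaplotagBarcode(*values)


def format_bx(barcode: HaplotagBarcode) -> str:
    """Render the canonical zero-padded AxxCxxBxxDxx string."""
    return "".join(
        f"{letter}{value:02d}"
        for letter, value in zip(SEGMENT_ORDER, barcode.segments)
    )


def barcode_validity(barcode: HaplotagBarcode) -> int:
    """1 if all four segments are nonzero, else 0 (the VX:i convention)."""
    return 1 if barcode.valid else 0


def tag_pair(barcode: HaplotagBarcode) -> TagPair:
    return TagPair(bx=format_bx(barcode), vx=barcode_validity(barcode))


@dataclass
class SegmentLookup:
    """Nucleotide -> segment-value table for one segment letter.

    Keys are fixed-length uppercase ACGT strings; values are unique
    integers in [1, 99]. The value 0 is reserved as the "no match"
    sentinel and never appears in a table.
    """

    segment_letter: str
    table: Dict[str, int]
    seg_length: int = field(init=False)

    def __post_init__(self) -> None:
        if self.segment_letter not in SEGMENT_ORDER:
            raise ValueError(f"unknown segment letter {self.segment_letter!r}")
        if not self.table:
            raise ValueError(f"empty lookup table for segment {self.segment_letter}")
        lengths = {len(k) for k in self.table}
        if len(lengths) != 1:
            raise ValueError(
                f"segment {self.segment_letter}: keys have mixed lengths {sorted(lengths)}"
            )
        self.seg_length = lengths.pop()
        for key, value in self.table.items():
            if set(key) - set(_BASES):
                raise ValueError(
                    f"segment {self.segment_letter}: key {key!r} has non-ACGT characters"
                )
            if not 1 <= value <= 99:
                raise ValueError(
                    f"segment {self.segment_letter}: value {value} for key {key!r} "
                    "outside [1, 99]"
                )
        values = list(self.table.values())
        if len(set(values)) != len(values):
            raise ValueError(
                f"segment {self.segment_letter}: values are not unique"
            )
        # inverse map, used by the simulator to emit barcode nucleotides
        self.inverse: Dict[int, str] = {v: k for k, v in self.table.items()}


def lookup_segment(nt: str, lookup: SegmentLookup, max_mismatch: int = 1) -> int:
    """Translate a nucleotide segment to its integer alias.

    Exact table hits always win. With ``max_mismatch=1`` an unmatched
    query is rescued when exactly one key lies at Hamming distance 1;
    ambiguity (two or more keys tie) or no near key returns 0, the
    "invalid segment" sentinel. ``N`` never matches any base and counts
    as a mismatch at its position.
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    if len(nt) != lookup.seg_length:
        raise ValueError(
            f"segment query {nt!r} has length {len(nt)}, expected {lookup.seg_length}"
        )
    if set(nt) - set(_BASES + "N"):
        raise ValueError(f"segment query {nt!r} contains non-ACGTN characters")
    hit = lookup.table.get(nt)
    if hit is not None:
        return hit
    if max_mismatch == 0:
        return 0
    best = 0
    n_best = 0
    for key, value in lookup.table.items():
        dist = sum(1 for x, y in zip(nt, key) if x != y)
        if dist == 1:
            best = value
            n_best += 1
            if n_best > 1:
                return 0
    return best if n_best == 1 else 0


def translate_segments(
    segment_nts: Mapping[str, str],
    lookups: Mapping[str, SegmentLookup],
    max_mismatch: int = 1,
) -> HaplotagBarcode:
    """Translate the four nucleotide segments into an ACBD barcode."""
    values = {}
    for letter in SEGMENT_ORDER:
        nt = segment_nts.get(letter)
        if nt is None:
            values[letter] = 0
            continue
        values[letter] = lookup_segment(nt, lookups[letter], max_mismatch)
    return HaplotagBarcode(values["A"], values["C"], values["B"], values["D"])


# ---------------------------------------------------------------------------
# Lookup-table file I/O: two-column TSV `nucleotides<TAB>alias` where alias is
# e.g. C54; one file may hold all four segment letters. `#` starts a comment.
# ---------------------------------------------------------------------------

def load_lookup_tables(path: str | Path) -> Dict[str, SegmentLookup]:
    tables: Dict[str, Dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            nt, alias = parts[0].strip().upper(), parts[1].strip().upper()
            letter, digits = alias[:1], alias[1:]
            if letter not in SEGMENT_ORDER or not digits.isdigit():
                raise ValueError(f"{path}:{lineno}: malformed alias {alias!r}")
            value = int(digits)
            tbl = tables.setdefault(letter, {})
            if nt in tbl:
                raise ValueError(f"{path}:{lineno}: duplicate nucleotide key {nt!r}")
            tbl[nt] = value
    return {
        letter: SegmentLookup(segment_letter=letter, table=tbl)
        for letter, tbl in tables.items()
    }


def write_lookup_tables(lookups: Mapping[str, SegmentLookup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# nucleotides\talias\n")
        for letter in SEGMENT_ORDER:
            if letter not in lookups:
                continue
            lk = lookups[letter]
            for value in sorted(lk.inverse):
                fh.write(f"{lk.inverse[value]}\t{letter}{value:02d}\n")


# ---------------------------------------------------------------------------
# Default codewords: 6-nt segments, 64 values per letter, built as the
# lexicographic greedy code with minimum pairwise Hamming distance 4 (64 is
# the Singleton-bound maximum for a length-6 quaternary code at d=4). At
# distance 4 every single-base error is uniquely correctable and a two-error
# segment can never be mis-rescued into a different value.
# ---------------------------------------------------------------------------

def _hamming(x: str, y: str) -> int:
    return sum(1 for a, b in zip(x, y) if a != b)


def _lexicode(length: int, min_distance: int) -> list[str]:
    chosen: list[str] = []
    for i in range(4 ** length):
        w = "".join(_BASES[(i >> (2 * p)) & 3] for p in range(length))
        if all(_hamming(w, c) >= min_distance for c in chosen):
            chosen.append(w)
    return chosen


_DEFAULT_CODE_CACHE: Dict[Tuple[int, int], list] = {}


def default_lookup_tables(
    values_per_segment: int = 64, seg_length: int = 6
) -> Dict[str, SegmentLookup]:
    """Deterministic built-in lookup tables for all four segment letters.

    All four letters share the same codeword set (as real haplotagging bead
    segments do); the integer alias is the codeword's rank in the code.
    """
    key = (seg_length, 4)
    if key not in _DEFAULT_CODE_CACHE:
        _DEFAULT_CODE_CACHE[key] = _lexicode(seg_length, 4)
    words = _DEFAULT_CODE_CACHE[key]
    if values_per_segment > len(words):
        raise ValueError(
            f"only {len(words)} distance-4 codewords exist at length {seg_length}; "
            f"requested {values_per_segment}"
        )
    table = {w: v for v, w in enumerate(words[:values_per_segment], start=1)}
    return {
        letter: SegmentLookup(segment_letter=letter, table=dict(table))
        for letter in SEGMENT_ORDER
    }
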