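"""Read layout: where the inline barcode segments sit in the raw reads.

Haplotagging library designs differ in barcode placement, so the layout is
fully configurable: each segment letter names a source read (R1, R2, I1,
I2), a 0-based offset, and a length. The shipped default places the four
6-nt segments contiguously at the 5' start of R2 in A, C, B, D order, and
trims them (with their quality values) from the stored sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

from .barcodes import SEGMENT_ORDER

SOURCES = ("R1", "R2", "I1", "I2")


@dataclass(frozen=True)
class SegmentPlacement:
    source: str
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"segment source must be one of {SOURCES}, got {self.source!r}")
        if self.offset < 0 or self.length < 1:
            raise ValueError(f"invalid placement offset={self.offset} length={self.length}")

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass
class ReadLayout:
    segments: Dict[str, SegmentPlacement]
    trim: bool = True

    def __post_init__(self) -> None:
        missing = [l for l in SEGMENT_ORDER if l not in self.segments]
        if missing:
            raise ValueError(f"layout missing segment letters: {missing}")
        # segments sharing a source read must not overlap
        by_source: Dict[str, list] = {}
        for letter, seg in self.segments.items():
            by_source.setdefault(seg.source, []).append((seg.offset, seg.end, letter))
        for source, spans in by_source.items():
            spans.sort()
            for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"segments {l1} and {l2} overlap on {source}: "
                        f"[{s1},{e1}) vs [{s2},{e2})"
                    )

    def trim_spans(self, source: str) -> Tuple[Tuple[int, int], ...]:
        """Merged, sorted (start, end) spans to cut from a given read."""
        spans = sorted(
            (seg.offset, seg.end)
            for seg in self.segments.values()
            if seg.source == source
        )
        merged: list[Tuple[int, int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return tuple(merged)

    def uses_index_reads(self) -> bool:
        return any(seg.source in ("I1", "I2") for seg in self.segments.values())


def default_layout(seg_length: int = 6) -> ReadLayout:
    """A, C, B, D contiguous at the 5' start of R2; trimmed after extraction."""
    segments = {
        letter: SegmentPlacement(source="R2", offset=i * seg_length, length=seg_length)
        for i, letter in enumerate(SEGMENT_ORDER)
    }
    return ReadLayout(segments=segments, trim=True)


def load_layout(path: str | Path) -> ReadLayout:
    """Load a layout from JSON: {"trim": bool, "segments": {"A": {...}, ...}}."""
    with open(path) as fh:
        doc = json.load(fh)
    segments = {
        letter: SegmentPlacement(
            source=spec["source"], offset=int(spec["offset"]), length=int(spec["length"])
        )
        for letter, spec in doc["segments"].items()
    }
    return ReadLayout(segments=segments, trim=bool(doc.get("trim", True)))


def save_layout(layout: ReadLayout, path: str | Path) -> None:
    doc = {
        "trim": layout.trim,
        "segments": {
            letter: {"source": seg.source, "offset": seg.offset, "length": seg.length}
            for letter, seg in layout.segments.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
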