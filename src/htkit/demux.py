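"""Demultiplex raw haplotagging paired-end FASTQ into per-sample tagged FASTQ.

For each read pair the inline barcode nucleotides are extracted according
to the read layout, translated to the ACBD integer alias through the
segment lookup tables, stripped from the stored sequence (and quality),
and recorded in the header comment as SAM-style ``BX:Z:`` and ``VX:i:``
tags. Pairs are routed to per-sample output files by the schema's
identifying segment; pairs whose identifying segment failed to translate,
or is not in the schema, go to an ``unassigned`` output — never dropped,
so input pairs always equal assigned plus unassigned pairs.
"""

from __future__ import annotations

import json
from contextlib import ExitStack
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import pysam

from .barcodes import (
    SEGMENT_ORDER,
    SegmentLookup,
    barcode_validity,
    format_bx,
    translate_segments,
)
from .layout import ReadLayout
from .schema import SampleSchema
from ._io import xopen_write

UNASSIGNED = "unassigned"


@dataclass
class DemuxSummary:
    total_pairs: int = 0
    per_sample_pairs: Dict[str, int] = field(default_factory=dict)
    unassigned_pairs: int = 0
    invalid_barcode_pairs: int = 0
    per_segment_invalid: Dict[str, int] = field(
        default_factory=lambda: {l: 0 for l in SEGMENT_ORDER}
    )

    def validate(self) -> None:
        assert self.total_pairs == sum(self.per_sample_pairs.values()) + self.unassigned_pairs
        assert self.invalid_barcode_pairs <= self.total_pairs

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [
            f"total pairs:            {self.total_pairs}",
            f"unassigned pairs:       {self.unassigned_pairs}",
            f"invalid-barcode pairs:  {self.invalid_barcode_pairs}",
            "invalid segments:       "
            + " ".join(f"{l}={n}" for l, n in sorted(self.per_segment_invalid.items())),
            "pairs per sample:",
        ]
        for sample in sorted(self.per_sample_pairs):
            lines.append(f"  {sample}\t{self.per_sample_pairs[sample]}")
        return "\n".join(lines) + "\n"


class DesynchronizedStreams(RuntimeError):
    """Paired input streams disagree on the read identifier at some record."""


def _base_id(name: str) -> str:
    # strip a trailing /1 or /2 mate suffix for identifier comparison
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def _cut_spans(seq: str, spans) -> str:
    if not spans:
        return seq
    kept = []
    prev = 0
    for s, e in spans:
        kept.append(seq[prev:s])
        prev = e
    kept.append(seq[prev:])
    return "".join(kept)


def _write_record(fh, name: str, comment: str, seq: str, qual: str) -> None:
    header = f"@{name} {comment}" if comment else f"@{name}"
    fh.write(f"{header}\n{seq}\n+\n{qual}\n")


def demultiplex(
    r1: str | Path,
    r2: str | Path,
    layout: ReadLayout,
    lookups: Mapping[str, SegmentLookup],
    schema: SampleSchema,
    outdir: str | Path,
    i1: Optional[str | Path] = None,
    i2: Optional[str | Path] = None,
    max_mismatch: int = 1,
) -> DemuxSummary:
    """Split a pooled haplotagging run into per-sample, barcode-tagged FASTQ.

    Returns a :class:`DemuxSummary`; per-sample files are written under
    ``outdir`` as ``<sample>.R1.fq.gz`` / ``<sample>.R2.fq.gz`` along with
    the ``unassigned`` pair and ``demux_summary.json`` / ``.txt``.
    """
    missing = [l for l in SEGMENT_ORDER if l not in lookups]
    if missing:
        raise ValueError(f"lookup tables missing for segment letters: {missing}")
    if layout.uses_index_reads() and (i1 is None and i2 is None):
        raise ValueError("layout uses index reads but no index FASTQ was provided")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise ValueError(f"output directory {outdir} is not writable: {exc}") from exc

    summary = DemuxSummary()
    summary.per_sample_pairs = {s: 0 for s in schema.samples}
    sources: Dict[str, Optional[Path]] = {
        "R1": Path(r1),
        "R2": Path(r2),
        "I1": Path(i1) if i1 else None,
        "I2": Path(i2) if i2 else None,
    }

    with ExitStack() as stack:
        streams = {
            key: stack.enter_context(pysam.FastxFile(str(path)))
            for key, path in sources.items()
            if path is not None
        }
        iterators = {key: iter(fx) for key, fx in streams.items()}
        writers: Dict[str, tuple] = {}

        def get_writer(sample: str):
            if sample not in writers:
                w1 = stack.enter_context(xopen_write(outdir / f"{sample}.R1.fq.gz"))
                w2 = stack.enter_context(xopen_write(outdir / f"{sample}.R2.fq.gz"))
                writers[sample] = (w1, w2)
            return writers[sample]

        # open outputs for every schema sample plus unassigned up front so
        # byte-identical runs produce identical file sets
        for sample in schema.samples + [UNASSIGNED]:
            get_writer(sample)

        pair_index = 0
        while True:
            records = {}
            exhausted = []
            for key, it in iterators.items():
                rec = next(it, None)
                if rec is None:
                    exhausted.append(key)
                records[key] = rec
            if exhausted:
                if len(exhausted) != len(iterators):
                    raise DesynchronizedStreams(
                        f"streams {exhausted} ended at record {pair_index} while others continue"
                    )
                break
            names = {key: _base_id(rec.name) for key, rec in records.items()}
            if len(set(names.values())) != 1:
                raise DesynchronizedStreams(
                    f"record {pair_index}: read identifiers disagree: {names}"
                )
            for key in ("R1", "R2"):
                comment = records[key].comment or ""
                if "BX:Z:" in comment or "VX:i:" in comment:
                    raise ValueError(
                        f"record {pair_index} ({records[key].name}) already carries "
                        "BX/VX tags; refusing to double-tag"
                    )

            # extract nucleotide segments; a read too short for its placement
            # yields an untranslatable (value 0) segment, not an error
            segment_nts: Dict[str, str] = {}
            for letter, seg in layout.segments.items():
                rec = records.get(seg.source)
                if rec is None or len(rec.sequence) < seg.end:
                    continue
                segment_nts[letter] = rec.sequence[seg.offset : seg.end].upper()

            barcode = translate_segments(segment_nts, lookups, max_mismatch=max_mismatch)
            vx = barcode_validity(barcode)
            bx = format_bx(barcode)
            for letter, value in zip(SEGMENT_ORDER, barcode.segments):
                if value == 0:
                    summary.per_segment_invalid[letter] += 1
            if vx == 0:
                summary.invalid_barcode_pairs += 1

            id_value = getattr(barcode, schema.id_segment.lower())
            sample = schema.sample_for(id_value) if id_value != 0 else None
            if sample is None:
                summary.unassigned_pairs += 1
                dest = UNASSIGNED
            else:
                summary.per_sample_pairs[sample] = summary.per_sample_pairs.get(sample, 0) + 1
                dest = sample

            w1, w2 = get_writer(dest)
            for key, writer in (("R1", w1), ("R2", w2)):
                rec = records[key]
                seq, qual = rec.sequence, rec.quality
                if layout.trim:
                    spans = layout.trim_spans(key)
                    spans = tuple((s, e) for s, e in spans if e <= len(seq))
                    seq = _cut_spans(seq, spans)
                    qual = _cut_spans(qual, spans)
                comment = rec.comment or ""
                tagged = f"{comment} BX:Z:{bx} VX:i:{vx}".strip()
                _write_record(writer, rec.name, tagged, seq, qual)

            summary.total_pairs += 1
            pair_index += 1

    summary.validate()
    (outdir / "demux_summary.json").write_text(summary.to_json())
    (outdir / "demux_summary.txt").write_text(summary.to_text())
    return summary
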