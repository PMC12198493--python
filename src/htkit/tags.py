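"""Move barcode information between FASTQ header comments and SAM tags.

Aligners differ in how (or whether) they carry the FASTQ header comment
into the alignment record. Two cases are detected per record:

* the aligner copied the comment through as real SAM tags (bwa mem ``-C``
  style) — the record already carries ``BX:Z``, possibly without ``VX:i``;
* the raw comment text was stashed in a ``CO:Z`` tag — the ``BX:Z:`` /
  ``VX:i:`` fields are parsed out of it and promoted to real tags.

Records with neither are passed through untouched and counted. A record
whose existing BX conflicts with its comment-derived BX aborts, since that
signals upstream data corruption.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pysam

from .barcodes import BarcodeFormatError, TagPair, parse_bx, barcode_validity

_BX_RE = re.compile(r"BX:Z:(\S+)")
_VX_RE = re.compile(r"VX:i:([01])")
_NUC_RE = re.compile(r"^[ACGT]+$")


@dataclass
class TransferCounts:
    total: int = 0
    tagged: int = 0
    untagged: int = 0


def _comment_tags(record: pysam.AlignedSegment) -> tuple[str | None, int | None]:
    if not record.has_tag("CO"):
        return None, None
    comment = str(record.get_tag("CO"))
    bx = _BX_RE.search(comment)
    vx = _VX_RE.search(comment)
    return (bx.group(1) if bx else None), (int(vx.group(1)) if vx else None)


def _derive_vx(bx: str) -> int | None:
    """VX from the barcode itself when it parses as a haplotag barcode."""
    try:
        return barcode_validity(parse_bx(bx))
    except BarcodeFormatError:
        return None


def transfer_record(record: pysam.AlignedSegment) -> bool:
    """Promote comment-held BX/VX into SAM tags on one record, in place.

    Returns True when the record ends up carrying a BX tag.
    """
    comment_bx, comment_vx = _comment_tags(record)
    existing_bx = str(record.get_tag("BX")) if record.has_tag("BX") else None
    if existing_bx is not None and comment_bx is not None and existing_bx != comment_bx:
        raise ValueError(
            f"record {record.query_name!r}: BX tag {existing_bx!r} conflicts with "
            f"comment barcode {comment_bx!r}"
        )
    bx = existing_bx or comment_bx
    if bx is None:
        return False
    if existing_bx is None:
        record.set_tag("BX", bx, value_type="Z")
    if not record.has_tag("VX"):
        vx = comment_vx if comment_vx is not None else _derive_vx(bx)
        if vx is not None:
            record.set_tag("VX", vx, value_type="i")
    return True


def fastq_tags_to_bam(bam_in: str | Path, bam_out: str | Path) -> TransferCounts:
    """Rewrite an alignment file promoting comment-held barcodes to tags.

    Input need not be sorted; record count and order are preserved.
    """
    counts = TransferCounts()
    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        mode = "wb" if str(bam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(bam_out), mode, template=src) as dst:
            for record in src:
                counts.total += 1
                if transfer_record(record):
                    counts.tagged += 1
                else:
                    counts.untagged += 1
                dst.write(record)
    return counts


def standardize_barcode(raw: str, style: str = "haplotag") -> TagPair:
    """Normalize a technology-specific barcode into the BX + VX convention.

    * ``haplotag``: canonical AxxCxxBxxDxx; VX=1 iff all segments nonzero.
    * ``nucleotide``: VX=0 iff any non-ACGT character (N etc.), else 1.
    * ``generic``: barcode taken verbatim, VX=1 always.
    """
    if not raw:
        raise ValueError("barcode string is empty")
    if style == "haplotag":
        barcode = parse_bx(raw)
        from .barcodes import format_bx

        return TagPair(bx=format_bx(barcode), vx=barcode_validity(barcode))
    if style == "nucleotide":
        return TagPair(bx=raw, vx=1 if _NUC_RE.match(raw) else 0)
    if style == "generic":
        return TagPair(bx=raw, vx=1)
    raise ValueError(f"unknown barcode style {style!r}")


def standardize_bam(bam_in: str | Path, bam_out: str | Path, style: str) -> TransferCounts:
    """Rewrite BX tags of an alignment file into the standardized BX+VX form."""
    counts = TransferCounts()
    with pysam.AlignmentFile(str(bam_in), check_sq=False) as src:
        mode = "wb" if str(bam_out).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(bam_out), mode, template=src) as dst:
            for record in src:
                counts.total += 1
                if record.has_tag("BX"):
                    pair = standardize_barcode(str(record.get_tag("BX")), style)
                    record.set_tag("BX", pair.bx, value_type="Z")
                    record.set_tag("VX", pair.vx, value_type="i")
                    counts.tagged += 1
                else:
                    counts.untagged += 1
                dst.write(record)
    return counts
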