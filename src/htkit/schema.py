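"""Sample-barcode schema: which barcode segment value identifies which sample.

Demultiplexing splits pooled reads by a single *identifying* segment letter
(commonly C in haplotagging designs): the schema maps values of that segment
to sample names. TSV format: ``sample<TAB>alias`` with alias like ``C54``;
``#`` starts a comment line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

from .barcodes import SEGMENT_ORDER

_SAFE_NAME = re.compile(r"^[A-Za-z0-9._-]+$")


@dataclass
class SampleSchema:
    id_segment: str
    assignments: Dict[int, str]  # segment value -> sample name

    def __post_init__(self) -> None:
        if self.id_segment not in SEGMENT_ORDER:
            raise ValueError(f"unknown id segment letter {self.id_segment!r}")
        if not self.assignments:
            raise ValueError("schema has no sample assignments")
        for value, name in self.assignments.items():
            if not 1 <= value <= 99:
                raise ValueError(f"segment value {value} outside [1, 99]")
            if not name or not _SAFE_NAME.match(name):
                raise ValueError(f"sample name {name!r} is empty or not filesystem-safe")

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def sample_for(self, value: int) -> str | None:
        return self.assignments.get(value)


def load_schema(path: str | Path) -> SampleSchema:
    """Load and validate a sample<TAB>alias TSV.

    Aborts (ValueError naming the row) on mixed segment letters, duplicate
    aliases, malformed rows, or an empty file.
    """
    assignments: Dict[int, str] = {}
    letter: str | None = None
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
            sample, alias = parts[0].strip(), parts[1].strip().upper()
            this_letter, digits = alias[:1], alias[1:]
            if this_letter not in SEGMENT_ORDER or not digits.isdigit():
                raise ValueError(f"{path}:{lineno}: malformed segment alias {alias!r}")
            if letter is None:
                letter = this_letter
            elif this_letter != letter:
                raise ValueError(
                    f"{path}:{lineno}: mixed segment letters ({this_letter!r} after "
                    f"{letter!r}); all schema rows must use one letter"
                )
            value = int(digits)
            if value in assignments:
                raise ValueError(
                    f"{path}:{lineno}: duplicate alias {alias!r} "
                    f"(already assigned to {assignments[value]!r})"
                )
            assignments[value] = sample
    if letter is None:
        raise ValueError(f"{path}: schema file is empty")
    return SampleSchema(id_segment=letter, assignments=assignments)


def write_schema(schema: SampleSchema, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\talias\n")
        for value in sorted(schema.assignments):
            fh.write(f"{schema.assignments[value]}\t{schema.id_segment}{value:02d}\n")
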