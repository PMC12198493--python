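"""Small I/O helpers shared across modules."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import IO


def xopen_write(path: str | Path, compresslevel: int = 4) -> IO[str]:
    """Open text output, gzip-compressed when the path ends in .gz.

    The gzip header is written with mtime=0 and no filename so identical
    content produces byte-identical files (seed determinism contract).
    """
    path = Path(path)
    if path.suffix == ".gz":
        raw = open(path, "wb")
        gz = gzip.GzipFile(
            filename="", mode="wb", fileobj=raw, compresslevel=compresslevel, mtime=0
        )
        return io.TextIOWrapper(gz, encoding="ascii", newline="\n")
    return open(path, "w", encoding="ascii", newline="\n")


def xopen_read(path: str | Path) -> IO[str]:
    """Open text input, transparently decompressing gzip (magic-sniffed)."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, encoding="ascii")
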