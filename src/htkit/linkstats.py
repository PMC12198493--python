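"""Linked-read QC statistics and a minimal self-contained HTML report.

The metric set is the linked-read QC canon that molecule deconvolution
makes computable: molecule span N50, reads per molecule, molecules per
barcode, valid-barcode fraction and singleton-molecule fraction. N50 is
the span S such that molecules with span >= S account for at least half
of the total summed span.
"""

from __future__ import annotations

import json
import math
import re
import statistics
from dataclasses import dataclass, field, asdict
from pathlib import Path
from string import Template
from typing import Dict, Iterable, List, Optional, Sequence

import pysam

from .deconvolve import MoleculeInterval, _is_eligible, _record_vx


@dataclass
class DistributionSummary:
    mean: Optional[float] = None
    median: Optional[float] = None
    max: Optional[float] = None
    n50: Optional[float] = None  # only populated for span distributions

    @staticmethod
    def from_values(values: Sequence[float], with_n50: bool = False) -> "DistributionSummary":
        if not values:
            return DistributionSummary()
        out = DistributionSummary(
            mean=round(float(statistics.fmean(values)), 4),
            median=float(statistics.median(values)),
            max=float(max(values)),
        )
        if with_n50:
            out.n50 = float(span_n50(values))
        return out


def span_n50(spans: Sequence[float]) -> float:
    """Smallest span S with molecules of span >= S covering >= half the total."""
    if not spans:
        raise ValueError("N50 of an empty span set is undefined")
    total = sum(spans)
    acc = 0.0
    for s in sorted(spans, reverse=True):
        acc += s
        if acc * 2 >= total:
            return s
    return min(spans)  # pragma: no cover - loop always terminates above


@dataclass
class AlignmentTallies:
    total_records: int = 0
    mapped_primary: int = 0
    bx_tagged: int = 0
    vx_valid: int = 0


def tally_alignments(bam: str | Path) -> AlignmentTallies:
    t = AlignmentTallies()
    with pysam.AlignmentFile(str(bam), check_sq=False) as src:
        for record in src:
            t.total_records += 1
            if _is_eligible(record):
                t.mapped_primary += 1
            if record.has_tag("BX"):
                t.bx_tagged += 1
                if _record_vx(record) == 1:
                    t.vx_valid += 1
    return t


@dataclass
class LinkedReadStats:
    total_records: int = 0
    mapped_primary: int = 0
    bx_tagged: int = 0
    valid_bx_fraction: Optional[float] = None
    n_barcodes: int = 0
    n_molecules: int = 0
    reads_per_molecule: DistributionSummary = field(default_factory=DistributionSummary)
    molecules_per_barcode: DistributionSummary = field(default_factory=DistributionSummary)
    molecule_span: DistributionSummary = field(default_factory=DistributionSummary)
    singleton_molecule_fraction: Optional[float] = None

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def compute_stats(
    molecules: Sequence[MoleculeInterval],
    tallies: AlignmentTallies | None = None,
) -> LinkedReadStats:
    """Summarize a deconvolved molecule set (optionally with record tallies).

    An empty molecule list yields zero counts with distribution fields left
    undefined (None), not an error.
    """
    tallies = tallies or AlignmentTallies()
    stats = LinkedReadStats(
        total_records=tallies.total_records,
        mapped_primary=tallies.mapped_primary,
        bx_tagged=tallies.bx_tagged,
    )
    if tallies.bx_tagged:
        stats.valid_bx_fraction = round(tallies.vx_valid / tallies.bx_tagged, 6)
    if not molecules:
        return stats

    per_barcode: Dict[str, int] = {}
    for m in molecules:
        per_barcode[m.bx] = per_barcode.get(m.bx, 0) + 1
    stats.n_barcodes = len(per_barcode)
    stats.n_molecules = len(molecules)
    stats.reads_per_molecule = DistributionSummary.from_values([m.n_reads for m in molecules])
    stats.molecules_per_barcode = DistributionSummary.from_values(list(per_barcode.values()))
    stats.molecule_span = DistributionSummary.from_values(
        [m.span for m in molecules], with_n50=True
    )
    stats.singleton_molecule_fraction = round(
        sum(1 for m in molecules if m.n_reads == 1) / len(molecules), 6
    )
    return stats


_REPORT_TEMPLATE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Linked-read QC report</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #999; padding: 0.3em 0.8em; text-align: left; }
th { background: #eee; }
.nodata { color: #a00; font-style: italic; }
</style>
</head>
<body>
<h1>Linked-read QC report</h1>
$body
<h2>Machine-readable summary</h2>
<script type="application/json" id="stats-json">$stats_json</script>
</body>
</html>
"""
)


def _fmt(value) -> str:
    # table cells use the JSON rendering so HTML and JSON agree bit-for-bit
    if value is None:
        return '<span class="nodata">no data</span>'
    return json.dumps(value)


def render_report(stats: LinkedReadStats, out: str | Path) -> None:
    """Write a single self-contained HTML report.

    Every number shown in the tables is rendered from the same dict that is
    embedded verbatim as JSON, so the HTML and the JSON summary always agree.
    """
    d = stats.to_dict()
    rows = []
    scalar_keys = [
        "total_records",
        "mapped_primary",
        "bx_tagged",
        "valid_bx_fraction",
        "n_barcodes",
        "n_molecules",
        "singleton_molecule_fraction",
    ]
    for key in scalar_keys:
        rows.append(f"<tr><td>{key}</td><td>{_fmt(d[key])}</td></tr>")
    scalar_table = (
        "<h2>Summary</h2>\n<table><tr><th>metric</th><th>value</th></tr>\n"
        + "\n".join(rows)
        + "\n</table>"
    )
    dist_rows = []
    for key in ("reads_per_molecule", "molecules_per_barcode", "molecule_span"):
        ds = d[key]
        dist_rows.append(
            f"<tr><td>{key}</td><td>{_fmt(ds['mean'])}</td><td>{_fmt(ds['median'])}</td>"
            f"<td>{_fmt(ds['max'])}</td><td>{_fmt(ds['n50'])}</td></tr>"
        )
    dist_table = (
        "<h2>Distributions</h2>\n"
        "<table><tr><th>distribution</th><th>mean</th><th>median</th><th>max</th><th>N50</th></tr>\n"
        + "\n".join(dist_rows)
        + "\n</table>"
    )
    if d["n_molecules"] == 0:
        banner = '<p class="nodata">No molecules: distribution metrics undefined (no data).</p>'
    else:
        banner = ""
    html = _REPORT_TEMPLATE.substitute(
        body=banner + scalar_table + "\n" + dist_table,
        stats_json=json.dumps(d, sort_keys=True),
    )
    Path(out).write_text(html)


def stats_from_report(path: str | Path) -> Dict:
    """Parse the embedded JSON summary back out of a rendered report."""
    html = Path(path).read_text()
    m = re.search(
        r'<script type="application/json" id="stats-json">(.*?)</script>', html, re.S
    )
    if not m:
        raise ValueError(f"{path}: no embedded stats JSON found")
    return json.loads(m.group(1))
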