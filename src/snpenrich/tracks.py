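"""Epigenomic annotation tracks: BED parsing and point-overlap semantics.

A biosample is one cell type or tissue assayed for one mark (DNase I hotspot,
histone broadPeak, or a chromatin-state segment class) by one consortium; its
annotation is a set of genomic intervals in BED convention (0-based,
half-open).  A SNP overlaps a track iff its single base position falls inside
some interval.  Chromosome names are matched literally: "chr1" and "1" are
distinct unless the caller strips the prefix at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .errors import InputFormatError

log = logging.getLogger(__name__)

Interval = Tuple[str, int, int]

MANIFEST_COLUMNS = ["sample_id", "tissue", "cell_type", "mark", "consortium", "bed_path"]


@dataclass
class TrackSample:
    """One biosample's annotation intervals plus its metadata labels."""

    sample_id: str
    tissue: str
    cell_type: str
    mark: str
    consortium: str
    intervals: List[Interval] = field(default_factory=list)


def parse_bed(path, strip_chr_prefix: bool = False) -> List[Interval]:
    """Parse a BED3+ file into (chrom, start, end) tuples.

    Track/browser header lines and ``#`` comments are skipped.  Overlapping or
    adjacent intervals are kept as-is (point-membership tests are unaffected
    by merging).  Empty intervals (start >= end) and non-integer coordinates
    are hard errors naming the line.
    """
    intervals: List[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer coordinates {parts[1]!r}, {parts[2]!r}"
                ) from exc
            if start >= end:
                raise InputFormatError(
                    f"{path}:{lineno}: empty interval ({start} >= {end})"
                )
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            intervals.append((chrom, start, end))
    return intervals


def snp_overlaps(pos: Tuple[str, int], intervals: Sequence[Interval]) -> bool:
    """True iff the 1-bp point (chrom, position) lies inside some interval.

    Membership is 0-based half-open: interval (c, s, e) contains position p on
    chromosome c iff s <= p < e.
    """
    chrom, p = pos
    return any(c == chrom and s <= p < e for c, s, e in intervals)


def load_manifest(path, strip_chr_prefix: bool = False) -> List[TrackSample]:
    """Load a samples manifest TSV and every BED file it references.

    Columns: ``sample_id tissue cell_type mark consortium bed_path``; relative
    BED paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputFormatError(f"missing manifest columns: {missing}")
    samples: List[TrackSample] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        bed = Path(row.bed_path)
        if not bed.is_absolute():
            bed = path.parent / bed
        if not bed.exists():
            raise InputFormatError(f"manifest row {i} ({row.sample_id}): "
                                   f"BED file not found: {bed}")
        samples.append(TrackSample(
            sample_id=str(row.sample_id), tissue=str(row.tissue),
            cell_type=str(row.cell_type), mark=str(row.mark),
            consortium=str(row.consortium),
            intervals=parse_bed(bed, strip_chr_prefix=strip_chr_prefix),
        ))
    return samples


def write_manifest(samples: List[TrackSample], bed_paths: Dict[str, str], path) -> None:
    """Write a samples manifest TSV referencing already-written BED files."""
    rows = [{"sample_id": s.sample_id, "tissue": s.tissue, "cell_type": s.cell_type,
             "mark": s.mark, "consortium": s.consortium,
             "bed_path": bed_paths[s.sample_id]} for s in samples]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)
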