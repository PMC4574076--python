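"""Stranded 5' read positions: BED6 ingest, deduplication, window counting.

A sequencing read is reduced to the genomic position of its 5' end (BED start
for + strand, BED end - 1 for - strand). Duplicate reads — identical
(chromosome, strand, position) — are collapsed to one representative, so a
window of width N can hold at most 2N reads: one per strand per base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import ChromSizes, WindowGrid, WindowVector

logger = logging.getLogger(__name__)


@dataclass
class ReadSet:
    """Per-chromosome arrays of 5' positions and strands (0 = '+', 1 = '-')."""

    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)
    dedup_applied: bool = False

    def __post_init__(self) -> None:
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in self.positions.items()}
        self.strands = {c: np.asarray(s, dtype=np.int8) for c, s in self.strands.items()}

    @property
    def n_reads(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def chroms(self) -> list[str]:
        return list(self.positions)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, str]], dedup_applied: bool = False
    ) -> "ReadSet":
        """Build from (chrom, 5'-position, strand) triples."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, strand in records:
            by_chrom.setdefault(chrom, []).append((pos, 0 if strand == "+" else 1))
        positions, strands = {}, {}
        for chrom, items in by_chrom.items():
            arr = np.array(items, dtype=np.int64).reshape(-1, 2)
            positions[chrom] = arr[:, 0]
            strands[chrom] = arr[:, 1].astype(np.int8)
        return cls(positions, strands, dedup_applied=dedup_applied)

    def iter_records(self):
        for chrom in self.positions:
            for pos, s in zip(self.positions[chrom], self.strands[chrom]):
                yield chrom, int(pos), "+" if s == 0 else "-"


def read_bed_reads(path: str | Path, sizes: ChromSizes) -> ReadSet:
    """Parse a BED6 file of mapped reads into a :class:`ReadSet`.

    The 5' position is the BED start for '+' reads and BED end - 1 for '-'
    reads. Reads on chromosomes absent from ``sizes``, or with a 5' position
    at or beyond the chromosome end, are dropped (with a logged count).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    dropped_chrom = dropped_bounds = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns, got {len(parts)}")
            chrom, start_s, end_s, _name, _score, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            if chrom not in sizes:
                dropped_chrom += 1
                continue
            pos = start if strand == "+" else end - 1
            if pos < 0 or pos >= sizes[chrom]:
                dropped_bounds += 1
                continue
            by_chrom.setdefault(chrom, []).append((pos, 0 if strand == "+" else 1))
    if dropped_chrom:
        logger.info("%s: dropped %d reads on chromosomes absent from sizes", path, dropped_chrom)
    if dropped_bounds:
        logger.info("%s: rejected %d reads outside chromosome bounds", path, dropped_bounds)
    positions, strands = {}, {}
    for chrom, items in by_chrom.items():
        arr = np.array(items, dtype=np.int64)
        positions[chrom] = arr[:, 0]
        strands[chrom] = arr[:, 1].astype(np.int8)
    return ReadSet(positions, strands, dedup_applied=False)


def write_bed_reads(reads: ReadSet, path: str | Path, read_length: int = 36) -> None:
    """Write reads back out as BED6; the 5' convention round-trips."""
    with open(path, "w") as fh:
        i = 0
        for chrom in reads.positions:
            for pos, s in zip(reads.positions[chrom], reads.strands[chrom]):
                if s == 0:
                    start, end, strand = int(pos), int(pos) + read_length, "+"
                else:
                    start, end, strand = max(0, int(pos) - read_length + 1), int(pos) + 1, "-"
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")
                i += 1


def deduplicate(reads: ReadSet) -> ReadSet:
    """Collapse reads sharing (chromosome, strand, position) to one read."""
    positions, strands = {}, {}
    n_before = n_after = 0
    for chrom in reads.positions:
        pos, strand = reads.positions[chrom], reads.strands[chrom]
        n_before += len(pos)
        key = np.stack([pos, strand.astype(np.int64)], axis=1)
        uniq = np.unique(key, axis=0)
        positions[chrom] = uniq[:, 0]
        strands[chrom] = uniq[:, 1].astype(np.int8)
        n_after += len(uniq)
    if n_before != n_after:
        logger.info("deduplicate: %d reads -> %d unique", n_before, n_after)
    return ReadSet(positions, strands, dedup_applied=True)


def count_reads(reads: ReadSet, grid: WindowGrid) -> WindowVector:
    """Tabulate reads per window by 5' position.

    Reads in the dropped trailing remainder of a chromosome (or on
    chromosomes outside the grid) are ignored.
    """
    if not reads.dedup_applied:
        logger.warning("count_reads: read set has not been deduplicated")
    values = np.zeros(grid.n_total, dtype=float)
    offsets = grid.offsets
    for chrom, n in zip(grid.chroms, grid.n_windows):
        if n == 0 or chrom not in reads.positions:
            continue
        pos = reads.positions[chrom]
        win = pos // grid.width
        ok = (pos >= 0) & (win < n)
        counts = np.bincount(win[ok].astype(np.int64), minlength=n)
        values[offsets[chrom] : offsets[chrom] + n] = counts
    return WindowVector(values, grid, kind="read_count")


def count_in_intervals(
    reads: ReadSet, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Count 5' positions inside arbitrary half-open intervals.

    Intervals may overlap; each is counted independently, so one read can
    contribute to several intervals.
    """
    for i, (_, start, end) in enumerate(intervals):
        if start >= end:
            raise ValueError(f"interval {i}: start {start} >= end {end}")
    sorted_pos = {c: np.sort(p) for c, p in reads.positions.items()}
    out = np.zeros(len(intervals), dtype=float)
    for i, (chrom, start, end) in enumerate(intervals):
        pos = sorted_pos.get(chrom)
        if pos is None:
            continue
        out[i] = np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left")
    return out
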