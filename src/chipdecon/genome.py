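"""Genome plumbing: chromosome sizes, per-base binary tracks, window grids.

ChIP-seq bias decomposition works on fixed-width genomic windows. This module
holds the per-base 0/1 tracks (mappability, GC) and the tiling of chromosomes
into consecutive, non-overlapping, equal-width windows. Coordinates are
0-based, half-open (BED convention) throughout the package.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Chromosomes dropped from every analysis unless the caller overrides.
#: chrY is excluded because read sets differ in whether they carry it.
DEFAULT_EXCLUDE = ("chrY",)


class ChromSizes(Mapping[str, int]):
    """Ordered mapping of chromosome name to length in bp."""

    def __init__(self, sizes: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(sizes)
        for name, length in items.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._sizes: dict[str, int] = {str(k): int(v) for k, v in items.items()}

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    @classmethod
    def from_file(cls, path: str | Path) -> "ChromSizes":
        """Read a two-column ``chrom.sizes`` text file (name, length)."""
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length'")
                sizes[parts[0]] = int(parts[1])
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")


@dataclass
class BinaryTrack:
    """Per-base 0/1 signal over a set of chromosomes.

    ``label`` states the semantics: ``"mappability"`` (1 = uniquely mappable)
    or ``"gc"`` (1 = G or C at that base).
    """

    data: dict[str, np.ndarray]
    label: str = "track"

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=np.uint8) for c, v in self.data.items()}

    def validate_against(self, sizes: ChromSizes) -> None:
        for chrom, arr in self.data.items():
            if chrom in sizes and len(arr) != sizes[chrom]:
                raise ValueError(
                    f"track {self.label!r}: chromosome {chrom} has {len(arr)} bases, "
                    f"chrom.sizes says {sizes[chrom]}"
                )


@dataclass(frozen=True)
class WindowGrid:
    """Consecutive non-overlapping windows of one odd width per chromosome.

    Window *i* of a chromosome covers ``[i*width, (i+1)*width)``; the trailing
    partial window is dropped so every window has identical width (counts and
    track fractions stay comparable). Excluded chromosomes contribute no
    windows.
    """

    width: int
    chroms: tuple[str, ...]
    n_windows: tuple[int, ...]
    excluded: tuple[str, ...] = ()

    @property
    def n_total(self) -> int:
        return int(sum(self.n_windows))

    @property
    def offsets(self) -> dict[str, int]:
        """Start index of each chromosome's block in the concatenated vector."""
        out, acc = {}, 0
        for c, n in zip(self.chroms, self.n_windows):
            out[c] = acc
            acc += n
        return out

    def windows_for(self, chrom: str) -> int:
        return self.n_windows[self.chroms.index(chrom)]

    def iter_windows(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, start, end) for every window, in vector order."""
        for chrom, n in zip(self.chroms, self.n_windows):
            for i in range(n):
                yield chrom, i * self.width, (i + 1) * self.width


@dataclass
class WindowVector:
    """One numeric value per window of a :class:`WindowGrid`.

    ``kind`` is ``"read_count"`` (non-negative integers) or
    ``"track_fraction"`` (values in [0, 1]).
    """

    values: np.ndarray
    grid: WindowGrid
    kind: str = "read_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_total:
            raise ValueError(
                f"vector length {len(self.values)} != grid windows {self.grid.n_total}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self, path: str | Path, name: str = "value") -> None:
        """Write (chrom, start, end, value) rows, tab-separated."""
        with open(path, "w") as fh:
            fh.write(f"#chrom\tstart\tend\t{name}\n")
            for (chrom, start, end), v in zip(self.grid.iter_windows(), self.values):
                fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")


def make_window_grid(
    sizes: ChromSizes,
    width: int,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> WindowGrid:
    """Tile every non-excluded chromosome into ``floor(length/width)`` windows.

    ``width`` must be odd and >= 3 (odd widths are symmetric around a centre
    base; the multiscale driver uses widths 2**k + 1).
    """
    if width < 3 or width % 2 == 0:
        raise ValueError(f"window width must be odd and >= 3, got {width}")
    excl = set(exclude or ())
    chroms = tuple(c for c in sizes if c not in excl)
    n_windows = tuple(sizes[c] // width for c in chroms)
    return WindowGrid(width=width, chroms=chroms, n_windows=n_windows,
                      excluded=tuple(sorted(excl)))


# ---------------------------------------------------------------------------
# track construction


def gc_track(fasta_path: str | Path, sizes: ChromSizes | None = None) -> BinaryTrack:
    """Binarized GC-content track from a FASTA file.

    G/C (either case) scores 1; A/T scores 0; every other symbol, including N,
    scores 0 (conservative: an ambiguous base is not evidence of GC).
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), rebuild=False, build_index=True)
    data: dict[str, np.ndarray] = {}
    for name in fa.keys():
        seq = np.frombuffer(str(fa[name][:]).encode("ascii"), dtype=np.uint8)
        bits = np.zeros(len(seq), dtype=np.uint8)
        for ch in b"GCgc":
            bits |= seq == ch
        data[name] = bits
    track = BinaryTrack(data, label="gc")
    if sizes is not None:
        track.validate_against(sizes)
    return track


def gc_track_from_sequences(seqs: Mapping[str, str]) -> BinaryTrack:
    """Same binarization as :func:`gc_track`, from in-memory sequences."""
    data = {}
    for name, seq in seqs.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        bits = np.zeros(len(arr), dtype=np.uint8)
        for ch in b"GCgc":
            bits |= arr == ch
        data[name] = bits
    return BinaryTrack(data, label="gc")


def binarize_mappability(
    path: str | Path,
    sizes: ChromSizes,
    threshold: float = 1.0,
) -> BinaryTrack:
    """Binarize a mappability signal (bedGraph or fixed-step wiggle) per base.

    A base scores 1 iff its signal value is >= ``threshold`` (default 1.0 =
    uniquely mappable). Bases covered by no interval score 0. Overlapping
    intervals with conflicting values are an error.
    """
    data = {c: np.zeros(sizes[c], dtype=np.uint8) for c in sizes}
    covered = {c: np.zeros(sizes[c], dtype=bool) for c in sizes}
    values = {c: np.zeros(sizes[c], dtype=np.float32) for c in sizes}

    def apply(chrom: str, start: int, end: int, value: float, lineno: int) -> None:
        if chrom not in data:
            return
        end = min(end, sizes[chrom])
        if start >= end:
            return
        seg = slice(start, end)
        prev = covered[chrom][seg]
        if prev.any():
            conflict = prev & (values[chrom][seg] != np.float32(value))
            if conflict.any():
                raise ValueError(
                    f"line {lineno}: overlapping intervals with conflicting values "
                    f"at {chrom}:{start}-{end}"
                )
        values[chrom][seg] = value
        covered[chrom][seg] = True
        data[chrom][seg] = 1 if value >= threshold else 0

    with open(path) as fh:
        mode = "bedgraph"
        chrom, pos, step, span = "", 0, 1, 1
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                mode = "fixedstep"
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if mode == "fixedstep":
                apply(chrom, pos, pos + span, float(line), lineno)
                pos += step
            else:
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"line {lineno}: expected 4-column bedGraph")
                apply(parts[0], int(parts[1]), int(parts[2]), float(parts[3]), lineno)
    return BinaryTrack(data, label="mappability")


# ---------------------------------------------------------------------------
# windowed summaries of tracks


def track_fraction(track: BinaryTrack, grid: WindowGrid) -> WindowVector:
    """Fraction of 1-bases per window: (number of 1s in window) / width."""
    parts = []
    for chrom, n in zip(grid.chroms, grid.n_windows):
        if chrom not in track.data:
            raise ValueError(f"track {track.label!r} missing chromosome {chrom}")
        if n == 0:
            continue
        arr = track.data[chrom][: n * grid.width]
        parts.append(arr.reshape(n, grid.width).sum(axis=1) / grid.width)
    values = np.concatenate(parts) if parts else np.zeros(0)
    return WindowVector(values, grid, kind="track_fraction")


def track_fraction_intervals(
    track: BinaryTrack, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Fraction of 1-bases inside arbitrary half-open intervals."""
    out = np.zeros(len(intervals))
    for i, (chrom, start, end) in enumerate(intervals):
        if start >= end:
            raise ValueError(f"interval {i}: start {start} >= end {end}")
        if chrom not in track.data:
            raise ValueError(f"track {track.label!r} missing chromosome {chrom}")
        seg = track.data[chrom][start:end]
        out[i] = seg.sum() / (end - start)
    return out


def file_sha1(path: str | Path) -> str:
    """Short content hash used to key cached window vectors and run headers."""
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]
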