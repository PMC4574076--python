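"""Peak purification and motif-based evaluation of binding estimates.

Peaks are redefined as symmetric windows around the caller's summit
(summit +/- h, default h = 64 giving 129-bp windows, matching the model's
training width). Three binding estimates are compared per peak:

* B — purified signal: raw window read count minus the background model's
  prediction on that exact window,
* R — raw window read count,
* S — the peak caller's own score (opaque; larger = better).

Each estimate is judged by its Pearson correlation with M, the number of
DNA-binding-motif occurrences inside the peak, on the premise that stronger
true binding should co-occur with more motifs. Ranking quality is examined
via moving-window motif fractions and sextile-overlap matrices, and the
"best estimator" tally across datasets is tested with an exact upper-tail
binomial (the ratio test).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .background import BackgroundModelResults
from .genome import BinaryTrack, ChromSizes, track_fraction_intervals
from .reads import ReadSet, count_in_intervals

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    """Symmetric summit-centred window [summit - h, summit + h], half-open end."""

    chrom: str
    summit: int
    start: int
    end: int
    peak_id: str
    score: float  # caller score S; larger = better

    @property
    def width(self) -> int:
        return self.end - self.start


def summit_windows(
    path: str | Path,
    sizes: ChromSizes,
    h: int = 64,
    score_col: int | None = None,
) -> list[Peak]:
    """Read MACS summit BED or narrowPeak rows into summit +/- h peaks.

    Summit BED rows are 1-bp intervals whose score column carries S;
    narrowPeak rows (10 columns) place the summit at start + column-10
    offset, with S taken from column 7 (signalValue) unless ``score_col``
    (1-based) says otherwise. Peaks whose window would cross a chromosome
    edge are excluded (and counted) rather than truncated, so every peak
    matches the trained window width. narrowPeak rows with summit offset -1
    are skipped with a warning.
    """
    peaks: list[Peak] = []
    clipped = unknown_summit = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"peak{lineno}"
            if len(parts) >= 10:  # narrowPeak
                offset = int(parts[9])
                if offset < 0:
                    unknown_summit += 1
                    continue
                summit = start + offset
                col = 7 if score_col is None else score_col
                score = float(parts[col - 1])
            else:  # summit BED: 1-bp interval, score in column 5
                summit = start
                col = 5 if score_col is None else score_col
                score = float(parts[col - 1]) if len(parts) >= col else 0.0
            if chrom not in sizes:
                continue
            w_start, w_end = summit - h, summit + h + 1
            if w_start < 0 or w_end > sizes[chrom]:
                clipped += 1
                continue
            peaks.append(Peak(chrom, summit, w_start, w_end, name, score))
    if clipped:
        logger.info("%s: excluded %d peaks whose window crossed a chromosome edge", path, clipped)
    if unknown_summit:
        logger.warning("%s: skipped %d narrowPeak rows with unknown summit (-1)", path, unknown_summit)
    return peaks


def score_peaks(
    peaks: Sequence[Peak],
    chip_reads: ReadSet,
    results: BackgroundModelResults,
    tracks: Mapping[str, BinaryTrack],
    control_reads: Mapping[str, ReadSet],
) -> pd.DataFrame:
    """Per-peak score table with R (raw), predicted background, and B = R - predicted.

    Features are recomputed on each exact peak window with the same
    definitions used in training (track fractions, control read counts), so
    the model must have been trained at the peak window width.
    """
    if not peaks:
        raise ValueError("no peaks to score")
    width = peaks[0].width
    if results.width is not None and results.width != width:
        raise ValueError(
            f"model trained at width {results.width} but peak windows are {width} bp"
        )
    intervals = [(p.chrom, p.start, p.end) for p in peaks]
    feats: dict[str, np.ndarray] = {}
    for name in results.model.exog_names:
        if name in tracks:
            feats[name] = track_fraction_intervals(tracks[name], intervals)
        elif name in control_reads:
            feats[name] = count_in_intervals(control_reads[name], intervals)
        else:
            raise KeyError(f"predictor {name!r} found in neither tracks nor control reads")
    raw = count_in_intervals(chip_reads, intervals)
    predicted = results.predict(feats)
    return pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "chrom": [p.chrom for p in peaks],
            "start": [p.start for p in peaks],
            "end": [p.end for p in peaks],
            "summit": [p.summit for p in peaks],
            "R": raw,
            "predicted": predicted,
            "B": raw - predicted,
            "S": [p.score for p in peaks],
        }
    )


# ---------------------------------------------------------------------------
# motif occurrences (FIMO output)


_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_fimo_tsv(path: str | Path) -> pd.DataFrame:
    """Parse FIMO tab-separated output into genomic motif occurrences.

    Returns a frame with 0-based half-open genomic ``start``/``end``. FIMO
    reports 1-based inclusive coordinates relative to the scanned sequence;
    when the sequence name looks like ``chrom:start-end`` (sequences
    extracted per peak) the offsets are lifted back to the genome, otherwise
    the sequence name is taken as the chromosome.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    seq_col = next((c for c in ("sequence_name", "sequence", "seq_name") if c in df.columns), None)
    for required in (seq_col, "start", "stop"):
        if required is None or required not in df.columns:
            raise ValueError(f"FIMO file {path}: missing column {required or 'sequence_name'}")
    chroms, starts, ends = [], [], []
    for seq, s, e in zip(df[seq_col], df["start"], df["stop"]):
        m = _REGION_RE.match(str(seq))
        if m:
            offset = int(m.group("start"))
            chroms.append(m.group("chrom"))
        else:
            offset = 0
            chroms.append(str(seq))
        lo, hi = int(min(s, e)), int(max(s, e))
        starts.append(offset + lo - 1)
        ends.append(offset + hi)
    out = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if "strand" in df.columns:
        out["strand"] = df["strand"].values
    if "motif_id" in df.columns:
        out["motif_id"] = df["motif_id"].values
    return out


def count_motifs_in_peaks(occurrences: pd.DataFrame, peaks: Sequence[Peak]) -> np.ndarray:
    """Motif count M per peak: occurrences lying fully inside the window.

    Either strand counts; an occurrence straddling the window edge does not.
    """
    m = np.zeros(len(peaks), dtype=int)
    if len(occurrences) == 0:
        return m
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in occurrences.groupby("chrom"):
        arr = sub[["start", "end"]].to_numpy(dtype=np.int64)
        by_chrom[chrom] = arr[np.argsort(arr[:, 0], kind="stable")]
    for i, p in enumerate(peaks):
        arr = by_chrom.get(p.chrom)
        if arr is None:
            continue
        lo = np.searchsorted(arr[:, 0], p.start, "left")
        hi = np.searchsorted(arr[:, 0], p.end, "left")
        m[i] = int(np.count_nonzero(arr[lo:hi, 1] <= p.end))
    return m


def attach_motif_counts(table: pd.DataFrame, m: np.ndarray) -> pd.DataFrame:
    table = table.copy()
    table["M"] = np.asarray(m, dtype=int)
    table["has_motif"] = table["M"] > 0
    return table


# ---------------------------------------------------------------------------
# estimator comparison


def correlate_estimates(
    table: pd.DataFrame,
    estimators: Sequence[str] = ("B", "R", "S"),
    binary: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each estimate against M (or motif presence).

    Estimates with zero variance in either signal are flagged undefined and
    excluded from downstream tallies.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 peaks to correlate")
    target = table["has_motif"].astype(float) if binary else table["M"].astype(float)
    rows = []
    for est in estimators:
        x = table[est].astype(float)
        if np.var(x) == 0 or np.var(target) == 0:
            rows.append({"estimator": est, "pcc": np.nan, "p_value": np.nan, "defined": False})
            continue
        r, p = stats.pearsonr(x, target)
        rows.append({"estimator": est, "pcc": float(r), "p_value": float(p), "defined": True})
    return pd.DataFrame(rows)


def ratio_test(successes: int, trials: int, n_methods: int = 3) -> float:
    """Exact upper-tail binomial P(X >= successes), X ~ Bin(trials, 1/n_methods).

    The null: all methods are equally likely to win a dataset, so one
    method's win count is binomial with success probability 1/n_methods.
    """
    if not (0 <= successes <= trials):
        raise ValueError("need 0 <= successes <= trials")
    if n_methods < 2:
        raise ValueError("need at least 2 methods")
    return float(stats.binom.sf(successes - 1, trials, 1.0 / n_methods))


def best_estimator_tally(
    comparisons: Sequence[pd.DataFrame],
    estimators: Sequence[str] = ("B", "R", "S"),
) -> dict:
    """Across datasets, who wins? Tally of best-PCC estimators plus ratio test.

    Ties break toward the earlier estimator in ``estimators`` (logged).
    Datasets where every estimate is undefined are dropped from the tally.
    """
    tally = {est: 0 for est in estimators}
    winners = []
    for comp in comparisons:
        defined = comp[comp["defined"]]
        if defined.empty:
            winners.append(None)
            continue
        best_pcc = defined["pcc"].max()
        tied = [e for e in estimators if e in set(defined.loc[defined["pcc"] == best_pcc, "estimator"])]
        if len(tied) > 1:
            logger.info("tie between %s broken toward %s", tied, tied[0])
        winners.append(tied[0])
        tally[tied[0]] += 1
    trials = sum(v for v in tally.values())
    top = max(tally, key=lambda e: tally[e])
    p = ratio_test(tally[top], trials, len(estimators)) if trials else float("nan")
    return {"tally": tally, "winners": winners, "best": top,
            "trials": trials, "ratio_test_p": p}


# ---------------------------------------------------------------------------
# ranking diagnostics


def _ranked(table: pd.DataFrame, by: str) -> pd.DataFrame:
    """Sort descending by score, stable, genomic coordinate as final key."""
    t = table.sort_values(["chrom", "start"], kind="stable")
    return t.sort_values(by, ascending=False, kind="stable")


def moving_motif_fraction(table: pd.DataFrame, by: str, window: int = 1000) -> np.ndarray:
    """Fraction of motif-bearing peaks in a moving window down the ranking.

    Peaks are ranked best-to-worst by column ``by``; entry j of the curve is
    the fraction of peaks j..j+window-1 with at least one motif.
    """
    n = len(table)
    if n < window:
        raise ValueError(f"only {n} peaks; reduce window below {window}")
    has = _ranked(table, by)["has_motif"].to_numpy(dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(has)])
    return (csum[window:] - csum[:-window]) / window


def sextile_overlap(
    table: pd.DataFrame, by_a: str, by_b: str, n_groups: int = 6
) -> np.ndarray:
    """Overlap counts between rank-sextiles of two scorings of the same peaks.

    Both rankings partition the peaks into ``n_groups`` blocks of near-equal
    size (a remainder r puts one extra peak into each of the first r blocks);
    cell (i, j) counts peaks in block i of ranking A and block j of ranking B.
    """
    n = len(table)
    if n < n_groups:
        raise ValueError("fewer peaks than groups")

    def groups(by: str) -> np.ndarray:
        order = _ranked(table, by).index.to_numpy()
        base, rem = divmod(n, n_groups)
        sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
        g = np.empty(n, dtype=int)
        start = 0
        for gi, size in enumerate(sizes):
            g[start : start + size] = gi
            start += size
        out = pd.Series(g, index=order)
        return out.reindex(table.index).to_numpy()

    ga, gb = groups(by_a), groups(by_b)
    mat = np.zeros((n_groups, n_groups), dtype=int)
    np.add.at(mat, (ga, gb), 1)
    return mat


# ---------------------------------------------------------------------------
# writers


def write_peak_table(table: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_peaks_bed9(table: pd.DataFrame, path: str | Path) -> None:
    """BED9 with purified signal B in the score slot for browser loading."""
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t{row['peak_id']}\t"
                f"{row['B']:.4g}\t.\t{row['start']}\t{row['end']}\t0,0,0\n"
            )
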