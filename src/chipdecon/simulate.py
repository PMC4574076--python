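"""Synthetic genomes with planted bias structure, peaks, motifs and expression.

The generator mirrors the composition model the decomposition assumes: the
per-window expected ChIP-seq count is a linear function of the bias
predictors plus, inside peaks, a planted enrichment, and realized counts are
Poisson. Because emission is linear-rate (not log-linear), the fitted OLS
model is correctly specified and planted coefficients are recoverable in
expectation. Negative linear rates are clamped to zero before the Poisson
draw — the one deliberate mis-specification knob (off under default
coefficients, which keep rates positive).

What is emulated: mappability with blocky runs, GC composition drifting
smoothly along the chromosome, a smooth non-negative chromatin-accessibility
field (mixture of bumps over a baseline) that drives the DNase control,
control read sets with their own coefficient vectors, summit-centred peaks
placed preferentially in open chromatin with motif occurrences whose
frequency increases with true enrichment, and CAGE expression counts
log-linearly coupled to accessibility so that a "specific-TF" signal driven
only by accessibility is conditionally independent of expression given
accessibility — the confounding structure the expression audit exists to
detect.

What is not emulated: fragment-length/shift effects, PCR duplication,
sequencing errors, diploid genomes. Counts are drawn at window level and
then placed on mappable base/strand slots; coincident placements can arise
and deduplication collapses them, as with real reads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import (
    BinaryTrack,
    ChromSizes,
    WindowGrid,
    make_window_grid,
    track_fraction,
)
from .reads import ReadSet, count_reads, write_bed_reads

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Parameters of the planted-truth simulation. ``seed`` is mandatory."""

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrS1": 1_290_000})
    width: int = 129  # analysis window width (odd)

    # mappability: alternating mappable/unmappable runs, geometric lengths
    mappable_run: float = 600.0
    unmappable_run: float = 60.0

    # GC composition: per-base G/C probability drifts smoothly around the mean
    gc_mean: float = 0.41
    gc_amp: float = 0.08
    gc_scale: float = 2_000.0  # bp correlation scale of the drift

    # accessibility: baseline + Gaussian bumps (per-base, >= 0)
    access_baseline: float = 0.10
    bump_density: float = 1 / 5_000.0  # expected bumps per bp
    bump_amp_mean: float = 0.6
    bump_sd: float = 300.0  # bp
    access_max: float = 1.2  # saturation: a region cannot be more than fully open

    # per-window control read rates (scaled by window mappable fraction)
    dnase_depth: float = 100.0  # lambda = depth * (0.1 + access) * map_frac
    idna_depth: float = 3.0  # lambda = depth * map_frac
    igg_depth: float = 2.0  # lambda = depth * map_frac

    # planted linear coefficients for the ChIP rate:
    # (intercept, mappability frac, GC frac, DNase count, iDNA count, IgG count)
    beta_star: tuple[float, ...] = (0.5, 1.5, 1.0, 0.2, 0.25, 0.15)

    # peaks
    n_peaks: int = 300
    peak_h: int = 64  # summit +/- h
    delta_mean: float = 20.0  # mean planted enrichment (reads per peak window)
    delta_shape: float = 2.0  # Gamma shape of per-peak enrichment
    motif_rate: float = 1.2  # E[M] = motif_rate * delta / delta_mean
    motif_length: int = 8

    # expression (CAGE at TSSs): count ~ Poisson(exp(a + b * access))
    n_tss: int = 2_000
    expr_a: float = 0.5
    expr_b: float = 2.0
    faketf_base: float = 2.0  # specific-TF rate = base + slope * access
    faketf_slope: float = 8.0
    general_coupling: float = 0.0  # direct expression term in the general factor

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(v < 0 for v in (self.access_baseline, self.dnase_depth,
                               self.idna_depth, self.igg_depth, self.delta_mean)):
            raise ValueError("rates must be non-negative")

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_lengths)


@dataclass
class SimTruth:
    """Planted parameters and realized expectations, kept for recovery tests."""

    beta_star: np.ndarray
    window_rate: np.ndarray  # expected ChIP count per window (before peaks)
    access_window: np.ndarray  # mean accessibility per window
    peak_delta: np.ndarray  # planted enrichment per peak
    tss_expression_mean: np.ndarray  # E[CAGE count] per TSS

    def to_json(self, path: str | Path) -> None:
        doc = {k: np.asarray(v).tolist() for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# tracks


def _smooth_field(length: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth random field via coarse white noise + interpolation."""
    n_knots = max(int(length / scale) + 2, 4)
    knots = rng.standard_normal(n_knots)
    x = np.linspace(0, n_knots - 1, length)
    return np.interp(x, np.arange(n_knots), knots)


def _bump_field(length: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Accessibility: baseline plus Gaussian bumps with exponential amplitudes."""
    field_ = np.full(length, cfg.access_baseline)
    n_bumps = rng.poisson(cfg.bump_density * length)
    centers = rng.uniform(0, length, n_bumps)
    amps = rng.exponential(cfg.bump_amp_mean, n_bumps)
    half = int(4 * cfg.bump_sd)
    offs = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offs / cfg.bump_sd) ** 2)
    for c, a in zip(centers, amps):
        ci = int(c)
        lo, hi = max(0, ci - half), min(length, ci + half + 1)
        field_[lo:hi] += a * kernel[(lo - ci + half) : (hi - ci + half)]
    return np.minimum(field_, cfg.access_max)


def simulate_tracks(
    config: SimConfig, rng: np.random.Generator
) -> tuple[BinaryTrack, BinaryTrack, dict[str, np.ndarray]]:
    """Mappability bits, GC bits, and the per-base accessibility rate field."""
    map_data, gc_data, access = {}, {}, {}
    for chrom, length in config.chrom_lengths.items():
        # alternating mappable / unmappable runs
        bits = np.ones(length, dtype=np.uint8)
        pos, mappable = 0, True
        while pos < length:
            mean = config.mappable_run if mappable else config.unmappable_run
            run = int(rng.geometric(1.0 / max(mean, 1.0)))
            if not mappable:
                bits[pos : pos + run] = 0
            pos += run
            mappable = not mappable
        map_data[chrom] = bits

        gc_prob = np.clip(
            config.gc_mean + config.gc_amp * _smooth_field(length, config.gc_scale, rng),
            0.0, 1.0,
        )
        gc_data[chrom] = (rng.random(length) < gc_prob).astype(np.uint8)
        access[chrom] = _bump_field(length, config, rng)
    return (
        BinaryTrack(map_data, label="mappability"),
        BinaryTrack(gc_data, label="gc"),
        access,
    )


def sequences_from_gc(gc: BinaryTrack, rng: np.random.Generator) -> dict[str, str]:
    """FASTA letters consistent with the GC bit track (G/C where 1, A/T where 0)."""
    seqs = {}
    for chrom, bits in gc.data.items():
        pick = rng.integers(0, 2, len(bits))
        letters = np.where(bits == 1, np.where(pick == 0, ord("G"), ord("C")),
                           np.where(pick == 0, ord("A"), ord("T")))
        seqs[chrom] = letters.astype(np.uint8).tobytes().decode("ascii")
    return seqs


def window_mean(per_base: Mapping[str, np.ndarray], grid: WindowGrid) -> np.ndarray:
    """Mean of a per-base field over each complete window, in grid order."""
    parts = []
    for chrom, n in zip(grid.chroms, grid.n_windows):
        if n == 0:
            continue
        arr = np.asarray(per_base[chrom][: n * grid.width], dtype=float)
        parts.append(arr.reshape(n, grid.width).mean(axis=1))
    return np.concatenate(parts) if parts else np.zeros(0)


# ---------------------------------------------------------------------------
# counts and reads


def place_reads_in_windows(
    counts: np.ndarray,
    grid: WindowGrid,
    mappability: BinaryTrack,
    rng: np.random.Generator,
) -> ReadSet:
    """Place per-window counts uniformly on mappable bases, random strands.

    Reads land only on mappable positions; a window with no mappable base
    has its reads suppressed (logged). Placement is with replacement, so
    coincident 5' positions can occur (collapsed later by deduplication).
    """
    positions, strands = {}, {}
    offsets = grid.offsets
    suppressed = 0
    for chrom, n in zip(grid.chroms, grid.n_windows):
        if n == 0:
            continue
        mp = np.flatnonzero(mappability.data[chrom][: n * grid.width]).astype(np.int64)
        c = np.asarray(counts[offsets[chrom] : offsets[chrom] + n], dtype=np.int64)
        edges = np.arange(0, (n + 1) * grid.width, grid.width)
        lo = np.searchsorted(mp, edges[:-1], "left")
        hi = np.searchsorted(mp, edges[1:], "left")
        empty = (hi == lo) & (c > 0)
        if empty.any():
            suppressed += int(c[empty].sum())
            c = c.copy()
            c[empty] = 0
        total = int(c.sum())
        if total == 0:
            positions[chrom] = np.zeros(0, dtype=np.int64)
            strands[chrom] = np.zeros(0, dtype=np.int8)
            continue
        win_ids = np.repeat(np.arange(n), c)
        u = rng.random(total)
        idx = lo[win_ids] + np.floor(u * (hi[win_ids] - lo[win_ids])).astype(np.int64)
        pos = mp[idx]
        order = np.argsort(pos, kind="stable")
        positions[chrom] = pos[order]
        strands[chrom] = rng.integers(0, 2, total).astype(np.int8)[order]
    if suppressed:
        logger.info("suppressed %d reads in fully unmappable windows", suppressed)
    return ReadSet(positions, strands, dedup_applied=False)


def simulate_window_counts(
    config: SimConfig,
    rng: np.random.Generator,
    grid: WindowGrid,
    map_frac: np.ndarray,
    gc_frac: np.ndarray,
    access_win: np.ndarray,
    peak_bonus: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Draw control and ChIP window counts from the planted linear-rate model.

    Returns (counts by dataset, expected ChIP rate per window before peaks).
    """
    lam_dnase = config.dnase_depth * (0.1 + access_win) * map_frac
    lam_idna = config.idna_depth * map_frac
    lam_igg = config.igg_depth * map_frac
    dnase = rng.poisson(lam_dnase).astype(float)
    idna = rng.poisson(lam_idna).astype(float)
    igg = rng.poisson(lam_igg).astype(float)

    b = np.asarray(config.beta_star, dtype=float)
    rate = b[0] + b[1] * map_frac + b[2] * gc_frac + b[3] * dnase + b[4] * idna + b[5] * igg
    rate = np.clip(rate, 0.0, None)
    lam_chip = rate + (peak_bonus if peak_bonus is not None else 0.0)
    chip = rng.poisson(lam_chip).astype(float)
    counts = {"chip": chip, "dnase": dnase, "idna": idna, "igg": igg}
    return counts, rate


# ---------------------------------------------------------------------------
# peaks, motifs, expression


def simulate_peaks(
    config: SimConfig,
    rng: np.random.Generator,
    mappability: BinaryTrack,
    access: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Summit positions (biased toward open chromatin) with planted enrichment.

    Returns a frame (chrom, summit, delta) with per-peak enrichment
    delta ~ Gamma(shape, delta_mean / shape), independent of accessibility.
    """
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    h = config.peak_h
    rows = []
    for _ in range(config.n_peaks):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = config.chrom_lengths[chrom]
        for _attempt in range(200):
            pos = int(rng.integers(h, length - h - 1))
            if not mappability.data[chrom][pos]:
                continue
            # accept proportionally to local openness (peaks live in open chromatin)
            a = float(access[chrom][pos])
            if rng.random() < (0.15 + a) / (0.15 + a + 1.0):
                rows.append((chrom, pos))
                break
        else:
            rows.append((chrom, int(rng.integers(h, length - h - 1))))
    delta = rng.gamma(config.delta_shape, config.delta_mean / config.delta_shape,
                      len(rows))
    df = pd.DataFrame(rows, columns=["chrom", "summit"])
    df["delta"] = delta
    df = df.sort_values(["chrom", "summit"], kind="stable").reset_index(drop=True)
    df["peak_id"] = [f"peak{i}" for i in range(len(df))]
    return df


def peak_bonus_per_window(peaks: pd.DataFrame, grid: WindowGrid, h: int) -> np.ndarray:
    """Spread each peak's enrichment over the grid windows its window overlaps."""
    bonus = np.zeros(grid.n_total)
    offsets = grid.offsets
    n_by_chrom = dict(zip(grid.chroms, grid.n_windows))
    for _, p in peaks.iterrows():
        chrom = p["chrom"]
        if chrom not in offsets:
            continue
        start, end = p["summit"] - h, p["summit"] + h + 1
        w0, w1 = start // grid.width, (end - 1) // grid.width
        for w in range(max(w0, 0), min(w1, n_by_chrom[chrom] - 1) + 1):
            ov = min(end, (w + 1) * grid.width) - max(start, w * grid.width)
            bonus[offsets[chrom] + w] += p["delta"] * ov / (2 * h + 1)
    return bonus


def simulate_peak_reads(
    peaks: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    mappability: BinaryTrack,
) -> ReadSet:
    """Extra ChIP reads inside peak windows: Poisson(delta) on mappable bases."""
    positions: dict[str, list[int]] = {}
    strands: dict[str, list[int]] = {}
    h = config.peak_h
    for _, p in peaks.iterrows():
        chrom = p["chrom"]
        start, end = int(p["summit"]) - h, int(p["summit"]) + h + 1
        mp = np.flatnonzero(mappability.data[chrom][start:end]).astype(np.int64) + start
        if len(mp) == 0:
            continue
        k = rng.poisson(p["delta"])
        if k == 0:
            continue
        idx = rng.integers(0, len(mp), k)
        positions.setdefault(chrom, []).extend(mp[idx].tolist())
        strands.setdefault(chrom, []).extend(rng.integers(0, 2, k).tolist())
    return ReadSet(
        {c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        {c: np.array(v, dtype=np.int8) for c, v in strands.items()},
        dedup_applied=False,
    )


def simulate_motifs(
    peaks: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Motif occurrences per peak, count increasing with true enrichment.

    M ~ Poisson(motif_rate * delta / delta_mean), occurrences placed uniformly
    inside the peak window. Returned in FIMO-style genomic rows.
    """
    rows = []
    h, L = config.peak_h, config.motif_length
    for _, p in peaks.iterrows():
        lam = config.motif_rate * p["delta"] / max(config.delta_mean, 1e-12)
        m = rng.poisson(lam)
        start, end = int(p["summit"]) - h, int(p["summit"]) + h + 1
        for _j in range(int(m)):
            s = int(rng.integers(start, end - L))
            rows.append(
                {
                    "motif_id": "SIM_MOTIF",
                    "motif_alt_id": "sim",
                    "sequence_name": p["chrom"],
                    "start": s + 1,  # FIMO is 1-based inclusive
                    "stop": s + L,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "score": float(np.round(10 + rng.random() * 10, 3)),
                    "p-value": 1e-5,
                    "q-value": 1e-2,
                    "matched_sequence": "N" * L,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["motif_id", "motif_alt_id", "sequence_name", "start", "stop",
                 "strand", "score", "p-value", "q-value", "matched_sequence"],
    )


def simulate_expression(
    config: SimConfig,
    rng: np.random.Generator,
    mappability: BinaryTrack,
    access: Mapping[str, np.ndarray],
) -> tuple[pd.DataFrame, ReadSet, dict[str, ReadSet], np.ndarray]:
    """TSS set, CAGE reads, and TSS-window factor read sets with known coupling.

    Expression: CAGE count ~ Poisson(exp(a + b * mean accessibility in the
    TSS window)). The "specific TF" read set is driven only by accessibility,
    so expression and that signal are conditionally independent given
    accessibility. The "general factor" additionally receives
    ``general_coupling`` * realized expression — genuine signal beyond the
    confounder when the coupling is positive.
    """
    h = config.peak_h
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    import bisect

    rows = []
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    min_sep = 2 * h + 1  # non-overlapping TSS windows: each read counts once
    attempts = 0
    while len(rows) < config.n_tss and attempts < 200 * config.n_tss:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = config.chrom_lengths[chrom]
        pos = int(rng.integers(h, length - h - 1))
        if not mappability.data[chrom][pos]:
            continue
        # TSSs concentrate in open chromatin — the very reason accessibility
        # confounds TSS-signal associations
        a = float(access[chrom][pos])
        if rng.random() >= (0.1 + a) / (0.1 + a + 0.6):
            continue
        lst = taken[chrom]
        i = bisect.bisect_left(lst, pos)
        if (i > 0 and pos - lst[i - 1] < min_sep) or (i < len(lst) and lst[i] - pos < min_sep):
            continue
        lst.insert(i, pos)
        rows.append((chrom, pos))
    if len(rows) < config.n_tss:
        logger.warning("placed only %d of %d TSSs", len(rows), config.n_tss)
    tss = pd.DataFrame(rows, columns=["chrom", "tss"])
    tss = tss.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)
    tss["gene_id"] = [f"gene{i}" for i in range(len(tss))]
    tss["start"], tss["end"] = tss["tss"] - h, tss["tss"] + h + 1

    a_win = np.array(
        [access[c][s:e].mean() for c, s, e in zip(tss["chrom"], tss["start"], tss["end"])]
    )
    mu = np.exp(config.expr_a + config.expr_b * a_win)
    cage_counts = rng.poisson(mu)

    def place(counts: np.ndarray) -> ReadSet:
        positions: dict[str, list[int]] = {}
        strands: dict[str, list[int]] = {}
        for (chrom, s, e), k in zip(zip(tss["chrom"], tss["start"], tss["end"]), counts):
            if k == 0:
                continue
            mp = np.flatnonzero(mappability.data[chrom][s:e]).astype(np.int64) + s
            if len(mp) == 0:
                continue
            idx = rng.integers(0, len(mp), int(k))
            positions.setdefault(chrom, []).extend(mp[idx].tolist())
            strands.setdefault(chrom, []).extend(rng.integers(0, 2, int(k)).tolist())
        return ReadSet(
            {c: np.array(v, dtype=np.int64) for c, v in positions.items()},
            {c: np.array(v, dtype=np.int8) for c, v in strands.items()},
            dedup_applied=False,
        )

    cage = place(cage_counts)
    faketf_lam = config.faketf_base + config.faketf_slope * a_win
    factors = {"specific_tf": place(rng.poisson(faketf_lam))}
    general_lam = faketf_lam + config.general_coupling * cage_counts
    factors["general_factor"] = place(rng.poisson(general_lam))
    return tss, cage, factors, mu


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulationBundle:
    """Everything one simulated study produces, in memory, plus its truth."""

    config: SimConfig
    sizes: ChromSizes
    grid: WindowGrid
    mappability: BinaryTrack
    gc: BinaryTrack
    access: dict[str, np.ndarray]
    window_features: dict[str, np.ndarray]  # map_frac, gc_frac, access
    #: window-level draws from the planted linear-rate model (no peak
    #: component, no mappability suppression) — the regression test bed
    counts: dict[str, np.ndarray]
    #: placed reads for the same datasets; ChIP additionally carries the
    #: peak enrichment, and reads in fully unmappable windows are suppressed
    read_sets: dict[str, ReadSet]
    peaks: pd.DataFrame
    motifs: pd.DataFrame
    tss: pd.DataFrame
    cage: ReadSet
    tss_factors: dict[str, ReadSet]
    truth: SimTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the whole fixture as plain-text files; returns paths by role."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 7]))
        paths: dict[str, Path] = {}

        paths["chrom_sizes"] = out / "chrom.sizes"
        self.sizes.to_file(paths["chrom_sizes"])

        paths["fasta"] = out / "genome.fa"
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in sequences_from_gc(self.gc, rng).items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

        paths["mappability"] = out / "mappability.bedgraph"
        with open(paths["mappability"], "w") as fh:
            for chrom, bits in self.mappability.data.items():
                edges = np.flatnonzero(np.diff(np.concatenate([[255], bits, [255]])))
                for s, e in zip(edges[:-1], edges[1:]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(bits[s])}\n")

        for name, rs in self.read_sets.items():
            paths[name] = out / f"{name}.bed"
            write_bed_reads(rs, paths[name])

        paths["summits"] = out / "summits.bed"
        with open(paths["summits"], "w") as fh:
            # caller score: noisy monotone transform of raw window reads
            for _, p in self.peaks.iterrows():
                fh.write(
                    f"{p['chrom']}\t{p['summit']}\t{p['summit'] + 1}\t{p['peak_id']}\t"
                    f"{p['caller_score']:.3f}\n"
                )

        paths["fimo"] = out / "fimo.tsv"
        self.motifs.to_csv(paths["fimo"], sep="\t", index=False)

        paths["tss"] = out / "tss.bed"
        with open(paths["tss"], "w") as fh:
            for _, t in self.tss.iterrows():
                fh.write(f"{t['chrom']}\t{t['tss']}\t{t['tss'] + 1}\t{t['gene_id']}\t0\t+\n")

        paths["cage"] = out / "cage.bed"
        write_bed_reads(self.cage, paths["cage"])
        for name, rs in self.tss_factors.items():
            paths[name] = out / f"{name}.bed"
            write_bed_reads(rs, paths[name])

        paths["truth"] = out / "truth.json"
        self.truth.to_json(paths["truth"])
        return paths


def simulate_study(config: SimConfig) -> SimulationBundle:
    """Run the full generator: tracks, counts, reads, peaks, motifs, expression.

    Deterministic under ``config.seed`` (single integer-seeded PCG64 stream,
    consumed in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes
    grid = make_window_grid(sizes, config.width, exclude=())

    mappability, gc, access = simulate_tracks(config, rng)
    map_frac = track_fraction(mappability, grid).values
    gc_frac = track_fraction(gc, grid).values
    access_win = window_mean(access, grid)

    peaks = simulate_peaks(config, rng, mappability, access)
    counts, rate = simulate_window_counts(
        config, rng, grid, map_frac, gc_frac, access_win, peak_bonus=None
    )

    read_sets = {
        name: place_reads_in_windows(counts[name], grid, mappability, rng)
        for name in ("chip", "dnase", "idna", "igg")
    }
    # peak enrichment goes in at base level so summit windows carry it exactly
    peak_reads = simulate_peak_reads(peaks, config, rng, mappability)
    chip = read_sets["chip"]
    merged_pos, merged_str = {}, {}
    for chrom in set(chip.positions) | set(peak_reads.positions):
        p1 = chip.positions.get(chrom, np.zeros(0, dtype=np.int64))
        p2 = peak_reads.positions.get(chrom, np.zeros(0, dtype=np.int64))
        s1 = chip.strands.get(chrom, np.zeros(0, dtype=np.int8))
        s2 = peak_reads.strands.get(chrom, np.zeros(0, dtype=np.int8))
        merged_pos[chrom] = np.concatenate([p1, p2])
        merged_str[chrom] = np.concatenate([s1, s2])
    read_sets["chip"] = ReadSet(merged_pos, merged_str, dedup_applied=False)

    # caller score S: noisy monotone transform of raw reads near the summit
    h = config.peak_h
    intervals = [(c, s - h, s + h + 1) for c, s in zip(peaks["chrom"], peaks["summit"])]
    from .reads import count_in_intervals  # local import to avoid cycle at top

    raw = count_in_intervals(read_sets["chip"], intervals)
    peaks = peaks.copy()
    peaks["caller_score"] = raw + rng.normal(0, np.sqrt(np.maximum(raw, 1.0)))

    motifs = simulate_motifs(peaks, config, rng)
    tss, cage, factors, mu = simulate_expression(config, rng, mappability, access)

    truth = SimTruth(
        beta_star=np.asarray(config.beta_star, dtype=float),
        window_rate=rate,
        access_window=access_win,
        peak_delta=peaks["delta"].to_numpy(),
        tss_expression_mean=mu,
    )
    return SimulationBundle(
        config=config,
        sizes=sizes,
        grid=grid,
        mappability=mappability,
        gc=gc,
        access=access,
        window_features={"mappability": map_frac, "gc": gc_frac, "access": access_win},
        counts=counts,
        read_sets=read_sets,
        peaks=peaks,
        motifs=motifs,
        tss=tss,
        cage=cage,
        tss_factors=factors,
        truth=truth,
    )


def simulate_base_rate_reads(
    rate: Mapping[str, np.ndarray], rng: np.random.Generator
) -> ReadSet:
    """Reads from a per-base Poisson rate field (for multiscale fixtures)."""
    positions, strands = {}, {}
    for chrom, lam in rate.items():
        counts = rng.poisson(np.asarray(lam, dtype=float))
        total = int(counts.sum())
        pos = np.repeat(np.arange(len(lam), dtype=np.int64), counts)
        positions[chrom] = pos
        strands[chrom] = rng.integers(0, 2, total).astype(np.int8)
    return ReadSet(positions, strands, dedup_applied=False)


def simulate_smooth_fixture(
    seed: int, length: int = 300_000
) -> tuple[ChromSizes, dict[str, BinaryTrack], dict[str, ReadSet]]:
    """Smooth-rate genome for multiscale analysis: reads from per-base rates.

    The ChIP rate follows the accessibility field smoothly, so window
    averaging cancels Poisson sampling noise and predictability rises with
    window width — the regime in which larger scales explain more variance.
    Returns (sizes, tracks, read sets for chip/dnase/idna/igg).
    """
    cfg = SimConfig(seed=seed, chrom_lengths={"chrS1": length})
    rng = np.random.default_rng(seed)
    mappability, gc, access = simulate_tracks(cfg, rng)
    rates: dict[str, dict[str, np.ndarray]] = {}
    for chrom in cfg.chrom_lengths:
        a = access[chrom]
        m = mappability.data[chrom].astype(float)
        rates.setdefault("chip", {})[chrom] = (0.02 + 0.10 * a) * m
        rates.setdefault("dnase", {})[chrom] = 0.5 * a * m
        rates.setdefault("idna", {})[chrom] = 0.02 * m
        rates.setdefault("igg", {})[chrom] = 0.015 * m
    read_sets = {name: simulate_base_rate_reads(r, rng) for name, r in rates.items()}
    return cfg.sizes, {"mappability": mappability, "gc": gc}, read_sets
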