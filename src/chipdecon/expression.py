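"""Expression-association audit at transcription start sites.

Gene expression is measured as the CAGE 5'-tag count in a small window
centred at each TSS (TSS +/- h, default 129 bp). Windowed ChIP-seq or bias
signals in the same windows are used to predict expression by OLS under
tenfold cross-validation; the headline number is the Pearson correlation
between pooled out-of-fold predictions and observed expression.

The confounding audit asks how much a signal adds *beyond* the core bias
predictors (mappability, GC, accessibility, iDNA, IgG): delta-PCC =
PCC(core + signal) - PCC(core), computed on identical fold assignments. A
signal with high standalone PCC but near-zero delta-PCC predicts expression
only through what it shares with the core set — the signature of chromatin
accessibility acting as a confounder rather than of direct regulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import BinaryTrack, ChromSizes, track_fraction_intervals
from .reads import ReadSet, count_in_intervals

logger = logging.getLogger(__name__)


def tss_windows(
    tss_bed: str | Path | pd.DataFrame,
    sizes: ChromSizes,
    h: int = 64,
) -> pd.DataFrame:
    """Symmetric TSS windows from a BED of TSS positions.

    Rows are 1-bp intervals, or wider intervals whose start is taken as the
    TSS for '+' and end-1 for '-'. Near-edge TSSs are excluded (logged);
    TSSs sharing one (chrom, position) collapse to a single window with the
    gene ids concatenated (comma-separated).

    Returns a frame with columns gene_id, chrom, tss, start, end.
    """
    if isinstance(tss_bed, pd.DataFrame):
        rows = tss_bed
    else:
        rows = pd.read_csv(
            tss_bed, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6), dtype={"chrom": str, "name": str},
        )
    records: dict[tuple[str, int], list[str]] = {}
    clipped = 0
    for _, row in rows.iterrows():
        chrom = row["chrom"]
        if chrom not in sizes:
            continue
        strand = row.get("strand", "+")
        tss = int(row["start"]) if strand != "-" else int(row["end"]) - 1
        if tss - h < 0 or tss + h + 1 > sizes[chrom]:
            clipped += 1
            continue
        records.setdefault((chrom, tss), []).append(str(row.get("name", f"{chrom}:{tss}")))
    if clipped:
        logger.info("excluded %d near-edge TSSs", clipped)
    if not records:
        raise ValueError("no usable TSSs after filtering")
    items = sorted(records.items())
    return pd.DataFrame(
        {
            "gene_id": [",".join(ids) for (_, _), ids in items],
            "chrom": [c for (c, _), _ in items],
            "tss": [t for (_, t), _ in items],
            "start": [t - h for (_, t), _ in items],
            "end": [t + h + 1 for (_, t), _ in items],
        }
    )


def tss_feature_matrix(
    windows: pd.DataFrame,
    tracks: Mapping[str, BinaryTrack] = (),
    read_sets: Mapping[str, ReadSet] = (),
) -> pd.DataFrame:
    """Named per-TSS features: track fractions and read counts on the windows."""
    intervals = list(zip(windows["chrom"], windows["start"], windows["end"]))
    feats = {}
    for name, track in dict(tracks).items():
        feats[name] = track_fraction_intervals(track, intervals)
    for name, rs in dict(read_sets).items():
        feats[name] = count_in_intervals(rs, intervals)
    return pd.DataFrame(feats, index=windows.index)


# ---------------------------------------------------------------------------
# cross-validated prediction


@dataclass
class CvResult:
    """Tenfold-CV prediction accuracy for one feature set."""

    feature_set: str
    seed: int
    n_folds: int
    fold_assignment: np.ndarray  # fold id per observation
    fold_pcc: np.ndarray  # PCC within each held-out fold
    pooled_pcc: float  # PCC of pooled out-of-fold predictions
    predictions: np.ndarray  # pooled out-of-fold predictions

    @property
    def mean_fold_pcc(self) -> float:
        return float(np.mean(self.fold_pcc))

    @property
    def ci95(self) -> tuple[float, float]:
        """mean +/- t(0.975, folds-1) * sd / sqrt(folds) across folds."""
        m = self.mean_fold_pcc
        sd = float(np.std(self.fold_pcc, ddof=1))
        half = stats.t.ppf(0.975, self.n_folds - 1) * sd / np.sqrt(self.n_folds)
        return (m - half, m + half)


def assign_folds(n: int, folds: int, seed: int) -> np.ndarray:
    """Random partition into ``folds`` groups whose sizes differ by <= 1."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, folds)
    assignment = np.empty(n, dtype=int)
    start = 0
    for f in range(folds):
        size = base + (1 if f < rem else 0)
        assignment[perm[start : start + size]] = f
        start += size
    return assignment


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X.reshape(len(X), -1)


def cv_predict(
    y,
    X,
    folds: int = 10,
    seed: int = 0,
    feature_set: str = "features",
    fold_assignment: np.ndarray | None = None,
) -> CvResult:
    """OLS prediction of expression under k-fold cross-validation.

    Each fold trains an intercept-bearing OLS model on the other folds and
    predicts the held-out group; the pooled out-of-fold PCC is the headline
    accuracy, per-fold PCCs give the confidence interval.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = _as_matrix(X)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y and X disagree on the number of TSSs")
    if n < folds * (X.shape[1] + 2):
        raise ValueError(f"too few TSSs ({n}) for {folds}-fold CV with {X.shape[1]} features")
    if fold_assignment is None:
        fold_assignment = assign_folds(n, folds, seed)
    preds = np.empty(n)
    fold_pcc = np.empty(folds)
    for f in range(folds):
        test = fold_assignment == f
        train = ~test
        if np.var(y[train]) == 0:
            raise ValueError(f"zero-variance expression in training data of fold {f}")
        Xtr = np.column_stack([np.ones(train.sum()), X[train]])
        beta, _, _, _ = np.linalg.lstsq(Xtr, y[train], rcond=None)
        yhat = beta[0] + X[test] @ beta[1:]
        preds[test] = yhat
        fold_pcc[f] = _safe_pcc(yhat, y[test])
    pooled = _safe_pcc(preds, y)
    return CvResult(feature_set, seed, folds, fold_assignment, fold_pcc, pooled, preds)


def _safe_pcc(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(stats.pearsonr(a, b)[0])


@dataclass
class DeltaPcc:
    """Gain in CV accuracy from adding one signal to the core predictors."""

    baseline: CvResult
    augmented: CvResult

    @property
    def increase(self) -> float:
        return self.augmented.pooled_pcc - self.baseline.pooled_pcc


def delta_pcc(
    y,
    core_features,
    extra_feature,
    folds: int = 10,
    seed: int = 0,
    label: str = "extra",
) -> DeltaPcc:
    """delta-PCC of one extra signal over the core set, on shared folds."""
    y = np.asarray(y, dtype=float).ravel()
    core = _as_matrix(core_features)
    extra = np.asarray(extra_feature, dtype=float).reshape(len(y), -1)
    assignment = assign_folds(len(y), folds, seed)
    base = cv_predict(y, core, folds, seed, "core", fold_assignment=assignment)
    aug = cv_predict(
        y, np.column_stack([core, extra]), folds, seed, f"core+{label}",
        fold_assignment=assignment,
    )
    return DeltaPcc(base, aug)


def association_report(
    y,
    feature_sets: Mapping[str, "pd.DataFrame | np.ndarray"],
    core: "pd.DataFrame | np.ndarray | None" = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Standalone PCC (and delta-PCC over core, if given) per feature set."""
    rows = []
    for name, X in feature_sets.items():
        res = cv_predict(y, X, folds, seed, name)
        lo, hi = res.ci95
        row = {
            "feature_set": name,
            "pooled_pcc": res.pooled_pcc,
            "mean_fold_pcc": res.mean_fold_pcc,
            "ci_low": lo,
            "ci_high": hi,
        }
        if core is not None:
            row["delta_pcc_vs_core"] = delta_pcc(y, core, _as_matrix(X), folds, seed, name).increase
        rows.append(row)
    return pd.DataFrame(rows)
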