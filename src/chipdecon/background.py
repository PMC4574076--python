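"""Staged OLS decomposition of windowed ChIP-seq signal into bias components.

The model regresses per-window ChIP-seq read counts y on non-binding
predictors added one at a time in a fixed priority order (by default:
mappability, GC-content, DNaseI hypersensitivity, input-DNA control, IgG
control). Stage 0 is the intercept-only model; stage i refits the full OLS
model with the first i predictors. With

    MSE_i = RSS_i / (n - 1)

the percentage of variance attributed to the predictor added at stage i is

    POV_i = 100 * (MSE_{i-1} - MSE_i) / var(y),

where var(y) uses the same (n - 1) denominator, so that the per-predictor
POVs telescope exactly to 100 * R-squared of the full model. Each predictor
is thus credited only with what it explains beyond all earlier predictors —
the device that untangles correlated biases (unmappable regions, for
instance, force every read-count predictor to zero simultaneously).

The fitted full model predicts the non-binding ("background") component of
the signal in any window; subtracting it from observed counts yields the
purified binding estimate used for peak scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import BinaryTrack, ChromSizes, WindowGrid, WindowVector, make_window_grid, track_fraction
from .reads import ReadSet, count_reads

#: Priority order in which predictors enter the staged model.
DEFAULT_ORDER = ("mappability", "gc", "dnase", "idna", "igg")

#: POVs may be negative only by numerical round-off; anything below this
#: indicates an internal inconsistency (RSS cannot grow when adding a column).
POV_TOLERANCE = -1e-8


@dataclass
class StageFit:
    """OLS fit after adding the stage's predictor (all coefficients refit)."""

    stage: int
    params: np.ndarray  # intercept first, then predictors 1..stage
    mse: float


class BackgroundModel:
    """Staged OLS model of windowed signal against ordered bias predictors.

    Parameters
    ----------
    endog : array-like
        Per-window response (read counts), length n.
    exog : mapping of str -> array-like
        Ordered named predictor columns, each length n. Insertion order is
        the staging order.
    grid : WindowGrid, optional
        The tiling the vectors live on; recorded for width checks.
    """

    def __init__(
        self,
        endog,
        exog: Mapping[str, np.ndarray],
        grid: WindowGrid | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog_names = tuple(exog)
        if not self.exog_names:
            raise ValueError("at least one predictor is required")
        cols = [np.asarray(exog[k], dtype=float).ravel() for k in self.exog_names]
        n = len(self.endog)
        for name, c in zip(self.exog_names, cols):
            if len(c) != n:
                raise ValueError(f"predictor {name!r} has length {len(c)} != {n}")
        self.exog = np.column_stack(cols)
        if n < self.exog.shape[1] + 2:
            raise ValueError(f"too few windows (n={n}) for {self.exog.shape[1]} predictors")
        self.grid = grid

    @classmethod
    def from_window_vectors(
        cls, y: WindowVector, predictors: Mapping[str, WindowVector]
    ) -> "BackgroundModel":
        for name, v in predictors.items():
            if v.grid is not y.grid and v.grid != y.grid:
                raise ValueError(f"predictor {name!r} is on a different window grid")
        return cls(y.values, {k: v.values for k, v in predictors.items()}, grid=y.grid)

    def fit(self) -> "BackgroundModelResults":
        """Fit all stages and compute the POV decomposition."""
        y = self.endog
        n = len(y)
        var_y = float(np.var(y, ddof=1))
        if var_y == 0:
            raise ValueError("degenerate regressand: var(y) = 0")

        stages: list[StageFit] = [StageFit(0, np.array([y.mean()]), var_y)]
        mse = [var_y]
        for i in range(1, len(self.exog_names) + 1):
            X = np.column_stack([np.ones(n), self.exog[:, :i]])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            stages.append(StageFit(i, beta, rss / (n - 1)))
            mse.append(rss / (n - 1))

        pov = 100.0 * (np.array(mse[:-1]) - np.array(mse[1:])) / var_y
        if (pov < POV_TOLERANCE).any():
            worst = self.exog_names[int(np.argmin(pov))]
            raise RuntimeError(
                f"internal inconsistency: POV for {worst!r} = {pov.min():.3e} < {POV_TOLERANCE}"
            )
        return BackgroundModelResults(self, stages, np.array(mse), pov, var_y)


class BackgroundModelResults:
    """Fitted staged decomposition: coefficients, MSE path, POV accounting."""

    def __init__(
        self,
        model: BackgroundModel,
        stages: list[StageFit],
        mse_path: np.ndarray,
        pov_values: np.ndarray,
        var_y: float,
    ):
        self.model = model
        self.stages = stages
        self.mse_path = mse_path
        self._pov = pov_values
        self.var_y = var_y
        self.nobs = len(model.endog)

    # -- headline quantities ------------------------------------------------

    @property
    def pov(self) -> pd.Series:
        """Percentage of variance credited to each predictor at its stage."""
        return pd.Series(self._pov, index=list(self.model.exog_names), name="POV")

    @property
    def total_pov(self) -> float:
        """Sum of per-stage POVs = 100 * R-squared of the full model."""
        return float(100.0 * (self.mse_path[0] - self.mse_path[-1]) / self.var_y)

    @property
    def rsquared(self) -> float:
        return self.total_pov / 100.0

    @property
    def params(self) -> pd.Series:
        """Final-stage coefficients (intercept first)."""
        return pd.Series(
            self.stages[-1].params,
            index=["intercept", *self.model.exog_names],
            name="coef",
        )

    @property
    def bse(self) -> pd.Series:
        """Standard errors of the final-stage coefficients (OLS, homoskedastic)."""
        n = self.nobs
        X = np.column_stack([np.ones(n), self.model.exog])
        p = X.shape[1]
        resid = self.model.endog - X @ self.stages[-1].params
        s2 = float(resid @ resid) / (n - p)
        xtx_inv = np.linalg.pinv(X.T @ X)
        return pd.Series(
            np.sqrt(np.clip(s2 * np.diag(xtx_inv), 0, None)),
            index=["intercept", *self.model.exog_names],
            name="se",
        )

    @property
    def width(self) -> int | None:
        return self.model.grid.width if self.model.grid is not None else None

    # -- prediction ---------------------------------------------------------

    def predict(
        self,
        exog: Mapping[str, np.ndarray] | np.ndarray | None = None,
        round_to_int: bool = False,
    ) -> np.ndarray:
        """Background prediction y-hat = X @ beta from the final stage.

        ``exog`` may be a mapping of predictor name -> values (all training
        predictors required, order enforced by name) or a 2-D array with
        columns in training order. Predictions are real-valued and may be
        negative; ``round_to_int`` rounds for display alongside integer
        counts.
        """
        if exog is None:
            X = self.model.exog
        elif isinstance(exog, Mapping):
            missing = [k for k in self.model.exog_names if k not in exog]
            if missing:
                raise ValueError(f"missing predictors: {missing}")
            X = np.column_stack([np.asarray(exog[k], dtype=float) for k in self.model.exog_names])
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X.reshape(-1, 1)
            if X.shape[1] != len(self.model.exog_names):
                raise ValueError(
                    f"feature matrix has {X.shape[1]} columns, model expects "
                    f"{len(self.model.exog_names)}"
                )
        beta = self.stages[-1].params
        yhat = beta[0] + X @ beta[1:]
        return np.rint(yhat) if round_to_int else yhat

    # -- reporting ----------------------------------------------------------

    def pov_table(self, clip_negative: bool = True) -> pd.DataFrame:
        pov = self._pov.copy()
        if clip_negative:
            pov = np.clip(pov, 0.0, None)
        return pd.DataFrame(
            {
                "predictor": list(self.model.exog_names),
                "stage": np.arange(1, len(pov) + 1),
                "pov": pov,
                "mse": self.mse_path[1:],
            }
        )

    def summary(self) -> str:
        lines = [
            "Staged background decomposition of windowed signal",
            "=" * 58,
            f"windows (n):       {self.nobs}",
            f"window width:      {self.width if self.width is not None else 'n/a'}",
            f"var(y) [ddof=1]:   {self.var_y:.6g}",
            f"total POV:         {self.total_pov:.4f} %  (= 100 x R^2)",
            "-" * 58,
            f"{'predictor':<14}{'POV %':>10}{'coef':>12}{'se':>12}",
        ]
        bse = self.bse
        for name, p in zip(self.model.exog_names, np.clip(self._pov, 0, None)):
            lines.append(
                f"{name:<14}{p:>10.4f}{self.params[name]:>12.5g}{bse[name]:>12.3g}"
            )
        lines.append("-" * 58)
        lines.append(f"{'intercept':<14}{'':>10}{self.params['intercept']:>12.5g}{bse['intercept']:>12.3g}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "predictor_order": list(self.model.exog_names),
            "stages": [
                {"stage": s.stage, "params": s.params.tolist(), "mse": s.mse}
                for s in self.stages
            ],
            "pov": self._pov.tolist(),
            "total_pov": self.total_pov,
            "var_y": self.var_y,
            "nobs": self.nobs,
            "window_width": self.width,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# assembling designs from raw genomic inputs


def window_design(
    grid: WindowGrid,
    tracks: Mapping[str, BinaryTrack],
    control_reads: Mapping[str, ReadSet],
    order: Sequence[str] = DEFAULT_ORDER,
) -> dict[str, np.ndarray]:
    """Per-window predictor columns in staging order.

    Track predictors become per-window 1-base fractions; read-set predictors
    become per-window 5' counts.
    """
    design: dict[str, np.ndarray] = {}
    for name in order:
        if name in tracks:
            design[name] = track_fraction(tracks[name], grid).values
        elif name in control_reads:
            design[name] = count_reads(control_reads[name], grid).values
        else:
            raise KeyError(f"predictor {name!r} found in neither tracks nor control reads")
    return design


def decompose_windows(
    chip_reads: ReadSet,
    tracks: Mapping[str, BinaryTrack],
    control_reads: Mapping[str, ReadSet],
    sizes: ChromSizes,
    width: int = 129,
    exclude: Sequence[str] = ("chrY",),
    order: Sequence[str] = DEFAULT_ORDER,
) -> BackgroundModelResults:
    """Tile, count, and fit the staged decomposition at one window width."""
    grid = make_window_grid(sizes, width, exclude)
    if grid.n_total == 0:
        raise ValueError(f"window width {width} exceeds every chromosome length")
    y = count_reads(chip_reads, grid)
    design = window_design(grid, tracks, control_reads, order)
    return BackgroundModel(y.values, design, grid=grid).fit()


def multiscale_decompose(
    chip_reads: ReadSet,
    tracks: Mapping[str, BinaryTrack],
    control_reads: Mapping[str, ReadSet],
    sizes: ChromSizes,
    k_range: Sequence[int] = tuple(range(7, 21)),
    exclude: Sequence[str] = ("chrY",),
    order: Sequence[str] = DEFAULT_ORDER,
) -> dict[int, BackgroundModelResults]:
    """Re-tile and refit at widths 2**k + 1 for each k; keyed by width.

    Each scale re-counts from the base-pair level — windows at different
    widths do not nest (2**k + 1 is odd), so no cross-scale aggregation is
    possible.
    """
    if not k_range:
        raise ValueError("k_range must be non-empty")
    out: dict[int, BackgroundModelResults] = {}
    for k in sorted(k_range):
        width = 2**k + 1
        out[width] = decompose_windows(
            chip_reads, tracks, control_reads, sizes, width=width,
            exclude=exclude, order=order,
        )
    return out


def multiscale_table(results: Mapping[int, BackgroundModelResults]) -> pd.DataFrame:
    """Long-format (width, predictor, pov, total_pov) table across scales."""
    rows = []
    for width, res in results.items():
        for name, p in res.pov.items():
            rows.append(
                {"width": width, "predictor": name, "pov": max(p, 0.0),
                 "total_pov": res.total_pov}
            )
    return pd.DataFrame(rows)
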