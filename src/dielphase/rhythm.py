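"""Single-cell reporter rhythm quantification.

Traces are YFP fluorescence of single cells carrying a clock-output promoter
fusion (e.g. the sigC promoter, a prototypical dusk-peaking Class I promoter),
tracked for up to 72 h under continuous light after entrainment. Each trace is
detrended and fitted with a cosinor (intercept + cosine + sine) over a grid of
candidate periods; the residual-minimizing period is reported, and a cell is
called rhythmic when the cosinor F-test survives a multiplicity correction for
the period search and the fitted amplitude is non-negligible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

DEFAULT_PERIOD_GRID = (16.0, 32.0)
DEFAULT_GRID_STEP = 0.05
MIN_DETREND_POINTS = 10


@dataclass
class TraceSet:
    """Per-cell fluorescence time series in long form.

    ``data`` has columns ``cell_id``, ``time_h``, ``fluorescence``; times are
    strictly increasing within each cell.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"cell_id", "time_h", "fluorescence"}
        if not req.issubset(self.data.columns):
            raise InvalidInputError(f"trace table must have columns {sorted(req)}")
        for cid, grp in self.data.groupby("cell_id", sort=False):
            if not np.all(np.diff(grp["time_h"].to_numpy(float)) > 0):
                raise InvalidInputError(f"times not strictly increasing for cell {cid!r}")

    @property
    def cell_ids(self) -> list:
        return list(dict.fromkeys(self.data["cell_id"]))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        grp = self.data[self.data["cell_id"] == cell_id]
        return grp["time_h"].to_numpy(float), grp["fluorescence"].to_numpy(float)

    def common_grid(self) -> np.ndarray | None:
        """Shared time grid if every cell was sampled identically, else None."""
        grids = [g["time_h"].to_numpy(float) for _, g in self.data.groupby("cell_id", sort=False)]
        first = grids[0]
        if all(len(g) == len(first) and np.allclose(g, first) for g in grids[1:]):
            return first
        return None

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, columns=["cell_id", "time_h", "fluorescence"])

    @classmethod
    def from_csv(cls, path) -> "TraceSet":
        return cls(data=pd.read_csv(path))


@dataclass
class CellRhythm:
    """Cosinor fit summary for one cell."""

    period_h: float
    amplitude: float
    phase_h: float
    rhythmic: bool
    pvalue: float        # grid-search-corrected cosinor p


@dataclass
class PopulationRhythm:
    """Population summary across cells (rhythmic cells only for period stats)."""

    per_cell: pd.DataFrame
    mean_period: float
    sd_period: float
    fraction_rhythmic: float
    amplitude_fold: float | None = None
    arrhythmic_population: bool = False

    def to_json_dict(self) -> dict:
        out = {
            "n_cells": int(len(self.per_cell)),
            "mean_period_h": None if math.isnan(self.mean_period) else self.mean_period,
            "sd_period_h": None if math.isnan(self.sd_period) else self.sd_period,
            "fraction_rhythmic": self.fraction_rhythmic,
            "arrhythmic_population": self.arrhythmic_population,
        }
        if self.amplitude_fold is not None:
            out["amplitude_fold"] = self.amplitude_fold
        return out


def detrend_trace(time_h: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (drift/bleaching) from a trace."""
    t = np.asarray(time_h, float)
    y = np.asarray(y, float)
    if len(t) < MIN_DETREND_POINTS:
        raise InvalidInputError(f"detrending needs at least {MIN_DETREND_POINTS} points")
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _period_grid(span_h: float, grid: tuple[float, float], step: float, dt: float) -> np.ndarray:
    lo, hi = grid
    if not (hi > lo > 0 and step > 0):
        raise InvalidInputError("period grid must satisfy 0 < lo < hi with positive step")
    periods = np.arange(lo, hi + step / 2.0, step)
    # need >= 2 cycles in span, and sampling below the Nyquist limit
    periods = periods[(periods <= span_h / 2.0) & (periods > 2.0 * dt)]
    if len(periods) == 0:
        raise InvalidInputError(
            "no candidate period admits two full cycles at this trace span/sampling"
        )
    return periods


def _n_effective_frequencies(n_periods: int) -> int:
    """Bonferroni factor for the period grid search.

    The minimum F-test p over the scanned grid is corrected by the full grid
    size. This is conservative (neighbouring grid periods are correlated) but
    a null pilot showed that counting only the independent Fourier
    frequencies in the band under-corrects (~2% false positives at the 1%
    level); circadian-strength signals yield p-values many orders below the
    corrected threshold, so the power cost is negligible.
    """
    return max(1, n_periods)


def _cosinor_scan(t: np.ndarray, Y: np.ndarray, periods: np.ndarray):
    """Fit intercept + trend + cosine + sine at every grid period.

    The linear drift term is estimated jointly with the oscillation —
    detrending first and fitting after biases the period whenever the cosine
    has a nonzero covariance with time over the finite window. Returns
    (best_idx, rss_best, beta_best, rss_null) where beta rows are
    (intercept, trend, cos, sin) and rss_null is the residual sum of squares
    of the trend-only model.
    """
    n, m = Y.shape
    X0 = np.column_stack([np.ones_like(t), t])
    beta0, *_ = np.linalg.lstsq(X0, Y, rcond=None)
    resid0 = Y - X0 @ beta0
    rss_null = np.sum(resid0 * resid0, axis=0)
    best_rss = np.full(m, np.inf)
    best_idx = np.zeros(m, dtype=int)
    best_beta = np.zeros((4, m))
    for k, period in enumerate(periods):
        w = 2.0 * np.pi / period
        X = np.column_stack([np.ones_like(t), t, np.cos(w * t), np.sin(w * t)])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        rss = np.sum(resid * resid, axis=0)
        better = rss < best_rss
        best_rss[better] = rss[better]
        best_idx[better] = k
        best_beta[:, better] = beta[:, better]
    return best_idx, best_rss, best_beta, rss_null


def _call_cells(
    t: np.ndarray,
    Y: np.ndarray,
    grid: tuple[float, float],
    step: float,
    alpha: float,
    min_rel_amplitude: float,
) -> pd.DataFrame:
    span = float(t[-1] - t[0])
    dt = float(np.median(np.diff(t)))
    periods = _period_grid(span, grid, step, dt)
    m_eff = _n_effective_frequencies(len(periods))
    n = len(t)
    if n < MIN_DETREND_POINTS:
        raise InvalidInputError("too few samples for a cosinor fit")
    best_idx, rss, beta, rss_null = _cosinor_scan(t, Y, periods)
    amp = np.hypot(beta[2], beta[3])
    w = 2.0 * np.pi / periods[best_idx]
    phase = np.mod(np.arctan2(beta[3], beta[2]), 2.0 * np.pi) / w
    df_resid = n - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_null - rss) / 2.0) / (rss / df_resid)
    p = np.where(np.isfinite(F), stats.f.sf(F, 2, df_resid), 0.0)
    p_adj = np.minimum(1.0, p * m_eff)
    detrended_sd = np.sqrt(rss_null / n)
    rhythmic = (p_adj < alpha) & (amp >= min_rel_amplitude * np.maximum(detrended_sd, 1e-300))
    return pd.DataFrame(
        {
            "period_h": periods[best_idx],
            "amplitude": amp,
            "phase_h": phase,
            "rhythmic": rhythmic,
            "pvalue": p_adj,
        }
    )


def estimate_period(
    time_h: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, float] = DEFAULT_PERIOD_GRID,
    step: float = DEFAULT_GRID_STEP,
    alpha: float = 0.01,
    min_rel_amplitude: float = 0.05,
) -> CellRhythm:
    """Period/amplitude/phase of a single trace by cosinor grid search.

    For each candidate period in ``grid`` (restricted so at least two full
    cycles fit in the trace span) an intercept + linear-trend + cosine + sine
    model is fitted by least squares; the residual-minimizing period wins.
    The rhythmicity call requires the cosinor F-test p (against the
    trend-only model), Bonferroni-corrected for the period grid search, to
    fall below ``alpha``, and the amplitude to reach ``min_rel_amplitude`` of
    the detrended-trace SD.
    """
    t = np.asarray(time_h, float)
    y = np.asarray(y, float)
    if len(t) < MIN_DETREND_POINTS:
        raise InvalidInputError(f"period estimation needs at least {MIN_DETREND_POINTS} points")
    row = _call_cells(t, y[:, None], grid, step, alpha, min_rel_amplitude).iloc[0]
    return CellRhythm(
        period_h=float(row["period_h"]),
        amplitude=float(row["amplitude"]),
        phase_h=float(row["phase_h"]),
        rhythmic=bool(row["rhythmic"]),
        pvalue=float(row["pvalue"]),
    )


def population_rhythm(
    ts: TraceSet,
    ref: TraceSet | None = None,
    grid: tuple[float, float] = DEFAULT_PERIOD_GRID,
    step: float = DEFAULT_GRID_STEP,
    alpha: float = 0.01,
    min_rel_amplitude: float = 0.05,
    min_span_h: float = 48.0,
) -> PopulationRhythm:
    """Per-cell rhythm calls plus population period mean/SD and amplitude fold.

    Cells tracked for less than ``min_span_h`` (two circadian cycles) are
    excluded. Period statistics are computed over rhythmic cells only; if no
    cell is rhythmic the population is flagged arrhythmic. With a reference
    set, ``amplitude_fold`` is the ratio of median fitted amplitudes
    (rhythmic cells where available, otherwise all cells).
    """
    per_cell = _per_cell_table(ts, grid, step, alpha, min_rel_amplitude, min_span_h)
    if len(per_cell) < 3:
        raise InvalidInputError("population summaries need at least 3 sufficiently long cells")
    rhythmic = per_cell[per_cell["rhythmic"]]
    frac = float(len(rhythmic) / len(per_cell))
    if len(rhythmic) == 0:
        mean_p, sd_p, arrhythmic = float("nan"), float("nan"), True
    else:
        mean_p = float(rhythmic["period_h"].mean())
        sd_p = float(rhythmic["period_h"].std(ddof=1)) if len(rhythmic) > 1 else 0.0
        arrhythmic = False
    fold = None
    if ref is not None:
        ref_cells = _per_cell_table(ref, grid, step, alpha, min_rel_amplitude, min_span_h)
        fold = float(_median_amplitude(per_cell) / _median_amplitude(ref_cells))
    return PopulationRhythm(
        per_cell=per_cell,
        mean_period=mean_p,
        sd_period=sd_p,
        fraction_rhythmic=frac,
        amplitude_fold=fold,
        arrhythmic_population=arrhythmic,
    )


def _median_amplitude(per_cell: pd.DataFrame) -> float:
    sub = per_cell[per_cell["rhythmic"]]
    if len(sub) == 0:
        sub = per_cell
    return float(sub["amplitude"].median())


def _per_cell_table(
    ts: TraceSet,
    grid: tuple[float, float],
    step: float,
    alpha: float,
    min_rel_amplitude: float,
    min_span_h: float,
) -> pd.DataFrame:
    common = ts.common_grid()
    rows: list[pd.DataFrame] = []
    if common is not None and common[-1] - common[0] >= min_span_h:
        t = common
        Y = np.column_stack([ts.cell(cid)[1] for cid in ts.cell_ids])
        table = _call_cells(t, Y, grid, step, alpha, min_rel_amplitude)
        table.insert(0, "cell_id", ts.cell_ids)
        return table
    for cid in ts.cell_ids:
        t, y = ts.cell(cid)
        if t[-1] - t[0] < min_span_h:
            continue
        r = estimate_period(t, y, grid, step, alpha, min_rel_amplitude)
        rows.append(
            pd.DataFrame(
                [
                    {
                        "cell_id": cid,
                        "period_h": r.period_h,
                        "amplitude": r.amplitude,
                        "phase_h": r.phase_h,
                        "rhythmic": r.rhythmic,
                        "pvalue": r.pvalue,
                    }
                ]
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["cell_id", "period_h", "amplitude", "phase_h", "rhythmic", "pvalue"]
        )
    return pd.concat(rows, ignore_index=True)
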