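"""Growth kinetics from OD720 time series.

Cyanobacterial growth is tracked as optical density at 720 nm (a turbidity
proxy outside the pigment absorption bands). The effective growth rate K' is
the slope of ln(OD720) against time in the early exponential phase, and the
doubling time is ln(2)/K'. Serial-passage experiments additionally account
generations per iteration as n = log2(OD_f) - log2(OD_i).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NoExponentialPhaseError, NonPositiveGrowthError

MIN_FIT_POINTS = 5


@dataclass
class GrowthCurve:
    """An OD720 time series with optional condition metadata."""

    time: np.ndarray
    od720: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od720 = np.asarray(self.od720, dtype=float)
        if self.time.shape != self.od720.shape or self.time.ndim != 1:
            raise InvalidInputError("time and od720 must be 1-d arrays of equal length")
        if len(self.time) and not np.all(np.diff(self.time) > 0):
            raise InvalidInputError("time must be strictly increasing")
        if np.any(self.od720 < 0):
            raise InvalidInputError("od720 values must be nonnegative")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.time, "od720": self.od720}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        for col in ("time_h", "od720"):
            if col not in df.columns:
                raise InvalidInputError(f"{path}: missing required column {col!r}")
        return cls(time=df["time_h"].to_numpy(float), od720=df["od720"].to_numpy(float))


@dataclass
class GrowthFit:
    """Least-squares fit of ln(OD720) over the selected exponential window."""

    kprime: float                 # per hour
    doubling_time: float          # hours, ln(2)/kprime
    window: tuple[float, float]   # [t_start, t_end] of the fitted points
    r_squared: float
    n_points: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kprime": self.kprime,
                    "doubling_time_h": self.doubling_time,
                    "window": list(self.window),
                    "r2": self.r_squared,
                    "n_points": self.n_points,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _window_scan(t: np.ndarray, y: np.ndarray, runs, min_points: int, r2_min: float):
    """Best log-linear window among all contiguous sub-windows of the runs.

    Returns (i, j, slope, intercept, r2) of the longest window with R^2 >=
    r2_min (ties broken by earliest start), or None. Prefix sums make each
    window O(1).
    """
    z = np.zeros(len(t) + 1)
    St = np.concatenate(([0.0], np.cumsum(t)))
    Sy = np.concatenate(([0.0], np.cumsum(y)))
    Stt = np.concatenate(([0.0], np.cumsum(t * t)))
    Sty = np.concatenate(([0.0], np.cumsum(t * y)))
    Syy = np.concatenate(([0.0], np.cumsum(y * y)))
    del z
    best = None  # (length, -start, i, j, slope, intercept, r2)
    for lo, hi in runs:  # hi exclusive
        for i in range(lo, hi - min_points + 1):
            for j in range(i + min_points - 1, hi):
                n = j - i + 1
                st = St[j + 1] - St[i]
                sy = Sy[j + 1] - Sy[i]
                stt = Stt[j + 1] - Stt[i]
                sty = Sty[j + 1] - Sty[i]
                syy = Syy[j + 1] - Syy[i]
                sxx = stt - st * st / n
                sxy = sty - st * sy / n
                syy_c = syy - sy * sy / n
                if sxx <= 0:
                    continue
                slope = sxy / sxx
                if syy_c <= max(1e-300, 1e-14 * abs(syy)):
                    r2 = 1.0  # flat window: zero residual, zero variance
                else:
                    r2 = min(1.0, max(0.0, slope * sxy / syy_c))
                if r2 < r2_min:
                    continue
                key = (n, -i)
                if best is None or key > best[:2]:
                    intercept = (sy - slope * st) / n
                    best = (n, -i, i, j, slope, intercept, r2)
    if best is None:
        return None
    _, _, i, j, slope, intercept, r2 = best
    return i, j, slope, intercept, r2


def fit_growth_rate(
    curve: GrowthCurve,
    r2_min: float = 0.99,
    min_points: int = MIN_FIT_POINTS,
) -> GrowthFit:
    """Estimate K' as the slope of ln(OD720) in the early exponential phase.

    The "early exponential phase" is selected objectively: among all contiguous
    windows of >= ``min_points`` points whose OD lies between 2*min(OD) and
    0.5*max(OD), the windows with log-linear R^2 >= ``r2_min`` are kept and the
    longest (earliest on ties) is fitted. Curves spanning fewer than two net
    doublings (where that band is empty) are fitted over all points.

    Raises
    ------
    NoExponentialPhaseError : no candidate window reaches ``r2_min``.
    NonPositiveGrowthError : the selected window has slope <= 0.
    """
    keep = curve.od720 > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} nonpositive OD720 points before log transform",
            stacklevel=2,
        )
    t = curve.time[keep]
    od = curve.od720[keep]
    if len(t) < min_points:
        raise InvalidInputError(f"need at least {min_points} positive OD points to fit")
    y = np.log(od)

    lo_od, hi_od = 2.0 * od.min(), 0.5 * od.max()
    elig = (od >= lo_od) & (od <= hi_od)
    runs: list[tuple[int, int]] = []
    start = None
    for k, flag in enumerate(elig):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            if k - start >= min_points:
                runs.append((start, k))
            start = None
    if start is not None and len(elig) - start >= min_points:
        runs.append((start, len(elig)))
    if not runs:
        if od.max() < 4.0 * od.min():
            runs = [(0, len(t))]  # under two net doublings: use the whole curve
        else:
            raise NoExponentialPhaseError(
                "no contiguous window of sufficient length inside the exponential OD band"
            )

    hit = _window_scan(t, y, runs, min_points, r2_min)
    if hit is None:
        raise NoExponentialPhaseError(
            f"no candidate window reaches log-linear R^2 >= {r2_min}"
        )
    i, j, slope, _, r2 = hit
    if slope <= 1e-12:  # flat to numerical precision counts as no growth
        raise NonPositiveGrowthError(f"fitted K' = {slope:.4g} per hour is not positive")
    return GrowthFit(
        kprime=float(slope),
        doubling_time=doubling_time(slope),
        window=(float(t[i]), float(t[j])),
        r_squared=float(r2),
        n_points=int(j - i + 1),
    )


def doubling_time(kprime: float) -> float:
    """Doubling time ln(2)/K' in hours; K' must be positive."""
    if not kprime > 0:
        raise InvalidInputError(f"doubling time undefined for K' = {kprime}")
    return float(np.log(2.0) / kprime)


def _kprime_of(fit) -> float:
    return float(fit.kprime) if hasattr(fit, "kprime") else float(fit)


def percent_rate_increase(fit_test, fit_ref) -> float:
    """Growth-rate increase of test over reference, as 100*(K'_test/K'_ref - 1)."""
    k_test, k_ref = _kprime_of(fit_test), _kprime_of(fit_ref)
    if not k_ref > 0:
        raise InvalidInputError("reference K' must be positive")
    if not k_test > 0:
        raise InvalidInputError("test K' must be positive")
    return 100.0 * (k_test / k_ref - 1.0)


def generations(od_i: float, od_f: float) -> float:
    """Generations in one passage, n = log2(od_f) - log2(od_i).

    A negative value (culture shrank) is returned with a warning.
    """
    if not (od_i > 0 and od_f > 0):
        raise InvalidInputError("OD values must be positive")
    n = float(np.log2(od_f) - np.log2(od_i))
    if n < 0:
        warnings.warn(f"od_f < od_i: negative generation count {n:.3f}", stacklevel=2)
    return n


@dataclass
class PassageLog:
    """Serial-passage bookkeeping: per-iteration (OD_i, OD_f) pairs."""

    passages: list[tuple[float, float]] = field(default_factory=list)

    def add(self, od_i: float, od_f: float) -> float:
        n = generations(od_i, od_f)
        self.passages.append((float(od_i), float(od_f)))
        return n

    @property
    def per_iteration(self) -> list[float]:
        return [float(np.log2(f) - np.log2(i)) for i, f in self.passages]

    @property
    def cumulative_generations(self) -> float:
        return float(sum(self.per_iteration))
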