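"""Shared containers: uniformly sampled series and log-log scaling fits.

Every estimator in this package reduces to the same primitive: a set of
(scale, measure) pairs regressed on log-log axes, whose slope is the scaling
exponent.  :class:`ScalingFit` keeps the points together with the fitted
range so that scaling-range selection and diagnostics stay inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeSeries",
    "ScalingFit",
    "DegenerateSignalError",
    "loglog_fit",
    "log_spaced_windows",
    "moment_average",
]

MIN_SERIES_LENGTH = 8


class DegenerateSignalError(ValueError):
    """The signal has no fluctuation to measure (e.g. constant input)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    values : array-like
        The samples. Must be finite and at least 8 long for any analysis.
    dt : float
        Sampling interval in seconds (> 0).
    label : str
        Free-text identifier carried through reports.
    """

    values: np.ndarray
    dt: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if vals.size < MIN_SERIES_LENGTH:
            raise ValueError(
                f"series too short: {vals.size} < {MIN_SERIES_LENGTH}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("series contains non-finite values")
        if not (self.dt > 0):
            raise ValueError("sampling interval dt must be positive")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(values, dt=self.dt, label=self.label if label is None else label)


@dataclass(frozen=True)
class ScalingFit:
    """An OLS fit of log10(measure) against log10(scale).

    ``lo``/``hi`` delimit the half-open index range actually fitted; points
    outside it are retained for plotting and for scaling-range re-selection.
    """

    log_scales: np.ndarray
    log_measures: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    lo: int
    hi: int

    @property
    def n_points(self) -> int:
        return self.hi - self.lo

    def refit(self, lo: int, hi: int) -> "ScalingFit":
        return loglog_fit(
            10.0 ** self.log_scales, 10.0 ** self.log_measures, lo=lo, hi=hi
        )

    def to_dict(self) -> dict:
        return {
            "log_scales": self.log_scales.tolist(),
            "log_measures": self.log_measures.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "fit_range": [self.lo, self.hi],
        }


def loglog_fit(
    scales: np.ndarray,
    measures: np.ndarray,
    lo: int = 0,
    hi: int | None = None,
) -> ScalingFit:
    """Ordinary least squares on log10-log10 points, one point per scale.

    Non-positive measures are invalid on log axes and raise; callers are
    expected to have excluded degenerate scales beforehand.
    """
    scales = np.asarray(scales, dtype=float)
    measures = np.asarray(measures, dtype=float)
    if scales.shape != measures.shape or scales.ndim != 1:
        raise ValueError("scales and measures must be 1-d arrays of equal length")
    if hi is None:
        hi = scales.size
    if hi - lo < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if np.any(scales <= 0) or np.any(measures[lo:hi] <= 0):
        raise ValueError("non-positive values cannot be fitted on log-log axes")
    lx = np.log10(scales)
    ly = np.log10(measures)
    x, y = lx[lo:hi], ly[lo:hi]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScalingFit(lx, ly, float(slope), float(intercept), float(r2), lo, hi)


def log_spaced_windows(
    n: int,
    min_size: int = 4,
    max_size: int | None = None,
    n_sizes: int = 20,
) -> np.ndarray:
    """Log-spaced integer window sizes in [min_size, max_size].

    Defaults follow the common practice of capping scales at N/4; duplicates
    after rounding are dropped, so fewer than ``n_sizes`` values may return.
    """
    if max_size is None:
        max_size = n // 4
    if max_size < min_size:
        raise ValueError(
            f"cannot build window grid: max {max_size} < min {min_size}"
        )
    grid = np.unique(
        np.round(
            np.logspace(np.log10(min_size), np.log10(max_size), n_sizes)
        ).astype(int)
    )
    return grid[(grid >= min_size) & (grid <= max_size)]


def moment_average(fv: np.ndarray, q: np.ndarray) -> np.ndarray:
    """q-th order moment average F_q = (mean F_v^q)^(1/q) of per-window
    fluctuations, with the q = 0 entry as the log-average limit
    exp(mean log F_v).

    Evaluated in log space so extreme moments (|q| ~ 15) neither overflow
    nor underflow.  Zero windows would blow up negative moments and are
    excluded with a warning; monofractal DFA and its multifractal
    generalization share this exact code path, so they agree to the last
    bit at q = 2.
    """
    import warnings

    fv = np.asarray(fv, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(fv == 0):
        n_zero = int(np.count_nonzero(fv == 0))
        warnings.warn(
            f"excluding {n_zero} zero-fluctuation window(s) from the "
            "moment average", RuntimeWarning, stacklevel=3,
        )
        fv = fv[fv > 0]
    if fv.size == 0:
        raise DegenerateSignalError("no windows with non-zero fluctuation")
    out = np.empty(q.size)
    log_fv = np.log(fv)
    for i, qi in enumerate(q):
        if qi == 0.0:
            out[i] = np.exp(np.mean(log_fv))
        else:
            m = qi * log_fv
            mx = m.max()
            out[i] = np.exp((mx + np.log(np.mean(np.exp(m - mx)))) / qi)
    return out
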