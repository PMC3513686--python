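"""Monofractal estimators and the fGn/fBm exponent algebra.

A single scale-free signal can be a stationary fractional Gaussian noise
(fGn, Hurst exponent H in (0,1)) or a non-stationary fractional Brownian
motion (fBm, the cumulative sum of an fGn).  Every estimator here measures
a power-law scaling exponent (alpha, H, or beta) that maps onto the
*extended* Hurst exponent H' — H for fGn, H + 1 for fBm — so results from
different methods and both classes live on one (0, 2) scale with the 1/f
boundary at H' = 1.

Estimators
----------
dfa       detrended fluctuation analysis (class-independent, alpha = H')
swv       scaled windowed variance, raw / line- / bridge-detrended (fBm only)
ssc       signal summation conversion: cumulative sum + bdSWV (classifier)
psd_low   windowed, endmatched power spectrum fitted on low frequencies
disp      dispersional analysis (fGn only)
awc       averaged wavelet coefficient (fBm only)
fa_raw    non-detrended fluctuation analysis on the summed profile
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateSignalError,
    ScalingFit,
    TimeSeries,
    log_spaced_windows,
    loglog_fit,
    moment_average,
)

__all__ = [
    "DegenerateSignalError",
    "ClassMismatchError",
    "SignalClass",
    "MonofractalResult",
    "PowerSpectrum",
    "DEFAULT_BOUNDARY_BAND",
    "classify_hurst_prime",
    "preprocess",
    "autocovariance",
    "dfa",
    "swv",
    "ssc",
    "psd_low",
    "disp",
    "awc",
    "fa_raw",
    "convert_exponents",
]


class ClassMismatchError(ValueError):
    """A class-dependent estimator was applied to the wrong signal class."""


DEFAULT_BOUNDARY_BAND = (0.9, 1.1)


@dataclass(frozen=True)
class SignalClass:
    """Dichotomous class label: 'fGn', 'fBm', or 'boundary' when the
    estimate sits inside the configurable band around H' = 1."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in {"fGn", "fBm", "boundary"}:
            raise ValueError(f"invalid signal class {self.value!r}")

    def __str__(self) -> str:
        return self.value


def classify_hurst_prime(
    hurst_prime: float, band: tuple = DEFAULT_BOUNDARY_BAND
) -> SignalClass:
    """Class from H': fGn for H' <= 1, fBm above, 'boundary' inside the band."""
    lo, hi = band
    if lo <= hurst_prime <= hi:
        return SignalClass("boundary")
    return SignalClass("fGn" if hurst_prime <= 1.0 else "fBm")


@dataclass(frozen=True)
class MonofractalResult:
    """One estimator's verdict: raw exponent, H', class, and the log-log fit."""

    method: str
    exponent_name: str
    exponent: float
    hurst_prime: float
    signal_class: SignalClass
    fit: ScalingFit

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "exponent_name": self.exponent_name,
            "exponent": self.exponent,
            "hurst_prime": self.hurst_prime,
            "signal_class": str(self.signal_class),
            "fit": self.fit.to_dict(),
        }


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided periodogram: frequencies in Hz and power A_n^2 (phase
    discarded); the DC bin is excluded before any fitting."""

    frequencies: np.ndarray
    power: np.ndarray


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _endmatch(x: np.ndarray) -> np.ndarray:
    """Subtract the line through the first and last samples (bridge detrend)."""
    n = x.size
    line = x[0] + (x[-1] - x[0]) * np.arange(n) / (n - 1)
    return x - line


def _parabolic_window(n: int) -> np.ndarray:
    """Welch (parabolic) taper, zero at both ends."""
    j = np.arange(n)
    return 1.0 - ((j - (n - 1) / 2) / ((n - 1) / 2)) ** 2


def preprocess(ts: TimeSeries, steps) -> TimeSeries:
    """Apply preprocessing steps in the given order.

    Supported: ``demean``, ``endmatch`` (bridge detrend), ``window``
    (parabolic taper, meant for spectral analysis), ``difference``, ``sum``.
    """
    x = ts.values
    out_dt = ts.dt
    for step in steps:
        if x.size == 0:
            raise ValueError("empty series")
        if step == "demean":
            x = x - x.mean()
        elif step == "endmatch":
            x = _endmatch(x)
        elif step == "window":
            x = x * _parabolic_window(x.size)
        elif step == "difference":
            x = np.diff(x)
        elif step == "sum":
            x = np.cumsum(x)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return TimeSeries(x, dt=out_dt, label=ts.label)


def autocovariance(
    ts: TimeSeries, max_lag: int, normalize: bool = False
) -> np.ndarray:
    """Sample autocovariance C(tau) = (1/(N-tau)) sum I(t) I(t+tau) of the
    demeaned signal for tau = 0..max_lag; normalized by C(0) on request."""
    n = ts.n
    if max_lag >= n // 2:
        raise ValueError(f"max_lag {max_lag} must be < n/2 = {n // 2}")
    x = ts.values - ts.values.mean()
    c = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        c[tau] = np.dot(x[: n - tau], x[tau:]) / (n - tau)
    if normalize:
        if c[0] == 0:
            raise DegenerateSignalError("zero-variance signal")
        c = c / c[0]
    return c


# ---------------------------------------------------------------------------
# windowed fluctuation machinery (shared by DFA / MF-DFA / SWV)
# ---------------------------------------------------------------------------


def _window_view(x: np.ndarray, size: int) -> np.ndarray:
    """Non-overlapping windows of ``size``; the tail remainder is discarded."""
    n_win = x.size // size
    if n_win < 1:
        raise ValueError(f"window size {size} exceeds series length {x.size}")
    return x[: n_win * size].reshape(n_win, size)


def detrended_window_variance(
    x: np.ndarray, size: int, order: int
) -> np.ndarray:
    """Per-window mean squared residual around a local polynomial trend.

    The least-squares fit is solved once per window size through a
    precomputed pseudo-inverse of the Vandermonde design, so all windows of
    one size are detrended in a single matrix product.
    """
    seg = _window_view(x, size)
    t = np.arange(size, dtype=float)
    design = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
    resid = seg.T - design @ coef
    return np.mean(resid**2, axis=0)


def dfa(
    ts: TimeSeries,
    window_sizes: np.ndarray | None = None,
    detrend_order: int = 1,
) -> MonofractalResult:
    """Detrended fluctuation analysis.

    The demeaned signal is cumulatively summed into a profile; in
    non-overlapping windows of each size a polynomial trend (default
    linear) is removed, and F(n) is the RMS residual.  alpha is the log-log
    slope of F(n) vs n; it equals H for fGn input and H + 1 for fBm input,
    i.e. alpha estimates H' directly.
    """
    if window_sizes is None:
        window_sizes = log_spaced_windows(ts.n, min_size=max(4, detrend_order + 2))
    window_sizes = np.asarray(window_sizes, dtype=int)
    if window_sizes.min() < detrend_order + 2:
        raise ValueError("minimum window must be >= detrend_order + 2")
    profile = np.cumsum(ts.values - ts.values.mean())
    fluct = np.empty(window_sizes.size)
    q2 = np.array([2.0])
    for i, size in enumerate(window_sizes):
        fv2 = detrended_window_variance(profile, size, detrend_order)
        if np.all(fv2 == 0):
            raise DegenerateSignalError("zero fluctuation: degenerate signal")
        # shared moment kernel => bit-identical to the multifractal variant
        fluct[i] = moment_average(np.sqrt(fv2), q2)[0]
    fit = loglog_fit(window_sizes, fluct)
    alpha = fit.slope
    return MonofractalResult(
        "dfa", "alpha", alpha, alpha, classify_hurst_prime(alpha), fit
    )


def _swv_sds(x: np.ndarray, size: int, variant: str) -> np.ndarray:
    seg = _window_view(x, size)
    if variant == "bridge":
        t = np.arange(size) / (size - 1)
        seg = seg - (seg[:, :1] + (seg[:, -1:] - seg[:, :1]) * t)
    elif variant == "line":
        t = np.arange(size, dtype=float)
        design = np.vander(t, 2)
        coef, *_ = np.linalg.lstsq(design, seg.T, rcond=None)
        seg = (seg.T - design @ coef).T
    elif variant != "none":
        raise ValueError(f"unknown SWV variant {variant!r}")
    return np.std(seg, axis=1, ddof=1)


def _check_class(known: str | None, invalid: str, method: str) -> None:
    if known is not None and str(known) == invalid:
        raise ClassMismatchError(
            f"{method} is not valid for {invalid}-class input"
        )


def swv(
    ts: TimeSeries,
    variant: str = "bridge",
    window_sizes: np.ndarray | None = None,
    signal_class: str | None = None,
) -> MonofractalResult:
    """Scaled windowed variance on an fBm-class signal.

    The SD within non-overlapping windows of size n (optionally line- or
    bridge-detrended first, per Cannon et al.) is averaged per size; H is
    the log-log slope of SD(n) vs n.  Valid only for fBm or cumulatively
    summed fGn input; pass ``signal_class`` when known and fGn input is
    rejected.
    """
    _check_class(signal_class, "fGn", "SWV")
    if window_sizes is None:
        window_sizes = log_spaced_windows(ts.n, min_size=4)
    window_sizes = np.asarray(window_sizes, dtype=int)
    if window_sizes.min() < 4:
        raise ValueError("SWV window sizes must be >= 4")
    sds = np.array(
        [np.mean(_swv_sds(ts.values, s, variant)) for s in window_sizes]
    )
    # relative floor: exact lines/constants leave only rounding noise
    if np.any(sds <= 1e-10 * max(np.std(ts.values), 1e-300)):
        raise DegenerateSignalError(
            "zero windowed SD: signal is degenerate (e.g. a pure line under "
            "bridge detrending)"
        )
    fit = loglog_fit(window_sizes, sds)
    h = fit.slope
    # SWV measures H of the fBm it was given, so H' = H + 1
    return MonofractalResult(
        "swv-" + variant, "H", h, h + 1.0, classify_hurst_prime(h + 1.0), fit
    )


def ssc(
    ts: TimeSeries,
    window_sizes: np.ndarray | None = None,
    boundary_band: tuple = DEFAULT_BOUNDARY_BAND,
) -> MonofractalResult:
    """Signal summation conversion: the class-independent reference method.

    Cumulatively sum the signal, then run bridge-detrended SWV on the
    cumulant.  The slope is reported as the extended Hurst exponent H':
    values <= 1 identify the input as fGn (H = H'), values > 1 as fBm
    (H = H' - 1); estimates inside the boundary band are flagged.
    """
    cumulant = np.cumsum(ts.values)
    inner = swv(ts.with_values(cumulant), variant="bridge", window_sizes=window_sizes)
    hp = inner.exponent  # slope on the cumulant IS H' of the original signal
    return MonofractalResult(
        "ssc", "H'", hp, hp, classify_hurst_prime(hp, boundary_band), inner.fit
    )


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------


def periodogram(ts: TimeSeries, preprocessed: bool = False) -> PowerSpectrum:
    """One-sided periodogram (DC bin dropped).

    With ``preprocessed=False`` the ^low^PSD_w,e preprocessing is applied
    first, in the order mean subtraction, parabolic taper, endmatching.
    (The taper already zeroes both ends, so endmatching is a near no-op in
    this order; applying it before the taper would inject the spectrum of a
    random line, ~1/f^2, and bias beta upward on weakly correlated signals.)
    """
    work = ts if preprocessed else preprocess(ts, ["demean", "window", "endmatch"])
    amp = np.fft.rfft(work.values)
    power = np.abs(amp) ** 2
    freqs = np.fft.rfftfreq(work.n, d=ts.dt)
    return PowerSpectrum(freqs[1:], power[1:])


def psd_low(
    ts: TimeSeries,
    fit_band: tuple | None = None,
    boundary_band: tuple = DEFAULT_BOUNDARY_BAND,
):
    """Low-frequency power-spectral estimator (^low^PSD_w,e).

    The signal is demeaned, endmatched, and tapered with a parabolic
    window; beta is minus the log-log slope of the periodogram over the fit
    band.  High-frequency estimates carry most of the bias for scale-free
    signals, so the default band runs from the lowest available frequency
    up to one eighth of the Nyquist frequency.  H' = (beta + 1) / 2 on the
    extended scale regardless of class; the class itself is read off beta
    (< 1 fGn, > 1 fBm, boundary inside the band).

    Returns ``(MonofractalResult, PowerSpectrum)``.
    """
    spectrum = periodogram(ts)
    nyquist = 0.5 / ts.dt
    if fit_band is None:
        fit_band = (0.0, nyquist / 8.0)
    f_lo, f_hi = fit_band
    sel = (spectrum.frequencies > f_lo) & (spectrum.frequencies <= f_hi)
    if np.count_nonzero(sel) < 4:
        raise ValueError(
            f"fit band {fit_band} contains fewer than 4 spectral estimates"
        )
    freqs = spectrum.frequencies[sel]
    power = spectrum.power[sel]
    if np.any(power <= 0):
        raise DegenerateSignalError("zero spectral power in the fit band")
    fit = loglog_fit(freqs, power)
    beta = -fit.slope
    hp = (beta + 1.0) / 2.0
    result = MonofractalResult(
        "psd_low", "beta", beta, hp, classify_hurst_prime(hp, boundary_band), fit
    )
    return result, spectrum


# ---------------------------------------------------------------------------
# dispersional analysis (fGn)
# ---------------------------------------------------------------------------


def disp(
    ts: TimeSeries,
    bin_sizes: np.ndarray | None = None,
    signal_class: str | None = None,
) -> MonofractalResult:
    """Dispersional analysis of an fGn-class signal.

    The SD of the means of non-overlapping bins of size m scales as
    m^(H-1); H is 1 plus the log-log slope.  Requires at least two bin
    sizes and enough bins per size for a stable SD; pass ``signal_class``
    when known and fBm input is rejected.
    """
    _check_class(signal_class, "fBm", "dispersional analysis")
    if bin_sizes is None:
        bin_sizes = log_spaced_windows(ts.n, min_size=1, max_size=ts.n // 16)
    bin_sizes = np.asarray(bin_sizes, dtype=int)
    if bin_sizes.size < 2:
        raise ValueError("dispersional analysis needs >= 2 bin sizes")
    sds = np.empty(bin_sizes.size)
    for i, m in enumerate(bin_sizes):
        means = _window_view(ts.values, m).mean(axis=1)
        if means.size < 2:
            raise ValueError(f"bin size {m} leaves fewer than 2 bins")
        sds[i] = np.std(means, ddof=1)
    if np.any(sds <= 0):
        raise DegenerateSignalError("zero dispersion: degenerate signal")
    fit = loglog_fit(bin_sizes, sds)
    h = 1.0 + fit.slope
    return MonofractalResult("disp", "H", h, h, classify_hurst_prime(h), fit)


# ---------------------------------------------------------------------------
# averaged wavelet coefficient (fBm)
# ---------------------------------------------------------------------------


def awc(
    ts: TimeSeries,
    scales: np.ndarray | None = None,
    wavelet: str = "mexh",
    signal_class: str | None = None,
) -> MonofractalResult:
    """Averaged wavelet coefficient method for fBm-class signals.

    |W(a, b)| from a continuous wavelet transform (default analyzing
    wavelet: the Mexican hat, i.e. the second derivative of a Gaussian) is
    averaged over translations b at each scale a, excluding the cone of
    influence at the edges.  Self-affinity gives W_bar(a) ~ a^(1/2 + H), so
    H is the log-log slope minus 1/2.
    """
    import pywt

    _check_class(signal_class, "fGn", "AWC")
    if np.ptp(ts.values) == 0:
        raise DegenerateSignalError("all wavelet coefficients zero")
    n = ts.n
    if scales is None:
        scales = np.unique(
            np.round(np.logspace(np.log10(2), np.log10(n // 16), 16)).astype(int)
        )
    scales = np.asarray(scales, dtype=float)
    if scales.max() > n / 4:
        raise ValueError("scales must not exceed n/4")
    coeffs, _ = pywt.cwt(ts.values, scales, wavelet)
    mean_abs = np.empty(scales.size)
    body_min = max(16, n // 8)
    for i, a in enumerate(scales):
        # the discretized analyzing wavelet extends ~4 scale units each way,
        # so the cone of influence excluded at the edges is 4a (capped to
        # keep a usable body)
        margin = min(int(np.ceil(4 * a)), (n - body_min) // 2)
        body = np.abs(coeffs[i, margin : n - margin])
        mean_abs[i] = body.mean()
    if np.any(mean_abs <= 1e-10 * max(np.std(ts.values), 1e-300)):
        raise DegenerateSignalError("all wavelet coefficients zero")
    fit = loglog_fit(scales, mean_abs)
    h = fit.slope - 0.5
    return MonofractalResult(
        "awc", "H", h, h + 1.0, classify_hurst_prime(h + 1.0), fit
    )


# ---------------------------------------------------------------------------
# raw (non-detrended) fluctuation analysis
# ---------------------------------------------------------------------------


def fa_raw(ts: TimeSeries, lags: np.ndarray | None = None) -> MonofractalResult:
    """Fluctuation analysis without detrending.

    F(tau) is the RMS increment of the summed profile at lag tau; alpha is
    the log-log slope of F(tau) vs tau.  Related to DFA but without local
    trend removal, so trends bias it.
    """
    if lags is None:
        lags = log_spaced_windows(ts.n, min_size=1, max_size=ts.n // 4)
    lags = np.asarray(lags, dtype=int)
    if lags.size < 2:
        raise ValueError("need >= 2 lags to regress")
    profile = np.cumsum(ts.values - ts.values.mean())
    fl = np.empty(lags.size)
    for i, tau in enumerate(lags):
        d = profile[tau:] - profile[:-tau]
        fl[i] = np.sqrt(np.mean(d**2))
    if np.any(fl == 0):
        raise DegenerateSignalError("zero fluctuation: degenerate signal")
    fit = loglog_fit(lags, fl)
    alpha = fit.slope
    return MonofractalResult(
        "fa_raw", "alpha", alpha, alpha, classify_hurst_prime(alpha), fit
    )


# ---------------------------------------------------------------------------
# exponent conversion algebra
# ---------------------------------------------------------------------------

# Each exponent is affine in H' (the extended Hurst exponent), possibly
# class-dependently.  Entries map exponent -> {class or None: (a, b)} with
# exponent = a * H' + b.
_CLASSLESS = None
_AFFINE = {
    "H'": {_CLASSLESS: (1.0, 0.0)},
    "alpha": {_CLASSLESS: (1.0, 0.0)},
    "beta": {_CLASSLESS: (2.0, -1.0)},
    "H": {"fGn": (1.0, 0.0), "fBm": (1.0, -1.0)},
    "gamma": {"fGn": (-2.0, 2.0)},
    "D": {"fGn": (-1.0, 2.0), "fBm": (-1.0, 3.0)},
}
_ALIASES = {
    "hprime": "H'", "h'": "H'", "H_prime": "H'",
    "a": "alpha", "α": "alpha",
    "b": "beta", "β": "beta",
    "g": "gamma", "γ": "gamma",
    "d": "D", "h": "H",
}


def _affine_params(name: str, signal_class: str | None):
    key = _ALIASES.get(name, name)
    if key not in _AFFINE:
        raise ValueError(f"unknown exponent {name!r}")
    table = _AFFINE[key]
    if _CLASSLESS in table:
        return table[_CLASSLESS]
    if signal_class is None:
        raise ValueError(
            f"conversion involving {key!r} is class-dependent; "
            "pass signal_class='fGn' or 'fBm'"
        )
    sc = str(signal_class)
    if sc not in table:
        raise ValueError(f"exponent {key!r} is not defined for class {sc!r}")
    return table[sc]


def convert_exponents(
    value: float,
    from_: str,
    to: str,
    signal_class: str | None = None,
) -> float:
    """Convert between scaling exponents H', H, beta, alpha, gamma, D.

    All relations follow the dichotomous fGn/fBm model: alpha = H' on the
    extended scale, beta = 2H' - 1 (i.e. beta = 2H - 1 for fGn and 2H + 1
    for fBm), gamma = 2 - 2H (fGn only), and H = 2 - D.  Conversions that
    touch H, gamma, or D need the signal class.
    """
    a_from, b_from = _affine_params(from_, signal_class)
    a_to, b_to = _affine_params(to, signal_class)
    hurst_prime = (value - b_from) / a_from
    return a_to * hurst_prime + b_to
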