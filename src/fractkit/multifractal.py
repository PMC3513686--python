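"""Multifractal estimators and the multifractal formalism.

The moment-based methods (MF-DFA, MF-DMA) generalize their monofractal
cores by raising the per-window fluctuation to a range of moment orders q:
F_q(n) = (mean_v F_v^q)^(1/q), with the q = 0 column defined through the
logarithmic average.  The slope of log F_q(n) vs log n is the generalized
Hurst exponent H(q); for a time series the multiscaling exponent is
tau(q) = q H(q) - 1 and the singularity spectrum D(h) follows by Legendre
transform, h = tau'(q), D(h) = q h - tau(q).

WTMM instead builds the partition function from the moduli of wavelet
transform maxima chained across scales; only chains that propagate to the
finest analyzed scale enter Z(s, q), and tau(q) is the log-log slope of Z.

Monofractals yield a constant H(q) (a point-like spectrum, widened only by
estimation noise); multiplicative cascades yield the full concave spectrum
whose closed-form tau(q) the synthesis module provides as an oracle.
"""

from __future__ import annotations

import warnings
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
from .monofractal import detrended_window_variance

__all__ = [
    "default_qgrid",
    "wide_qgrid",
    "GeneralizedHurstSet",
    "MultiscalingExponent",
    "SingularitySpectrum",
    "SpectrumDescriptors",
    "mf_dfa",
    "mf_dma",
    "tau_and_dimensions",
    "legendre_spectrum",
    "spectrum_descriptors",
    "delta_h",
    "wtmm",
]


def default_qgrid(q_min: float = -5.0, q_max: float = 5.0, step: float = 0.5) -> np.ndarray:
    """Moment orders for spectrum estimation; spans [-5, 5] by default and
    always contains 0 and 2."""
    q = np.arange(q_min, q_max + step / 2, step)
    q = np.union1d(q, [0.0, 2.0])
    return q[(q >= q_min) & (q <= q_max)]


def wide_qgrid() -> np.ndarray:
    """The wide grid q in [-15, 15] used for the spectrum-width endpoint
    Delta-h = h(q=-15) - h(q=+15)."""
    return default_qgrid(-15.0, 15.0, 1.0)


@dataclass(frozen=True)
class GeneralizedHurstSet:
    """H(q) estimates with their per-q log-log fits."""

    q: np.ndarray
    hq: np.ndarray
    fits: tuple
    source: str

    def h_at(self, q_value: float) -> float:
        idx = np.flatnonzero(np.isclose(self.q, q_value))
        if idx.size == 0:
            raise KeyError(f"q = {q_value} not on the grid")
        return float(self.hq[idx[0]])

    def to_dict(self) -> dict:
        return {"q": self.q.tolist(), "hq": self.hq.tolist(), "source": self.source}


@dataclass(frozen=True)
class MultiscalingExponent:
    """tau(q) with the generalized dimensions D(q); D_T = 1 for series."""

    q: np.ndarray
    tau: np.ndarray
    dq: np.ndarray
    source: str
    fits: tuple = ()
    scales: np.ndarray | None = None
    n_lines: np.ndarray | None = None

    def tau_at(self, q_value: float) -> float:
        idx = np.flatnonzero(np.isclose(self.q, q_value))
        if idx.size == 0:
            raise KeyError(f"q = {q_value} not on the grid")
        return float(self.tau[idx[0]])


@dataclass(frozen=True)
class SingularitySpectrum:
    """(h, D(h)) pairs, ordered by decreasing q (increasing h for a concave
    tau); ``concave`` flags points where local concavity held."""

    h: np.ndarray
    d: np.ndarray
    q: np.ndarray
    concave: np.ndarray
    source: str

    def valid(self) -> tuple:
        return self.h[self.concave], self.d[self.concave], self.q[self.concave]


@dataclass(frozen=True)
class SpectrumDescriptors:
    """Scalar summaries of the singularity spectrum.

    h_max/D_max locate the peak; W- and W+ are the widths left/right of
    h_max at half maximum (FWHM = W- + W+); P_c = h_max / (D_max * FWHM);
    W = W+ / W-; delta_h = h(q=-15) - h(q=+15) from the wide moment grid.
    Descriptors that require a half-maximum crossing the spectrum never
    reaches are None.
    """

    h_max: float
    d_max: float
    fwhm: float | None
    w_plus: float | None
    w_minus: float | None
    p_c: float | None
    w: float | None
    delta_h: float | None = None

    def to_dict(self) -> dict:
        return {
            "h_max": self.h_max, "d_max": self.d_max, "fwhm": self.fwhm,
            "w_plus": self.w_plus, "w_minus": self.w_minus,
            "p_c": self.p_c, "w": self.w, "delta_h": self.delta_h,
        }


# ---------------------------------------------------------------------------
# moment machinery shared by MF-DFA and MF-DMA
# ---------------------------------------------------------------------------


def _fit_hq(
    q: np.ndarray, window_sizes: np.ndarray, fq: np.ndarray, source: str
) -> GeneralizedHurstSet:
    """Per-q log-log regression of F_q(n) on n."""
    hq = np.empty(q.size)
    fits = []
    for i in range(q.size):
        fit = loglog_fit(window_sizes, fq[i])
        hq[i] = fit.slope
        fits.append(fit)
    return GeneralizedHurstSet(q, hq, tuple(fits), source)


def mf_dfa(
    ts: TimeSeries,
    q: np.ndarray | None = None,
    window_sizes: np.ndarray | None = None,
    detrend_order: int = 1,
    bidirectional: bool = False,
) -> GeneralizedHurstSet:
    """Multifractal detrended fluctuation analysis.

    The profile is the cumulative sum of the globally demeaned signal.  In
    non-overlapping windows of each size a local polynomial (default
    linear) is removed; per-window RMS fluctuations are pooled into moment
    averages F_q(n), and H(q) is the slope of log F_q vs log n.  At q = 2
    the procedure reduces exactly to monofractal DFA (same windows, same
    detrending).  ``bidirectional`` additionally windows the reversed
    profile (the common 2 N_n variant) to use the tail remainder.
    """
    if q is None:
        q = default_qgrid()
    q = np.asarray(q, dtype=float)
    if window_sizes is None:
        # coarsest scale N/8 keeps >= 8 windows in every moment average;
        # finest 16 limits the small-window bias of the extreme moments
        window_sizes = log_spaced_windows(
            ts.n, min_size=max(16, detrend_order + 2), max_size=ts.n // 8
        )
    window_sizes = np.asarray(window_sizes, dtype=int)
    if window_sizes.min() < detrend_order + 2:
        raise ValueError("minimum window must be >= detrend_order + 2")
    profile = np.cumsum(ts.values - ts.values.mean())
    fq = np.empty((q.size, window_sizes.size))
    for j, size in enumerate(window_sizes):
        fv2 = detrended_window_variance(profile, size, detrend_order)
        if bidirectional:
            fv2_rev = detrended_window_variance(profile[::-1], size, detrend_order)
            fv2 = np.concatenate([fv2, fv2_rev])
        fq[:, j] = moment_average(np.sqrt(fv2), q)
    return _fit_hq(q, window_sizes, fq, "mfdfa")


def _moving_average(y: np.ndarray, n: int, theta: float) -> tuple:
    """Moving average of window n at delay theta, and the valid index range.

    theta = 0 uses only past samples (backward), 1 only future (forward),
    0.5 a centred window.  Returns (ma over valid t, slice of valid t).
    """
    big_n = y.size
    s_fut = int(np.floor((n - 1) * theta))        # samples ahead of t
    s_past = int(np.floor((n - 1) * (1 - theta)))  # samples behind t
    width = s_past + s_fut + 1
    kernel_means = np.convolve(y, np.ones(width) / width, mode="valid")
    # kernel_means[i] = mean(y[i : i + width]); t = i + s_past
    t_lo = s_past
    t_hi = big_n - s_fut  # exclusive
    return kernel_means, slice(t_lo, t_hi)


def mf_dma(
    ts: TimeSeries,
    q: np.ndarray | None = None,
    window_sizes: np.ndarray | None = None,
    theta: float = 0.0,
) -> GeneralizedHurstSet:
    """Multifractal detrended moving average.

    The profile (plain cumulative sum) is detrended point-by-point by a
    moving average of each window size, positioned by theta in [0, 1]
    (0 backward, 0.5 centred, 1 forward; backward is the best-performing
    variant in the MF-DMA literature and the default).  The residual is
    split into floor(N/n - 1) windows of size n and the same moment
    machinery as MF-DFA yields H(q).

    Valid only in the stationary range: on fBm input (extended Hurst above
    1) the H(q) estimate is known to saturate near 1.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0, 1]")
    if q is None:
        q = default_qgrid()
    q = np.asarray(q, dtype=float)
    if window_sizes is None:
        window_sizes = log_spaced_windows(ts.n, min_size=16, max_size=ts.n // 8)
    window_sizes = np.asarray(window_sizes, dtype=int)
    y = np.cumsum(ts.values)
    big_n = y.size
    fq = np.empty((q.size, window_sizes.size))
    for j, n in enumerate(window_sizes):
        ma, valid = _moving_average(y, n, theta)
        resid = y[valid] - ma
        n_win = int(big_n // n - 1)
        if n_win < 1:
            raise ValueError(f"window size {n} leaves no complete window")
        seg = resid[: n_win * n].reshape(n_win, n)
        fv = np.sqrt(np.mean(seg**2, axis=1))
        fq[:, j] = moment_average(fv, q)
    return _fit_hq(q, window_sizes, fq, "mfdma")


# ---------------------------------------------------------------------------
# multifractal formalism
# ---------------------------------------------------------------------------


def tau_and_dimensions(hq: GeneralizedHurstSet) -> MultiscalingExponent:
    """tau(q) = q H(q) - D_T with D_T = 1, and D(q) = tau(q) / (q - 1).

    tau(0) = -1 holds exactly by construction.  D at q = 1 is filled by
    linear interpolation from its neighbours (the ratio is 0/0 there only
    for normalized measures).
    """
    q = hq.q
    tau = q * hq.hq - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dq = tau / (q - 1.0)
    at_one = np.isclose(q, 1.0)
    if np.any(at_one) and np.count_nonzero(~at_one) >= 2:
        dq[at_one] = np.interp(q[at_one], q[~at_one], dq[~at_one])
    return MultiscalingExponent(q, tau, dq, hq.source)


def legendre_spectrum(tau: MultiscalingExponent) -> SingularitySpectrum:
    """Numeric Legendre transform of tau(q).

    h = tau'(q) by centred finite differences; D(h) = q h - tau(q).  For a
    concave tau, h decreases with q; points where that ordering fails are
    flagged non-concave (and excluded from descriptor calculations).  A
    severely non-concave tau triggers a warning — the transform is then
    poorly behaved.
    """
    if tau.q.size < 5:
        raise ValueError("need tau on at least 5 grid points")
    h = np.gradient(tau.tau, tau.q)
    d = tau.q * h - tau.tau
    # concavity: h must be non-increasing in q
    dh = np.diff(h)
    tol = 1e-9 + 1e-3 * (np.abs(h).max() or 1.0)
    bad_step = dh > tol
    concave = np.ones(h.size, dtype=bool)
    concave[1:] &= ~bad_step
    concave[:-1] &= ~bad_step
    if np.count_nonzero(~concave) > h.size // 3:
        warnings.warn(
            "tau(q) is severely non-concave; the Legendre transform is "
            "poorly behaved and the spectrum is unreliable",
            RuntimeWarning, stacklevel=2,
        )
    return SingularitySpectrum(h, d, tau.q, concave, tau.source)


def delta_h(hq_wide: GeneralizedHurstSet) -> float:
    """Spectrum-width endpoint Delta-h = h(q=-15) - h(q=+15).

    h at the extreme moments comes from one-sided finite differences of
    tau(q) = q H(q) - 1 at the ends of the wide grid.  Values below ~0.2
    indicate that true multifractality is unlikely (apparent width from
    estimation noise alone).
    """
    q = hq_wide.q
    tau = q * hq_wide.hq - 1.0
    h_neg = (tau[1] - tau[0]) / (q[1] - q[0])
    h_pos = (tau[-1] - tau[-2]) / (q[-1] - q[-2])
    return float(h_neg - h_pos)


def spectrum_descriptors(
    spec: SingularitySpectrum,
    hq_wide: GeneralizedHurstSet | None = None,
) -> SpectrumDescriptors:
    """Scalar descriptors of a singularity spectrum.

    Half-maximum crossings are located by linear interpolation along each
    branch of the spectrum.  When a branch never descends to half maximum
    the affected widths (and P_c, W) are None with a warning.  If
    ``hq_wide`` (the q = +/-15 grid) is given, Delta-h is attached.
    """
    h, d, q = spec.valid()
    if h.size < 3:
        raise ValueError("too few valid spectrum points for descriptors")
    i_max = int(np.argmax(d))
    h_max, d_max = float(h[i_max]), float(d[i_max])
    half = d_max / 2.0

    def _crossing(branch_h, branch_d):
        # branch ordered from the peak outward; first descent through half
        for a in range(1, branch_h.size):
            if branch_d[a] <= half:
                h0, h1 = branch_h[a - 1], branch_h[a]
                d0, d1 = branch_d[a - 1], branch_d[a]
                if d1 == d0:
                    return float(h1)
                frac = (d0 - half) / (d0 - d1)
                return float(h0 + frac * (h1 - h0))
        return None

    # q decreasing along the grid => h increasing for concave tau; the
    # left branch (h < h_max) is q > q_peak, the right branch q < q_peak.
    order = np.argsort(h)
    h_s, d_s = h[order], d[order]
    i_peak = int(np.argmax(d_s))
    left_h, left_d = h_s[: i_peak + 1][::-1], d_s[: i_peak + 1][::-1]
    right_h, right_d = h_s[i_peak:], d_s[i_peak:]
    cross_left = _crossing(left_h, left_d)
    cross_right = _crossing(right_h, right_d)

    w_minus = None if cross_left is None else h_max - cross_left
    w_plus = None if cross_right is None else cross_right - h_max
    if w_minus is None or w_plus is None:
        warnings.warn(
            "spectrum does not reach half maximum on both sides; "
            "FWHM-based descriptors are null", RuntimeWarning, stacklevel=2,
        )
        fwhm = p_c = w_ratio = None
    else:
        fwhm = w_plus + w_minus
        if fwhm <= 0:
            warnings.warn(
                "point-like spectrum (FWHM ~ 0); P_c undefined",
                RuntimeWarning, stacklevel=2,
            )
            p_c = w_ratio = None
        else:
            p_c = h_max / (d_max * fwhm)
            w_ratio = w_plus / w_minus if w_minus > 0 else None
    dh = delta_h(hq_wide) if hq_wide is not None else None
    return SpectrumDescriptors(h_max, d_max, fwhm, w_plus, w_minus, p_c, w_ratio, dh)


# ---------------------------------------------------------------------------
# wavelet transform modulus maxima
# ---------------------------------------------------------------------------


def _cwt_mexh_l1(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """L1-normalized CWT with the Mexican-hat (Gaussian second derivative)
    wavelet, computed in the frequency domain.

    The wavelet's Fourier transform is the closed form (a w)^2
    exp(-(a w)^2 / 2), so coefficients are smooth at every scale — a
    sampled-wavelet convolution would ripple at coarse scales and those
    ripples masquerade as modulus maxima.  L1 normalization makes
    |W(a, .)| scale as a^h along a singularity of Hoelder exponent h.

    The frequency-domain product is circular, so the signal is bridge
    detrended (the wavelet has two vanishing moments, hence removing a
    line leaves the true coefficients untouched) and zero-padded to twice
    its length to suppress wrap-around; callers still exclude the cone of
    influence at the edges.
    """
    n = x.size
    line = x[0] + (x[-1] - x[0]) * np.arange(n) / (n - 1)
    y = np.concatenate([x - line, np.zeros(n)])
    xf = np.fft.fft(y)
    omega = 2.0 * np.pi * np.fft.fftfreq(y.size)
    out = np.empty((scales.size, n))
    for i, a in enumerate(scales):
        aw2 = (a * omega) ** 2
        out[i] = np.fft.ifft(xf * aw2 * np.exp(-0.5 * aw2)).real[:n]
    return out


def _local_maxima(row: np.ndarray, margin: int) -> np.ndarray:
    """Indices of local maxima of a modulus row.

    Asymmetric neighbourhood rule: strictly greater than the right
    neighbour, greater-or-equal to the left (so plateaus yield their
    leftmost point once).  ``margin`` excludes the cone of influence at
    both edges.
    """
    n = row.size
    lo, hi = max(1, margin), min(n - 1, n - margin)
    if hi <= lo:
        return np.array([], dtype=int)
    mid = row[lo:hi]
    cond = (mid >= row[lo - 1 : hi - 1]) & (mid > row[lo + 1 : hi + 1])
    return np.flatnonzero(cond) + lo


def wtmm(
    ts: TimeSeries,
    q: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    wavelet: str = "mexh",
    supremum: bool = False,
) -> MultiscalingExponent:
    """Wavelet transform modulus maxima estimate of tau(q).

    The CWT (default analyzing wavelet: second derivative of a Gaussian)
    is L1-normalized so that |W(s)| scales as s^h along a singularity of
    Hoelder exponent h.  Local modulus maxima at each scale are chained
    across adjacent scales (nearest maximum within a time distance equal to
    the coarser scale); only chains propagating to the finest scale
    contribute.  Z(s, q) sums the moduli at scale s along surviving chains
    (``supremum=True`` replaces each modulus by the running supremum along
    its line, the canonical variant that stabilizes negative q), and tau(q)
    is the log-log slope of Z against s.
    """
    if wavelet not in {"mexh", "gaus2"}:
        raise ValueError(
            "only the Gaussian-second-derivative analyzing wavelet "
            "('mexh'/'gaus2') is supported for WTMM"
        )
    if q is None:
        q = default_qgrid()
    q = np.asarray(q, dtype=float)
    n = ts.n
    if scales is None:
        # drop the finest (< 4, poorly resolved) and coarsest (> n/8,
        # edge-dominated) scales
        scales = np.unique(
            np.round(np.logspace(np.log10(4), np.log10(n // 8), 32)).astype(int)
        ).astype(float)
    scales = np.asarray(scales, dtype=float)
    if scales.max() > n / 4:
        raise ValueError("scales must not exceed n/4")
    modulus = np.abs(_cwt_mexh_l1(ts.values, scales))

    # maxima per scale, finest first
    order = np.argsort(scales)
    scales_sorted = scales[order]
    maxima = []
    for k in order:
        margin = int(np.ceil(scales[k]))
        idx = _local_maxima(modulus[k], margin)
        maxima.append((idx, modulus[k][idx]))
    if maxima[0][0].size == 0:
        raise DegenerateSignalError("no modulus maxima at the finest scale")

    # chain fine -> coarse; a chain survives at a coarser scale if a maximum
    # lies within |dt| <= that scale of its current position
    pos = maxima[0][0].astype(float)
    sup = maxima[0][1].copy()
    z_vals = np.empty((q.size, scales_sorted.size))
    n_lines = np.empty(scales_sorted.size, dtype=int)

    def _partition(values: np.ndarray, out_col: int) -> None:
        vals = values[values > 0]
        if vals.size == 0:
            z_vals[:, out_col] = np.nan
            return
        logs = np.log(vals)
        for i, qi in enumerate(q):
            m = qi * logs
            mx = m.max()
            z_vals[i, out_col] = (mx + np.log(np.sum(np.exp(m - mx))))

    n_lines[0] = pos.size
    _partition(sup if supremum else maxima[0][1], 0)
    for level in range(1, scales_sorted.size):
        idx, mods = maxima[level]
        if idx.size == 0 or pos.size == 0:
            pos = np.array([])
            n_lines[level:] = 0
            z_vals[:, level:] = np.nan
            break
        tol = scales_sorted[level]
        # nearest chained position for each candidate maximum
        nearest = np.searchsorted(np.sort(pos), idx)
        sorted_pos = np.sort(pos)
        sorted_sup = sup[np.argsort(pos)]
        keep = np.zeros(idx.size, dtype=bool)
        new_sup = np.empty(idx.size)
        for a, t0 in enumerate(idx):
            j = np.clip(nearest[a], 0, sorted_pos.size - 1)
            cand = [j] + ([j - 1] if j > 0 else [])
            dists = [abs(sorted_pos[c] - t0) for c in cand]
            best = cand[int(np.argmin(dists))]
            if abs(sorted_pos[best] - t0) <= tol:
                keep[a] = True
                new_sup[a] = max(sorted_sup[best], mods[a])
        pos = idx[keep].astype(float)
        sup = new_sup[keep]
        n_lines[level] = pos.size
        if pos.size == 0:
            z_vals[:, level:] = np.nan
            n_lines[level:] = 0
            break
        _partition(sup if supremum else mods[keep], level)

    # fit tau(q) over scales with surviving chains
    good = n_lines > 0
    if np.count_nonzero(good) < 4:
        raise DegenerateSignalError(
            "too few scales with surviving maxima chains for a tau(q) fit"
        )
    log_s = np.log10(scales_sorted[good])
    tau = np.empty(q.size)
    fits = []
    for i in range(q.size):
        log_z = z_vals[i, good] / np.log(10.0)
        slope, intercept = np.polyfit(log_s, log_z, 1)
        resid = log_z - (slope * log_s + intercept)
        ss_tot = float(np.sum((log_z - log_z.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        tau[i] = slope
        fits.append(ScalingFit(log_s, log_z, float(slope), float(intercept), r2,
                               0, log_s.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        dq = tau / (q - 1.0)
    at_one = np.isclose(q, 1.0)
    if np.any(at_one):
        dq[at_one] = np.interp(q[at_one], q[~at_one], dq[~at_one])
    return MultiscalingExponent(
        q, tau, dq, "wtmm", tuple(fits),
        scales=scales_sorted, n_lines=n_lines,
    )
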