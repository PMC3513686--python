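"""Exact scale-free signal synthesis and surrogates.

Fractional Gaussian noise (fGn) is synthesized by the Davies-Harte method:
the target autocovariance is embedded in a circulant matrix whose
eigenvalues come from one FFT, and a Hermitian complex Gaussian vector is
coloured by their square roots.  The output has the *exact* fGn
autocovariance in expectation at O(n log n) cost.  Non-stationary signals
(fractional Brownian motion, fBm) are obtained by cumulative summation,
following the extended-Hurst convention H' = H for fGn and H' = H + 1 for
fBm.

Deterministic multifractals are built as multiplicative cascades (the
Devil's-staircase family); their multiscaling exponent has the closed form
tau(q) = -log_b(sum_i p_i^q), which serves as an independent oracle for the
moment-based estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeries
from .volume import VoxelVolume

__all__ = [
    "fgn_autocovariance",
    "generate_fgn",
    "generate_fbm",
    "generate_signal",
    "class_convert",
    "CascadeSpec",
    "generate_cascade",
    "cascade_tau_oracle",
    "cascade_holder_oracle",
    "shuffle_surrogate",
    "RegionParams",
    "PhantomSpec",
    "generate_phantom",
]


def fgn_autocovariance(lags, hurst: float, sigma: float = 1.0) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k).

    gamma(k) = (sigma^2 / 2) * (|k+1|^(2H) - 2|k|^(2H) + |k-1|^(2H)).
    At H = 1/2 this vanishes for every k >= 1 (white noise).
    """
    k = np.abs(np.asarray(lags, dtype=float))
    two_h = 2.0 * hurst
    return 0.5 * sigma**2 * (
        np.abs(k + 1) ** two_h - 2.0 * k**two_h + np.abs(k - 1) ** two_h
    )


def generate_fgn(
    n: int,
    hurst: float,
    sigma: float = 1.0,
    seed: int | None = None,
    dt: float = 1.0,
) -> TimeSeries:
    """Exact fGn of length ``n`` with Hurst exponent ``hurst`` in (0, 1).

    Circulant-embedding synthesis: the 2n-periodic extension of gamma(k) is
    diagonalized by the FFT; its eigenvalues must be non-negative for the
    embedding to define a covariance (guaranteed for fGn, checked anyway).
    Identical (n, hurst, sigma, seed) always reproduce the same series.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 8:
        raise ValueError(f"need n >= 8, got {n}")
    m = 2 * n
    gamma = fgn_autocovariance(np.arange(n + 1), hurst, sigma)
    # first row of the circulant embedding: gamma(0..n), then mirrored tail
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    tol = -1e-8 * lam.max()
    if lam.min() < tol:
        raise RuntimeError(
            "circulant embedding produced a negative eigenvalue "
            f"({lam.min():.3e}); cannot synthesize exact fGn for H={hurst}"
        )
    lam = np.clip(lam, 0.0, None)

    rng = np.random.default_rng(seed)
    w = np.zeros(m, dtype=complex)
    w[0] = np.sqrt(lam[0] / m) * rng.standard_normal()
    w[n] = np.sqrt(lam[n] / m) * rng.standard_normal()
    re = rng.standard_normal(n - 1)
    im = rng.standard_normal(n - 1)
    half = np.sqrt(lam[1:n] / (2.0 * m)) * (re + 1j * im)
    w[1:n] = half
    w[n + 1 :] = np.conj(half[::-1])
    x = np.fft.fft(w)[:n].real
    return TimeSeries(x, dt=dt, label=f"fGn(H={hurst:g})")


def generate_fbm(
    n: int,
    hurst_prime: float,
    sigma: float = 1.0,
    seed: int | None = None,
    dt: float = 1.0,
) -> TimeSeries:
    """fBm with extended Hurst exponent H' in (1, 2).

    Synthesized as the cumulative sum of exact fGn with H = H' - 1, the
    construction under which the fGn/fBm dichotomy is exact.
    """
    if not (1.0 < hurst_prime < 2.0):
        raise ValueError(f"extended Hurst for fBm must lie in (1, 2), got {hurst_prime}")
    incr = generate_fgn(n, hurst_prime - 1.0, sigma=sigma, seed=seed, dt=dt)
    out = class_convert(incr, "sum")
    return out.with_values(out.values, label=f"fBm(H'={hurst_prime:g})")


def generate_signal(
    n: int,
    hurst_prime: float,
    sigma: float = 1.0,
    seed: int | None = None,
    dt: float = 1.0,
) -> TimeSeries:
    """Monofractal signal on the extended Hurst scale H' in (0,2) \\ {1}."""
    if 0.0 < hurst_prime < 1.0:
        return generate_fgn(n, hurst_prime, sigma=sigma, seed=seed, dt=dt)
    if 1.0 < hurst_prime < 2.0:
        return generate_fbm(n, hurst_prime, sigma=sigma, seed=seed, dt=dt)
    raise ValueError(f"extended Hurst must lie in (0,1) or (1,2), got {hurst_prime}")


def class_convert(ts: TimeSeries, mode: str) -> TimeSeries:
    """Convert between the fGn and fBm classes.

    ``sum`` cumulatively sums (fGn -> fBm); ``difference`` first-differences
    (fBm -> fGn, length n - 1).
    """
    if mode == "sum":
        return ts.with_values(np.cumsum(ts.values), label=f"sum({ts.label})")
    if mode == "difference":
        return ts.with_values(np.diff(ts.values), label=f"diff({ts.label})")
    raise ValueError(f"mode must be 'sum' or 'difference', got {mode!r}")


# ---------------------------------------------------------------------------
# deterministic multifractal cascades
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CascadeSpec:
    """A multiplicative cascade: ``base`` subintervals per refinement,
    mass split by ``weights`` (positive, summing to one), ``depth`` levels.

    The classic Devil's staircase uses base 3 with weights (0.2, 0.6, 0.2).
    """

    base: int
    weights: tuple
    depth: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.base < 2:
            raise ValueError("cascade base must be >= 2")
        if self.depth < 1:
            raise ValueError("cascade depth must be >= 1")
        if w.size != self.base:
            raise ValueError("need exactly `base` weights")
        if np.any(w <= 0):
            raise ValueError("cascade weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"cascade weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def n(self) -> int:
        return self.base**self.depth


def generate_cascade(spec: CascadeSpec, staircase: bool = False) -> TimeSeries:
    """Increments of the multiplicative measure (total mass exactly 1).

    With ``staircase=True`` returns the cumulative sum instead — the
    Devil's staircase itself, useful for wavelet-based analysis and display.
    """
    measure = np.array([1.0])
    w = np.asarray(spec.weights)
    for _ in range(spec.depth):
        measure = np.kron(measure, w)
    # renormalize away accumulated round-off so the mass is exactly 1
    measure /= measure.sum()
    label = f"cascade(base={spec.base}, depth={spec.depth})"
    if staircase:
        return TimeSeries(np.cumsum(measure), label="staircase " + label)
    return TimeSeries(measure, label=label)


def cascade_tau_oracle(spec: CascadeSpec, q) -> np.ndarray:
    """Exact multiscaling exponent tau(q) = -log_base(sum_i p_i^q).

    tau(0) = -1 and tau(1) = 0 for every valid cascade.
    """
    q = np.asarray(q, dtype=float)
    w = np.asarray(spec.weights)
    s = np.sum(w[None, ...] ** q[..., None], axis=-1)
    return -np.log(s) / np.log(spec.base)


def cascade_holder_oracle(spec: CascadeSpec, q) -> np.ndarray:
    """Exact Hoelder exponent h(q) = tau'(q) for the cascade.

    h(q) = -sum_i p_i^q ln p_i / (sum_i p_i^q * ln base).
    """
    q = np.asarray(q, dtype=float)
    w = np.asarray(spec.weights)
    pq = w[None, ...] ** q[..., None]
    num = -np.sum(pq * np.log(w), axis=-1)
    den = np.sum(pq, axis=-1) * np.log(spec.base)
    return num / den


def shuffle_surrogate(ts: TimeSeries, seed: int | None = None) -> TimeSeries:
    """Random permutation of the samples.

    Destroys serial correlation while preserving the value distribution
    exactly — the surrogate used to test whether multifractality originates
    from correlations rather than a broad amplitude distribution.
    """
    rng = np.random.default_rng(seed)
    return ts.with_values(
        rng.permutation(ts.values), label=f"shuffled({ts.label})"
    )


# ---------------------------------------------------------------------------
# synthetic 4D BOLD phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionParams:
    """Per-region scale-free structure: extended Hurst H' and amplitude."""

    hurst_prime: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        hp = self.hurst_prime
        if not (0.0 < hp < 2.0) or hp == 1.0:
            raise ValueError(
                f"region extended Hurst must lie in (0,2) excluding 1, got {hp}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic 4D phantom: a labelled spatial grid whose voxels carry
    band-limited scale-free signals plus white instrument noise.

    ``region_map`` is an integer label per voxel; every label present must
    have an entry in ``regions``.  Emulates multi-region BOLD acquisitions
    with per-region prescribed H'.
    """

    region_map: np.ndarray
    regions: dict
    n_timepoints: int = 256
    dt: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        rmap = np.asarray(self.region_map)
        if rmap.ndim != 3:
            raise ValueError("region_map must be a 3-d integer array")
        missing = set(np.unique(rmap).tolist()) - set(self.regions)
        if missing:
            raise ValueError(f"region labels without parameters: {sorted(missing)}")
        if self.n_timepoints < 8:
            raise ValueError("phantom needs at least 8 time points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "region_map", rmap)


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> VoxelVolume:
    """Synthesize the 4D phantom voxel by voxel.

    Each voxel receives amplitude x (exact fGn for H' < 1, summed fGn for
    H' > 1) + iid Gaussian noise of the stated SD.  Voxel streams are
    seeded as (seed, flat voxel index): the full volume is reproducible and
    any single voxel can be regenerated in isolation.
    """
    rmap = spec.region_map
    shape = rmap.shape + (spec.n_timepoints,)
    data = np.zeros(shape)
    flat_labels = rmap.ravel()
    for idx, label in enumerate(flat_labels):
        params: RegionParams = spec.regions[int(label)]
        voxel_seed = (seed, idx)
        if params.amplitude != 0.0:
            sig = generate_signal(
                spec.n_timepoints, params.hurst_prime,
                seed=voxel_seed, dt=spec.dt,
            ).values * params.amplitude
        else:
            sig = np.zeros(spec.n_timepoints)
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng((seed, idx, 1))
            sig = sig + noise_rng.normal(0.0, spec.noise_sd, spec.n_timepoints)
        data.reshape(-1, spec.n_timepoints)[idx] = sig
    return VoxelVolume(data, dt=spec.dt)
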