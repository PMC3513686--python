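"""Voxel-wise fractal parameter mapping of 4D volumes.

Each in-mask voxel's time series is analyzed with the single-series
estimators and the results are assembled into 3D parametric maps:

beta     spectral index from the low-frequency PSD fit (default band
         0.02-0.3 Hz when the sampling interval makes it realizable)
hprime   extended Hurst exponent from SSC
class    fGn / fBm / boundary coded as integers (1 / 2 / 0, null -1)
pc       P_c = h_max / (D_max * FWHM) from the MF-DFA singularity spectrum
dh       spectrum width Delta-h from the wide moment grid

A voxel whose estimator fails is recorded as null and counted; a bad voxel
never aborts the map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import TimeSeries
from .monofractal import psd_low, ssc
from .multifractal import (
    default_qgrid,
    delta_h,
    legendre_spectrum,
    mf_dfa,
    spectrum_descriptors,
    tau_and_dimensions,
    wide_qgrid,
)
from .volume import CLASS_CODES, ParametricMap, VoxelVolume

__all__ = ["DEFAULT_BAND", "map_parameters", "map_histogram"]

DEFAULT_BAND = (0.02, 0.3)  # Hz
MIN_MAP_LENGTH = 2**7
KNOWN_PARAMS = ("beta", "hprime", "class", "pc", "dh")


def _resolve_band(band: tuple | None, vol: VoxelVolume) -> tuple | None:
    """Validate the spectral fit band against the volume's Nyquist frequency
    before any voxel is touched; fall back to the estimator default (up to
    Nyquist/8) when the requested band is not realizable."""
    nyquist = 0.5 / vol.dt
    if band is None:
        band = DEFAULT_BAND
        if band[1] > nyquist:
            return None  # psd_low default band
        # also require enough spectral estimates inside the band
        df = 1.0 / (vol.n_timepoints * vol.dt)
        if (band[1] - band[0]) / df < 4:
            return None
        return band
    if not (0.0 <= band[0] < band[1] <= nyquist):
        raise ValueError(
            f"fit band {band} is not inside (0, Nyquist={nyquist:g} Hz]"
        )
    return band


def map_parameters(
    vol: VoxelVolume,
    params=("beta", "hprime", "class"),
    band: tuple | None = None,
    boundary_band: tuple = (0.9, 1.1),
) -> dict:
    """Compute the requested parametric maps voxel by voxel.

    Returns a dict parameter id -> :class:`ParametricMap`.  Map values at a
    voxel equal the single-series estimate on that voxel's series — the
    pipeline adds no smoothing or other spatial processing.
    """
    unknown = set(params) - set(KNOWN_PARAMS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    if vol.n_timepoints < MIN_MAP_LENGTH:
        raise ValueError(
            f"mapping needs >= {MIN_MAP_LENGTH} time points, "
            f"got {vol.n_timepoints}"
        )
    band = _resolve_band(band, vol)

    shape = vol.spatial_shape
    out = {}
    for p in params:
        fill = float(CLASS_CODES["null"]) if p == "class" else np.nan
        out[p] = np.full(shape, fill)
    failures = {p: 0 for p in params}
    need_spectrum = bool({"pc", "dh"} & set(params))
    reporting_q = default_qgrid()
    wide_q = wide_qgrid()

    for idx, series in vol.iter_series():
        ts = TimeSeries(series, dt=vol.dt)
        if "beta" in params:
            try:
                res, _ = psd_low(ts, fit_band=band)
                out["beta"][idx] = res.exponent
            except Exception:
                failures["beta"] += 1
        if "hprime" in params or "class" in params:
            try:
                res = ssc(ts, boundary_band=boundary_band)
                if "hprime" in params:
                    out["hprime"][idx] = res.hurst_prime
                if "class" in params:
                    out["class"][idx] = CLASS_CODES[str(res.signal_class)]
            except Exception:
                for p in ("hprime", "class"):
                    if p in params:
                        failures[p] += 1
        if need_spectrum:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if "pc" in params:
                        hq = mf_dfa(ts, q=reporting_q)
                        spec = legendre_spectrum(tau_and_dimensions(hq))
                        desc = spectrum_descriptors(spec)
                        out["pc"][idx] = (
                            np.nan if desc.p_c is None else desc.p_c
                        )
                    if "dh" in params:
                        out["dh"][idx] = delta_h(mf_dfa(ts, q=wide_q))
            except Exception:
                for p in ("pc", "dh"):
                    if p in params:
                        failures[p] += 1

    return {
        p: ParametricMap(out[p], p, n_failed=failures[p], affine=vol.affine)
        for p in params
    }


def map_histogram(
    pmap: ParametricMap,
    mask: np.ndarray | None = None,
    bins=20,
) -> tuple:
    """Histogram of a parametric map within a mask.

    Returns ``(table, n_null)`` where the table has one row per bin with
    columns ``bin_left``, ``bin_right``, ``count``; null voxels are
    excluded from the counts and reported separately.
    """
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        total = int(mask.sum())
    else:
        total = pmap.data.size
    vals = pmap.valid_values(mask)
    n_null = total - vals.size
    if vals.size == 0:
        raise ValueError("map contains only null voxels within the mask")
    counts, edges = np.histogram(vals, bins=bins)
    table = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return table, n_null
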