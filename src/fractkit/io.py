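"""Reading and writing univariate series as delimited text."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries

__all__ = ["read_series", "write_series"]


def read_series(path: str | Path, dt: float = 1.0, column=None) -> TimeSeries:
    """Read a series from one-value-per-line text or a CSV with header.

    For CSV input, ``column`` selects the column (name or index); by
    default the first numeric column is used.
    """
    path = Path(path)
    text_head = path.open().readline()
    if "," in text_head:
        df = pd.read_csv(path)
        if column is not None:
            col = df[column] if isinstance(column, str) else df.iloc[:, column]
        else:
            numeric = df.select_dtypes("number")
            if numeric.shape[1] == 0:
                raise ValueError(f"no numeric column in {path}")
            col = numeric.iloc[:, 0]
        values = col.to_numpy(dtype=float)
    else:
        values = np.loadtxt(path, dtype=float, ndmin=1)
    return TimeSeries(values, dt=dt, label=path.stem)


def write_series(ts: TimeSeries, path: str | Path) -> None:
    """Write as single-column delimited text."""
    np.savetxt(Path(path), ts.values, fmt="%.12g")
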