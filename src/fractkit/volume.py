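"""4D voxel volumes and derived parametric maps, with NIfTI-1 and CSV I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelVolume",
    "ParametricMap",
    "CLASS_CODES",
    "load_volume",
    "save_volume",
    "save_map",
]

# integer coding of signal class in class maps
CLASS_CODES = {"fGn": 1, "fBm": 2, "boundary": 0, "null": -1}


@dataclass
class VoxelVolume:
    """A 4D (x, y, z, t) array of voxel time series.

    ``mask`` marks voxels to analyze (defaults to all); ``affine`` is the
    spatial metadata passed through to NIfTI output unchanged.
    """

    data: np.ndarray
    dt: float = 1.0
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VoxelVolume data must be 4-d (x, y, z, t)")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spatial_shape:
                raise ValueError("mask shape must match the spatial grid")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.spatial_shape, dtype=bool)
        return self.mask

    def iter_series(self):
        """Yield (index triple, 1-d series) over in-mask voxels."""
        mask = self.effective_mask()
        for idx in np.ndindex(*self.spatial_shape):
            if mask[idx]:
                yield idx, self.data[idx]


@dataclass
class ParametricMap:
    """A per-voxel scalar map derived from a VoxelVolume.

    Failed voxels hold NaN (``class`` maps use the integer null code).
    """

    data: np.ndarray
    parameter: str
    n_failed: int = 0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ParametricMap data must be 3-d")
        if self.affine is None:
            self.affine = np.eye(4)

    def valid_values(self, mask: np.ndarray | None = None) -> np.ndarray:
        vals = self.data if mask is None else self.data[mask]
        vals = np.ravel(vals)
        if self.parameter == "class":
            return vals[vals != CLASS_CODES["null"]]
        return vals[np.isfinite(vals)]


# ---------------------------------------------------------------------------
# I/O: NIfTI-1 or CSV matrix + JSON sidecar
# ---------------------------------------------------------------------------


def load_volume(path: str | Path, dt: float | None = None) -> VoxelVolume:
    """Read a 4D volume from NIfTI-1 (.nii/.nii.gz) or a CSV matrix whose
    rows are voxel time series, with a JSON sidecar giving ``shape`` and
    ``dt``.

    For NIfTI, dt comes from the header's time zooms unless overridden.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 4:
            raise ValueError(f"expected a 4D NIfTI volume, got shape {data.shape}")
        if dt is None:
            zooms = img.header.get_zooms()
            dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return VoxelVolume(data, dt=dt, affine=np.asarray(img.affine))
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"CSV volume input requires a JSON sidecar at {sidecar}"
        )
    meta = json.loads(sidecar.read_text())
    rows = np.loadtxt(path, delimiter=",", ndmin=2)
    shape = tuple(meta["shape"])
    if dt is None:
        dt = float(meta.get("dt", 1.0))
    data = rows.reshape(shape + (rows.shape[1],))
    return VoxelVolume(data, dt=dt)


def save_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 plus a JSON sidecar holding dt."""
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms((1.0, 1.0, 1.0, vol.dt))
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    sidecar.write_text(json.dumps({"dt": vol.dt, "shape": list(vol.data.shape)}))


def save_map(pmap: ParametricMap, path: str | Path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(pmap.data, pmap.affine)
    nib.save(img, str(Path(path)))
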