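"""Volumetric and tabular I/O for the gradient pipeline.

Containers for masked 4D BOLD data, NIfTI read/write, run concatenation,
cohort tables, and JSON configuration.

Voxel ordering convention
-------------------------
Everywhere in this package, the voxels of a 3D boolean mask are ordered
row-major (C order) over the 3D index grid — the order produced by
``numpy.argwhere(mask)`` and by boolean indexing ``array[mask]``. Connectivity
fingerprints, similarity matrices, gradient values, and trend-surface design
rows all share this ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("connectograd")

#: Column names of the 9 order-3 trend-surface coefficients, in report order.
TSM_COLUMNS = ["x", "y", "z", "x2", "y2", "z2", "x3", "y3", "z3"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid with a voxel-to-world (mm) affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff)) < 1e-12:
            raise ValueError("affine is not invertible")
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (N x 3) to world mm coordinates (N x 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (hom @ self.affine.T)[:, :3]

    def mask_world_coords(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates of the True voxels of ``mask``, in C order."""
        return self.voxel_to_world(np.argwhere(mask))

    def same_as(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class MaskVolume:
    """A boolean 3D volume on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class BoldData:
    """Masked 4D time series: T timepoints x V mask voxels.

    ``series[:, j]`` is the time series of the j-th True voxel of ``mask``
    in row-major order (see module docstring).
    """

    grid: VolumeGrid
    mask: np.ndarray
    series: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid shape")
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("series must be a T x V matrix")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")
        t, v = self.series.shape
        if t < 2:
            raise ValueError(f"need at least 2 timepoints, got {t}")
        if v < 2:
            raise ValueError(f"need at least 2 voxels, got {v}")
        if v != int(self.mask.sum()):
            raise ValueError(
                f"series has {v} voxels but mask has {int(self.mask.sum())}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.series.shape[1]

    def coords_world(self) -> np.ndarray:
        """World mm coordinates of the mask voxels (V x 3)."""
        return self.grid.mask_world_coords(self.mask)


def read_volume(path, mask: MaskVolume | None = None):
    """Read a NIfTI file; 3D files yield a :class:`MaskVolume` (nonzero voxels
    True), 4D files a :class:`BoldData`.

    For 4D files an explicit ``mask`` restricts the extracted voxels; otherwise
    voxels whose series is not identically zero form the mask.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    grid = VolumeGrid(data.shape[:3], img.affine)
    if data.ndim == 3:
        m = data != 0
        if not m.any():
            raise ValueError(f"empty mask: {path} has no nonzero voxels")
        return MaskVolume(grid, m)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 3D or 4D volume, got ndim={data.ndim}")
    if data.shape[3] < 2:
        raise ValueError(f"{path}: 4D file with fewer than 2 timepoints")
    if mask is not None:
        if not grid.same_as(mask.grid):
            raise ValueError("mask grid does not match BOLD grid")
        m = mask.data
    else:
        m = np.any(data != 0, axis=3)
    series = data[m].T.astype(float)  # (T, V), C-order voxels
    return BoldData(grid, m, series)


def write_volume(path, obj) -> None:
    """Write a :class:`BoldData` (4D) or :class:`MaskVolume` (3D uint8) to NIfTI."""
    path = Path(path)
    if isinstance(obj, BoldData):
        vol = np.zeros(obj.grid.shape + (obj.n_timepoints,), dtype=np.float32)
        vol[obj.mask] = obj.series.T
        img = nib.Nifti1Image(vol, obj.grid.affine)
    elif isinstance(obj, MaskVolume):
        img = nib.Nifti1Image(obj.data.astype(np.uint8), obj.grid.affine)
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    nib.save(img, str(path))


def write_map(path, grid: VolumeGrid, mask: np.ndarray, values: np.ndarray,
              fill=np.nan) -> None:
    """Write per-mask-voxel scalar values as a 3D float NIfTI (``fill`` elsewhere)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if values.shape != (int(mask.sum()),):
        raise ValueError("values length does not match mask voxel count")
    vol = np.full(grid.shape, fill, dtype=np.float32)
    vol[mask] = values
    nib.save(nib.Nifti1Image(vol, grid.affine), str(Path(path)))


def read_map(path, mask: MaskVolume) -> np.ndarray:
    """Read per-voxel values written by :func:`write_map` back as a vector."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.shape != mask.grid.shape:
        raise ValueError("map shape does not match mask grid")
    return np.asarray(data[mask.data], dtype=float)


def concat_runs(runs: list[BoldData]) -> BoldData:
    """Concatenate runs along time after per-run, per-voxel normalization.

    Each voxel series in each run is mean-centered and scaled to unit standard
    deviation (population sd) before concatenation. Voxels with zero variance
    within a run are set to all-zeros for that run, with a warning.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    first = runs[0]
    for r in runs[1:]:
        if not first.grid.same_as(r.grid) or not np.array_equal(first.mask, r.mask):
            raise ValueError("runs must share an identical grid and mask")
    blocks = []
    for i, r in enumerate(runs):
        x = r.series - r.series.mean(axis=0, keepdims=True)
        sd = r.series.std(axis=0)
        dead = sd <= 0
        if dead.any():
            log.warning(
                "run %d: %d zero-variance voxel(s) set to zeros", i, int(dead.sum())
            )
        sd_safe = np.where(dead, 1.0, sd)
        x = x / sd_safe
        x[:, dead] = 0.0
        blocks.append(x)
    return BoldData(first.grid, first.mask, np.concatenate(blocks, axis=0))


# ---------------------------------------------------------------------------
# Tabular I/O

def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table (TSV with header; empty fields are missing values)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """Pipeline configuration, loadable from a JSON file.

    Thresholds mirror the subject-inclusion rules: a trend-surface model must
    explain at least ``var_min`` of the gradient's spatial variance, and the
    dominant gradient must correlate (in absolute value) at least ``r_min``
    with the reference gradient.
    """

    roi_mask: str | None = None
    target_mask: str | None = None
    n_gradients: int = 1
    k_neighbors: int = 8
    dense_graph: bool = False
    variance_kept: float = 1.0
    tsm_order: int = 3
    r_min: float = 0.5
    var_min: float = 0.70
    seed: int = 0
    required_columns: list[str] = field(
        default_factory=lambda: ["subject", "age", "sex", "education"]
    )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = json.load(fh)
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr with level INFO (or DEBUG if verbose)."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
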