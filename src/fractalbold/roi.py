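"""Spherical ROI masks, mean time-course extraction, linear detrending.

ROI centers are mm coordinates in the volume's own reference frame (the
affine maps voxel indices to mm); a voxel belongs to the sphere when its
center lies within the closed ball of the given radius. The packaged
default ROI set is the 8-region waiting-impulsivity network (10 mm
spheres around the peak coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMask, MaskVolumeMismatch
from .series import TimeSeries, linear_detrend  # re-export: detrend precedes AFA

__all__ = [
    "RoiDef",
    "RoiMask",
    "DEFAULT_ROIS",
    "default_roi_table",
    "sphere_mask",
    "extract_mean_timecourse",
    "linear_detrend",
]


@dataclass(frozen=True)
class RoiDef:
    """A spherical region of interest: label, center (mm), radius (mm)."""

    label: str
    center: tuple[float, float, float]
    radius: float = 10.0

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be > 0")


#: The 8-region waiting-impulsivity network (MNI mm, 10 mm spheres).
DEFAULT_ROIS: tuple[RoiDef, ...] = (
    RoiDef("rHC", (24.0, -28.0, -6.0)),
    RoiDef("lHC", (-22.0, -28.0, -6.0)),
    RoiDef("lMFG", (-44.0, 6.0, 28.0)),
    RoiDef("rMFG", (40.0, 8.0, 34.0)),
    RoiDef("ACC", (6.0, 30.0, 28.0)),
    RoiDef("rNAcc", (8.0, 12.0, -10.0)),
    RoiDef("lAMY", (-22.0, 0.0, -12.0)),
    RoiDef("vmPFC", (0.0, 48.0, -12.0)),
)


def default_roi_table() -> pd.DataFrame:
    """The packaged ROI set as a (label, x, y, z, radius) table."""
    return pd.DataFrame(
        [(r.label, *r.center, r.radius) for r in DEFAULT_ROIS],
        columns=["label", "x", "y", "z", "radius"],
    )


def read_roi_table(path) -> tuple[RoiDef, ...]:
    """Read an ROI set from CSV with columns label, x, y, z[, radius]."""
    df = pd.read_csv(path)
    radius = df["radius"] if "radius" in df else pd.Series(10.0, index=df.index)
    return tuple(
        RoiDef(str(row.label), (float(row.x), float(row.y), float(row.z)),
               float(rad))
        for row, rad in zip(df.itertuples(index=False), radius)
    )


@dataclass(frozen=True)
class RoiMask:
    """Voxel-index set of a sphere, bound to the affine/shape it was built for."""

    indices: np.ndarray          # (n_voxels, 3) int
    affine: np.ndarray
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])


def sphere_mask(roi: RoiDef, affine: np.ndarray,
                shape: tuple[int, int, int]) -> RoiMask:
    """Voxels whose affine-mapped center lies within the closed ball.

    Geometry only: independent of any image data. Raises
    :class:`EmptyMask` when no voxel center qualifies.
    """
    from nibabel.affines import apply_affine

    affine = np.asarray(affine, dtype=float)
    inv = np.linalg.inv(affine)                      # must be invertible
    # restrict the search to the bounding box of the sphere in voxel space
    center_vox = apply_affine(inv, np.asarray(roi.center))
    # conservative per-axis half-width: radius / smallest voxel step
    steps = np.linalg.norm(affine[:3, :3], axis=0)
    half = np.ceil(roi.radius / steps).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(center_vox).astype(int) + half + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        raise EmptyMask(f"ROI {roi.label} lies outside the volume")
    grid = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                                indexing="ij"), axis=-1).reshape(-1, 3)
    mm = apply_affine(affine, grid)
    dist = np.linalg.norm(mm - np.asarray(roi.center), axis=1)
    inside = grid[dist <= roi.radius]
    if inside.shape[0] == 0:
        raise EmptyMask(f"no voxel center within {roi.radius} mm of "
                        f"{roi.center} ({roi.label})")
    return RoiMask(indices=inside, affine=affine, shape=tuple(shape))


def extract_mean_timecourse(vol4d, mask: RoiMask, dt: float = 2.0,
                            label: str = "") -> TimeSeries:
    """Arithmetic mean over masked voxels, one value per volume.

    ``vol4d`` may be a nibabel spatial image or a 4D ndarray; its spatial
    shape must match the mask's.
    """
    data = np.asarray(vol4d.dataobj) if hasattr(vol4d, "dataobj") else \
        np.asarray(vol4d, dtype=float)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise MaskVolumeMismatch(
            f"volume shape {data.shape} incompatible with mask {mask.shape}")
    i, j, k = mask.indices.T
    return TimeSeries(data[i, j, k, :].mean(axis=0), dt=dt, label=label)
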