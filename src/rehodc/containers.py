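"""Core in-memory containers shared across the pipeline.

The pipeline passes three kinds of objects between stages: 4D BOLD time
series (:class:`Bold4D`), 3D scalar metric maps tied to a gray-matter mask
(:class:`MetricMap`), and voxelwise statistic maps with degrees of freedom
(:class:`StatMap`).  All of them carry a NIfTI-style 4x4 affine so voxel
indices can be reported as world (mm) coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

__all__ = [
    "Bold4D",
    "MetricMap",
    "StatMap",
    "default_affine",
    "voxel_to_world",
    "world_to_voxel",
]

#: metric kinds a MetricMap may carry
METRIC_KINDS = ("ReHo", "mReHo", "DC", "mDC", "change", "weight")


def default_affine(voxel_size_mm: float | tuple[float, float, float],
                   shape: tuple[int, int, int]) -> np.ndarray:
    """Build a simple RAS affine with the grid centred on the origin."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.diag([vs[0], vs[1], vs[2], 1.0])
    aff[:3, 3] = -vs * (np.asarray(shape, dtype=float) - 1) / 2.0
    return aff


def voxel_to_world(affine: np.ndarray, idx) -> np.ndarray:
    """Map a voxel index (i, j, k) to world mm coordinates."""
    ijk = np.asarray(idx, dtype=float)
    return affine[:3, :3] @ ijk + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz) -> tuple[int, int, int]:
    """Map world mm coordinates to the nearest voxel index."""
    inv = np.linalg.inv(affine)
    ijk = inv[:3, :3] @ np.asarray(xyz, dtype=float) + inv[:3, 3]
    return tuple(int(round(v)) for v in ijk)


@dataclass
class Bold4D:
    """A 4D BOLD run: ``data[x, y, z, t]`` plus timing and grid geometry.

    Parameters
    ----------
    data:
        Float array ordered (x, y, z, t); all values must be finite.
    tr_s:
        Repetition time in seconds (time between consecutive volumes).
    voxel_size_mm:
        Isotropic voxel edge in mm (or a 3-tuple).
    affine:
        4x4 grid-to-world transform; derived from ``voxel_size_mm`` if None.
    """

    data: np.ndarray
    tr_s: float
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Bold4D data must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("Bold4D needs at least 2 time points")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Bold4D data contains non-finite values")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm, self.data.shape[:3])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(data=data, tr_s=self.tr_s,
                      voxel_size_mm=self.voxel_size_mm, affine=self.affine)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        zooms = list(img.header.get_zooms()[:3]) + [self.tr_s]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Bold4D":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        return cls(data=np.asarray(img.dataobj, dtype=float), tr_s=tr,
                   voxel_size_mm=tuple(float(z) for z in zooms[:3]),
                   affine=np.asarray(img.affine, dtype=float))


@dataclass
class MetricMap:
    """A 3D scalar map (ReHo/DC/normalized/change/weight) tied to a mask.

    Values are finite inside the mask and zero outside; ``kind`` records
    what the map measures and ``provenance`` how it was produced.
    """

    values: np.ndarray
    kind: str
    mask: np.ndarray
    affine: np.ndarray | None = None
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in METRIC_KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm, self.values.shape)
        # keep the out-of-mask region identically zero
        self.values = np.where(self.mask, self.values, 0.0)

    def mask_mean(self) -> float:
        return float(self.values[self.mask].mean())

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, str(path))


@dataclass
class StatMap:
    """Voxelwise test statistics: an F or t map with degrees of freedom."""

    values: np.ndarray
    stat: str  # "F" or "t"
    df: tuple[float, ...] | float
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    tail: str = "upper"  # upper (F, positive t) or two-sided

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stat not in ("F", "t"):
            raise ValueError("stat must be 'F' or 't'")
        if self.stat == "F":
            df = np.atleast_1d(np.asarray(self.df, dtype=float))
            if df.size != 2 or np.any(df <= 0):
                raise ValueError("F map needs a positive (df1, df2) pair")
            self.df = (float(df[0]), float(df[1]))
            inmask = self.values if self.mask is None else self.values[self.mask]
            if np.any(inmask[np.isfinite(inmask)] < 0):
                raise ValueError("F values must be nonnegative")
        else:
            if float(np.atleast_1d(self.df)[0]) <= 0:
                raise ValueError("t map needs positive df")
            self.df = float(np.atleast_1d(self.df)[0])
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.affine is None:
            self.affine = default_affine(self.voxel_size_mm, self.values.shape)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.values.astype(np.float32), self.affine)
        nib.save(img, str(path))
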