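"""Subject-level block-design GLM and peak localization.

Used to find each subject's individual activation peak in a 4-min
rest/task alternating block run (30-s blocks, rest first): a boxcar
convolved with the canonical double-gamma HRF, a discrete-cosine
high-pass set (cutoff 128 s), OLS per voxel, and the maximum-t voxel
within a search region as the stimulation target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Bold4D, StatMap, voxel_to_world

__all__ = [
    "BlockDesign",
    "PeakResult",
    "canonical_hrf",
    "build_design",
    "glm_t_map",
    "locate_target",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlockDesign:
    """Rest-first alternating block paradigm sampled at TR."""

    tr_s: float
    n_timepoints: int
    block_length_s: float = 30.0
    high_pass_cutoff_s: float = 128.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0 or self.n_timepoints < 2:
            raise ValueError("invalid timing")
        block_vols = self.block_length_s / self.tr_s
        if abs(block_vols - round(block_vols)) > 1e-9:
            raise ValueError("block boundaries must align to the TR grid")

    @property
    def block_vols(self) -> int:
        return int(round(self.block_length_s / self.tr_s))

    @property
    def duration_s(self) -> float:
        return self.n_timepoints * self.tr_s

    def boxcar(self) -> np.ndarray:
        idx = np.arange(self.n_timepoints)
        return ((idx // self.block_vols) % 2 == 1).astype(float)


@dataclass(frozen=True)
class PeakResult:
    voxel: tuple[int, int, int]
    world_mm: tuple[float, float, float]
    t: float
    p: float


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled every ``tr_s``.

    Difference of two gamma densities (response peaking near 5–6 s, an
    undershoot near 16 s weighted 1/6), peak-normalized to 1; the kernel
    starts at exactly 0 at t = 0.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, duration_s + tr_s / 2.0, tr_s)
    h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def build_design(bd: BlockDesign) -> pd.DataFrame:
    """Design matrix: HRF-convolved task regressor, intercept, DCT drift set.

    The task column is mean-centered.  The discrete-cosine high-pass set
    contains floor(2 * duration / cutoff) columns, i.e. every cosine whose
    period exceeds the cutoff (128 s by default).
    """
    box = bd.boxcar()
    if not box.any():
        raise ValueError("block design contains no task blocks")
    hrf = canonical_hrf(bd.tr_s)
    task = np.convolve(box, hrf)[:bd.n_timepoints]
    task = task - task.mean()
    cols = {"task": task, "intercept": np.ones(bd.n_timepoints)}
    n_dct = int(np.floor(2.0 * bd.duration_s / bd.high_pass_cutoff_s))
    t = np.arange(bd.n_timepoints)
    for k in range(1, n_dct + 1):
        cols[f"dct{k}"] = np.cos(np.pi * (2 * t + 1) * k / (2 * bd.n_timepoints))
    return pd.DataFrame(cols)


def glm_t_map(bold: Bold4D, design: pd.DataFrame, task_column: str = "task"
              ) -> StatMap:
    """Voxelwise OLS t map for the task regressor; df = n - rank(design).

    Voxels fit exactly (zero residual) are guarded against division by
    zero and receive a large finite t, never NaN.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n != bold.n_timepoints:
        raise ValueError("design rows must equal the number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    j = list(design.columns).index(task_column)
    pinv = np.linalg.pinv(X)
    Y = bold.data.reshape(-1, n).T
    beta = pinv @ Y
    resid = Y - X @ beta
    df = n - rank
    sigma2 = np.sum(resid ** 2, axis=0) / df
    cjj = float(np.linalg.inv(X.T @ X)[j, j])
    se = np.sqrt(np.maximum(sigma2 * cjj, 1e-300))
    tvals = (beta[j] / se).reshape(bold.data.shape[:3])
    return StatMap(values=tvals, stat="t", df=float(df), affine=bold.affine,
                   voxel_size_mm=bold.voxel_size_mm)


def locate_target(tmap: StatMap, search_mask: np.ndarray) -> PeakResult:
    """Maximum-t voxel inside the search region (target localization).

    Ties are broken toward the lowest linear index; a peak with t <= 0 is
    still returned but logged as a warning.
    """
    search_mask = np.asarray(search_mask, dtype=bool)
    if search_mask.shape != tmap.values.shape:
        raise ValueError("search mask shape does not match the t map")
    if not search_mask.any():
        raise ValueError("empty search mask")
    vals = np.where(search_mask, tmap.values, -np.inf)
    flat = int(np.argmax(vals))  # argmax takes the lowest linear index on ties
    voxel = tuple(int(v) for v in np.unravel_index(flat, vals.shape))
    t = float(tmap.values[voxel])
    if t <= 0:
        log.warning("locate_target: no voxel with t > 0 in the search region "
                    "(peak t = %.3f)", t)
    p = float(stats.t.sf(t, tmap.df))  # positive-tail p for the reported peak
    world = tuple(float(v) for v in voxel_to_world(tmap.affine, voxel))
    return PeakResult(voxel=voxel, world_mm=world, t=t, p=p)
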