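"""Voxel-level resting-state metrics: regional homogeneity and degree centrality.

Regional homogeneity (ReHo) is Kendall's coefficient of concordance (W)
computed over a voxel's time series together with its nearest neighbors
(7, 19, or 27-voxel cluster including the center), measuring local
temporal synchronization.  Degree centrality (DC) sums each in-mask
voxel's suprathreshold Pearson correlations with every other in-mask
voxel ("weighted positive" form: r values above the cutoff, negatives
excluded).  Both maps are normalized by their gray-matter mean (mReHo,
mDC) before spatial smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import Bold4D, MetricMap

__all__ = [
    "MetricConfig",
    "kcc",
    "neighborhood_offsets",
    "reho_map",
    "dc_map",
    "normalize_by_mask_mean",
    "change_map",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricConfig:
    """Parameters of the metric maps.

    ``reho_neighborhood``: 7 (center + faces), 19 (+ edges) or 27 (+ corners).
    ``dc_r_threshold``: correlations must strictly exceed this to count.
    ``dc_weighted``: sum correlation values rather than counting edges.
    ``dc_positive_only``: exclude negative correlations entirely.
    """

    reho_neighborhood: int = 7
    dc_r_threshold: float = 0.25
    dc_weighted: bool = True
    dc_positive_only: bool = True

    def __post_init__(self) -> None:
        if self.reho_neighborhood not in (7, 19, 27):
            raise ValueError("reho_neighborhood must be 7, 19 or 27")
        if not -1.0 < self.dc_r_threshold < 1.0:
            raise ValueError("dc_r_threshold must lie in (-1, 1)")


# ---------------------------------------------------------------------------
# Kendall's coefficient of concordance


def kcc(series: np.ndarray) -> float:
    """Kendall's W of K time series of length n (rows are series).

    Each series is ranked over time (ties -> average ranks); with R_t the
    column sum of ranks, W = 12 * sum_t (R_t - Rbar)^2 / (K^2 (n^3 - n)).
    W is 1 iff all series rank every time point identically with no ties,
    and 0 under perfect anti-concordance.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("kcc needs a (K >= 2, n >= 2) array")
    k, n = arr.shape
    if np.any(np.ptp(arr, axis=1) == 0):
        log.info("kcc: constant series present; average ranks deflate W")
    ranks = rankdata(arr, axis=1)
    rank_sums = ranks.sum(axis=0)
    dev = rank_sums - k * (n + 1) / 2.0
    return float(12.0 * np.sum(dev ** 2) / (k ** 2 * (n ** 3 - n)))


def neighborhood_offsets(size: int) -> list[tuple[int, int, int]]:
    """Voxel offsets of the 7/19/27 neighborhood (center included)."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if size == 7 and order > 1:
                    continue
                if size == 19 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def _shifted(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Shift a volume (first 3 axes) by ``off``, filling with zeros."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, d in enumerate(off):
        n = arr.shape[ax]
        if d == 0:
            continue
        if d > 0:
            dst[ax], src[ax] = slice(d, n), slice(0, n - d)
        else:
            dst[ax], src[ax] = slice(0, n + d), slice(-d, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def reho_map(bold: Bold4D, mask: np.ndarray, cfg: MetricConfig = MetricConfig()
             ) -> MetricMap:
    """ReHo: Kendall's W over each in-mask voxel and its in-mask neighbors.

    Voxels whose neighborhood holds fewer than 2 in-mask members get 0.
    Vectorized over the grid by accumulating rank volumes over the
    neighborhood shifts; identical to a per-voxel :func:`kcc` loop.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.data.shape[:3]:
        raise ValueError("mask shape does not match the BOLD grid")
    if not mask.any():
        raise ValueError("empty mask")
    n = bold.n_timepoints
    ranks = rankdata(bold.data, axis=-1)
    ranks[~mask] = 0.0
    rank_sum = np.zeros_like(ranks)
    count = np.zeros(mask.shape)
    maskf = mask.astype(float)
    for off in neighborhood_offsets(cfg.reho_neighborhood):
        rank_sum += _shifted(ranks, off)
        count += _shifted(maskf, off)
    dev = rank_sum - count[..., None] * (n + 1) / 2.0
    num = 12.0 * np.sum(dev ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = num / (count ** 2 * (n ** 3 - n))
    valid = mask & (count >= 2)
    n_flagged = int(np.count_nonzero(mask & ~valid))
    if n_flagged:
        log.warning("reho_map: %d in-mask voxels had < 2 in-mask neighborhood "
                    "members; set to 0", n_flagged)
    values = np.where(valid, w, 0.0)
    return MetricMap(values=values, kind="ReHo", mask=mask, affine=bold.affine,
                     voxel_size_mm=bold.voxel_size_mm,
                     provenance={"neighborhood": cfg.reho_neighborhood,
                                 "n_timepoints": n, "flagged": n_flagged})


# ---------------------------------------------------------------------------
# degree centrality


def dc_map(bold: Bold4D, mask: np.ndarray, cfg: MetricConfig = MetricConfig(),
           block_size: int = 1024) -> MetricMap:
    """Weighted degree centrality restricted to the gray-matter mask.

    DC(i) = sum over j != i of r_ij for every pair with r_ij strictly above
    the threshold (and, unless ``dc_positive_only`` is off, only positive
    connections).  Zero-variance voxels contribute no connections.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bold.data.shape[:3]:
        raise ValueError("mask shape does not match the BOLD grid")
    idx = np.flatnonzero(mask.ravel())
    if idx.size < 2:
        raise ValueError("dc_map needs at least 2 in-mask voxels")
    n = bold.n_timepoints
    ts = bold.data.reshape(-1, n)[idx]
    ts = ts - ts.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ts, axis=1)
    degenerate = norm <= 1e-12
    if degenerate.any():
        log.warning("dc_map: %d zero-variance voxels; their correlations set to 0",
                    int(degenerate.sum()))
    z = np.zeros_like(ts)
    z[~degenerate] = ts[~degenerate] / norm[~degenerate, None]

    thr = cfg.dc_r_threshold
    dc = np.zeros(idx.size)
    for start in range(0, idx.size, block_size):
        stop = min(start + block_size, idx.size)
        corr = z[start:stop] @ z.T  # (block, V)
        pos = corr > thr
        contrib = corr * pos if cfg.dc_weighted else pos.astype(float)
        if not cfg.dc_positive_only:
            neg = corr < -thr
            contrib = contrib + (-corr * neg if cfg.dc_weighted else neg.astype(float))
        # exclude self-correlation
        rows = np.arange(start, stop)
        contrib[np.arange(stop - start), rows] = 0.0
        dc[start:stop] = contrib.sum(axis=1)
    values = np.zeros(mask.shape)
    values.ravel()[idx] = dc
    return MetricMap(values=values, kind="DC", mask=mask, affine=bold.affine,
                     voxel_size_mm=bold.voxel_size_mm,
                     provenance={"r_threshold": thr, "weighted": cfg.dc_weighted,
                                 "positive_only": cfg.dc_positive_only,
                                 "n_timepoints": n})


# ---------------------------------------------------------------------------
# normalization and change


_M_KIND = {"ReHo": "mReHo", "DC": "mDC"}


def normalize_by_mask_mean(metric: MetricMap, mask: np.ndarray | None = None
                           ) -> MetricMap:
    """Divide a map by its mean over the gray-matter mask (mask-mean -> 1)."""
    mask = metric.mask if mask is None else np.asarray(mask, dtype=bool)
    mean = float(metric.values[mask].mean())
    if mean <= 0:
        raise ValueError(f"mask mean must be positive to normalize (got {mean})")
    kind = _M_KIND.get(metric.kind, metric.kind)
    prov = dict(metric.provenance)
    prov["mask_mean"] = mean
    return MetricMap(values=metric.values / mean, kind=kind, mask=mask,
                     affine=metric.affine, voxel_size_mm=metric.voxel_size_mm,
                     provenance=prov)


def change_map(post: MetricMap, pre: MetricMap) -> MetricMap:
    """Voxelwise post-minus-pre change of two like-kind maps."""
    if post.kind != pre.kind:
        raise ValueError(f"kind mismatch: {post.kind} vs {pre.kind}")
    if post.mask.shape != pre.mask.shape or not np.array_equal(post.mask, pre.mask):
        raise ValueError("change_map requires identical masks")
    prov = {"base_kind": post.kind, "post": post.provenance, "pre": pre.provenance}
    return MetricMap(values=post.values - pre.values, kind="change",
                     mask=post.mask, affine=post.affine,
                     voxel_size_mm=post.voxel_size_mm, provenance=prov)
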