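"""Group-level univariate statistics on change maps.

Voxelwise repeated-measures one-way ANOVA across the three stimulation
conditions (subjects as blocks), cluster-level correction under
stationary Gaussian-random-field (GRF) theory (voxel-forming p < 0.001,
cluster-level p < 0.05), pairwise paired t tests with Bonferroni
control, image-smoothness (FWHM) estimation from residual maps, and a
permutation-based cluster null for cross-checking the GRF correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy import ndimage, stats

from .containers import MetricMap, StatMap, voxel_to_world, world_to_voxel

__all__ = [
    "ChangePanel",
    "PairedTResult",
    "ClusterTable",
    "rm_anova_map",
    "paired_t",
    "t_from_summary",
    "bonferroni_alpha",
    "estimate_fwhm",
    "grf_cluster_table",
    "permutation_max_cluster_null",
    "extract_values",
]

log = logging.getLogger(__name__)


@dataclass
class ChangePanel:
    """Per-subject, per-condition change maps on a common grid and mask.

    ``data`` has shape (n_subjects, n_conditions, x, y, z).
    """

    data: np.ndarray
    subjects: list[str]
    conditions: list[str]
    mask: np.ndarray
    affine: np.ndarray
    voxel_size_mm: float | tuple[float, float, float] = 3.0
    metric: str = "change"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 5:
            raise ValueError("panel data must be (subjects, conditions, x, y, z)")
        n, k = self.data.shape[:2]
        if n != len(self.subjects) or k != len(self.conditions):
            raise ValueError("panel labels do not match data shape")
        if self.data.shape[2:] != self.mask.shape:
            raise ValueError("panel grid does not match mask")
        if not np.all(np.isfinite(self.data[:, :, self.mask])):
            raise ValueError("panel contains non-finite in-mask values")

    @classmethod
    def from_maps(cls, maps: dict[str, dict[str, MetricMap]],
                  conditions: list[str] | None = None) -> "ChangePanel":
        """Assemble from {subject: {condition: MetricMap}} (complete panel)."""
        subjects = sorted(maps)
        conditions = conditions or sorted(maps[subjects[0]])
        first = maps[subjects[0]][conditions[0]]
        data = np.stack([
            np.stack([maps[s][c].values for c in conditions]) for s in subjects])
        for s in subjects:
            missing = [c for c in conditions if c not in maps[s]]
            if missing:
                raise ValueError(f"subject {s} missing conditions {missing}")
        return cls(data=data, subjects=subjects, conditions=list(conditions),
                   mask=first.mask, affine=first.affine,
                   voxel_size_mm=first.voxel_size_mm)

    def condition_values(self, condition: str) -> np.ndarray:
        """(n_subjects, x, y, z) slab for one condition."""
        return self.data[:, self.conditions.index(condition)]


# ---------------------------------------------------------------------------
# ANOVA and t tests


def rm_anova_map(panel: ChangePanel, within_subject: bool = True) -> StatMap:
    """Voxelwise one-way ANOVA F map over conditions.

    With ``within_subject`` (default) the design is repeated measures:
    the subject x condition table is decomposed into condition, subject
    and residual sums of squares, F = MS_condition / MS_error with
    df = (k-1, (k-1)(n-1)).  With the flag off, conditions are treated
    as independent groups (between-subjects one-way ANOVA,
    df = (k-1, k(n-1))) for sensitivity analysis.

    Voxels with zero error variance but nonzero condition variance get
    an infinite F (flagged in the log); downstream feature selection
    excludes non-finite values.
    """
    n, k = panel.data.shape[:2]
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    flat = panel.data.reshape(n, k, -1)
    grand = flat.mean(axis=(0, 1))
    cond_mean = flat.mean(axis=0)    # (k, V)
    ss_cond = n * np.sum((cond_mean - grand) ** 2, axis=0)
    if within_subject:
        subj_mean = flat.mean(axis=1)  # (n, V)
        ss_tot = np.sum((flat - grand) ** 2, axis=(0, 1))
        ss_subj = k * np.sum((subj_mean - grand) ** 2, axis=0)
        ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
        df = (k - 1.0, (k - 1.0) * (n - 1.0))
    else:
        ss_err = np.sum((flat - cond_mean[None]) ** 2, axis=(0, 1))
        df = (k - 1.0, k * (n - 1.0))
    ms_cond = ss_cond / df[0]
    ms_err = ss_err / df[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_cond / ms_err
    # numerically-zero variances, relative to the voxel's total scale
    ss_tot_all = np.sum((flat - grand) ** 2, axis=(0, 1))
    tiny = 1e-12 * (ss_tot_all / (n * k - 1) + np.finfo(float).tiny)
    zero_err = ms_err <= tiny
    if np.any(zero_err):
        f = np.where(zero_err & (ms_cond > tiny), np.inf, f)
        f = np.where(zero_err & (ms_cond <= tiny), 0.0, f)
        n_inmask = int(np.count_nonzero(zero_err.reshape(panel.mask.shape) & panel.mask))
        if n_inmask:
            log.warning("rm_anova_map: %d in-mask voxels with zero error variance "
                        "flagged as infinite F", n_inmask)
    values = np.where(panel.mask.ravel(), f, 0.0).reshape(panel.mask.shape)
    return StatMap(values=values, stat="F", df=df, mask=panel.mask,
                   affine=panel.affine, voxel_size_mm=panel.voxel_size_mm)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    sd_diff: float
    n: int
    degenerate: bool = False

    @property
    def df(self) -> int:
        return self.n - 1


def paired_t(a, b) -> PairedTResult:
    """Paired t test on per-subject values: d = a - b, t = mean/(sd/sqrt(n)).

    Two-tailed p.  A zero-variance difference is degenerate: t is 0 when
    the mean difference is also 0, otherwise signed infinity, and the
    result is flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired_t needs two equal-length 1D arrays, n >= 2")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean)) * np.inf
        p = 1.0 if mean == 0.0 else 0.0
        return PairedTResult(t=t, p=p, mean_diff=mean, sd_diff=sd, n=n,
                             degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), p=p, mean_diff=mean, sd_diff=sd, n=n)


def t_from_summary(mean_diff: float, sd_diff: float, n: int) -> float:
    """Recompute a paired t value from its printed mean, SD and n."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    return float(mean_diff / (sd_diff / np.sqrt(n)))


def bonferroni_alpha(alpha: float = 0.05, m: int = 15) -> float:
    """Bonferroni-corrected per-comparison significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# smoothness and GRF cluster correction


def estimate_fwhm(residuals: np.ndarray, mask: np.ndarray,
                  voxel_size_mm: float | tuple[float, float, float] = 3.0
                  ) -> np.ndarray:
    """Per-axis image smoothness (FWHM, mm) from residual maps.

    Residual maps (m, x, y, z) are standardized voxelwise across maps;
    the variance of their spatial first differences along each axis
    estimates the derivative variance lambda of the unit-variance field,
    and FWHM = sqrt(4 ln 2 / lambda) voxels (Gaussian autocorrelation
    model).  The estimate is floored at one voxel.
    """
    res = np.asarray(residuals, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if res.ndim != 4 or res.shape[0] < 2:
        raise ValueError("need >= 2 residual maps of shape (m, x, y, z)")
    sd = res.std(axis=0)
    ok = mask & (sd > 1e-12)
    u = np.zeros_like(res)
    u[:, ok] = res[:, ok] / sd[ok]
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    fwhm = np.empty(3)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        both = ok[tuple(sl_a)] & ok[tuple(sl_b)]
        if not both.any():
            fwhm[ax] = vs[ax]
            continue
        diff = (u[(slice(None),) + tuple(sl_a)] - u[(slice(None),) + tuple(sl_b)])
        lam = float(np.mean(diff[:, both] ** 2))
        fwhm_vox = np.sqrt(4.0 * np.log(2.0) / lam) if lam > 0 else np.inf
        fwhm[ax] = max(fwhm_vox, 1.0) * vs[ax]
    return fwhm


@dataclass
class ClusterTable:
    """Suprathreshold clusters with GRF-corrected p values."""

    table: pd.DataFrame
    voxel_p: float
    cluster_p: float
    stat_threshold: float
    fwhm_mm: np.ndarray
    resels: float
    connectivity: int = 6
    labels: np.ndarray | None = field(default=None, repr=False)

    def surviving(self) -> pd.DataFrame:
        return self.table[self.table["survives"]]

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


_CONN_STRUCTS = {6: 1, 18: 2, 26: 3}


def _stat_threshold(stat: StatMap, voxel_p: float) -> float:
    if stat.stat == "F":
        return float(stats.f.isf(voxel_p, *stat.df))
    return float(stats.t.isf(voxel_p, stat.df))


def grf_cluster_table(stat: StatMap, mask: np.ndarray, fwhm_mm,
                      voxel_p: float = 0.001, cluster_p: float = 0.05,
                      connectivity: int = 6) -> ClusterTable:
    """Cluster-level familywise correction under stationary GRF theory.

    The statistic map is thresholded at the voxel-forming p; clusters are
    formed by face connectivity (configurable).  The voxel threshold is
    mapped to an equivalent Gaussian height u, the search volume to
    resels R = V / prod(FWHM); the expected number of clusters follows
    the 3D Euler-characteristic density,

        E[m] = R (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2),

    and cluster extents follow the standard exponential tail
    P(n >= s) = exp(-beta s^{2/3}) with beta = (Gamma(5/2) E[m]/E[N])^{2/3}.
    The familywise-corrected cluster p is 1 - exp(-E[m] P(n >= s)).
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in _CONN_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    thr = _stat_threshold(stat, voxel_p)
    supra = mask & np.isfinite(stat.values) & (stat.values > thr)
    # GRF constants
    vs = np.broadcast_to(np.asarray(stat.voxel_size_mm, dtype=float), (3,))
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    n_mask = int(mask.sum())
    resels = n_mask * float(np.prod(vs / np.maximum(fwhm, vs)))
    u = float(stats.norm.isf(voxel_p))
    e_clusters = (resels * (4 * np.log(2.0)) ** 1.5 / (2.0 * np.pi) ** 2
                  * (u ** 2 - 1.0) * np.exp(-u ** 2 / 2.0))
    e_voxels = n_mask * float(stats.norm.sf(u))
    cols = ["x_mm", "y_mm", "z_mm", "extent_voxels", "extent_mm3",
            "peak_stat", "peak_p", "cluster_p_fwe", "survives"]
    structure = ndimage.generate_binary_structure(3, _CONN_STRUCTS[connectivity])
    labels, n_clusters = ndimage.label(supra, structure=structure)
    if n_clusters == 0:
        return ClusterTable(table=pd.DataFrame(columns=cols), voxel_p=voxel_p,
                            cluster_p=cluster_p, stat_threshold=thr,
                            fwhm_mm=np.asarray(fwhm), resels=resels,
                            connectivity=connectivity, labels=labels)
    mean_extent = e_voxels / max(e_clusters, 1e-300)
    beta = (math.gamma(2.5) / mean_extent) ** (2.0 / 3.0)
    voxel_volume = float(np.prod(vs))
    rows = []
    for lab in range(1, n_clusters + 1):
        in_cluster = labels == lab
        extent = int(in_cluster.sum())
        vals = np.where(in_cluster, stat.values, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        peak_stat = float(stat.values[peak])
        if stat.stat == "F":
            peak_p = float(stats.f.sf(peak_stat, *stat.df))
        else:
            peak_p = float(stats.t.sf(peak_stat, stat.df))
        p_extent = float(np.exp(-beta * extent ** (2.0 / 3.0)))
        p_fwe = float(1.0 - np.exp(-e_clusters * p_extent))
        world = voxel_to_world(stat.affine, peak)
        rows.append({"x_mm": world[0], "y_mm": world[1], "z_mm": world[2],
                     "extent_voxels": extent, "extent_mm3": extent * voxel_volume,
                     "peak_stat": peak_stat, "peak_p": peak_p,
                     "cluster_p_fwe": p_fwe, "survives": p_fwe < cluster_p})
    table = pd.DataFrame(rows, columns=cols).sort_values(
        "extent_voxels", ascending=False, ignore_index=True)
    return ClusterTable(table=table, voxel_p=voxel_p, cluster_p=cluster_p,
                        stat_threshold=thr, fwhm_mm=np.asarray(fwhm),
                        resels=resels, connectivity=connectivity, labels=labels)


def permutation_max_cluster_null(panel: ChangePanel, n_permutations: int = 500,
                                 voxel_p: float = 0.001, connectivity: int = 6,
                                 seed: int = 0) -> np.ndarray:
    """Null distribution of the maximum cluster extent (in voxels).

    Condition labels are permuted independently within each subject
    (exchangeability under the within-subject null), the repeated-
    measures F map is recomputed, thresholded at the voxel-forming p,
    and the largest face-connected cluster extent recorded.  Serves as a
    nonparametric cross-check of the GRF cluster correction.
    """
    rng = default_rng(SeedSequence([seed, 71]))
    n, k = panel.data.shape[:2]
    thr = None
    structure = ndimage.generate_binary_structure(
        3, _CONN_STRUCTS[connectivity])
    out = np.zeros(n_permutations)
    for i in range(n_permutations):
        perm = panel.data.copy()
        for s in range(n):
            perm[s] = perm[s, rng.permutation(k)]
        fmap = rm_anova_map(ChangePanel(
            data=perm, subjects=panel.subjects, conditions=panel.conditions,
            mask=panel.mask, affine=panel.affine,
            voxel_size_mm=panel.voxel_size_mm))
        if thr is None:
            thr = _stat_threshold(fmap, voxel_p)
        supra = panel.mask & np.isfinite(fmap.values) & (fmap.values > thr)
        labels, n_clusters = ndimage.label(supra, structure=structure)
        if n_clusters:
            out[i] = ndimage.sum_labels(
                np.ones_like(labels), labels, range(1, n_clusters + 1)).max()
    return out


def extract_values(panel: ChangePanel, coordinate_mm) -> pd.DataFrame:
    """Per-subject x condition values at a world-coordinate peak voxel."""
    voxel = world_to_voxel(panel.affine, coordinate_mm)
    if not (all(0 <= v < s for v, s in zip(voxel, panel.mask.shape))
            and panel.mask[voxel]):
        raise ValueError(f"coordinate {tuple(coordinate_mm)} maps to voxel "
                         f"{voxel}, outside the mask")
    values = panel.data[:, :, voxel[0], voxel[1], voxel[2]]
    return pd.DataFrame(values, index=pd.Index(panel.subjects, name="subject_id"),
                        columns=panel.conditions)
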