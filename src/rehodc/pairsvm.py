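"""PAIR SVM: within-subject two-condition classification.

For a contrast (X, Y) between stimulation conditions, subjects are
randomly split into group A ("X minus Y" change vectors, labeled +1) and
group B ("Y minus X", labeled -1).  Features are the voxels whose
uncorrected ANOVA-F p falls below a threshold (default 0.05).  A linear
soft-margin SVM is trained on stratified random half-splits, the
held-out accuracy and the weight vector are averaged over repetitions
(default 100), and mean weights are projected back into a brain map.
A single-voxel ROC/AUC (Mann-Whitney concordance) provides the
univariate baseline the multivariate classifier is compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import stats
from sklearn.svm import SVC

from .containers import MetricMap, StatMap
from .groupstats import ChangePanel

__all__ = [
    "FeatureMask",
    "PairDataset",
    "SvmModel",
    "CvResult",
    "feature_mask_from_f",
    "build_pair_dataset",
    "train_linear_svm",
    "split_half_cv",
    "split_half_cv_clean",
    "project_weights",
    "voxel_auc",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMask:
    """Ordered voxel indices (flat, C order) selected for classification."""

    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    p_threshold: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.size != np.unique(idx).size:
            raise ValueError("feature indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class PairDataset:
    """Signed-difference samples: one row per subject, labels +-1."""

    samples: np.ndarray
    labels: np.ndarray
    subjects: list[str]
    groups: np.ndarray  # "A" or "B" per subject
    contrast: tuple[str, str]
    seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.shape[0] != self.labels.size:
            raise ValueError("samples and labels disagree")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +-1")

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class SvmModel:
    weights: np.ndarray
    bias: float
    C: float
    tol: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x) >= 0, 1, -1)


@dataclass
class CvResult:
    accuracies: np.ndarray
    mean_weights: np.ndarray
    repeats: int
    seed: int
    C: float

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


def feature_mask_from_f(fmap: StatMap, mask: np.ndarray,
                        p_thresh: float = 0.05) -> FeatureMask:
    """Voxels with uncorrected F-derived p below the threshold, in-mask.

    Non-finite F values (flagged zero-error-variance voxels) are excluded.
    """
    if fmap.stat != "F":
        raise ValueError("feature selection expects an F map")
    mask = np.asarray(mask, dtype=bool)
    finite = np.isfinite(fmap.values)
    p = np.ones_like(fmap.values)
    p[finite] = stats.f.sf(fmap.values[finite], *fmap.df)
    selected = mask & finite & (p < p_thresh)
    idx = np.flatnonzero(selected.ravel())
    if idx.size == 0:
        raise ValueError("no voxels pass the feature threshold; relax p_thresh")
    log.info("feature mask: %d of %d gray-matter voxels at p < %g",
             idx.size, int(mask.sum()), p_thresh)
    return FeatureMask(indices=idx, grid_shape=mask.shape, p_threshold=p_thresh)


def build_pair_dataset(panel: ChangePanel, contrast: tuple[str, str],
                       fm: FeatureMask, seed: int = 0) -> PairDataset:
    """Randomly split subjects into groups A and B and form signed samples.

    Group A (floor(n/2) subjects) carries change(X) - change(Y) with
    label +1; group B carries the reversed difference with label -1.
    """
    cond_x, cond_y = contrast
    if panel.mask.shape != fm.grid_shape:
        raise ValueError("feature mask grid does not match the panel")
    n = len(panel.subjects)
    if n < 4:
        raise ValueError("need at least 4 subjects for split-half training")
    diff = (panel.condition_values(cond_x) - panel.condition_values(cond_y))
    feats = diff.reshape(n, -1)[:, fm.indices]
    rng = default_rng(SeedSequence([seed, 101]))
    order = rng.permutation(n)
    n_a = n // 2
    groups = np.empty(n, dtype="<U1")
    groups[order[:n_a]] = "A"
    groups[order[n_a:]] = "B"
    sign = np.where(groups == "A", 1, -1)
    samples = feats * sign[:, None]
    return PairDataset(samples=samples, labels=sign, subjects=list(panel.subjects),
                       groups=groups, contrast=(cond_x, cond_y), seed=seed)


def train_linear_svm(samples: np.ndarray, labels: np.ndarray,
                     C: float = 1.0, tol: float = 1e-3) -> SvmModel:
    """Soft-margin linear SVM fit by an SMO-type dual solver.

    The decision function is w.x + b; weights come from the support
    vectors of the dual solution at KKT tolerance ``tol``.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both classes")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(np.asarray(samples, dtype=float), labels)
    return SvmModel(weights=clf.coef_.ravel().copy(),
                    bias=float(clf.intercept_[0]), C=C, tol=tol)


def split_half_cv(ds: PairDataset, repeats: int = 100, C: float = 1.0,
                  seed: int = 0, tol: float = 1e-3) -> CvResult:
    """Repeated stratified split-half validation.

    Each repetition draws half of group A and half of group B for
    training (so both classes are represented on both sides), tests on
    the held-out half, and records accuracy and the weight vector; the
    mean accuracy and the mean (signed) weight vector are returned.
    Degenerate single-class training halves are redrawn and logged.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = default_rng(SeedSequence([seed, 103]))
    idx_a = np.flatnonzero(ds.groups == "A")
    idx_b = np.flatnonzero(ds.groups == "B")
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each group needs >= 2 subjects to split")
    accs = np.empty(repeats)
    w_sum = np.zeros(ds.samples.shape[1])
    for rep in range(repeats):
        for attempt in range(100):
            tr = np.concatenate([
                rng.permutation(idx_a)[: idx_a.size // 2],
                rng.permutation(idx_b)[: idx_b.size // 2],
            ])
            if np.unique(ds.labels[tr]).size == 2:
                break
            log.warning("split_half_cv: single-class training half redrawn "
                        "(repetition %d)", rep)
        else:  # pragma: no cover - unreachable with both groups >= 2
            raise RuntimeError("could not draw a two-class training half")
        te = np.setdiff1d(np.arange(ds.n), tr)
        model = train_linear_svm(ds.samples[tr], ds.labels[tr], C=C, tol=tol)
        pred = model.predict(ds.samples[te])
        accs[rep] = float(np.mean(pred == ds.labels[te]))
        w_sum += model.weights
    return CvResult(accuracies=accs, mean_weights=w_sum / repeats,
                    repeats=repeats, seed=seed, C=C)


def split_half_cv_clean(panel: ChangePanel, contrast: tuple[str, str],
                        repeats: int = 100, C: float = 1.0, seed: int = 0,
                        p_thresh: float = 0.05, tol: float = 1e-3) -> CvResult:
    """Split-half validation with feature selection inside each training fold.

    Selecting features from an ANOVA F map computed on the *whole* cohort
    and then cross-validating on that same cohort is circular ("double
    dipping"): even null contrasts classify above chance because the
    selected voxels have, by construction, consistent condition
    differences in these subjects.  This variant recomputes the F map
    from the training half only in every repetition, which is the safe
    procedure for new data.  Weight vectors live on per-fold feature sets
    and are not averaged; ``mean_weights`` is empty.
    """
    from .groupstats import rm_anova_map

    ds_full = build_pair_dataset(  # group assignment only; features resolved per fold
        panel, contrast,
        FeatureMask(indices=np.flatnonzero(panel.mask.ravel()),
                    grid_shape=panel.mask.shape, p_threshold=1.0),
        seed=seed)
    rng = default_rng(SeedSequence([seed, 107]))
    idx_a = np.flatnonzero(ds_full.groups == "A")
    idx_b = np.flatnonzero(ds_full.groups == "B")
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each group needs >= 2 subjects to split")
    subjects = np.asarray(panel.subjects)
    accs = np.empty(repeats)
    for rep in range(repeats):
        tr = np.concatenate([rng.permutation(idx_a)[: idx_a.size // 2],
                             rng.permutation(idx_b)[: idx_b.size // 2]])
        te = np.setdiff1d(np.arange(ds_full.n), tr)
        sub_panel = ChangePanel(
            data=panel.data[tr], subjects=list(subjects[tr]),
            conditions=panel.conditions, mask=panel.mask, affine=panel.affine,
            voxel_size_mm=panel.voxel_size_mm)
        fmap = rm_anova_map(sub_panel)
        fm = feature_mask_from_f(fmap, panel.mask, p_thresh=p_thresh)
        model = train_linear_svm(ds_full.samples[tr][:, fm.indices],
                                 ds_full.labels[tr], C=C, tol=tol)
        pred = model.predict(ds_full.samples[te][:, fm.indices])
        accs[rep] = float(np.mean(pred == ds_full.labels[te]))
    return CvResult(accuracies=accs, mean_weights=np.empty(0), repeats=repeats,
                    seed=seed, C=C)


def project_weights(cv: CvResult, fm: FeatureMask, mask: np.ndarray,
                    affine: np.ndarray | None = None,
                    voxel_size_mm: float = 3.0) -> MetricMap:
    """Write the mean weight vector back to its voxel positions."""
    if cv.mean_weights.size != len(fm):
        raise ValueError("weight vector length does not match the feature mask")
    values = np.zeros(int(np.prod(fm.grid_shape)))
    values[fm.indices] = cv.mean_weights
    values = values.reshape(fm.grid_shape)
    return MetricMap(values=values, kind="weight", mask=np.asarray(mask, bool),
                     affine=affine, voxel_size_mm=voxel_size_mm,
                     provenance={"repeats": cv.repeats, "C": cv.C, "seed": cv.seed})


def voxel_auc(values_a, values_b) -> float:
    """ROC AUC of one voxel's values: condition A treated as positive.

    Computed through the Mann-Whitney rank identity; tied pairs count
    one half.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("voxel_auc needs nonempty value lists")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = ranks[: a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))
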