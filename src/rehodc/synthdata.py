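"""Synthetic resting-state and task fMRI cohorts with known ground truth.

The study design emulated here is within-subject: every subject is scanned
before and after each of three stimulation conditions (High, Low, Sham),
plus one block-design motor task run used to localize a stimulation target.
Because real data of this kind are rarely shareable, the simulator produces
a full cohort on a small common grid with the statistical structure the
downstream analysis assumes:

* baseline ~100 with a small linear drift per voxel,
* AR(1) temporal noise, spatially smoothed to a configurable FWHM,
* six motion parameters (random walks) coupled weakly into the signal,
* an injectable *local-synchronization* effect — a band-limited
  (0.01–0.08 Hz) signal field that neighboring voxels share, raising
  regional homogeneity inside a ground-truth ellipsoid, and
* an injectable *hub-connectivity* effect — one band-limited signal
  coupled to every ground-truth voxel, raising their degree centrality.

Effects are injected only in the (condition, phase) cells named by the
:class:`GroundTruth`, by default the post-stimulation phase of the High
condition, with per-subject amplitude heterogeneity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import ndimage

from .containers import Bold4D, default_affine

__all__ = [
    "SimConfig",
    "Ellipsoid",
    "GroundTruth",
    "SessionRecord",
    "ConfigError",
    "make_mask",
    "simulate_rest_session",
    "simulate_task_session",
    "simulate_cohort",
    "save_manifest",
    "load_manifest",
]

log = logging.getLogger(__name__)

CONDITIONS = ("High", "Low", "Sham")
PHASES = ("pre", "post")

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_rad", "rot_y_rad", "rot_z_rad"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates: center and radii."""

    center: tuple[int, int, int]
    radii: tuple[float, float, float]

    def mask(self, shape: Sequence[int]) -> np.ndarray:
        if min(self.radii) <= 0:
            raise ConfigError("effect region radii must all be positive")
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        d2 = sum(((g - c) / r) ** 2
                 for g, c, r in zip(grids, self.center, self.radii))
        return d2 <= 1.0


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort.

    Defaults mirror the emulated study: 31 subjects, TR 2 s, 8-min rest
    runs (240 volumes), 4-min task runs, three conditions x two phases,
    on a 24x24x18 grid of 3-mm voxels (a small stand-in for the acquired
    64x64x43 matrix so the full pipeline runs in minutes).
    """

    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 3.0
    tr_s: float = 2.0
    n_timepoints: int = 240
    n_subjects: int = 31
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    spatial_fwhm_mm: float = 4.0
    effect_region: Ellipsoid = field(
        default_factory=lambda: Ellipsoid(center=(16, 8, 6), radii=(3.0, 3.0, 2.0)))
    reho_effect: float = 1.0
    dc_effect: float = 1.2
    subject_sd_frac: float = 0.3
    seed: int = 0
    # task run
    task_duration_s: float = 240.0
    block_length_s: float = 30.0
    task_amplitude: float = 1.5
    task_target: tuple[int, int, int] = (7, 8, 13)
    # nuisance structure
    drift_sd: float = 0.005
    motion_step_mm: float = 0.01
    motion_step_rad: float = 2e-4
    motion_coupling: float = 0.2
    # which (condition, phase) cells carry the injected effect
    effect_cells: tuple[tuple[str, str], ...] = (("High", "post"),)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 8:
            raise ConfigError("grid_shape must be 3 axes, each >= 8")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigError("ar1_rho must lie in [0, 1)")
        if self.n_timepoints <= 10:
            raise ConfigError("n_timepoints must exceed 10")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ConfigError("tr_s and voxel_size_mm must be positive")
        if self.n_subjects < 1:
            raise ConfigError("need at least one subject")
        for cond, phase in self.effect_cells:
            if cond not in CONDITIONS or phase not in PHASES:
                raise ConfigError(f"unknown effect cell ({cond}, {phase})")

    @property
    def n_task_timepoints(self) -> int:
        return int(round(self.task_duration_s / self.tr_s))

    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_size_mm, self.grid_shape)


@dataclass
class GroundTruth:
    """The injected effect: where, in which cells, and how strong."""

    effect_mask: np.ndarray
    condition_phase: tuple[tuple[str, str], ...]
    reho_effect: float
    dc_effect: float
    seed: int
    subject_amplitudes: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.effect_mask = np.asarray(self.effect_mask, dtype=bool)
        if not self.effect_mask.any():
            raise ConfigError("ground-truth effect mask is empty")

    def amplitudes_for(self, subject_id: str) -> tuple[float, float]:
        return self.subject_amplitudes.get(
            subject_id, (self.reho_effect, self.dc_effect))


@dataclass(frozen=True)
class SessionRecord:
    subject_id: str
    condition: str
    phase: str
    bold_path: str
    motion_path: str


# ---------------------------------------------------------------------------
# mask


def make_mask(cfg: SimConfig) -> np.ndarray:
    """Generate the gray-matter analysis mask.

    A smooth tissue-probability blob (radial falloff plus smoothed noise)
    thresholded at 0.2, reduced to its largest face-connected component —
    the synthetic analogue of masking at >20% gray-matter probability.
    The configured effect region must fall entirely inside the mask.
    """
    shape = cfg.grid_shape
    rng = default_rng(SeedSequence([cfg.seed, 11]))
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((2.0 * (g - (s - 1) / 2.0) / s) ** 2 for g, s in zip(grids, shape))
    prob = 1.2 * np.exp(-1.8 * r2)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    prob = prob + 0.08 * noise / max(noise.std(), 1e-12)
    mask = prob > 0.2
    labels, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp == 0:
        raise ConfigError("mask generation produced no voxels")
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    effect = cfg.effect_region.mask(shape)
    if not effect.any():
        raise ConfigError("effect region is empty")
    if np.any(effect & ~mask):
        raise ConfigError("effect region extends outside the gray-matter mask")
    return mask


# ---------------------------------------------------------------------------
# building blocks


def _band_limited(rng: Generator, shape: tuple[int, ...], tr_s: float,
                  low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """White noise restricted to [low, high] Hz, unit SD along the last axis."""
    n = shape[-1]
    x = rng.standard_normal(shape)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-12)


def _ar1_smooth_noise(rng: Generator, cfg: SimConfig, n_t: int) -> np.ndarray:
    """AR(1) temporal noise, spatially smoothed, scaled to cfg.noise_sd."""
    e = rng.standard_normal(cfg.grid_shape + (n_t,))
    rho = cfg.ar1_rho
    if rho > 0:
        innov = np.sqrt(1.0 - rho ** 2)
        for t in range(1, n_t):
            e[..., t] = rho * e[..., t - 1] + innov * e[..., t]
    sigma_vox = cfg.spatial_fwhm_mm * _FWHM_TO_SIGMA / cfg.voxel_size_mm
    if sigma_vox > 0:
        e = ndimage.gaussian_filter(e, sigma=(sigma_vox,) * 3 + (0.0,))
    return e * (cfg.noise_sd / max(e.std(), 1e-12))


def _motion_table(rng: Generator, cfg: SimConfig, n_t: int) -> pd.DataFrame:
    steps = np.concatenate([
        rng.normal(0.0, cfg.motion_step_mm, size=(n_t, 3)),
        rng.normal(0.0, cfg.motion_step_rad, size=(n_t, 3)),
    ], axis=1)
    walk = np.cumsum(steps, axis=0)
    return pd.DataFrame(walk, columns=MOTION_COLUMNS)


def _base_signal(rng: Generator, cfg: SimConfig, n_t: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Baseline + drift + motion-coupled nuisance + AR(1) smooth noise."""
    noise = _ar1_smooth_noise(rng, cfg, n_t)
    slope = rng.normal(0.0, cfg.drift_sd, size=cfg.grid_shape)
    t_idx = np.arange(n_t, dtype=float)
    motion = _motion_table(rng, cfg, n_t)
    gamma = rng.normal(0.0, cfg.motion_coupling, size=cfg.grid_shape + (6,))
    y = (100.0
         + slope[..., None] * t_idx
         + np.einsum("tk,xyzk->xyzt", motion.to_numpy(), gamma)
         + noise)
    return y, motion


# ---------------------------------------------------------------------------
# sessions


def simulate_rest_session(cfg: SimConfig, subject_id: str, condition: str,
                          phase: str, truth: GroundTruth,
                          seed: int | SeedSequence) -> tuple[Bold4D, pd.DataFrame]:
    """Simulate one resting-state run and its motion-parameter table.

    If (condition, phase) is an effect cell of ``truth``, the run carries
    the subject's local-synchronization signal (amplitude ``a``) and the
    global hub signal (amplitude ``b``) inside the ground-truth region.
    Reproducible bit-for-bit from ``seed``.
    """
    if condition not in CONDITIONS or phase not in PHASES:
        raise ConfigError(f"unknown session cell ({condition}, {phase})")
    if truth.effect_mask.shape != cfg.grid_shape:
        raise ConfigError("ground truth grid does not match the configuration")
    rng = default_rng(seed)
    n_t = cfg.n_timepoints
    y, motion = _base_signal(rng, cfg, n_t)

    if (condition, phase) in truth.condition_phase:
        a, b = truth.amplitudes_for(subject_id)
        if a != 0.0:
            # band-limited field smoothed so that *neighboring* voxels share
            # signal: raises local synchrony (ReHo) without long-range coupling
            g = _band_limited(rng, cfg.grid_shape + (n_t,), cfg.tr_s)
            g = ndimage.gaussian_filter(g, sigma=(1.2, 1.2, 1.2, 0.0))
            g /= np.maximum(g.std(axis=-1, keepdims=True), 1e-12)
            y[truth.effect_mask] += a * g[truth.effect_mask]
        if b != 0.0:
            # one shared signal coupled to every effect voxel: raises their
            # connectivity to the rest of the region (degree centrality)
            h = _band_limited(rng, (n_t,), cfg.tr_s)
            y[truth.effect_mask] += b * h
    return Bold4D(y, tr_s=cfg.tr_s, voxel_size_mm=cfg.voxel_size_mm,
                  affine=cfg.affine()), motion


def task_boxcar(cfg: SimConfig) -> np.ndarray:
    """Rest-first alternating 30-s block indicator sampled at TR."""
    n_t = cfg.n_task_timepoints
    block_vols = int(round(cfg.block_length_s / cfg.tr_s))
    idx = np.arange(n_t)
    return ((idx // block_vols) % 2 == 1).astype(float)


def simulate_task_session(cfg: SimConfig, subject_id: str,
                          target_center: tuple[int, int, int],
                          seed: int | SeedSequence,
                          amplitude: float | None = None) -> Bold4D:
    """Simulate one block-design task run with activation at ``target_center``.

    The activation is a boxcar convolved with the canonical HRF, scaled by
    a Gaussian spatial profile (sigma 1.5 voxels) around the target.
    """
    from .taskglm import canonical_hrf  # local import: no module cycle

    mask = make_mask(cfg)
    tc = tuple(int(v) for v in target_center)
    if not (all(0 <= c < s for c, s in zip(tc, cfg.grid_shape)) and mask[tc]):
        raise ConfigError(f"task target {tc} lies outside the gray-matter mask")
    amp = cfg.task_amplitude if amplitude is None else float(amplitude)
    rng = default_rng(seed)
    n_t = cfg.n_task_timepoints
    y, _ = _base_signal(rng, cfg, n_t)
    if amp != 0.0:
        hrf = canonical_hrf(cfg.tr_s)
        reg = np.convolve(task_boxcar(cfg), hrf)[:n_t]
        grids = np.ogrid[tuple(slice(0, s) for s in cfg.grid_shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, tc))
        profile = np.exp(-d2 / (2.0 * 1.5 ** 2))
        profile[~mask] = 0.0
        y += amp * profile[..., None] * reg
    return Bold4D(y, tr_s=cfg.tr_s, voxel_size_mm=cfg.voxel_size_mm,
                  affine=cfg.affine())


# ---------------------------------------------------------------------------
# cohort


def _session_seed(cfg: SimConfig, *key: int) -> int:
    return int(SeedSequence([cfg.seed, *key]).generate_state(1)[0])


def _subject_ids(n: int) -> list[str]:
    return [f"sub{i + 1:03d}" for i in range(n)]


def make_ground_truth(cfg: SimConfig) -> GroundTruth:
    """Build the cohort ground truth, drawing per-subject effect amplitudes."""
    mask = make_mask(cfg)
    effect = cfg.effect_region.mask(cfg.grid_shape) & mask
    rng = default_rng(SeedSequence([cfg.seed, 23]))
    amps: dict[str, tuple[float, float]] = {}
    for sid in _subject_ids(cfg.n_subjects):
        a = max(0.0, rng.normal(cfg.reho_effect, cfg.subject_sd_frac * abs(cfg.reho_effect)))
        b = max(0.0, rng.normal(cfg.dc_effect, cfg.subject_sd_frac * abs(cfg.dc_effect)))
        amps[sid] = (a, b)
    return GroundTruth(effect_mask=effect, condition_phase=tuple(cfg.effect_cells),
                       reho_effect=cfg.reho_effect, dc_effect=cfg.dc_effect,
                       seed=cfg.seed, subject_amplitudes=amps)


def iter_rest_sessions(cfg: SimConfig, truth: GroundTruth
                       ) -> Iterable[tuple[str, str, str, Bold4D, pd.DataFrame]]:
    """Yield every (subject, condition, phase) rest run, generated in memory."""
    for si, sid in enumerate(_subject_ids(cfg.n_subjects)):
        for ci, cond in enumerate(CONDITIONS):
            for pi, phase in enumerate(PHASES):
                seed = _session_seed(cfg, 31, si, ci, pi)
                bold, motion = simulate_rest_session(cfg, sid, cond, phase, truth, seed)
                yield sid, cond, phase, bold, motion


def simulate_cohort(cfg: SimConfig, out_dir: str | Path
                    ) -> tuple[pd.DataFrame, GroundTruth]:
    """Write the full cohort to ``out_dir`` and return (manifest, truth).

    Produces n_subjects x 3 conditions x 2 phases resting runs with motion
    TSVs, one task run per subject, the gray-matter mask, the ground-truth
    region, and a ``manifest.tsv`` indexing all resting sessions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask = make_mask(cfg)
    truth = make_ground_truth(cfg)
    affine = cfg.affine()

    import nibabel as nib
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(out / "mask.nii.gz"))
    nib.save(nib.Nifti1Image(truth.effect_mask.astype(np.uint8), affine),
             str(out / "effect_mask.nii.gz"))

    records: list[SessionRecord] = []
    for sid, cond, phase, bold, motion in iter_rest_sessions(cfg, truth):
        bold_path = out / f"{sid}_{cond}_{phase}_rest.nii.gz"
        motion_path = out / f"{sid}_{cond}_{phase}_motion.tsv"
        bold.save(bold_path)
        motion.to_csv(motion_path, sep="\t", index=False)
        records.append(SessionRecord(sid, cond, phase, str(bold_path), str(motion_path)))

    target_rng = default_rng(SeedSequence([cfg.seed, 47]))
    targets: dict[str, tuple[int, int, int]] = {}
    for si, sid in enumerate(_subject_ids(cfg.n_subjects)):
        tc = cfg.task_target
        for _ in range(20):  # jitter the target per subject, stay inside mask
            cand = tuple(int(c + j) for c, j in
                         zip(cfg.task_target, target_rng.integers(-1, 2, size=3)))
            if all(0 <= c < s for c, s in zip(cand, cfg.grid_shape)) and mask[cand]:
                tc = cand
                break
        targets[sid] = tc
        bold = simulate_task_session(cfg, sid, tc, _session_seed(cfg, 53, si))
        bold.save(out / f"{sid}_task.nii.gz")

    manifest = pd.DataFrame([r.__dict__ for r in records])
    save_manifest(manifest, out / "manifest.tsv")

    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "condition_phase": list(map(list, truth.condition_phase)),
            "reho_effect": truth.reho_effect,
            "dc_effect": truth.dc_effect,
            "seed": truth.seed,
            "subject_amplitudes": {k: list(v) for k, v in truth.subject_amplitudes.items()},
            "task_targets": {k: list(v) for k, v in targets.items()},
        }, fh, indent=2)
    log.info("simulated cohort: %d rest sessions, %d task runs -> %s",
             len(records), cfg.n_subjects, out)
    return manifest, truth


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["subject_id", "condition", "phase", "bold_path", "motion_path"]
    if list(df.columns) != expected:
        raise ValueError(f"manifest columns must be {expected}")
    dup = df.duplicated(subset=["subject_id", "condition", "phase"])
    if dup.any():
        raise ValueError("duplicate (subject, condition, phase) rows in manifest")
    return df
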