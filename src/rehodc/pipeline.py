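"""Stage orchestration: simulate -> preprocess -> metrics -> stats -> SVM.

Each stage reads the previous stage's files from the run directory,
writes its outputs into its own subdirectory together with a
``provenance.json`` sidecar (parameters, seed, package version, SHA-256
of every output), and verifies the hashes of the inputs it consumes
against the producing stage's sidecar, warning on mismatch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import Bold4D, MetricMap, voxel_to_world
from .groupstats import (ChangePanel, bonferroni_alpha, estimate_fwhm,
                         extract_values, grf_cluster_table, paired_t,
                         rm_anova_map)
from .metrics import (MetricConfig, change_map, dc_map, normalize_by_mask_mean,
                      reho_map)
from .pairsvm import (build_pair_dataset, feature_mask_from_f, project_weights,
                      split_half_cv, voxel_auc)
from .preprocess import bandpass, discard_initial, friston24, regress_nuisance, smooth_map
from .synthdata import (CONDITIONS, PHASES, Ellipsoid, SimConfig, load_manifest,
                        simulate_cohort)
from .taskglm import BlockDesign, build_design, glm_t_map, locate_target

__all__ = ["RunConfig", "StageError", "run_stage", "run_all", "STAGES"]

log = logging.getLogger(__name__)

CONTRASTS = (("High", "Low"), ("High", "Sham"), ("Low", "Sham"))
METRICS = ("mReHo", "mDC")


class StageError(RuntimeError):
    """A stage cannot run, typically because its inputs are missing."""


@dataclass
class RunConfig:
    """Every pipeline parameter, with the study defaults."""

    out_dir: str = "rehodc_run"
    seed: int = 0
    # cohort
    n_subjects: int = 31
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    n_timepoints: int = 240
    reho_effect: float = 1.0
    dc_effect: float = 1.2
    # preprocessing
    discard_volumes: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    # metrics
    reho_neighborhood: int = 7
    dc_r_threshold: float = 0.25
    smooth_fwhm_mm: float = 6.0
    # group statistics
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    bonferroni_m: int | None = None  # None: number of tests actually run
    # SVM / ROC
    feature_p: float = 0.05
    svm_repeats: int = 100
    svm_C: float = 1.0
    # extra keyword overrides forwarded to SimConfig
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kw = dict(grid_shape=tuple(self.grid_shape), n_timepoints=self.n_timepoints,
                  n_subjects=self.n_subjects, reho_effect=self.reho_effect,
                  dc_effect=self.dc_effect, seed=self.seed)
        kw.update(self.sim_overrides)
        if "effect_region" in kw and not isinstance(kw["effect_region"], Ellipsoid):
            spec = kw["effect_region"]
            kw["effect_region"] = Ellipsoid(center=tuple(spec["center"]),
                                            radii=tuple(spec["radii"]))
        return SimConfig(**kw)

    def metric_config(self) -> MetricConfig:
        return MetricConfig(reho_neighborhood=self.reho_neighborhood,
                            dc_r_threshold=self.dc_r_threshold)


# ---------------------------------------------------------------------------
# provenance helpers


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_provenance(stage_dir: Path, stage: str, params: dict,
                      outputs: list[Path]) -> None:
    prov = {
        "stage": stage,
        "package_version": __version__,
        "params": params,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    with open(stage_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, default=str)


def _verify_inputs(producer_dir: Path, paths: list[Path]) -> None:
    prov_path = producer_dir / "provenance.json"
    if not prov_path.exists():
        return
    with open(prov_path) as fh:
        recorded = json.load(fh).get("outputs", {})
    for p in paths:
        expected = recorded.get(p.name)
        if expected is not None and _sha256(p) != expected:
            log.warning("provenance mismatch: %s differs from the hash recorded "
                        "by its producing stage", p)


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(f"missing input {path}; run the '{producer}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir) / "data"
    manifest, _ = simulate_cohort(cfg.sim_config(), out)
    outputs = [out / "manifest.tsv", out / "mask.nii.gz",
               out / "effect_mask.nii.gz", out / "ground_truth.json"]
    outputs += [Path(p) for p in manifest["bold_path"]]
    _write_provenance(out, "simulate", {"seed": cfg.seed,
                                        "n_subjects": cfg.n_subjects}, outputs)
    return out


def _load_mask(cfg: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    path = _require(Path(cfg.out_dir) / "data" / "mask.nii.gz", "simulate")
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(bool), np.asarray(img.affine)


def _stage_preprocess(cfg: RunConfig) -> Path:
    data_dir = Path(cfg.out_dir) / "data"
    manifest = load_manifest(_require(data_dir / "manifest.tsv", "simulate"))
    _verify_inputs(data_dir, [Path(p) for p in manifest["bold_path"]])
    out = Path(cfg.out_dir) / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for row in manifest.itertuples(index=False):
        bold = Bold4D.load(_require(Path(row.bold_path), "simulate"))
        motion = pd.read_csv(_require(Path(row.motion_path), "simulate"), sep="\t")
        bold = discard_initial(bold, cfg.discard_volumes)
        nuis = friston24(motion.iloc[cfg.discard_volumes:].reset_index(drop=True))
        bold = regress_nuisance(bold, nuis, include_trend=True)
        bold = bandpass(bold, cfg.band_low_hz, cfg.band_high_hz)
        dest = out / f"{row.subject_id}_{row.condition}_{row.phase}_clean.nii.gz"
        bold.save(dest)
        outputs.append(dest)
    _write_provenance(out, "preprocess",
                      {"discard": cfg.discard_volumes,
                       "band_hz": [cfg.band_low_hz, cfg.band_high_hz]}, outputs)
    return out


def _stage_metrics(cfg: RunConfig) -> Path:
    mask, affine = _load_mask(cfg)
    pre_dir = Path(cfg.out_dir) / "preproc"
    manifest = load_manifest(
        _require(Path(cfg.out_dir) / "data" / "manifest.tsv", "simulate"))
    out = Path(cfg.out_dir) / "maps"
    out.mkdir(parents=True, exist_ok=True)
    mcfg = cfg.metric_config()
    outputs = []
    for row in manifest.itertuples(index=False):
        src = _require(pre_dir / f"{row.subject_id}_{row.condition}_{row.phase}"
                       "_clean.nii.gz", "preprocess")
        _verify_inputs(pre_dir, [src])
        bold = Bold4D.load(src)
        for raw_map in (reho_map(bold, mask, mcfg), dc_map(bold, mask, mcfg)):
            norm = normalize_by_mask_mean(raw_map)
            smoothed = smooth_map(norm, cfg.smooth_fwhm_mm)
            dest = out / (f"{row.subject_id}_{row.condition}_{row.phase}_"
                          f"{norm.kind}.nii.gz")
            smoothed.save(dest)
            outputs.append(dest)
    _write_provenance(out, "metrics",
                      {"neighborhood": cfg.reho_neighborhood,
                       "dc_r_threshold": cfg.dc_r_threshold,
                       "smooth_fwhm_mm": cfg.smooth_fwhm_mm}, outputs)
    return out


def _stage_glm_target(cfg: RunConfig) -> Path:
    mask, affine = _load_mask(cfg)
    data_dir = Path(cfg.out_dir) / "data"
    sim = cfg.sim_config()
    out = Path(cfg.out_dir) / "targets"
    out.mkdir(parents=True, exist_ok=True)
    bd = BlockDesign(tr_s=sim.tr_s, n_timepoints=sim.n_task_timepoints,
                     block_length_s=sim.block_length_s)
    design = build_design(bd)
    rows = []
    manifest = load_manifest(_require(data_dir / "manifest.tsv", "simulate"))
    for sid in sorted(manifest["subject_id"].unique()):
        bold = Bold4D.load(_require(data_dir / f"{sid}_task.nii.gz", "simulate"))
        tmap = glm_t_map(bold, design)
        peak = locate_target(tmap, mask)
        rows.append({"subject_id": sid, "x_mm": peak.world_mm[0],
                     "y_mm": peak.world_mm[1], "z_mm": peak.world_mm[2],
                     "i": peak.voxel[0], "j": peak.voxel[1], "k": peak.voxel[2],
                     "t": peak.t, "p": peak.p})
    table = pd.DataFrame(rows)
    dest = out / "targets.tsv"
    table.to_csv(dest, sep="\t", index=False)
    _write_provenance(out, "glm-target", {"high_pass_s": bd.high_pass_cutoff_s},
                      [dest])
    return out


def _load_change_panel(cfg: RunConfig, metric: str) -> ChangePanel:
    mask, affine = _load_mask(cfg)
    maps_dir = Path(cfg.out_dir) / "maps"
    manifest = load_manifest(
        _require(Path(cfg.out_dir) / "data" / "manifest.tsv", "simulate"))
    sim = cfg.sim_config()
    per_subject: dict[str, dict[str, MetricMap]] = {}
    for sid in sorted(manifest["subject_id"].unique()):
        per_subject[sid] = {}
        for cond in CONDITIONS:
            phase_maps = {}
            for phase in PHASES:
                src = _require(maps_dir / f"{sid}_{cond}_{phase}_{metric}.nii.gz",
                               "metrics")
                img = nib.load(str(src))
                phase_maps[phase] = MetricMap(
                    values=np.asarray(img.dataobj, dtype=float), kind=metric,
                    mask=mask, affine=affine, voxel_size_mm=sim.voxel_size_mm)
            per_subject[sid][cond] = change_map(phase_maps["post"], phase_maps["pre"])
    return ChangePanel.from_maps(per_subject, conditions=list(CONDITIONS))


def _stage_group_stats(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir) / "group"
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    paired_rows = []
    for metric in METRICS:
        panel = _load_change_panel(cfg, metric)
        fmap = rm_anova_map(panel)
        fmap.save(out / f"{metric}_F.nii.gz")
        with open(out / f"{metric}_F.json", "w") as fh:
            json.dump({"df": list(fmap.df), "stat": "F"}, fh)
        n, k = panel.data.shape[:2]
        flat = panel.data.reshape(n, k, -1)
        resid = (flat - flat.mean(axis=0) - flat.mean(axis=1)[:, None, :]
                 + flat.mean(axis=(0, 1)))
        fwhm = estimate_fwhm(resid.reshape(n * k, *panel.mask.shape), panel.mask,
                             panel.voxel_size_mm)
        clusters = grf_cluster_table(fmap, panel.mask, fwhm,
                                     voxel_p=cfg.voxel_p, cluster_p=cfg.cluster_p)
        clusters.save(out / f"{metric}_clusters.tsv")
        outputs += [out / f"{metric}_F.nii.gz", out / f"{metric}_clusters.tsv"]
        for _, row in clusters.surviving().iterrows():
            coord = (row["x_mm"], row["y_mm"], row["z_mm"])
            extract = extract_values(panel, coord)
            extract.to_csv(out / f"{metric}_peak_{int(row.name)}_values.tsv",
                           sep="\t")
            for ca, cb in CONTRASTS:
                res = paired_t(extract[ca].to_numpy(), extract[cb].to_numpy())
                paired_rows.append({
                    "metric": metric, "cluster": int(row.name),
                    "x_mm": coord[0], "y_mm": coord[1], "z_mm": coord[2],
                    "contrast": f"{ca} vs {cb}", "mean_diff": res.mean_diff,
                    "sd_diff": res.sd_diff, "t": res.t, "p": res.p})
    paired = pd.DataFrame(paired_rows)
    if len(paired):
        m = cfg.bonferroni_m or len(paired)
        alpha = bonferroni_alpha(0.05, m)
        paired["bonferroni_alpha"] = alpha
        paired["significant_bonferroni"] = paired["p"] < alpha
    dest = out / "paired_t_tests.tsv"
    paired.to_csv(dest, sep="\t", index=False)
    outputs.append(dest)
    _write_provenance(out, "group-stats",
                      {"voxel_p": cfg.voxel_p, "cluster_p": cfg.cluster_p}, outputs)
    return out


def _stage_pair_svm(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir) / "svm"
    out.mkdir(parents=True, exist_ok=True)
    mask, affine = _load_mask(cfg)
    outputs = []
    acc_rows = []
    for metric in METRICS:
        panel = _load_change_panel(cfg, metric)
        fmap = rm_anova_map(panel)
        fm = feature_mask_from_f(fmap, panel.mask, p_thresh=cfg.feature_p)
        for ca, cb in CONTRASTS:
            ds = build_pair_dataset(panel, (ca, cb), fm, seed=cfg.seed)
            cv = split_half_cv(ds, repeats=cfg.svm_repeats, C=cfg.svm_C,
                               seed=cfg.seed)
            wmap = project_weights(cv, fm, panel.mask, affine=panel.affine,
                                   voxel_size_mm=panel.voxel_size_mm)
            wdest = out / f"{metric}_{ca}_vs_{cb}_weights.nii.gz"
            wmap.save(wdest)
            rep_dest = out / f"{metric}_{ca}_vs_{cb}_accuracies.tsv"
            pd.DataFrame({"accuracy": cv.accuracies}).to_csv(
                rep_dest, sep="\t", index=False)
            outputs += [wdest, rep_dest]
            acc_rows.append({"metric": metric, "contrast": f"{ca} vs {cb}",
                             "mean_accuracy": cv.mean_accuracy,
                             "n_features": len(fm), "repeats": cv.repeats})
    dest = out / "accuracy_matrix.tsv"
    pd.DataFrame(acc_rows).to_csv(dest, sep="\t", index=False)
    outputs.append(dest)
    _write_provenance(out, "pair-svm",
                      {"feature_p": cfg.feature_p, "repeats": cfg.svm_repeats,
                       "C": cfg.svm_C, "seed": cfg.seed}, outputs)
    return out


def _stage_roc(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir) / "roc"
    out.mkdir(parents=True, exist_ok=True)
    group_dir = Path(cfg.out_dir) / "group"
    rows = []
    for metric in METRICS:
        panel = _load_change_panel(cfg, metric)
        ctab = pd.read_csv(_require(group_dir / f"{metric}_clusters.tsv",
                                    "group-stats"), sep="\t")
        if len(ctab) == 0:
            log.warning("roc: no clusters for %s; using the global F peak", metric)
            fmap = rm_anova_map(panel)
            vals = np.where(panel.mask, fmap.values, -np.inf)
            peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
            coord = voxel_to_world(panel.affine, peak)
        else:
            top = ctab.sort_values("extent_voxels", ascending=False).iloc[0]
            coord = (top["x_mm"], top["y_mm"], top["z_mm"])
        extract = extract_values(panel, coord)
        for ca, cb in CONTRASTS:
            auc = voxel_auc(extract[ca].to_numpy(), extract[cb].to_numpy())
            rows.append({"metric": metric, "contrast": f"{ca} vs {cb}",
                         "x_mm": coord[0], "y_mm": coord[1], "z_mm": coord[2],
                         "auc": auc})
    dest = out / "auc_table.tsv"
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)
    _write_provenance(out, "roc", {}, [dest])
    return out


STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "metrics": _stage_metrics,
    "glm-target": _stage_glm_target,
    "group-stats": _stage_group_stats,
    "pair-svm": _stage_pair_svm,
    "roc": _stage_roc,
}


def run_stage(name: str, cfg: RunConfig) -> Path:
    """Run one named stage; raises :class:`StageError` on missing inputs."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {sorted(STAGES)}")
    log.info("running stage %s -> %s", name, cfg.out_dir)
    return STAGES[name](cfg)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run the whole pipeline in order and return the stage directories."""
    results = {}
    master = {"package_version": __version__, "seed": cfg.seed,
              "config": asdict(cfg), "stages": list(STAGES)}
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(master, fh, indent=2, default=str)
    for name in STAGES:
        results[name] = run_stage(name, cfg)
    return results
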