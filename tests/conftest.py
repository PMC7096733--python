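"""Shared fixtures: small synthetic configurations and panel builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rehodc.groupstats import ChangePanel
from rehodc.metrics import MetricConfig, change_map, dc_map, normalize_by_mask_mean, reho_map
from rehodc.preprocess import bandpass, discard_initial, friston24, regress_nuisance, smooth_map
from rehodc.synthdata import (Ellipsoid, SimConfig, iter_rest_sessions,
                              make_ground_truth, make_mask)

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def tiny_config(**overrides) -> SimConfig:
    """A 14x14x10 cohort configuration that simulates in well under a second."""
    kw = dict(grid_shape=(14, 14, 10), n_timepoints=60, n_subjects=4,
              effect_region=Ellipsoid((9, 5, 4), (2.0, 2.0, 1.5)),
              task_target=(5, 8, 6), seed=0)
    kw.update(overrides)
    return SimConfig(**kw)


def clean_series(bold, motion, discard=10):
    """The study's cleaning chain: discard, 24-par regression+trend, band-pass."""
    b = discard_initial(bold, discard)
    nuis = friston24(motion.iloc[discard:].reset_index(drop=True))
    return bandpass(regress_nuisance(b, nuis, include_trend=True))


def build_change_panel(cfg: SimConfig, metric: str = "mReHo",
                       smooth_fwhm: float = 6.0, discard: int = 10,
                       metric_cfg: MetricConfig = MetricConfig()) -> tuple:
    """Simulate a cohort in memory and assemble its change panel.

    Returns (panel, mask, truth).  ``metric`` is 'mReHo' or 'mDC'.
    """
    mask = make_mask(cfg)
    truth = make_ground_truth(cfg)
    per_subject: dict[str, dict[str, dict[str, object]]] = {}
    for sid, cond, phase, bold, motion in iter_rest_sessions(cfg, truth):
        series = clean_series(bold, motion, discard=discard)
        raw = (reho_map(series, mask, metric_cfg) if metric == "mReHo"
               else dc_map(series, mask, metric_cfg))
        smoothed = smooth_map(normalize_by_mask_mean(raw), smooth_fwhm)
        per_subject.setdefault(sid, {}).setdefault(cond, {})[phase] = smoothed
    changes = {s: {c: change_map(p["post"], p["pre"]) for c, p in conds.items()}
               for s, conds in per_subject.items()}
    panel = ChangePanel.from_maps(changes, conditions=["High", "Low", "Sham"])
    return panel, mask, truth


@pytest.fixture(scope="session")
def tiny_effect_panel():
    """ReHo change panel from a 7-subject tiny cohort with the default effect."""
    cfg = tiny_config(n_subjects=7)
    return build_change_panel(cfg)


@pytest.fixture(scope="session")
def tiny_null_panel():
    """ReHo change panel from a tiny cohort with zero injected effects."""
    cfg = tiny_config(n_subjects=5, reho_effect=0.0, dc_effect=0.0, seed=3)
    return build_change_panel(cfg)


@pytest.fixture(scope="session")
def independent_null_panel():
    """Null panel with spatially independent voxels (no noise smoothing, no
    map smoothing), so tests that assume independent voxelwise samples
    (e.g. a KS test of p-value uniformity) are actually valid."""
    cfg = tiny_config(n_subjects=5, reho_effect=0.0, dc_effect=0.0,
                      spatial_fwhm_mm=0.0, seed=3)
    return build_change_panel(cfg, smooth_fwhm=0.0)


@pytest.fixture(scope="session")
def default_mask_truth():
    cfg = SimConfig()
    return cfg, make_mask(cfg), make_ground_truth(cfg)
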