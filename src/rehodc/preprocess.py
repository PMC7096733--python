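"""Per-session time-series cleaning and map smoothing.

The resting-state cleaning chain is: discard the first volumes, regress
out the 24-parameter motion model (plus intercept and linear trend), then
band-pass filter 0.01–0.08 Hz with an ideal frequency-domain filter.
Spatial smoothing is applied only to metric maps (after normalization),
never to the time series.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import Bold4D, MetricMap

__all__ = [
    "discard_initial",
    "friston24",
    "regress_nuisance",
    "bandpass",
    "smooth_map",
    "fwhm_to_sigma",
]

log = logging.getLogger(__name__)

FRISTON24_COLUMNS = (
    [f"{c}" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"{c}_lag" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"{c}_sq" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
    + [f"{c}_lag_sq" for c in ("tx", "ty", "tz", "rx", "ry", "rz")]
)


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian FWHM -> standard deviation: sigma = FWHM / (2 sqrt(2 ln 2))."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def discard_initial(bold: Bold4D, k: int = 10) -> Bold4D:
    """Drop the first ``k`` volumes (signal-equilibration period)."""
    if not 0 <= k < bold.n_timepoints:
        raise ValueError(f"cannot discard {k} of {bold.n_timepoints} volumes")
    if k == 0:
        return bold
    return bold.with_data(bold.data[..., k:])


def friston24(motion: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Expand 6 realignment parameters into the 24-parameter motion model.

    Columns are ordered [R(t), R(t-1), R(t)^2, R(t-1)^2]; the lagged block
    is zero-padded at the first row.
    """
    arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns, got shape {arr.shape}")
    lag = np.vstack([np.zeros((1, 6)), arr[:-1]])
    out = np.hstack([arr, lag, arr ** 2, lag ** 2])
    return pd.DataFrame(out, columns=FRISTON24_COLUMNS)


def regress_nuisance(bold: Bold4D, nuisance: pd.DataFrame | np.ndarray | None,
                     include_trend: bool = True) -> Bold4D:
    """Voxelwise OLS residuals against [intercept, trend, nuisance columns].

    Collinear (rank-deficient) designs are handled by the minimum-norm
    least-squares solution, which leaves the residual well defined; a
    warning is logged in that case.  Residuals are orthogonal to every
    design column.
    """
    n_t = bold.n_timepoints
    cols = [np.ones((n_t, 1))]
    if include_trend:
        trend = np.linspace(-1.0, 1.0, n_t)
        cols.append(trend[:, None])
    if nuisance is not None:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.size:
            if nuis.shape[0] != n_t:
                raise ValueError(
                    f"nuisance rows ({nuis.shape[0]}) != time points ({n_t})")
            cols.append(nuis)
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        log.warning("nuisance design is rank deficient (rank %d of %d columns); "
                    "using minimum-norm residuals", rank, X.shape[1])
    Y = bold.data.reshape(-1, n_t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return bold.with_data(resid.T.reshape(bold.data.shape))


def bandpass(bold: Bold4D, low_hz: float = 0.01, high_hz: float = 0.08) -> Bold4D:
    """Ideal (frequency-domain boxcar) band-pass filter along time.

    Frequencies in [low_hz, high_hz] pass unchanged; everything else —
    including the DC component — is removed exactly.
    """
    nyquist = 1.0 / (2.0 * bold.tr_s)
    if not 0.0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyquist})")
    n_t = bold.n_timepoints
    freqs = np.fft.rfftfreq(n_t, d=bold.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(bold.data, axis=-1)
    spec[..., ~keep] = 0.0
    return bold.with_data(np.fft.irfft(spec, n=n_t, axis=-1))


def smooth_map(metric: MetricMap, fwhm_mm: float = 6.0) -> MetricMap:
    """Mask-normalized Gaussian smoothing of a metric map.

    Values outside the mask do not leak in: the map is smoothed as
    ``smooth(values * mask) / smooth(mask)`` and re-masked, so a constant
    map stays constant over the mask.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return metric
    vs = np.broadcast_to(np.asarray(metric.voxel_size_mm, dtype=float), (3,))
    sigma = tuple(fwhm_to_sigma(fwhm_mm) / v for v in vs)
    m = metric.mask.astype(float)
    num = ndimage.gaussian_filter(metric.values * m, sigma=sigma)
    den = ndimage.gaussian_filter(m, sigma=sigma)
    out = np.zeros_like(metric.values)
    inside = metric.mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    prov = dict(metric.provenance)
    prov["smoothing_fwhm_mm"] = fwhm_mm
    return MetricMap(values=out, kind=metric.kind, mask=metric.mask,
                     affine=metric.affine, voxel_size_mm=metric.voxel_size_mm,
                     provenance=prov)
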