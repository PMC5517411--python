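"""Time-series conditioning before spectral estimation.

Pipeline order: discard initial volumes -> confound regression -> polynomial
detrend + frequency filtering -> (optionally) principal-eigenvariate
summarization of voxel blocks.  Filtering is implemented as regression on a
discrete-cosine basis rather than IIR filtering, to avoid edge transients on
~160-sample sessions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import replace

from .errors import ValidationError
from .simulate import SessionSeries

__all__ = [
    "discard_initial",
    "regress_confounds",
    "detrend_and_filter",
    "principal_eigenvariate",
]

logger = logging.getLogger(__name__)


def discard_initial(series: SessionSeries, n_discard: int = 5) -> SessionSeries:
    """Drop the first ``n_discard`` volumes (magnetic-equilibration discard)."""
    if n_discard < 0:
        raise ValidationError("n_discard must be >= 0")
    if n_discard >= series.n_volumes:
        raise ValidationError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    if n_discard == 0:
        return series
    return replace(series, data=series.data[n_discard:].copy())


def _drop_dependent_columns(x: np.ndarray, labels: list[str]):
    """QR-based removal of linearly dependent columns (logged, not fatal)."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping linearly dependent confound column %r", labels[j])
    return x[:, keep], [labels[j] for j in keep]


def regress_confounds(series: SessionSeries, confounds) -> SessionSeries:
    """Residualize each region on [confounds, intercept] by least squares."""
    if isinstance(confounds, pd.DataFrame):
        labels = [str(c) for c in confounds.columns]
        cmat = confounds.to_numpy(dtype=float)
    else:
        cmat = np.asarray(confounds, dtype=float)
        labels = [f"c{j}" for j in range(cmat.shape[1])]
    if cmat.shape[0] != series.n_volumes:
        raise ValidationError(
            f"confounds have {cmat.shape[0]} rows, series has {series.n_volumes}"
        )
    if np.any(np.all(cmat == 0.0, axis=0)):
        raise ValidationError("confound matrix has an all-zero column")
    cmat, labels = _drop_dependent_columns(cmat, labels)
    design = np.column_stack([cmat, np.ones(cmat.shape[0])])
    coef, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    resid = series.data - design @ coef
    return replace(series, data=resid)


def dct_basis(T: int, order: int) -> np.ndarray:
    """DCT-II regressors cos(pi k (2t+1) / 2T), k = 1..order (T x order)."""
    t = np.arange(T)
    return np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2 * T)) for k in range(1, order + 1)]
    )


def detrend_and_filter(
    series: SessionSeries,
    highpass_hz: float = 0.009,
    lowpass_hz: float | None = None,
) -> SessionSeries:
    """Remove linear/quadratic trends, then frequency components by DCT regression.

    High-pass: components strictly below ``highpass_hz`` are regressed out
    (the DCT component k spans frequency k / (2 T tr) Hz).  No low-pass is
    applied by default; passing ``lowpass_hz`` additionally removes
    components above that frequency.
    """
    T = series.n_volumes
    nyquist = 0.5 / series.tr
    if not (0.0 < highpass_hz < nyquist):
        raise ValidationError(f"highpass must lie in (0, {nyquist}) Hz")
    if lowpass_hz is not None and not (highpass_hz < lowpass_hz <= nyquist):
        raise ValidationError("lowpass must lie in (highpass, nyquist]")
    t = np.arange(T, dtype=float)
    t = (t - t.mean()) / t.std()
    cols = [np.ones(T), t, t**2 - np.mean(t**2)]
    comp_freq = np.arange(1, T) / (2 * T * series.tr)
    low = np.nonzero(comp_freq < highpass_hz)[0] + 1
    if low.size:
        cols.append(dct_basis(T, int(low.max()))[:, low - 1])
    if lowpass_hz is not None:
        high = np.nonzero(comp_freq > lowpass_hz)[0] + 1
        full = dct_basis(T, T - 1)
        cols.append(full[:, high - 1])
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, series.data, rcond=None)
    return replace(series, data=series.data - design @ coef)


def principal_eigenvariate(voxels: np.ndarray) -> np.ndarray:
    """First singular-vector summary of a time x voxel block.

    Returns the first left singular vector of the demeaned block, scaled so
    its variance equals the leading covariance eigenvalue divided by the
    voxel count, and signed to correlate positively with the voxel mean.
    """
    voxels = np.asarray(voxels, dtype=float)
    if voxels.ndim != 2 or voxels.shape[1] < 2 or voxels.shape[0] < 3:
        raise ValidationError("need a time x voxel block with >= 3 x 2 entries")
    demeaned = voxels - voxels.mean(axis=0)
    if np.allclose(demeaned, 0.0):
        raise ValidationError("degenerate voxel block: all series constant")
    u, s, _ = np.linalg.svd(demeaned, full_matrices=False)
    v_count = voxels.shape[1]
    e = u[:, 0] * (s[0] / np.sqrt(v_count))
    if np.dot(e, demeaned.mean(axis=1)) < 0:
        e = -e
    return e
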