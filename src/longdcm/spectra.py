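"""Cross-spectral density estimation: the second-order data features.

Fitting targets for inversion are not the time series themselves but their
complex cross spectra.  The default estimator fits a multivariate
autoregression (MAR) by least squares and evaluates its rational spectrum on
an arbitrary grid, which is smooth and well behaved on short (~160 sample)
sessions; a Welch cross-periodogram is provided as a non-parametric
cross-check.

Convention: all spectra are two-sided densities (signal^2/Hz) on grids in Hz,
so a univariate AR(1) with coefficient a and innovation variance s2 sampled
at interval TR has S(f) = s2 * TR / |1 - a e^{-i 2 pi f TR}|^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .simulate import SessionSeries

__all__ = ["SpectralData", "MarModel", "fit_mar", "mar_spectrum", "estimate_csd",
           "welch_csd", "default_frequency_grid"]

logger = logging.getLogger(__name__)


@dataclass
class SpectralData:
    """Frequency grid (Hz) plus one Hermitian n x n CSD matrix per frequency."""

    freqs: np.ndarray
    csd: np.ndarray  # (n_freqs, n, n) complex
    region_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.freqs.ndim != 1 or np.any(np.diff(self.freqs) <= 0):
            raise ValidationError("freqs must be strictly increasing")
        if np.any(self.freqs <= 0):
            raise ValidationError("freqs must be positive")
        if self.csd.shape[0] != self.freqs.size or self.csd.shape[1] != self.csd.shape[2]:
            raise ValidationError(f"csd shape {self.csd.shape} does not match grid")
        herm = np.abs(self.csd - np.conj(np.swapaxes(self.csd, 1, 2))).max()
        if herm > 1e-8:
            raise ValidationError(f"csd not Hermitian (max asymmetry {herm:g})")
        diags = np.diagonal(self.csd, axis1=1, axis2=2)
        if np.any(diags.real < -1e-10) or np.abs(diags.imag).max(initial=0.0) > 1e-10:
            raise ValidationError("csd diagonals must be real and >= 0")

    @property
    def n_regions(self) -> int:
        return self.csd.shape[1]


@dataclass
class MarModel:
    """Least-squares multivariate autoregression of a fixed order."""

    coefs: np.ndarray  # (order, n, n); x_t = sum_m coefs[m] x_{t-m} + innov
    innov_cov: np.ndarray  # (n, n) symmetric PSD
    tr: float

    @property
    def order(self) -> int:
        return self.coefs.shape[0]


def fit_mar(series: SessionSeries, order: int = 8, ridge: float = 0.0) -> MarModel:
    """Fit a MAR(order) by multivariate least squares on the demeaned series."""
    if order < 1:
        raise ValidationError("MAR order must be >= 1")
    data = series.data - series.data.mean(axis=0)
    T, n = data.shape
    if T <= n * order + n:
        raise ValidationError(
            f"series too short (T={T}) for MAR order {order} with {n} regions"
        )
    rows = T - order
    design = np.empty((rows, n * order))
    for m in range(order):
        design[:, m * n : (m + 1) * n] = data[order - 1 - m : T - 1 - m]
    target = data[order:]
    gram = design.T @ design
    cond = np.linalg.cond(gram)
    if cond > 1e10 or ridge > 0:
        lam = ridge if ridge > 0 else 1e-8 * np.trace(gram) / gram.shape[0]
        if ridge == 0:
            logger.warning(
                "ill-conditioned MAR regression (cond=%.2g); ridge %.2g applied",
                cond, lam,
            )
        gram = gram + lam * np.eye(gram.shape[0])
    coef_flat = np.linalg.solve(gram, design.T @ target)  # (n*order, n)
    resid = target - design @ coef_flat
    dof = max(rows - n * order, 1)
    innov = resid.T @ resid / dof
    innov = 0.5 * (innov + innov.T)
    w, v = np.linalg.eigh(innov)
    innov = (v * np.clip(w, 0.0, None)) @ v.T
    coefs = np.stack(
        [coef_flat[m * n : (m + 1) * n].T for m in range(order)]
    )
    return MarModel(coefs=coefs, innov_cov=innov, tr=series.tr)


def mar_spectrum(model: MarModel, freqs: np.ndarray) -> np.ndarray:
    """Rational CSD of a MAR model: S(f) = TR * T(f)^-1 Sigma T(f)^-H."""
    freqs = np.asarray(freqs, dtype=float)
    n = model.innov_cov.shape[0]
    orders = np.arange(1, model.order + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * orders[None, :] * model.tr)
    tf = np.eye(n)[None] - np.einsum("fm,mij->fij", phase, model.coefs)
    inv = np.linalg.inv(tf)
    s = model.tr * inv @ model.innov_cov @ np.conj(np.swapaxes(inv, 1, 2))
    return 0.5 * (s + np.conj(np.swapaxes(s, 1, 2)))


def default_frequency_grid(series: SessionSeries, n_freqs: int = 32,
                           fmin: float | None = None, fmax: float = 0.25) -> np.ndarray:
    """Logarithmic grid from 1/(T*TR) (or fmin) to fmax, n_freqs points."""
    lo = fmin if fmin is not None else 1.0 / (series.n_volumes * series.tr)
    nyq = 0.5 / series.tr
    return np.geomspace(lo, min(fmax, nyq), n_freqs)


def estimate_csd(
    series: SessionSeries,
    order: int = 8,
    freqs: np.ndarray | None = None,
) -> SpectralData:
    """Parametric cross-spectrum of the fitted MAR, evaluated on ``freqs``."""
    if freqs is None:
        freqs = default_frequency_grid(series)
    freqs = np.asarray(freqs, dtype=float)
    nyq = 0.5 / series.tr
    if np.any(freqs <= 0) or np.any(freqs > nyq + 1e-12):
        raise ValidationError(f"frequencies must lie in (0, {nyq}] Hz")
    model = fit_mar(series, order=order)
    csd = mar_spectrum(model, freqs)
    return SpectralData(
        freqs=freqs,
        csd=csd,
        region_names=list(series.region_names),
        meta={"estimator": "mar", "order": order, "tr": series.tr},
    )


def welch_csd(
    data: np.ndarray,
    dt: float,
    segment_length: int = 256,
    overlap: float = 0.5,
) -> SpectralData:
    """Welch-averaged cross-periodogram (two-sided density, Hann window)."""
    data = np.asarray(data, dtype=float)
    T, n = data.shape
    seg = min(segment_length, T)
    step = max(int(seg * (1.0 - overlap)), 1)
    window = np.hanning(seg)
    norm = (window**2).sum()
    starts = range(0, T - seg + 1, step)
    acc = None
    count = 0
    for s0 in starts:
        block = data[s0 : s0 + seg]
        block = (block - block.mean(axis=0)) * window[:, None]
        spec = np.fft.rfft(block, axis=0)  # (nf, n)
        cross = spec[:, :, None] * np.conj(spec[:, None, :]) * (dt / norm)
        acc = cross if acc is None else acc + cross
        count += 1
    csd = acc / count
    freqs = np.fft.rfftfreq(seg, dt)
    keep = freqs > 0
    return SpectralData(
        freqs=freqs[keep],
        csd=0.5 * (csd[keep] + np.conj(np.swapaxes(csd[keep], 1, 2))),
        meta={"estimator": "welch", "segments": count, "segment_length": seg},
    )
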