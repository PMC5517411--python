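"""Forward simulation of resting-state BOLD from a linear stochastic network.

The neural model is a multivariate Ornstein-Uhlenbeck process

    dx/dt = A_eff x + v

where ``A_eff`` is the effective coupling matrix (off-diagonal entries are
rates in 1/s; the stored diagonal entries are log-scale parameters, with the
effective self-inhibition rate ``-0.5 * exp(a_ii)``) and ``v`` is endogenous
neuronal fluctuation with a scale-free (power-law) spectrum.  Observation runs
through the Balloon-Windkessel hemodynamic model per region, sampling at the
repetition time, plus power-law channel noise, slow drifts, and leaked
confounds.

Spectral conventions used throughout the package: all spectra are two-sided
power spectral densities (signal^2 per Hz) on a frequency grid in Hz, so a
white state noise of amplitude ``amp`` driving a single node with self-rate
``-lam`` yields the stationary variance ``amp / (2 lam)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .errors import StabilityError, ValidationError

__all__ = [
    "ConnectivityMatrix",
    "NoiseSpec",
    "HemoParams",
    "SessionSeries",
    "self_rate",
    "effective_matrix",
    "is_stable",
    "powerlaw_noise",
    "simulate_neural",
    "simulate_cohort_neural",
    "simulate_bold",
    "simulate_cohort_bold",
    "balloon_bold",
    "sample_and_corrupt",
    "make_confounds",
    "make_voxels",
]

SELF_RATE_BASE = 0.5  # effective self rate is -SELF_RATE_BASE * exp(a_ii)


def self_rate(a_ii: float) -> float:
    """Effective self-inhibition rate (1/s) for a diagonal log-scale entry."""
    return -SELF_RATE_BASE * np.exp(a_ii)


def _as_array(a) -> np.ndarray:
    if isinstance(a, ConnectivityMatrix):
        a = a.a
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"coupling matrix must be square, got {a.shape}")
    return a


def effective_matrix(a) -> np.ndarray:
    """Rate matrix with the diagonal log-scale convention applied.

    Off-diagonals pass through unchanged; diagonal entries a_ii are mapped to
    -0.5 * exp(a_ii) so the self-connection is negative by construction.
    """
    a = _as_array(a)
    if not np.all(np.isfinite(a)):
        raise ValidationError("coupling matrix has non-finite entries")
    eff = a.copy()
    np.fill_diagonal(eff, -SELF_RATE_BASE * np.exp(np.diag(a)))
    return eff


def is_stable(a) -> bool:
    """True iff every eigenvalue of the effective rate matrix has Re < 0."""
    eig = np.linalg.eigvals(effective_matrix(a))
    return bool(np.all(eig.real < 0.0))


@dataclass
class ConnectivityMatrix:
    """n x n coupling matrix; row = target region, column = source region."""

    a: np.ndarray
    region_names: list[str] | None = None

    def __post_init__(self):
        self.a = _as_array(self.a)
        if not np.all(np.isfinite(self.a)):
            raise ValidationError("coupling matrix has non-finite entries")
        if self.region_names is None:
            self.region_names = default_region_names(self.a.shape[0])

    @property
    def n(self) -> int:
        return self.a.shape[0]

    def effective(self) -> np.ndarray:
        return effective_matrix(self.a)

    def is_stable(self) -> bool:
        return is_stable(self.a)


def default_region_names(n: int) -> list[str]:
    """Motor-network labels for the 6-region model, generic otherwise."""
    if n == 6:
        return ["PrcG", "SMA", "VL", "Thal", "Put", "rDT"]
    return [f"R{i + 1}" for i in range(n)]


@dataclass
class NoiseSpec:
    """Power-law noise amplitudes/exponents for state and observation noise.

    ``state_amp * f**-state_exp`` is the two-sided spectral density of the
    neuronal fluctuations v (per region, independent); likewise for the
    observation noise e.  ``drift_amp`` scales slow linear+quadratic scanner
    drifts added at acquisition time (percent-signal units).
    """

    state_amp: float = 3e-5
    state_exp: float = 1.0
    obs_amp: float = 0.02
    obs_exp: float = 0.5
    drift_amp: float = 0.1

    def __post_init__(self):
        for name in ("state_amp", "obs_amp", "drift_amp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("state_exp", "obs_exp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 2.0):
                raise ValidationError(f"{name} must lie in [0, 2], got {v}")


@dataclass
class HemoParams:
    """Balloon-Windkessel hemodynamic parameters (one region).

    kappa: vasodilatory signal decay rate (1/s); gamma: autoregulatory
    feedback rate (1/s); tau: mean venous transit time (s); alpha: Grubb
    vessel-stiffness exponent; E0: resting oxygen extraction fraction;
    epsilon: neurovascular gain from neural state to vasodilatory drive;
    V0: resting venous blood volume fraction.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    epsilon: float = 1.0
    V0: float = 0.04

    def __post_init__(self):
        for name in ("kappa", "gamma", "tau", "alpha", "E0", "epsilon", "V0"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"hemodynamic parameter {name} must be > 0")
        if not (0 < self.E0 < 1):
            raise ValidationError("E0 must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")

    def bold_constants(self) -> dict[str, float]:
        """Static BOLD output-equation constants (recorded in run manifests)."""
        return {"k1": 7.0 * self.E0, "k2": 2.0, "k3": 2.0 * self.E0 - 0.2}


@dataclass
class SessionSeries:
    """T x n sampled BOLD matrix (percent signal change) at repetition time tr."""

    data: np.ndarray
    tr: float
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("series data must be 2-D (time x regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series contains missing/non-finite values")
        if self.data.shape[0] < 32:
            raise ValidationError("series must have at least 32 time points")
        if self.tr <= 0:
            raise ValidationError("tr must be positive")
        if not self.region_names:
            self.region_names = default_region_names(self.data.shape[1])

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.region_names)


# ---------------------------------------------------------------------------
# noise synthesis


def powerlaw_noise(
    n_samples: int,
    dt: float,
    amp: float,
    exponent: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Gaussian noise with two-sided spectral density ``amp * f**-exponent``.

    Synthesized in the frequency domain (zero-frequency bin set to 0), which
    realizes the target spectrum exactly in expectation.  Returns an
    (n_samples, n_series) array.
    """
    if amp == 0.0:
        return np.zeros((n_samples, n_series))
    freqs = np.fft.rfftfreq(n_samples, dt)
    spec = np.zeros_like(freqs)
    spec[1:] = amp * freqs[1:] ** (-exponent)
    # E|X_k|^2 = S(f_k) * N / dt makes the periodogram match S in expectation
    sd = np.sqrt(spec * n_samples / dt)
    coefs = sd[:, None] * (
        rng.standard_normal((freqs.size, n_series))
        + 1j * rng.standard_normal((freqs.size, n_series))
    ) / np.sqrt(2.0)
    coefs[0] = 0.0
    if n_samples % 2 == 0:  # Nyquist bin must be real
        coefs[-1] = sd[-1] * rng.standard_normal(n_series)
    return np.fft.irfft(coefs, n=n_samples, axis=0)


# ---------------------------------------------------------------------------
# neural dynamics


def _discrete_propagators(a_eff: np.ndarray, dt: float):
    """Exact matrix-exponential propagator E and zero-order-hold input map F."""
    E = expm(a_eff * dt)
    F = np.linalg.solve(a_eff, E - np.eye(a_eff.shape[0]))
    return E, F


def _propagate(E: np.ndarray, F: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Integrate x_{k+1} = E x_k + F v_k from rest; v is (..., T, n)."""
    T = v.shape[-2]
    x = np.zeros_like(v)
    state = np.zeros(v.shape[:-2] + (v.shape[-1],))
    for k in range(T):
        x[..., k, :] = state
        state = (E @ state[..., None])[..., 0] + (F @ v[..., k, :, None])[..., 0]
    return x


def simulate_neural(
    a,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.05,
    seed: int | np.random.Generator = 0,
    burn_in: float = 32.0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the neural states of ``dx/dt = A_eff x + v``.

    The linear drift is propagated with the exact matrix exponential over dt;
    the power-law fluctuation v enters as a zero-order-hold input per step.
    A burn-in of at least 32 s is prepended and discarded so the returned
    (T x n) trajectory is approximately stationary.
    """
    a_eff = effective_matrix(a)
    if not np.all(np.linalg.eigvals(a_eff).real < 0):
        raise StabilityError("coupling matrix is unstable; cannot simulate")
    if dt > 0.1:
        raise ValidationError("dt must be <= 0.1 s")
    if duration < 64.0:
        raise ValidationError("duration must be >= 64 s")
    burn_in = max(float(burn_in), 32.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a_eff.shape[0]
    n_burn = int(round(burn_in / dt))
    n_total = n_burn + int(round(duration / dt))
    v = powerlaw_noise(n_total, dt, noise.state_amp, noise.state_exp, rng, n)
    E, F = _discrete_propagators(a_eff, dt)
    x = _propagate(E, F, v)
    if x0 is not None:
        # deterministic decay from x0 superposes on the stationary response
        decay = np.empty((n_total, n))
        state = np.asarray(x0, dtype=float)
        for k in range(n_total):
            decay[k] = state
            state = E @ state
        x = x + decay
    return x[n_burn:]


def simulate_cohort_neural(
    a_list,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.05,
    seed: int | np.random.Generator = 0,
    burn_in: float = 32.0,
) -> np.ndarray:
    """Simulate many sessions at once; returns (n_sessions, T, n) states.

    Equivalent to calling :func:`simulate_neural` per session (up to the
    random stream), but integrates all sessions in a single time loop, which
    is an order of magnitude faster for cohort-sized batches.
    """
    mats = [effective_matrix(a) for a in a_list]
    for i, m in enumerate(mats):
        if not np.all(np.linalg.eigvals(m).real < 0):
            raise StabilityError(f"session {i}: coupling matrix is unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B, n = len(mats), mats[0].shape[0]
    burn_in = max(float(burn_in), 32.0)
    n_burn = int(round(burn_in / dt))
    n_total = n_burn + int(round(duration / dt))
    v = powerlaw_noise(n_total, dt, noise.state_amp, noise.state_exp, rng, B * n)
    v = v.reshape(n_total, B, n).transpose(1, 0, 2)  # (B, T, n)
    E = np.stack([expm(m * dt) for m in mats])
    F = np.stack(
        [np.linalg.solve(m, e - np.eye(n)) for m, e in zip(mats, E)]
    )
    x = _propagate(E, F, v)
    return x[:, n_burn:, :]


# ---------------------------------------------------------------------------
# Balloon-Windkessel hemodynamics


def _balloon_derivs(state, drive, h: HemoParams):
    """Time derivatives of the (s, f, v, q) hemodynamic states."""
    s, f, v, q = state
    f = np.maximum(f, 1e-6)
    v = np.maximum(v, 1e-6)
    Ef = 1.0 - (1.0 - h.E0) ** (1.0 / f)
    ds = h.epsilon * drive - h.kappa * s - h.gamma * (f - 1.0)
    df = s
    dv = (f - v ** (1.0 / h.alpha)) / h.tau
    dq = (f * Ef / h.E0 - v ** (1.0 / h.alpha - 1.0) * q) / h.tau
    return np.array([ds, df, dv, dq])


def _bold_output(v, q, h: HemoParams) -> np.ndarray:
    c = h.bold_constants()
    return 100.0 * h.V0 * (
        c["k1"] * (1.0 - q) + c["k2"] * (1.0 - q / v) + c["k3"] * (1.0 - v)
    )


def balloon_bold(x: np.ndarray, h: HemoParams | None = None, dt: float = 0.05) -> np.ndarray:
    """Map a neural trajectory (T x ...) to percent-signal BOLD (same shape).

    Classical fixed-step 4th-order Runge-Kutta on the Balloon-Windkessel
    states (vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin
    q), starting from the resting fixed point s=0, f=v=q=1, with the neural
    drive held constant over each dt interval (zero-order hold).
    """
    if h is None:
        h = HemoParams()
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    shape = x.shape[1:]
    state = np.stack(
        [np.zeros(shape), np.ones(shape), np.ones(shape), np.ones(shape)]
    )
    out = np.empty_like(x)
    for k in range(T):
        out[k] = _bold_output(state[2], state[3], h)
        u = x[k]
        k1 = _balloon_derivs(state, u, h)
        k2 = _balloon_derivs(state + 0.5 * dt * k1, u, h)
        k3 = _balloon_derivs(state + 0.5 * dt * k2, u, h)
        k4 = _balloon_derivs(state + dt * k3, u, h)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return out


# ---------------------------------------------------------------------------
# acquisition


def simulate_bold(
    a,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.05,
    seed: int | np.random.Generator = 0,
    hemo: HemoParams | None = None,
    burn_in: float = 64.0,
) -> np.ndarray:
    """Neural simulation + Balloon observation with a joint burn-in.

    Both the neural and the hemodynamic states are integrated through the
    burn-in period and the burn-in is discarded from the BOLD output, so the
    returned (T x n) percent-signal trajectory is free of the onset
    transient of either stage.
    """
    burn_in = max(float(burn_in), 64.0)
    x = simulate_neural(a, noise, duration + burn_in, dt, seed, burn_in=32.0)
    y = balloon_bold(x, hemo, dt)
    return y[int(round(burn_in / dt)) :]


def simulate_cohort_bold(
    a_list,
    noise: NoiseSpec,
    duration: float,
    dt: float = 0.05,
    seed: int | np.random.Generator = 0,
    hemo: HemoParams | None = None,
    burn_in: float = 64.0,
) -> np.ndarray:
    """Batched :func:`simulate_bold` over sessions; returns (B, T, n)."""
    burn_in = max(float(burn_in), 64.0)
    x = simulate_cohort_neural(a_list, noise, duration + burn_in, dt, seed, burn_in=32.0)
    y = balloon_bold(x.transpose(1, 0, 2), hemo, dt)  # time-major for the ODE loop
    return y[int(round(burn_in / dt)) :].transpose(1, 0, 2)


def make_confounds(
    n_volumes: int, rng: np.random.Generator, n_motion: int = 6, n_pc: int = 3
) -> pd.DataFrame:
    """Motion-like and nuisance-component regressors for one session.

    Six smooth random walks stand in for rigid-body motion traces, their first
    differences for motion derivatives, and low-frequency cosine mixtures for
    principal components of white-matter/CSF signal.  Columns are scaled to
    unit standard deviation.
    """
    t = np.arange(n_volumes)
    motion = np.cumsum(rng.standard_normal((n_volumes, n_motion)), axis=0)
    motion -= motion.mean(axis=0)
    deriv = np.vstack([np.zeros((1, n_motion)), np.diff(motion, axis=0)])
    basis = np.column_stack(
        [np.cos(np.pi * k * (t + 0.5) / n_volumes) for k in range(1, 5)]
    )
    pcs = basis @ rng.standard_normal((basis.shape[1], n_pc))
    cols, names = [], []
    for i in range(n_motion):
        cols.append(motion[:, i])
        names.append(f"motion_{i + 1}")
    for i in range(n_motion):
        cols.append(deriv[:, i])
        names.append(f"motion_d{i + 1}")
    for i in range(n_pc):
        cols.append(pcs[:, i])
        names.append(f"nuisance_pc{i + 1}")
    mat = np.column_stack(cols)
    sd = mat.std(axis=0)
    sd[sd == 0] = 1.0
    return pd.DataFrame(mat / sd, columns=names)


def sample_and_corrupt(
    bold: np.ndarray,
    tr: float,
    n_volumes: int,
    noise: NoiseSpec,
    seed: int | np.random.Generator = 0,
    dt: float = 0.05,
    confound_leak: float = 0.1,
    region_names: list[str] | None = None,
) -> tuple[SessionSeries, pd.DataFrame]:
    """Sample a BOLD trajectory at the TR grid and add acquisition artifacts.

    Adds power-law observation noise, linear+quadratic drifts scaled by
    ``drift_amp``, and emits a confound matrix whose columns leak into the
    data with small random gains (sd ``confound_leak``), so the downstream
    confound regression has real work to do.
    """
    bold = np.asarray(bold, dtype=float)
    step = int(round(tr / dt))
    if abs(step * dt - tr) > 1e-9:
        raise ValidationError("tr must be an integer multiple of dt")
    if bold.shape[0] < (n_volumes - 1) * step + 1:
        raise ValidationError("trajectory shorter than tr * n_volumes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = bold.shape[1]
    data = bold[: (n_volumes - 1) * step + 1 : step].copy()
    data = data + powerlaw_noise(n_volumes, tr, noise.obs_amp, noise.obs_exp, rng, n)
    t = np.linspace(-1.0, 1.0, n_volumes)
    drift_basis = np.column_stack([t, t**2 - np.mean(t**2)])
    data = data + noise.drift_amp * drift_basis @ rng.standard_normal((2, n))
    confounds = make_confounds(n_volumes, rng)
    gains = confound_leak * rng.standard_normal((confounds.shape[1], n))
    data = data + confounds.to_numpy() @ gains
    series = SessionSeries(data=data, tr=tr, region_names=region_names or None)
    return series, confounds


def make_voxels(
    region_series: SessionSeries,
    n_voxels_per_region: int,
    voxel_noise_sd: float,
    seed: int | np.random.Generator = 0,
    gains: np.ndarray | None = None,
    gain_jitter: float = 0.3,
) -> dict[str, np.ndarray]:
    """Replicate each region series into noisy voxels (eigenvariate fixture).

    Each voxel is a random positive gain times the region series plus white
    noise; pass explicit ``gains`` (per voxel) to pin them.
    """
    if n_voxels_per_region < 2:
        raise ValidationError("need at least 2 voxels per region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks: dict[str, np.ndarray] = {}
    for j, name in enumerate(region_series.region_names):
        if gains is None:
            g = np.abs(1.0 + gain_jitter * rng.standard_normal(n_voxels_per_region))
        else:
            g = np.asarray(gains, dtype=float)
            if g.size != n_voxels_per_region:
                raise ValidationError("gains length must equal n_voxels_per_region")
        block = region_series.data[:, [j]] * g[None, :]
        block = block + voxel_noise_sd * rng.standard_normal(block.shape)
        blocks[name] = block
    return blocks
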