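"""Parametric empirical Bayes over first-level posteriors.

Levels two and three of the hierarchy are Bayesian general linear models on
the coupling parameters: per-subject PEB pools the four session posteriors
through the session design matrix (baseline / transient / sustained), and a
second PEB across subjects ("PEB of PEB") yields group effects.  First-level
posteriors enter with their full covariances, so uncertain sessions are
down-weighted automatically.

Model for units k = 1..K with carried posterior means m_k and covariances
S_k, design X (K x E) and random-effect covariance Sigma_b = exp(-gamma) I:

    m_k ~ N((x_k^T kron I_c) beta,  S_k + Sigma_b),   beta ~ N(0, sb2 I)

With beta integrated out analytically the log marginal likelihood of gamma
is available in closed form; the single hyperparameter is optimized by
bounded scalar search, which plays the role of the M-step and makes the
free-energy ascent monotone by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .cohort import SCORE_TIMEPOINTS, DesignMatrix, validate_scores
from .errors import ValidationError
from .spdcm import DcmPosterior

__all__ = [
    "PebOptions",
    "PebPosterior",
    "reduce_gaussian",
    "peb_fit",
    "peb_of_peb",
    "covariate_peb",
    "threshold_nonzero",
]

logger = logging.getLogger(__name__)


@dataclass
class PebOptions:
    """Hyperparameters of the between-level model.

    beta_prior_var: prior variance of each group-effect coefficient;
    gamma_mean/gamma_var: Gaussian hyperprior on the log precision of the
    between-level random effects (mean 4 centres the random-effect sd at
    exp(-2) ~ 0.14 coupling units); gamma_bounds: search interval.
    """

    beta_prior_var: float = 1.0
    gamma_mean: float = 4.0
    gamma_var: float = 1.0
    gamma_bounds: tuple[float, float] = (-5.0, 20.0)


@dataclass
class PebPosterior:
    """Gaussian posterior over effect-by-parameter coefficients beta."""

    beta_mean: np.ndarray  # (n_effects, n_carried)
    beta_cov: np.ndarray  # (n_effects*n_carried, n_effects*n_carried)
    gamma: float
    free_energy: float
    design: DesignMatrix
    carried: np.ndarray
    param_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_effects(self) -> int:
        return self.beta_mean.shape[0]

    @property
    def n_carried(self) -> int:
        return self.beta_mean.shape[1]

    def beta_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov)).reshape(self.beta_mean.shape)

    def flat_mean(self) -> np.ndarray:
        return self.beta_mean.reshape(-1)


def _psd_project(mat: np.ndarray, floor: float = 1e-12, what: str = "matrix") -> np.ndarray:
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    if w.min() < 0:
        logger.warning("projecting %s onto the PSD cone (min eig %.2g)", what, w.min())
        mat = (v * np.clip(w, floor, None)) @ v.T
    return mat


def reduce_gaussian(
    mean: np.ndarray,
    cov: np.ndarray,
    prior_mean: np.ndarray,
    prior_cov: np.ndarray,
    new_prior_mean: np.ndarray,
    new_prior_cov: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-evaluate a Gaussian posterior under a changed Gaussian prior.

    Standard Bayesian reduction: swap the prior precision out of the
    posterior precision and swap the new one in.  Used for the downward pass
    that imposes empirical (second-level) priors on session posteriors.
    """
    P = np.linalg.inv(_psd_project(cov, what="posterior covariance"))
    P0 = np.linalg.inv(_psd_project(prior_cov, what="prior covariance"))
    P1 = np.linalg.inv(_psd_project(new_prior_cov, what="new prior covariance"))
    P_new = _psd_project(P - P0 + P1, what="reduced precision")
    cov_new = np.linalg.inv(P_new)
    mean_new = cov_new @ (P @ mean - P0 @ prior_mean + P1 @ new_prior_mean)
    return mean_new, _psd_project(cov_new, what="reduced covariance")


def _extract_gaussians(posteriors, carried: np.ndarray):
    means, covs = [], []
    for post in posteriors:
        if isinstance(post, DcmPosterior):
            means.append(post.mean[carried])
            covs.append(post.cov[np.ix_(carried, carried)])
        elif isinstance(post, PebPosterior):
            means.append(post.flat_mean()[carried])
            covs.append(post.beta_cov[np.ix_(carried, carried)])
        else:  # anything with .mean / .cov (test doubles, reduced posteriors)
            means.append(np.asarray(post.mean, dtype=float)[carried])
            covs.append(np.asarray(post.cov, dtype=float)[np.ix_(carried, carried)])
    return means, covs


def peb_fit(
    posteriors,
    design: DesignMatrix | np.ndarray,
    carried: np.ndarray | None = None,
    opts: PebOptions | None = None,
    gamma_fixed: float | None = None,
    param_labels: list[str] | None = None,
) -> tuple[PebPosterior, list[tuple[np.ndarray, np.ndarray]]]:
    """Fit the between-level Bayesian GLM over first-level posteriors.

    Returns the beta posterior and the empirical prior (mean, covariance)
    each unit's carried parameters would receive from this level.  Pass
    ``gamma_fixed`` to pin the between-level log precision (no M-step); the
    E-step is then the exact generalized-least-squares solution.
    """
    opts = opts or PebOptions()
    if isinstance(design, DesignMatrix):
        X = design.values
        dm = design
    else:
        X = np.asarray(design, dtype=float)
        dm = None
    K, E = X.shape
    if len(posteriors) != K:
        raise ValidationError(f"{len(posteriors)} posteriors but design has {K} rows")
    if carried is None:
        first = posteriors[0]
        if isinstance(first, DcmPosterior):
            carried = first.spec.a_indices
        else:
            raise ValidationError("carried indices required for non-DCM posteriors")
    carried = np.asarray(carried, dtype=int)
    c = carried.size
    if isinstance(posteriors[0], DcmPosterior):
        sizes = {p.mean.size for p in posteriors}
        if len(sizes) != 1:
            raise ValidationError("posteriors have mismatched parameter orderings")
    means, covs = _extract_gaussians(posteriors, carried)
    dim = E * c
    sb2 = opts.beta_prior_var

    def fit_at(gamma: float):
        sig_b = np.exp(-gamma) * np.eye(c)
        P = np.zeros((dim, dim))
        b = np.zeros(dim)
        quad = 0.0
        ln_det = 0.0
        for k in range(K):
            Dk = covs[k] + sig_b
            Ak = np.linalg.inv(_psd_project(Dk, what="marginal covariance"))
            s, ld = np.linalg.slogdet(Dk)
            ln_det += ld
            Am = Ak @ means[k]
            quad += means[k] @ Am
            for e in range(E):
                b[e * c : (e + 1) * c] += X[k, e] * Am
                for f in range(E):
                    P[e * c : (e + 1) * c, f * c : (f + 1) * c] += (
                        X[k, e] * X[k, f] * Ak
                    )
        P += np.eye(dim) / sb2
        cov_beta = np.linalg.inv(P)
        mu = cov_beta @ b
        sign, ld_P = np.linalg.slogdet(P)
        log_ev = -0.5 * (
            K * c * np.log(2 * np.pi)
            + ln_det
            + dim * np.log(sb2)
            + ld_P
            + quad
            - mu @ b
        )
        return mu, cov_beta, float(log_ev)

    def objective(gamma: float) -> float:
        _, _, log_ev = fit_at(gamma)
        return -(log_ev - 0.5 * (gamma - opts.gamma_mean) ** 2 / opts.gamma_var)

    if gamma_fixed is not None:
        gamma = float(gamma_fixed)
        free_energy = -objective(gamma)
    else:
        f_init = -objective(opts.gamma_mean)
        res = minimize_scalar(
            objective, bounds=opts.gamma_bounds, method="bounded",
            options={"xatol": 1e-4},
        )
        gamma = float(res.x)
        free_energy = -float(res.fun)
        if free_energy < f_init:  # bounded search never worse than the init
            gamma, free_energy = opts.gamma_mean, f_init

    mu, cov_beta, _ = fit_at(gamma)
    cov_beta = _psd_project(cov_beta, what="beta covariance")

    # empirical priors for the level below: X_k beta with its uncertainty
    sig_b = np.exp(-gamma) * np.eye(c)
    empirical = []
    for k in range(K):
        Xk = np.kron(X[k : k + 1], np.eye(c))  # (c, dim)
        m_k = Xk @ mu
        c_k = sig_b + Xk @ cov_beta @ Xk.T
        empirical.append((m_k, _psd_project(c_k, what="empirical prior")))

    if dm is None:
        # raw matrices (e.g. covariate designs with a possibly-zero column)
        # bypass DesignMatrix validation deliberately
        dm = SimpleNamespace(
            values=X,
            effect_names=[f"effect_{e}" for e in range(E)],
            unit_names=[f"unit_{k}" for k in range(K)],
        )
    peb = PebPosterior(
        beta_mean=mu.reshape(E, c),
        beta_cov=cov_beta,
        gamma=gamma,
        free_energy=free_energy,
        design=dm,
        carried=carried,
        param_labels=list(param_labels) if param_labels else _default_labels(posteriors[0], carried),
    )
    return peb, empirical


def _default_labels(post, carried: np.ndarray) -> list[str]:
    if isinstance(post, DcmPosterior):
        names = post.spec.names()
        return [names[i] for i in carried]
    return [f"p{i}" for i in carried]


def peb_of_peb(
    session_pebs: list[PebPosterior],
    X2: np.ndarray | DesignMatrix | None = None,
    opts: PebOptions | None = None,
) -> PebPosterior:
    """Group-level PEB over per-subject session-PEB posteriors.

    Default design is the all-ones column (group commonalities).  The
    carried quantity is each subject's full vectorized beta (all session
    effects by all connections), so the group posterior exposes group-level
    transient and sustained effects per connection.
    """
    if not session_pebs:
        raise ValidationError("no subject posteriors supplied")
    ref = session_pebs[0]
    for p in session_pebs[1:]:
        if p.beta_mean.shape != ref.beta_mean.shape or list(
            p.design.effect_names
        ) != list(ref.design.effect_names):
            raise ValidationError("subjects have heterogeneous session designs")
    J = len(session_pebs)
    if X2 is None:
        X2 = DesignMatrix(
            values=np.ones((J, 1)),
            effect_names=["group"],
            unit_names=[f"S{j + 1}" for j in range(J)],
        )
    X2v = X2.values if isinstance(X2, DesignMatrix) else np.asarray(X2, dtype=float)
    if X2v.shape[0] != J:
        raise ValidationError("X2 rows must equal the number of subjects")
    dim = ref.beta_mean.size
    labels = [
        f"{eff}:{par}" for eff in ref.design.effect_names for par in ref.param_labels
    ]
    group, _ = peb_fit(
        session_pebs,
        X2 if isinstance(X2, DesignMatrix) else X2v,
        carried=np.arange(dim),
        opts=opts,
        param_labels=labels,
    )
    group.meta["level1_effects"] = list(ref.design.effect_names)
    group.meta["level1_params"] = list(ref.param_labels)
    return group


def covariate_peb(
    subject_posteriors: dict[str, dict[str, DcmPosterior]],
    scores: pd.DataFrame,
    score_name: str = "score",
    carried: np.ndarray | None = None,
    opts: PebOptions | None = None,
    param_labels: list[str] | None = None,
) -> PebPosterior:
    """Symptom-score PEB: sessions regressed on mean-centred scores.

    ``subject_posteriors`` maps subject id to {timepoint: DcmPosterior} and
    is restricted to the three scored time points.  Each subject's design is
    [ones, centred score]; the per-subject score-association posteriors are
    then pooled over subjects with an all-ones design.
    """
    scores = validate_scores(scores)
    session_pebs = []
    for subject in sorted(subject_posteriors):
        posts = subject_posteriors[subject]
        missing = set(SCORE_TIMEPOINTS) - set(posts)
        if missing:
            raise ValidationError(f"subject {subject}: missing sessions {sorted(missing)}")
        sub_scores = scores[scores["subject"] == subject].set_index("timepoint")["score"]
        missing_scores = set(SCORE_TIMEPOINTS) - set(sub_scores.index)
        if missing_scores:
            raise ValidationError(
                f"subject {subject}: no score for {sorted(missing_scores)}"
            )
        tps = list(SCORE_TIMEPOINTS)
        vals = sub_scores.loc[tps].to_numpy(dtype=float)
        centred = vals - vals.mean()
        X1 = np.column_stack([np.ones(len(tps)), centred])
        peb, _ = peb_fit(
            [posts[tp] for tp in tps],
            X1,
            carried=carried,
            opts=opts,
            param_labels=param_labels,
        )
        peb.design.effect_names[:] = ["mean", score_name]
        session_pebs.append(peb)
    group = peb_of_peb(session_pebs, opts=opts)
    group.meta["score_name"] = score_name
    return group


Z95 = 1.959964


def threshold_nonzero(
    peb: PebPosterior,
    level: float = 0.95,
    region_names: list[str] | None = None,
) -> pd.DataFrame:
    """Credible-interval thresholding: an effect survives iff 0 is outside
    its central ``level`` interval.  No multiplicity correction is applied
    (a single multivariate Bayesian model underlies all intervals).

    Returns a table with columns source, target, effect, mean, sd, lo95,
    hi95, survives.  Source/target are parsed from parameter labels of the
    form ``a[i,k]`` (row = target) when present.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    means = peb.beta_mean
    sds = peb.beta_sd()
    rows = []
    for e, eff in enumerate(peb.design.effect_names):
        for p, label in enumerate(peb.param_labels):
            inner, _, par = label.rpartition(":")
            effect = f"{eff}:{inner}" if inner else eff
            src = tgt = ""
            if par.startswith("a[") and par.endswith("]"):
                i, k = par[2:-1].split(",")
                if region_names:
                    tgt, src = region_names[int(i)], region_names[int(k)]
                else:
                    tgt, src = f"R{int(i) + 1}", f"R{int(k) + 1}"
            m, s = means[e, p], sds[e, p]
            lo, hi = m - z * s, m + z * s
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "effect": effect,
                    "param": par,
                    "mean": m,
                    "sd": s,
                    "lo95": lo,
                    "hi95": hi,
                    "survives": bool(lo > 0.0 or hi < 0.0),
                }
            )
    return pd.DataFrame(rows)
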