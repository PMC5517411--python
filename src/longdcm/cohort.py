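"""Synthetic longitudinal cohorts with a three-level hierarchical structure.

The generator mirrors the hierarchy used for inference: group-level effect
coefficients (baseline / transient / sustained rows of ``beta3``) generate
per-subject coefficients ``beta2`` with between-subject scatter ``sigma3``,
which in turn generate per-session coupling matrices ``theta`` through the
session design matrix with between-session scatter ``sigma2``.  Symptom
scores are linearly coupled to designated connections at three of the four
time points (the day-1 post-treatment session carries no score).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ValidationError
from .simulate import default_region_names, is_stable

__all__ = [
    "DesignMatrix",
    "GroupTruth",
    "SESSION_LABELS",
    "SCORE_TIMEPOINTS",
    "make_session_design",
    "sample_group_truth",
    "generate_scores",
    "validate_scores",
]

SESSION_LABELS = ["op-1d", "op+1d", "op+7d", "op+3m"]
#: time points carrying a symptom score, mapped to session indices
SCORE_TIMEPOINTS = {"op-1d": 0, "op+7d": 2, "op+3m": 3}


@dataclass
class DesignMatrix:
    """Units x effects design matrix whose first column is the baseline."""

    values: np.ndarray
    effect_names: list[str]
    unit_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("design matrix must be 2-D")
        rows, cols = self.values.shape
        if cols > rows:
            raise ValidationError("design has more effects than units")
        if len(self.effect_names) != cols or len(self.unit_names) != rows:
            raise ValidationError("design labels do not match matrix shape")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValidationError("first design column must be the baseline (all ones)")
        if np.linalg.matrix_rank(self.values) < cols:
            raise ValidationError("design matrix is rank deficient")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_effects(self) -> int:
        return self.values.shape[1]


def make_session_design(n_sessions: int) -> DesignMatrix:
    """Four-session design with baseline, transient, and sustained columns.

    The transient contrast [1 -1 -1 1] codes a change that recovers to
    baseline by the last session; the sustained contrast [1 1 -1 -1] codes an
    enduring post-treatment change (sessions 3 and 4 flipped relative to the
    two early sessions).
    """
    if n_sessions != 4:
        raise ValidationError(
            "only the 4-session baseline/transient/sustained design is defined"
        )
    values = np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, 1.0],
            [1.0, -1.0, -1.0],
            [1.0, 1.0, -1.0],
        ]
    )
    return DesignMatrix(
        values=values,
        effect_names=["baseline", "transient", "sustained"],
        unit_names=list(SESSION_LABELS),
    )


@dataclass
class GroupTruth:
    """Ground truth for one synthetic cohort.

    beta3: (3, n*n) group-level effect coefficients on the vectorized
    coupling matrix (row-major, row = target); beta2: (J, 3, n*n) per-subject
    coefficients; theta: (J, 4, n, n) per-session coupling matrices exactly
    as generated (stored, not refit); sigma2/sigma3: between-session and
    between-subject random-effect standard deviations (coupling units);
    score_coupling: connection -> gain linking session-wise coupling to the
    symptom score.
    """

    beta3: np.ndarray
    beta2: np.ndarray
    theta: np.ndarray
    sigma2: float
    sigma3: float
    score_coupling: dict[tuple[int, int], float] = field(default_factory=dict)
    design: DesignMatrix = field(default_factory=lambda: make_session_design(4))
    region_names: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        self.beta3 = np.asarray(self.beta3, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not self.region_names:
            self.region_names = default_region_names(self.theta.shape[-1])

    @property
    def n_subjects(self) -> int:
        return self.theta.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.theta.shape[1]

    @property
    def n_regions(self) -> int:
        return self.theta.shape[2]


def sample_group_truth(
    n_subjects: int,
    n_regions: int,
    effect_spec: dict[tuple[int, int], tuple[float, float]] | None = None,
    sigma2: float = 0.05,
    sigma3: float = 0.05,
    seed: int = 0,
    score_coupling: dict[tuple[int, int], float] | None = None,
    baseline_offdiag_sd: float = 0.05,
    max_retries: int = 100,
) -> GroupTruth:
    """Draw a cohort's ground-truth hierarchy, fully reproducible from seed.

    ``effect_spec`` maps a connection ``(target, source)`` to its
    ``(transient, sustained)`` regression coefficients; unnamed connections
    carry fixed effects of zero.  Every session coupling matrix is required
    to be stable; only the session-level random component is re-jittered on a
    stability failure (fixed effects untouched), up to ``max_retries`` times.
    """
    if n_regions < 2:
        raise ValidationError("need at least 2 regions")
    if sigma2 < 0 or sigma3 < 0:
        raise ValidationError("sigma2 and sigma3 must be >= 0")
    effect_spec = effect_spec or {}
    for (i, k), (tr_eff, su_eff) in effect_spec.items():
        if not (0 <= i < n_regions and 0 <= k < n_regions):
            raise ValidationError(f"effect_spec names unknown connection ({i},{k})")
        if not (np.isfinite(tr_eff) and np.isfinite(su_eff)):
            raise ValidationError("effect sizes must be finite")
    rng = np.random.default_rng(seed)
    design = make_session_design(4)
    X1 = design.values
    c = n_regions * n_regions

    # baseline row: weakly coupled stable random network
    for attempt in range(max_retries + 1):
        base = baseline_offdiag_sd * rng.standard_normal((n_regions, n_regions))
        np.fill_diagonal(base, 0.0)
        if is_stable(base):
            break
    else:  # pragma: no cover - essentially unreachable at default scale
        raise GenerationError("could not sample a stable baseline network")

    beta3 = np.zeros((3, c))
    beta3[0] = base.ravel()
    for (i, k), (tr_eff, su_eff) in effect_spec.items():
        beta3[1, i * n_regions + k] = tr_eff
        beta3[2, i * n_regions + k] = su_eff

    beta2 = np.empty((n_subjects, 3, c))
    theta = np.empty((n_subjects, 4, n_regions, n_regions))
    for j in range(n_subjects):
        beta2[j] = beta3 + sigma3 * rng.standard_normal((3, c))
        for s in range(4):
            fixed = X1[s] @ beta2[j]
            for attempt in range(max_retries + 1):
                cand = fixed + sigma2 * rng.standard_normal(c)
                mat = cand.reshape(n_regions, n_regions)
                if is_stable(mat):
                    theta[j, s] = mat
                    break
                if sigma2 == 0:
                    raise GenerationError(
                        f"subject {j} session {s}: fixed effects alone are unstable"
                    )
            else:
                raise GenerationError(
                    f"subject {j} session {s}: no stable draw in {max_retries} retries"
                )

    return GroupTruth(
        beta3=beta3,
        beta2=beta2,
        theta=theta,
        sigma2=float(sigma2),
        sigma3=float(sigma3),
        score_coupling=dict(score_coupling or {}),
        design=design,
        region_names=default_region_names(n_regions),
        seed=seed,
    )


def generate_scores(
    truth: GroupTruth,
    baseline_score: float = 20.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    score_coupling: dict[tuple[int, int], float] | None = None,
) -> pd.DataFrame:
    """Symptom scores at three time points, linearly coupled to connections.

    score(j, t) = baseline + sum_c g_c * theta[j, session(t), c] + noise,
    clipped at zero (clinical scales are non-negative).  Returns a tidy table
    with columns ``subject``, ``timepoint``, ``score``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    coupling = truth.score_coupling if score_coupling is None else score_coupling
    rng = np.random.default_rng(seed)
    rows = []
    for j in range(truth.n_subjects):
        for label, s in SCORE_TIMEPOINTS.items():
            val = baseline_score
            for (i, k), g in coupling.items():
                val += g * truth.theta[j, s, i, k]
            val += noise_sd * rng.standard_normal()
            rows.append((f"S{j + 1}", label, max(val, 0.0)))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "score"])


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Check the score-table contract: 3 finite, non-negative values/subject."""
    required = {"subject", "timepoint", "score"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"score table must have columns {sorted(required)}")
    if not np.all(np.isfinite(scores["score"])) or (scores["score"] < 0).any():
        raise ValidationError("scores must be finite and >= 0")
    counts = scores.groupby("subject")["timepoint"].nunique()
    if not (counts == 3).all():
        raise ValidationError("each subject needs exactly 3 scored time points")
    unknown = set(scores["timepoint"]) - set(SCORE_TIMEPOINTS)
    if unknown:
        raise ValidationError(f"unknown time points: {sorted(unknown)}")
    return scores
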