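"""Ground-truth cohort generation: designs, hierarchy, scores."""

import numpy as np
import pandas as pd
import pytest

from longdcm.cohort import (
    SCORE_TIMEPOINTS,
    DesignMatrix,
    generate_scores,
    make_session_design,
    sample_group_truth,
    validate_scores,
)
from longdcm.errors import GenerationError, ValidationError
from longdcm.simulate import is_stable


class TestSessionDesign:
    def test_columns_match_contrasts(self):
        dm = make_session_design(4)
        assert dm.effect_names == ["baseline", "transient", "sustained"]
        assert np.array_equal(dm.values[:, 0], [1, 1, 1, 1])
        assert np.array_equal(dm.values[:, 1], [1, -1, -1, 1])
        assert np.array_equal(dm.values[:, 2], [1, 1, -1, -1])

    def test_baseline_column_sums_to_session_count(self):
        assert make_session_design(4).values[:, 0].sum() == 4

    def test_contrast_columns_are_orthogonal(self):
        dm = make_session_design(4)
        assert dm.values[:, 1] @ dm.values[:, 2] == 0

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    def test_other_session_counts_rejected(self, n):
        with pytest.raises(ValidationError):
            make_session_design(n)

    def test_design_matrix_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DesignMatrix(
                values=np.array([[0.0, 1.0], [1.0, 1.0]]),
                effect_names=["baseline", "x"],
                unit_names=["u1", "u2"],
            )
        with pytest.raises(ValidationError):
            DesignMatrix(
                values=np.ones((3, 2)),
                effect_names=["baseline", "dup"],
                unit_names=["u1", "u2", "u3"],
            )


class TestGroupTruth:
    def test_no_noise_degenerates_to_baseline(self):
        truth = sample_group_truth(3, 3, {}, sigma2=0.0, sigma3=0.0, seed=0)
        base = truth.beta3[0].reshape(3, 3)
        for j in range(3):
            for s in range(4):
                assert np.allclose(truth.theta[j, s], base)

    def test_sustained_effect_follows_design_column(self):
        truth = sample_group_truth(
            2, 3, {(2, 1): (0.0, 0.3)}, sigma2=0.0, sigma3=0.0, seed=0
        )
        base = truth.beta3[0].reshape(3, 3)[2, 1]
        sustained_col = truth.design.values[:, 2]
        for s in range(4):
            assert truth.theta[0, s, 2, 1] == pytest.approx(
                base + 0.3 * sustained_col[s]
            )

    def test_between_subject_scatter_matches_sigma3(self):
        # large-subject Monte Carlo estimate of the level-3 random effect sd
        truth = sample_group_truth(200, 3, {}, sigma2=0.0, sigma3=0.05, seed=7)
        devs = truth.beta2 - truth.beta3[None]
        assert np.std(devs) == pytest.approx(0.05, rel=0.1)

    def test_refitting_design_recovers_beta2(self):
        # with no session-level noise, per-subject OLS on X1 is exact
        truth = sample_group_truth(4, 3, {(1, 0): (0.2, -0.1)}, 0.0, 0.04, seed=3)
        X1 = truth.design.values
        for j in range(truth.n_subjects):
            thetas = truth.theta[j].reshape(4, -1)
            beta_hat, *_ = np.linalg.lstsq(X1, thetas, rcond=None)
            assert np.allclose(beta_hat, truth.beta2[j], atol=1e-10)

    def test_all_sessions_stable(self):
        truth = sample_group_truth(8, 3, {(2, 1): (0.0, 0.3)}, 0.05, 0.05, seed=11)
        for j in range(8):
            for s in range(4):
                assert is_stable(truth.theta[j, s])

    def test_deterministic_given_seed(self):
        a = sample_group_truth(4, 3, {(0, 1): (0.1, 0.2)}, 0.05, 0.05, seed=5)
        b = sample_group_truth(4, 3, {(0, 1): (0.1, 0.2)}, 0.05, 0.05, seed=5)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.beta2, b.beta2)

    def test_unattainable_stability_reports_location(self):
        with pytest.raises(GenerationError, match=r"subject \d+ session \d+"):
            sample_group_truth(2, 2, {(0, 1): (0.0, 2.0), (1, 0): (0.0, 2.0)},
                               sigma2=0.0, sigma3=0.0, seed=0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            sample_group_truth(2, 1, {}, 0.05, 0.05, seed=0)
        with pytest.raises(ValidationError):
            sample_group_truth(2, 3, {}, -0.1, 0.05, seed=0)
        with pytest.raises(ValidationError):
            sample_group_truth(2, 3, {(5, 0): (0.1, 0.0)}, 0.05, 0.05, seed=0)


class TestScores:
    def test_zero_coupling_gives_baseline(self):
        truth = sample_group_truth(3, 3, {}, 0.05, 0.05, seed=0)
        scores = generate_scores(truth, baseline_score=12.0, noise_sd=0.0, seed=0,
                                 score_coupling={})
        assert np.allclose(scores["score"], 12.0)
        assert validate_scores(scores) is scores

    def test_score_differences_track_coupling_differences(self):
        truth = sample_group_truth(
            3, 3, {(2, 1): (0.0, 0.3)}, 0.05, 0.05, seed=1,
            score_coupling={(2, 1): 4.0},
        )
        scores = generate_scores(truth, 20.0, noise_sd=0.0, seed=0)
        for j in range(truth.n_subjects):
            sub = scores[scores["subject"] == f"S{j + 1}"].set_index("timepoint")
            for t1, t2 in [("op-1d", "op+7d"), ("op+7d", "op+3m")]:
                s1, s2 = SCORE_TIMEPOINTS[t1], SCORE_TIMEPOINTS[t2]
                expected = 4.0 * (truth.theta[j, s1, 2, 1] - truth.theta[j, s2, 2, 1])
                assert sub.loc[t1, "score"] - sub.loc[t2, "score"] == pytest.approx(
                    expected
                )

    def test_regression_recovers_gain(self):
        # OLS of scores on the coupled connection across a large cohort
        truth = sample_group_truth(
            200, 3, {(2, 1): (0.0, 0.3)}, 0.05, 0.05, seed=2,
            score_coupling={(2, 1): 4.0},
        )
        scores = generate_scores(truth, 50.0, noise_sd=1.0, seed=3)
        rows = []
        for j in range(truth.n_subjects):
            for tp, s in SCORE_TIMEPOINTS.items():
                rows.append((f"S{j + 1}", tp, truth.theta[j, s, 2, 1]))
        x = pd.DataFrame(rows, columns=["subject", "timepoint", "theta"])
        merged = scores.merge(x, on=["subject", "timepoint"])
        X = np.column_stack([np.ones(len(merged)), merged["theta"]])
        coef, *_ = np.linalg.lstsq(X, merged["score"], rcond=None)
        resid = merged["score"] - X @ coef
        se = np.sqrt(
            resid @ resid / (len(merged) - 2) * np.linalg.inv(X.T @ X)[1, 1]
        )
        assert abs(coef[1] - 4.0) < 2 * se

    def test_scores_clipped_at_zero(self):
        truth = sample_group_truth(5, 3, {}, 0.05, 0.05, seed=0)
        scores = generate_scores(truth, baseline_score=0.0, noise_sd=5.0, seed=1)
        assert (scores["score"] >= 0).all()

    def test_score_table_validation(self):
        bad = pd.DataFrame(
            {"subject": ["S1"], "timepoint": ["op+1d"], "score": [1.0]}
        )
        with pytest.raises(ValidationError):
            validate_scores(bad)
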