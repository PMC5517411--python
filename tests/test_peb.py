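"""Hierarchical (parametric empirical Bayes) general linear models."""

import numpy as np
import pandas as pd
import pytest
from types import SimpleNamespace

from longdcm.cohort import make_session_design
from longdcm.errors import ValidationError
from longdcm.peb import (
    PebOptions,
    covariate_peb,
    peb_fit,
    peb_of_peb,
    reduce_gaussian,
    threshold_nonzero,
)


def gaussian(mean, cov):
    return SimpleNamespace(mean=np.atleast_1d(np.asarray(mean, dtype=float)),
                           cov=np.atleast_2d(np.asarray(cov, dtype=float)))


FLAT = PebOptions(beta_prior_var=1e8)


class TestPebFit:
    def test_equal_precision_average(self):
        # all-ones design, equal first-level covariances, fixed gamma, flat
        # beta prior: the posterior mean is the arithmetic mean
        posts = [gaussian([x], [[0.2]]) for x in (1.0, 2.0, 4.0)]
        peb, _ = peb_fit(posts, np.ones((3, 1)), carried=np.array([0]),
                         opts=FLAT, gamma_fixed=30.0)
        assert peb.beta_mean[0, 0] == pytest.approx(7.0 / 3.0, abs=1e-8)

    def test_matches_gls_oracle(self, rng):
        c, K = 3, 4
        X = make_session_design(4).values
        means = [rng.standard_normal(c) for _ in range(K)]
        covs = [np.diag(rng.uniform(0.1, 0.5, c)) for _ in range(K)]
        posts = [gaussian(m, S) for m, S in zip(means, covs)]
        gamma = 2.0
        peb, _ = peb_fit(posts, X, carried=np.arange(c), gamma_fixed=gamma)
        # independent dense GLS construction
        dim = 3 * c
        P = np.eye(dim)
        b = np.zeros(dim)
        for k in range(K):
            Xk = np.kron(X[k : k + 1], np.eye(c))
            A = np.linalg.inv(covs[k] + np.exp(-gamma) * np.eye(c))
            P += Xk.T @ A @ Xk
            b += Xk.T @ A @ means[k]
        oracle = np.linalg.solve(P, b)
        assert np.abs(peb.flat_mean() - oracle).max() < 1e-8

    def test_saturated_design_recovers_first_level(self, rng):
        means = [rng.standard_normal(2) for _ in range(3)]
        posts = [gaussian(m, 0.1 * np.eye(2)) for m in means]
        peb, _ = peb_fit(posts, np.eye(3), carried=np.arange(2),
                         opts=FLAT, gamma_fixed=30.0)
        for k in range(3):
            assert np.allclose(peb.beta_mean[k], means[k], atol=1e-4)

    def test_free_energy_not_worse_than_initial(self, rng):
        posts = [gaussian(rng.standard_normal(3), np.diag(rng.uniform(0.05, 0.2, 3)))
                 for _ in range(4)]
        opts = PebOptions()
        peb, _ = peb_fit(posts, make_session_design(4), carried=np.arange(3), opts=opts)
        init, _ = peb_fit(posts, make_session_design(4), carried=np.arange(3),
                          opts=opts, gamma_fixed=opts.gamma_mean)
        assert peb.free_energy >= init.free_energy - 1e-6

    def test_uncertain_subject_downweighted(self):
        # inflating one unit's covariance pulls the group mean toward the rest
        tight = [gaussian([1.0], [[0.01]]), gaussian([1.0], [[0.01]]),
                 gaussian([5.0], [[0.01]])]
        peb_eq, _ = peb_fit(tight, np.ones((3, 1)), carried=np.array([0]),
                            gamma_fixed=6.0)
        inflated = tight[:2] + [gaussian([5.0], [[1.0]])]
        peb_inf, _ = peb_fit(inflated, np.ones((3, 1)), carried=np.array([0]),
                             gamma_fixed=6.0)
        assert peb_inf.beta_mean[0, 0] < peb_eq.beta_mean[0, 0]

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValidationError):
            peb_fit([gaussian([0.0], [[1.0]])], np.ones((2, 1)), carried=np.array([0]))

    def test_empirical_priors_interpolate_design(self, rng):
        posts = [gaussian(rng.standard_normal(2), 0.05 * np.eye(2)) for _ in range(4)]
        peb, empirical = peb_fit(posts, make_session_design(4), carried=np.arange(2))
        X = make_session_design(4).values
        for k, (m_k, c_k) in enumerate(empirical):
            expect = (np.kron(X[k : k + 1], np.eye(2)) @ peb.flat_mean()).ravel()
            assert np.allclose(m_k, expect, atol=1e-10)
            assert np.linalg.eigvalsh(c_k).min() > 0


class TestReduceGaussian:
    def test_identity_prior_change_is_noop(self, rng):
        m = rng.standard_normal(3)
        S = np.diag(rng.uniform(0.1, 0.3, 3))
        m0, S0 = np.zeros(3), np.eye(3)
        m1, S1 = reduce_gaussian(m, S, m0, S0, m0, S0)
        assert np.allclose(m1, m) and np.allclose(S1, S)

    def test_tighter_prior_shrinks_toward_it(self, rng):
        m = np.array([1.0])
        S = np.array([[0.5]])
        m1, S1 = reduce_gaussian(m, S, np.zeros(1), np.eye(1) * 10,
                                 np.array([3.0]), np.array([[0.01]]))
        assert 1.0 < m1[0] < 3.0 + 1e-9
        assert S1[0, 0] < S[0, 0]


class TestPebOfPeb:
    def _session_peb(self, beta, cov_scale=1e-8):
        posts = [gaussian(row @ beta, 0.01 * np.eye(beta.shape[1]))
                 for row in make_session_design(4).values]
        peb, _ = peb_fit(posts, make_session_design(4),
                         carried=np.arange(beta.shape[1]))
        if cov_scale is not None:
            peb.beta_cov = cov_scale * np.eye(peb.beta_cov.shape[0])
            peb.beta_mean = beta.copy()
        return peb

    def test_identical_subjects_reproduce_common_beta(self):
        beta = np.array([[0.1, -0.2], [0.0, 0.3], [0.25, 0.0]])
        pebs = [self._session_peb(beta) for _ in range(4)]
        group = peb_of_peb(pebs)
        assert np.allclose(group.beta_mean.reshape(3, 2), beta, atol=1e-3)

    def test_subject_permutation_invariance(self, rng):
        betas = [rng.standard_normal((3, 2)) * 0.2 for _ in range(4)]
        pebs = [self._session_peb(b) for b in betas]
        g1 = peb_of_peb(pebs)
        g2 = peb_of_peb(pebs[::-1])
        assert np.allclose(g1.beta_mean, g2.beta_mean, atol=1e-8)
        assert np.allclose(g1.beta_cov, g2.beta_cov, atol=1e-8)

    def test_planted_group_effect_survives(self, rng):
        # 8 subjects, sustained effect 0.3 on one of 4 carried parameters
        beta_true = np.zeros((3, 4))
        beta_true[0] = 0.05
        beta_true[2, 1] = 0.3
        pebs = []
        for _ in range(8):
            beta_j = beta_true + 0.05 * rng.standard_normal((3, 4))
            posts = [gaussian(row @ beta_j, 0.02 * np.eye(4))
                     for row in make_session_design(4).values]
            peb, _ = peb_fit(posts, make_session_design(4), carried=np.arange(4))
            pebs.append(peb)
        group = peb_of_peb(pebs)
        table = threshold_nonzero(group)
        hit = table[(table["effect"] == "group:sustained") & (table["param"] == "p1")]
        assert bool(hit.iloc[0]["survives"]) and hit.iloc[0]["mean"] > 0

    def test_heterogeneous_designs_rejected(self, rng):
        pebs = [self._session_peb(rng.standard_normal((3, 2))) for _ in range(2)]
        pebs[1].design.effect_names = ["baseline", "other", "sustained"]
        with pytest.raises(ValidationError):
            peb_of_peb(pebs)


class TestCovariatePeb:
    def _posts(self, rng, slope=0.0, c=2):
        # three scored sessions; carried parameter 0 tracks the score
        subject_posts, rows = {}, []
        for j, subject in enumerate(["S1", "S2", "S3", "S4"]):
            scores = {"op-1d": 10.0 + j, "op+7d": 6.0 + j, "op+3m": 4.0 + j}
            posts = {}
            for tp, sc in scores.items():
                theta = np.zeros(c)
                theta[0] = slope * (sc - np.mean(list(scores.values())))
                posts[tp] = gaussian(theta, 0.01 * np.eye(c))
                rows.append((subject, tp, sc))
            subject_posts[subject] = posts
        table = pd.DataFrame(rows, columns=["subject", "timepoint", "score"])
        return subject_posts, table

    def test_constant_scores_give_null_association(self, rng):
        posts, table = self._posts(rng, slope=0.3)
        table["score"] = 7.0
        group = covariate_peb(posts, table, "posture", carried=np.arange(2))
        idx = group.meta["level1_effects"].index("posture")
        assoc = group.beta_mean.reshape(2, 2)[idx]
        assert np.allclose(assoc, 0.0, atol=1e-6)
        tab = threshold_nonzero(group)
        assert not tab[tab["effect"] == "group:posture"]["survives"].any()

    def test_association_sign_and_survival(self, rng):
        posts, table = self._posts(rng, slope=0.3)
        group = covariate_peb(posts, table, "posture", carried=np.arange(2))
        tab = threshold_nonzero(group)
        hit = tab[(tab["effect"] == "group:posture") & (tab["param"] == "p0")].iloc[0]
        assert hit["survives"] and hit["mean"] > 0

    def test_affine_score_rescale_halves_association(self, rng):
        posts, table = self._posts(rng, slope=0.3)
        g1 = covariate_peb(posts, table, "posture", carried=np.arange(2))
        doubled = table.copy()
        doubled["score"] = 2 * doubled["score"]
        g2 = covariate_peb(posts, doubled, "posture", carried=np.arange(2))
        idx = g1.meta["level1_effects"].index("posture")
        a1 = g1.beta_mean.reshape(2, 2)[idx, 0]
        a2 = g2.beta_mean.reshape(2, 2)[idx, 0]
        assert a2 == pytest.approx(a1 / 2, rel=0.05)

    def test_missing_score_rejected(self, rng):
        posts, table = self._posts(rng)
        with pytest.raises(ValidationError):
            covariate_peb(posts, table[table["timepoint"] != "op+7d"], "posture",
                          carried=np.arange(2))


class TestThreshold:
    @pytest.mark.parametrize(
        "mean,sd,survives", [(0.3, 0.1, True), (0.1, 0.1, False), (0.0, 0.5, False)]
    )
    def test_gaussian_interval_criterion(self, mean, sd, survives):
        peb = SimpleNamespace(
            beta_mean=np.array([[mean]]),
            beta_cov=np.array([[sd**2]]),
            beta_sd=lambda: np.array([[sd]]),
            design=SimpleNamespace(effect_names=["sustained"]),
            param_labels=["a[1,0]"],
        )
        table = threshold_nonzero(peb, 0.95, ["PrcG", "SMA"])
        row = table.iloc[0]
        assert row["survives"] == survives
        assert row["target"] == "SMA" and row["source"] == "PrcG"
        assert row["lo95"] == pytest.approx(mean - 1.959964 * sd)

    def test_invalid_level_rejected(self):
        peb = SimpleNamespace(
            beta_mean=np.zeros((1, 1)), beta_cov=np.eye(1),
            beta_sd=lambda: np.ones((1, 1)),
            design=SimpleNamespace(effect_names=["e"]), param_labels=["p0"],
        )
        with pytest.raises(ValidationError):
            threshold_nonzero(peb, 1.5)
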