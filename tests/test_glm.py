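"""Design matrices, OLS fits, contrasts: exactness and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rewardkit.glm import (DesignMatrix, RankDeficientDesignError,
                           build_design, compute_contrast,
                           cosine_highpass_basis, fit_glm, grand_mean_scale)
from rewardkit.simulate import simulate_mid_events, simulate_sr_events


class TestCosineBasis:
    def test_printed_run_yields_seven_columns(self):
        basis = cosine_highpass_basis(283, 1.615, cutoff=128.0)
        assert basis.shape == (283, 7)

    def test_cutoff_beyond_twice_run_length_is_empty(self):
        assert cosine_highpass_basis(100, 1.0, cutoff=200.0).shape[1] == 0
        assert cosine_highpass_basis(100, 1.0, cutoff=500.0).shape[1] == 0

    def test_gram_matrix_with_constant_is_identity(self):
        basis = cosine_highpass_basis(283, 1.615, cutoff=128.0)
        M = np.column_stack([np.ones(283) / np.sqrt(283), basis])
        gram = M.T @ M
        assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-10

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            cosine_highpass_basis(100, 1.0, cutoff=0.0)


class TestBuildDesign:
    def test_empty_events_only_nuisance_columns(self):
        conf = pd.DataFrame({"fd": np.random.default_rng(0).random(100)})
        d = build_design(pd.DataFrame(columns=["onset", "duration",
                                               "trial_type", "partner"]),
                         "mid", 100, 1.615, confounds=conf)
        assert set(d.names) == {"cosine01", "cosine02", "fd", "intercept"}

    def test_mid_has_four_named_task_columns(self, config):
        events = simulate_mid_events(config, (1, 1, 1))
        d = build_design(events, "mid", 283, config.tr)
        task_cols = [n for n in d.names if not n.startswith("cosine")
                     and n != "intercept"]
        assert task_cols == ["reward_anticipation", "neutral_anticipation",
                             "reward_outcome", "neutral_outcome"]

    def test_sr_has_eight_task_columns(self, config):
        events = simulate_sr_events(config, (1, 1, 1))
        d = build_design(events, "sr", 265, config.tr)
        task_cols = [n for n in d.names if n.startswith(("decision",
                                                         "outcome"))]
        assert len(task_cols) == 8

    def test_single_event_support_window(self):
        events = pd.DataFrame([{"onset": 20.0, "duration": 1.0,
                                "trial_type": "reward_anticipation",
                                "partner": "none"}])
        d = build_design(events, "mid", 100, 1.0, highpass_cutoff=1e9)
        col = d.column("reward_anticipation")
        assert np.allclose(col[:19], 0.0)
        assert col[22:30].max() > 0.01
        assert np.abs(col[53:]).max() < 1e-3  # decayed by 52 s

    def test_unknown_condition_label_raises(self):
        events = pd.DataFrame([{"onset": 1.0, "duration": 1.0,
                                "trial_type": "mystery", "partner": "none"}])
        with pytest.raises(ValueError, match="mystery"):
            build_design(events, "mid", 100, 1.0)


class TestFitGlm:
    def _random_design(self, rng, n=50, p=4):
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        return DesignMatrix(values=X, names=[f"c{i}" for i in range(p)],
                            tr=1.0, frame_times=np.arange(n) + 0.5)

    def test_exact_interpolation_zero_noise(self, rng):
        d = self._random_design(rng)
        beta = rng.standard_normal((4, 7))
        y = d.values @ beta
        fit = fit_glm(y, d)
        assert np.abs(fit.beta - beta).max() < 1e-8
        assert np.abs(fit.sigma2).max() < 1e-16

    def test_matches_normal_equations_oracle(self, rng):
        d = self._random_design(rng, n=50, p=5)
        y = rng.standard_normal((50, 10))
        fit = fit_glm(y, d)
        X = d.values
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(fit.beta - oracle).max() < 1e-8

    def test_sigma2_recovers_noise_variance(self, rng):
        d = self._random_design(rng, n=200)
        y = 1.7 * rng.standard_normal((200, 1000))
        fit = fit_glm(y, d)
        assert fit.dof == 196
        assert fit.sigma2.mean() == pytest.approx(1.7 ** 2, rel=0.05)

    def test_rank_deficient_design_names_columns(self, rng):
        X = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        d = DesignMatrix(values=X, names=["intercept", "a", "a_twice"],
                         tr=1.0, frame_times=np.arange(30) + 0.5)
        with pytest.raises(RankDeficientDesignError, match="a_twice|a"):
            fit_glm(np.random.default_rng(0).random((30, 2)), d)

    def test_frame_mismatch_raises(self, rng):
        d = self._random_design(rng)
        with pytest.raises(ValueError, match="frames"):
            fit_glm(rng.standard_normal((49, 3)), d)


class TestContrast:
    def test_zero_weights_zero_everywhere(self, rng):
        d = TestFitGlm()._random_design(rng)
        fit = fit_glm(rng.standard_normal((50, 5)), d)
        c = compute_contrast(fit, d, np.zeros(4))
        assert np.all(c.effect == 0) and np.all(c.z == 0)

    def test_equal_betas_cancel_in_difference(self, rng):
        n = 60
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x.copy() * 1.0])
        X[:, 2] = rng.standard_normal(n)
        d = DesignMatrix(values=X, names=["intercept", "reward", "neutral"],
                         tr=1.0, frame_times=np.arange(n) + 0.5)
        y = (2.0 + 1.3 * X[:, 1] + 1.3 * X[:, 2])[:, None]
        fit = fit_glm(y, d)
        c = compute_contrast(fit, d, {"reward": 1.0, "neutral": -1.0})
        assert abs(c.effect[0]) < 1e-10

    def test_t_matches_textbook_formula_on_hand_fixture(self):
        """5-frame, 2-regressor fixture: t = w'b / sqrt(s2 w'(X'X)^-1 w)."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0],
                      [1.0, 4.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])[:, None]
        d = DesignMatrix(values=X, names=["b0", "b1"], tr=1.0,
                         frame_times=np.arange(5) + 0.5)
        fit = fit_glm(y, d)
        w = np.array([0.0, 1.0])
        beta = np.linalg.solve(X.T @ X, X.T @ y).ravel()
        resid = y.ravel() - X @ beta
        s2 = resid @ resid / 3
        t_oracle = (w @ beta) / np.sqrt(s2 * w @ np.linalg.inv(X.T @ X) @ w)
        c = compute_contrast(fit, d, w)
        z_expected = np.sign(t_oracle) * stats.norm.isf(
            stats.t.sf(abs(t_oracle), 3))
        assert c.z[0] == pytest.approx(z_expected, abs=1e-10)
        t_ours = c.effect[0] / np.sqrt(fit.sigma2[0]
                                       * w @ fit.xtx_inv @ w)
        assert t_ours == pytest.approx(t_oracle, abs=1e-10)

    def test_regressor_order_permutation_invariance(self, rng):
        d = TestFitGlm()._random_design(rng, n=80, p=4)
        y = rng.standard_normal((80, 6))
        fit = fit_glm(y, d)
        c = compute_contrast(fit, d, np.array([0.0, 1.0, -1.0, 0.0]))
        perm = [2, 0, 3, 1]
        d2 = DesignMatrix(values=d.values[:, perm],
                          names=[d.names[i] for i in perm], tr=1.0,
                          frame_times=d.frame_times)
        fit2 = fit_glm(y, d2)
        w2 = np.zeros(4)
        w2[perm.index(1)] = 1.0
        w2[perm.index(2)] = -1.0
        c2 = compute_contrast(fit2, d2, w2)
        assert np.allclose(c.effect, c2.effect, atol=1e-10)
        assert np.allclose(c.z, c2.z, atol=1e-8)

    def test_scaling_equivariance(self, rng):
        """BOLD x c scales betas and effects by c; z is unchanged."""
        d = TestFitGlm()._random_design(rng, n=70, p=3)
        y = rng.standard_normal((70, 5))
        fit1 = fit_glm(y, d)
        fit2 = fit_glm(3.7 * y, d)
        assert np.allclose(3.7 * fit1.beta, fit2.beta)
        w = np.array([0.0, 1.0, -0.5])
        c1 = compute_contrast(fit1, d, w)
        c2 = compute_contrast(fit2, d, w)
        assert np.allclose(3.7 * c1.effect, c2.effect)
        assert np.allclose(c1.z, c2.z, atol=1e-8)


def test_grand_mean_scale_targets_10000(rng):
    data = 50.0 + rng.random((30, 8))
    scaled = grand_mean_scale(data)
    assert scaled.mean() == pytest.approx(10000.0)
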