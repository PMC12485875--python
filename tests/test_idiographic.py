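"""Within-person standardization and idiographic mixed models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rewardkit.config import SimulationConfig
from rewardkit.idiographic import (fit_idiographic,
                                   induction_habituation_effects,
                                   within_person_standardize)
from rewardkit.simulate import simulate_index_series


def _subject_series(rng, n_sessions=12, beta=(0.0, 0.0, 0.0),
                    s2_sess=0.25, s2_e=0.5, induction=0.0):
    rows = []
    for s in range(1, n_sessions + 1):
        u = rng.normal(0.0, np.sqrt(s2_sess))
        for run in (1, 2):
            mood, panas, kss = rng.standard_normal(3)
            y = (beta[0] * mood + beta[1] * panas + beta[2] * kss + u
                 + induction * (run == 2)
                 + rng.normal(0.0, np.sqrt(s2_e)))
            rows.append({"subject": 1, "session": s, "run": run,
                         "vs_activation": y, "mood": mood,
                         "panas_pa": panas, "kss": kss})
    return pd.DataFrame(rows)


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        df = pd.DataFrame({"subject": np.repeat([1, 2], 10),
                           "x": rng.normal(5, 3, 20)})
        std = within_person_standardize(df, ["x"])
        for _, g in std.groupby("subject"):
            assert g["x"].mean() == pytest.approx(0.0, abs=1e-12)
            assert g["x"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_variable_zeros_with_warning(self):
        df = pd.DataFrame({"subject": [1, 1, 1], "x": [4.0, 4.0, 4.0]})
        with pytest.warns(UserWarning, match="constant within subject"):
            std = within_person_standardize(df, ["x"])
        assert (std["x"] == 0).all()

    def test_single_observation_raises(self):
        df = pd.DataFrame({"subject": [1], "x": [1.0]})
        with pytest.raises(ValueError, match="single observation"):
            within_person_standardize(df, ["x"])

    def test_scale_invariance_across_subjects(self):
        """Two subjects with different raw scales but identical z-profiles
        standardize to identical values."""
        base = np.array([1.0, 2.0, 4.0, 0.0, 3.0, 2.0])
        df = pd.DataFrame({
            "subject": np.repeat([1, 2], 6),
            "x": np.concatenate([base, 100.0 + 7.0 * base]),
        })
        std = within_person_standardize(df, ["x"])
        a = std.loc[std.subject == 1, "x"].to_numpy()
        b = std.loc[std.subject == 2, "x"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    def test_idempotence(self, rng):
        df = pd.DataFrame({"subject": np.repeat([1, 2, 3], 8),
                           "x": rng.normal(2, 5, 24),
                           "y": rng.normal(-1, 0.5, 24)})
        once = within_person_standardize(df, ["x", "y"])
        twice = within_person_standardize(once, ["x", "y"])
        pd.testing.assert_frame_equal(once, twice)


class TestFitIdiographic:
    def test_null_effects_small_marginal_r2(self):
        r2 = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            fit = fit_idiographic(_subject_series(rng))
            r2.append(fit.marginal_r2)
        assert np.median(r2) < 0.1

    def test_known_effect_recovers_variance_share(self):
        """True standardized effect (0.5, 0, 0) with unit total variance:
        marginal R2 near 0.25 and the active predictor's semi-partial
        carrying the bulk of it.  The semi-partial sits slightly below the
        marginal at 24 observations because the reduced model's two null
        predictors still absorb ~p/n fitted variance."""
        marg, semi = [], []
        for rep in range(50):
            rng = np.random.default_rng(300 + rep)
            fit = fit_idiographic(_subject_series(
                rng, beta=(0.5, 0.0, 0.0), s2_sess=0.25, s2_e=0.5))
            marg.append(fit.marginal_r2)
            semi.append(fit.semi_partial_r2["mood"])
        assert np.median(marg) == pytest.approx(0.25, abs=0.1)
        assert np.median(semi) == pytest.approx(np.median(marg), abs=0.1)
        assert np.median(semi) > 0.1  # clearly above a null predictor's share

    def test_null_predictor_semi_partial_small(self):
        semis = []
        for rep in range(50):
            rng = np.random.default_rng(500 + rep)
            fit = fit_idiographic(_subject_series(rng,
                                                  beta=(0.5, 0.0, 0.0)))
            semis.append(fit.semi_partial_r2["kss"])
        assert np.median(semis) <= 0.05

    def test_removing_predictor_rarely_increases_marginal_r2(self):
        """Dropping a predictor should not raise the explained-variance
        share.  Because the variance components in the denominator are
        re-estimated per model, exact monotonicity can fail by a hair at
        24 observations; violations must be rare and tiny (hence the
        semi-partial floor at zero)."""
        violations = []
        for rep in range(30):
            rng = np.random.default_rng(1300 + rep)
            series = _subject_series(rng, beta=(0.4, 0.2, 0.0))
            full = fit_idiographic(series)
            for keep in (["mood", "panas_pa"], ["mood"],
                         ["panas_pa", "kss"]):
                reduced = fit_idiographic(series, predictors=keep)
                violations.append(reduced.marginal_r2 - full.marginal_r2)
        violations = np.array(violations)
        assert np.median(violations) < 0.0
        assert (violations > 0.02).mean() == 0.0

    def test_collinear_predictors_raise(self, rng):
        series = _subject_series(rng)
        series["panas_pa"] = 2.0 * series["mood"]
        with pytest.raises(ValueError, match="collinear"):
            fit_idiographic(series)

    def test_mid_vs_sr_asymmetry(self):
        """With state effects scaled down for SR, MID fits explain more
        intraindividual variance (median over replicates)."""
        mid_r2, sr_r2 = [], []
        for rep in range(25):
            cfg = SimulationConfig(seed=700 + rep, n_subjects=1,
                                   gamma_mood=0.4, gamma_alert=0.0,
                                   sr_effect_scale=0.0)
            series = simulate_index_series(cfg, tasks=("mid", "sr"))
            std = within_person_standardize(
                series, ["vs_activation", "mood", "panas_pa", "kss"])
            for task, sink in (("mid", mid_r2), ("sr", sr_r2)):
                block = std[std["task"] == task]
                sink.append(fit_idiographic(block).marginal_r2)
        assert np.median(mid_r2) > np.median(sr_r2)


class TestInductionHabituation:
    def test_null_induction_within_two_se(self, rng):
        series = _subject_series(rng, induction=0.0)
        eff = induction_habituation_effects(series).set_index("effect")
        row = eff.loc["induction"]
        assert abs(row["estimate"]) <= 2.0 * row["se"]

    def test_session_decline_sign_recovery(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(900 + rep)
            series = _subject_series(rng, s2_sess=0.02, s2_e=0.05)
            series["vs_activation"] -= 0.05 * series["session"]
            eff = induction_habituation_effects(series).set_index("effect")
            hits += eff.loc["habituation", "estimate"] < 0
        assert hits >= 38  # >= 95% of replicates

    def test_pooled_scope_uses_subject_grouping(self):
        cfg = SimulationConfig(seed=41, n_subjects=3, n_sessions=6)
        series = simulate_index_series(cfg, tasks=("mid",))
        eff = induction_habituation_effects(series, scope="pooled")
        assert set(eff["subject"]) == {"pooled"}
        assert set(eff["effect"]) == {"induction", "habituation"}

    def test_too_few_sessions_raise(self, rng):
        series = _subject_series(rng, n_sessions=3)
        with pytest.raises(ValueError, match="sessions"):
            induction_habituation_effects(series)
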