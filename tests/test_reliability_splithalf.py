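"""Split-half resampling: limits, analytic law, trial-count curve."""

import numpy as np
import pandas as pd
import pytest

from rewardkit.reliability import (split_half, split_half_correlations,
                                   trial_count_curve)


def _grouped_data(rng, n_units, n_trials, s2_unit, s2_trial):
    means = rng.normal(0.0, np.sqrt(s2_unit), n_units)
    return [m + rng.normal(0.0, np.sqrt(s2_trial), n_trials) for m in means]


def test_noiseless_limit_every_split_is_one(rng):
    units = [np.full(10, v) for v in (0.3, 1.2, -0.4, 0.9)]
    rs = split_half_correlations(units, n_splits=50, rng=rng)
    assert np.allclose(rs, 1.0)


def test_null_structure_mean_near_zero(rng):
    units = _grouped_data(rng, 80, 20, s2_unit=0.0, s2_trial=1.0)
    rs = split_half_correlations(units, n_splits=500, rng=rng)
    se = rs.std(ddof=1) / np.sqrt(len(rs))
    # splits are correlated, so bound by the cross-unit sampling error
    assert abs(rs.mean()) < 3.0 / np.sqrt(80 - 1)


def test_analytic_expectation_single_cell(rng):
    """sigma2_T=1, sigma2_e=4, n=40, 60 units: mean r near
    1 / (1 + 2*4/40) = 0.8333."""
    reps = [split_half_correlations(
        _grouped_data(rng, 60, 40, 1.0, 4.0), 1000, rng).mean()
        for _ in range(8)]
    se = np.std(reps, ddof=1) / np.sqrt(len(reps))
    assert np.mean(reps) == pytest.approx(1.0 / 1.2, abs=3 * se)


def test_odd_trial_counts_drop_one_per_split(rng):
    units = [rng.normal(size=9) + m for m in (0.0, 1.0, 2.0, 3.0)]
    rs = split_half_correlations(units, n_splits=100, rng=rng)
    assert np.isfinite(rs).all()


def test_too_few_units_or_trials_raise(rng):
    with pytest.raises(ValueError, match="units"):
        split_half_correlations([np.ones(4), np.ones(4)], 10, rng)
    with pytest.raises(ValueError, match="trials"):
        split_half_correlations([np.ones(4), np.ones(4), np.ones(1)], 10,
                                rng)


def _phase_frame(seed=5, n_sessions=5):
    vals = _grouped_data(np.random.default_rng(seed), 2 * n_sessions, 8,
                         1.0, 1.0)
    return pd.DataFrame({
        "subject": 1,
        "session": np.repeat(np.arange(n_sessions), 16),
        "run": np.tile(np.repeat([1, 2], 8), n_sessions),
        "phase": np.tile(np.repeat(["pre_induction", "post_induction"], 8),
                         n_sessions),
        "value": np.concatenate(vals),
    })


def test_invariance_to_common_affine_transform():
    """A common affine rescaling of the index leaves every split
    correlation, and hence the estimate, numerically unchanged."""
    frame = _phase_frame()
    res1 = split_half(frame, "value", n_splits=200,
                      rng=np.random.default_rng(7))
    affine = frame.copy()
    affine["value"] = 2.5 * affine["value"] - 7.0
    res2 = split_half(affine, "value", n_splits=200,
                      rng=np.random.default_rng(7))
    assert res2.pooled == pytest.approx(res1.pooled, abs=1e-12)
    assert res2.per_subject == pytest.approx(res1.per_subject, abs=1e-12)


def test_invariance_to_unit_relabeling():
    """Relabeling units only reorders which permutation stream hits which
    unit, so the estimate is invariant in distribution: with many splits
    the two estimates agree within resampling error."""
    frame = _phase_frame(n_sessions=10)
    res1 = split_half(frame, "value", n_splits=2000,
                      rng=np.random.default_rng(7))
    relabeled = frame.copy()
    relabeled["session"] = relabeled["session"].map(
        {0: 40, 1: 13, 2: 22, 3: 7, 4: 99, 5: 3, 6: 77, 7: 18, 8: 61,
         9: 54})
    res2 = split_half(relabeled, "value", n_splits=2000,
                      rng=np.random.default_rng(123))
    assert res2.pooled == pytest.approx(res1.pooled, abs=0.05)


def test_phase_estimates_are_reported_and_averaged(rng):
    frame = pd.DataFrame({
        "subject": np.repeat([1, 2], 40),
        "session": np.tile(np.repeat(np.arange(4), 10), 2),
        "run": np.tile(np.repeat([1, 2], 5), 8),
        "phase": np.tile(np.repeat(["pre_induction", "post_induction"], 5),
                         8),
        "value": rng.normal(size=80) + np.repeat(rng.normal(size=16,
                                                            scale=2.0), 5),
    })
    res = split_half(frame, "value", n_splits=100, rng=rng)
    assert set(res.per_phase) == {"pre_induction", "post_induction"}
    assert set(res.per_subject) == {1, 2}
    assert -1.0 <= res.pooled <= 1.0


class TestTrialCountCurve:
    def _trials(self, rng, n_sessions=20, n_per_run=28, s2_sess=1.0,
                s2_trial=1.0, run_shift=0.0):
        rows = []
        for s in range(n_sessions):
            m = rng.normal(0.0, np.sqrt(s2_sess))
            for run in (1, 2):
                vals = m + run_shift * (run == 2) + rng.normal(
                    0.0, np.sqrt(s2_trial), n_per_run)
                for v in vals:
                    rows.append({"subject": 1, "session": s, "run": run,
                                 "value": v})
        return pd.DataFrame(rows)

    def test_zero_trial_noise_gives_unity(self, rng):
        trials = self._trials(rng, s2_trial=0.0, run_shift=0.7)
        curve = trial_count_curve(trials, [8], value_col="value",
                                  n_splits=50, rng=rng)
        assert curve["split_half"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_grid_beyond_available_names_maximum(self, rng):
        trials = self._trials(rng, n_per_run=10)
        with pytest.raises(ValueError, match="20"):
            trial_count_curve(trials, [8, 24], value_col="value",
                              n_splits=10, rng=rng)

    def test_curve_increases_with_trial_count(self, rng):
        trials = self._trials(rng, n_sessions=30, s2_sess=1.0, s2_trial=4.0)
        curve = trial_count_curve(trials, [8, 56], value_col="value",
                                  n_splits=400, rng=rng)
        assert curve["split_half"].iloc[1] > curve["split_half"].iloc[0]
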