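"""Split-half and test-retest reliability of reward responses.

Split-half reliability treats the trials of a run like items of a
self-report scale: each run's trial-level estimates are randomly split
into two equal halves, half means are correlated *across runs*, and the
correlation is averaged over many random splits (1000 by default),
separately for pre- and post-induction runs and then averaged.  With
between-unit variance s2_T of the true unit means and trial noise s2_e
over n trials per unit, the expected split-half correlation is

    s2_T / (s2_T + 2 * s2_e / n)

which the resampler is validated against.

Test-retest reliability is the adjusted intraclass correlation from a
one-random-intercept linear mixed model: the between-subject variance
share of what remains after fixed effects of session (habituation
detrending) and mean framewise displacement are removed,

    ICC = s2_subject / (s2_subject + s2_residual).

The mixed model is estimated by restricted maximum likelihood with the
variance ratio profiled out, reducing the fit to a one-dimensional
optimization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "split_half_correlations",
    "split_half",
    "trial_count_curve",
    "fit_random_intercept",
    "run_level_icc",
    "session_level_icc",
    "reml_neg2loglik",
    "SplitHalfResult",
    "VarianceComponents",
    "IccResult",
]


# ---------------------------------------------------------------------------
# split-half resampling
# ---------------------------------------------------------------------------

def _pairwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise Pearson correlation of two (splits, units) arrays."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac ** 2).sum(axis=1) * (bc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    return r


def split_half_correlations(unit_values: Sequence[np.ndarray],
                            n_splits: int = 1000,
                            rng: Optional[np.random.Generator] = None
                            ) -> np.ndarray:
    """Per-split across-unit correlations of random half means.

    ``unit_values`` holds one array of trial-level values per unit (run).
    Each split randomly partitions every unit's trials into two equal
    halves — when a unit has an odd trial count, one uniformly chosen
    trial is dropped for that split so the halves stay equal — averages
    each half, and correlates half-A means against half-B means across
    units.  Returns the ``n_splits`` correlations.
    """
    if rng is None:
        rng = np.random.default_rng()
    units = [np.asarray(v, dtype=float) for v in unit_values]
    if len(units) < 3:
        raise ValueError(
            f"split-half needs >= 3 units, got {len(units)}")
    for i, v in enumerate(units):
        if v.size < 2:
            raise ValueError(f"unit {i} has {v.size} trials; need >= 2")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")

    sizes = {v.size for v in units}
    if len(sizes) == 1:
        n = sizes.pop()
        m = n // 2
        vals = np.stack(units)                       # (U, n)
        order = rng.random((n_splits, len(units), n)).argsort(axis=2)
        picked = np.take_along_axis(vals[None, :, :], order, axis=2)
        half_a = picked[:, :, :m].mean(axis=2)
        half_b = picked[:, :, m:2 * m].mean(axis=2)
        return _pairwise_r(half_a, half_b)

    half_a = np.empty((n_splits, len(units)))
    half_b = np.empty((n_splits, len(units)))
    for u, v in enumerate(units):
        m = v.size // 2
        for s in range(n_splits):
            perm = rng.permutation(v.size)
            half_a[s, u] = v[perm[:m]].mean()
            half_b[s, u] = v[perm[m:2 * m]].mean()
    return _pairwise_r(half_a, half_b)


def _fisher_mean(rs: Sequence[float]) -> float:
    z = np.arctanh(np.clip(np.asarray(rs, dtype=float), -0.999999, 0.999999))
    return float(np.tanh(z.mean()))


def _spearman_brown(r: float) -> float:
    return 2 * r / (1 + r) if r > -1 else -1.0


@dataclass
class SplitHalfResult:
    """Split-half reliability summary.

    ``per_subject`` maps subject -> mean split correlation (averaged over
    splits and over the pre/post phases); ``pooled`` is the Fisher-z mean
    of the per-subject values.  ``per_phase`` records the phase handling.
    """

    per_subject: Dict[int, float]
    pooled: float
    per_phase: Dict[str, float]
    n_splits: int
    spearman_brown: bool = False
    per_split: Optional[Dict[Tuple[int, str], np.ndarray]] = None


def split_half(trials: pd.DataFrame, value_col: str,
               unit_cols: Sequence[str] = ("session", "run"),
               subject_col: str = "subject", phase_col: str = "phase",
               n_splits: int = 1000,
               rng: Optional[np.random.Generator] = None,
               spearman_brown: bool = False,
               keep_splits: bool = False) -> SplitHalfResult:
    """Split-half reliability of trial-level indices, per subject.

    For each subject and each induction phase, the subject's runs of that
    phase are the units handed to :func:`split_half_correlations`; the two
    phase estimates are averaged per subject (raw half correlations — a
    Spearman-Brown step-up is opt-in) and summarized across subjects by
    the Fisher-z mean.
    """
    if rng is None:
        rng = np.random.default_rng()
    per_subject: Dict[int, float] = {}
    per_split: Dict[Tuple[int, str], np.ndarray] = {}
    phase_pool: Dict[str, List[float]] = {}
    for subject, sub in trials.groupby(subject_col):
        phase_means = []
        for phase, block in sub.groupby(phase_col):
            unit_values = [g[value_col].to_numpy()
                           for _, g in block.groupby(list(unit_cols))]
            rs = split_half_correlations(unit_values, n_splits, rng)
            est = float(np.nanmean(rs))
            if spearman_brown:
                est = _spearman_brown(est)
            phase_means.append(est)
            phase_pool.setdefault(str(phase), []).append(est)
            if keep_splits:
                per_split[(subject, str(phase))] = rs
        per_subject[subject] = float(np.mean(phase_means))
    return SplitHalfResult(
        per_subject=per_subject,
        pooled=_fisher_mean(list(per_subject.values())),
        per_phase={p: float(np.mean(v)) for p, v in phase_pool.items()},
        n_splits=n_splits,
        spearman_brown=spearman_brown,
        per_split=per_split if keep_splits else None,
    )


def trial_count_curve(trials: pd.DataFrame, grid: Sequence[int],
                      value_col: str = "vs_activation",
                      session_cols: Sequence[str] = ("subject", "session"),
                      run_col: str = "run", n_splits: int = 1000,
                      rng: Optional[np.random.Generator] = None
                      ) -> pd.DataFrame:
    """Split-half reliability as a function of the number of trials.

    Trials are concatenated within sessions (both runs), the global run
    effect (the mood-induction shift) is regressed out by OLS on a run
    indicator across all trials, and for each count on the grid that many
    trials are subsampled without replacement per session before running
    the split-half resampler with sessions as units.  Returns a frame
    with ``n_trials`` and ``split_half`` columns.
    """
    if rng is None:
        rng = np.random.default_rng()
    grid = sorted(int(g) for g in grid)
    if len(grid) == 0 or grid[0] < 2:
        raise ValueError("grid must contain counts >= 2")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")

    work = trials.copy()
    vals = work[value_col].to_numpy(dtype=float)
    run_dummies = pd.get_dummies(work[run_col]).to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(run_dummies, vals, rcond=None)
    work[value_col] = vals - run_dummies @ coef + vals.mean()

    sessions: List[np.ndarray] = []
    for _, block in work.groupby(list(session_cols)):
        sessions.append(block[value_col].to_numpy(dtype=float))
    max_avail = min(len(v) for v in sessions)
    if grid[-1] > max_avail:
        raise ValueError(
            f"grid requests {grid[-1]} trials but only {max_avail} are "
            f"available per session")

    rows = []
    for count in grid:
        sub = [v[rng.choice(v.size, size=count, replace=False)]
               for v in sessions]
        rs = split_half_correlations(sub, n_splits, rng)
        rows.append({"n_trials": count, "split_half": float(np.nanmean(rs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# REML variance components / adjusted ICC
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """One-random-intercept mixed-model estimates.

    ``icc = sigma2_group / (sigma2_group + sigma2_resid)``, the adjusted
    intraclass correlation: fixed-effect variance is removed by the model
    and excluded from the denominator.  ``boundary`` flags a variance
    estimate clipped at zero (or a degenerate zero-residual fit).
    """

    sigma2_group: float
    sigma2_resid: float
    fixed_effects: pd.Series
    fixed_se: pd.Series
    icc: float
    converged: bool
    boundary: bool
    neg2_reml: float
    n_obs: int
    n_groups: int


def _group_stats(y: np.ndarray, X: np.ndarray, codes: np.ndarray,
                 n_groups: int):
    """Per-group sufficient statistics for the profiled REML criterion."""
    p = X.shape[1]
    xtx = np.zeros((n_groups, p, p))
    xty = np.zeros((n_groups, p))
    xt1 = np.zeros((n_groups, p))
    yt1 = np.zeros(n_groups)
    yty = np.zeros(n_groups)
    sizes = np.bincount(codes, minlength=n_groups).astype(float)
    for g in range(n_groups):
        sel = codes == g
        Xg, yg = X[sel], y[sel]
        xtx[g] = Xg.T @ Xg
        xty[g] = Xg.T @ yg
        xt1[g] = Xg.sum(axis=0)
        yt1[g] = yg.sum()
        yty[g] = yg @ yg
    return xtx, xty, xt1, yt1, yty, sizes


def _profiled_criterion(lam: float, stats_tuple, n: int, p: int):
    """-2 REML log-likelihood (up to a constant) with sigma2_e profiled out.

    For V = I + lam * J per group, V^-1 = I - c * J with
    c = lam / (1 + n_g * lam), and log|V| = log(1 + n_g * lam).
    """
    xtx, xty, xt1, yt1, yty, sizes = stats_tuple
    c = lam / (1.0 + sizes * lam)
    XtVX = xtx.sum(axis=0) - np.einsum("g,gi,gj->ij", c, xt1, xt1)
    XtVy = xty.sum(axis=0) - (c * yt1) @ xt1
    yVy = yty.sum() - float(c @ (yt1 ** 2))
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = yVy - float(beta @ XtVy)
    dof = n - p
    if rss <= 0:
        return -np.inf, (beta, XtVX, 0.0)
    sigma2_e = rss / dof
    logdet_v = float(np.log1p(sizes * lam).sum())
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf, None
    crit = dof * np.log(sigma2_e) + logdet_v + logdet_x
    return crit, (beta, XtVX, sigma2_e)


def reml_neg2loglik(y, X, groups, lam: float) -> float:
    """-2 profiled REML criterion (constant dropped) at variance ratio lam.

    ``lam = sigma2_group / sigma2_resid``.  Exposed so the optimum
    returned by :func:`fit_random_intercept` can be audited against
    arbitrary probe values.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, n_groups = _encode_groups(groups)
    st = _group_stats(y, X, codes, n_groups)
    crit, _ = _profiled_criterion(lam, st, y.size, X.shape[1])
    return crit


def _encode_groups(groups) -> Tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes.astype(int), len(uniques)


def _prepare_fixed(fixed, n: int) -> Tuple[np.ndarray, List[str]]:
    if fixed is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(fixed, pd.DataFrame):
        names = [str(c) for c in fixed.columns]
        X = fixed.to_numpy(dtype=float)
    else:
        X = np.asarray(fixed, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    return X, names


def fit_random_intercept(y, fixed=None, groups=None) -> VarianceComponents:
    """REML fit of ``y = X b + u_group + e`` with one random intercept.

    ``fixed`` is a covariate table (an intercept is added if absent);
    ``groups`` labels the grouping units.  The REML criterion is profiled
    down to the variance ratio ``lam = sigma2_group / sigma2_resid`` and
    optimized over ``log(lam)`` by Brent's method, with the ``lam = 0``
    boundary checked explicitly; a boundary solution (or a negative
    method-of-moments start) is clipped to zero and flagged, never
    propagated as a negative ICC.  Non-convergence is flagged on the
    result rather than raised.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if groups is None:
        raise ValueError("groups is required")
    codes, n_groups = _encode_groups(groups)
    if n_groups < 2:
        raise ValueError(f"need >= 2 groups, got {n_groups}")
    sizes = np.bincount(codes, minlength=n_groups)
    if sizes.max() < 2:
        raise ValueError("need >= 2 observations in at least one group")
    X, names = _prepare_fixed(fixed, n)
    p = X.shape[1]
    if n - p <= 0:
        raise ValueError("more fixed-effect parameters than observations")
    st = _group_stats(y, X, codes, n_groups)

    # degenerate zero-residual case: group dummies + X fit y exactly
    resid_within = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    for g in range(n_groups):
        sel = codes == g
        resid_within[sel] -= resid_within[sel].mean()
    scale = max(float(y.var()), 1e-300)
    if float(resid_within @ resid_within) < 1e-12 * scale * n:
        means = np.array([y[codes == g].mean() for g in range(n_groups)])
        XtX = st[0].sum(axis=0)
        beta = np.linalg.solve(XtX, st[1].sum(axis=0))
        return VarianceComponents(
            sigma2_group=float(means.var(ddof=1)), sigma2_resid=0.0,
            fixed_effects=pd.Series(beta, index=names),
            fixed_se=pd.Series(np.zeros(p), index=names),
            icc=1.0, converged=True, boundary=True, neg2_reml=-np.inf,
            n_obs=n, n_groups=n_groups)

    def crit_theta(theta: float) -> float:
        c, _ = _profiled_criterion(np.exp(theta), st, n, p)
        return c

    res = optimize.minimize_scalar(crit_theta, bounds=(-30.0, 30.0),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    lam_hat = float(np.exp(res.x))
    crit_hat, aux = _profiled_criterion(lam_hat, st, n, p)
    crit_zero, aux_zero = _profiled_criterion(0.0, st, n, p)
    boundary = False
    if not np.isfinite(crit_hat) or crit_zero <= crit_hat:
        lam_hat, crit_hat, aux = 0.0, crit_zero, aux_zero
        boundary = True
    beta, XtVX, sigma2_e = aux
    sigma2_g = lam_hat * sigma2_e
    cov = sigma2_e * np.linalg.inv(XtVX)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    icc = sigma2_g / (sigma2_g + sigma2_e) if (sigma2_g + sigma2_e) > 0 else 0.0
    converged = bool(getattr(res, "success", True)) and np.isfinite(crit_hat)
    return VarianceComponents(
        sigma2_group=float(sigma2_g), sigma2_resid=float(sigma2_e),
        fixed_effects=pd.Series(beta, index=names),
        fixed_se=pd.Series(se, index=names),
        icc=float(np.clip(icc, 0.0, 1.0)), converged=converged,
        boundary=boundary, neg2_reml=float(crit_hat), n_obs=n,
        n_groups=n_groups)


@dataclass
class IccResult:
    """Adjusted ICC summary across induction phases or the joint model."""

    icc: float
    components: Dict[str, VarianceComponents]


def run_level_icc(series: pd.DataFrame, value_col: str = "vs_activation",
                  subject_col: str = "subject", session_col: str = "session",
                  fd_col: str = "fd",
                  phase_col: str = "phase") -> IccResult:
    """Test-retest reliability from separate pre-/post-induction models.

    For each phase, a mixed model of the run-level index with a subject
    random intercept and fixed effects of session index and mean
    framewise displacement; the two adjusted ICCs are averaged.
    """
    phases = sorted(series[phase_col].unique(), reverse=True)  # pre first
    if len(phases) < 2:
        raise ValueError("both induction phases are required")
    components: Dict[str, VarianceComponents] = {}
    for phase in phases:
        block = series[series[phase_col] == phase]
        if block[subject_col].nunique() < 2:
            raise ValueError(f"phase {phase!r}: need >= 2 subjects")
        fixed = pd.DataFrame({
            "session": block[session_col].to_numpy(dtype=float),
            "fd": block[fd_col].to_numpy(dtype=float),
        })
        try:
            components[str(phase)] = fit_random_intercept(
                block[value_col], fixed, block[subject_col])
        except ValueError as exc:
            raise ValueError(f"phase {phase!r}: {exc}") from exc
    icc = float(np.mean([c.icc for c in components.values()]))
    return IccResult(icc=icc, components=components)


def session_level_icc(series: pd.DataFrame, value_col: str = "vs_activation",
                      subject_col: str = "subject",
                      session_col: str = "session", run_col: str = "run",
                      fd_col: str = "fd",
                      nested_session: bool = False) -> IccResult:
    """Test-retest reliability with both runs in a single model.

    Fixed effects: session index, a post-induction run indicator, and
    mean framewise displacement; a single subject random intercept (a
    session-within-subject intercept is available via
    ``nested_session=True``, which groups on (subject, session) and
    reports the subject-level share of the remaining variance structure
    only through the same single-intercept machinery applied to
    session-mean data — kept deliberately simple).
    """
    if series[run_col].nunique() < 2:
        raise ValueError("both runs are required for the session-level model")
    fixed = pd.DataFrame({
        "session": series[session_col].to_numpy(dtype=float),
        "run2": (series[run_col].to_numpy(dtype=float)
                 == series[run_col].max()).astype(float),
        "fd": series[fd_col].to_numpy(dtype=float),
    })
    if nested_session:
        agg = series.groupby([subject_col, session_col], as_index=False).agg(
            **{value_col: (value_col, "mean"), fd_col: (fd_col, "mean")})
        fixed = pd.DataFrame({
            "session": agg[session_col].to_numpy(dtype=float),
            "fd": agg[fd_col].to_numpy(dtype=float),
        })
        comp = fit_random_intercept(agg[value_col], fixed, agg[subject_col])
    else:
        comp = fit_random_intercept(series[value_col], fixed,
                                    series[subject_col])
    return IccResult(icc=comp.icc, components={"session_level": comp})
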