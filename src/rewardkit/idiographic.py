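"""Intraindividual (N = 1) models of the reward response.

Within-person standardization, mood-induction and habituation effect
estimation, and idiographic mixed models relating run-level reward
indices to momentary mood, session-level positive affect (PANAS-PA) and
alertness (KSS), with variance explained summarized as a marginal R-squared
(fixed-effect variance share) and per-predictor semi-partial R-squared
(drop in marginal R-squared when that predictor is removed, floored at
zero).  All models use a categorical session random intercept; pooled
models use a subject random intercept instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import VarianceComponents, fit_random_intercept

__all__ = [
    "within_person_standardize",
    "fit_idiographic",
    "induction_habituation_effects",
    "IdiographicFit",
]

DEFAULT_PREDICTORS = ("mood", "panas_pa", "kss")


def within_person_standardize(series: pd.DataFrame,
                              variables: Sequence[str],
                              subject_col: str = "subject") -> pd.DataFrame:
    """Per-subject z-scoring: subtract the subject mean, divide by the SD.

    Variables that are constant within a subject map to zeros with a
    warning (their within-person association is undefined).  A subject
    with a single observation raises.
    """
    out = series.copy()
    for subject, idx in series.groupby(subject_col).groups.items():
        if len(idx) < 2:
            raise ValueError(
                f"subject {subject} has a single observation; "
                "within-person standardization needs >= 2")
        for var in variables:
            v = series.loc[idx, var].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                warnings.warn(
                    f"variable {var!r} is constant within subject {subject}; "
                    "standardized values set to 0", stacklevel=2)
                out.loc[idx, var] = 0.0
            else:
                out.loc[idx, var] = (v - v.mean()) / sd
    return out


@dataclass
class IdiographicFit:
    """A single subject's mixed-model fit and variance decomposition.

    ``marginal_r2 = Var(X b) / (Var(X b) + s2_session + s2_resid)``;
    ``semi_partial_r2[p]`` is the marginal R-squared drop when predictor
    ``p`` is removed from the fixed effects, floored at zero (shared
    variance can push the raw difference slightly negative).
    """

    subject: int
    outcome: str
    coefficients: pd.Series
    standard_errors: pd.Series
    sigma2_session_re: float
    sigma2_resid: float
    marginal_r2: float
    semi_partial_r2: Dict[str, float]
    n_obs: int
    #: containment degrees of freedom for Wald-t inference on coefficients
    dof: int
    low_power: bool
    converged: bool


def _marginal_r2(comp: VarianceComponents, X: np.ndarray,
                 names: Sequence[str]) -> float:
    """Nakagawa-style marginal R2 from a fitted random-intercept model."""
    beta = comp.fixed_effects.reindex(names).to_numpy()
    fitted = X @ beta
    var_f = float(np.var(fitted))
    denom = var_f + comp.sigma2_group + comp.sigma2_resid
    return var_f / denom if denom > 0 else 0.0


def fit_idiographic(series: pd.DataFrame, outcome: str = "vs_activation",
                    predictors: Sequence[str] = DEFAULT_PREDICTORS,
                    session_col: str = "session",
                    subject_col: str = "subject") -> IdiographicFit:
    """Idiographic mixed model for one subject.

    ``series`` holds one subject's run-level rows (already within-person
    standardized).  The model has fixed effects for the predictors and a
    categorical session random intercept.  Predictor collinearity
    (condition number above 1e8) raises; fewer than 6 sessions of
    two-run data flags the fit as low power rather than refusing it.
    """
    subjects = series[subject_col].unique()
    if len(subjects) != 1:
        raise ValueError(f"expected one subject, got {len(subjects)}")
    subject = int(subjects[0])
    n = len(series)
    if n < len(predictors) + 3:
        raise ValueError(
            f"subject {subject}: {n} observations cannot support "
            f"{len(predictors)} predictors")
    P = series[list(predictors)].to_numpy(dtype=float)
    if np.linalg.cond(np.column_stack([np.ones(n), P])) > 1e8:
        raise ValueError(
            f"subject {subject}: predictors {list(predictors)} are collinear")
    low_power = series[session_col].nunique() < 6 or n < 12

    fixed = series[list(predictors)].astype(float)
    comp = fit_random_intercept(series[outcome], fixed, series[session_col])
    names = ["intercept"] + list(predictors)
    X = np.column_stack([np.ones(n), P])
    full_r2 = _marginal_r2(comp, X, names)

    semi: Dict[str, float] = {}
    for drop in predictors:
        keep = [p for p in predictors if p != drop]
        sub_fixed = series[keep].astype(float) if keep else None
        sub_comp = fit_random_intercept(series[outcome], sub_fixed,
                                        series[session_col])
        sub_names = ["intercept"] + keep
        sub_X = np.column_stack(
            [np.ones(n)] + [series[p].to_numpy(dtype=float) for p in keep])
        semi[drop] = max(0.0, full_r2 - _marginal_r2(sub_comp, sub_X,
                                                     sub_names))
    return IdiographicFit(
        subject=subject, outcome=outcome,
        coefficients=comp.fixed_effects,
        standard_errors=comp.fixed_se,
        sigma2_session_re=comp.sigma2_group,
        sigma2_resid=comp.sigma2_resid,
        marginal_r2=full_r2,
        semi_partial_r2=semi,
        n_obs=n,
        dof=max(1, n - series[session_col].nunique() - len(predictors)),
        low_power=low_power, converged=comp.converged)


def induction_habituation_effects(series: pd.DataFrame,
                                  scope: str = "per_subject",
                                  outcome: str = "vs_activation",
                                  subject_col: str = "subject",
                                  session_col: str = "session",
                                  run_col: str = "run",
                                  conf_level: float = 0.95) -> pd.DataFrame:
    """Run (mood induction) and session (habituation) effects on an index.

    Per subject: a mixed model of the index on a post-induction run
    indicator and the session index with a session random intercept.
    Pooled: the same fixed effects with a subject random intercept.
    Returns one row per (subject, effect) with the estimate, standard
    error and a Wald-t confidence interval on containment degrees of
    freedom (observations minus groups minus within-group fixed effects).
    """
    if scope not in ("per_subject", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")

    def _one(block: pd.DataFrame, label, group_col: str) -> List[dict]:
        if block[session_col].nunique() < 4:
            raise ValueError(
                f"{label}: need >= 4 sessions for induction/habituation "
                "effects")
        if block[run_col].nunique() < 2:
            raise ValueError(f"{label}: both runs are required")
        fixed = pd.DataFrame({
            "run2": (block[run_col].to_numpy(dtype=float)
                     == block[run_col].max()).astype(float),
            "session": block[session_col].to_numpy(dtype=float),
        })
        comp = fit_random_intercept(block[outcome], fixed, block[group_col])
        dof = max(1, comp.n_obs - comp.n_groups - 2)
        tcrit = stats.t.ppf(0.5 + conf_level / 2.0, dof)
        rows = []
        for effect, coef_name in (("induction", "run2"),
                                  ("habituation", "session")):
            est = float(comp.fixed_effects[coef_name])
            se = float(comp.fixed_se[coef_name])
            rows.append({
                "subject": label, "effect": effect, "estimate": est,
                "se": se, "ci_low": est - tcrit * se,
                "ci_high": est + tcrit * se, "dof": dof,
                "converged": comp.converged,
            })
        return rows

    rows: List[dict] = []
    if scope == "pooled":
        rows.extend(_one(series, "pooled", subject_col))
    else:
        for subject, block in series.groupby(subject_col):
            rows.extend(_one(block, subject, session_col))
    return pd.DataFrame(rows)
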