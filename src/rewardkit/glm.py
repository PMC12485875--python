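"""First-level GLM machinery for the synthetic reward tasks.

Covers the canonical double-gamma hemodynamic response function, a
discrete-cosine high-pass basis (128 s cut-off by default), run-level
design matrices for the MID and SR tasks, ordinary-least-squares fitting
with voxelwise residual variance, linear contrasts with z-transformed
t-statistics, and Least Squares Single (LSS) trial-wise estimation.

Conventions, fixed so that simulation and estimation share one forward
model:

* regressors are built on a microtime grid of ``tr / oversampling``
  (oversampling 10 by default) and sampled at frame midpoints
  ``(i + 0.5) * tr``;
* the HRF has unit peak and support truncated at 32 s;
* no prewhitening — noise handling is ordinary least squares with
  documented residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "double_gamma_hrf",
    "cosine_highpass_basis",
    "convolve_events",
    "build_design",
    "fit_glm",
    "compute_contrast",
    "lss_estimate",
    "grand_mean_scale",
    "DesignMatrix",
    "GlmFit",
    "ContrastMap",
    "TrialEstimates",
    "RankDeficientDesignError",
]

MID_CONDITIONS = [
    "reward_anticipation",
    "neutral_anticipation",
    "reward_outcome",
    "neutral_outcome",
]
SR_PARTNERS = ["stranger", "computer"]
SR_OUTCOMES = ["gain", "loss", "neutral"]


class RankDeficientDesignError(ValueError):
    """Raised when a design matrix is not of full column rank."""


@dataclass
class DesignMatrix:
    values: np.ndarray          # frames x regressors
    names: List[str]
    tr: float
    frame_times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class GlmFit:
    beta: np.ndarray            # regressors x voxels
    sigma2: np.ndarray          # voxels
    dof: int
    names: List[str]
    xtx_inv: np.ndarray         # (X'X)^-1, regressors x regressors


@dataclass
class ContrastMap:
    effect: np.ndarray
    z: np.ndarray
    contrast_name: str = ""


@dataclass
class TrialEstimates:
    """Per-trial LSS beta maps with their trial bookkeeping.

    ``frame`` has one row per modeled trial, in event order; ``betas`` is
    the matching (n_trials, n_voxels) array of trial-specific coefficients.
    """

    frame: pd.DataFrame
    betas: np.ndarray
    target_type: str

    def __len__(self) -> int:
        return len(self.frame)


def double_gamma_hrf(tr: float, oversampling: int = 10,
                     peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0,
                     duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr / oversampling``.

    The response peaks at ``peak_delay`` seconds (gamma density of shape
    ``peak_delay + 1``, unit scale, whose mode is exactly the delay), with
    an undershoot peaking at ``undershoot_delay`` and relative depth
    ``undershoot_ratio``.  The kernel is zero at t = 0 (causality), has
    unit peak, and is truncated at ``duration`` seconds.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    dt = tr / oversampling
    t = np.arange(0.0, duration + dt / 2, dt)
    h = (stats.gamma.pdf(t, peak_delay + 1.0)
         - undershoot_ratio * stats.gamma.pdf(t, undershoot_delay + 1.0))
    return h / h.max()


def cosine_highpass_basis(n_frames: int, tr: float,
                          cutoff: float = 128.0) -> np.ndarray:
    """Unit-norm discrete-cosine drift basis for a high-pass cut-off.

    Returns ``K = floor(2 * n_frames * tr / cutoff)`` DCT-II columns (the
    slowest K non-constant cosines), mutually orthogonal and orthogonal to
    the constant.  Components whose period equals or exceeds twice the run
    length are excluded, so a cut-off of at least twice the run length
    yields an empty basis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    total = n_frames * tr
    k_max = int(np.floor(2.0 * total / cutoff * (1.0 - 1e-12)))
    k_max = max(0, min(k_max, n_frames - 1))
    i = np.arange(n_frames)
    basis = np.empty((n_frames, k_max))
    for k in range(1, k_max + 1):
        col = np.cos(np.pi * k * (i + 0.5) / n_frames)
        basis[:, k - 1] = col / np.linalg.norm(col)
    return basis


def frame_midtimes(n_frames: int, tr: float) -> np.ndarray:
    return (np.arange(n_frames) + 0.5) * tr


def convolve_events(onsets: Sequence[float], durations: Sequence[float],
                    n_frames: int, tr: float,
                    amplitudes: Optional[Sequence[float]] = None,
                    oversampling: int = 10,
                    hrf: Optional[np.ndarray] = None) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at frame midpoints.

    Boxcars are built on the microtime grid, scaled by per-event
    amplitudes (1.0 if omitted), convolved with the unit-peak HRF and
    integrated (Riemann sum x dt), then sampled at ``(i + 0.5) * tr``.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    amplitudes = np.asarray(amplitudes, dtype=float)
    dt = tr / oversampling
    n_micro = n_frames * oversampling
    neural = np.zeros(n_micro)
    micro_t = np.arange(n_micro) * dt
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        lo = np.searchsorted(micro_t, onset, side="left")
        hi = np.searchsorted(micro_t, onset + dur, side="left")
        neural[lo:hi] += amp
    if hrf is None:
        hrf = double_gamma_hrf(tr, oversampling)
    x_micro = np.convolve(neural, hrf)[:n_micro] * dt
    idx = np.arange(n_frames) * oversampling + oversampling // 2
    return x_micro[idx]


def _task_condition_columns(events: pd.DataFrame, task: str):
    """(name, row-selector) pairs for the task regressors, canonical order."""
    task = task.lower()
    cols = []
    if task == "mid":
        known = set(MID_CONDITIONS)
        unknown = set(events["trial_type"]) - known
        if unknown:
            raise ValueError(f"unknown MID condition labels: {sorted(unknown)}")
        for cond in MID_CONDITIONS:
            sel = events["trial_type"] == cond
            if sel.any():
                cols.append((cond, sel))
    elif task == "sr":
        known = {"decision", *SR_OUTCOMES}
        unknown = set(events["trial_type"]) - known
        if unknown:
            raise ValueError(f"unknown SR condition labels: {sorted(unknown)}")
        for partner in SR_PARTNERS:
            sel = (events["trial_type"] == "decision") & (events["partner"] == partner)
            if sel.any():
                cols.append((f"decision_{partner}", sel))
        for partner in SR_PARTNERS:
            for outc in SR_OUTCOMES:
                sel = (events["trial_type"] == outc) & (events["partner"] == partner)
                if sel.any():
                    cols.append((f"outcome_{partner}_{outc}", sel))
    else:
        raise ValueError(f"unknown task {task!r}")
    return cols


def build_design(events: pd.DataFrame, task: str, n_frames: int, tr: float,
                 confounds: Optional[pd.DataFrame] = None,
                 oversampling: int = 10,
                 highpass_cutoff: float = 128.0) -> DesignMatrix:
    """Run-level design: task regressors + cosine drift + confounds + intercept.

    MID yields up to four task columns (reward/neutral x
    anticipation/outcome); SR yields decision-per-partner plus
    outcome-per-partner split by gain/loss/neutral (up to eight).
    Anticipation events are expected to already span cue onset through the
    end of that trial's interstimulus interval.  Confound columns are
    mean-centered so the intercept keeps its baseline interpretation.
    """
    columns: List[np.ndarray] = []
    names: List[str] = []
    hrf = double_gamma_hrf(tr, oversampling)
    if len(events):
        for name, sel in _task_condition_columns(events, task):
            sub = events.loc[sel]
            col = convolve_events(sub["onset"].to_numpy(),
                                  sub["duration"].to_numpy(),
                                  n_frames, tr, oversampling=oversampling,
                                  hrf=hrf)
            columns.append(col)
            names.append(name)
    basis = cosine_highpass_basis(n_frames, tr, highpass_cutoff)
    for k in range(basis.shape[1]):
        columns.append(basis[:, k])
        names.append(f"cosine{k + 1:02d}")
    if confounds is not None and len(confounds.columns):
        if len(confounds) != n_frames:
            raise ValueError("confound table length does not match n_frames")
        for c in confounds.columns:
            col = confounds[c].to_numpy(dtype=float)
            columns.append(col - col.mean())
            names.append(str(c))
    columns.append(np.ones(n_frames))
    names.append("intercept")
    X = np.column_stack(columns)
    return DesignMatrix(values=X, names=names, tr=tr,
                        frame_times=frame_midtimes(n_frames, tr))


def grand_mean_scale(data: np.ndarray, target: float = 10000.0) -> np.ndarray:
    """Rescale a run by a single multiplicative factor to grand mean ``target``."""
    mean = float(np.mean(data))
    if mean == 0:
        raise ValueError("cannot grand-mean scale data with zero mean")
    return data * (target / mean)


def _as_frames_by_voxels(bold) -> np.ndarray:
    """Accept a BoldRun, a 4-D (x,y,z,t) array, or a (frames, voxels) array."""
    data = getattr(bold, "data", bold)
    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        n_frames = data.shape[-1]
        return data.reshape(-1, n_frames).T
    if data.ndim == 2:
        return data
    if data.ndim == 1:
        return data[:, None]
    raise ValueError("BOLD data must be 4-D (x,y,z,t) or 2-D (frames, voxels)")


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR localizes the dependent columns for the error message
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}")


def fit_glm(bold, design: DesignMatrix) -> GlmFit:
    """Voxelwise ordinary least squares.

    ``sigma2 = RSS / dof`` with ``dof = frames - rank(design)``; a
    rank-deficient design raises :class:`RankDeficientDesignError` naming
    the collinear columns.
    """
    Y = _as_frames_by_voxels(bold)
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"BOLD has {Y.shape[0]} frames but design has {X.shape[0]}")
    _check_rank(X, design.names)
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    r_inv = np.linalg.solve(R, np.eye(R.shape[0]))
    xtx_inv = r_inv @ r_inv.T
    return GlmFit(beta=beta, sigma2=sigma2, dof=dof,
                  names=list(design.names), xtx_inv=xtx_inv)


def _weights_vector(weights, names: Sequence[str]) -> np.ndarray:
    if isinstance(weights, dict):
        w = np.zeros(len(names))
        for key, val in weights.items():
            if key not in names:
                raise KeyError(f"no regressor named {key!r}")
            w[list(names).index(key)] = val
        return w
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(names),):
        raise ValueError(
            f"contrast weights have length {w.size}, expected {len(names)}")
    return w


def compute_contrast(fit: GlmFit, design: DesignMatrix, weights,
                     name: str = "") -> ContrastMap:
    """Linear contrast of betas with a z-transformed t statistic.

    ``weights`` may be a full-length vector or a dict of
    ``{regressor name: weight}`` (unnamed regressors get weight zero).
    The t statistic uses the OLS variance ``sigma2 * w'(X'X)^-1 w``; z is
    the standard-normal quantile of the t CDF, computed tail-symmetrically
    so extreme values stay finite.  Voxels with zero contrast variance get
    z = 0.
    """
    w = _weights_vector(weights, fit.names)
    effect = w @ fit.beta
    quad = float(w @ fit.xtx_inv @ w)
    var = fit.sigma2 * quad
    t = np.zeros_like(effect)
    ok = var > 0
    t[ok] = effect[ok] / np.sqrt(var[ok])
    z = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), fit.dof))
    z[~ok] = 0.0
    return ContrastMap(effect=effect, z=z, contrast_name=name)


def lss_estimate(bold, events: pd.DataFrame, task: str, target_type: str,
                 n_frames: int, tr: float,
                 confounds: Optional[pd.DataFrame] = None,
                 oversampling: int = 10,
                 highpass_cutoff: float = 128.0) -> TrialEstimates:
    """Least Squares Single trial-wise beta estimation.

    For each event of ``target_type``, a GLM is fit with (i) a regressor
    for that single event, (ii) one regressor for all *other* events of
    the target type (omitted when the run has a single target event),
    (iii) one regressor per non-target condition, and (iv) the cosine
    drift basis, confounds and intercept.  The trial-specific coefficient
    map is recorded; the model is re-fit for every target trial.
    """
    Y = _as_frames_by_voxels(bold)
    target_sel = events["trial_type"] == target_type
    if not target_sel.any():
        raise ValueError(f"no events of target type {target_type!r}")
    hrf = double_gamma_hrf(tr, oversampling)

    # shared nuisance block: non-target conditions + drift + confounds + 1
    nuis_cols, nuis_names = [], []
    others = events.loc[~target_sel]
    if len(others):
        for cname, sel in _task_condition_columns(others, task):
            sub = others.loc[sel]
            nuis_cols.append(convolve_events(
                sub["onset"].to_numpy(), sub["duration"].to_numpy(),
                n_frames, tr, oversampling=oversampling, hrf=hrf))
            nuis_names.append(cname)
    basis = cosine_highpass_basis(n_frames, tr, highpass_cutoff)
    for k in range(basis.shape[1]):
        nuis_cols.append(basis[:, k])
        nuis_names.append(f"cosine{k + 1:02d}")
    if confounds is not None and len(confounds.columns):
        for c in confounds.columns:
            col = confounds[c].to_numpy(dtype=float)
            nuis_cols.append(col - col.mean())
            nuis_names.append(str(c))
    nuis_cols.append(np.ones(n_frames))
    nuis_names.append("intercept")
    nuisance = np.column_stack(nuis_cols)

    targets = events.loc[target_sel]
    single_cols = [
        convolve_events([row.onset], [row.duration], n_frames, tr,
                        oversampling=oversampling, hrf=hrf)
        for row in targets.itertuples()
    ]
    single_cols = np.column_stack(single_cols)
    total = single_cols.sum(axis=1)

    betas = np.empty((len(targets), Y.shape[1]))
    rows = []
    for j, row in enumerate(targets.itertuples()):
        trial_col = single_cols[:, j]
        blocks = [trial_col[:, None]]
        names = [f"trial_{j:03d}"]
        if len(targets) > 1:
            blocks.append((total - trial_col)[:, None])
            names.append("other_targets")
        blocks.append(nuisance)
        names.extend(nuis_names)
        X = np.hstack(blocks)
        _check_rank(X, names)
        Q, R = np.linalg.qr(X)
        b = np.linalg.solve(R, Q.T @ Y)
        betas[j] = b[0]
        rows.append({
            "trial_index": int(row.trial_index),
            "condition": row.trial_type,
            "onset": float(row.onset),
        })
    frame = pd.DataFrame(rows)
    return TrialEstimates(frame=frame, betas=betas, target_type=target_type)
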