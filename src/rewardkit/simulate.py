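"""Synthetic precision-imaging study generator.

Produces task event schedules, behavioral rating streams, ground-truth
trial amplitudes with a person/session/trial variance decomposition, and
forward-modeled 4-D BOLD runs, all as pure functions of a
:class:`~rewardkit.config.SimulationConfig`.

The emulated study: a few participants scanned over many evening
sessions; each session holds two runs each of a monetary incentive delay
(MID) task and a social card-guessing shared-reward (SR) task, with a
positive mood induction between the first and second runs.  Momentary
mood (0-100) is rated before each of six acquisitions, sleepiness (KSS,
reverse-coded to alertness, 1-9) before and midway through the scan, and
positive affect (PANAS-PA, 10-50) once per session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .config import (SR_OUTCOME_COUNTS, SimulationConfig, n_frames_for_task,
                     run_length_seconds)
from .glm import convolve_events, double_gamma_hrf

__all__ = [
    "ScheduleOverflowError",
    "BoldRun",
    "simulate_mid_events",
    "simulate_sr_events",
    "simulate_ratings",
    "simulate_trial_amplitudes",
    "attach_amplitudes",
    "synthesize_bold",
    "simulate_confounds",
    "simulate_index_series",
    "simulate_dataset",
    "make_roi_mask",
    "make_signature_map",
    "validate_events",
    "rating_observation_for_run",
    "target_condition",
    "SimulatedStudy",
    "RunRecord",
]

# MID timing (seconds)
MID_CUE = 0.75
MID_ISI = (1.5, 3.0)
MID_ITI = (2.0, 7.0)
MID_OUTCOME = 1.0
# SR timing (seconds)
SR_DECISION_MAX = 2.5
SR_DECISION_MIN = 0.8
SR_ISI = (0.85, 2.55)
SR_ITI = (1.0, 4.0)
SR_OUTCOME = 1.0
SR_BLOCK = 9  # trials per partner block

#: which mood observation (1-6) immediately precedes each task run
RUN_RATING_OBSERVATION = {("mid", 1): 1, ("sr", 1): 2,
                          ("mid", 2): 4, ("sr", 2): 5}

_TASK_STREAM_ID = {"mid": 0, "sr": 1}

EVENT_COLUMNS = ["onset", "duration", "trial_type", "partner",
                 "trial_index", "success", "amplitude_true"]


class ScheduleOverflowError(RuntimeError):
    """A trial schedule cannot fit inside the fixed run length."""


@dataclass
class BoldRun:
    """A synthetic 4-D BOLD run on the simulation lattice."""

    data: np.ndarray   # (x, y, z, frame)
    tr: float
    task: str

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


def target_condition(task: str) -> str:
    """The reward condition whose trial amplitudes carry the state model."""
    return {"mid": "reward_anticipation", "sr": "gain"}[task]


def _round_jitter(x: np.ndarray) -> np.ndarray:
    """Jitters are uniform over the printed ranges, rounded to 10 ms."""
    return np.round(np.asarray(x, dtype=float), 2)


def draw_jitters(rng: np.random.Generator, low: float, high: float,
                 n: int) -> np.ndarray:
    """Uniform jitter draws on [low, high], rounded to 10 ms."""
    return _round_jitter(rng.uniform(low, high, size=n))


def _normalize_run_id(run_id) -> Tuple[int, int, int]:
    if isinstance(run_id, (tuple, list)):
        subject, session, run = (int(v) for v in run_id)
        return subject, session, run
    return 0, 0, int(run_id)


def _check_min_schedule(n_trials: int, fixed_per_trial: float,
                        min_isi: float, min_iti: float,
                        limit: float) -> None:
    t = 0.0
    for i in range(n_trials):
        end = t + fixed_per_trial + min_isi
        if end > limit:
            raise ScheduleOverflowError(
                f"trial {i} cannot fit: even with minimal jitter the schedule "
                f"reaches {end:.2f} s against a run limit of {limit:.2f} s")
        t = end + min_iti


def simulate_mid_events(config: SimulationConfig,
                        run_id=(0, 0, 1)) -> pd.DataFrame:
    """Event schedule for one MID run.

    56 trials (half reward, half neutral, randomized order): a 0.75 s cue,
    an interstimulus interval jittered on U(1.5, 3.0) s, a 1 s outcome
    screen, and intertrial intervals jittered on U(2.0, 7.0) s.  The
    response-target staircase of the live task is replaced by
    Bernoulli(success_rate) success draws.  The anticipation event spans
    cue onset through the end of that trial's ISI; jitter sets are redrawn
    until the final outcome ends at least half a frame before the end of
    the run, so every schedule is legal by construction.
    """
    subject, session, run = _normalize_run_id(run_id)
    rng = config.rng("mid_events", subject, session, run)
    n = config.n_trials_mid
    if n == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    run_len = run_length_seconds("mid", config.tr)
    margin = config.tr / 2.0
    _check_min_schedule(n, MID_CUE + MID_OUTCOME, MID_ISI[0], MID_ITI[0],
                        run_len - margin)

    n_reward = n - n // 2
    conditions = np.array(["reward"] * n_reward + ["neutral"] * (n - n_reward))
    rng.shuffle(conditions)
    success = rng.random(n) < config.success_rate

    for _ in range(10000):
        isi = draw_jitters(rng, *MID_ISI, n)
        iti = draw_jitters(rng, *MID_ITI, n - 1) if n > 1 else np.empty(0)
        trial_len = MID_CUE + isi + MID_OUTCOME
        starts = np.concatenate([[0.0], np.cumsum(trial_len[:-1] + iti)])
        last_end = starts[-1] + trial_len[-1]
        if last_end <= run_len - margin:
            break
    else:  # pragma: no cover - astronomically unlikely with printed ranges
        raise ScheduleOverflowError(
            f"trial {n - 1} never fit within {run_len:.2f} s in 10000 draws")

    rows = []
    for i in range(n):
        cond = conditions[i]
        rows.append({
            "onset": starts[i],
            "duration": MID_CUE + isi[i],
            "trial_type": f"{cond}_anticipation",
            "partner": "none",
            "trial_index": i,
            "success": bool(success[i]),
            "amplitude_true": np.nan,
        })
        rows.append({
            "onset": starts[i] + MID_CUE + isi[i],
            "duration": MID_OUTCOME,
            "trial_type": f"{cond}_outcome",
            "partner": "none",
            "trial_index": i,
            "success": bool(success[i]),
            "amplitude_true": np.nan,
        })
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events.sort_values("onset", kind="stable", ignore_index=True)


def _sr_outcome_labels(n: int, rng: np.random.Generator) -> np.ndarray:
    if n == SR_OUTCOME_COUNTS["gain"] + SR_OUTCOME_COUNTS["loss"] + \
            SR_OUTCOME_COUNTS["neutral"]:
        counts = dict(SR_OUTCOME_COUNTS)
    else:  # overridden trial count: keep the printed proportions
        total = sum(SR_OUTCOME_COUNTS.values())
        counts = {k: int(round(n * v / total))
                  for k, v in SR_OUTCOME_COUNTS.items()}
        counts["neutral"] += n - sum(counts.values())
    labels = np.array([lab for lab, c in counts.items() for _ in range(c)])
    rng.shuffle(labels)
    return labels


def simulate_sr_events(config: SimulationConfig,
                       run_id=(0, 0, 1)) -> pd.DataFrame:
    """Event schedule for one SR (card-guessing) run.

    54 trials with outcome labels permuted so the totals are exactly
    22 gain / 22 loss / 10 neutral; the partner alternates between
    stranger and computer in blocks of 9 trials (random starting
    partner).  Decision durations are drawn on U(0.8, 2.5) s (2.5 s
    response deadline); ISIs on U(0.85, 2.55) s, outcomes last 1 s and
    ITIs are drawn on U(1.0, 4.0) s.
    """
    subject, session, run = _normalize_run_id(run_id)
    rng = config.rng("sr_events", subject, session, run)
    n = config.n_trials_sr
    if n == 0:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    run_len = run_length_seconds("sr", config.tr)
    margin = config.tr / 2.0
    _check_min_schedule(n, SR_DECISION_MIN + SR_OUTCOME, SR_ISI[0], SR_ITI[0],
                        run_len - margin)

    outcome = _sr_outcome_labels(n, rng)
    first = rng.integers(2)
    partner = np.array([
        ["stranger", "computer"][(first + i // SR_BLOCK) % 2] for i in range(n)
    ])

    for _ in range(10000):
        decision = draw_jitters(rng, SR_DECISION_MIN, SR_DECISION_MAX, n)
        isi = draw_jitters(rng, *SR_ISI, n)
        iti = draw_jitters(rng, *SR_ITI, n - 1) if n > 1 else np.empty(0)
        trial_len = decision + isi + SR_OUTCOME
        starts = np.concatenate([[0.0], np.cumsum(trial_len[:-1] + iti)])
        last_end = starts[-1] + trial_len[-1]
        if last_end <= run_len - margin:
            break
    else:  # pragma: no cover
        raise ScheduleOverflowError(
            f"trial {n - 1} never fit within {run_len:.2f} s in 10000 draws")

    rows = []
    for i in range(n):
        rows.append({
            "onset": starts[i],
            "duration": decision[i],
            "trial_type": "decision",
            "partner": partner[i],
            "trial_index": i,
            "success": bool(outcome[i] == "gain"),
            "amplitude_true": np.nan,
        })
        rows.append({
            "onset": starts[i] + decision[i] + isi[i],
            "duration": SR_OUTCOME,
            "trial_type": outcome[i],
            "partner": partner[i],
            "trial_index": i,
            "success": bool(outcome[i] == "gain"),
            "amplitude_true": np.nan,
        })
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return events.sort_values("onset", kind="stable", ignore_index=True)


def validate_events(events: pd.DataFrame, task: str,
                    tr: Optional[float] = None) -> None:
    """Assert the schedule invariants of a generated event table."""
    tr = tr if tr is not None else 1.615
    if len(events) == 0:
        return
    onsets = events["onset"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise AssertionError("event onsets are not strictly increasing")
    if not np.all(events["duration"].to_numpy() > 0):
        raise AssertionError("non-positive event duration")
    limit = run_length_seconds(task, tr)
    ends = onsets + events["duration"].to_numpy()
    if ends.max() > limit:
        raise AssertionError(
            f"event ends at {ends.max():.3f} s, past run length {limit:.3f} s")
    n_trials = events["trial_index"].nunique()
    if task == "mid" and n_trials not in (0, 56):
        raise AssertionError(f"MID run has {n_trials} trials, expected 56")
    if task == "sr" and n_trials not in (0, 54):
        raise AssertionError(f"SR run has {n_trials} trials, expected 54")
    if task == "sr" and n_trials == 54:
        counts = events.loc[events["trial_type"].isin(
            ["gain", "loss", "neutral"]), "trial_type"].value_counts()
        if dict(counts) != SR_OUTCOME_COUNTS:
            raise AssertionError(f"SR outcome counts {dict(counts)}")


def _truncnorm(rng: np.random.Generator, sd: float, size=None):
    """Zero-mean truncated-Gaussian noise (+/- 3 SD support)."""
    if sd == 0:
        return 0.0 if size is None else np.zeros(size)
    return stats.truncnorm.rvs(-3.0, 3.0, scale=sd, size=size,
                               random_state=rng)


def simulate_ratings(config: SimulationConfig) -> pd.DataFrame:
    """Behavioral rating streams for every subject and session.

    One row per (subject, session, observation 1-6).  Mood starts at a
    per-subject baseline, drifts by ``mood_decline`` between observations,
    and jumps by ``mood_bump`` at the induction boundary (observation 3 to
    4); observations 1-3 are pre-induction.  KSS (alertness) is observed
    pre-scan and mid-scan and drops by ``|kss_decline|``; the pre-scan
    value is carried on observations 1-3 and the mid-scan value on 4-6.
    PANAS-PA follows a per-subject AR(1) across sessions, constant within
    a session.  All values are clipped to their scale bounds.
    """
    rows = []
    for subject in range(1, config.n_subjects + 1):
        rng = config.rng("ratings", subject)
        base = config.mood_baseline + (
            rng.normal(0.0, config.mood_subject_sd)
            if config.mood_subject_sd > 0 else 0.0)
        panas_state = 0.0
        for session in range(1, config.n_sessions + 1):
            panas_state = (config.panas_ar1 * panas_state
                           + _truncnorm(rng, config.panas_noise_sd, None))
            panas = float(np.clip(config.panas_mean + panas_state, 10, 50))
            kss_pre = float(np.clip(
                config.kss_baseline + _truncnorm(rng, config.kss_noise_sd, None),
                1, 9))
            kss_mid = float(np.clip(
                kss_pre + config.kss_decline
                + _truncnorm(rng, config.kss_noise_sd, None), 1, 9))
            traj = np.empty(6)
            traj[0] = base
            for k in range(1, 6):
                step = config.mood_bump if k == 3 else config.mood_decline
                traj[k] = traj[k - 1] + step
            mood = np.clip(traj + _truncnorm(rng, config.mood_noise_sd, 6),
                           0, 100)
            for obs in range(1, 7):
                rows.append({
                    "subject": subject,
                    "session": session,
                    "observation_index": obs,
                    "phase": "pre_induction" if obs <= 3 else "post_induction",
                    "mood": float(mood[obs - 1]),
                    "kss": kss_pre if obs <= 3 else kss_mid,
                    "panas_pa": panas,
                })
    return pd.DataFrame(rows)


def rating_observation_for_run(ratings: pd.DataFrame, subject: int,
                               session: int, task: str, run: int) -> pd.Series:
    """The rating row immediately preceding a given task run."""
    obs = RUN_RATING_OBSERVATION[(task, run)]
    sel = ratings[(ratings["subject"] == subject)
                  & (ratings["session"] == session)
                  & (ratings["observation_index"] == obs)]
    if len(sel) != 1:
        raise KeyError(
            f"no rating for subject={subject} session={session} "
            f"task={task} run={run} (observation {obs})")
    return sel.iloc[0]


def _zscore_or_zero(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate_trial_amplitudes(config: SimulationConfig, ratings: pd.DataFrame,
                              task: str = "mid") -> pd.DataFrame:
    """Ground-truth amplitudes for the reward-condition trials of one task.

    amplitude = mu_i + u_session + gamma_mood * z(mood) + gamma_alert * z(kss)
                + delta_induction * 1[post-induction] + eps_trial

    with the covariates within-person standardized over the subject's
    runs, u ~ N(0, sigma2_session) shared by both runs of a session, and
    eps ~ N(0, sigma2_trial).  The gamma/delta effects are multiplied by
    ``sr_effect_scale`` for the SR task.  Returns one row per
    (subject, session, run, trial) with all components retained.
    """
    task = task.lower()
    n_target = {"mid": config.n_trials_mid - config.n_trials_mid // 2,
                "sr": int(round(config.n_trials_sr * 22 / 54))}[task]
    scale = 1.0 if task == "mid" else config.sr_effect_scale
    task_id = _TASK_STREAM_ID[task]

    rows = []
    for subject in range(1, config.n_subjects + 1):
        rng_subj = config.rng("subjects", subject)
        mu_i = config.mu_subject + rng_subj.normal() * np.sqrt(
            config.sigma2_subject)
        # within-person standardized covariates over this subject's runs
        keys, mood_v, kss_v = [], [], []
        for session in range(1, config.n_sessions + 1):
            for run in range(1, config.n_runs + 1):
                r = rating_observation_for_run(ratings, subject, session,
                                               task, run)
                keys.append((session, run))
                mood_v.append(r["mood"])
                kss_v.append(r["kss"])
        zmood = dict(zip(keys, _zscore_or_zero(np.array(mood_v))))
        zkss = dict(zip(keys, _zscore_or_zero(np.array(kss_v))))

        for session in range(1, config.n_sessions + 1):
            rng = config.rng("amplitudes", subject, session, task_id)
            u = rng.normal() * np.sqrt(config.sigma2_session)
            for run in range(1, config.n_runs + 1):
                state = scale * (config.gamma_mood * zmood[(session, run)]
                                 + config.gamma_alert * zkss[(session, run)])
                induction = scale * config.delta_induction * (run >= 2)
                eps = rng.normal(size=n_target) * np.sqrt(config.sigma2_trial)
                for trial in range(n_target):
                    rows.append({
                        "subject": subject,
                        "session": session,
                        "run": run,
                        "task": task,
                        "trial": trial,
                        "phase": ("pre_induction" if run == 1
                                  else "post_induction"),
                        "amplitude": mu_i + u + state + induction + eps[trial],
                        "subject_mean": mu_i,
                        "session_effect": u,
                        "state_effect": state,
                        "induction_effect": induction,
                        "trial_noise": eps[trial],
                    })
    return pd.DataFrame(rows)


def attach_amplitudes(events: pd.DataFrame, amplitudes: Sequence[float],
                      task: str, nontarget_amplitude: float) -> pd.DataFrame:
    """Write ground-truth amplitudes onto an event table.

    The reward-condition events receive ``amplitudes`` in trial order; all
    other events get the fixed ``nontarget_amplitude``.
    """
    target = target_condition(task)
    out = events.copy()
    out["amplitude_true"] = float(nontarget_amplitude)
    sel = out.index[out["trial_type"] == target]
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(sel) != len(amplitudes):
        raise ValueError(
            f"{len(amplitudes)} amplitudes for {len(sel)} {target} events")
    out.loc[sel, "amplitude_true"] = amplitudes
    return out


def make_roi_mask(grid_shape: Tuple[int, int, int],
                  half_width: int = 1) -> np.ndarray:
    """Binary striatal stand-in: a cubic blob centered in the lattice."""
    mask = np.zeros(grid_shape, dtype=bool)
    c = [d // 2 for d in grid_shape]
    sl = tuple(slice(ci - half_width, ci + half_width + 1) for ci in c)
    mask[sl] = True
    return mask


def make_signature_map(grid_shape: Tuple[int, int, int],
                       rng: np.random.Generator) -> np.ndarray:
    """Synthetic stand-in for a published multivariate reward signature.

    A smoothed Gaussian random field plus a dominant positive Gaussian
    bump over the center of the lattice: like published reward
    signatures, most of the weight mass concentrates in the reward
    region, so whole-grid pattern correlations are informative rather
    than diluted by off-target weights, and the signature is reliably
    positive inside the region-of-interest blob.
    """
    field = ndimage.gaussian_filter(rng.standard_normal(grid_shape), 1.2)
    field = 0.5 * (field - field.mean()) / field.std()
    grids = np.meshgrid(*(np.arange(d) for d in grid_shape), indexing="ij")
    c = [d // 2 for d in grid_shape]
    d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return field + 4.0 * np.exp(-d2 / (2 * 2.0 ** 2))


def _spatial_profile(roi: np.ndarray, signature: np.ndarray) -> np.ndarray:
    """Signal weights: proportional to the signature inside the ROI, mean 1."""
    if roi.shape != signature.shape:
        raise ValueError(
            f"ROI grid {roi.shape} != signature grid {signature.shape}")
    w = signature[roi]
    m = w.mean()
    if m <= 0:
        raise ValueError("signature has non-positive mean inside the ROI")
    profile = np.zeros(roi.shape)
    profile[roi] = w / m
    return profile


def simulate_confounds(config: SimulationConfig, subject: int, session: int,
                       task: str, run: int, n_frames: int) -> pd.DataFrame:
    """Per-frame confound table: framewise displacement + a drift regressor."""
    rng_subj = config.rng("confounds", subject)
    lo, hi = config.fd_subject_range
    base = rng_subj.uniform(lo, hi)
    rng = config.rng("confounds", subject, session,
                     _TASK_STREAM_ID[task] * 10 + run)
    fd = np.abs(base + rng.normal(0.0, config.fd_frame_sd, n_frames))
    trend = np.linspace(-0.5, 0.5, n_frames)
    return pd.DataFrame({"framewise_displacement": fd, "trend": trend})


def synthesize_bold(events: pd.DataFrame, config: SimulationConfig,
                    roi: np.ndarray, signature: np.ndarray, task: str,
                    run_id=(0, 0, 1)) -> BoldRun:
    """Forward-model a 4-D BOLD run from an amplitude-annotated event table.

    Voxel time series:

        baseline + gain * profile(v) * sum_e amp_e * (HRF * boxcar_e)(t)
                 + drift(v, t) + AR(1) noise

    where ``gain = baseline * percent_signal_per_unit / 100`` (so a 1 a.u.
    amplitude peaks near ``percent_signal_per_unit`` percent signal
    change), ``profile`` places signal inside the ROI blob with weights
    proportional to the signature there, drift is a shared low-frequency
    shape with per-voxel random loadings, and the AR(1) noise is scaled so
    the no-signal temporal SNR equals ``config.tsnr``.  ``tsnr = inf`` and
    ``drift_percent_sd = 0`` give a noiseless run.
    """
    if roi.shape != tuple(config.grid_shape):
        raise ValueError(
            f"ROI grid {roi.shape} != configured grid {config.grid_shape}")
    profile = _spatial_profile(roi, signature)
    subject, session, run = _normalize_run_id(run_id)
    n_frames = n_frames_for_task(task)
    tr = config.tr
    rng = config.rng("bold", subject, session,
                     _TASK_STREAM_ID[task] * 10 + run)

    if len(events):
        amps = events["amplitude_true"].to_numpy(dtype=float)
        if np.isnan(amps).any():
            raise ValueError("events must carry amplitude_true; "
                             "see attach_amplitudes")
        s = convolve_events(events["onset"].to_numpy(),
                            events["duration"].to_numpy(),
                            n_frames, tr, amplitudes=amps)
    else:
        s = np.zeros(n_frames)

    n_vox = int(np.prod(config.grid_shape))
    gain = config.baseline * config.percent_signal_per_unit / 100.0
    data = np.empty((n_frames, n_vox))
    data[:] = config.baseline
    data += gain * np.outer(s, profile.ravel())

    if config.drift_percent_sd > 0:
        t = np.arange(n_frames) * tr
        shape = (np.cos(2 * np.pi * t / 220.0 + rng.uniform(0, 2 * np.pi))
                 + 0.5 * np.cos(2 * np.pi * t / 350.0
                                + rng.uniform(0, 2 * np.pi)))
        loadings = rng.standard_normal(n_vox) * (
            config.drift_percent_sd / 100.0 * config.baseline)
        data += np.outer(shape, loadings)

    if np.isfinite(config.tsnr):
        sd = config.baseline / config.tsnr
        rho = config.noise_ar1
        white = rng.standard_normal((n_frames, n_vox))
        if rho != 0.0:
            noise = signal.lfilter([1.0], [1.0, -rho], white, axis=0)
            noise *= sd * np.sqrt(1.0 - rho ** 2)
        else:
            noise = white * sd
        data += noise

    vol = data.T.reshape(*config.grid_shape, n_frames)
    return BoldRun(data=vol, tr=tr, task=task)


@dataclass
class RunRecord:
    """One task run of the simulated study, with its ground truth."""

    subject: int
    session: int
    task: str
    run: int
    phase: str
    events: pd.DataFrame
    confounds: pd.DataFrame
    amplitudes: np.ndarray  # target-condition trial amplitudes, trial order


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    roi: np.ndarray
    signature: np.ndarray
    ratings: pd.DataFrame
    amplitudes: pd.DataFrame   # all tasks, long format with components
    runs: List[RunRecord]

    def bold(self, record: RunRecord) -> BoldRun:
        """Synthesize (deterministically) the BOLD volume for one run."""
        return synthesize_bold(
            record.events, self.config, self.roi, self.signature,
            record.task, (record.subject, record.session, record.run))


def simulate_dataset(config: SimulationConfig,
                     tasks: Sequence[str] = ("mid", "sr")) -> SimulatedStudy:
    """Generate the full study (events, ratings, amplitudes, confounds).

    BOLD volumes are not materialized here — use :meth:`SimulatedStudy.bold`
    per run to keep memory flat.
    """
    ratings = simulate_ratings(config)
    roi = make_roi_mask(config.grid_shape)
    signature = make_signature_map(config.grid_shape, config.rng("signature"))
    amp_frames = []
    runs: List[RunRecord] = []
    simulators = {"mid": simulate_mid_events, "sr": simulate_sr_events}
    for task in tasks:
        amps = simulate_trial_amplitudes(config, ratings, task)
        amp_frames.append(amps)
        for subject in range(1, config.n_subjects + 1):
            for session in range(1, config.n_sessions + 1):
                for run in range(1, config.n_runs + 1):
                    events = simulators[task](config, (subject, session, run))
                    a = amps[(amps["subject"] == subject)
                             & (amps["session"] == session)
                             & (amps["run"] == run)].sort_values("trial")
                    events = attach_amplitudes(
                        events, a["amplitude"].to_numpy(), task,
                        config.nontarget_amplitude)
                    conf = simulate_confounds(config, subject, session, task,
                                              run, n_frames_for_task(task))
                    runs.append(RunRecord(
                        subject=subject, session=session, task=task, run=run,
                        phase=("pre_induction" if run == 1
                               else "post_induction"),
                        events=events, confounds=conf,
                        amplitudes=a["amplitude"].to_numpy()))
    return SimulatedStudy(config=config, roi=roi, signature=signature,
                          ratings=ratings,
                          amplitudes=pd.concat(amp_frames, ignore_index=True),
                          runs=runs)


def simulate_index_series(config: SimulationConfig,
                          tasks: Sequence[str] = ("mid",),
                          brs_noise_sd: float = 0.3) -> pd.DataFrame:
    """Run-level index series generated directly from the amplitude model.

    A fast stand-in for the full BOLD+GLM path: the univariate index of a
    run is the mean of its reward-condition trial amplitudes (so it
    inherits the person/session/trial variance structure plus mean trial
    noise), and the multivariate index is a noisy monotone transform of it
    bounded in [-1, 1].  Used for reliability and idiographic analyses
    where forward-modeling volumes adds nothing.
    """
    ratings = simulate_ratings(config)
    rng = config.rng("analysis")
    frames = []
    for task in tasks:
        amps = simulate_trial_amplitudes(config, ratings, task)
        g = amps.groupby(["subject", "session", "run", "task", "phase"],
                         as_index=False)["amplitude"].mean()
        g = g.rename(columns={"amplitude": "vs_activation"})
        v = g["vs_activation"].to_numpy()
        zv = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        g["brs_correlation"] = np.tanh(
            0.55 * zv + brs_noise_sd * rng.standard_normal(len(g)))
        frames.append(g)
    series = pd.concat(frames, ignore_index=True)

    covs = []
    for row in series.itertuples():
        r = rating_observation_for_run(ratings, row.subject, row.session,
                                       row.task, row.run)
        covs.append((r["mood"], r["panas_pa"], r["kss"]))
    series[["mood", "panas_pa", "kss"]] = pd.DataFrame(covs,
                                                       index=series.index)
    fd = []
    for row in series.itertuples():
        rng_subj = config.rng("confounds", row.subject)
        lo, hi = config.fd_subject_range
        base = rng_subj.uniform(lo, hi)
        fd.append(abs(base + 0.01 * rng.standard_normal()))
    series["fd"] = fd
    return series
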