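"""Study configuration and reproducible random-stream management.

A :class:`SimulationConfig` fully determines a synthetic precision-imaging
study: a handful of participants scanned over many sessions, two reward
tasks (a monetary incentive delay task, "MID", and a social card-guessing
"shared reward" task, "SR") with two runs each per session, a mid-session
positive mood induction, and behavioral rating streams (momentary mood,
Karolinska sleepiness, positive affect).

All randomness flows through named substreams derived from the single root
seed, so that regenerating any one run, rating stream, or noise volume is
stable regardless of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

# Scan timing printed parameters
TR_SECONDS = 1.615
MID_N_FRAMES = 283
SR_N_FRAMES = 265
MID_N_TRIALS = 56
SR_N_TRIALS = 54
SR_OUTCOME_COUNTS = {"gain": 22, "loss": 22, "neutral": 10}

# Named substreams; the integers below are stable tags mixed with the root
# seed and (subject, session, run) indices to spawn independent generators.
_STREAMS = {
    "subjects": 1,
    "mid_events": 2,
    "sr_events": 3,
    "ratings": 4,
    "amplitudes": 5,
    "bold": 6,
    "signature": 7,
    "confounds": 8,
    "analysis": 9,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Amplitude model (arbitrary units, a.u.): the reward-condition response
    on trial t of run r in session s for subject i is

        a = mu_i + u_{is} + gamma_mood * z(mood_{isr}) + gamma_alert * z(kss_{isr})
            + delta_induction * 1[post-induction run] + eps_t

    with mu_i ~ N(mu_subject, sigma2_subject), u ~ N(0, sigma2_session)
    and eps ~ N(0, sigma2_trial).  The default variance components are
    calibrated so that run split-half reliability sits near 0.6 and the
    between-person ICC of run-level indices sits near 0.1 — the regime the
    analysis pipeline is designed to characterize.
    """

    seed: int = 0
    n_subjects: int = 4
    n_sessions: int = 12
    n_runs: int = 2  # per task per session; run 1 pre-, run 2 post-induction

    # --- trial amplitude model (a.u.) ---
    mu_subject: float = 1.0
    sigma2_subject: float = 0.008
    sigma2_session: float = 0.05
    sigma2_trial: float = 1.0
    gamma_mood: float = 0.10
    gamma_alert: float = 0.05
    delta_induction: float = 0.10
    #: multiplies gamma_mood / gamma_alert / delta_induction for the SR task;
    #: state effects concentrate in MID anticipation.
    sr_effect_scale: float = 0.5
    #: fixed mean response of non-target conditions (neutral anticipation,
    #: outcomes, decision phase), a.u.
    nontarget_amplitude: float = 0.3

    # --- behavioral ratings ---
    mood_baseline: float = 60.0
    mood_subject_sd: float = 8.0
    mood_bump: float = 10.0        # induction jump, 0-100 scale
    mood_decline: float = -2.0     # drift between non-induction observations
    mood_noise_sd: float = 4.0
    kss_baseline: float = 6.0      # reverse-coded: higher = more alert
    kss_decline: float = -0.8      # pre-scan -> mid-scan alertness change
    kss_noise_sd: float = 0.5
    panas_mean: float = 35.0
    panas_ar1: float = 0.5
    panas_noise_sd: float = 3.0

    # --- task schedules (overridable for degenerate fixtures) ---
    n_trials_mid: int = MID_N_TRIALS
    n_trials_sr: int = SR_N_TRIALS
    success_rate: float = 0.66

    # --- BOLD forward model ---
    tr: float = TR_SECONDS
    grid_shape: Tuple[int, int, int] = (12, 12, 12)
    baseline: float = 1000.0
    #: peak percent-signal-change per 1 a.u. of amplitude
    percent_signal_per_unit: float = 1.0
    tsnr: float = 50.0
    noise_ar1: float = 0.3
    drift_percent_sd: float = 0.3  # low-frequency drift loading, % of baseline

    # --- head-motion covariate ---
    fd_subject_range: Tuple[float, float] = (0.05, 0.25)
    fd_frame_sd: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("sigma2_subject", "sigma2_session", "sigma2_trial"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tsnr <= 0:
            raise ValueError("tsnr must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if len(self.grid_shape) != 3 or any(d < 4 for d in self.grid_shape):
            raise ValueError("grid_shape must be 3-D with all dimensions >= 4")
        if not 0.0 <= self.success_rate <= 1.0:
            raise ValueError("success_rate must be in [0, 1]")
        if not -1.0 < self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must be in (-1, 1)")
        if self.n_subjects < 1 or self.n_sessions < 1 or self.n_runs < 1:
            raise ValueError("n_subjects, n_sessions and n_runs must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def rng(self, stream: str, subject: int = 0, session: int = 0,
            run: int = 0) -> np.random.Generator:
        """Generator for a named substream of the root seed.

        The seed sequence is built from the tuple
        ``(root seed, stream tag, subject, session, run)`` so each
        (stream, subject, session, run) cell is an independent, stable
        stream: regenerating subject 2's session 5 never touches any other
        cell's draws.
        """
        if stream not in _STREAMS:
            raise KeyError(f"unknown random stream {stream!r}")
        ss = np.random.SeedSequence(
            (self.seed, _STREAMS[stream], subject, session, run))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        d["fd_subject_range"] = list(d["fd_subject_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "fd_subject_range" in d:
            d["fd_subject_range"] = tuple(d["fd_subject_range"])
        return cls(**d)


def run_length_seconds(task: str, tr: float = TR_SECONDS) -> float:
    """Total run duration implied by the fixed frame counts."""
    n = {"mid": MID_N_FRAMES, "sr": SR_N_FRAMES}[task]
    return n * tr


def n_frames_for_task(task: str) -> int:
    return {"mid": MID_N_FRAMES, "sr": SR_N_FRAMES}[task]
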