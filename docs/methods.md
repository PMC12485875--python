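# Methods

`rewardkit` simulates an intensively sampled ("precision imaging") reward
fMRI study with known ground truth and runs the full measurement-property
analysis on it: first-level GLMs and trial-wise estimates, scalar reward
indices, split-half and test-retest reliability, and within-person
(idiographic) mood/alertness models. This note records the models, the
defaults and why they are what they are, and the places where a design
choice was genuinely open.

## The simulated study

Four participants are scanned over twelve evening sessions. Each session
holds two runs each of two reward tasks — a monetary incentive delay task
(MID; 56 trials, 283 frames at TR = 1.615 s) and a social card-guessing
shared-reward task (SR; 54 trials, 265 frames) — with a positive mood
induction between the first and second runs. Momentary mood (0–100) is
rated before each of six acquisitions, sleepiness (KSS, reverse-coded so
higher = more alert, 1–9) pre-scan and mid-scan, and positive affect
(PANAS-PA, 10–50) once per session.

### Trial amplitude model

The reward-condition response (MID reward anticipation; SR gain outcome)
on a trial is

    a = μ_i + u_is + γ_mood · z(mood) + γ_alert · z(KSS)
        + δ_induction · 1[post-induction run] + ε_t

with μ_i ~ N(μ, σ²_subject), u_is ~ N(0, σ²_session) shared by both runs
of a session, ε_t ~ N(0, σ²_trial), and the covariates within-person
standardized. For the SR task the state terms (γ's and δ) are multiplied
by `sr_effect_scale` (default 0.5): state effects concentrate in MID
anticipation, which the pipeline should be able to detect as a
MID-vs-SR asymmetry in explained variance.

Defaults (a.u.): μ = 1, σ²_subject = 0.008, σ²_session = 0.05,
σ²_trial = 1.0, γ_mood = 0.10, γ_alert = 0.05, δ_induction = 0.10.
These are calibrated so that, at 28 reward trials per run, the expected
split-half reliability σ²_B/(σ²_B + 2σ²_trial/n) sits near 0.6 while the
between-person share of run-level variance sits near 0.1 — the regime of
interest: runs that are internally consistent yet carry almost no stable
trait signal. With only four subjects the *estimated* ICC is itself
highly variable (roughly 0–0.35 across seeds), which is part of the
phenomenon, not a defect.

### Task schedules

Timing uses the printed constants: MID cue 0.75 s, ISI ~ U(1.5, 3.0) s,
outcome 1 s, ITI ~ U(2.0, 7.0) s; SR decision ≤ 2.5 s (drawn
U(0.8, 2.5)), ISI ~ U(0.85, 2.55) s, outcome 1 s, ITI ~ U(1.0, 4.0) s.
Jitters are rounded to 10 ms. The MID jitter means imply an expected
schedule (~471 s) slightly longer than the fixed 283-frame run
(457.045 s), so — as any real task program with a fixed run length must —
the generator constrains the jitter budget: the full jitter set is
redrawn until the last outcome ends at least half a frame before the end
of the run (~8% acceptance; deterministic given the seed). A
configuration whose *minimal* schedule cannot fit raises a
schedule-overflow error naming the first offending trial. The MID
reward:neutral split is 28/28 in randomized order; the response-target
staircase is replaced by Bernoulli(0.66) success draws; the response
window is subsumed in the ISI rather than modeled as its own event. SR
outcome labels are a permutation of exactly 22 gain / 22 loss /
10 neutral, and the partner alternates stranger/computer in blocks of 9.

### Rating streams

Mood starts at a per-subject baseline (60 ± 8), drifts by −2 points
between observations, jumps by +10 at the induction boundary
(observation 3 → 4), with truncated-Gaussian observation noise (SD 4,
±3 SD support), clipped to 0–100. KSS drops by 0.8 from pre- to
mid-scan (noise SD 0.5). PANAS-PA follows a per-subject AR(1) across
sessions (mean 35, autocorrelation 0.5, innovation SD 3). Each task run
inherits the rating immediately preceding it (MID run 1 ← observation 1,
SR run 1 ← observation 2, MID run 2 ← observation 4, SR run 2 ←
observation 5).

### BOLD forward model

Voxel time series on a 12×12×12 lattice:

    y_v(t) = baseline + gain · profile(v) · Σ_e a_e (h * box_e)(t)
             + drift_v(t) + AR(1) noise

with `gain = baseline · percent_signal_per_unit / 100` (default: 1 a.u.
peaks near 1% signal change on a baseline of 1000), a unit-peak
double-gamma HRF, low-frequency drift (two cosines with 220 s and 350 s
periods, per-voxel loadings at 0.3% of baseline), and AR(1) noise
(ρ = 0.3) scaled so the no-signal temporal SNR is 50. `profile` places
signal inside a 27-voxel central ROI blob with weights proportional to
the signature there (mean 1 in the ROI, zero outside). Setting
`tsnr = inf` and `drift_percent_sd = 0` gives exact, noiseless runs used
by the estimator-exactness tests. No motion, physics, or multi-echo
simulation; head motion exists only as a framewise-displacement
covariate column.

The synthetic signature stand-in (the repository does not ship or
re-derive any published weight map) is a smoothed Gaussian random field
(SD 0.5) plus a dominant positive bump (amplitude 4, width 2 voxels)
over the ROI. The concentration matters: with weights spread uniformly
over the grid, a whole-grid pattern correlation against signal confined
to 27 of 1728 voxels is geometrically diluted to ≈ 0.03 and the
multivariate index would be pure noise; concentrated weights mirror how
published reward signatures load on reward circuitry.

## Estimation

**HRF.** Double gamma parametrized directly by its peak: gamma density
of shape `peak + 1` (unit scale) minus `1/6` of a shape-17 density, so
the kernel mode is exactly 6 s with a 16 s undershoot; unit peak,
support truncated at 32 s, zero at t = 0. (The common SPM-style
`gamma(6) − gamma(16)/6` form actually peaks near 5 s; we pin the peak
itself.) No temporal derivatives.

**Design matrices.** Regressors are boxcars convolved at 10× microtime
resolution and sampled at frame midpoints `(i + 0.5)·TR`, the same
sampling the forward model uses, so convolution is reproducible
bit-for-bit. MID: four task regressors (reward/neutral ×
anticipation/outcome), the anticipation boxcar spanning cue onset
through the end of that trial's ISI. SR: decision per partner plus
outcome per partner × {gain, loss, neutral} (eight). A discrete-cosine
high-pass basis with 128 s cut-off (`K = floor(2·T/cutoff)` unit-norm
DCT-II columns; 7 for an MID run), mean-centered confound columns, and
an intercept complete the design. Runs are grand-mean scaled to 10,000
by a single multiplicative factor before fitting.

**GLM.** Ordinary least squares per voxel via QR, `σ² = RSS/(T − p)`;
no prewhitening — the synthetic noise model is configurable, and an
AR(1)-aware estimator is deliberately out of scope. Rank-deficient
designs raise an error naming the collinear columns. Contrast
z statistics are tail-symmetric normal transforms of the t CDF; the
run-level contrasts are MID reward > neutral anticipation and SR gain >
loss outcome aggregated across partners.

**LSS.** For each target-type event: one regressor for that event, one
for all other target-type events (omitted for single-trial runs), one
per non-target condition, plus drift/confounds/intercept; the
trial-specific coefficient map is kept. Exact amplitude recovery on
noiseless data holds when the shared "other trials" regressor spans the
truth — i.e. when trial amplitudes are equal, which is exactly the
zero-trial-variance generator; with heterogeneous amplitudes LSS is
validated by correlation with ground truth (r ≈ 0.94 at temporal SNR 50
on the full MID schedule).

**Indices.** Run-level: mean z inside the ROI mask (univariate) and the
Pearson correlation of the unthresholded effect map with the signature
over all grid voxels (multivariate; an `in_mask` scope exists as a
sensitivity option). Trial-level: the same reductions applied to LSS
beta maps, since a per-trial z is not well defined.

## Reliability

**Split-half.** Per subject and induction phase, the subject's runs of
that phase are the units: each of 1000 splits randomly partitions every
unit's trials into equal halves (an odd count drops one uniformly chosen
trial for that split), half means are correlated across units, the mean
over splits is taken, phase estimates are averaged, and subjects are
summarized by the Fisher-z mean. Raw half correlations are reported;
Spearman-Brown step-up is opt-in. Under the amplitude model the expected
estimate is σ²_B/(σ²_B + 2σ²_e/n); the resampler is validated against
this law on a grid of variance ratios and trial counts in the
moderate-reliability range (≈ 0.55–0.95). Above ≈ 0.97 the O(1/units)
finite-sample bias of the Pearson coefficient exceeds Monte-Carlo error,
so the population law stops being the finite-sample expectation there.

**Trial-count curves.** Trials are concatenated within sessions, the
global run effect (the induction shift) is regressed out, counts from 8
up to the per-session maximum (56 for MID anticipation, 44 for SR gain
outcomes) are subsampled without replacement, and the split-half
procedure is rerun with sessions as units.

**Test-retest (adjusted ICC).** A one-random-intercept linear mixed
model estimated by restricted maximum likelihood, with the variance
ratio λ = σ²_group/σ²_resid profiled out so the fit is a 1-D Brent
optimization over log λ (the λ = 0 boundary is checked explicitly;
boundary solutions are clipped to zero and flagged, never returned as
negative ICCs; a zero-residual degenerate fit short-circuits to
ICC = 1 with a boundary flag). Adjusted ICC =
σ²_group/(σ²_group + σ²_resid) after fixed effects of session index
(habituation detrending) and mean framewise displacement —
fixed-effect variance is excluded from the denominator. Run-level
reliability fits separate pre- and post-induction models and averages
the two ICCs; the session-level model includes both runs with a run
indicator and a single subject intercept (no nested session intercept
by default — nesting is unidentified at two runs per session; a
session-mean variant is available behind a flag). On balanced data the
REML optimum coincides with the one-way ANOVA moment estimator to 1e-6,
and it matches statsmodels' MixedLM on covariate-adjusted fixtures.

## Idiographic models

All variables are within-person standardized (per-subject mean 0,
SD 1; constant variables map to zeros with a warning). Each subject's
model regresses a run-level index on standardized momentary mood,
PANAS-PA (a session constant repeated across runs) and KSS, with a
categorical session random intercept — "random effects of session" is
read as a random intercept, not a slope. Marginal R² =
Var(Xβ̂)/(Var(Xβ̂) + σ²_session + σ²_resid); each predictor's
semi-partial R² is the drop in marginal R² when it is refit without that
predictor, floored at zero. Because the variance components are
re-estimated per sub-model, exact monotonicity of marginal R² under
predictor removal can fail by a hair at 24 observations — the floor
exists precisely for that. Induction (run) and habituation (session)
effects come from the same machinery with fixed effects {run indicator,
session index} and session (per-subject) or subject (pooled) random
intercepts; intervals are Wald-t on containment degrees of freedom
(observations − groups − within-group fixed effects), which keeps
nominal 95% coverage honest at twelve sessions.

## Power arithmetic

Classical attenuation, r_obs = r_true·√(rel_x·rel_y), feeding the
Fisher-z normal-approximation sample size
n = ((z_{1−α/2} + z_{power})/atanh(r_obs))² + 3, **truncated** to an
integer. Truncation, not the conventional round-up, is what reproduces
both benchmark values (361.13 → 361; 1087.89 → 1087). The same
procedure at both reliabilities = .80 gives n ≈ 134, not the
sometimes-quoted 53; we flag rather than force-fit that discrepancy
(53 is close to what one gets with a *one*-sided α or by other
approximations, but no variant of this formula yields it).

## Numerical and reproducibility choices

One root seed; every random stream is spawned from
`SeedSequence((seed, stream_tag, subject, session, run))`, so
regenerating any single run or rating stream is stable regardless of
order, and the full dataset is a pure function of the configuration.
The REML optimizer uses bounded Brent on log λ with xatol 1e-12; its
returned optimum is property-tested against random variance-ratio
probes. Split permutations are drawn by argsorting uniform arrays, which
vectorizes 1000 splits at once. CSV outputs contain no timestamps, so a
repeated pipeline run is byte-identical.

Problem sizes used by the shipped analyses: the demo pipeline runs
2 subjects × 4 sessions on the 12³ grid (32 task runs) — enough to
exercise every stage end-to-end with stable, reproducible outputs —
and the validation suite uses 40–60 units for resampling checks and
50–100 replicates for recovery/coverage checks.

## What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis
assumes — variance components, induction and drift effects, jittered
schedules, HRF-convolved signal with AR(1) noise — not real fMRI data:
no motion, no physiological noise, no spatial autocorrelation beyond the
signature field, no echo physics, no nonlinearity in the hemodynamics.
Estimator exactness, resampling laws, and recovery/coverage results
therefore validate the *pipeline*; they say nothing new about any real
dataset's reward response. Empirical headline numbers from the real
study (split-half ≈ 0.5–0.6, ICC ≈ 0.07–0.36, the +10-point mood bump,
10–31% idiographic variance explained) serve here only as calibration
anchors for generator defaults, and the pipeline's outputs land in those
regimes rather than reproducing any specific printed value.
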