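"""End-to-end orchestration: simulate -> fit -> indices -> reliability ->
idiographic -> report.

`run_pipeline` executes the whole analysis in memory on a simulated
study and writes CSV/JSON results plus a provenance record and summary
figures; the staged helpers (`stage_simulate`, `stage_glm`, ...) back the
command-line interface and exchange intermediates on disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig, n_frames_for_task
from .glm import (build_design, compute_contrast, fit_glm, grand_mean_scale,
                  lss_estimate)
from .idiographic import (fit_idiographic, induction_habituation_effects,
                          within_person_standardize)
from .indices import build_index_series, reduce_trials, roi_mean, \
    signature_similarity
from .power import PowerQuery, attenuated_r, required_n
from .reliability import run_level_icc, session_level_icc, split_half, \
    trial_count_curve
from .simulate import (RunRecord, SimulatedStudy, simulate_dataset,
                       target_condition)

__all__ = ["run_pipeline", "load_config", "analyze_run", "default_config",
           "stage_simulate", "stage_glm", "stage_lss", "stage_indices"]

OUTCOMES = ("vs_activation", "brs_correlation")
#: trial-count grids: 8 up to the per-session reward-trial maximum
#: (28 x 2 runs = 56 for MID anticipation, 22 x 2 = 44 for SR outcome)
TRIAL_GRIDS = {"mid": (8, 16, 24, 32, 40, 48, 56),
               "sr": (8, 14, 20, 26, 32, 38, 44)}


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Desk-scale demo configuration: 2 subjects x 4 sessions, 12^3 grid."""
    params = dict(seed=seed, n_subjects=2, n_sessions=4)
    params.update(overrides)
    return SimulationConfig(**params)


def load_config(path_or_dict) -> Dict:
    """Load a pipeline configuration from YAML/JSON or a dict.

    Recognized keys: ``seed`` (int), ``generator`` (SimulationConfig field
    overrides), ``analysis`` (``tasks``, ``n_splits``, ``trial_grid``).
    """
    if path_or_dict is None:
        return {}
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    path = Path(path_or_dict)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text) or {}
    return json.loads(text)


def _contrast_weights(task: str, names: Sequence[str]) -> Dict[str, float]:
    """Reward > control contrast for each task.

    MID: reward anticipation > neutral anticipation.  SR: reward (gain)
    outcome > punishment (loss) outcome, aggregated across partners.
    """
    if task == "mid":
        return {"reward_anticipation": 1.0, "neutral_anticipation": -1.0}
    w: Dict[str, float] = {}
    for name in names:
        if name.startswith("outcome_") and name.endswith("_gain"):
            w[name] = 0.5
        elif name.startswith("outcome_") and name.endswith("_loss"):
            w[name] = -0.5
    return w


def analyze_run(study: SimulatedStudy, record: RunRecord,
                grand_mean: bool = True):
    """First-level analysis of one run: contrast indices + LSS trial indices.

    Returns ``(run_record_dict, trial_frame)`` where the dict carries the
    run-level indices (ROI mean of the contrast z map, signature
    correlation of the unthresholded effect map) and the frame holds the
    per-trial scalar indices from the LSS betas.
    """
    bold = study.bold(record)
    n_frames = bold.n_frames
    data = bold.data.reshape(-1, n_frames).T
    if grand_mean:
        data = grand_mean_scale(data)
    design = build_design(record.events, record.task, n_frames, bold.tr,
                          confounds=record.confounds)
    fit = fit_glm(data, design)
    weights = _contrast_weights(record.task, design.names)
    contrast = compute_contrast(fit, design, weights,
                                name=f"{record.task}_reward_vs_control")
    rec = {
        "subject": record.subject, "session": record.session,
        "task": record.task, "run": record.run, "phase": record.phase,
        "vs_activation": roi_mean(contrast.z, study.roi),
        "brs_correlation": signature_similarity(contrast.effect,
                                                study.signature),
    }
    trials = lss_estimate(data, record.events, record.task,
                          target_condition(record.task), n_frames, bold.tr,
                          confounds=record.confounds)
    trial_frame = reduce_trials(trials, study.roi, study.signature)
    for key in ("subject", "session", "task", "run", "phase"):
        trial_frame[key] = getattr(record, key)
    return rec, trial_frame


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config=None, outdir="results", seed: Optional[int] = None,
                 make_plots: bool = True) -> Dict[str, object]:
    """Run the full simulate-and-analyze pipeline and write a report bundle.

    ``config`` may be a path to a YAML/JSON file, a dict, or None (the
    desk-scale demo).  ``seed`` overrides the configured root seed.
    Writes index/trial CSVs, split-half, trial-count, ICC, idiographic
    and induction-effect tables, a power table, a provenance log and
    summary figures under ``outdir``; returns the result tables.
    """
    cfg = load_config(config)
    gen = dict(cfg.get("generator", {}))
    if seed is not None:
        gen["seed"] = int(seed)
    elif "seed" in cfg:
        gen.setdefault("seed", int(cfg["seed"]))
    sim_config = default_config(**gen) if "n_subjects" not in gen \
        else SimulationConfig(**gen)
    analysis = dict(cfg.get("analysis", {}))
    tasks = tuple(analysis.get("tasks", ("mid", "sr")))
    n_splits = int(analysis.get("n_splits", 1000))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_dataset(sim_config, tasks=tasks)

    run_records, trial_frames = [], []
    for record in study.runs:
        rec, trials = analyze_run(study, record)
        run_records.append(rec)
        trial_frames.append(trials)
    fd_by_run = {
        (r.subject, r.session, r.task, r.run):
            float(r.confounds["framewise_displacement"].mean())
        for r in study.runs
    }
    series = build_index_series(run_records, study.ratings, fd_by_run)
    trial_indices = pd.concat(trial_frames, ignore_index=True)
    _write_csv(series, outdir / "index_series.csv")
    _write_csv(trial_indices, outdir / "trial_indices.csv")

    rng = sim_config.rng("analysis")

    sh_rows, curve_rows = [], []
    for task in tasks:
        block = trial_indices[trial_indices["task"] == task]
        for outcome in OUTCOMES:
            res = split_half(block, outcome, n_splits=n_splits, rng=rng)
            for subject, val in res.per_subject.items():
                sh_rows.append({"task": task, "outcome": outcome,
                                "subject": subject, "split_half": val})
            sh_rows.append({"task": task, "outcome": outcome,
                            "subject": "pooled", "split_half": res.pooled})
            grid = [g for g in TRIAL_GRIDS[task]]
            curve = trial_count_curve(block, grid, value_col=outcome,
                                      n_splits=n_splits, rng=rng)
            curve["task"], curve["outcome"] = task, outcome
            curve_rows.append(curve)
    split_half_table = pd.DataFrame(sh_rows)
    curve_table = pd.concat(curve_rows, ignore_index=True)
    _write_csv(split_half_table, outdir / "split_half.csv")
    _write_csv(curve_table, outdir / "trial_count_curve.csv")

    icc_rows = []
    for task in tasks:
        block = series[series["task"] == task]
        for outcome in OUTCOMES:
            run_res = run_level_icc(block, value_col=outcome)
            sess_res = session_level_icc(block, value_col=outcome)
            comps = run_res.components
            icc_rows.append({
                "task": task, "outcome": outcome,
                "icc_run_level": run_res.icc,
                "icc_pre": comps["pre_induction"].icc,
                "icc_post": comps["post_induction"].icc,
                "icc_session_level": sess_res.icc,
                "converged": all(c.converged for c in comps.values()),
            })
    icc_table = pd.DataFrame(icc_rows)
    _write_csv(icc_table, outdir / "icc.csv")

    idio_rows, induction_frames = [], []
    for task in tasks:
        block = series[series["task"] == task].reset_index(drop=True)
        std = within_person_standardize(
            block, ["vs_activation", "brs_correlation", "mood", "panas_pa",
                    "kss"])
        for outcome in OUTCOMES:
            for subject, sub in std.groupby("subject"):
                fit = fit_idiographic(sub, outcome=outcome)
                row = {"task": task, "outcome": outcome, "subject": subject,
                       "marginal_r2": fit.marginal_r2,
                       "low_power": fit.low_power,
                       "converged": fit.converged}
                for pred, val in fit.semi_partial_r2.items():
                    row[f"semi_partial_{pred}"] = val
                for pred in fit.coefficients.index:
                    row[f"coef_{pred}"] = fit.coefficients[pred]
                idio_rows.append(row)
            eff = induction_habituation_effects(std, scope="per_subject",
                                                outcome=outcome)
            pooled = induction_habituation_effects(std, scope="pooled",
                                                   outcome=outcome)
            eff = pd.concat([eff, pooled], ignore_index=True)
            eff["task"], eff["outcome"] = task, outcome
            induction_frames.append(eff)
    idiographic_table = pd.DataFrame(idio_rows)
    induction_table = pd.concat(induction_frames, ignore_index=True)
    _write_csv(idiographic_table, outdir / "idiographic.csv")
    _write_csv(induction_table, outdir / "induction_effects.csv")

    power_rows = []
    for rel_y in (0.80, 0.30, 0.10):
        q = PowerQuery(r_true=0.30, rel_x=0.80, rel_y=rel_y, alpha=0.05,
                       power=0.80)
        power_rows.append({"r_true": q.r_true, "rel_x": q.rel_x,
                           "rel_y": rel_y, "r_observed": attenuated_r(q),
                           "required_n": required_n(q)})
    power_table = pd.DataFrame(power_rows)
    _write_csv(power_table, outdir / "power.csv")

    config_dict = sim_config.to_dict()
    provenance = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "seed": sim_config.seed,
        "tasks": list(tasks),
        "n_splits": n_splits,
        "versions": _versions(),
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)

    if make_plots:
        _plots(outdir, study, split_half_table, curve_table, series)

    return {
        "index_series": series, "trial_indices": trial_indices,
        "split_half": split_half_table, "trial_count_curve": curve_table,
        "icc": icc_table, "idiographic": idiographic_table,
        "induction_effects": induction_table, "power": power_table,
        "provenance": provenance,
    }


def _versions() -> Dict[str, str]:
    import numpy
    import pandas
    import scipy
    return {"rewardkit": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__}


def _plots(outdir: Path, study: SimulatedStudy,
           split_half_table: pd.DataFrame, curve_table: pd.DataFrame,
           series: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    subj_rows = split_half_table[split_half_table["subject"] != "pooled"]
    for (task, outcome), g in subj_rows.groupby(["task", "outcome"]):
        axes[0].scatter([f"{task}\n{outcome[:3]}"] * len(g), g["split_half"],
                        alpha=0.7)
    axes[0].set_ylabel("split-half reliability")
    axes[0].set_title("per-subject split-half")
    for (task, outcome), g in curve_table.groupby(["task", "outcome"]):
        axes[1].plot(g["n_trials"], g["split_half"], marker="o",
                     label=f"{task} {outcome[:3]}")
    axes[1].set_xlabel("reward-condition trials")
    axes[1].set_ylabel("split-half reliability")
    axes[1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "reliability.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for subject, g in study.ratings.groupby("subject"):
        m = g.groupby("observation_index")["mood"].mean()
        ax.plot(m.index, m.values, marker="o", label=f"sub-{subject:02d}")
    ax.axvline(3.5, color="k", ls="--", lw=1)
    ax.set_xlabel("mood observation (induction after 3)")
    ax.set_ylabel("mood (0-100)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figdir / "mood.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# staged, on-disk variants backing the CLI subcommands
# ---------------------------------------------------------------------------

def stage_simulate(sim_config: SimulationConfig, outdir,
                   tasks: Sequence[str] = ("mid", "sr"),
                   write_bold: bool = True) -> SimulatedStudy:
    """Write a BIDS-style simulated dataset tree under ``outdir``."""
    from .io import (RunManifest, write_events, write_manifest, write_map,
                     write_table, write_volume)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_dataset(sim_config, tasks=tasks)
    with open(outdir / "config.json", "w") as fh:
        json.dump(sim_config.to_dict(), fh, indent=2)
    write_table(study.ratings, outdir / "ratings.tsv")
    study.amplitudes.to_csv(outdir / "ground_truth_amplitudes.csv",
                            index=False)
    write_map(study.roi.astype(float), outdir / "roi_mask.nii.gz")
    write_map(study.signature, outdir / "signature.nii.gz")
    manifests = []
    for r in study.runs:
        stem = (f"sub-{r.subject:02d}/ses-{r.session:02d}/func/"
                f"sub-{r.subject:02d}_ses-{r.session:02d}_task-{r.task}"
                f"_run-{r.run}")
        write_events(r.events, outdir / f"{stem}_events.tsv")
        write_table(r.confounds, outdir / f"{stem}_confounds.tsv")
        bold_path = f"{stem}_bold.nii.gz"
        if write_bold:
            write_volume(study.bold(r), outdir / bold_path)
        manifests.append(RunManifest(
            subject=r.subject, session=r.session, task=r.task, run=r.run,
            phase=r.phase, bold_path=bold_path,
            events_path=f"{stem}_events.tsv",
            confounds_path=f"{stem}_confounds.tsv",
            ratings_path="ratings.tsv", root_seed=sim_config.seed))
    write_manifest(manifests, outdir / "manifest.json")
    return study


def _load_staged(datadir):
    from .io import read_manifest, read_map, read_table
    datadir = Path(datadir)
    with open(datadir / "config.json") as fh:
        sim_config = SimulationConfig.from_dict(json.load(fh))
    manifests = read_manifest(datadir / "manifest.json", check_paths=False)
    roi = read_map(datadir / "roi_mask.nii.gz").astype(bool)
    signature = read_map(datadir / "signature.nii.gz")
    ratings = read_table(datadir / "ratings.tsv")
    return sim_config, manifests, roi, signature, ratings


def stage_glm(datadir, derivdir) -> pd.DataFrame:
    """Fit run-level GLMs + contrasts over a staged dataset; save z/effect maps."""
    from .io import read_events, read_table, read_volume
    datadir, derivdir = Path(datadir), Path(derivdir)
    derivdir.mkdir(parents=True, exist_ok=True)
    sim_config, manifests, roi, signature, ratings = _load_staged(datadir)
    rows = []
    for m in manifests:
        bold = read_volume(datadir / m.bold_path, task=m.task,
                           expect_shape=sim_config.grid_shape)
        events = read_events(datadir / m.events_path)
        confounds = read_table(datadir / m.confounds_path)
        data = grand_mean_scale(bold.data.reshape(-1, bold.n_frames).T)
        design = build_design(events, m.task, bold.n_frames, bold.tr,
                              confounds=confounds)
        fit = fit_glm(data, design)
        contrast = compute_contrast(fit, design,
                                    _contrast_weights(m.task, design.names))
        stem = (f"sub-{m.subject:02d}_ses-{m.session:02d}_task-{m.task}"
                f"_run-{m.run}")
        np.savez_compressed(derivdir / f"{stem}_contrast.npz",
                            effect=contrast.effect, z=contrast.z)
        rows.append({
            "subject": m.subject, "session": m.session, "task": m.task,
            "run": m.run, "phase": m.phase,
            "vs_activation": roi_mean(contrast.z, roi),
            "brs_correlation": signature_similarity(contrast.effect,
                                                    signature),
            "fd": float(confounds["framewise_displacement"].mean()),
        })
    table = pd.DataFrame(rows)
    table.to_csv(derivdir / "run_contrasts.csv", index=False)
    return table


def stage_lss(datadir, derivdir) -> pd.DataFrame:
    """Trial-wise LSS estimation over a staged dataset; save scalar indices."""
    from .io import read_events, read_table, read_volume
    datadir, derivdir = Path(datadir), Path(derivdir)
    derivdir.mkdir(parents=True, exist_ok=True)
    sim_config, manifests, roi, signature, ratings = _load_staged(datadir)
    frames = []
    for m in manifests:
        bold = read_volume(datadir / m.bold_path, task=m.task,
                           expect_shape=sim_config.grid_shape)
        events = read_events(datadir / m.events_path)
        confounds = read_table(datadir / m.confounds_path)
        data = grand_mean_scale(bold.data.reshape(-1, bold.n_frames).T)
        trials = lss_estimate(data, events, m.task, target_condition(m.task),
                              bold.n_frames, bold.tr, confounds=confounds)
        frame = reduce_trials(trials, roi, signature)
        for key, val in (("subject", m.subject), ("session", m.session),
                         ("task", m.task), ("run", m.run),
                         ("phase", m.phase)):
            frame[key] = val
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(derivdir / "trial_indices.csv", index=False)
    return table


def stage_indices(datadir, derivdir, resultsdir) -> pd.DataFrame:
    """Join staged run-level contrasts with covariates into an index series."""
    datadir, derivdir = Path(datadir), Path(derivdir)
    resultsdir = Path(resultsdir)
    resultsdir.mkdir(parents=True, exist_ok=True)
    _, _, _, _, ratings = _load_staged(datadir)
    contrasts = pd.read_csv(derivdir / "run_contrasts.csv")
    fd_by_run = {(r.subject, r.session, r.task, r.run): r.fd
                 for r in contrasts.itertuples()}
    series = build_index_series(contrasts.to_dict("records"), ratings,
                                fd_by_run)
    series.to_csv(resultsdir / "index_series.csv", index=False)
    return series
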