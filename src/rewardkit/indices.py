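"""Scalar reward indices from contrast maps and trial-level beta maps.

Two indices summarize a reward-contrast map: the mean statistic inside a
binary ventral-striatum-style region of interest (univariate), and the
voxelwise Pearson correlation of the unthresholded map with a
multivariate reward-signature weight map (multivariate).  Run-level
indices reduce the contrast z map ("mean Z"); trial-level indices reduce
LSS beta maps, since a per-trial z statistic is not well defined.
"""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .glm import ContrastMap, TrialEstimates
from .simulate import rating_observation_for_run

__all__ = ["roi_mean", "signature_similarity", "reduce_trials",
           "build_index_series"]


def _as_flat(map_like) -> np.ndarray:
    if isinstance(map_like, ContrastMap):
        map_like = map_like.z
    return np.asarray(map_like, dtype=float).ravel()


def roi_mean(map_like, mask: np.ndarray) -> float:
    """Arithmetic mean of a map over the voxels of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("ROI mask is empty")
    values = _as_flat(map_like)
    if values.size != mask.size:
        raise ValueError(
            f"map has {values.size} voxels but mask has {mask.size}")
    return float(values[mask.ravel()].mean())


def signature_similarity(map_like, signature: np.ndarray,
                         scope: str = "whole_grid",
                         mask: Optional[np.ndarray] = None) -> float:
    """Pearson correlation between an unthresholded map and a signature.

    ``scope='whole_grid'`` correlates over all voxels; ``scope='in_mask'``
    restricts to the voxels of ``mask`` (a sensitivity option).  Constant
    inputs over the chosen scope raise, since the correlation is
    undefined there.
    """
    if isinstance(map_like, ContrastMap):
        map_like = map_like.effect  # unthresholded effect map
    values = np.asarray(map_like, dtype=float).ravel()
    sig = np.asarray(signature, dtype=float).ravel()
    if values.size != sig.size:
        raise ValueError("map and signature grids differ")
    if scope == "in_mask":
        if mask is None:
            raise ValueError("scope='in_mask' requires a mask")
        sel = np.asarray(mask, dtype=bool).ravel()
        values, sig = values[sel], sig[sel]
    elif scope != "whole_grid":
        raise ValueError(f"unknown scope {scope!r}")
    if values.std() == 0 or sig.std() == 0:
        raise ValueError("correlation undefined: constant input over scope")
    r = float(np.corrcoef(values, sig)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def reduce_trials(trials: TrialEstimates, roi: np.ndarray,
                  signature: np.ndarray) -> pd.DataFrame:
    """Reduce LSS beta maps to per-trial scalar indices.

    Returns the trial bookkeeping frame with ``vs_activation`` (ROI mean
    of the trial beta map) and ``brs_correlation`` columns appended, one
    row per modeled trial in event order.
    """
    mask = np.asarray(roi, dtype=bool).ravel()
    sig = np.asarray(signature, dtype=float).ravel()
    out = trials.frame.copy()
    out["vs_activation"] = trials.betas[:, mask].mean(axis=1)
    centered = trials.betas - trials.betas.mean(axis=1, keepdims=True)
    sig_c = sig - sig.mean()
    denom = (np.sqrt((centered ** 2).sum(axis=1)) * np.linalg.norm(sig_c))
    with np.errstate(invalid="ignore"):
        out["brs_correlation"] = np.clip(centered @ sig_c / denom, -1.0, 1.0)
    return out


def build_index_series(contrasts: Iterable[Mapping], ratings: pd.DataFrame,
                       fd_by_run: Mapping) -> pd.DataFrame:
    """Join run-level indices with their behavioral covariates.

    ``contrasts`` is an iterable of records with keys ``subject, session,
    task, run, phase, vs_activation, brs_correlation``.  Each run inherits
    the mood/KSS/PANAS-PA rating immediately preceding it and its mean
    framewise displacement from ``fd_by_run`` (keyed by
    ``(subject, session, task, run)``).  Missing covariates raise with the
    full run key.
    """
    rows = []
    for rec in contrasts:
        key = (rec["subject"], rec["session"], rec["task"], rec["run"])
        r = rating_observation_for_run(ratings, rec["subject"],
                                       rec["session"], rec["task"],
                                       rec["run"])
        if key not in fd_by_run:
            raise KeyError(f"no framewise displacement for run {key}")
        rows.append({
            "subject": rec["subject"],
            "session": rec["session"],
            "task": rec["task"],
            "run": rec["run"],
            "phase": rec["phase"],
            "vs_activation": float(rec["vs_activation"]),
            "brs_correlation": float(rec["brs_correlation"]),
            "mood": float(r["mood"]),
            "panas_pa": float(r["panas_pa"]),
            "kss": float(r["kss"]),
            "fd": float(fd_by_run[key]),
        })
    return pd.DataFrame(rows)
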