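"""Readers and writers for the standard on-disk formats.

Event tables and rating/confound tables travel as BIDS-style TSV; BOLD
runs, masks and signature maps as NIfTI-1 (via nibabel) with the TR
carried in the header's fourth pixdim; run manifests and ground-truth
sidecars as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import BoldRun

__all__ = [
    "SchemaError",
    "read_events", "write_events",
    "read_table", "write_table",
    "read_volume", "write_volume",
    "read_map", "write_map",
    "RunManifest", "write_manifest", "read_manifest",
]

MANDATORY_EVENT_COLUMNS = ("onset", "duration", "trial_type")


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates value constraints."""


def read_events(path) -> pd.DataFrame:
    """Read a BIDS-style events.tsv and validate its schema.

    Requires ``onset``, ``duration`` and ``trial_type`` columns; onsets
    and durations are parsed as float seconds and must be non-negative /
    positive respectively (violations are reported with row indices).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANDATORY_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for col in ("onset", "duration"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    bad = df.index[df["onset"] < 0].tolist()
    if bad:
        raise SchemaError(f"{path}: negative onset at row(s) {bad}")
    bad = df.index[df["duration"] <= 0].tolist()
    if bad:
        raise SchemaError(f"{path}: non-positive duration at row(s) {bad}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV table (confounds, ratings)."""
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="n/a")


def write_volume(run: BoldRun, path) -> None:
    """Write a 4-D BOLD run as NIfTI-1, TR in pixdim[4] (seconds)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float64), np.eye(4))
    img.header.set_data_dtype(np.float64)
    img.header.set_zooms((1.0, 1.0, 1.0, float(run.tr)))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_volume(path, task: str = "", expect_shape=None) -> BoldRun:
    """Read a 4-D NIfTI-1 BOLD run back, preserving data, grid and TR."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - normalize nibabel's errors
        raise IOError(f"{path}: could not parse NIfTI volume: {exc}") from exc
    if data.ndim != 4:
        raise IOError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    if expect_shape is not None and data.shape[:3] != tuple(expect_shape):
        raise ValueError(
            f"{path}: grid {data.shape[:3]} does not match expected "
            f"{tuple(expect_shape)}")
    if not np.isfinite(data).all():
        raise IOError(f"{path}: volume contains non-finite values")
    tr = float(img.header.get_zooms()[3])
    return BoldRun(data=data, tr=tr, task=task)


def write_map(values: np.ndarray, path) -> None:
    """Write a 3-D map (mask or signature) as NIfTI-1."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), np.eye(4))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def read_map(path) -> np.ndarray:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"{path}: could not parse NIfTI map: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3-D map, got {data.ndim}-D")
    return data


@dataclass
class RunManifest:
    """Paths and identity of one simulated task run."""

    subject: int
    session: int
    task: str
    run: int
    phase: str
    bold_path: str
    events_path: str
    confounds_path: str
    ratings_path: str
    root_seed: int


def write_manifest(manifests: List[RunManifest], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    keys = {(m.subject, m.session, m.task, m.run) for m in manifests}
    if len(keys) != len(manifests):
        raise ValueError("duplicate (subject, session, task, run) in manifest")
    with open(path, "w") as fh:
        json.dump([asdict(m) for m in manifests], fh, indent=2)


def read_manifest(path, check_paths: bool = True) -> List[RunManifest]:
    with open(path) as fh:
        entries = json.load(fh)
    manifests = [RunManifest(**e) for e in entries]
    if check_paths:
        root = Path(path).parent
        for m in manifests:
            for p in (m.bold_path, m.events_path, m.confounds_path,
                      m.ratings_path):
                if not (root / p).exists() and not Path(p).exists():
                    raise FileNotFoundError(
                        f"manifest entry ({m.subject}, {m.session}, "
                        f"{m.task}, {m.run}) references missing file {p}")
    return manifests
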