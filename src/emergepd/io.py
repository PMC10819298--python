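"""Plain-text readers and writers for the pipeline's file formats.

All files are UTF-8 CSV with a header (or flat JSON for models and
manifests).  Missing values are forbidden in every tabular format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .pk import ConcentrationTrajectory

TRAJECTORY_COLUMNS = ["patient_id", "time_min", "cep_ugml", "cer_ngml"]
OAAS_COLUMNS = ["patient_id", "time_min", "oaas"]
LABELED_COLUMNS = ["patient_id", "time_min", "cep_ugml", "cer_ngml", "label"]


def _read_csv(path, columns: List[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {sorted(missing)}")
    if df[columns].isna().any().any():
        raise InvalidInputError(f"{path}: missing values are forbidden")
    return df


def write_trajectories(trajectories: Iterable[ConcentrationTrajectory], path) -> None:
    frames = [t.to_frame() for t in trajectories]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_trajectories(path) -> List[ConcentrationTrajectory]:
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        out.append(
            ConcentrationTrajectory(
                str(pid),
                grp["time_min"].to_numpy(dtype=float),
                grp["cep_ugml"].to_numpy(dtype=float),
                grp["cer_ngml"].to_numpy(dtype=float),
            )
        )
    return out


def write_oaas(df: pd.DataFrame, path) -> None:
    df[OAAS_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_oaas(path) -> pd.DataFrame:
    df = _read_csv(path, OAAS_COLUMNS)
    if not np.all(np.isin(df["oaas"].to_numpy(), np.arange(6))):
        raise InvalidInputError(f"{path}: OAA/S scores must be integers in 0..5")
    return df[OAAS_COLUMNS]


def write_labeled(df: pd.DataFrame, path) -> None:
    df[LABELED_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_labeled(path) -> pd.DataFrame:
    df = _read_csv(path, LABELED_COLUMNS)
    if not np.all(np.isin(df["label"].to_numpy(), (0, 1))):
        raise InvalidInputError(f"{path}: labels must be binary 0/1")
    return df[LABELED_COLUMNS]


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_model(model_dict: dict, path) -> None:
    Path(path).write_text(json.dumps(model_dict, indent=2, sort_keys=True) + "\n")


def read_model(path) -> dict:
    return json.loads(Path(path).read_text())
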