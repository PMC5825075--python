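"""Readers and writers for the delimited-text formats the pipeline exchanges.

Episodes, DRG reference tables and generator ground truth travel as UTF-8
CSV with a header row.  Multi-valued fields (additional diagnoses, code
lists) are semicolon-joined inside a single column; dates are ISO 8601.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

EPISODE_COLUMNS = [
    "person_id",
    "episode_id",
    "age",
    "sex",
    "los_days",
    "drg",
    "principal_dx",
    "additional_dx",
    "surgical",
    "admission_date",
]


def _join_codes(codes: Iterable[str]) -> str:
    return ";".join(codes)


def _split_codes(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return str(cell).split(";")


def write_episodes(path: os.PathLike | str, episodes: pd.DataFrame) -> None:
    """Write an episode table; ``additional_dx`` lists are semicolon-joined."""
    out = episodes.loc[:, EPISODE_COLUMNS].copy()
    out["additional_dx"] = out["additional_dx"].map(_join_codes)
    out["surgical"] = out["surgical"].astype(int)
    out["admission_date"] = pd.to_datetime(out["admission_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_episodes(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"person_id": str, "episode_id": str, "drg": str, "principal_dx": str},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in EPISODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"episode file {path} is missing columns: {missing}")
    df["age"] = df["age"].astype(int)
    df["los_days"] = df["los_days"].astype(int)
    df["surgical"] = df["surgical"].astype(int).astype(bool)
    df["additional_dx"] = df["additional_dx"].map(_split_codes)
    df["admission_date"] = pd.to_datetime(df["admission_date"])
    return df.loc[:, EPISODE_COLUMNS]


def write_drg_reference(path: os.PathLike | str, ref: pd.DataFrame) -> None:
    ref.to_csv(path, index=False)


def read_drg_reference(path: os.PathLike | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"drg": str})
    if "drg" not in df.columns or "avg_overnight_los" not in df.columns:
        raise ValueError(f"DRG reference file {path} lacks drg/avg_overnight_los columns")
    return df


def write_ground_truth(path: os.PathLike | str, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path: os.PathLike | str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"person_id": str, "episode_id": str})
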