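"""Delimited-text readers and writers for cage traces and cohort tables.

Cage traces are TSV with the fixed header
``animal_id  timestamp_min  vo2_l_min  vco2_l_min  activity_m  food_g``
(optionally ``temperature``); cohort weights and truth ledgers are plain
TSV. Column names are part of the file contract and are kept bit-stable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calorimetry import CageTrace

TRACE_COLUMNS = ["animal_id", "timestamp_min", "vo2_l_min", "vco2_l_min",
                 "activity_m", "food_g"]


def write_cage_trace(trace: CageTrace, path: str | Path) -> None:
    df = pd.DataFrame({
        "animal_id": trace.animal_id,
        "timestamp_min": trace.t,
        "vo2_l_min": trace.vo2,
        "vco2_l_min": trace.vco2,
        "activity_m": trace.activity,
        "food_g": trace.food,
        "temperature": trace.temperature_label,
    })
    df.to_csv(path, sep="\t", index=False)


def read_cage_trace(path: str | Path) -> list[CageTrace]:
    """Read a trace file; returns one CageTrace per animal_id found."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    traces = []
    for aid, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("timestamp_min")
        temp = grp["temperature"].iloc[0] if "temperature" in grp else "22C"
        traces.append(CageTrace(
            animal_id=str(aid),
            t=grp["timestamp_min"].to_numpy(dtype=float),
            vo2=grp["vo2_l_min"].to_numpy(dtype=float),
            vco2=grp["vco2_l_min"].to_numpy(dtype=float),
            activity=grp["activity_m"].to_numpy(dtype=float),
            food=grp["food_g"].to_numpy(dtype=float),
            temperature_label=str(temp)))
    return traces


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
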