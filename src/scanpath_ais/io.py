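"""Readers and writers for the pipeline's delimited-text formats.

* Gaze logs: CSV with columns participant, trial, condition, t, x, y,
  confidence (one row per sample, t in seconds).
* AOI layouts: YAML listing name, symbol, rect [x0, y0, x1, y1], priority.
* Scanpaths: CSV with one row per fixation (participant, trial, condition,
  fixation_index, onset, duration, aoi_symbol); onset/duration may be empty
  for simulated symbol sequences.
* Per-trial result tables and group reports: plain CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocessing import AOILayout, AOIRegion, Fixation, GazeRecording, Scanpath

__all__ = [
    "read_gaze_log",
    "write_gaze_log",
    "read_aoi_layout",
    "write_aoi_layout",
    "read_scanpaths",
    "write_scanpaths",
]

GAZE_COLUMNS = ["participant", "trial", "condition", "t", "x", "y", "confidence"]
SCANPATH_COLUMNS = [
    "participant",
    "trial",
    "condition",
    "fixation_index",
    "onset",
    "duration",
    "aoi_symbol",
]


def read_gaze_log(path: str | Path) -> list[GazeRecording]:
    """Load a delimited gaze log into one recording per (participant, trial)."""
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze log missing columns: {sorted(missing)}")
    recs = []
    for (pid, trial), g in df.groupby(["participant", "trial"], sort=False):
        g = g.sort_values("t")
        recs.append(
            GazeRecording(
                participant_id=str(pid),
                trial_id=str(trial),
                condition=str(g["condition"].iloc[0]),
                t=g["t"].to_numpy(),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                confidence=g["confidence"].to_numpy(),
            )
        )
    return recs


def write_gaze_log(recordings: Iterable[GazeRecording], path: str | Path) -> None:
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "participant": rec.participant_id,
                    "trial": rec.trial_id,
                    "condition": rec.condition,
                    "t": rec.t,
                    "x": rec.x,
                    "y": rec.y,
                    "confidence": rec.confidence,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_aoi_layout(path: str | Path) -> AOILayout:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regions = [
        AOIRegion(
            symbol=int(r["symbol"]),
            name=str(r["name"]),
            rect=tuple(float(v) for v in r["rect"]),
            priority=int(r["priority"]),
        )
        for r in doc["regions"]
    ]
    return AOILayout(regions=tuple(regions))


def write_aoi_layout(layout: AOILayout, path: str | Path) -> None:
    doc = {
        "regions": [
            {
                "name": r.name,
                "symbol": r.symbol,
                "rect": list(r.rect),
                "priority": r.priority,
            }
            for r in layout.regions
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_scanpaths(
    scanpaths: Iterable[Scanpath],
    path: str | Path,
    fixations: dict[tuple[str, str], Sequence[Fixation]] | None = None,
) -> None:
    """Write scanpaths (optionally with fixation onsets/durations) to CSV."""
    rows = []
    for sp in scanpaths:
        fx = (fixations or {}).get((sp.participant_id, sp.trial_id))
        for i, sym in enumerate(sp.symbols):
            rows.append(
                {
                    "participant": sp.participant_id,
                    "trial": sp.trial_id,
                    "condition": sp.condition,
                    "fixation_index": i,
                    "onset": fx[i].onset if fx is not None else np.nan,
                    "duration": fx[i].duration if fx is not None else np.nan,
                    "aoi_symbol": int(sym),
                }
            )
    pd.DataFrame(rows, columns=SCANPATH_COLUMNS).to_csv(path, index=False)


def read_scanpaths(path: str | Path, alphabet_size: int | None = None) -> list[Scanpath]:
    """Load AOI-coded scanpaths; alphabet size defaults to max symbol + 1."""
    df = pd.read_csv(path)
    missing = {"participant", "trial", "condition", "fixation_index", "aoi_symbol"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"scanpath file missing columns: {sorted(missing)}")
    if alphabet_size is None:
        alphabet_size = int(df["aoi_symbol"].max()) + 1
    out = []
    for (pid, trial), g in df.groupby(["participant", "trial"], sort=False):
        g = g.sort_values("fixation_index")
        out.append(
            Scanpath(
                symbols=g["aoi_symbol"].to_numpy(dtype=np.int64),
                alphabet_size=alphabet_size,
                participant_id=str(pid),
                trial_id=str(trial),
                condition=str(g["condition"].iloc[0]),
            )
        )
    return out
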