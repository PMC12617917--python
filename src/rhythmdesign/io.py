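"""Reading and writing designs and time series as plain CSV / JSON.

Design CSV: a single ``time`` column, one measurement time per row, values
on the unit study interval.  Design JSON additionally carries metadata
(``time_unit``, ``study_length``); times stored in physical units (e.g.
hours with ``study_length`` 24) are normalised to the unit interval on read.
Series CSV: ``time,value`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cosinor import Design

__all__ = ["read_design", "write_design", "read_series", "write_series"]


def write_design(
    design: Design,
    path,
    time_unit: str = "fraction",
    study_length: float = 1.0,
) -> None:
    """Write a design as CSV (times only) or JSON (times + metadata),
    chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "times": [float(t) * study_length for t in design.times],
            "n": design.n,
            "time_unit": time_unit,
            "study_length": float(study_length),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        lines = ["time"] + [repr(float(t)) for t in design.times]
        path.write_text("\n".join(lines) + "\n")


def read_design(path) -> Design:
    """Read a design written by :func:`write_design`.

    JSON times are divided by ``study_length``; CSV times must already lie
    on the unit interval (there is no metadata to normalise by).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        study_length = float(payload.get("study_length", 1.0))
        times = np.asarray(payload["times"], float) / study_length
        if np.any(times < 0) or np.any(times >= 1.0):
            raise ValueError(
                f"{path}: times fall outside the unit interval after "
                f"normalising by study_length={study_length}"
            )
        return Design(times)
    times = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",")[0].strip().lower() != "time":
            raise ValueError(f"{path}:1: expected a 'time' header, got {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            try:
                value = float(raw.split(",")[0])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: cannot parse time {raw!r}") from None
            if not 0.0 <= value < 1.0:
                raise ValueError(
                    f"{path}:{lineno}: time {value} outside [0, 1); "
                    "use JSON with a study_length to store physical units"
                )
            times.append(value)
    if not times:
        raise ValueError(f"{path}: no measurement times found")
    return Design(times)


def write_series(times, values, path) -> None:
    """Write a (time, value) series as CSV."""
    pd.DataFrame({"time": np.asarray(times, float),
                  "value": np.asarray(values, float)}).to_csv(path, index=False)


def read_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``time,value`` CSV; returns (times, values) sorted by time."""
    df = pd.read_csv(path)
    missing = {"time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.sort_values("time")
    return df["time"].to_numpy(float), df["value"].to_numpy(float)
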