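"""Plain-text readers and writers for the pipeline's artifacts.

Dyad series travel as 2-column CSV (one column per member, frame index
implicit), cohort metadata and measure tables as CSV, and ground-truth
coupling schedules as JSON lists of {start, end, lag, beta, sign}.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import CouplingInterval, DyadTimeSeries

__all__ = [
    "write_dyad_csv",
    "read_dyad_csv",
    "write_schedule_json",
    "read_schedule_json",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_dyad_csv(dyad: DyadTimeSeries, path: str | Path,
                   names: tuple[str, str] = ("A", "B")) -> None:
    pd.DataFrame({names[0]: dyad.a, names[1]: dyad.b}).to_csv(path, index=False)


def read_dyad_csv(path: str | Path, fps: int = 25,
                  dyad_id: str | None = None) -> DyadTimeSeries:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValueError("dyad CSV must have exactly two columns")
    return DyadTimeSeries(a=df.iloc[:, 0].to_numpy(float),
                          b=df.iloc[:, 1].to_numpy(float), fps=fps,
                          dyad_id=dyad_id or Path(path).stem)


def write_schedule_json(schedule: list[CouplingInterval], path: str | Path) -> None:
    payload = [{"start": iv.start_frame, "end": iv.end_frame, "lag": iv.lag_tau,
                "beta": iv.strength_beta, "sign": iv.sign} for iv in schedule]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_schedule_json(path: str | Path) -> list[CouplingInterval]:
    payload = json.loads(Path(path).read_text())
    return [CouplingInterval(start_frame=d["start"], end_frame=d["end"],
                             lag_tau=d["lag"], strength_beta=d["beta"],
                             sign=d.get("sign", 1)) for d in payload]


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
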