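"""Reading and writing the pipeline's delimited text formats.

Epoch files are long-format CSV with columns ``participant_id``,
``timestamp`` (ISO-8601, local clock), ``vm_mg`` (float, >= 0) and an
optional ``wear`` column; cohort files are one row per participant with the
column dictionary documented in the methods note.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSeries

EPOCH_COLUMNS = ("participant_id", "timestamp", "vm_mg")


def write_epochs(series_list, path) -> None:
    frames = []
    for s in series_list:
        idx = pd.date_range(s.start, periods=s.n_epochs, freq=f"{s.epoch_seconds}s")
        frame = pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "timestamp": idx.strftime("%Y-%m-%dT%H:%M:%S"),
                "vm_mg": np.round(s.vm, 3),
            }
        )
        if not s.wear.all():
            frame["wear"] = s.wear.astype(int)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_epochs(path) -> list:
    df = pd.read_csv(path)
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"epoch file {path} lacks columns {missing}")
    if (df["vm_mg"] < 0).any():
        bad = int(df.index[df["vm_mg"] < 0][0]) + 2  # header + 1-based
        raise ValueError(f"epoch file {path}: negative vm_mg at line {bad}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=False):
        ts = pd.to_datetime(grp["timestamp"])
        step = ts.diff().dropna().dt.total_seconds()
        if len(step) and not (step == step.iloc[0]).all():
            raise ValueError(f"epoch file {path}: non-uniform spacing for {pid}")
        wear = grp["wear"].to_numpy(dtype=bool) if "wear" in grp else None
        out.append(
            EpochSeries(
                participant_id=str(pid),
                start=ts.iloc[0],
                vm=grp["vm_mg"].to_numpy(dtype=float),
                wear=wear,
                epoch_seconds=int(step.iloc[0]) if len(step) else 5,
            )
        )
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
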