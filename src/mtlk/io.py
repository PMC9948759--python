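"""CSV / TIFF / JSON input-output with the documented column schemas."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .simulate.dynamics import TipTrajectory

TRACE_COLUMNS = ["mt_id", "time_s", "position_um"]
LOC_COLUMNS = ["tid", "t_s", "x_nm", "y_nm", "z_nm", "dcr"]
PF_COLUMNS = ["mt_id", "pf_id", "point_idx", "x_nm", "y_nm", "z_nm"]
ANNOTATION_COLUMNS = ["tomogram_id", "mt_id", "length_um", "n_defects", "has_ilp"]


def write_trajectories_csv(trajectories: Iterable[TipTrajectory], path) -> None:
    pd.concat([t.to_frame() for t in trajectories], ignore_index=True).to_csv(
        path, index=False
    )


def read_trajectories_csv(path) -> list[TipTrajectory]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for mt_id, grp in df.groupby("mt_id"):
        grp = grp.sort_values("time_s")
        traj = TipTrajectory(
            times=grp.time_s.to_numpy(), positions=grp.position_um.to_numpy(),
            true_states=grp.state.to_numpy() if "state" in grp else None,
        )
        traj.mt_id = mt_id
        out.append(traj)
    return out


def write_localizations_csv(table: pd.DataFrame, path) -> None:
    table[[c for c in LOC_COLUMNS if c in table.columns]].to_csv(path, index=False)


def read_localizations_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"tid", "x_nm", "y_nm", "dcr"} - set(df.columns)
    if missing:
        raise ValueError(f"localization CSV missing columns: {sorted(missing)}")
    if "z_nm" not in df:
        df["z_nm"] = 0.0
    return df


def write_image_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_ground_truth_json(obj, path) -> None:
    """JSON sidecar for generator ground truth / specs / summaries."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
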