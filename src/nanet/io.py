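"""Readers and writers for the pipeline's on-disk artifacts.

Formats: ROI tables / events / metrics as CSV, trace matrices as HDF5 (one
dataset per dish/timepoint with a sampling-rate attribute) or wide CSV,
adjacency matrices as Matrix Market plus dense CSV with ROI-id headers,
study configuration as YAML, reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from scipy import io as sio
from scipy.sparse import coo_array

from .types import Population, Roi, TraceSet


def write_roi_table(populations, path: Path) -> None:
    frames = [p.to_frame() for p in populations]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_roi_table(path: Path, fov: tuple[float, float]) -> dict[str, Population]:
    df = pd.read_csv(path)
    pops: dict[str, Population] = {}
    for dish_id, sub in df.groupby("dish_id", sort=False):
        rois = [
            Roi(
                roi_id=str(r.roi_id),
                cell_type=str(r.cell_type),
                x=float(r.x),
                y=float(r.y),
                parent_cell_id=None if pd.isna(r.parent_cell_id) else str(r.parent_cell_id),
            )
            for r in sub.itertuples()
        ]
        pops[str(dish_id)] = Population(
            rois=rois, fov_width=fov[0], fov_height=fov[1], dish_id=str(dish_id)
        )
    return pops


def write_traces_h5(tracesets: list[TraceSet], path: Path) -> None:
    with h5py.File(path, "w") as f:
        for ts in tracesets:
            key = f"{ts.dish_id}/{ts.condition.timepoint}"
            d = f.create_dataset(key, data=ts.traces)
            d.attrs["sampling_rate"] = ts.sampling_rate
            d.attrs["roi_ids"] = np.array(ts.roi_ids, dtype="S")
            d.attrs["group"] = ts.condition.group


def write_events_csv(trains_by_ts, tracesets, path: Path) -> None:
    rows = []
    for ts, trains in zip(tracesets, trains_by_ts):
        for e in trains:
            for t, r in zip(e.times, e.correlations):
                rows.append(
                    {
                        "dish_id": ts.dish_id,
                        "timepoint": ts.condition.timepoint,
                        "roi_id": e.roi_id,
                        "t_onset_s": t,
                        "r": r,
                    }
                )
    pd.DataFrame(
        rows, columns=["dish_id", "timepoint", "roi_id", "t_onset_s", "r"]
    ).to_csv(path, index=False)


def write_adjacency(weights: np.ndarray, roi_ids: list[str], stem: Path) -> None:
    """Matrix Market + dense CSV (ROI ids as header/index) side by side."""
    sio.mmwrite(str(stem.with_suffix(".mtx")), coo_array(weights))
    pd.DataFrame(weights, index=roi_ids, columns=roi_ids).to_csv(
        stem.with_suffix(".csv")
    )


def write_partition_csv(roi_ids, partition, path: Path) -> None:
    pd.DataFrame({"roi_id": roi_ids, "community": partition}).to_csv(path, index=False)


def write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_yaml(obj, path: Path) -> None:
    path.write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: Path):
    return yaml.safe_load(Path(path).read_text())
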