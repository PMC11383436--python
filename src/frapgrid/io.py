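"""File I/O: TIFF movies with JSON sidecars, and CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .conditions import ConditionSummary
from .simulate import FilamentEnsemble, ImageStack
from .tracking import AreaTrajectory, UnitCellTrack

__all__ = [
    "write_movie", "read_movie",
    "ensemble_to_csv",
    "tracks_to_csv", "read_tracks_csv",
    "area_statistics_to_csv", "read_area_statistics_csv",
    "read_conditions_csv",
]


def _sidecar_path(tif_path: Path) -> Path:
    return tif_path.with_suffix(".json")


def write_movie(stack: ImageStack, path, meta_path=None) -> Path:
    """Write a 16-bit multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(path)
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = dict(stack.meta)
    meta.update({
        "pixel_size_um": stack.pixel_size,
        "times_s": stack.times.tolist(),
        "bleach_time_s": stack.bleach_time,
    })
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta_path


def read_movie(path, meta_path=None) -> ImageStack:
    """Read a TIFF stack and its JSON sidecar back into an ImageStack."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else _sidecar_path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(meta_path.read_text())
    times = np.asarray(meta["times_s"], dtype=float)
    return ImageStack(data=data, pixel_size=float(meta["pixel_size_um"]),
                      times=times,
                      bleach_time=float(meta.get("bleach_time_s", 0.0)),
                      meta=meta)


def ensemble_to_csv(ensemble: FilamentEnsemble, path) -> None:
    """Ground-truth trajectories as time_s, filament_id, x_um, y_um, fluorescent."""
    t_rep = np.repeat(ensemble.times, ensemble.n_filaments)
    ids = np.tile(np.arange(ensemble.n_filaments), ensemble.times.size)
    pos = ensemble.positions.reshape(-1, 2)
    fl = np.tile(ensemble.fluorescent, ensemble.times.size)
    pd.DataFrame({
        "time_s": t_rep, "filament_id": ids,
        "x_um": pos[:, 0], "y_um": pos[:, 1], "fluorescent": fl,
    }).to_csv(path, index=False)


def tracks_to_csv(tracks: list[UnitCellTrack], path) -> None:
    rows = []
    for tr in tracks:
        for k in range(tr.times.size):
            rows.append({
                "cell_id": tr.cell_id, "frame": k,
                "time_s": tr.times[k],
                "x_um": tr.centroids[k, 0], "y_um": tr.centroids[k, 1],
                "area_um2": tr.areas[k], "valid": bool(tr.valid[k]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path) -> list[UnitCellTrack]:
    df = pd.read_csv(path)
    tracks = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_s")
        tracks.append(UnitCellTrack(
            cell_id=int(cid),
            times=g["time_s"].to_numpy(),
            centroids=g[["x_um", "y_um"]].to_numpy(),
            areas=g["area_um2"].to_numpy(),
            valid=g["valid"].to_numpy(dtype=bool),
        ))
    return tracks


def area_statistics_to_csv(median: AreaTrajectory, q1: AreaTrajectory,
                           q3: AreaTrajectory, path) -> None:
    pd.DataFrame({
        "time_s": median.times,
        "median": median.normalized_area,
        "q1": q1.normalized_area,
        "q3": q3.normalized_area,
    }).to_csv(path, index=False)


def read_area_statistics_csv(path) -> dict[str, AreaTrajectory]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    return {name: AreaTrajectory(t, df[name].to_numpy(), source=name)
            for name in ("median", "q1", "q3")}


def read_conditions_csv(path) -> list[ConditionSummary]:
    """Read a conditions table (label, atp_uM, alpha_per_s, d_eff, d_q1, d_q3)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(ConditionSummary(
            label=str(row["label"]),
            atp_uM=float(row["atp_uM"]),
            alpha=float(row["alpha_per_s"]),
            d_eff=float(row["d_eff"]),
            d_q1=float(row["d_q1"]) if "d_q1" in row and
            np.isfinite(row["d_q1"]) else None,
            d_q3=float(row["d_q3"]) if "d_q3" in row and
            np.isfinite(row["d_q3"]) else None,
        ))
    return out
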