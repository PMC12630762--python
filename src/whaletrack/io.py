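"""File round-tripping: ESRI ASCII bathymetry grids, detection tables,
track tables, probability grids, and YAML scene configs.

All delimited files are UTF-8 CSV with a header row and '.' decimals.  The
detection-table schema is::

    array_id, arrival_time_s, rl_db, tdoa_12, tdoa_13, tdoa_14,
    tdoa_23, tdoa_24, tdoa_34[, truth_whale_id]

Unknown extra columns are preserved on read with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .localize import Track
from .scene import Bathymetry, ReceiverDetection

__all__ = [
    "read_esri_ascii",
    "write_esri_ascii",
    "read_detections",
    "write_detections",
    "detections_to_frame",
    "frame_to_detections",
    "read_tracks",
    "write_tracks",
    "grid_to_frame",
]

TDOA_COLUMNS = ["tdoa_12", "tdoa_13", "tdoa_14", "tdoa_23", "tdoa_24", "tdoa_34"]
DETECTION_COLUMNS = ["array_id", "arrival_time_s", "rl_db"] + TDOA_COLUMNS


# ---------------------------------------------------------------------------
# ESRI ASCII grids


def write_esri_ascii(bathymetry: Bathymetry, path, nodata: float = -9999.0):
    """Write a bathymetry grid as an ESRI ASCII raster (row 1 = northernmost)."""
    b = bathymetry
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {b.x.size}\n")
        fh.write(f"nrows {b.y.size}\n")
        fh.write(f"xllcorner {b.x[0] - b.cell_size / 2:.6f}\n")
        fh.write(f"yllcorner {b.y[0] - b.cell_size / 2:.6f}\n")
        fh.write(f"cellsize {b.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in b.depth[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_esri_ascii(path) -> Bathymetry:
    """Read an ESRI ASCII raster as a bathymetry grid (cell-centre axes)."""
    header = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ESRI ASCII header missing {key!r}")
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"grid shape {data.shape} != header ({nrows}, {ncols})")
    cs = header["cellsize"]
    x = header["xllcorner"] + cs / 2 + np.arange(ncols) * cs
    y = header["yllcorner"] + cs / 2 + np.arange(nrows) * cs
    return Bathymetry(x=x, y=y, depth=data[::-1], cell_size=cs)


# ---------------------------------------------------------------------------
# detection tables


def detections_to_frame(detections) -> pd.DataFrame:
    rows = []
    for d in detections:
        row = {"array_id": d.array_id, "arrival_time_s": d.arrival_time,
               "rl_db": d.received_level}
        row.update(dict(zip(TDOA_COLUMNS, d.tdoas)))
        row["truth_whale_id"] = "" if d.whale_id is None else d.whale_id
        rows.append(row)
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS + ["truth_whale_id"])


def frame_to_detections(df: pd.DataFrame) -> list[ReceiverDetection]:
    out = []
    has_truth = "truth_whale_id" in df.columns
    for _, row in df.iterrows():
        wid = None
        if has_truth and str(row["truth_whale_id"]) not in ("", "nan"):
            wid = str(row["truth_whale_id"])
        out.append(ReceiverDetection(
            array_id=str(row["array_id"]), whale_id=wid,
            arrival_time=float(row["arrival_time_s"]),
            received_level=float(row["rl_db"]),
            tdoas=row[TDOA_COLUMNS].to_numpy(dtype=float),
        ))
    return out


def write_detections(df_or_detections, path):
    """Write a detection table (DataFrame or list of detections) as CSV."""
    df = df_or_detections
    if not isinstance(df, pd.DataFrame):
        df = detections_to_frame(df)
    df.to_csv(path, index=False, float_format="%.12g")


def read_detections(path) -> pd.DataFrame:
    """Read a detection table, validating the schema.

    Missing required columns raise; malformed numerics raise with the
    offending row and column; unknown columns are preserved with a warning.
    A header-only file yields an empty table.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    extra = [c for c in df.columns
             if c not in DETECTION_COLUMNS + ["truth_whale_id"]]
    if extra:
        warnings.warn(f"unknown detection-table columns preserved: {extra}",
                      stacklevel=2)
    numeric = [c for c in DETECTION_COLUMNS if c != "array_id"]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"malformed numeric in column {col!r}, row(s) {list(bad[:5])}"
            ) from None
    return df


# ---------------------------------------------------------------------------
# track tables


TRACK_COLUMNS = ["whale_id", "time_s", "x_m", "y_m", "depth_m",
                 "ci95_x_m", "ci95_y_m", "ci95_z_m",
                 "smoothed_x_m", "smoothed_y_m", "smoothed_z_m"]


def write_tracks(tracks, path):
    """Write one or more tracks as a long CSV (schema in TRACK_COLUMNS)."""
    frames = []
    for t in tracks:
        sm = t.smoothed_positions if t.smoothed_positions is not None else t.positions
        frames.append(pd.DataFrame({
            "whale_id": t.whale_id, "time_s": t.times,
            "x_m": t.positions[:, 0], "y_m": t.positions[:, 1],
            "depth_m": t.positions[:, 2],
            "ci95_x_m": t.ci95[:, 0], "ci95_y_m": t.ci95[:, 1],
            "ci95_z_m": t.ci95[:, 2],
            "smoothed_x_m": sm[:, 0], "smoothed_y_m": sm[:, 1],
            "smoothed_z_m": sm[:, 2],
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    out = []
    for wid, sub in df.groupby("whale_id", sort=False):
        out.append(Track(
            whale_id=str(wid), times=sub["time_s"].to_numpy(float),
            positions=sub[["x_m", "y_m", "depth_m"]].to_numpy(float),
            ci95=sub[["ci95_x_m", "ci95_y_m", "ci95_z_m"]].to_numpy(float),
            smoothed_positions=sub[["smoothed_x_m", "smoothed_y_m",
                                    "smoothed_z_m"]].to_numpy(float),
        ))
    return out


# ---------------------------------------------------------------------------
# probability grids / configs


def grid_to_frame(grid) -> pd.DataFrame:
    """Long-format (x_bin, y_bin, p) frame of a probability grid; bin values
    are bin centres."""
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    return pd.DataFrame({"x_bin": xx.ravel(), "y_bin": yy.ravel(),
                         "p": grid.probability.ravel()})


def load_yaml(path) -> dict:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
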