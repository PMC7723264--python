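"""Track tables, CSV I/O, detection linking, and fiducial drift correction.

The track CSV is the pipeline's central exchange format.  Columns, in order:
``track_id, frame, time_h, x_um, y_um, compartment, phase, ch1, ch2``
(phase/ch1/ch2 may be empty).  Coordinates are continuous µm with the origin
on the wound centerline.

Linking is a greedy mutual-nearest-neighbor matcher between consecutive
frames (the behavior of simple centroid trackers); drift estimation uses the
per-step median displacement of a static reference compartment
(hair-follicle cells, which do not migrate) so a minority of moving outliers
cannot bias the correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "TRACK_COLUMNS", "read_tracks", "write_tracks", "validate_tracks",
    "link_detections", "estimate_drift", "apply_drift",
]

TRACK_COLUMNS = ["track_id", "frame", "time_h", "x_um", "y_um",
                 "compartment", "phase", "ch1", "ch2"]
REQUIRED = ["track_id", "frame", "time_h", "x_um", "y_um", "compartment"]


def validate_tracks(table: pd.DataFrame) -> None:
    """Raise ValueError on schema violations (missing columns, duplicate
    (track_id, frame) keys, non-increasing frames within a track)."""
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"track table is missing required column(s): {missing}")
    dup = table.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = table.loc[dup.idxmax()]
        raise ValueError(
            "duplicate (track_id, frame) key: "
            f"({int(row['track_id'])}, {int(row['frame'])})")
    frames = table.sort_index().groupby("track_id", sort=False)["frame"]
    bad = frames.apply(lambda s: bool((np.diff(s.to_numpy()) <= 0).any()))
    if bad.any():
        tid = bad.index[np.argmax(bad.to_numpy())]
        raise ValueError(f"frames not strictly increasing within track {tid}")


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track CSV; malformed rows are reported with their
    line numbers."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed track CSV {path}: {err}") from err
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    bad_rows = []
    for col in ("track_id", "frame", "time_h", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        bad_rows.extend((int(i) + 2, col) for i in bad)  # +2: header + 1-based
        df[col] = vals
    if bad_rows:
        desc = ", ".join(f"line {ln} ({col})" for ln, col in bad_rows[:10])
        raise ValueError(f"{path}: non-numeric values at {desc}")
    if df[["track_id", "frame", "x_um", "y_um"]].isna().any().any():
        ln = int(df[["track_id", "frame", "x_um", "y_um"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: missing required value at line {ln}")
    df["track_id"] = df["track_id"].astype(np.int64)
    df["frame"] = df["frame"].astype(np.int64)
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    validate_tracks(df)
    return df[TRACK_COLUMNS]


def write_tracks(table: pd.DataFrame, path) -> None:
    validate_tracks(table)
    out = table.copy()
    for col in TRACK_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[TRACK_COLUMNS].to_csv(path, index=False, lineterminator="\n")


# ----------------------------------------------------------------------
def link_detections(detections, max_disp: float, dt_minutes: float = 30.0,
                    compartment: str = "unknown") -> pd.DataFrame:
    """Link per-frame centroid lists into tracks.

    ``detections`` is a sequence of (n_i, 2) arrays of (x, y) µm.  Between
    consecutive frames, detections are paired when each is the other's
    nearest neighbor and their distance is <= ``max_disp``; ties resolve to
    the lowest detection index (KD-tree nearest query order).  Unmatched
    detections start new tracks.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    detections = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]
    if len(detections) == 0:
        raise ValueError("detections must contain at least one frame")

    rows = []
    next_id = 0
    prev_ids: np.ndarray | None = None
    for k, pts in enumerate(detections):
        n = pts.shape[0]
        ids = np.full(n, -1, dtype=np.int64)
        if prev_ids is not None and n and prev_ids.size:
            prev = detections[k - 1]
            tree_prev = cKDTree(prev)
            tree_cur = cKDTree(pts)
            d_pc, nn_of_cur = tree_prev.query(pts, k=1)  # per current det
            _, nn_of_prev = tree_cur.query(prev, k=1)  # per previous det
            for j in range(n):
                i = nn_of_cur[j]
                if d_pc[j] <= max_disp and nn_of_prev[i] == j:
                    ids[j] = prev_ids[i]
        fresh = ids < 0
        n_new = int(fresh.sum())
        ids[fresh] = np.arange(next_id, next_id + n_new)
        next_id += n_new
        for j in range(n):
            rows.append((ids[j], k, k * dt_minutes / 60.0, pts[j, 0], pts[j, 1]))
        prev_ids = ids
    df = pd.DataFrame(rows, columns=["track_id", "frame", "time_h", "x_um", "y_um"])
    df["compartment"] = compartment
    df["phase"] = np.nan
    df["ch1"] = np.nan
    df["ch2"] = np.nan
    return df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)


# ----------------------------------------------------------------------
def estimate_drift(table: pd.DataFrame,
                   reference_compartment: str = "follicle") -> pd.DataFrame:
    """Per-frame stage translation from a static reference compartment.

    Translation at frame k is the cumulative sum of the per-step median
    displacement vector of the reference agents (median over agents present
    in both frames), so a minority of moving outliers is ignored.  Frame 0
    is (0, 0) by definition.  Requires >= 3 reference tracks.
    """
    validate_tracks(table)
    ref = table[table["compartment"] == reference_compartment]
    n_ref = ref["track_id"].nunique()
    if n_ref < 3:
        raise ValueError(
            f"need >= 3 reference ({reference_compartment}) tracks, found {n_ref}")
    frames = np.sort(table["frame"].unique())
    by_frame = {f: g.set_index("track_id")[["x_um", "y_um"]]
                for f, g in ref.groupby("frame")}
    dx = np.zeros(frames.size)
    dy = np.zeros(frames.size)
    for k in range(1, frames.size):
        a = by_frame.get(frames[k - 1])
        b = by_frame.get(frames[k])
        if a is None or b is None:
            continue
        common = a.index.intersection(b.index)
        if len(common) == 0:
            continue
        step = b.loc[common].to_numpy() - a.loc[common].to_numpy()
        dx[k] = float(np.median(step[:, 0]))
        dy[k] = float(np.median(step[:, 1]))
    return pd.DataFrame({
        "frame": frames,
        "dx_um": np.cumsum(dx),
        "dy_um": np.cumsum(dy),
    })


def apply_drift(table: pd.DataFrame, drift: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-frame translation from x/y; other columns untouched."""
    missing = set(table["frame"].unique()) - set(drift["frame"])
    if missing:
        raise ValueError(f"drift series missing frame(s): {sorted(missing)[:5]}")
    out = table.merge(drift, on="frame", how="left")
    out["x_um"] = out["x_um"] - out["dx_um"]
    out["y_um"] = out["y_um"] - out["dy_um"]
    return out.drop(columns=["dx_um", "dy_um"])
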