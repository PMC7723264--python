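"""Per-track motility metrics and binned migration analyses.

Conventions (each deliberate, each switchable where noted):

* "velocity" is path length / elapsed time (a speed, µm/min), not net
  displacement / time — displacement is reported separately.
* "migratory" means net displacement strictly greater than 10 µm over an
  8-h window, measured between the window's first point and the point
  closest to first + 8 h.
* persistence is net displacement / path length in [0, 1] for tracks whose
  mean speed strictly exceeds a 5 µm/h gate (undefined below the gate);
  the reciprocal convention is available via ``ratio="path_over_net"``.
* direction angles are measured clockwise from the wound-ward unit vector
  (pointing from the track start toward the nearest wound edge): 0° heads
  straight at the wound, 180° straight away.

Cell-size context: 380 µm² is the conventional area cut separating basal
from suprabasal cells; it is exposed as
:data:`SUPRABASAL_AREA_THRESHOLD` for joining segmented areas to records.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import distance_to_wound

__all__ = [
    "SUPRABASAL_AREA_THRESHOLD",
    "mean_speed", "is_migratory", "persistence", "direction_angle",
    "rose_histogram", "motility_records", "velocity_by_distance",
    "displacement_by_compartment", "DISTANCE_BIN_EDGES_UM",
]

#: Area (µm²) above which a cell is labeled suprabasal-sized.
SUPRABASAL_AREA_THRESHOLD = 380.0

#: Default distance bins (µm from the wound edge): <0.5 mm, 0.5–1 mm, >1 mm.
DISTANCE_BIN_EDGES_UM = (500.0, 1000.0)


def _as_track(track):
    """Accept a track DataFrame (time_h, x_um, y_um) or (t_min, x, y) arrays."""
    if isinstance(track, pd.DataFrame):
        t = track["time_h"].to_numpy(float) * 60.0
        x = track["x_um"].to_numpy(float)
        y = track["y_um"].to_numpy(float)
    else:
        t, x, y = (np.asarray(a, dtype=float) for a in track)
    order = np.argsort(t, kind="mergesort")
    return t[order], x[order], y[order]


def _path_and_net(x, y):
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    net = float(math.hypot(x[-1] - x[0], y[-1] - y[0]))
    return path, net


def mean_speed(track) -> float:
    """Total path length / total elapsed time, in µm/min."""
    t, x, y = _as_track(track)
    if t.size < 2:
        raise ValueError("mean_speed needs a track with >= 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("track times must be strictly increasing")
    path, _ = _path_and_net(x, y)
    return path / (t[-1] - t[0])


def is_migratory(track, window: float = 8.0, threshold: float = 10.0) -> bool:
    """Net displacement strictly exceeding ``threshold`` µm across a window
    of ``window`` hours measured from the first point (endpoint = the point
    closest in time to first + window)."""
    t, x, y = _as_track(track)
    if t.size < 2:
        raise ValueError("is_migratory needs a track with >= 2 points")
    span_h = (t[-1] - t[0]) / 60.0
    if span_h + 1e-9 < window:
        raise ValueError(
            f"track spans {span_h:.2f} h, shorter than the {window} h window")
    target = t[0] + window * 60.0
    j = int(np.argmin(np.abs(t - target)))
    net = math.hypot(x[j] - x[0], y[j] - y[0])
    return net > threshold


def persistence(track, speed_gate: float = 5.0,
                ratio: str = "net_over_path") -> float | None:
    """Directional persistence of a migratory track, or None below the gate.

    ``speed_gate`` is in µm/h.  Default ratio net/path lies in [0, 1]
    (1 = perfectly straight); ``ratio="path_over_net"`` gives the
    reciprocal in [1, ∞).
    """
    t, x, y = _as_track(track)
    if t.size < 2:
        raise ValueError("persistence needs a track with >= 2 points")
    path, net = _path_and_net(x, y)
    speed_um_h = path / (t[-1] - t[0]) * 60.0
    if not speed_um_h > speed_gate:
        return None
    assert path > 0, "a passing speed gate implies movement"
    if ratio == "net_over_path":
        return net / path
    if ratio == "path_over_net":
        return math.inf if net == 0 else path / net
    raise ValueError(f"unknown ratio {ratio!r}")


def direction_angle(track, wound_half_width: float) -> float | None:
    """Angle (degrees, [0, 360)) between the net-displacement vector and the
    wound-ward direction at the track start; None for zero net displacement."""
    t, x, y = _as_track(track)
    if t.size < 2:
        raise ValueError("direction_angle needs a track with >= 2 points")
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    if math.hypot(dx, dy) < 1e-12:
        return None
    side = math.copysign(1.0, x[0]) if x[0] != 0 else 1.0
    wound_ward = (-side, 0.0)  # toward the nearest wound edge
    ang = math.degrees(
        math.atan2(wound_ward[1], wound_ward[0]) - math.atan2(dy, dx))
    return ang % 360.0


def rose_histogram(angles, n_bins: int = 24) -> pd.DataFrame:
    """Counts over equal angular sectors covering [0, 360)."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    a = np.asarray([x for x in angles if x is not None], dtype=float) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    return pd.DataFrame({
        "sector_lo_deg": edges[:-1],
        "sector_hi_deg": edges[1:],
        "count": counts,
    })


# ----------------------------------------------------------------------
def motility_records(tracks: pd.DataFrame, wound_half_width: float,
                     t_start: float | None = None, t_end: float | None = None,
                     migratory_window: float = 8.0,
                     migratory_threshold: float = 10.0,
                     speed_gate: float = 5.0) -> pd.DataFrame:
    """Per-track motility summary over an analysis window.

    Tracks are clipped to [t_start, t_end] (hours); tracks with fewer than
    two points in the window are dropped, and the migratory flag is NaN for
    tracks shorter than the migratory window.  ``initial_distance_um`` is
    the distance to the wound edge at the first point in the window.
    """
    df = tracks
    if t_start is not None:
        df = df[df["time_h"] >= t_start - 1e-9]
    if t_end is not None:
        df = df[df["time_h"] <= t_end + 1e-9]
    records = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        if len(g) < 2:
            continue
        t = g["time_h"].to_numpy(float) * 60.0
        x = g["x_um"].to_numpy(float)
        y = g["y_um"].to_numpy(float)
        path, net = _path_and_net(x, y)
        duration = t[-1] - t[0]
        speed = path / duration
        span_h = duration / 60.0
        if span_h + 1e-9 >= migratory_window:
            migratory = is_migratory((t, x, y), migratory_window,
                                     migratory_threshold)
        else:
            migratory = np.nan
        pers = persistence((t, x, y), speed_gate)
        ang = direction_angle((t, x, y), wound_half_width)
        records.append({
            "track_id": tid,
            "compartment": g["compartment"].iloc[0],
            "phase": g["phase"].iloc[0] if "phase" in g else np.nan,
            "initial_distance_um": float(
                distance_to_wound(x[0], wound_half_width)),
            "mean_speed_um_min": speed,
            "net_displacement_um": net,
            "path_length_um": path,
            "persistence": np.nan if pers is None else pers,
            "migratory": migratory,
            "direction_angle_deg": np.nan if ang is None else ang,
        })
    return pd.DataFrame(records)


def _bin_labels(edges):
    e = [0.0, *edges, math.inf]
    return [(e[i], e[i + 1]) for i in range(len(e) - 1)]


def velocity_by_distance(records: pd.DataFrame,
                         bin_edges=DISTANCE_BIN_EDGES_UM) -> pd.DataFrame:
    """Median + IQR of mean speed per initial-distance bin, restricted to
    migratory basal records."""
    if records.empty:
        raise ValueError("records must be nonempty")
    sel = records[(records["compartment"] == "basal")
                  & (records["migratory"] == True)]  # noqa: E712
    rows = []
    for lo, hi in _bin_labels(bin_edges):
        v = sel.loc[(sel["initial_distance_um"] >= lo)
                    & (sel["initial_distance_um"] < hi), "mean_speed_um_min"]
        rows.append({
            "bin_lo_um": lo, "bin_hi_um": hi, "n": int(v.size),
            "median_um_min": float(v.median()) if v.size else np.nan,
            "q25_um_min": float(v.quantile(0.25)) if v.size else np.nan,
            "q75_um_min": float(v.quantile(0.75)) if v.size else np.nan,
        })
    return pd.DataFrame(rows)


def displacement_by_compartment(records: pd.DataFrame,
                                bin_edges=DISTANCE_BIN_EDGES_UM) -> pd.DataFrame:
    """Net-displacement summaries per compartment per distance bin (the
    hair-follicle vs basal comparison; follicle medians sit at ~0)."""
    rows = []
    for comp, g in records.groupby("compartment", sort=True):
        for lo, hi in _bin_labels(bin_edges):
            v = g.loc[(g["initial_distance_um"] >= lo)
                      & (g["initial_distance_um"] < hi),
                      "net_displacement_um"]
            rows.append({
                "compartment": comp, "bin_lo_um": lo, "bin_hi_um": hi,
                "n": int(v.size),
                "median_um": float(v.median()) if v.size else np.nan,
                "q25_um": float(v.quantile(0.25)) if v.size else np.nan,
                "q75_um": float(v.quantile(0.75)) if v.size else np.nan,
            })
    return pd.DataFrame(rows)
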