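"""Neighbor graphs and the original-neighbor-retention statistic.

Neighborhood is approximated by the Delaunay triangulation of cell
centroids pruned at a maximum edge length (default 2x the median
nearest-neighbor distance) — a standard proxy for membrane-contact topology
in an epithelium.  For a focal cell with original neighbor set N0 at time
t0, the retention fraction at time t is |N0 ∩ N(t)| / |N0| with N(t) the
*instantaneous* adjacency, so a neighbor that drifts away and returns
counts again.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "build_graph", "default_max_edge", "retention_fraction",
    "group_retention", "DISTANCE_GROUP_EDGES_UM", "SPEED_GROUP_EDGES",
]

#: Initial-distance grouping (µm): <0.5 mm, 0.5–1 mm, >1 mm.
DISTANCE_GROUP_EDGES_UM = (500.0, 1000.0)
#: Migration-speed grouping (µm/min): <0.08, 0.08–0.18, >0.18.
SPEED_GROUP_EDGES = (0.08, 0.18)

_DEDUP_EPS = 1e-6  # µm, deterministic perturbation for coincident points


def default_max_edge(positions) -> float:
    """2x the median nearest-neighbor distance of the point set."""
    pts = np.asarray(positions, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 positions")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return 2.0 * float(np.median(d[:, 1]))


def _dedup(pts: np.ndarray) -> np.ndarray:
    """Deterministically perturb exact duplicates so qhull sees distinct
    sites; warns because contact topology is ill-defined for coincident
    cells."""
    seen: dict[tuple[float, float], int] = {}
    out = pts.copy()
    n_dup = 0
    for i, (x, y) in enumerate(pts):
        key = (float(x), float(y))
        k = seen.get(key, 0)
        if k:
            n_dup += 1
            out[i, 0] = x + _DEDUP_EPS * k
            out[i, 1] = y + _DEDUP_EPS * ((k % 3) - 1)
        seen[key] = k + 1
    if n_dup:
        warnings.warn(f"perturbed {n_dup} duplicate position(s) by {_DEDUP_EPS} µm")
    return out


def build_graph(positions, max_edge: float) -> set[tuple[int, int]]:
    """Adjacency over point indices: Delaunay edges no longer than
    ``max_edge``.  With < 3 points or degenerate (collinear) input, falls
    back to plain distance-cutoff adjacency."""
    if max_edge <= 0:
        raise ValueError("max_edge must be > 0")
    pts = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    pts = _dedup(pts)

    def cutoff_graph():
        tree = cKDTree(pts)
        return {tuple(sorted(p)) for p in tree.query_pairs(max_edge)}

    if n < 3:
        return cutoff_graph()
    try:
        tri = Delaunay(pts)
    except QhullError:
        return cutoff_graph()
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            if i > j:
                i, j = j, i
            if np.hypot(*(pts[i] - pts[j])) <= max_edge:
                edges.add((i, j))
    return edges


# ----------------------------------------------------------------------
def retention_fraction(tracks: pd.DataFrame, t0: float, horizon: float,
                       max_edge: float | None = None) -> pd.DataFrame:
    """Per-focal-cell time series of the original-neighbor retention.

    Uses every row of ``tracks`` (filter by compartment first if needed).
    All frames from t0 to t0 + horizon must exist; cells whose track ends
    early are reported up to their last frame (censoring at track end).
    Focal cells with no neighbor at t0 are excluded; their number is stored
    in ``result.attrs['n_no_neighbors']``.

    Returns columns: track_id, time_h, fraction.
    """
    times = np.sort(tracks["time_h"].unique())
    window = times[(times >= t0 - 1e-9) & (times <= t0 + horizon + 1e-9)]
    if window.size < 2:
        raise ValueError(
            f"no frames inside [{t0}, {t0 + horizon}] h (have {times.size} frames)")
    frames = {t: g for t, g in tracks.groupby("time_h") if t in set(window)}

    g0 = frames[window[0]].sort_values("track_id")
    ids0 = g0["track_id"].to_numpy()
    pts0 = g0[["x_um", "y_um"]].to_numpy(float)
    if max_edge is None:
        max_edge = default_max_edge(pts0)
    adj0 = _adjacency_by_id(ids0, pts0, max_edge)

    n_no_neighbors = sum(1 for v in adj0.values() if not v)
    focal = {i: nbrs for i, nbrs in adj0.items() if nbrs}

    rows = []
    for t in window:
        g = frames[t].sort_values("track_id")
        ids = g["track_id"].to_numpy()
        present = set(ids.tolist())
        adj = (adj0 if t == window[0]
               else _adjacency_by_id(ids, g[["x_um", "y_um"]].to_numpy(float),
                                     max_edge))
        for fid, n0 in focal.items():
            if fid not in present:
                continue  # censored at track end
            nt = adj.get(fid, set())
            rows.append((fid, float(t), len(n0 & nt) / len(n0)))
    out = pd.DataFrame(rows, columns=["track_id", "time_h", "fraction"])
    out.attrs["n_no_neighbors"] = n_no_neighbors
    out.attrs["max_edge_um"] = float(max_edge)
    return out


def _adjacency_by_id(ids: np.ndarray, pts: np.ndarray,
                     max_edge: float) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {int(i): set() for i in ids}
    if ids.size < 2:
        return adj
    for i, j in build_graph(pts, max_edge):
        a, b = int(ids[i]), int(ids[j])
        adj[a].add(b)
        adj[b].add(a)
    return adj


# ----------------------------------------------------------------------
def group_retention(series: pd.DataFrame, values: pd.Series,
                    grouping: str = "distance",
                    edges=None, unit_col: str | None = None) -> pd.DataFrame:
    """Mean ± SEM retention curves per group.

    ``values`` maps track_id -> grouping value: initial distance to the
    wound edge (µm) for ``grouping="distance"`` or mean migration speed
    (µm/min) for ``grouping="speed"``; default bin edges are the
    conventional <0.5/0.5–1/>1 mm and <0.08/0.08–0.18/>0.18 µm/min.
    Aggregation unit is the cell unless ``unit_col`` names a column of
    ``series`` identifying a coarser unit (e.g. an imaging position), in
    which case cell curves are first averaged within each unit.

    Returns columns: group, time_h, mean_fraction, sem, n_units.
    """
    if grouping == "distance":
        edges = DISTANCE_GROUP_EDGES_UM if edges is None else edges
    elif grouping == "speed":
        edges = SPEED_GROUP_EDGES if edges is None else edges
    else:
        raise ValueError(f"grouping must be 'distance' or 'speed', got {grouping!r}")
    e = list(edges)
    labels = [f"<{e[0]}", *[f"{a}-{b}" for a, b in zip(e[:-1], e[1:])], f">{e[-1]}"]
    bins = [-np.inf, *e, np.inf]

    df = series.copy()
    df["group"] = pd.cut(df["track_id"].map(values), bins=bins, labels=labels)
    if unit_col is not None:
        df = (df.groupby([unit_col, "group", "time_h"], observed=True)["fraction"]
              .mean().reset_index())
    rows = []
    for lab in labels:
        g = df[df["group"] == lab]
        for t, vals in g.groupby("time_h")["fraction"]:
            v = vals.to_numpy(float)
            sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
            rows.append({
                "group": lab, "time_h": float(t),
                "mean_fraction": float(v.mean()),
                "sem": sem, "n_units": int(v.size),
            })
        if g.empty:
            rows.append({"group": lab, "time_h": np.nan,
                         "mean_fraction": np.nan, "sem": np.nan, "n_units": 0})
    return pd.DataFrame(rows)
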