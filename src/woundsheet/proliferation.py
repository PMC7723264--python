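"""Cell-cycle (Fucci) classification, zone-binned proliferation, EdU
counting, scratch-size regressions and phase-stratified motility.

Fucci logic: channel 1 reports G1, channel 2 reports S/G2; a cell is called
S/G2 when ch2 > ch1, ties go to G1.  Zone fractions use 200-µm distance
zones out to 1 mm from the wound edge.  Statistical tests are delegated to
standard routines (Welch t for velocity, Kruskal–Wallis for persistence) —
the quantities feeding them are the contribution here, not test internals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ZONE_EDGES_UM", "RegressionResult",
    "fucci_classify", "fraction_by_zone", "zone_fractions_over_time",
    "edu_fraction", "regress", "compare_by_phase",
]

DEFAULT_ZONE_EDGES_UM = (0.0, 200.0, 400.0, 600.0, 800.0, 1000.0)


def fucci_classify(ch1_g1_intensity, ch2_sg2_intensity):
    """Phase call per cell: 'SG2' where ch2 > ch1 else 'G1' (ties → G1)."""
    ch1 = np.asarray(ch1_g1_intensity, dtype=float)
    ch2 = np.asarray(ch2_sg2_intensity, dtype=float)
    if np.any(ch1 < 0) or np.any(ch2 < 0):
        raise ValueError("intensities must be >= 0")
    out = np.where(ch2 > ch1, "SG2", "G1")
    return out if out.ndim else str(out)


def fraction_by_zone(cells: pd.DataFrame,
                     edges=DEFAULT_ZONE_EDGES_UM,
                     distance_col: str = "distance_to_wound_um",
                     phase_col: str = "phase") -> pd.DataFrame:
    """S/G2 fraction per distance zone.

    ``cells`` needs a distance column (µm >= 0) and a phase column with
    values 'G1'/'SG2'.  Cells beyond the last edge are excluded; their count
    lands in ``result.attrs['n_excluded']``.  Zones with no cells report
    fraction NaN.
    """
    d = cells[distance_col].to_numpy(float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    sg2 = cells[phase_col].to_numpy() == "SG2"
    e = np.asarray(edges, dtype=float)
    rows = []
    for lo, hi in zip(e[:-1], e[1:]):
        m = (d >= lo) & (d < hi)
        n = int(m.sum())
        k = int(sg2[m].sum())
        rows.append({"zone_lo_um": lo, "zone_hi_um": hi,
                     "n_total": n, "n_sg2": k,
                     "fraction_sg2": k / n if n else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int((d >= e[-1]).sum())
    return out


def zone_fractions_over_time(per_frame_cells: pd.DataFrame,
                             edges=DEFAULT_ZONE_EDGES_UM,
                             t_start: float | None = None,
                             t_end: float | None = None,
                             time_col: str = "time_h",
                             mode: str = "time_average",
                             **kwargs) -> pd.DataFrame:
    """Zone S/G2 fractions over an analysis window.

    ``mode="time_average"`` (default) computes the per-frame zone fraction
    and averages across frames; ``mode="pooled"`` pools all cell-frames
    before computing one fraction per zone.
    """
    df = per_frame_cells
    if t_start is not None:
        df = df[df[time_col] >= t_start - 1e-9]
    if t_end is not None:
        df = df[df[time_col] <= t_end + 1e-9]
    if df.empty:
        raise ValueError("no cells inside the analysis window")
    if mode == "pooled":
        return fraction_by_zone(df, edges, **kwargs)
    if mode != "time_average":
        raise ValueError(f"mode must be 'time_average' or 'pooled', got {mode!r}")
    per_frame = [fraction_by_zone(g, edges, **kwargs)
                 for _, g in df.groupby(time_col)]
    out = per_frame[0][["zone_lo_um", "zone_hi_um"]].copy()
    fr = np.array([p["fraction_sg2"].to_numpy() for p in per_frame])
    out["fraction_sg2"] = np.nanmean(fr, axis=0)
    out["n_total"] = np.array([p["n_total"].to_numpy() for p in per_frame]).sum(axis=0)
    out["n_sg2"] = np.array([p["n_sg2"].to_numpy() for p in per_frame]).sum(axis=0)
    out["n_frames"] = len(per_frame)
    return out


def edu_fraction(n_positive: int, n_total_basal: int) -> float:
    """EdU-positive cells per total basal cells (a plain ratio, bounds
    checked).  The simulator's divided-within-lookback flags are the
    matching synthetic stand-in for EdU positivity."""
    if n_total_basal <= 0:
        raise ValueError("n_total_basal must be > 0")
    if not 0 <= n_positive <= n_total_basal:
        raise ValueError(
            f"need 0 <= n_positive <= n_total_basal, got {n_positive}/{n_total_basal}")
    return n_positive / n_total_basal


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def regress(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with R² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    fit = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    resid = y - (fit.intercept + fit.slope * x)
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=r2, n=int(x.size))


def compare_by_phase(records: pd.DataFrame,
                     zone_edges=DEFAULT_ZONE_EDGES_UM,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-zone comparison of G1 vs S/G2 motility.

    Velocity is compared with an unpaired (Welch) t test, persistence with
    the rank-based Kruskal–Wallis test.  Zones where a phase is absent (or
    has a single record) get NaN p-values and a warning, not an error.
    """
    phases = set(records["phase"].dropna().unique())
    if not {"G1", "SG2"} <= phases:
        raise ValueError(f"records must contain both phases, found {sorted(phases)}")
    e = np.asarray(zone_edges, dtype=float)
    rows = []
    for lo, hi in zip(e[:-1], e[1:]):
        zone = records[(records["initial_distance_um"] >= lo)
                       & (records["initial_distance_um"] < hi)]
        g1 = zone[zone["phase"] == "G1"]
        sg2 = zone[zone["phase"] == "SG2"]
        row = {
            "zone_lo_um": lo, "zone_hi_um": hi,
            "n_g1": len(g1), "n_sg2": len(sg2),
            "mean_speed_g1": g1["mean_speed_um_min"].mean(),
            "mean_speed_sg2": sg2["mean_speed_um_min"].mean(),
            "t_stat": np.nan, "p_velocity": np.nan, "p_persistence": np.nan,
        }
        if len(g1) > 1 and len(sg2) > 1:
            t, p = stats.ttest_ind(g1["mean_speed_um_min"],
                                   sg2["mean_speed_um_min"], equal_var=False)
            row["t_stat"], row["p_velocity"] = float(t), float(p)
            pg1 = g1["persistence"].dropna()
            psg2 = sg2["persistence"].dropna()
            if len(pg1) > 1 and len(psg2) > 1:
                row["p_persistence"] = float(stats.kruskal(pg1, psg2).pvalue)
        else:
            warnings.warn(
                f"zone {lo:.0f}-{hi:.0f} µm: a phase has < 2 records, tests skipped")
        row["significant_velocity"] = (row["p_velocity"] < alpha
                                       if np.isfinite(row["p_velocity"]) else False)
        rows.append(row)
    return pd.DataFrame(rows)
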