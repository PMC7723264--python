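"""Pipeline orchestration: simulate → export → analyze → report.

One configuration document and one master seed drive every stage.  Each
stage draws from a seed derived as CRC32(stage name) mixed into the master
seed, so adding a stage never shifts another stage's random stream, and
reruns with identical inputs reproduce identical CSV outputs byte for byte
(figures are exempt).
"""

from __future__ import annotations

import json
import time as _time
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import motility as mot
from . import neighbors as nbr
from . import proliferation as prolif
from . import segmentation as seg
from . import tracks as trk
from .config import SimConfig, load_config
from .render import RenderParams, default_cell_radius, render_fucci, render_membrane_image
from .simulate import (SimulationResult, closure_time, distance_to_wound,
                       entry_time, export_tracks, simulate)

__all__ = [
    "derive_seed", "run_pipeline", "make_report",
    "fucci_zone_percentages", "headline_metrics", "ALL_STAGES",
]

ALL_STAGES = ("simulate", "render", "segment", "motility", "neighbors",
              "prolif", "report")

#: Analysis window (h post wounding) used by the track-based analyses.
ANALYSIS_WINDOW_H = (16.0, 24.0)


def derive_seed(master: int, stage: str) -> int:
    """Stage-specific 31-bit seed derived from the master seed."""
    return (int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


# ----------------------------------------------------------------------
# analysis helpers shared by the pipeline, the report and the test suite

def fucci_zone_percentages(result: SimulationResult, seed: int,
                           t_start: float = ANALYSIS_WINDOW_H[0],
                           t_end: float = ANALYSIS_WINDOW_H[1],
                           edges=prolif.DEFAULT_ZONE_EDGES_UM,
                           params: RenderParams | None = None) -> pd.DataFrame:
    """Zone S/G2 percentages via the full measurement loop.

    For every frame in the window, basal nuclei are rendered as two-channel
    Fucci intensities, phases are called from the intensities alone, and
    the per-frame zone fractions are averaged over the window.
    """
    params = params or RenderParams()
    cfg = result.config
    tables = []
    for k, frame in enumerate(result.frames):
        if not (t_start - 1e-9 <= frame.time <= t_end + 1e-9):
            continue
        tab = render_fucci(frame, params, seed=derive_seed(seed, f"fucci{k}"))
        tab = tab[tab["compartment"] == "basal"].copy()
        tab["phase"] = prolif.fucci_classify(tab["ch1"], tab["ch2"])
        tab["distance_to_wound_um"] = distance_to_wound(
            tab["x_um"], cfg.wound_half_width)
        tab["time_h"] = frame.time
        tables.append(tab)
    cells = pd.concat(tables, ignore_index=True)
    out = prolif.zone_fractions_over_time(cells, edges=edges,
                                          mode="time_average")
    out["percent_sg2"] = 100.0 * out["fraction_sg2"]
    return out


def headline_metrics(result: SimulationResult, seed: int = 0) -> dict:
    """The run's headline numbers: near/far median migratory speeds, zone
    S/G2 percentages, entry and closure times."""
    cfg = result.config
    tracks = export_tracks(result)
    records = mot.motility_records(tracks, cfg.wound_half_width,
                                   *ANALYSIS_WINDOW_H)
    vel = mot.velocity_by_distance(records)
    zones = fucci_zone_percentages(result, seed=seed)
    near = vel.loc[vel["bin_lo_um"] == 0.0].iloc[0]
    far = vel.iloc[-1]
    return {
        "median_speed_near_um_min": float(near["median_um_min"]),
        "n_migratory_near": int(near["n"]),
        "median_speed_far_um_min": float(far["median_um_min"]),
        "n_migratory_far": int(far["n"]),
        "percent_sg2_0_200": float(
            zones.loc[zones["zone_lo_um"] == 0.0, "percent_sg2"].iloc[0]),
        "percent_sg2_200_400": float(
            zones.loc[zones["zone_lo_um"] == 200.0, "percent_sg2"].iloc[0]),
        "n_zone_200_400_per_frame": int(
            zones.loc[zones["zone_lo_um"] == 200.0, "n_total"].iloc[0]
            // max(1, int(zones["n_frames"].iloc[0]))),
        "entry_time_h": float(entry_time(result)),
        "closure_time_h": float(closure_time(result)),
    }


# ----------------------------------------------------------------------
def run_pipeline(config: SimConfig | str | Path | None = None, seed: int = 0,
                 out_dir: str | Path = "woundsheet_run",
                 stages=None, force: bool = False) -> dict:
    """Execute the pipeline stages in dependency order.

    Returns the run manifest (also written to ``manifest.json``): config
    snapshot, seed, per-stage outputs and wall times, warnings.  An existing
    ``out_dir`` is refused unless ``force`` is set.  With a stage subset,
    later stages reuse ``tracks.csv`` already present in ``out_dir``.
    """
    if config is None:
        cfg = SimConfig()
    elif isinstance(config, SimConfig):
        cfg = config
    else:
        cfg = load_config(config)
    cfg.validate()
    stages = list(stages) if stages else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)

    from . import __version__

    manifest: dict = {
        "config": cfg.to_dict(), "seed": int(seed),
        "package_version": __version__,
        "stages": {}, "warnings": [],
    }
    result: SimulationResult | None = None
    tracks_df: pd.DataFrame | None = None
    w = cfg.wound_half_width

    def _stage(name):
        t0 = _time.perf_counter()

        def done(outputs: dict):
            manifest["stages"][name] = {
                "outputs": {k: str(v) for k, v in outputs.items()},
                "wall_time_s": round(_time.perf_counter() - t0, 3),
            }
        return done

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "simulate" in stages:
            done = _stage("simulate")
            result = simulate(cfg, seed=derive_seed(seed, "simulate"))
            tracks_df = export_tracks(result)
            path = out / "tracks.csv"
            trk.write_tracks(tracks_df, path)
            gt_path = out / "ground_truth.json"
            gt_path.write_text(json.dumps(result.ground_truth, indent=1))
            done({"tracks": path, "ground_truth": gt_path})
        if tracks_df is None and (set(stages) & {"motility", "neighbors", "prolif"}):
            tracks_df = trk.read_tracks(out / "tracks.csv")

        if "render" in stages or "segment" in stages:
            if result is None:
                raise ValueError("render/segment stages need the simulate stage")
            done = _stage("render-segment")
            frame = result.frame_at(ANALYSIS_WINDOW_H[0])
            area_rows = []
            for layer, arange in (("basal", cfg.basal_target_area_range),
                                  ("suprabasal", cfg.suprabasal_target_area_range)):
                params = RenderParams(max_cell_radius=default_cell_radius(arange))
                rimg = render_membrane_image(
                    frame, layer, params,
                    bbox=(w + 50.0, w + 450.0, -cfg.domain_half_depth,
                          cfg.domain_half_depth),
                    seed=derive_seed(seed, f"render-{layer}"))
                prob = seg.pixel_classify(rimg.image)
                labels = seg.segment(prob, threshold=0.15)
                table = seg.region_props(labels, params.pixel_size,
                                         origin=rimg.origin, layer=layer)
                table = seg.filter_regions(table)
                table = seg.assign_wound_distance(table, w)
                area_rows.append(table)
            regions = pd.concat(area_rows, ignore_index=True)
            rpath = out / "regions.csv"
            regions.to_csv(rpath, index=False, lineterminator="\n")
            done({"regions": rpath})

        records = None
        if "motility" in stages:
            done = _stage("motility")
            records = mot.motility_records(tracks_df, w, *ANALYSIS_WINDOW_H)
            mpath = out / "motility.csv"
            records.to_csv(mpath, index=False, lineterminator="\n")
            vel = mot.velocity_by_distance(records)
            vpath = out / "velocity_by_distance.csv"
            vel.to_csv(vpath, index=False, lineterminator="\n")
            basal = records[records["compartment"] == "basal"]
            rose = mot.rose_histogram(basal["direction_angle_deg"].dropna())
            rpath = out / "rose.csv"
            rose.to_csv(rpath, index=False, lineterminator="\n")
            done({"records": mpath, "velocity": vpath, "rose": rpath})

        if "neighbors" in stages:
            done = _stage("neighbors")
            basal_tracks = tracks_df[tracks_df["compartment"] == "basal"]
            series = nbr.retention_fraction(basal_tracks, ANALYSIS_WINDOW_H[0],
                                            ANALYSIS_WINDOW_H[1] - ANALYSIS_WINDOW_H[0])
            t0_frame = basal_tracks[np.isclose(basal_tracks["time_h"],
                                               ANALYSIS_WINDOW_H[0])]
            dist = pd.Series(
                distance_to_wound(t0_frame["x_um"].to_numpy(), w),
                index=t0_frame["track_id"].to_numpy())
            curves = nbr.group_retention(series, dist, grouping="distance")
            npath = out / "retention.csv"
            curves.to_csv(npath, index=False, lineterminator="\n")
            done({"curves": npath})

        if "prolif" in stages:
            if result is None:
                raise ValueError("prolif stage needs the simulate stage "
                                 "(Fucci intensities come from the renderer)")
            done = _stage("prolif")
            zones = fucci_zone_percentages(result, seed=seed)
            zpath = out / "zone_fractions.csv"
            zones.to_csv(zpath, index=False, lineterminator="\n")
            done({"zones": zpath})

        manifest["warnings"] = [str(c.message) for c in caught]

    if "report" in stages:
        done = _stage("report")
        outputs = make_report(out, result=result, seed=seed)
        done(outputs)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ----------------------------------------------------------------------
def make_report(out_dir: str | Path, result: SimulationResult | None = None,
                seed: int = 0) -> dict:
    """Deterministic figure files + one summary CSV of headline numbers.

    Figures are rendered from the stage CSVs in ``out_dir``; missing stage
    outputs skip the corresponding figure with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    made: dict = {}

    def _plot(name, fn):
        try:
            fig = fn()
        except FileNotFoundError as err:
            warnings.warn(f"report: skipping {name}: {err}")
            return
        path = out / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made[name] = path

    def rose_fig():
        rose = pd.read_csv(out / "rose.csv")
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(projection="polar")
        theta = np.deg2rad((rose["sector_lo_deg"] + rose["sector_hi_deg"]) / 2)
        width = np.deg2rad(rose["sector_hi_deg"] - rose["sector_lo_deg"])
        ax.bar(theta, rose["count"], width=width, bottom=0.0)
        ax.set_theta_zero_location("N")
        ax.set_title("Migration direction (0° = wound-ward)")
        return fig

    def retention_fig():
        curves = pd.read_csv(out / "retention.csv")
        if curves["n_units"].fillna(0).sum() == 0:
            raise FileNotFoundError("retention output is empty")
        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, g in curves.dropna(subset=["time_h"]).groupby("group"):
            g = g.sort_values("time_h")
            ax.plot(g["time_h"], g["mean_fraction"], label=f"{lab} µm")
            ax.fill_between(g["time_h"], g["mean_fraction"] - g["sem"],
                            g["mean_fraction"] + g["sem"], alpha=0.3)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fraction of original neighbors retained")
        ax.legend(title="initial distance")
        return fig

    def velocity_fig():
        vel = pd.read_csv(out / "velocity_by_distance.csv")
        fig, ax = plt.subplots(figsize=(4, 4))
        xs = np.arange(len(vel))
        ax.errorbar(xs, vel["median_um_min"],
                    yerr=[vel["median_um_min"] - vel["q25_um_min"],
                          vel["q75_um_min"] - vel["median_um_min"]],
                    fmt="o", capsize=4)
        ax.set_xticks(xs)
        ax.set_xticklabels(["<0.5 mm", "0.5–1 mm", ">1 mm"])
        ax.set_ylabel("median speed (µm/min)")
        return fig

    def zones_fig():
        zones = pd.read_csv(out / "zone_fractions.csv")
        fig, ax = plt.subplots(figsize=(5, 4))
        labels = [f"{int(a)}–{int(b)}" for a, b in
                  zip(zones["zone_lo_um"], zones["zone_hi_um"])]
        ax.bar(labels, zones["percent_sg2"], color="seagreen")
        ax.set_xlabel("distance to wound (µm)")
        ax.set_ylabel("% S/G2 cells")
        return fig

    _plot("rose.png", rose_fig)
    _plot("retention.png", retention_fig)
    _plot("velocity_by_distance.png", velocity_fig)
    _plot("zone_fractions.png", zones_fig)

    summary: dict = {}
    vel_path = out / "velocity_by_distance.csv"
    if vel_path.exists():
        vel = pd.read_csv(vel_path)
        summary["median_speed_near_um_min"] = float(vel["median_um_min"].iloc[0])
        summary["median_speed_far_um_min"] = float(vel["median_um_min"].iloc[-1])
    z_path = out / "zone_fractions.csv"
    if z_path.exists():
        zones = pd.read_csv(z_path)
        summary["percent_sg2_0_200"] = float(zones["percent_sg2"].iloc[0])
        summary["percent_sg2_200_400"] = float(zones["percent_sg2"].iloc[1])
    if result is not None:
        summary["entry_time_h"] = float(entry_time(result))
        summary["closure_time_h"] = float(closure_time(result))
    spath = out / "summary.csv"
    pd.DataFrame([summary]).to_csv(spath, index=False, lineterminator="\n")
    made["summary.csv"] = spath
    return {k: str(v) for k, v in made.items()}
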