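"""Shared fixtures.

Heavy simulation products are session-scoped so the full default-scale model
runs once and every analysis test reuses it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from woundsheet import SimConfig, Follicle, simulate, export_tracks, entry_time
from woundsheet.motility import motility_records
from woundsheet.neighbors import group_retention, retention_fraction
from woundsheet.simulate import distance_to_wound

DEFAULT_SEED = 1
TEN_SEEDS = tuple(range(1, 11))
NULL_SEEDS = tuple(range(101, 121))


@pytest.fixture(scope="session")
def default_result():
    """One default-scale simulation shared across the suite."""
    return simulate(SimConfig(), seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_tracks(default_result):
    return export_tracks(default_result)


@pytest.fixture(scope="session")
def default_records(default_tracks, default_result):
    cfg = default_result.config
    return motility_records(default_tracks, cfg.wound_half_width, 16.0, 24.0)


def small_config(**overrides) -> SimConfig:
    """A fast, reduced-domain configuration for unit tests."""
    base = dict(
        domain_half_extent=400.0,
        domain_half_depth=60.0,
        t_end=24.0,
        follicles=[Follicle((250.0, 0.0), 30.0)],
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture()
def tiny_config():
    return small_config()


def retention_group_means(tracks: pd.DataFrame, wound_half_width: float,
                          t0: float = 16.0, horizon: float = 8.0) -> dict:
    """Final-time retention means of the <0.5 / 0.5–1 / >1 mm groups."""
    basal = tracks[tracks["compartment"] == "basal"]
    series = retention_fraction(basal, t0, horizon)
    t0_rows = basal[np.isclose(basal["time_h"], t0)]
    dist = pd.Series(distance_to_wound(t0_rows["x_um"].to_numpy(), wound_half_width),
                     index=t0_rows["track_id"].to_numpy())
    curves = group_retention(series, dist, grouping="distance")
    last = curves[np.isclose(curves["time_h"], t0 + horizon)]
    means = {row["group"]: row["mean_fraction"] for _, row in last.iterrows()}
    ns = {row["group"]: row["n_units"] for _, row in last.iterrows()}
    return {"means": means, "n_units": ns}


@pytest.fixture(scope="session")
def ten_seed_stats():
    """Entry time and retention-group ordering for ten default-config seeds."""
    stats = []
    for seed in TEN_SEEDS:
        res = simulate(SimConfig(), seed=seed)
        tracks = export_tracks(res)
        stats.append({
            "seed": seed,
            "entry_time_h": entry_time(res),
            "retention": retention_group_means(
                tracks, res.config.wound_half_width),
        })
    return stats
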