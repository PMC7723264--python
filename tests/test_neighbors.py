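import numpy as np
import pandas as pd
import pytest

from woundsheet.neighbors import (build_graph, default_max_edge,
                                  group_retention, retention_fraction)

from oracles import delaunay_edges_bruteforce

BIG = 1e9


def test_triangle_within_reach_has_three_edges():
    pts = [(0.0, 0.0), (10.0, 0.0), (5.0, 8.0)]
    assert build_graph(pts, max_edge=20.0) == {(0, 1), (0, 2), (1, 2)}


def test_distant_pair_has_no_edge():
    assert build_graph([(0.0, 0.0), (30.0, 0.0)], max_edge=20.0) == set()


def test_adjacent_pair_without_triangulation():
    assert build_graph([(0.0, 0.0), (5.0, 0.0)], max_edge=20.0) == {(0, 1)}


def test_collinear_points_fall_back_to_distance_cutoff():
    pts = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0), (30.0, 0.0)]
    edges = build_graph(pts, max_edge=12.0)
    assert edges == {(0, 1), (1, 2), (2, 3)}


def test_duplicate_positions_are_perturbed_with_a_warning():
    pts = [(0.0, 0.0), (0.0, 0.0), (10.0, 0.0)]
    with pytest.warns(UserWarning, match="duplicate"):
        edges = build_graph(pts, max_edge=20.0)
    assert (0, 1) in edges


def test_four_point_instance_matches_the_circumcircle_oracle():
    pts = [(0.0, 0.0), (2.0, 0.0), (1.0, 1.0), (1.0, 3.0)]
    assert build_graph(pts, BIG) == delaunay_edges_bruteforce(pts, BIG)


@pytest.mark.parametrize("seed", range(30))
def test_random_instances_match_the_circumcircle_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    pts = rng.uniform(0, 100, size=(n, 2))
    assert build_graph(pts, BIG) == delaunay_edges_bruteforce(pts, BIG)


def test_graph_is_symmetric_by_construction():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 50, size=(20, 2))
    edges = build_graph(pts, max_edge=default_max_edge(pts))
    for i, j in edges:
        assert i < j  # canonical unordered representation, no self-edges
        assert i != j


# ----------------------------------------------------------------------
def moving_cloud(offsets, n=9, seed=0):
    """Track table of a point cloud rigidly translated by per-frame offsets."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 60, size=(n, 2))
    rows = []
    for k, (ox, oy) in enumerate(offsets):
        for i in range(n):
            rows.append((i, k, k * 0.5, base[i, 0] + ox, base[i, 1] + oy, "basal"))
    return pd.DataFrame(rows, columns=["track_id", "frame", "time_h",
                                       "x_um", "y_um", "compartment"])


def test_retention_is_one_at_the_reference_time():
    tracks = moving_cloud([(0, 0), (5, 2), (9, 1)])
    series = retention_fraction(tracks, t0=0.0, horizon=1.0)
    assert (series.loc[series["time_h"] == 0.0, "fraction"] == 1.0).all()


def test_rigid_translation_preserves_every_neighbor():
    tracks = moving_cloud([(0, 0), (12, -3), (25, 4), (40, 0)])
    series = retention_fraction(tracks, t0=0.0, horizon=1.5)
    assert (series["fraction"] == 1.0).all()


def test_teleported_focal_cell_loses_all_neighbors():
    tracks = moving_cloud([(0, 0), (0, 0)])
    jump = (tracks["track_id"] == 0) & (tracks["frame"] == 1)
    tracks.loc[jump, ["x_um", "y_um"]] = [5000.0, 5000.0]
    series = retention_fraction(tracks, t0=0.0, horizon=0.5, max_edge=30.0)
    at_t1 = series[(series["track_id"] == 0) & (series["time_h"] == 0.5)]
    assert at_t1["fraction"].iloc[0] == 0.0


def test_censoring_reports_cells_only_up_to_their_last_frame():
    tracks = moving_cloud([(0, 0), (1, 0), (2, 0)])
    tracks = tracks[~((tracks["track_id"] == 3) & (tracks["frame"] == 2))]
    series = retention_fraction(tracks, t0=0.0, horizon=1.0)
    t_of_3 = series.loc[series["track_id"] == 3, "time_h"].max()
    assert t_of_3 == 0.5


def test_hand_built_frames_match_brute_force_recomputation():
    """Retention on a 6-cell, 3-frame configuration equals a from-scratch
    recomputation with the oracle adjacency."""
    frames_xy = [
        [(0, 0), (10, 0), (5, 8), (18, 4), (2, 14), (14, 12)],
        [(0, 0), (11, 1), (6, 9), (25, 4), (2, 15), (15, 12)],
        [(0, 0), (12, 2), (7, 9), (40, 4), (3, 16), (16, 13)],
    ]
    max_edge = 15.0
    rows = []
    for k, pts in enumerate(frames_xy):
        for i, (x, y) in enumerate(pts):
            rows.append((i, k, k * 0.5, float(x), float(y), "basal"))
    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "time_h",
                                         "x_um", "y_um", "compartment"])
    series = retention_fraction(tracks, 0.0, 1.0, max_edge=max_edge)

    adj = []
    for pts in frames_xy:
        edges = delaunay_edges_bruteforce(np.asarray(pts, float), max_edge)
        a = {i: set() for i in range(6)}
        for i, j in edges:
            a[i].add(j)
            a[j].add(i)
        adj.append(a)
    for i in range(6):
        n0 = adj[0][i]
        if not n0:
            continue
        for k in range(3):
            expected = len(n0 & adj[k][i]) / len(n0)
            got = series[(series["track_id"] == i)
                         & (series["time_h"] == k * 0.5)]["fraction"].iloc[0]
            assert got == pytest.approx(expected)


def test_focal_cells_without_neighbors_are_excluded_and_counted():
    tracks = moving_cloud([(0, 0), (0, 0)], n=5)
    lone = pd.DataFrame(
        [(99, 0, 0.0, 900.0, 900.0, "basal"), (99, 1, 0.5, 900.0, 900.0, "basal")],
        columns=tracks.columns)
    series = retention_fraction(pd.concat([tracks, lone], ignore_index=True),
                                0.0, 0.5, max_edge=40.0)
    assert 99 not in set(series["track_id"])
    assert series.attrs["n_no_neighbors"] == 1


# ----------------------------------------------------------------------
def test_identical_series_have_zero_sem():
    series = pd.DataFrame({
        "track_id": [0, 0, 1, 1],
        "time_h": [0.0, 0.5, 0.0, 0.5],
        "fraction": [1.0, 0.8, 1.0, 0.8],
    })
    values = pd.Series({0: 100.0, 1: 200.0})
    curves = group_retention(series, values, grouping="distance")
    near = curves[(curves["group"] == "<500.0") & (curves["time_h"] == 0.5)]
    assert near["mean_fraction"].iloc[0] == pytest.approx(0.8)
    assert near["sem"].iloc[0] == 0.0
    assert near["n_units"].iloc[0] == 2


def test_group_sem_uses_sample_sd_over_sqrt_n():
    # series {1,1,1} and {1,0.5,0}: means {1,.75,.5}; SEM({1,0}) = 0.7071/sqrt(2)
    series = pd.DataFrame({
        "track_id": [0, 0, 0, 1, 1, 1],
        "time_h": [0.0, 0.5, 1.0] * 2,
        "fraction": [1.0, 1.0, 1.0, 1.0, 0.5, 0.0],
    })
    values = pd.Series({0: 100.0, 1: 100.0})
    curves = group_retention(series, values, grouping="distance")
    g = curves[curves["group"] == "<500.0"].sort_values("time_h")
    np.testing.assert_allclose(g["mean_fraction"], [1.0, 0.75, 0.5])
    assert g["sem"].iloc[2] == pytest.approx(np.std([1.0, 0.0], ddof=1) / np.sqrt(2))


def test_empty_group_reports_zero_units():
    series = pd.DataFrame({"track_id": [0], "time_h": [0.0], "fraction": [1.0]})
    values = pd.Series({0: 100.0})
    curves = group_retention(series, values, grouping="distance")
    far = curves[curves["group"] == ">1000.0"]
    assert (far["n_units"] == 0).all()


def test_speed_grouping_uses_the_conventional_edges():
    series = pd.DataFrame({"track_id": [0, 1, 2], "time_h": [0.0] * 3,
                           "fraction": [1.0] * 3})
    values = pd.Series({0: 0.05, 1: 0.1, 2: 0.3})
    curves = group_retention(series, values, grouping="speed")
    populated = curves[curves["n_units"] > 0]
    assert set(populated["group"]) == {"<0.08", "0.08-0.18", ">0.18"}
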