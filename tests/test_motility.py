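import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from woundsheet.motility import (direction_angle, displacement_by_compartment,
                                 is_migratory, mean_speed, motility_records,
                                 persistence, rose_histogram,
                                 velocity_by_distance)


def track(points, dt_min=30.0):
    t = np.arange(len(points)) * dt_min
    xy = np.asarray(points, dtype=float)
    return (t, xy[:, 0], xy[:, 1])


# ----------------------------------------------------------------------
def test_speed_of_the_3_4_5_track():
    # (0,0) -> (3,4) in 100 min: 5 µm over 100 min
    assert mean_speed(([0.0, 100.0], [0.0, 3.0], [0.0, 4.0])) == pytest.approx(0.05)


def test_speed_of_a_zigzag_counts_path_not_net():
    t = ([0.0, 30.0, 60.0], [0.0, 1.0, 0.0], [0.0, 0.0, 0.0])
    assert mean_speed(t) == pytest.approx(2.0 / 60.0)


def test_static_track_has_zero_speed():
    assert mean_speed(track([(5.0, 5.0), (5.0, 5.0)])) == 0.0


def test_single_point_track_is_rejected():
    with pytest.raises(ValueError):
        mean_speed(([0.0], [1.0], [1.0]))


# ----------------------------------------------------------------------
def test_net_displacement_above_threshold_is_migratory():
    t = ([0.0, 480.0], [0.0, 12.0], [0.0, 0.0])
    assert is_migratory(t) is True


def test_exactly_threshold_displacement_is_not_migratory():
    t = ([0.0, 480.0], [0.0, 10.0], [0.0, 0.0])
    assert is_migratory(t) is False


def test_large_path_with_zero_net_is_not_migratory():
    t = ([0.0, 240.0, 480.0], [0.0, 10.0, 0.0], [0.0, 0.0, 0.0])
    assert is_migratory(t) is False


def test_track_shorter_than_window_is_an_error():
    with pytest.raises(ValueError, match="window"):
        is_migratory(([0.0, 60.0], [0.0, 20.0], [0.0, 0.0]))


# ----------------------------------------------------------------------
def test_persistence_of_a_straight_line_is_one():
    t = ([0.0, 30.0, 60.0], [0.0, 5.0, 10.0], [0.0, 0.0, 0.0])
    assert persistence(t) == pytest.approx(1.0)


def test_persistence_out_and_back_is_zero():
    t = ([0.0, 30.0, 60.0], [0.0, 10.0, 0.0], [0.0, 0.0, 0.0])
    assert persistence(t) == pytest.approx(0.0)


def test_persistence_of_the_right_angle_track():
    # (0,0)->(1,0)->(1,1): net sqrt(2), path 2 (times chosen to pass the gate)
    t = ([0.0, 6.0, 12.0], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0])
    assert persistence(t) == pytest.approx(math.sqrt(2.0) / 2.0)


def test_persistence_absent_below_the_speed_gate():
    # 2 µm over 2 h = 1 µm/h < 5 µm/h
    t = ([0.0, 120.0], [0.0, 2.0], [0.0, 0.0])
    assert persistence(t) is None


def test_reciprocal_persistence_convention():
    t = ([0.0, 6.0, 12.0], [0.0, 1.0, 1.0], [0.0, 0.0, 1.0])
    assert persistence(t, ratio="path_over_net") == pytest.approx(2.0 / math.sqrt(2.0))


# ----------------------------------------------------------------------
@pytest.mark.parametrize("end, expected", [
    ((400.0, 0.0), 0.0),
    ((600.0, 0.0), 180.0),
    ((500.0, 100.0), 90.0),
])
def test_direction_angle_relative_to_wound(end, expected):
    t = ([0.0, 60.0], [500.0, end[0]], [0.0, end[1]])
    assert direction_angle(t, wound_half_width=75.0) == pytest.approx(expected)


def test_zero_net_displacement_has_no_direction():
    t = ([0.0, 30.0, 60.0], [500.0, 501.0, 500.0], [0.0, 0.0, 0.0])
    assert direction_angle(t, 75.0) is None


def test_rose_histogram_concentrates_identical_angles():
    rose = rose_histogram([0.0, 0.0, 0.0], n_bins=24)
    assert rose["count"].iloc[0] == 3
    assert rose["count"].sum() == 3


def test_rose_histogram_uniform_angles_fill_evenly():
    rose = rose_histogram(np.arange(360.0) + 0.5, n_bins=24)
    assert (rose["count"] == 15).all()


def test_default_sim_basal_directions_peak_wound_ward(default_records):
    """The modal rose sector of basal migration touches 0° (wound-ward)."""
    basal = default_records[default_records["compartment"] == "basal"]
    rose = rose_histogram(basal["direction_angle_deg"].dropna(), n_bins=24)
    modal = int(rose["count"].idxmax())
    assert modal in (0, len(rose) - 1)  # sectors adjoining 0° == 360°


def test_rose_histogram_requires_enough_bins():
    with pytest.raises(ValueError):
        rose_histogram([0.0], n_bins=3)


# ----------------------------------------------------------------------
@settings(max_examples=60, deadline=None)
@given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                min_size=2, max_size=8))
def test_path_is_at_least_net_and_persistence_bounded(points):
    t = track(points)
    path = np.hypot(np.diff(t[1]), np.diff(t[2])).sum()
    net = math.hypot(t[1][-1] - t[1][0], t[2][-1] - t[2][0])
    assert path >= net - 1e-9
    p = persistence(t, speed_gate=0.0)
    if p is not None:
        assert -1e-9 <= p <= 1 + 1e-9


@settings(max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                min_size=2, max_size=6),
       st.floats(-1000, 1000), st.floats(-1000, 1000),
       st.floats(0, 2 * math.pi))
def test_mean_speed_is_rigid_motion_invariant(points, tx, ty, theta):
    t, x, y = track(points)
    v0 = mean_speed((t, x, y))
    c, s = math.cos(theta), math.sin(theta)
    xr = c * x - s * y + tx
    yr = s * x + c * y + ty
    assert mean_speed((t, xr, yr)) == pytest.approx(v0, rel=1e-9, abs=1e-9)


# ----------------------------------------------------------------------
def records_df(rows):
    return pd.DataFrame(rows, columns=[
        "track_id", "compartment", "phase", "initial_distance_um",
        "mean_speed_um_min", "net_displacement_um", "path_length_um",
        "persistence", "migratory", "direction_angle_deg"])


def test_velocity_by_distance_median_of_one_bin():
    rows = [(i, "basal", "G1", 100.0, v, 20.0, 25.0, 0.8, True, 0.0)
            for i, v in enumerate([0.04, 0.05, 0.06])]
    vel = velocity_by_distance(records_df(rows))
    assert vel.loc[0, "median_um_min"] == pytest.approx(0.05)
    assert vel.loc[0, "n"] == 3
    assert vel.loc[1, "n"] == 0


def test_velocity_by_distance_single_record_has_zero_iqr():
    rows = [(0, "basal", "G1", 600.0, 0.03, 20.0, 25.0, 0.8, True, 0.0)]
    vel = velocity_by_distance(records_df(rows))
    assert vel.loc[1, "median_um_min"] == pytest.approx(0.03)
    assert vel.loc[1, "q25_um_min"] == vel.loc[1, "q75_um_min"]


def test_velocity_by_distance_rejects_empty_records():
    with pytest.raises(ValueError):
        velocity_by_distance(records_df([]))


def test_displacement_by_compartment_static_follicles():
    rows = ([(i, "follicle", "G1", 300.0, 0.0, 0.0, 0.0, np.nan, False, np.nan)
             for i in range(4)]
            + [(10 + i, "basal", "G1", 300.0, 0.05, 25.0, 30.0, 0.8, True, 5.0)
               for i in range(4)])
    out = displacement_by_compartment(records_df(rows))
    fol = out[(out["compartment"] == "follicle") & (out["n"] > 0)]
    bas = out[(out["compartment"] == "basal") & (out["n"] > 0)]
    assert (fol["median_um"] == 0.0).all()
    assert (bas["median_um"] > fol["median_um"].to_numpy()).all()


def test_motility_records_from_a_hand_built_table():
    rows = []
    for k in range(17):  # 16-24 h at 30 min
        t = 16.0 + k * 0.5
        rows.append((0, k, t, 500.0 - 1.5 * k, 0.0, "basal", "G1", np.nan, np.nan))
        rows.append((1, k, t, -900.0, 250.0, "follicle", "G1", np.nan, np.nan))
    tracks = pd.DataFrame(rows, columns=["track_id", "frame", "time_h", "x_um",
                                         "y_um", "compartment", "phase",
                                         "ch1", "ch2"])
    rec = motility_records(tracks, 75.0, 16.0, 24.0)
    basal = rec[rec["track_id"] == 0].iloc[0]
    assert basal["mean_speed_um_min"] == pytest.approx(0.05)
    assert basal["initial_distance_um"] == pytest.approx(425.0)
    assert basal["migratory"] == True  # noqa: E712  (24 µm > 10 µm / 8 h)
    assert basal["direction_angle_deg"] == pytest.approx(0.0)
    fol = rec[rec["track_id"] == 1].iloc[0]
    assert fol["net_displacement_um"] == 0.0
    assert fol["migratory"] == False  # noqa: E712
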