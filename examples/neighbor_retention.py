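"""Neighbor-exchange analysis: do cells keep their original neighbors?

For each basal cell, its neighbors (Delaunay contacts) at 16 h post
wounding are recorded and the fraction still adjacent is followed for 8 h,
grouped by initial distance to the wound.  Faster cells near the wound
slip past their neighbors more, so retention drops fastest there — the
signature of swarm-like migration inside a collectively moving sheet.
"""

import numpy as np
import pandas as pd

from woundsheet import SimConfig, simulate, export_tracks
from woundsheet.neighbors import retention_fraction, group_retention
from woundsheet.simulate import distance_to_wound

cfg = SimConfig()
tracks = export_tracks(simulate(cfg, seed=1))
basal = tracks[tracks["compartment"] == "basal"]

series = retention_fraction(basal, t0=16.0, horizon=8.0)
t0_rows = basal[np.isclose(basal["time_h"], 16.0)]
dist = pd.Series(distance_to_wound(t0_rows["x_um"].to_numpy(), cfg.wound_half_width),
                 index=t0_rows["track_id"].to_numpy())
curves = group_retention(series, dist, grouping="distance")

final = curves[np.isclose(curves["time_h"], 24.0)]
print("fraction of original neighbors retained after 8 h (mean ± SEM):")
for _, row in final.iterrows():
    print(f"  {row['group']:>15} µm: {row['mean_fraction']:.3f} "
          f"± {row['sem']:.3f}  (n={row['n_units']})")
print("\nRetention increases with distance: cells close to the wound "
      "exchange neighbors most, matching their higher speed.")
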