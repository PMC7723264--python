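"""Membrane segmentation: from a synthetic junctional image to cell areas.

Renders the basal and suprabasal layers of one simulated frame as
membrane-reporter images, segments them with the classical pipeline
(ridge-enhanced pixel classification + connected components + particle
filter), and summarizes areas by distance to the wound.  Basal cells
(50-300 µm²) separate cleanly from suprabasal cells (~300-600 µm²).
"""

import math

from woundsheet import SimConfig, simulate
from woundsheet import segmentation as seg
from woundsheet.render import RenderParams, render_membrane_image

cfg = SimConfig()
result = simulate(cfg, seed=1)
frame = result.frame_at(16.0)

for layer, area_range in (("basal", cfg.basal_target_area_range),
                          ("suprabasal", cfg.suprabasal_target_area_range)):
    params = RenderParams(max_cell_radius=math.sqrt(area_range[1] / math.pi))
    rimg = render_membrane_image(frame, layer, params,
                                 bbox=(150.0, 650.0, -100.0, 100.0), seed=0)
    prob = seg.pixel_classify(rimg.image)
    labels = seg.segment(prob, threshold=0.2)
    table = seg.region_props(labels, params.pixel_size, origin=rimg.origin,
                             layer=layer)
    table = seg.assign_wound_distance(seg.filter_regions(table),
                                      cfg.wound_half_width)
    summary = seg.area_by_distance(table, [0.0, 200.0, 400.0, 600.0])
    print(f"\n{layer} layer ({len(table)} cells after the 0.2-1 circularity, "
          f"60-2500 µm² particle filter):")
    print(summary.to_string(index=False))

print("\nMean areas per bin sit inside each layer's configured range and do "
      "not trend with distance — cell size alone distinguishes the layers.")
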