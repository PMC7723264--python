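# Methods

## The model

`woundsheet` simulates re-epithelialization of a partial-thickness scratch
wound in murine back skin as a 2-D agent-based model, and pairs it with the
measurement pipeline that would be applied to intravital imaging of the same
process.  The wound is the axis-aligned strip |x| < `wound_half_width` on a
plane of half-extent `domain_half_extent` (x) × `domain_half_depth` (y);
"distance to wound" always means distance to the nearest wound edge,
d = max(0, |x| − w).  Scratches in vivo are long and narrow, so a strip with
distance bands is the natural geometry.

Three agent populations share the plane:

* **Basal keratinocytes** drift toward the wound from t = 0 with speed
  v(d): `v_near` (0.05 µm/min) for d ≤ `d_near` (0.5 mm), `v_far`
  (0.025 µm/min) for d ≥ `d_far` (1 mm), linear in between — the simplest
  monotone field consistent with the observed near/far medians.  Inside the
  strip the drift points at the wound centerline so the advancing fronts
  meet and close the wound; "toward the nearest edge" is ill-defined there.
* **Suprabasal keratinocytes** receive positional fluctuation only; they are
  a separate static population in the same plane (no z mechanics, no
  suprabasal proliferation — the basal layer is the proliferative one).
* **Hair-follicle cells** fill circular obstacle disks and never move; the
  disks are impassable — a step ending inside a disk has its inward normal
  component removed, so migrating cells slide around follicles.  Because
  they are truly static they double as fiducials for drift correction.

**Jamming.** Before `t_unjam` (20 h) the wound edge is a reflecting
boundary; afterwards basal agents may enter the strip.  The sharp observed
transition is modeled as a global switch without asserting a mechanism
(loss of contact inhibition of locomotion and inflammatory signals are both
candidates); the trigger time is a parameter, not an emergent quantity.

**Fluctuation and neighbor exchange.** Each mobile agent receives isotropic
Gaussian displacement noise of scale `noise_sigma`·dt (default
0.02 µm/min).  For basal agents the scale is multiplied by v(d)/`v_near`,
so faster cells fluctuate more; suprabasal agents use the unscaled value.
This motility-coupled fluctuation is a deliberate model property: neighbor
exchange is observed to increase with migration speed, and a
speed-independent noise cannot produce that gradient inside the flat part
of the speed field (d ≤ `d_near`).  Pairwise soft-core repulsion
(magnitude `repulsion_strength`·(1 − r/`repulsion_radius`), default
0.02 µm/min within 10 µm) keeps spacing realistic while permitting
slip-past, i.e. neighbor exchange.  Noise and repulsion inflate the
realized path-length speed a few percent above the drift speed, which is
why measured medians sit slightly above the configured anchors.

**Cell cycle.** Basal agents outside follicles switch G1 → S/G2 with a
per-step hazard, remain S/G2 for exactly `sg2_duration` (6 h), then divide:
the daughter is placed `repulsion_radius` away in a uniform random
direction and both cells revert to G1.  The hazard is calibrated per zone
(0–200 µm: 5%, 200–400 µm: 10%, beyond: 2%) so the *stationary S/G2
fraction equals the configured fraction*.  The naive two-state closed form
h = dt·f/(T·(1−f)) undershoots slightly because each division injects two
G1 cells into a growing population; `sg2_hazard` therefore solves the
discrete renewal system (growth factor β = (1−h) + 2h·β^(−n),
f/(1−f) = h·Σ β^(−a)) by fixed-point iteration.  The calibration is tested
against a direct stochastic simulation of the cycle.  Cells adopt the
hazard of the zone they currently occupy; migration across zone boundaries
dilutes the realized fractions by a few tenths of a percentage point
(adaptation time ≈ one S/G2 duration).

**Initial condition.** Agents are placed by seeded uniform sampling thinned
by a minimum-spacing rule (spacing factor × √(mean target area); factors
0.7 basal / 0.75 suprabasal), at one agent per mean target area
(basal 175 µm², suprabasal 450 µm²), independently on each side of the
wound, excluding follicle disks.  Basal phases start at the per-zone
stationary fraction with staggered S/G2 entry times so divisions are not
synchronized.  At the default scale this yields ≈4,900 basal, ≈1,900
suprabasal and ≈170 follicle agents over 97 frames (48 h at 30 min), which
keeps every analysis bin well populated (≥200 migratory tracks per distance
bin, ≥500 cells per proliferation zone and frame) while a full run plus
analysis completes in seconds.

**EdU proxy.** EdU biology is not simulated.  The simulator records every
division; `recent_division_ids` flags cells that divided within a lookback
window (default 4 h, matching a typical pulse), and `edu_fraction` operates
on the resulting counts.

## Measurement pipeline

* **Tracks** are long-format tables (`track_id, frame, time_h, x_um, y_um,
  compartment, phase, ch1, ch2`); daughters start new track ids.  Linking
  of raw detections is greedy mutual-nearest-neighbor between consecutive
  frames with a `max_disp` gate — the behavior of simple centroid trackers —
  and is verified against the optimal-assignment solution on unambiguous
  instances.  Drift correction subtracts the cumulative per-step *median*
  displacement of follicle fiducials (2-D only; robust to a minority of
  moving outliers).
* **Motility.** "Velocity" is path length / elapsed time (a speed);
  net displacement is reported separately.  "Migratory" = net displacement
  strictly > 10 µm over 8 h.  Persistence = net/path ∈ [0, 1] for tracks
  whose speed strictly exceeds 5 µm/h; the wording of the source convention
  admits the reciprocal reading, so `ratio="path_over_net"` is exposed and
  the bounded form is the documented default.  Direction angles are
  measured from the wound-ward unit vector (0° = straight at the wound).
  The 380 µm² basal/suprabasal area cut is exposed as a constant.
* **Neighbors.** Contact topology is approximated by centroid Delaunay
  triangulation pruned at `max_edge` (default 2× median nearest-neighbor
  distance) — a standard proxy for membrane contact; the exact triangulation
  is property-tested against a brute-force empty-circumcircle oracle.
  Retention is *instantaneous* (a neighbor that leaves and returns counts
  again); the alternative cumulative-loss reading is not the default
  because "fraction of original neighbors remaining" is an instantaneous
  statement.  Cells are censored at track end.  Curves aggregate per cell
  by default (simulated tracks carry no imaging-position identity); a
  `unit_col` argument supports position-level aggregation, and SEM is
  sample SD (ddof = 1)/√n.
* **Segmentation.** A fixed classical pixel classifier (Gaussian smoothing
  σ = 0.5 px, Sato ridge enhancement at σ = 1 px, min–max normalization)
  stands in for a trained foreground/background classifier.  Cells are
  4-connected components of the sub-threshold region; ties at the threshold
  go to the membrane class.  Perimeter uses the Crofton estimator (the
  estimator choice is fixed because it sets circularity near 1; circularity
  is capped at 1 after discretization).  The particle filter keeps
  circularity 0.2–1 and area 60–2,500; the size filter is interpreted in
  µm² (applied after pixel-size scaling) because the adjacent area analyses
  are reported in µm² — the convention is configurable since the source
  convention does not state units.
* **Proliferation.** Phase is called S/G2 when the S/G2 reporter channel
  exceeds the G1 channel (ties → G1).  Zone fractions default to per-frame
  fractions *time-averaged* over the 16–24 h window; a pooled variant is
  exposed.  Group comparisons delegate to standard routines (Welch t for
  velocity, Kruskal–Wallis for persistence); the package's contribution is
  the upstream quantities, not test internals.

## Synthetic imaging

Membrane images are Voronoi tessellations of a layer's centroids, clipped
at the radius of the layer's maximum target area (so rendered areas respect
the configured 50–300 / 300–600 µm² ranges without a mechanical area
model), with ridges drawn at cell–cell interfaces (ink on both sides) and
on the background side of the cell rim (so an isolated cell's label area
matches the analytic clipped disk).  Fucci intensities are log-normal draws
(log-sd 0.25) around a 10:1 high/low mean pair, which makes phase
classification errors negligible by construction.  What the renders do
*not* emulate: microscope PSF, 3-D stacks, tile stitching, uneven
illumination, or segmentation-relevant image artifacts — passing
segmentation tests therefore demonstrates the correctness of the pipeline
logic, not robustness to real microscopy noise.

## Determinism and seeds

All randomness flows from one master seed through stage-derived seeds
(`derive_seed` mixes a CRC32 of the stage name), so adding a stage never
shifts another stage's stream and identical (config, seed) pairs reproduce
byte-identical CSV outputs.

## Degenerate inputs and numerical choices

`t_end = 0` is the legal "initial frame only" run; any positive `t_end`
must fit at least one step.  Duplicate positions passed to the neighbor
graph are perturbed deterministically by 1 µm × 10⁻⁶ with a warning;
collinear or <3-point inputs fall back to distance-cutoff adjacency.
`entry_time`/`closure_time` return `inf` ("never") when the event does not
occur.  Wound closure is declared when every point of a 10-µm lattice
spanning the strip lies within `coverage_radius` (default 20 µm, roughly a
basal cell diameter plus packing slack) of a basal centroid.

## Known limitations

The model is phenomenological: jamming release is a clock, not a
mechanism; drift is imposed rather than emerging from mechanics; there is
no basement-membrane adhesion, tissue tension, or plithotaxis inference;
suprabasal/basal layers do not interact.  Proliferation zone fractions are
inputs (recovered by the pipeline as a consistency loop), not predictions.
Real-data effects the synthetic generator omits — tracking errors, gap
closure, z-drift residuals, segmentation noise — mean quantitative
agreement here bounds pipeline correctness, not biological accuracy.
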