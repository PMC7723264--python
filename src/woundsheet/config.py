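"""Simulation configuration.

All lengths are micrometres, speeds are µm/min, times are hours except the
frame interval ``dt`` which is minutes to match the imaging cadence.  The
defaults encode the study conditions of a murine partial-thickness scratch
wound: a 50–200 µm wide wound strip, wound-ward basal drift with a median
speed of 0.05 µm/min within 0.5 mm of the wound falling to ~0.025 µm/min
beyond 1 mm, a jammed phase with no wound-bed entry before ~20 h, static
suprabasal cells (~300–600 µm²) above smaller basal cells (50–300 µm²),
immobile hair-follicle cells inside circular obstacles, and an S/G2
proliferation zone (~10 % at 200–400 µm, ~5 % at 0–200 µm from the wound
edge).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = ["Follicle", "SimConfig", "load_config"]


@dataclass(frozen=True)
class Follicle:
    """A circular hair-follicle obstacle: impassable disk of static cells."""

    center: tuple[float, float]
    radius: float


def _default_follicles() -> list[Follicle]:
    # Six follicles scattered on both sides of the wound, clear of the strip
    # and of the domain border.
    return [
        Follicle((350.0, 60.0), 40.0),
        Follicle((-350.0, -60.0), 40.0),
        Follicle((800.0, -60.0), 40.0),
        Follicle((-800.0, 60.0), 40.0),
        Follicle((1250.0, 0.0), 40.0),
        Follicle((-1250.0, 0.0), 40.0),
    ]


@dataclass
class SimConfig:
    """Parameters of the scratch-wound re-epithelialization model.

    The wound is the axis-aligned strip ``|x| < wound_half_width``;
    "distance to wound" always means distance to the nearest wound edge,
    ``max(0, |x| - wound_half_width)``.
    """

    # Geometry (µm)
    wound_half_width: float = 75.0
    domain_half_extent: float = 1500.0
    domain_half_depth: float = 150.0

    # Time
    dt: float = 30.0  # minutes per frame, imaging interval
    t_end: float = 48.0  # hours
    t_unjam: float = 20.0  # hours; wound edge reflects before this

    # Drift speed field (µm/min): v_near for d <= d_near, v_far for
    # d >= d_far, linear in between.
    v_near: float = 0.05
    v_far: float = 0.025
    d_near: float = 500.0
    d_far: float = 1000.0

    # Motility fluctuation (µm/min).  For basal agents the realized sigma is
    # scaled by v(d)/v_near when noise_speed_coupling is on, so faster cells
    # fluctuate (and exchange neighbors) more; suprabasal agents always use
    # the unscaled value.
    noise_sigma: float = 0.02
    noise_speed_coupling: bool = True

    # Cell geometry (µm²)
    basal_target_area_range: tuple[float, float] = (50.0, 300.0)
    suprabasal_target_area_range: tuple[float, float] = (300.0, 600.0)

    follicles: list[Follicle] = field(default_factory=_default_follicles)

    # Proliferation: per-zone stationary S/G2 fractions, zones measured from
    # the wound edge.
    prolif_zone_edges: tuple[float, float] = (200.0, 400.0)
    p_sg2_inner: float = 0.05
    p_sg2_zone: float = 0.10
    p_sg2_baseline: float = 0.02
    sg2_duration: float = 6.0  # hours spent in S/G2 before division

    # Soft-core repulsion (slip-past allowed)
    repulsion_radius: float = 10.0  # µm
    repulsion_strength: float = 0.02  # µm/min at full overlap

    # Initial placement: minimum spacing = factor * sqrt(mean target area)
    basal_spacing_factor: float = 0.7
    suprabasal_spacing_factor: float = 0.75

    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ValueError naming the offending field(s)."""
        pos = [
            "wound_half_width", "domain_half_extent", "domain_half_depth",
            "dt", "sg2_duration", "d_near", "d_far",
            "repulsion_radius",
        ]
        for name in pos:
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("t_unjam", "v_near", "v_far", "noise_sigma",
                     "repulsion_strength"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.v_near < self.v_far:
            raise ValueError(
                f"v_near ({self.v_near}) must be >= v_far ({self.v_far})")
        if self.d_near >= self.d_far:
            raise ValueError(
                f"d_near ({self.d_near}) must be < d_far ({self.d_far})")
        if self.wound_half_width >= self.domain_half_extent:
            raise ValueError(
                "wound_half_width must be < domain_half_extent "
                f"({self.wound_half_width} >= {self.domain_half_extent})")
        if not math.isfinite(self.t_end) or self.t_end < 0:
            raise ValueError(f"t_end must be finite and >= 0, got {self.t_end!r}")
        # t_end == 0 is the degenerate "initial frame only" run; any other
        # t_end must fit at least one step
        if self.t_end > 0 and self.dt / 60.0 >= self.t_end:
            raise ValueError(
                f"dt ({self.dt} min) must be shorter than t_end "
                f"({self.t_end} h)")
        edges = tuple(self.prolif_zone_edges)
        if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
            raise ValueError(
                f"prolif_zone_edges must be strictly ascending, got {edges}")
        for name in ("p_sg2_inner", "p_sg2_zone", "p_sg2_baseline"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1), got {v!r}")
        for name in ("basal_target_area_range", "suprabasal_target_area_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got {(lo, hi)!r}")
        for f in self.follicles:
            if f.radius <= 0:
                raise ValueError(f"follicle radius must be > 0, got {f.radius!r}")

    # ------------------------------------------------------------------
    def speed(self, distance):
        """Drift speed (µm/min) at distance-to-wound-edge ``distance`` (µm)."""
        import numpy as np

        d = np.asarray(distance, dtype=float)
        t = np.clip((d - self.d_near) / (self.d_far - self.d_near), 0.0, 1.0)
        return self.v_near + (self.v_far - self.v_near) * t

    def sg2_target_fraction(self, distance):
        """Configured stationary S/G2 fraction at a distance from the wound edge."""
        import numpy as np

        d = np.asarray(distance, dtype=float)
        e0, e1 = self.prolif_zone_edges
        out = np.full(d.shape, self.p_sg2_baseline)
        out[d < e1] = self.p_sg2_zone
        out[d < e0] = self.p_sg2_inner
        return out

    def n_frames(self) -> int:
        """Number of frames including t = 0."""
        return int(round(self.t_end * 60.0 / self.dt)) + 1

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["follicles"] = [
            {"center": list(f.center), "radius": f.radius} for f in self.follicles
        ]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        fol = data.get("follicles")
        if fol is not None:
            data["follicles"] = [
                f if isinstance(f, Follicle)
                else Follicle(tuple(f["center"]), float(f["radius"]))
                for f in fol
            ]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for name in ("basal_target_area_range", "suprabasal_target_area_range",
                     "prolif_zone_edges"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


def load_config(path, overrides: dict | None = None) -> SimConfig:
    """Load a SimConfig from a YAML (or JSON) document mirroring field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    cfg = SimConfig.from_dict(data)
    cfg.validate()
    return cfg
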