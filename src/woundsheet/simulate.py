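"""Agent-based model of partial-thickness scratch-wound re-epithelialization.

The model: basal keratinocytes drift toward the wound from the moment of
wounding, with a speed field anchored at the wound edge; the wound edge is a
reflecting boundary during an initial jammed phase, after which basal agents
may enter and close the wound strip.  Suprabasal agents only fluctuate in
place, follicle agents never move, and follicle disks are impassable
obstacles that migrating agents slide around.  Basal agents cycle between G1
and S/G2 with a per-step hazard calibrated so the stationary S/G2 fraction
matches the configured per-zone fraction; at the end of S/G2 the agent
divides.

Hazard calibration.  In discrete time with step ``dt`` (hours), G1 residence
is geometric with mean ``dt / h`` and S/G2 residence is the fixed
``sg2_duration`` T.  The stationary S/G2 fraction of the two-state chain is
``f = T / (T + dt / h)``, hence ``h = dt * f / (T * (1 - f))``.  Division
(one S/G2 exit producing two G1 cells) makes the population grow slowly and
biases the realized fraction a few percent *below* f; at the configured
rates the bias is well under half a percentage point of cells.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimConfig

__all__ = [
    "COMPARTMENTS", "PHASES", "NEVER",
    "FrameTable", "SimulationResult",
    "simulate", "entry_time", "closure_time", "export_tracks",
    "sg2_hazard", "recent_division_ids",
]

COMPARTMENTS = ("basal", "suprabasal", "follicle")
BASAL, SUPRABASAL, FOLLICLE = 0, 1, 2
PHASES = ("G1", "SG2")
G1, SG2 = 0, 1

#: Sentinel returned by :func:`entry_time` / :func:`closure_time` when the
#: event does not occur within the simulated interval.
NEVER = math.inf


@dataclass
class FrameTable:
    """Snapshot of every agent at one time point (arrays share one order)."""

    time: float  # hours
    agent_id: np.ndarray
    compartment: np.ndarray  # int8 codes into COMPARTMENTS
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray  # int8 codes into PHASES
    phase_entry_time: np.ndarray  # hours
    target_area: np.ndarray  # µm²

    def __len__(self) -> int:
        return self.agent_id.size

    def mask(self, compartment: str) -> np.ndarray:
        return self.compartment == COMPARTMENTS.index(compartment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "agent_id": self.agent_id,
                "compartment": np.array(COMPARTMENTS)[self.compartment],
                "x_um": self.x,
                "y_um": self.y,
                "phase": np.array(PHASES)[self.phase],
                "target_area_um2": self.target_area,
            }
        )


@dataclass
class SimulationResult:
    frames: list[FrameTable]
    config: SimConfig
    #: (time_h, mother_id, daughter_id) per division, in occurrence order
    divisions: list[tuple[float, int, int]] = field(default_factory=list)
    #: realized per-bin median basal speeds and per-zone S/G2 fractions
    ground_truth: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def frame_at(self, time_h: float) -> FrameTable:
        """Frame whose time is closest to ``time_h``."""
        return self.frames[int(np.argmin(np.abs(self.times - time_h)))]


# ----------------------------------------------------------------------
# calibration and small helpers

@functools.lru_cache(maxsize=64)
def sg2_hazard(fraction: float, sg2_duration: float, dt_hours: float,
               growth_corrected: bool = True) -> float:
    """Per-step G1→S/G2 switch probability giving stationary S/G2 ``fraction``.

    With ``growth_corrected=False`` this is the plain two-state closed form
    ``h = dt·f / (T·(1-f))`` (geometric G1 of mean dt/h, fixed S/G2 of
    duration T).  Because every S/G2 exit is a division producing two G1
    cells, the population grows and G1 cells are slightly over-represented
    in the stable age distribution; the default therefore solves the
    discrete renewal system

        beta = (1 - h) + 2 h beta^(-n)        (per-step growth factor)
        f / (1 - f) = h * sum_{a=1..n} beta^(-a)

    with n = T/dt steps of S/G2, by fixed-point iteration, so the realized
    stationary fraction of the growing population equals ``fraction``.
    """
    if fraction <= 0.0:
        return 0.0
    n = max(1, int(round(sg2_duration / dt_hours)))
    h = dt_hours * fraction / (sg2_duration * (1.0 - fraction))
    if not growth_corrected:
        return min(h, 1.0)
    odds = fraction / (1.0 - fraction)
    for _ in range(60):
        beta = 1.0
        for _ in range(60):
            beta = (1.0 - h) + 2.0 * h * beta ** (-n)
        s = sum(beta ** (-a) for a in range(1, n + 1))
        h_new = min(odds / s, 1.0)
        if abs(h_new - h) < 1e-14:
            h = h_new
            break
        h = h_new
    return h


def distance_to_wound(x, wound_half_width: float):
    """Distance from the nearest wound edge; 0 inside the strip."""
    return np.maximum(0.0, np.abs(np.asarray(x, dtype=float)) - wound_half_width)


def _dart_throw(rng, bounds, n_target, min_spacing, reject=None,
                max_attempts_factor=40):
    """Seeded uniform sampling thinned by a minimum-spacing rule.

    ``reject(x, y) -> bool array`` discards candidates (e.g. follicle
    interiors) before the spacing test.
    """
    xmin, xmax, ymin, ymax = bounds
    cell = max(min_spacing, 1e-9)
    grid: dict[tuple[int, int], list[int]] = {}
    xs: list[float] = []
    ys: list[float] = []
    batch = max(256, n_target)
    attempts = 0
    max_attempts = max_attempts_factor * max(n_target, 1)
    while len(xs) < n_target and attempts < max_attempts:
        cx = rng.uniform(xmin, xmax, size=batch)
        cy = rng.uniform(ymin, ymax, size=batch)
        if reject is not None:
            keep = ~reject(cx, cy)
            cx, cy = cx[keep], cy[keep]
        for px, py in zip(cx, cy):
            attempts += 1
            if len(xs) >= n_target or attempts >= max_attempts:
                break
            gi, gj = int(px // cell), int(py // cell)
            ok = True
            for ii in range(gi - 1, gi + 2):
                for jj in range(gj - 1, gj + 2):
                    for k in grid.get((ii, jj), ()):
                        if (px - xs[k]) ** 2 + (py - ys[k]) ** 2 < min_spacing ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gi, gj), []).append(len(xs))
                xs.append(px)
                ys.append(py)
    return np.array(xs), np.array(ys)


def _inside_follicle(cfg: SimConfig, x, y, margin: float = 0.0):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    for f in cfg.follicles:
        r = f.radius + margin
        inside |= (x - f.center[0]) ** 2 + (y - f.center[1]) ** 2 < r ** 2
    return inside


# ----------------------------------------------------------------------
# initial condition

def _initial_state(cfg: SimConfig, rng) -> FrameTable:
    w, L, D = cfg.wound_half_width, cfg.domain_half_extent, cfg.domain_half_depth
    strip_area = 2.0 * (L - w) * (2.0 * D)  # both sides of the wound

    def layer(area_range, spacing_factor):
        # each side of the wound is sampled independently at the layer's
        # target density (one agent per mean target area)
        mean_area = 0.5 * (area_range[0] + area_range[1])
        n_side = int(strip_area / mean_area / 2)
        spacing = spacing_factor * math.sqrt(mean_area)
        xs_parts, ys_parts = [], []
        for side in (1.0, -1.0):
            def in_follicle(x, y, side=side):
                return _inside_follicle(cfg, side * x, y)

            xs, ys = _dart_throw(rng, (w, L, -D, D), n_side, spacing,
                                 reject=in_follicle)
            xs_parts.append(side * xs)
            ys_parts.append(ys)
        return np.concatenate(xs_parts), np.concatenate(ys_parts)

    bx, by = layer(cfg.basal_target_area_range, cfg.basal_spacing_factor)
    sx, sy = layer(cfg.suprabasal_target_area_range, cfg.suprabasal_spacing_factor)

    # follicle-compartment agents populate each disk (static fiducials)
    fx_all, fy_all = [], []
    mean_basal = 0.5 * sum(cfg.basal_target_area_range)
    for f in cfg.follicles:
        n = max(3, int(math.pi * f.radius ** 2 / mean_basal))
        spacing = cfg.basal_spacing_factor * math.sqrt(mean_basal)
        cx, cy = f.center
        r = f.radius

        def outside_disk(x, y, cx=cx, cy=cy, r=r):
            return (x - cx) ** 2 + (y - cy) ** 2 > (0.98 * r) ** 2

        fx, fy = _dart_throw(
            rng, (cx - r, cx + r, cy - r, cy + r), n, spacing,
            reject=outside_disk,
        )
        fx_all.append(fx)
        fy_all.append(fy)
    fx = np.concatenate(fx_all) if fx_all else np.empty(0)
    fy = np.concatenate(fy_all) if fy_all else np.empty(0)

    x = np.concatenate([bx, sx, fx])
    y = np.concatenate([by, sy, fy])
    comp = np.concatenate([
        np.full(bx.size, BASAL, dtype=np.int8),
        np.full(sx.size, SUPRABASAL, dtype=np.int8),
        np.full(fx.size, FOLLICLE, dtype=np.int8),
    ])
    target_area = np.concatenate([
        rng.uniform(*cfg.basal_target_area_range, size=bx.size),
        rng.uniform(*cfg.suprabasal_target_area_range, size=sx.size),
        rng.uniform(*cfg.basal_target_area_range, size=fx.size),
    ])

    # initialize basal phases at the per-zone stationary fraction; stagger
    # S/G2 entry times so exits are not synchronized
    phase = np.zeros(x.size, dtype=np.int8)
    entry = np.zeros(x.size, dtype=float)
    basal = comp == BASAL
    f_target = cfg.sg2_target_fraction(distance_to_wound(x[basal], cfg.wound_half_width))
    in_sg2 = rng.random(basal.sum()) < f_target
    phase[np.flatnonzero(basal)[in_sg2]] = SG2
    entry[np.flatnonzero(basal)[in_sg2]] = rng.uniform(
        -cfg.sg2_duration, 0.0, size=int(in_sg2.sum()))

    return FrameTable(
        time=0.0,
        agent_id=np.arange(x.size, dtype=np.int64),
        compartment=comp,
        x=x.astype(float),
        y=y.astype(float),
        phase=phase,
        phase_entry_time=entry,
        target_area=target_area,
    )


def _state_from_table(cfg: SimConfig, initial_agents: pd.DataFrame, rng) -> FrameTable:
    """Build frame 0 from a user-supplied table (columns: compartment, x_um,
    y_um; optional agent_id, phase, target_area_um2)."""
    df = initial_agents
    n = len(df)
    ids = (df["agent_id"].to_numpy(np.int64) if "agent_id" in df
           else np.arange(n, dtype=np.int64))
    comp = np.array([COMPARTMENTS.index(c) for c in df["compartment"]], dtype=np.int8)
    phase = (np.array([PHASES.index(p) for p in df["phase"]], dtype=np.int8)
             if "phase" in df else np.zeros(n, dtype=np.int8))
    area = (df["target_area_um2"].to_numpy(float) if "target_area_um2" in df
            else np.full(n, 0.5 * sum(cfg.basal_target_area_range)))
    return FrameTable(
        time=0.0,
        agent_id=ids,
        compartment=comp,
        x=df["x_um"].to_numpy(float).copy(),
        y=df["y_um"].to_numpy(float).copy(),
        phase=phase,
        phase_entry_time=np.zeros(n),
        target_area=area,
    )


# ----------------------------------------------------------------------
# dynamics

def _repulsion(x, y, radius, strength_step, rng):
    """Pairwise soft-core displacement: magnitude strength*(1 - d/r) along the
    separation axis.  Coincident pairs get a deterministic-by-seed random axis."""
    disp = np.zeros((x.size, 2))
    if x.size < 2 or strength_step <= 0:
        return disp
    tree = cKDTree(np.column_stack([x, y]))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size == 0:
        return disp
    i, j = pairs[:, 0], pairs[:, 1]
    dx = x[i] - x[j]
    dy = y[i] - y[j]
    d = np.hypot(dx, dy)
    zero = d < 1e-9
    if zero.any():
        ang = rng.uniform(0, 2 * np.pi, size=int(zero.sum()))
        dx[zero], dy[zero], d[zero] = np.cos(ang), np.sin(ang), 1.0
    mag = strength_step * (1.0 - np.minimum(d / radius, 1.0))
    ux, uy = dx / d, dy / d
    np.add.at(disp, i, np.column_stack([mag * ux, mag * uy]))
    np.add.at(disp, j, np.column_stack([-mag * ux, -mag * uy]))
    return disp


def _slide_around_follicles(cfg: SimConfig, x0, y0, x1, y1):
    """Project steps that end inside a follicle disk onto the disk tangent."""
    for f in cfg.follicles:
        cx, cy = f.center
        r = f.radius
        inside = (x1 - cx) ** 2 + (y1 - cy) ** 2 < r ** 2
        if not inside.any():
            continue
        idx = np.flatnonzero(inside)
        nx = x0[idx] - cx
        ny = y0[idx] - cy
        nn = np.hypot(nx, ny)
        nn[nn < 1e-9] = 1.0
        nx, ny = nx / nn, ny / nn
        sx = x1[idx] - x0[idx]
        sy = y1[idx] - y0[idx]
        into = np.minimum(sx * nx + sy * ny, 0.0)  # inward normal component
        sx -= into * nx
        sy -= into * ny
        x1[idx] = x0[idx] + sx
        y1[idx] = y0[idx] + sy
        # numerical safety: push any remaining interior point to the rim
        still = (x1[idx] - cx) ** 2 + (y1[idx] - cy) ** 2 < r ** 2
        if still.any():
            s = idx[still]
            vx = x1[s] - cx
            vy = y1[s] - cy
            vn = np.hypot(vx, vy)
            vn[vn < 1e-9] = 1.0
            x1[s] = cx + vx / vn * (r + 1e-6)
            y1[s] = cy + vy / vn * (r + 1e-6)
    return x1, y1


def _reflect_interval(v, lo, hi):
    """Reflect values into [lo, hi] (single-bounce; steps are ≪ interval)."""
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi)


def simulate(config: SimConfig, initial_agents: pd.DataFrame | None = None,
             seed: int | None = None) -> SimulationResult:
    """Run the model and return every frame.

    ``initial_agents`` replaces the random initial condition (useful for
    controlled experiments); proliferation is then still active unless the
    configured fractions are zero.  ``seed`` overrides ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    state = (_initial_state(config, rng) if initial_agents is None
             else _state_from_table(config, initial_agents, rng))
    frames = [state]
    divisions: list[tuple[float, int, int]] = []
    next_id = int(state.agent_id.max()) + 1 if len(state) else 0

    w = config.wound_half_width
    L = config.domain_half_extent
    D = config.domain_half_depth
    dt_min = config.dt
    dt_h = config.dt / 60.0
    n_steps = config.n_frames() - 1

    for step in range(n_steps):
        t = frames[-1].time
        t_next = (step + 1) * dt_h
        cur = frames[-1]
        x = cur.x.copy()
        y = cur.y.copy()
        comp = cur.compartment.copy()
        phase = cur.phase.copy()
        entry = cur.phase_entry_time.copy()
        area = cur.target_area.copy()
        ids = cur.agent_id.copy()

        basal = comp == BASAL
        supra = comp == SUPRABASAL

        newx, newy = x.copy(), y.copy()

        if basal.any():
            bx, by = x[basal], y[basal]
            d = distance_to_wound(bx, w)
            v = config.speed(d)
            # wound-ward drift: toward the nearest edge outside the strip,
            # toward the centerline inside it
            direction = -np.sign(bx)
            drift = v * dt_min
            sigma = config.noise_sigma * dt_min
            if config.noise_speed_coupling and config.v_near > 0:
                sigma = sigma * v / config.v_near
            noise = rng.normal(size=(bx.size, 2)) * np.atleast_1d(sigma)[:, None]
            rep = _repulsion(bx, by, config.repulsion_radius,
                             config.repulsion_strength * dt_min, rng)
            px = bx + drift * direction + noise[:, 0] + rep[:, 0]
            py = by + noise[:, 1] + rep[:, 1]
            newx[basal], newy[basal] = px, py

        if supra.any():
            sigma = config.noise_sigma * dt_min
            noise = rng.normal(size=(int(supra.sum()), 2)) * sigma
            newx[supra] = x[supra] + noise[:, 0]
            newy[supra] = y[supra] + noise[:, 1]

        mobile = basal | supra
        if mobile.any():
            mx, my = newx[mobile], newy[mobile]
            mx, my = _slide_around_follicles(config, x[mobile], y[mobile], mx, my)
            # jamming: the wound edge reflects any step taken before t_unjam
            if t < config.t_unjam:
                strip = np.abs(mx) < w
                if strip.any():
                    side = np.sign(x[mobile][strip])
                    side[side == 0] = 1.0
                    mx[strip] = side * (2 * w - np.abs(mx[strip]))
            mx = _reflect_interval(mx, -L, L)
            my = _reflect_interval(my, -D, D)
            newx[mobile], newy[mobile] = mx, my

        x, y = newx, newy

        # --- cell cycle (basal, outside follicle disks) -------------------
        if basal.any():
            cyc = basal & ~_inside_follicle(config, x, y)
            g1 = cyc & (phase == G1)
            if g1.any():
                d = distance_to_wound(x[g1], w)
                f_tgt = config.sg2_target_fraction(d)
                haz = np.zeros(f_tgt.shape)
                for f_val in np.unique(f_tgt):
                    haz[f_tgt == f_val] = sg2_hazard(
                        float(f_val), config.sg2_duration, dt_h)
                switch = rng.random(int(g1.sum())) < haz
                idx = np.flatnonzero(g1)[switch]
                phase[idx] = SG2
                entry[idx] = t_next
            due = cyc & (phase == SG2) & (t_next - entry >= config.sg2_duration - 1e-9)
            if due.any():
                idx = np.flatnonzero(due)
                ang = rng.uniform(0, 2 * np.pi, size=idx.size)
                dx = config.repulsion_radius * np.cos(ang)
                dy = config.repulsion_radius * np.sin(ang)
                cx = x[idx] + dx
                cy = y[idx] + dy
                cx, cy = _slide_around_follicles(config, x[idx], y[idx], cx, cy)
                if t_next < config.t_unjam:
                    strip = np.abs(cx) < w
                    if strip.any():
                        side = np.sign(x[idx][strip])
                        side[side == 0] = 1.0
                        cx[strip] = side * (2 * w - np.abs(cx[strip]))
                cx = _reflect_interval(cx, -L, L)
                cy = _reflect_interval(cy, -D, D)
                lo, hi = config.basal_target_area_range
                d_ids = np.arange(next_id, next_id + idx.size, dtype=np.int64)
                next_id += idx.size
                phase[idx] = G1
                entry[idx] = t_next
                for m, dgt in zip(ids[idx], d_ids):
                    divisions.append((t_next, int(m), int(dgt)))
                x = np.concatenate([x, cx])
                y = np.concatenate([y, cy])
                ids = np.concatenate([ids, d_ids])
                comp = np.concatenate([comp, np.full(idx.size, BASAL, dtype=np.int8)])
                phase = np.concatenate([phase, np.zeros(idx.size, dtype=np.int8)])
                entry = np.concatenate([entry, np.full(idx.size, t_next)])
                area = np.concatenate([area, rng.uniform(lo, hi, size=idx.size)])

        frames.append(FrameTable(
            time=t_next, agent_id=ids, compartment=comp, x=x, y=y,
            phase=phase, phase_entry_time=entry, target_area=area,
        ))

    result = SimulationResult(frames=frames, config=config, divisions=divisions)
    result.ground_truth = _ground_truth(result)
    return result


def _ground_truth(result: SimulationResult) -> dict:
    """Realized per-bin median frame-to-frame basal speeds and per-zone S/G2
    fractions, time-averaged over the 16–24 h analysis window (or whatever of
    it the run covers)."""
    cfg = result.config
    t0, t1 = 16.0, 24.0
    frames = [f for f in result.frames if t0 - 1e-9 <= f.time <= t1 + 1e-9]
    if len(frames) < 2:
        frames = result.frames
    gt: dict = {}
    speeds: dict[str, list] = {"near": [], "mid": [], "far": []}
    for a, b in zip(frames[:-1], frames[1:]):
        common, ia, ib = np.intersect1d(a.agent_id, b.agent_id, return_indices=True)
        basal = a.compartment[ia] == BASAL
        ia, ib = ia[basal], ib[basal]
        step = np.hypot(b.x[ib] - a.x[ia], b.y[ib] - a.y[ia])
        v = step / cfg.dt
        d = distance_to_wound(a.x[ia], cfg.wound_half_width)
        speeds["near"].append(v[d < 500])
        speeds["mid"].append(v[(d >= 500) & (d < 1000)])
        speeds["far"].append(v[d >= 1000])
    for k, chunks in speeds.items():
        allv = np.concatenate(chunks) if chunks else np.empty(0)
        gt[f"median_speed_{k}"] = float(np.median(allv)) if allv.size else math.nan
    e = (0.0,) + tuple(cfg.prolif_zone_edges)
    fracs: dict[str, list] = {}
    for f in frames:
        basal = f.compartment == BASAL
        d = distance_to_wound(f.x[basal], cfg.wound_half_width)
        sg2 = f.phase[basal] == SG2
        for lo, hi in zip(e[:-1], e[1:]):
            m = (d >= lo) & (d < hi)
            if m.sum():
                fracs.setdefault(f"sg2_fraction_{int(lo)}_{int(hi)}", []).append(
                    float(sg2[m].mean()))
    for k, vals in fracs.items():
        gt[k] = float(np.mean(vals))
    return gt


# ----------------------------------------------------------------------
# summary observables

def entry_time(result: SimulationResult) -> float:
    """Time (h) of the first frame with a basal centroid strictly inside the
    wound strip; :data:`NEVER` if it never happens."""
    if len(result.frames) < 2:
        raise ValueError("result must contain at least 2 frames")
    if not any(f.mask("basal").any() for f in result.frames):
        raise ValueError("result contains no basal agents")
    w = result.config.wound_half_width
    for f in result.frames:
        basal = f.mask("basal")
        if np.any(np.abs(f.x[basal]) < w):
            return f.time
    return NEVER


def closure_time(result: SimulationResult, coverage_radius: float = 20.0,
                 lattice_step: float = 10.0) -> float:
    """First time every point of a regular lattice spanning the wound strip is
    within ``coverage_radius`` of a basal agent; :data:`NEVER` otherwise."""
    if coverage_radius <= 0:
        raise ValueError("coverage_radius must be > 0")
    if not any(f.mask("basal").any() for f in result.frames):
        raise ValueError("result contains no basal agents")
    cfg = result.config
    w, D = cfg.wound_half_width, cfg.domain_half_depth
    gx = np.arange(-w, w + 1e-9, lattice_step)
    gy = np.arange(-D, D + 1e-9, lattice_step)
    lattice = np.column_stack([np.repeat(gx, gy.size), np.tile(gy, gx.size)])
    for f in result.frames:
        basal = f.mask("basal")
        if not basal.any():
            continue
        if not np.any(np.abs(f.x[basal]) < w + coverage_radius):
            continue  # nobody near the strip yet
        tree = cKDTree(np.column_stack([f.x[basal], f.y[basal]]))
        dmax = tree.query(lattice, k=1)[0].max()
        if dmax <= coverage_radius:
            return f.time
    return NEVER


def recent_division_ids(result: SimulationResult, time_h: float,
                        lookback: float = 4.0) -> set[int]:
    """Agents (mothers and daughters) that took part in a division within
    ``lookback`` hours before ``time_h`` — the simulator's EdU-incorporation
    proxy (EdU marks cells that replicated recently)."""
    out: set[int] = set()
    for t, mother, daughter in result.divisions:
        if time_h - lookback <= t <= time_h:
            out.add(mother)
            out.add(daughter)
    return out


def export_tracks(result: SimulationResult) -> pd.DataFrame:
    """Long-format track table: one row per agent per frame.

    Columns: track_id, frame, time_h, x_um, y_um, compartment, phase, ch1,
    ch2 (intensity columns empty; fill via the rendering module).  Agent
    identity is the track id; daughters start new tracks at their birth
    frame.
    """
    parts = []
    comp_names = np.array(COMPARTMENTS)
    phase_names = np.array(PHASES)
    for k, f in enumerate(result.frames):
        parts.append(pd.DataFrame({
            "track_id": f.agent_id,
            "frame": np.full(len(f), k, dtype=np.int64),
            "time_h": np.full(len(f), f.time),
            "x_um": f.x,
            "y_um": f.y,
            "compartment": comp_names[f.compartment],
            "phase": phase_names[f.phase],
        }))
    df = pd.concat(parts, ignore_index=True)
    df["ch1"] = np.nan
    df["ch2"] = np.nan
    return df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
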