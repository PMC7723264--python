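"""Render simulator frames into synthetic microscopy-like data.

Two products: (1) membrane-reporter images of one epidermal layer — a
Voronoi tessellation of the layer's centroids with bright ridges at cell
boundaries, standing in for a junctional E-cadherin signal — together with a
ground-truth label map; (2) per-agent two-channel nuclear intensity tables
emulating a Fucci cell-cycle reporter (channel 1 high in G1, channel 2 high
in S/G2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy.spatial import cKDTree

from .simulate import COMPARTMENTS, PHASES, SG2, FrameTable

__all__ = ["RenderParams", "RenderedImage", "render_membrane_image",
           "render_fucci", "default_cell_radius", "write_tiff"]


@dataclass
class RenderParams:
    pixel_size: float = 0.5  # µm per pixel
    membrane_width: int = 2  # px
    membrane_intensity: float = 200.0
    interior_intensity: float = 60.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    max_cell_radius: float | None = None  # µm; Voronoi clip, see default_cell_radius
    # Fucci intensity model: log-normal draws around the high/low means
    fucci_high_mean: float = 1000.0
    fucci_low_mean: float = 100.0
    fucci_sigma_log: float = 0.25

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size!r}")
        if not (self.membrane_intensity > self.interior_intensity
                >= self.background_intensity >= 0):
            raise ValueError(
                "intensities must satisfy membrane > interior >= background >= 0")
        if self.membrane_width < 1:
            raise ValueError("membrane_width must be >= 1 px")


@dataclass
class RenderedImage:
    """Image plus ground truth; ``origin`` maps pixel (row 0, col 0) to µm."""

    image: np.ndarray
    labels: np.ndarray  # agent_id per interior pixel; 0 = background/membrane
    origin: tuple[float, float]  # (x_um, y_um) of the pixel-grid corner
    pixel_size: float

    def centroid_um(self, row: float, col: float) -> tuple[float, float]:
        return (self.origin[0] + (col + 0.5) * self.pixel_size,
                self.origin[1] + (row + 0.5) * self.pixel_size)


def default_cell_radius(area_range: tuple[float, float]) -> float:
    """Clip radius of a layer: radius of a disk with the layer's maximum
    target area, so rendered cells never exceed the configured size range."""
    return math.sqrt(area_range[1] / math.pi)


def render_membrane_image(frame: FrameTable, layer: str, params: RenderParams,
                          bbox: tuple[float, float, float, float] | None = None,
                          seed: int | None = None) -> RenderedImage:
    """Voronoi-render one layer's membrane signal.

    ``bbox`` = (xmin, xmax, ymin, ymax) in µm; defaults to the layer's
    centroid bounding box padded by the clip radius.  Returns the image, the
    ground-truth label map (0 on membrane/background) and the µm origin.
    """
    params.validate()
    if layer not in COMPARTMENTS:
        raise ValueError(f"unknown layer {layer!r}")
    mask = frame.mask(layer)
    if not mask.any():
        raise ValueError(f"frame contains no {layer!r} agents")
    px = params.pixel_size
    r_max = params.max_cell_radius
    if r_max is None:
        raise ValueError("params.max_cell_radius must be set "
                         "(see default_cell_radius)")
    cx, cy = frame.x[mask], frame.y[mask]
    ids = frame.agent_id[mask]
    if bbox is None:
        bbox = (cx.min() - r_max, cx.max() + r_max,
                cy.min() - r_max, cy.max() + r_max)
    xmin, xmax, ymin, ymax = bbox
    ncol = max(1, int(math.ceil((xmax - xmin) / px)))
    nrow = max(1, int(math.ceil((ymax - ymin) / px)))

    gx = xmin + (np.arange(ncol) + 0.5) * px
    gy = ymin + (np.arange(nrow) + 0.5) * px
    pts = np.column_stack([
        np.tile(gx, nrow),
        np.repeat(gy, ncol),
    ])
    tree = cKDTree(np.column_stack([cx, cy]))
    dist, idx = tree.query(pts, k=1)
    lab = np.where(dist <= r_max, ids[idx], 0).reshape(nrow, ncol).astype(np.int32)

    # membrane = pixels at an interface between different labels, thickened
    # to membrane_width; a pixel is marked when some 4-neighbor carries a
    # different *nonzero* label, so cell-cell interfaces get ink on both
    # sides while the cell/background rim is drawn on the background side
    # (interior label areas then match the analytic clipped disk)
    memb = np.zeros_like(lab, dtype=bool)
    for (sa, sb) in (((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
                     ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))):
        a, b = lab[sa], lab[sb]
        diff = a != b
        memb[sa] |= diff & (b > 0)
        memb[sb] |= diff & (a > 0)
    if params.membrane_width > 2:
        from scipy.ndimage import binary_dilation
        memb = binary_dilation(memb, iterations=(params.membrane_width - 1) // 2)

    labels = np.where(memb, 0, lab)
    image = np.full(lab.shape, params.background_intensity, dtype=float)
    image[labels > 0] = params.interior_intensity
    image[memb] = params.membrane_intensity
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    return RenderedImage(image=image, labels=labels, origin=(xmin, ymin),
                         pixel_size=px)


def render_fucci(frame: FrameTable, params: RenderParams,
                 seed: int | None = None) -> pd.DataFrame:
    """Two-channel nuclear intensity table for every agent of a frame.

    G1 agents draw channel 1 around ``fucci_high_mean`` and channel 2 around
    ``fucci_low_mean``; S/G2 agents the reverse.  Draws are log-normal with
    log-sd ``fucci_sigma_log`` (zero gives the exact means).  Deterministic
    under ``seed``.  The true phase is carried along as ``phase_true`` for
    validation; classification should use only ch1/ch2.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = len(frame)
    sg2 = frame.phase == SG2
    hi, lo = params.fucci_high_mean, params.fucci_low_mean
    ch1_mean = np.where(sg2, lo, hi)  # G1 reporter
    ch2_mean = np.where(sg2, hi, lo)  # S/G2 reporter
    s = params.fucci_sigma_log
    if s > 0:
        ch1 = ch1_mean * np.exp(rng.normal(0.0, s, size=n))
        ch2 = ch2_mean * np.exp(rng.normal(0.0, s, size=n))
    else:
        ch1, ch2 = ch1_mean.astype(float), ch2_mean.astype(float)
    return pd.DataFrame({
        "agent_id": frame.agent_id,
        "compartment": np.array(COMPARTMENTS)[frame.compartment],
        "x_um": frame.x,
        "y_um": frame.y,
        "ch1": ch1,
        "ch2": ch2,
        "phase_true": np.array(PHASES)[frame.phase],
    })


def write_tiff(path, rendered: RenderedImage) -> None:
    """Write the image and label map as single-plane TIFFs (labels 16-bit
    when ids fit, else 32-bit); label file gets a ``_labels`` suffix."""
    import os

    tifffile.imwrite(path, rendered.image.astype(np.float32))
    root, ext = os.path.splitext(str(path))
    lab = rendered.labels
    dtype = np.uint16 if lab.max() < 2 ** 16 else np.int32
    tifffile.imwrite(f"{root}_labels{ext or '.tif'}", lab.astype(dtype))
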