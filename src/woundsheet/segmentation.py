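"""Classical membrane segmentation and particle-style region analysis.

A fixed classical pixel classifier (Gaussian smoothing followed by ridge
enhancement, normalized to [0, 1]) takes the place of a trained
foreground/background classifier; cells are then the 4-connected components
of the sub-threshold (non-membrane) region.  Region geometry mirrors an
"analyze particles" pass: area, perimeter, circularity = 4π·area/perimeter²,
with the standard particle filter keeping circularity 0.2–1 and area
60–2,500 µm² (the size filter is taken in µm², applied after pixel-size
scaling).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure

__all__ = [
    "pixel_classify", "segment", "region_props", "circularity",
    "filter_regions", "assign_wound_distance", "area_by_distance",
    "DEFAULT_CIRCULARITY_RANGE", "DEFAULT_AREA_RANGE",
]

DEFAULT_CIRCULARITY_RANGE = (0.2, 1.0)
DEFAULT_AREA_RANGE = (60.0, 2500.0)  # µm²


def pixel_classify(image: np.ndarray, smooth_sigma: float = 0.5,
                   ridge_sigmas=(1.0,)) -> np.ndarray:
    """Membrane probability map in [0, 1].

    Gaussian smoothing + Sato ridge enhancement (bright ridges) + min-max
    normalization.  A constant image has no ridges and maps to all zeros.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    smoothed = filters.gaussian(image, sigma=smooth_sigma, preserve_range=True)
    resp = filters.sato(smoothed, sigmas=ridge_sigmas, black_ridges=False)
    lo, hi = float(resp.min()), float(resp.max())
    if hi - lo < 1e-12:
        return np.zeros_like(resp)
    return (resp - lo) / (hi - lo)


def segment(prob_map: np.ndarray, threshold: float) -> np.ndarray:
    """Label map of the sub-threshold region (4-connected components).

    Pixels with probability >= threshold count as membrane (ties go to the
    membrane class); background/membrane is label 0.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.ndim != 2:
        raise ValueError(f"expected a 2-D probability map, got ndim={prob_map.ndim}")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold!r}")
    if prob_map.min() < -1e-9 or prob_map.max() > 1 + 1e-9:
        raise ValueError("probability map values must lie in [0, 1]")
    interior = prob_map < threshold
    labels, _ = ndimage.label(interior, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return labels


def circularity(area: float, perimeter: float) -> float:
    """4π·area/perimeter², capped at 1.0 (discretization can overshoot)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be > 0")
    return min(1.0, 4.0 * np.pi * area / perimeter ** 2)


def region_props(label_map: np.ndarray, pixel_size: float,
                 origin: tuple[float, float] = (0.0, 0.0),
                 layer: str | None = None) -> pd.DataFrame:
    """Geometry per labeled region, in physical units.

    ``origin`` is the µm coordinate of the pixel-grid corner (as produced by
    the renderer) so centroids land in simulation coordinates.  Perimeter
    uses the Crofton 4-direction estimator, which is close to unbiased for
    smooth shapes; the estimator choice is fixed because it sets circularity
    near 1.
    """
    label_map = np.asarray(label_map)
    if not np.issubdtype(label_map.dtype, np.integer):
        raise ValueError(f"label map must be integer, got dtype {label_map.dtype}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    rows = []
    for rp in measure.regionprops(label_map):
        area = rp.area * pixel_size ** 2
        perim = rp.perimeter_crofton * pixel_size
        r, c = rp.centroid
        rows.append({
            "region_id": rp.label,
            "centroid_x_um": origin[0] + (c + 0.5) * pixel_size,
            "centroid_y_um": origin[1] + (r + 0.5) * pixel_size,
            "area_um2": area,
            "perimeter_um": perim,
            "circularity": circularity(area, perim) if perim > 0 else np.nan,
        })
    df = pd.DataFrame(rows, columns=["region_id", "centroid_x_um", "centroid_y_um",
                                     "area_um2", "perimeter_um", "circularity"])
    df["layer"] = layer
    return df


def filter_regions(table: pd.DataFrame,
                   circularity_range=DEFAULT_CIRCULARITY_RANGE,
                   area_range=DEFAULT_AREA_RANGE) -> pd.DataFrame:
    """Keep regions inside the closed circularity and area ranges (the
    classic particle filter); row order preserved."""
    c_lo, c_hi = circularity_range
    a_lo, a_hi = area_range
    if c_lo > c_hi or a_lo > a_hi:
        raise ValueError("filter ranges must be (low, high) with low <= high")
    keep = (
        table["circularity"].between(c_lo, c_hi)
        & table["area_um2"].between(a_lo, a_hi)
    )
    return table.loc[keep].copy()


def assign_wound_distance(table: pd.DataFrame, wound_half_width: float) -> pd.DataFrame:
    """Add distance-to-wound-edge from the centroid x coordinate."""
    out = table.copy()
    out["distance_to_wound_um"] = np.maximum(
        0.0, out["centroid_x_um"].abs() - wound_half_width)
    return out


def area_by_distance(table: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Per-distance-bin area summary (mean, median, n); regions outside all
    bins are excluded and counted in the ``n_excluded`` attribute."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly ascending")
    if table.empty:
        warnings.warn("area_by_distance received an empty region table")
        out = pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_area_um2",
                                    "median_area_um2", "n"])
        out.attrs["n_excluded"] = 0
        return out
    d = table["distance_to_wound_um"].to_numpy()
    a = table["area_um2"].to_numpy()
    rows = []
    inside = np.zeros(d.size, dtype=bool)
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi)
        inside |= m
        rows.append({
            "bin_lo": lo, "bin_hi": hi,
            "mean_area_um2": float(a[m].mean()) if m.any() else np.nan,
            "median_area_um2": float(np.median(a[m])) if m.any() else np.nan,
            "n": int(m.sum()),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = int((~inside).sum())
    return out
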