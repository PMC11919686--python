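"""Coat occupancy as a function of membrane curvedness.

The headline analysis: membrane surface points are classified as coat-
proximal when they lie within a distance threshold (default 50 A) of the
coat segmentation, sorted into fixed-width curvedness bins, and the
per-bin fraction of proximal points is the occupancy, a number in [0, 1]
(0 = bare membrane, 1 = fully coated). A piecewise linear-then-constant
model fitted to the profile summarizes the saturation behavior: occupancy
rising linearly with curvedness up to a breakpoint, constant beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volio import LabelVolume

__all__ = [
    "SaturationSummary",
    "label_proximal",
    "exclude_edges",
    "bin_occupancy",
    "fit_saturation",
    "saturation_diameter_nm",
]


@dataclass
class SaturationSummary:
    """Linear-ramp-plus-plateau summary of an occupancy profile.

    The model is occupancy(C) = intercept + slope * min(C, breakpoint);
    ``plateau`` is the fitted level beyond the breakpoint. The breakpoint
    is selected by scanning candidate bin edges and minimizing the
    n-weighted residual sum of squares.
    """

    slope: float            # occupancy per nm^-1
    intercept: float
    breakpoint: float       # nm^-1
    plateau: float
    rss: float
    residuals: np.ndarray

    def as_dict(self) -> dict:
        return dict(slope=self.slope, intercept=self.intercept,
                    breakpoint=self.breakpoint, plateau=self.plateau,
                    rss=self.rss)


def label_proximal(surface: pd.DataFrame, coat: LabelVolume,
                   max_distance: float = 50.0,
                   class_name: str = "coat") -> np.ndarray:
    """True for surface points within ``max_distance`` A of a coat voxel.

    Distance is measured point to voxel center. An empty coat class
    yields all-False with a warning rather than an error.
    """
    mask = coat.class_mask(class_name)
    if not mask.any():
        warnings.warn(f"class {class_name!r} has no voxels; "
                      "no point is proximal", stacklevel=2)
        return np.zeros(len(surface), dtype=bool)
    centers = coat.index_to_physical(np.argwhere(mask))
    tree = cKDTree(centers)
    pos = surface[["x", "y", "z"]].to_numpy(dtype=float)
    d, _ = tree.query(pos, k=1, distance_upper_bound=max_distance * 1.001)
    return d <= max_distance


def exclude_edges(surface: pd.DataFrame) -> pd.DataFrame:
    """Drop points flagged ``near_edge`` (set at surface extraction)."""
    kept = surface.loc[~surface["near_edge"].astype(bool)]
    if len(kept) == 0:
        raise ValueError(
            "all surface points were excluded as edge-proximal; "
            "re-extract with a smaller edge margin")
    return kept.reset_index(drop=True)


def bin_occupancy(surface: pd.DataFrame, proximal: np.ndarray,
                  bin_width: float = 0.004,
                  c_max: float | None = None) -> pd.DataFrame:
    """Fixed-width curvedness binning of the proximal fraction.

    Returns a profile DataFrame with columns ``curvedness_lo``,
    ``curvedness_hi``, ``n_points``, ``n_proximal``, ``occupancy``
    (NaN for empty bins). Bins tile [0, c_max); unreliable points (no
    curvature estimate) are dropped first.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    proximal = np.asarray(proximal, dtype=bool)
    if len(proximal) != len(surface):
        raise ValueError("proximal flags do not match the surface point set")
    ok = surface["reliable"].to_numpy(dtype=bool) & \
        np.isfinite(surface["curvedness"].to_numpy(dtype=float))
    curv = surface["curvedness"].to_numpy(dtype=float)[ok]
    prox = proximal[ok]
    if c_max is None:
        c_max = float(np.ceil(curv.max() / bin_width) * bin_width) \
            if curv.size else bin_width
    edges = np.arange(0.0, c_max + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    which = np.digitize(curv, edges) - 1
    inside = (which >= 0) & (which < len(edges) - 1)
    n_bins = len(edges) - 1
    n_points = np.bincount(which[inside], minlength=n_bins)
    n_prox = np.bincount(which[inside], weights=prox[inside].astype(float),
                         minlength=n_bins).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(n_points > 0, n_prox / np.maximum(n_points, 1), np.nan)
    return pd.DataFrame({
        "curvedness_lo": edges[:-1],
        "curvedness_hi": edges[1:],
        "n_points": n_points,
        "n_proximal": n_prox,
        "occupancy": occ,
    })


def fit_saturation(profile: pd.DataFrame) -> SaturationSummary:
    """Fit the linear-then-constant saturation model to a profile.

    Bin centers are weighted by their point counts. The breakpoint is
    scanned over interior bin edges; ties take the smallest candidate, so
    a flat profile reports its breakpoint at the start of the observed
    range and a purely linear one at the end.
    """
    nonempty = profile.loc[profile["n_points"] > 0]
    if len(nonempty) < 6:
        raise ValueError(
            f"need >= 6 nonempty bins to fit saturation, got {len(nonempty)}")
    c = ((nonempty["curvedness_lo"] + nonempty["curvedness_hi"]) / 2
         ).to_numpy(dtype=float)
    y = nonempty["occupancy"].to_numpy(dtype=float)
    w = nonempty["n_points"].to_numpy(dtype=float)

    edges = np.unique(np.concatenate([
        nonempty["curvedness_lo"].to_numpy(dtype=float),
        nonempty["curvedness_hi"].to_numpy(dtype=float)]))
    candidates = edges[(edges >= c.min()) & (edges <= c.max())]
    if candidates.size == 0:
        candidates = np.array([c.max()])

    best = None
    sw = np.sqrt(w)
    for bp in candidates:
        xb = np.minimum(c, bp)
        design = np.stack([np.ones_like(xb), xb], axis=1) * sw[:, None]
        coefs, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
        resid = y - (coefs[0] + coefs[1] * np.minimum(c, bp))
        rss = float(np.sum(w * resid ** 2))
        if best is None or rss < best[0] - 1e-15:
            best = (rss, bp, coefs, resid)
    rss, bp, coefs, resid = best
    intercept, slope = float(coefs[0]), float(coefs[1])
    plateau = float(np.clip(intercept + slope * bp, 0.0, 1.0))
    return SaturationSummary(slope=slope, intercept=intercept,
                             breakpoint=float(bp), plateau=plateau,
                             rss=rss, residuals=resid)


def saturation_diameter_nm(breakpoint_curvedness: float) -> float:
    """Vesicle diameter (nm) whose sphere curvedness equals the breakpoint.

    For a sphere C = 1/r, so d = 2/C: the diameter at which coat binding
    saturates.
    """
    if breakpoint_curvedness <= 0:
        raise ValueError("breakpoint curvedness must be > 0")
    return 2.0 / breakpoint_curvedness
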