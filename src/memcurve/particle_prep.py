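"""Subtomogram-style particle preparation from membrane surface points.

Takes the surface coordinates produced by the occupancy analysis and
turns them into a particle table ready for external averaging packages:
minimum interparticle spacing, orientation priors from membrane normals,
k-means clustering by curvedness, and rejection of particles whose
orientation diverges from their local neighborhood consensus.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

__all__ = [
    "enforce_min_distance",
    "orientations_from_normals",
    "euler_to_matrix",
    "cluster_by_curvature",
    "filter_orientation_outliers",
]


def enforce_min_distance(points: pd.DataFrame,
                         min_dist: float = 15.0) -> pd.DataFrame:
    """Greedy spacing filter: retain points at pairwise distance >= min_dist.

    Points are visited in input order; a point is kept unless it lies
    within ``min_dist`` of an already kept point. The result is maximal:
    every excluded point is within ``min_dist`` of a kept one.
    """
    pos = points[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("positions must be finite")
    n = len(pos)
    if n == 0:
        return points.copy()
    tree = cKDTree(pos)
    pairs = tree.query_pairs(min_dist, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    kept = np.zeros(n, dtype=bool)
    for i in range(n):
        if not any(kept[j] for j in neighbors[i]):
            kept[i] = True
    return points.loc[kept].reset_index(drop=True)


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix of ZYZ Euler angles (degrees): Rz(rot)Ry(tilt)Rz(psi)."""
    a, b, g = np.radians([rot, tilt, psi])
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), \
        np.cos(g), np.sin(g)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def orientations_from_normals(points: pd.DataFrame,
                              randomize_psi: bool = False,
                              seed: int = 0) -> pd.DataFrame:
    """Set ZYZ Euler priors so the rotated reference +z equals the normal.

    rot = atan2(ny, nx), tilt = arccos(nz), psi = 0 (the in-plane angle
    is unconstrained by a normal prior; set ``randomize_psi`` to draw it
    uniformly instead).
    """
    normals = points[["nx", "ny", "nz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(normals, axis=1)
    bad = np.flatnonzero(~np.isfinite(norms) | (norms < 1e-9))
    if bad.size:
        raise ValueError(f"zero-length or invalid normals at rows "
                         f"{bad[:10].tolist()}")
    unit = normals / norms[:, None]
    out = points.copy()
    out["rot"] = np.degrees(np.arctan2(unit[:, 1], unit[:, 0]))
    out["tilt"] = np.degrees(np.arccos(np.clip(unit[:, 2], -1.0, 1.0)))
    if randomize_psi:
        rng = np.random.default_rng(seed)
        out["psi"] = rng.uniform(0.0, 360.0, size=len(out))
    else:
        out["psi"] = 0.0
    return out


def cluster_by_curvature(points: pd.DataFrame, k: int,
                         seed: int = 0) -> pd.DataFrame:
    """k-means clustering of particles on their 1-D curvedness values."""
    if k < 1:
        raise ValueError("k must be >= 1")
    curv = points["curvedness"].to_numpy(dtype=float)
    if np.any(~np.isfinite(curv)):
        raise ValueError("curvedness must be present and finite for clustering")
    n_distinct = len(np.unique(curv))
    if k > n_distinct:
        warnings.warn(f"k={k} exceeds {n_distinct} distinct curvedness "
                      f"values; reducing k to {n_distinct}", stacklevel=2)
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(curv[:, None])
    # relabel clusters by ascending mean curvedness for determinism
    means = km.cluster_centers_[:, 0]
    remap = np.empty(k, dtype=int)
    remap[np.argsort(means)] = np.arange(k)
    out = points.copy()
    out["cluster_id"] = remap[labels]
    return out


def filter_orientation_outliers(points: pd.DataFrame,
                                radius: float = 100.0,
                                max_angle: float = 30.0,
                                min_neighbors: int = 3) -> pd.DataFrame:
    """Drop particles whose normal diverges from the local consensus.

    For each particle the component-wise median of its neighbors' normals
    (within ``radius`` A, self excluded) is renormalized to give the
    consensus direction; a particle deviating from it by more than
    ``max_angle`` degrees is excluded. Particles with fewer than
    ``min_neighbors`` neighbors are retained and flagged ``isolated`` in
    the ``flag`` column.
    """
    pos = points[["x", "y", "z"]].to_numpy(dtype=float)
    normals = points[["nx", "ny", "nz"]].to_numpy(dtype=float)
    tree = cKDTree(pos)
    neigh = tree.query_ball_point(pos, radius)
    n = len(points)
    keep = np.ones(n, dtype=bool)
    flags = np.array([""] * n, dtype=object)
    cos_max = np.cos(np.radians(max_angle))
    for i in range(n):
        others = [j for j in neigh[i] if j != i]
        if len(others) < min_neighbors:
            flags[i] = "isolated"
            continue
        med = np.median(normals[others], axis=0)
        nrm = np.linalg.norm(med)
        if nrm < 1e-9:
            flags[i] = "no_consensus"
            continue
        if float(normals[i] @ (med / nrm)) < cos_max:
            keep[i] = False
    out = points.loc[keep].copy()
    out["flag"] = flags[keep]
    return out.reset_index(drop=True)
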