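"""Cyclic (Cn) symmetry determination by map self-correlation.

A density map is compared with symmetry-averaged copies of itself: for a
candidate order n and axis position, the map is averaged over rotations
of k * 360/n degrees about a z-parallel axis, and the Pearson correlation
between the original and the average is recorded. Scanning the axis
offset along x (stage 1, per candidate n) and then the rotation register
(stage 2, at the best n and offset) and maximizing the correlation yields
the symmetry parameters. This works both for full rings (axis inside the
box) and for off-axis patches from subtomogram averaging, where most
rotated copies leave the box and are excluded by a support mask.

Because the identity copy correlates a noisy map with its own noise and
would favor small n, the search statistic by default averages only the
n - 1 nontrivial rotations; :func:`apply_cn` itself includes the identity
copy, which is what one applies to symmetrize a map once the parameters
are known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import DensityMap

__all__ = [
    "SymmetryResult",
    "apply_cn",
    "correlation",
    "search_symmetry",
    "align_axis_to_z",
]


@dataclass
class SymmetryResult:
    """Best-scoring symmetry parameters plus the full scan tables."""

    n: int
    axis_offset: float          # A along x from map center
    rotation: float             # deg
    correlation: float
    offset_scan: pd.DataFrame   # columns: n, axis_offset, correlation
    rotation_scan: pd.DataFrame  # columns: rotation, correlation
    mask_description: str
    low_confidence: bool = False
    params: dict = field(default_factory=dict)


def _rotate_about_z_axis(values: np.ndarray, angle_deg: float,
                         axis_xy: tuple[float, float]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a volume about a z-parallel axis through ``axis_xy`` (index
    units). Returns (rotated volume, 2D validity mask of in-grid pre-images).

    The rotation acts only in (x, y), so a single set of bilinear weights
    is reused across every z slice; this is exactly trilinear
    interpolation for a z-preserving rotation.
    """
    nx, ny, nz = values.shape
    th = np.radians(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = ix - axis_xy[0]
    dy = iy - axis_xy[1]
    # pre-image of each output pixel: rotate by -angle
    sx = axis_xy[0] + c * dx + s * dy
    sy = axis_xy[1] - s * dx + c * dy
    valid = (sx >= 0) & (sx <= nx - 1) & (sy >= 0) & (sy <= ny - 1)
    sx = np.clip(sx, 0, nx - 1)
    sy = np.clip(sy, 0, ny - 1)
    x0 = np.minimum(sx.astype(np.int64), nx - 2)
    y0 = np.minimum(sy.astype(np.int64), ny - 2)
    fx = (sx - x0)[..., None]
    fy = (sy - y0)[..., None]
    v00 = values[x0, y0, :]
    v10 = values[x0 + 1, y0, :]
    v01 = values[x0, y0 + 1, :]
    v11 = values[x0 + 1, y0 + 1, :]
    out = (v00 * (1 - fx) * (1 - fy) + v10 * fx * (1 - fy)
           + v01 * (1 - fx) * fy + v11 * fx * fy)
    out[~valid] = 0.0
    return out, valid


def _axis_index_xy(density_map: DensityMap, axis_offset: float
                   ) -> tuple[float, float]:
    nx, ny, _ = density_map.shape
    return ((nx - 1) / 2 + axis_offset / density_map.voxel_size,
            (ny - 1) / 2)


def _cn_average(density_map: DensityMap, n: int, axis_offset: float,
                rotation: float, include_identity: bool
                ) -> tuple[np.ndarray, np.ndarray]:
    """Average of the rotated copies; returns (average, 3D support mask)."""
    axis_xy = _axis_index_xy(density_map, axis_offset)
    values = density_map.values.astype(np.float64)
    acc = np.zeros_like(values)
    count = np.zeros(values.shape[:2], dtype=np.int32)
    ks = range(n) if include_identity else range(1, n)
    for k in ks:
        ang = rotation + 360.0 * k / n
        if abs(ang % 360.0) < 1e-12:
            acc += values
            count += 1
            continue
        rot, valid = _rotate_about_z_axis(values, ang, axis_xy)
        acc += rot
        count += valid
    support2d = count > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = acc / np.maximum(count, 1)[:, :, None]
    avg[~support2d] = 0.0
    support = np.broadcast_to(support2d[:, :, None], values.shape)
    return avg, support


def apply_cn(density_map: DensityMap, n: int, axis_offset: float = 0.0,
             rotation: float = 0.0) -> tuple[DensityMap, np.ndarray]:
    """Symmetrize a map: average its n rotated copies about the axis.

    The axis is parallel to z through (center_x + axis_offset, center_y).
    Each copy is rotated by ``rotation + k * 360 / n`` degrees (trilinear
    interpolation). Voxels whose pre-image falls outside the grid are
    excluded per copy; the returned boolean array marks voxels covered by
    at least one copy.
    """
    if n < 2:
        raise ValueError(f"symmetry order n must be >= 2, got {n}")
    avg, support = _cn_average(density_map, n, axis_offset, rotation,
                               include_identity=True)
    out = DensityMap(values=avg.astype(np.float32),
                     voxel_size=density_map.voxel_size,
                     origin=density_map.origin.copy())
    return out, np.ascontiguousarray(support)


def correlation(map_a: DensityMap | np.ndarray,
                map_b: DensityMap | np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two maps over ``mask`` (default: all voxels)."""
    a = map_a.values if isinstance(map_a, DensityMap) else np.asarray(map_a)
    b = map_b.values if isinstance(map_b, DensityMap) else np.asarray(map_b)
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        a = a[mask]
        b = b[mask]
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("correlation undefined: a map is constant "
                         "within the mask")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def molecular_mask(density_map: DensityMap, smooth_vox: float = 2.0,
                   z_thresh: float = 2.0, dilate_vox: int = 2) -> np.ndarray:
    """Boolean mask of the molecular region of a (possibly noisy) map.

    The map is Gaussian-smoothed, thresholded at ``z_thresh`` robust
    standard deviations above the median, and dilated. The mask depends
    only on the input map, so using it for every candidate in a symmetry
    search introduces no selection bias between candidates.
    """
    sm = ndimage.gaussian_filter(density_map.values.astype(np.float64),
                                 smooth_vox)
    med = np.median(sm)
    mad = np.median(np.abs(sm - med))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = max(sm.max() - med, 1e-12) / 10.0
    mask = sm > med + z_thresh * scale
    if not mask.any():
        mask = sm > med
    if dilate_vox > 0:
        mask = ndimage.binary_dilation(mask, iterations=dilate_vox)
    return mask


def _masked_pixel_scan(values: np.ndarray, axis_xy: tuple[float, float],
                       angles: np.ndarray, px: np.ndarray, py: np.ndarray,
                       mol3: np.ndarray, include_identity: bool
                       ) -> float:
    """Correlation of the map with its average over rotated copies,
    evaluated only on the masked pixel columns (px, py)."""
    nx, ny, nz = values.shape
    ref = values[px, py, :]                      # (P, nz)
    acc = np.zeros_like(ref, dtype=np.float64)
    count = np.zeros(len(px), dtype=np.int32)
    for ang in angles:
        if abs(ang % 360.0) < 1e-12:
            acc += ref
            count += 1
            continue
        th = np.radians(ang)
        c, s = np.cos(th), np.sin(th)
        dx = px - axis_xy[0]
        dy = py - axis_xy[1]
        sx = axis_xy[0] + c * dx + s * dy
        sy = axis_xy[1] - s * dx + c * dy
        valid = (sx >= 0) & (sx <= nx - 1) & (sy >= 0) & (sy <= ny - 1)
        if not valid.any():
            continue
        sxv = np.clip(sx[valid], 0, nx - 1)
        syv = np.clip(sy[valid], 0, ny - 1)
        x0 = np.minimum(sxv.astype(np.int64), nx - 2)
        y0 = np.minimum(syv.astype(np.int64), ny - 2)
        fx = (sxv - x0)[:, None]
        fy = (syv - y0)[:, None]
        rot = (values[x0, y0, :] * (1 - fx) * (1 - fy)
               + values[x0 + 1, y0, :] * fx * (1 - fy)
               + values[x0, y0 + 1, :] * (1 - fx) * fy
               + values[x0 + 1, y0 + 1, :] * fx * fy)
        acc[valid] += rot
        count[valid] += 1
    sel = mol3 & (count > 0)[:, None]
    if sel.sum() < 8:
        return np.nan
    a = ref[sel].astype(np.float64)
    b = (acc / np.maximum(count, 1)[:, None])[sel]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def search_symmetry(density_map: DensityMap,
                    n_range=range(18, 23),
                    offset_range: tuple[float, float] | None = None,
                    offset_step: float = 1.0,
                    rotation_step: float = 0.5,
                    mask: np.ndarray | str = "auto",
                    prefilter_vox: float = 1.5,
                    exclude_identity: bool = True,
                    min_correlation: float = 0.7,
                    min_rel_margin: float = 0.003) -> SymmetryResult:
    """Two-stage symmetry search maximizing map self-correlation.

    Stage 1 scans the axis offset along x at ``offset_step`` (A) for each
    candidate order n, correlating the map with its Cn average (identity
    copy excluded by default; see the module note). Stage 2 scans the
    rotation register at the winning (n, offset).

    The map is low-pass filtered (Gaussian, ``prefilter_vox`` voxels)
    before correlating: structural features are broader than one voxel,
    so the filter acts as a matched filter that suppresses white noise
    without moving the correlation optimum (0 disables).

    ``mask`` controls where the correlation is evaluated: ``"auto"``
    (default) restricts it to the molecular region of the input map (see
    :func:`molecular_mask`) intersected with the rotational support;
    ``"support"`` uses the rotational support only; a boolean array of
    the map's shape is used as given.

    ``low_confidence`` is a heuristic ambiguity flag: it is set when the
    best correlation falls below ``min_correlation`` or when the margin
    of the winning order over the runner-up, relative to the best
    correlation, falls below ``min_rel_margin`` — symptoms of the true
    symmetry lying outside ``n_range`` or of an uninformative map.
    """
    n_range = sorted(set(int(n) for n in n_range))
    if any(n < 2 for n in n_range):
        raise ValueError("all symmetry orders must be >= 2")
    if offset_range is None:
        nx = density_map.shape[0]
        offset_range = (0.0, (nx - 1) / 2 * density_map.voxel_size)
    lo, hi = offset_range
    if hi < lo:
        raise ValueError(f"empty offset range ({lo}, {hi})")
    offsets = np.arange(lo, hi + offset_step / 2, offset_step)
    if offsets.size == 0:
        raise ValueError(f"empty offset range ({lo}, {hi})")

    values = density_map.values.astype(np.float64)
    if prefilter_vox > 0:
        values = ndimage.gaussian_filter(values, prefilter_vox)
    filtered = DensityMap(values=values.astype(np.float32),
                          voxel_size=density_map.voxel_size,
                          origin=density_map.origin.copy())
    if isinstance(mask, str):
        if mask == "auto":
            mol = molecular_mask(filtered)
            mask_desc = "auto molecular mask and rotational support"
        elif mask == "support":
            mol = np.ones(density_map.shape, dtype=bool)
            mask_desc = "rotational support only"
        else:
            raise ValueError(f"unknown mask mode {mask!r}")
    else:
        mol = np.asarray(mask, dtype=bool)
        if mol.shape != density_map.shape:
            raise ValueError("mask shape does not match the map")
        mask_desc = "user-supplied mask and rotational support"
    mask_desc += (", identity copy excluded" if exclude_identity
                  else ", identity copy included")

    pix2d = mol.any(axis=2)
    px, py = np.nonzero(pix2d)
    mol3 = mol[px, py, :]

    def scan_corr(n: int, d: float, rotation: float) -> float:
        axis_xy = _axis_index_xy(density_map, d)
        ks = np.arange(0 if not exclude_identity else 1, n)
        angles = rotation + 360.0 * ks / n
        return _masked_pixel_scan(values, axis_xy, angles, px, py, mol3,
                                  include_identity=not exclude_identity)

    rows = []
    for n in n_range:
        for d in offsets:
            rows.append((n, float(d), scan_corr(n, float(d), 0.0)))
    offset_scan = pd.DataFrame(rows, columns=["n", "axis_offset",
                                              "correlation"])
    scores = offset_scan["correlation"].to_numpy()
    if np.all(~np.isfinite(scores)):
        raise ValueError("no valid correlation anywhere in the scan; "
                         "check the offset range and mask")
    ibest = int(np.nanargmax(scores))
    best_n = int(offset_scan["n"].iloc[ibest])
    best_d = float(offset_scan["axis_offset"].iloc[ibest])
    best_c = float(offset_scan["correlation"].iloc[ibest])

    per_n_peak = offset_scan.groupby("n")["correlation"].max()
    peaks = np.sort(per_n_peak.to_numpy())
    rel_margin = ((peaks[-1] - peaks[-2]) / max(peaks[-1], 1e-9)
                  if len(peaks) > 1 else np.inf)
    low_confidence = (best_c < min_correlation) or (rel_margin < min_rel_margin)

    rot_max = 360.0 / best_n
    rotations = np.arange(-rot_max / 2, rot_max / 2 + rotation_step / 2,
                          rotation_step)
    rrows = [(float(r), scan_corr(best_n, best_d, float(r)))
             for r in rotations]
    rotation_scan = pd.DataFrame(rrows, columns=["rotation", "correlation"])
    jbest = int(np.nanargmax(rotation_scan["correlation"].to_numpy()))
    best_r = float(rotation_scan["rotation"].iloc[jbest])
    best_c = max(best_c, float(rotation_scan["correlation"].iloc[jbest]))

    return SymmetryResult(
        n=best_n, axis_offset=best_d, rotation=best_r, correlation=best_c,
        offset_scan=offset_scan, rotation_scan=rotation_scan,
        mask_description=mask_desc, low_confidence=bool(low_confidence),
        params=dict(n_range=list(n_range), offset_range=(float(lo), float(hi)),
                    offset_step=offset_step, rotation_step=rotation_step,
                    prefilter_vox=prefilter_vox,
                    exclude_identity=exclude_identity,
                    rel_margin=float(rel_margin)))


def align_axis_to_z(density_map: DensityMap,
                    axis_guess: np.ndarray) -> DensityMap:
    """Rigidly rotate a map so that ``axis_guess`` becomes the +z axis.

    Helper for maps whose symmetry axis is not grid-aligned; rotation is
    about the grid center with trilinear interpolation.
    """
    v = np.asarray(axis_guess, dtype=float)
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("axis guess must be a nonzero vector")
    v = v / nv
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(v, z):
        return density_map
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(v @ z)
    if s < 1e-12:         # antiparallel
        rot = np.diag([1.0, -1.0, -1.0])
    else:
        axis = axis / s
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        ang = np.arctan2(s, c)
        rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
    center = (np.array(density_map.shape) - 1) / 2
    offset = center - rot.T @ center
    out = ndimage.affine_transform(density_map.values.astype(np.float64),
                                   rot.T, offset=offset, order=1)
    return DensityMap(values=out.astype(np.float32),
                      voxel_size=density_map.voxel_size,
                      origin=density_map.origin.copy())
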