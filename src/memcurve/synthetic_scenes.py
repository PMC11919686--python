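"""Synthetic label volumes and density maps with known ground truth.

The generators emulate the three kinds of input the analysis consumes:

* vesicle fields segmented into membrane/coat classes, where the
  protein-coat coverage of each vesicle follows a curvature-dependent
  ramp model (zero below a lower curvedness bound, linear in between,
  full coverage above the upper bound);
* membrane-containing tube reconstructions built from Gaussian annular
  shells (two bilayer leaflets plus an outer protein wall);
* Cn-symmetric ring densities — full rings or wedge-shaped patches of a
  ring, as produced by subtomogram averaging of a section of a larger
  assembly — made of small Gaussian blobs grouped into subunits.

Curvedness closed forms used for ground truth: a sphere of radius r has
C = 1/r; an infinite cylinder has C = 1/(r*sqrt(2)) (one principal
curvature is zero). Radii are Angstroms internally; curvedness is nm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volio import DensityMap, LabelVolume, DEFAULT_CLASS_TABLE

__all__ = [
    "SceneTruth",
    "CnMapTruth",
    "PlacementError",
    "coverage_ramp",
    "sphere_curvedness",
    "cylinder_curvedness",
    "make_vesicle_scene",
    "make_tube_map",
    "make_hourglass_map",
    "make_cn_map",
    "sphere_label_volume",
    "cylinder_label_volume",
    "slab_label_volume",
]


class PlacementError(RuntimeError):
    """Objects could not be placed in the volume within the retry budget."""


def sphere_curvedness(radius_angstrom: float) -> float:
    """Curvedness (nm^-1) of a sphere of the given radius (A)."""
    return 10.0 / radius_angstrom


def cylinder_curvedness(radius_angstrom: float) -> float:
    """Curvedness (nm^-1) of a cylinder of the given radius (A)."""
    return 10.0 / (radius_angstrom * math.sqrt(2.0))


def coverage_ramp(curvedness, c_lo: float = 0.02, c_hi: float = 0.06):
    """Coat coverage model: clamp((C - c_lo) / (c_hi - c_lo), 0, 1).

    ``curvedness`` and the bounds are nm^-1. Vectorized over arrays.
    """
    if not c_lo < c_hi:
        raise ValueError(f"require c_lo < c_hi, got {c_lo} >= {c_hi}")
    return np.clip((np.asarray(curvedness, dtype=float) - c_lo)
                   / (c_hi - c_lo), 0.0, 1.0)


@dataclass
class SceneTruth:
    """Ground truth of a generated vesicle scene.

    ``objects`` has one row per vesicle: kind, center (cx, cy, cz, A),
    radius (A, mid-shell), true_curvedness (nm^-1), target_coverage,
    n_caps, cap_half_angle (radians, drawn coat cap before dilation).
    """

    objects: pd.DataFrame
    c_lo: float
    c_hi: float
    rng_seed: int
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.objects.to_csv(path, sep="\t", index=False)


@dataclass
class CnMapTruth:
    """Ground truth of a generated Cn ring/patch density."""

    n: int
    ring_radius: float          # A, axis to subunit centers
    axis_offset: float          # A, axis x-position relative to map center
    rotation: float             # deg, global register of subunit 0
    patch_wedge: float          # deg, 360 = full ring
    noise_sd: float
    rng_seed: int


# ---------------------------------------------------------------------------
# Vesicle scenes


def _solve_cap_angle(f: float, n_caps: int, lateral_margins: np.ndarray,
                     surface_weights: np.ndarray, radius: float) -> float:
    """Half-angle of each drawn coat cap so that the margin-dilated caps
    cover the expected surface fraction ``f``.

    The occupancy measurement counts a membrane surface point as covered
    when it lies within the proximity threshold of a coat voxel, so the
    effective covered fraction on a surface at angular dilation ``m/r``
    exceeds the drawn cap fraction. We solve
    sum_s w_s * min(1, n*(1-cos(theta+m_s/r))/2) = f by bisection.
    """
    dil = lateral_margins / radius

    def expected(theta: float) -> float:
        fr = n_caps * (1.0 - np.cos(theta + dil)) / 2.0
        return float(np.sum(surface_weights * np.minimum(fr, 1.0)))

    lo, hi = 0.0, math.pi
    if expected(0.0) >= f:
        # dilation alone reaches the target; draw the smallest usable cap
        return 1e-3
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < f:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _place_caps(rng: np.random.Generator, n_caps: int, min_angle: float,
                retries: int = 200) -> np.ndarray | None:
    """Cap axis directions with pairwise angular separation >= min_angle."""
    for _ in range(retries):
        dirs = _random_unit_vectors(rng, n_caps)
        if n_caps == 1:
            return dirs
        coses = dirs @ dirs.T
        np.fill_diagonal(coses, -1.0)
        if np.max(coses) < math.cos(min_angle):
            return dirs
    return None


def make_vesicle_scene(
    radii: list[float] | np.ndarray,
    c_lo: float = 0.02,
    c_hi: float = 0.06,
    voxel_size: float = 12.0,
    shell_thickness: float = 35.0,
    noise_fraction: float = 0.02,
    seed: int = 0,
    n_patches: int = 3,
    coat_thickness: float = 30.0,
    proximity_margin: float = 50.0,
    edge_clearance: float = 80.0,
    min_gap: float = 130.0,
    box_shape: tuple[int, int, int] | None = None,
    fill_factor: float = 0.13,
    placement_retries: int = 2000,
) -> tuple[LabelVolume, SceneTruth]:
    """Generate a field of coated vesicles as a membrane/coat label volume.

    Each vesicle is a spherical shell of ``shell_thickness`` (A) centered
    on its mid radius. Its coat is rendered as ``n_patches`` contiguous
    spherical-cap patches in a thin radial band just outside the shell;
    the caps are sized so that the surface fraction lying within
    ``proximity_margin`` of coat voxels equals the ramp model
    ``coverage_ramp(C, c_lo, c_hi)`` evaluated at the vesicle's true
    curvedness C = 1/r. ``noise_fraction`` of the shell voxels are
    flipped to background to emulate segmentation errors.

    Returns the label volume and a :class:`SceneTruth` table.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii < 4 * voxel_size):
        raise ValueError("all radii must be >= 4 * voxel_size")
    rng = np.random.default_rng(seed)

    outer = radii + shell_thickness / 2 + coat_thickness
    if box_shape is None:
        total = np.sum(4 / 3 * math.pi * (outer + min_gap / 2) ** 3)
        edge = max((total / fill_factor) ** (1 / 3),
                   2 * (outer.max() + edge_clearance) + 4 * voxel_size)
        nvox = int(math.ceil(edge / voxel_size))
        box_shape = (nvox, nvox, nvox)
    labels = np.zeros(box_shape, dtype=np.int8)
    extent = (np.array(box_shape) - 1) * voxel_size

    # --- placement by rejection sampling, big vesicles first
    order = np.argsort(radii)[::-1]
    centers = np.full((len(radii), 3), np.nan)
    for i in order:
        lo = outer[i] + edge_clearance
        hi = extent - (outer[i] + edge_clearance)
        if np.any(hi <= lo):
            raise PlacementError(
                f"volume of extent {extent} too small for vesicle radius "
                f"{radii[i]:.0f} A with clearance {edge_clearance} A")
        placed = False
        for _ in range(placement_retries):
            c = rng.uniform(lo, hi)
            ok = True
            for j in order:
                if j == i or np.isnan(centers[j, 0]):
                    continue
                if np.linalg.norm(c - centers[j]) < outer[i] + outer[j] + min_gap:
                    ok = False
                    break
            if ok:
                centers[i] = c
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place vesicle of radius {radii[i]:.0f} A after "
                f"{placement_retries} attempts; enlarge the volume")

    # --- per-vesicle rendering and truth
    half_t = shell_thickness / 2
    truth_rows = []
    for i, r in enumerate(radii):
        curv = sphere_curvedness(r)
        f = float(coverage_ramp(curv, c_lo, c_hi))

        # expected occupancy is scored on the membrane mid-surface; the
        # nearest rendered coat voxel center sits half a voxel beyond the
        # coat band's inner edge (half the shell away from the mid-surface)
        gap = half_t + voxel_size / 2.0
        lat = np.array([math.sqrt(max(proximity_margin ** 2 - gap ** 2, 0.0))])
        w = np.array([1.0])

        n_caps, theta, cap_dirs = 0, 0.0, np.zeros((0, 3))
        if 0.0 < f < 1.0:
            for nc in range(n_patches, 0, -1):
                theta = _solve_cap_angle(f, nc, lat, w, r)
                sep = 2 * (theta + lat.max() / r) + 0.1
                if nc * (1 - math.cos(theta + lat.max() / r)) / 2 > 1.0:
                    continue
                dirs = _place_caps(rng, nc, sep)
                if dirs is not None:
                    n_caps, cap_dirs = nc, dirs
                    break
            else:
                raise PlacementError(
                    f"could not place coat caps for coverage {f:.2f}")
        elif f >= 1.0:
            n_caps, theta = 1, math.pi  # full coat

        # local sub-box
        c_idx = centers[i] / voxel_size
        rad_vox = (outer[i] + voxel_size) / voxel_size
        lo_i = np.maximum(np.floor(c_idx - rad_vox).astype(int), 0)
        hi_i = np.minimum(np.ceil(c_idx + rad_vox).astype(int) + 1, box_shape)
        ix, iy, iz = np.meshgrid(*[np.arange(lo_i[a], hi_i[a]) for a in range(3)],
                                 indexing="ij")
        pos = np.stack([ix, iy, iz], axis=-1) * voxel_size - centers[i]
        d = np.linalg.norm(pos, axis=-1)

        mem = np.abs(d - r) <= half_t
        coat = np.zeros_like(mem)
        if n_caps > 0:
            band = (d > r + half_t) & (d <= r + half_t + coat_thickness)
            if theta >= math.pi - 1e-9:
                coat = band
            else:
                with np.errstate(invalid="ignore"):
                    u = pos / np.maximum(d, 1e-9)[..., None]
                cos_theta = math.cos(theta)
                in_cap = np.zeros_like(mem)
                for k in range(n_caps):
                    in_cap |= (u @ cap_dirs[k]) >= cos_theta
                coat = band & in_cap

        sub = labels[lo_i[0]:hi_i[0], lo_i[1]:hi_i[1], lo_i[2]:hi_i[2]]
        sub[mem] = 1
        sub[coat & (sub == 0)] = 2

        truth_rows.append(dict(
            kind="sphere", cx=centers[i][0], cy=centers[i][1],
            cz=centers[i][2], radius=r, true_curvedness=curv,
            target_coverage=f, n_caps=n_caps, cap_half_angle=theta))

    # --- label noise: flip a fraction of non-background voxels to background
    if noise_fraction > 0:
        nz = np.flatnonzero(labels.ravel() != 0)
        n_flip = int(round(noise_fraction * nz.size))
        if n_flip:
            flip = rng.choice(nz, size=n_flip, replace=False)
            labels.ravel()[flip] = 0

    vol = LabelVolume(labels=labels, voxel_size=voxel_size,
                      class_table=dict(DEFAULT_CLASS_TABLE))
    truth = SceneTruth(
        objects=pd.DataFrame(truth_rows), c_lo=c_lo, c_hi=c_hi, rng_seed=seed,
        params=dict(voxel_size=voxel_size, shell_thickness=shell_thickness,
                    noise_fraction=noise_fraction, n_patches=n_patches,
                    coat_thickness=coat_thickness,
                    proximity_margin=proximity_margin,
                    edge_clearance=edge_clearance, box_shape=tuple(box_shape)))
    return vol, truth


# ---------------------------------------------------------------------------
# Tube density maps


def _radial_rho(shape, voxel_size, center_xy=None):
    nx, ny, nz = shape
    if center_xy is None:
        center_xy = ((nx - 1) / 2 * voxel_size, (ny - 1) / 2 * voxel_size)
    x = np.arange(nx) * voxel_size - center_xy[0]
    y = np.arange(ny) * voxel_size - center_xy[1]
    return np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)


def make_tube_map(
    r_inner_leaflet: float = 85.0,
    r_outer_leaflet: float = 120.0,
    r_protein: float = 150.0,
    leaflet_sd: float = 5.0,
    protein_sd: float = 10.0,
    voxel_size: float = 3.0,
    shape: tuple[int, int, int] = (128, 128, 48),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityMap, dict]:
    """Membrane tube emulator: three Gaussian annular shells about z.

    The two inner shells are the bilayer leaflets; the outer shell is the
    protein wall. Default radii put the leaflet peaks 35 A apart, the
    bilayer thickness typical of these tubes. Returns the map and a truth
    dict with the shell radii and peak-to-peak thickness.
    """
    if not (r_inner_leaflet < r_outer_leaflet < r_protein):
        raise ValueError("require r_inner_leaflet < r_outer_leaflet < r_protein")
    half_extent = min(shape[0], shape[1]) / 2 * voxel_size
    if r_protein + 3 * protein_sd > half_extent:
        raise ValueError(
            f"outermost shell radius {r_protein} A (+3 sigma) exceeds the "
            f"half extent {half_extent:.0f} A of the grid")
    rho = _radial_rho(shape, voxel_size)
    profile2d = (np.exp(-((rho - r_inner_leaflet) ** 2) / (2 * leaflet_sd ** 2))
                 + np.exp(-((rho - r_outer_leaflet) ** 2) / (2 * leaflet_sd ** 2))
                 + 1.2 * np.exp(-((rho - r_protein) ** 2) / (2 * protein_sd ** 2)))
    values = np.repeat(profile2d[:, :, None], shape[2], axis=2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    truth = dict(r_inner_leaflet=r_inner_leaflet,
                 r_outer_leaflet=r_outer_leaflet, r_protein=r_protein,
                 thickness=r_outer_leaflet - r_inner_leaflet,
                 leaflet_sd=leaflet_sd, protein_sd=protein_sd,
                 noise_sd=noise_sd, rng_seed=seed)
    return DensityMap(values=values.astype(np.float32),
                      voxel_size=voxel_size), truth


def make_hourglass_map(
    r_constriction: float = 90.0,
    flank_angle: float = 120.0,
    bilayer_thickness: float = 35.0,
    leaflet_sd: float = 5.0,
    voxel_size: float = 3.0,
    shape: tuple[int, int, int] = (160, 160, 120),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DensityMap, dict]:
    """Constricted (hourglass) bilayer tube for kink-angle analysis.

    The inner-leaflet radius follows r(z) = r0 + tan(90 - flank/2) * |z - z0|,
    so the two straight flanks of r(z) meet at the constriction with an
    enclosed angle of ``flank_angle`` degrees. The outer leaflet runs
    parallel at ``bilayer_thickness``.
    """
    if not 0 < flank_angle <= 180:
        raise ValueError("flank_angle must be in (0, 180] degrees")
    slope = math.tan(math.radians((180.0 - flank_angle) / 2.0))
    rho = _radial_rho(shape, voxel_size)
    z0 = (shape[2] - 1) / 2 * voxel_size
    z = np.arange(shape[2]) * voxel_size
    r_in = r_constriction + slope * np.abs(z - z0)       # (nz,)
    values = np.zeros(shape, dtype=np.float64)
    for k in range(shape[2]):
        values[:, :, k] = (
            np.exp(-((rho - r_in[k]) ** 2) / (2 * leaflet_sd ** 2))
            + np.exp(-((rho - (r_in[k] + bilayer_thickness)) ** 2)
                     / (2 * leaflet_sd ** 2)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    truth = dict(r_constriction=r_constriction, flank_angle=flank_angle,
                 slope=slope, bilayer_thickness=bilayer_thickness,
                 z0=z0, noise_sd=noise_sd, rng_seed=seed)
    return DensityMap(values=values.astype(np.float32),
                      voxel_size=voxel_size), truth


# ---------------------------------------------------------------------------
# Cn ring / patch maps


def make_cn_map(
    n: int,
    ring_radius: float,
    axis_offset: float | None = None,
    rotation: float = 0.0,
    patch_wedge: float = 360.0,
    noise_sd: float = 0.0,
    snr: float | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size: float = 2.0,
    blobs_per_subunit: int = 4,
    blob_sd: float = 4.0,
    subunit_extent: float = 14.0,
) -> tuple[DensityMap, CnMapTruth]:
    """Cn-symmetric blob density: full ring or wedge patch of a ring.

    ``n`` subunits sit at ``ring_radius`` from a symmetry axis parallel
    to z. The axis passes through (center_x + axis_offset, center_y); by
    default ``axis_offset = ring_radius`` so that one subunit region is
    centered in the box (the off-axis patch geometry of a subtomogram
    average of a section of a large ring). Pass ``axis_offset=0`` for a
    ring centered in the box.

    Each subunit is a seeded cluster of ``blobs_per_subunit`` Gaussian
    blobs (sd ``blob_sd`` A) spread over ``subunit_extent`` A, giving the
    motif internal structure at the scale of secondary-structure density.
    If ``patch_wedge`` < 360, only subunits within the wedge about the
    box-center direction are rendered. The noiseless map is normalized to
    peak 1. Noise is additive white Gaussian of ``noise_sd``; passing
    ``snr`` instead sets the noise level from the variance-based
    signal-to-noise ratio, noise_sd = sd(signal within the molecular
    envelope) / snr.
    """
    if n < 2:
        raise ValueError(f"symmetry order n must be >= 2, got {n}")
    if axis_offset is None:
        axis_offset = ring_radius
    rng = np.random.default_rng(seed)

    center = (np.array(shape) - 1) / 2 * voxel_size
    axis_xy = np.array([center[0] + axis_offset, center[1]])
    # direction from the axis toward the box center; subunit 0 sits there
    phi0 = math.atan2(center[1] - axis_xy[1], center[0] - axis_xy[0]) \
        if abs(axis_offset) > 1e-9 else 0.0

    # seeded subunit motif: offsets in (radial, tangential, z), amplitudes
    offs = rng.uniform(-subunit_extent / 2, subunit_extent / 2,
                       size=(blobs_per_subunit, 3))
    amps = rng.uniform(0.5, 1.0, size=blobs_per_subunit)

    values = np.zeros(shape, dtype=np.float64)
    nx, ny, nz = shape
    xs = np.arange(nx) * voxel_size
    ys = np.arange(ny) * voxel_size
    zs = np.arange(nz) * voxel_size
    half_wedge = math.radians(patch_wedge) / 2.0

    for k in range(n):
        ang = phi0 + math.radians(rotation) + 2 * math.pi * k / n
        d_ang = (ang - phi0 + math.pi) % (2 * math.pi) - math.pi
        if patch_wedge < 360.0 and abs(d_ang) > half_wedge + 1e-12:
            continue
        e_r = np.array([math.cos(ang), math.sin(ang)])
        e_t = np.array([-math.sin(ang), math.cos(ang)])
        su_center = np.array([axis_xy[0] + ring_radius * e_r[0],
                              axis_xy[1] + ring_radius * e_r[1],
                              center[2]])
        for b in range(blobs_per_subunit):
            p = su_center + np.array([
                offs[b, 0] * e_r[0] + offs[b, 1] * e_t[0],
                offs[b, 0] * e_r[1] + offs[b, 1] * e_t[1],
                offs[b, 2]])
            # render on a local sub-box
            r3 = 4 * blob_sd
            sl = []
            skip = False
            for dim, coord, axv in ((0, p[0], xs), (1, p[1], ys), (2, p[2], zs)):
                lo = np.searchsorted(axv, coord - r3)
                hi = np.searchsorted(axv, coord + r3)
                if lo >= hi:
                    skip = True
                    break
                sl.append(slice(lo, hi))
            if skip:
                continue
            gx = np.exp(-((xs[sl[0]] - p[0]) ** 2) / (2 * blob_sd ** 2))
            gy = np.exp(-((ys[sl[1]] - p[1]) ** 2) / (2 * blob_sd ** 2))
            gz = np.exp(-((zs[sl[2]] - p[2]) ** 2) / (2 * blob_sd ** 2))
            values[sl[0], sl[1], sl[2]] += (
                amps[b] * gx[:, None, None] * gy[None, :, None]
                * gz[None, None, :])

    peak = values.max()
    if peak > 0:
        values /= peak
    if snr is not None:
        envelope = values > 0.05
        if not envelope.any():
            raise ValueError("no rendered density; cannot set noise from snr")
        noise_sd = float(values[envelope].std() / snr)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    truth = CnMapTruth(n=n, ring_radius=ring_radius, axis_offset=axis_offset,
                       rotation=rotation, patch_wedge=patch_wedge,
                       noise_sd=noise_sd, rng_seed=seed)
    return DensityMap(values=values.astype(np.float32),
                      voxel_size=voxel_size), truth


# ---------------------------------------------------------------------------
# Simple analytic label-volume fixtures (curvature oracles)


def sphere_label_volume(radius: float, voxel_size: float = 10.0,
                        shell_thickness: float | None = None,
                        pad: float = 60.0) -> LabelVolume:
    """A single spherical membrane shell (or solid ball) label volume."""
    half = radius + (0 if shell_thickness is None else shell_thickness / 2) + pad
    nvox = int(math.ceil(2 * half / voxel_size)) | 1
    idx = np.arange(nvox) * voxel_size - (nvox - 1) / 2 * voxel_size
    d = np.sqrt(idx[:, None, None] ** 2 + idx[None, :, None] ** 2
                + idx[None, None, :] ** 2)
    if shell_thickness is None:
        mask = d <= radius
    else:
        mask = np.abs(d - radius) <= shell_thickness / 2
    return LabelVolume(labels=mask.astype(np.int8), voxel_size=voxel_size,
                       class_table={0: "background", 1: "membrane"})


def cylinder_label_volume(radius: float, length: float,
                          voxel_size: float = 10.0,
                          pad: float = 60.0) -> LabelVolume:
    """A solid cylinder (axis along z) label volume."""
    half = radius + pad
    nxy = int(math.ceil(2 * half / voxel_size)) | 1
    nz = int(math.ceil(length / voxel_size)) | 1
    idx = np.arange(nxy) * voxel_size - (nxy - 1) / 2 * voxel_size
    rho = np.sqrt(idx[:, None] ** 2 + idx[None, :] ** 2)
    mask = np.repeat((rho <= radius)[:, :, None], nz, axis=2)
    return LabelVolume(labels=mask.astype(np.int8), voxel_size=voxel_size,
                       class_table={0: "background", 1: "membrane"})


def slab_label_volume(thickness: float, extent: float,
                      voxel_size: float = 10.0,
                      pad: float = 60.0) -> LabelVolume:
    """A flat slab (normal along z) label volume."""
    nxy = int(math.ceil(extent / voxel_size)) | 1
    nz = int(math.ceil((thickness + 2 * pad) / voxel_size)) | 1
    z = np.arange(nz) * voxel_size - (nz - 1) / 2 * voxel_size
    mask = np.zeros((nxy, nxy, nz), dtype=bool)
    mask[:, :, np.abs(z) <= thickness / 2] = True
    return LabelVolume(labels=mask.astype(np.int8), voxel_size=voxel_size,
                       class_table={0: "background", 1: "membrane"})
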