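"""End-to-end workflows chaining the analysis stages.

Two pipelines mirror the two halves of the analysis:

* :func:`run_occupancy` — label volume in, occupancy-vs-curvedness
  profile, saturation fit and prepared particle table out.
* :func:`run_symprof` — density map in, symmetry search result plus
  radial profile / leaflet measurements out.

Every run writes a provenance record (parameters, package version, input
checksums) when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import coat_occupancy, particle_prep, surface_morpho
from .coat_occupancy import SaturationSummary
from .cyclic_symmetry import SymmetryResult, search_symmetry
from .tube_profiles import (AxialTrace, LeafletDetectionError, RadialProfile,
                            detect_leaflets, measure_outer_diameter,
                            radial_profile, axial_leaflet_trace)
from .volio import DensityMap, LabelVolume, write_particles

__all__ = ["OccupancyConfig", "SymprofConfig", "StageError",
           "run_occupancy", "run_symprof"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class OccupancyConfig:
    """Parameters of the occupancy workflow (defaults as analyzed)."""

    min_island_voxels: int = 150     # cleanup threshold, strict "<"
    surface_step: float | None = None  # A, default 2 * voxel_size
    edge_margin: float = 50.0        # A, tomogram-edge exclusion
    neighborhood_radius: float | None = None  # A, curvature fit
    proximity_distance: float = 50.0  # A, coat adjacency threshold
    bin_width: float = 0.004         # nm^-1
    c_max: float | None = None       # nm^-1, binning range end
    min_particle_distance: float = 15.0  # A
    cluster_k: int = 0               # 0 = skip curvature clustering
    outlier_radius: float = 100.0    # A
    outlier_max_angle: float = 30.0  # deg
    outlier_min_neighbors: int = 3
    require_coat_proximity: bool = True  # particles only from coated points
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SymprofConfig:
    """Parameters of the symmetry / tube-profile workflow."""

    n_lo: int = 18
    n_hi: int = 22
    offset_lo: float = 0.0
    offset_hi: float | None = None   # A, default half the grid extent
    offset_step: float = 1.0         # A
    rotation_step: float = 0.5       # deg
    run_search: bool = True
    axis: str = "z"
    prominence_fraction: float = 0.1
    measure_leaflets: bool = True
    measure_diameter: bool = True
    axial_trace: bool = False
    flank_window: float = 30.0       # A

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _write_provenance(out_dir: str, config: Any, checksums: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    record = dict(package="memcurve", version=__version__,
                  timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                  config=config.to_dict(), input_checksums=checksums)
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(record, fh, indent=2)


def run_occupancy(vol: LabelVolume,
                  config: OccupancyConfig | None = None,
                  out_dir: str | None = None
                  ) -> tuple[pd.DataFrame, SaturationSummary, pd.DataFrame]:
    """Occupancy workflow: cleanup -> surface -> curvature -> edge
    exclusion -> proximity -> binning -> saturation fit -> particle prep.

    Returns (occupancy profile, saturation summary, particle table).
    """
    cfg = config or OccupancyConfig()
    if "membrane" not in vol.class_table.values():
        raise StageError("config: label volume has no 'membrane' class")
    if "coat" not in vol.class_table.values():
        raise StageError("config: label volume has no 'coat' class")

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc

    clean = stage("cleanup", surface_morpho.remove_small_components,
                  vol, cfg.min_island_voxels)
    surface = stage("surface", surface_morpho.extract_surface, clean,
                    "membrane", step=cfg.surface_step,
                    edge_margin=cfg.edge_margin)
    surface = stage("curvature", surface_morpho.estimate_curvature,
                    surface, neighborhood_radius=cfg.neighborhood_radius)
    surface = stage("edge_exclusion", coat_occupancy.exclude_edges, surface)
    proximal = stage("proximity", coat_occupancy.label_proximal,
                     surface, clean, cfg.proximity_distance)
    profile = stage("binning", coat_occupancy.bin_occupancy,
                    surface, proximal, bin_width=cfg.bin_width,
                    c_max=cfg.c_max)
    fit = stage("saturation_fit", coat_occupancy.fit_saturation, profile)

    # particle preparation from coat-proximal, reliable surface points
    pts = surface.loc[np.asarray(proximal, dtype=bool)
                      if cfg.require_coat_proximity
                      else np.ones(len(surface), dtype=bool)]
    pts = pts.loc[pts["reliable"].astype(bool)].reset_index(drop=True)
    particles = stage("min_distance", particle_prep.enforce_min_distance,
                      pts, cfg.min_particle_distance)
    if len(particles):
        particles = stage("orientations",
                          particle_prep.orientations_from_normals, particles)
        particles = stage("orientation_filter",
                          particle_prep.filter_orientation_outliers,
                          particles, radius=cfg.outlier_radius,
                          max_angle=cfg.outlier_max_angle,
                          min_neighbors=cfg.outlier_min_neighbors)
        if cfg.cluster_k > 0:
            particles = stage("clustering",
                              particle_prep.cluster_by_curvature,
                              particles, cfg.cluster_k, seed=cfg.seed)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        profile.to_csv(os.path.join(out_dir, "occupancy_profile.tsv"),
                       sep="\t", index=False)
        pd.DataFrame([fit.as_dict()]).to_csv(
            os.path.join(out_dir, "saturation_fit.tsv"), sep="\t", index=False)
        write_particles(particles, os.path.join(out_dir, "particles.tsv"))
        _write_provenance(out_dir, cfg, dict(labels=_checksum(vol.labels)))
    return profile, fit, particles


def run_symprof(density_map: DensityMap,
                config: SymprofConfig | None = None,
                out_dir: str | None = None) -> dict:
    """Symmetry search and tube profiling on a density map.

    Returns a dict with keys ``symmetry`` (SymmetryResult or None),
    ``radial_profile`` (RadialProfile), ``leaflets`` (tuple or None),
    ``outer_diameter`` (float or None) and ``axial_trace`` (AxialTrace or
    None).
    """
    cfg = config or SymprofConfig()
    out: dict[str, Any] = dict(symmetry=None, radial_profile=None,
                               leaflets=None, outer_diameter=None,
                               axial_trace=None)
    if cfg.run_search:
        try:
            out["symmetry"] = search_symmetry(
                density_map, n_range=range(cfg.n_lo, cfg.n_hi + 1),
                offset_range=(None if cfg.offset_hi is None else
                              (cfg.offset_lo, cfg.offset_hi)),
                offset_step=cfg.offset_step,
                rotation_step=cfg.rotation_step)
        except ValueError as exc:
            raise StageError(f"symmetry_search: {exc}") from exc

    try:
        prof = radial_profile(density_map, axis=cfg.axis)
    except ValueError as exc:
        raise StageError(f"radial_profile: {exc}") from exc
    out["radial_profile"] = prof
    if cfg.measure_leaflets:
        try:
            out["leaflets"] = detect_leaflets(prof, cfg.prominence_fraction)
        except LeafletDetectionError:
            out["leaflets"] = None
    if cfg.measure_diameter:
        try:
            out["outer_diameter"] = measure_outer_diameter(prof)
        except ValueError:
            out["outer_diameter"] = None
    if cfg.axial_trace:
        try:
            out["axial_trace"] = axial_leaflet_trace(
                density_map, axis=cfg.axis,
                prominence_fraction=cfg.prominence_fraction,
                flank_window=cfg.flank_window)
        except LeafletDetectionError:
            out["axial_trace"] = None

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        prof.to_frame().to_csv(os.path.join(out_dir, "radial_profile.tsv"),
                               sep="\t", index=False)
        sym: SymmetryResult | None = out["symmetry"]
        if sym is not None:
            sym.offset_scan.to_csv(os.path.join(out_dir, "offset_scan.tsv"),
                                   sep="\t", index=False)
            sym.rotation_scan.to_csv(
                os.path.join(out_dir, "rotation_scan.tsv"),
                sep="\t", index=False)
        trace: AxialTrace | None = out["axial_trace"]
        if trace is not None:
            trace.table.to_csv(os.path.join(out_dir, "axial_trace.tsv"),
                               sep="\t", index=False)
        _write_provenance(out_dir, cfg,
                          dict(map=_checksum(density_map.values)))
    return out
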