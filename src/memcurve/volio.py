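"""Volume, surface and particle-table I/O plus the shared grid conventions.

Conventions used throughout the package
---------------------------------------
* Grids are numpy arrays indexed ``[ix, iy, iz]`` (axis 0 is x). Voxel
  indices are 0-based.
* Physical coordinates are Angstroms at voxel centers:
  ``physical = origin + index * voxel_size``.
* All inter-module exchange of positions happens in physical Angstroms.
* Curvatures and curvedness are reported in nm^-1 (1 nm^-1 = 10 A^-1);
  the single Angstrom -> nm conversion lives in
  :func:`memcurve.surface_morpho.estimate_curvature`.
* Particle orientations are ZYZ Euler angles in degrees that rotate the
  reference +z axis onto the particle's membrane normal; the third
  (in-plane) angle is free.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Mapping

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "DensityMap",
    "LabelVolume",
    "FormatError",
    "ClassTableError",
    "DEFAULT_CLASS_TABLE",
    "PARTICLE_COLUMNS",
    "read_map",
    "write_map",
    "read_labels",
    "write_labels",
    "read_particles",
    "write_particles",
]

#: Canonical class table for segmentations of coated membranes.
DEFAULT_CLASS_TABLE: dict[int, str] = {
    0: "background",
    1: "membrane",
    2: "coat",
    3: "ribbon",
}

VALID_CLASS_NAMES = frozenset({"background", "membrane", "coat", "ribbon"})


class FormatError(ValueError):
    """A file could not be interpreted as the expected format."""


class ClassTableError(ValueError):
    """A label volume contains values absent from its class table."""


@dataclass
class DensityMap:
    """A 3D scalar density grid with a physical frame.

    Parameters
    ----------
    values
        3D float array, indexed ``[ix, iy, iz]``, arbitrary density units.
    voxel_size
        Isotropic voxel edge length in Angstroms.
    origin
        Physical position (A) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3:
            raise FormatError("values: expected a 3D grid, got "
                              f"{self.values.ndim}D")
        if min(self.values.shape) < 2:
            raise FormatError(
                f"values: grid dimensions must be >= 2, got {self.values.shape}")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise FormatError(f"voxel_size: must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("values: grid contains non-finite entries")
        if self.origin.shape != (3,):
            raise FormatError("origin: expected a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical Angstroms."""
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def physical_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map physical Angstrom positions to fractional voxel indices."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.voxel_size

    def center(self) -> np.ndarray:
        """Physical position of the grid center (A)."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.voxel_size


@dataclass
class LabelVolume:
    """An integer-class 3D segmentation grid.

    ``class_table`` maps each label integer to one of the class names
    background / membrane / coat / ribbon; background is always label 0.
    """

    labels: np.ndarray
    voxel_size: float
    class_table: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_TABLE))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("labels: expected an integer grid")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise FormatError("labels: expected a 3D grid")
        if not np.isfinite(self.voxel_size) or self.voxel_size <= 0:
            raise FormatError(f"voxel_size: must be > 0, got {self.voxel_size}")
        self.class_table = dict(self.class_table)
        if self.class_table.get(0) != "background":
            raise ClassTableError("class_table: label 0 must map to 'background'")
        bad_names = set(self.class_table.values()) - VALID_CLASS_NAMES
        if bad_names:
            raise ClassTableError(
                f"class_table: unknown class names {sorted(bad_names)}")
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in self.class_table]
        if unknown:
            raise ClassTableError(
                f"label volume contains values {unknown} absent from the "
                f"class table {sorted(self.class_table)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_of(self, class_name: str) -> int:
        """Return the label integer of ``class_name``."""
        for lab, name in self.class_table.items():
            if name == class_name:
                return lab
        raise ClassTableError(f"class {class_name!r} not in class table")

    def class_mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of voxels belonging to ``class_name``."""
        return self.labels == self.label_of(class_name)

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def physical_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) physical corners of the voxel-center bounding box."""
        lo = self.origin.copy()
        hi = self.origin + (np.array(self.shape) - 1) * self.voxel_size
        return lo, hi


# ---------------------------------------------------------------------------
# MRC maps

_ORIGIN_WORDS = (50, 51, 52)  # MRC2014 ORIGIN record, 1-based word index


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC/CCP4 density volume.

    The voxel size is taken from the header cell dimensions; the physical
    origin from the MRC2014 ORIGIN record.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(path)
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable MRC/CCP4 volume: {exc}") from exc
    values = np.array(m.grid, copy=True)
    if m.grid.nu < 2 or m.grid.nv < 2 or m.grid.nw < 2:
        raise FormatError(f"{path}: grid dimensions {values.shape} too small")
    vx = m.grid.unit_cell.a / m.grid.nu
    vy = m.grid.unit_cell.b / m.grid.nv
    vz = m.grid.unit_cell.c / m.grid.nw
    if vx <= 0:
        raise FormatError(f"{path}: header cell gives non-positive voxel size")
    if not (np.isclose(vx, vy, rtol=1e-3) and np.isclose(vx, vz, rtol=1e-3)):
        raise FormatError(
            f"{path}: anisotropic voxel size ({vx:.4g}, {vy:.4g}, {vz:.4g}) "
            "unsupported")
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS])
    return DensityMap(values=values, voxel_size=float(vx), origin=origin)


def write_map(density_map: DensityMap, path: str | os.PathLike) -> None:
    """Write a DensityMap as a 32-bit float (mode 2) MRC volume."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(density_map.values,
                                                dtype=np.float32))
    nx, ny, nz = density_map.shape
    v = density_map.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, o in zip(_ORIGIN_WORDS, density_map.origin):
        m.set_header_float(w, float(o))
    m.write_ccp4_map(os.fspath(path))


def read_labels(path: str | os.PathLike,
                class_table: Mapping[int, str] | None = None) -> LabelVolume:
    """Read an integer MRC volume and validate it against ``class_table``."""
    path = os.fspath(path)
    if class_table is None:
        class_table = DEFAULT_CLASS_TABLE
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_mask(path)
        m.setup(0, gemmi.MapSetup.ReorderOnly)
        labels = np.array(m.grid, copy=True)
        vx = m.grid.unit_cell.a / m.grid.nu
    except (RuntimeError, ValueError):
        # fall back to float-mode files holding integral values
        dm = read_map(path)
        labels = dm.values
        if not np.all(labels == np.round(labels)):
            raise FormatError(f"{path}: volume is not integer-valued")
        labels = labels.astype(np.int32)
        vx = dm.voxel_size
        origin = dm.origin
        return LabelVolume(labels=labels, voxel_size=vx,
                           class_table=class_table, origin=origin)
    origin = np.array([m.header_float(w) for w in _ORIGIN_WORDS])
    return LabelVolume(labels=labels.astype(np.int32), voxel_size=float(vx),
                       class_table=class_table, origin=origin)


def write_labels(vol: LabelVolume, path: str | os.PathLike) -> None:
    """Write a LabelVolume as an int8 (mode 0) MRC volume."""
    if vol.labels.max(initial=0) > 127 or vol.labels.min(initial=0) < -128:
        raise FormatError("labels exceed int8 range of MRC mode 0")
    grid = gemmi.Int8Grid(np.ascontiguousarray(vol.labels, dtype=np.int8))
    nx, ny, nz = vol.shape
    v = vol.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    m = gemmi.Ccp4Mask()
    m.grid = grid
    m.update_ccp4_header()
    for w, o in zip(_ORIGIN_WORDS, vol.origin):
        m.set_header_float(w, float(o))
    m.write_ccp4_map(os.fspath(path))


# ---------------------------------------------------------------------------
# Particle tables

#: Mandatory and optional columns of the particle TSV dialect.
PARTICLE_COLUMNS = {
    "mandatory": ["x", "y", "z"],
    "optional": ["rot", "tilt", "psi", "nx", "ny", "nz",
                 "curvedness", "cluster_id", "flag"],
}


def _validate_particles(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS["mandatory"] if c not in df.columns]
    if missing:
        raise FormatError(f"particle table missing mandatory columns {missing}")
    for c in ["x", "y", "z", "rot", "tilt", "psi", "nx", "ny", "nz",
              "curvedness"]:
        if c in df.columns:
            df[c] = df[c].astype(float)
    if "cluster_id" in df.columns:
        df["cluster_id"] = df["cluster_id"].astype("Int64")
    return df


def read_particles(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated particle table.

    Columns: ``x y z`` (A, mandatory), ``rot tilt psi`` (ZYZ Euler angles,
    degrees), ``nx ny nz`` (unit membrane normal), ``curvedness`` (nm^-1),
    ``cluster_id``, ``flag``. Orientation columns may be absent.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed particle table: {exc}") from exc
    # locate malformed numeric cells with a row number
    for c in PARTICLE_COLUMNS["mandatory"]:
        if c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise FormatError(
                    f"{path}: non-numeric value {df[c].iloc[row]!r} in column "
                    f"{c!r} at data row {row}")
            df[c] = coerced
    return _validate_particles(df)


def write_particles(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a particle table as TSV with a header row."""
    _validate_particles(table.copy())
    table.to_csv(path, sep="\t", index=False)
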