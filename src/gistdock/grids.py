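"""Voxel grids of water thermodynamics from grid inhomogeneous solvation theory (GIST).

GIST discretizes inhomogeneous solvation theory onto a rectangular lattice of
cubic voxels covering a protein active site.  Each voxel ``k`` carries five
per-water ("normalized") quantities computed from an MD trajectory:

* ``rho`` — number density of water oxygen, in units of the bulk density
  (bulk == 1, dimensionless),
* ``e_sw`` — mean solute–water interaction energy (kcal/mol/water; zero in bulk),
* ``e_ww`` — one-half the mean water–water interaction energy (kcal/mol/water),
* ``ts_orient`` — first-order orientational entropy as −TΔS (kcal/mol/water),
* ``ts_trans`` — first-order translational entropy as −TΔS (kcal/mol/water).

From these, relative enthalpy, entropy and free energy per water follow as

    ΔH = ΔE_sw + 2 (E_ww − E_bulk,ww)
    −TΔS = −TΔS_orient − TΔS_trans
    ΔG = ΔH − TΔS

where ``E_bulk,ww`` is the water–water energy of neat bulk water under the same
one-half convention.  A voxel with ΔG > 0 holds water that is unfavorable
relative to bulk; displacing it is a driving force of ligand binding.

Arrays are stored in a single canonical C-order layout: index ``[i, j, k]``
with x slowest and z fastest, matching the OpenDX convention used by cpptraj.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from gridData import Grid as _DXGrid

__all__ = [
    "DEFAULT_BULK_EWW",
    "BULK_NUMBER_DENSITY",
    "GridGeometry",
    "GISTGrid",
    "read_dx",
    "write_dx",
    "read_gist_table",
    "write_gist_table",
    "derive_thermo",
]

#: Mean water–water interaction energy of neat TIP3P water under the one-half
#: convention, kcal/mol/water.  Used as the bulk reference E_bulk,ww when the
#: GIST output does not state one; override per run if your water model differs.
DEFAULT_BULK_EWW = -9.533

#: Number density of bulk water, molecules/Å³, used to convert absolute
#: densities to bulk units.
BULK_NUMBER_DENSITY = 0.0334

_GEOM_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned lattice of cubic voxels.

    ``origin`` is the coordinate (Å) of the *center* of voxel (0, 0, 0);
    ``dims`` counts voxels per axis.  A 22.5 Å box at 0.375 Å spacing is
    therefore 60 voxels per axis.
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @classmethod
    def from_box(cls, center, box_size: float, spacing: float) -> "GridGeometry":
        """Geometry of a cubic box of edge ``box_size`` Å centred at ``center``."""
        n = int(round(box_size / spacing))
        center = np.asarray(center, dtype=float)
        origin = center - spacing * (n - 1) / 2.0
        return cls(tuple(origin), spacing, (n, n, n))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_center(self, i: int, j: int, k: int) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.array([i, j, k], dtype=float)

    def centers(self) -> np.ndarray:
        """All voxel centers, shape (n_voxels, 3), canonical (x-slowest) order."""
        ax = [np.asarray(self.origin)[d] + self.spacing * np.arange(self.dims[d]) for d in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def index_of(self, coord) -> tuple[int, int, int]:
        """Voxel index whose center is nearest ``coord`` (must be in range)."""
        rel = (np.asarray(coord, dtype=float) - np.asarray(self.origin)) / self.spacing
        idx = np.rint(rel).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.dims)):
            raise IndexError(f"coordinate {coord} outside grid {self.dims}")
        return tuple(int(i) for i in idx)

    def close_to(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class GISTGrid:
    """Per-voxel GIST water thermodynamics on a :class:`GridGeometry`.

    The five raw fields are as produced by cpptraj's GIST action (normalized,
    per-water).  ``dH``, ``mTdS`` (storing −TΔS) and ``dG`` are populated by
    :func:`derive_thermo`.
    """

    geometry: GridGeometry
    rho: np.ndarray
    e_sw: np.ndarray
    e_ww: np.ndarray
    ts_orient: np.ndarray
    ts_trans: np.ndarray
    e_bulk_ww: float | None = None
    dH: np.ndarray | None = None
    mTdS: np.ndarray | None = None
    dG: np.ndarray | None = None

    def __post_init__(self):
        dims = self.geometry.dims
        for name in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != dims:
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected {dims}")
            setattr(self, name, arr)
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative everywhere")

    @property
    def has_thermo(self) -> bool:
        return self.dG is not None

    def copy(self) -> "GISTGrid":
        return dataclasses.replace(
            self,
            rho=self.rho.copy(),
            e_sw=self.e_sw.copy(),
            e_ww=self.e_ww.copy(),
            ts_orient=self.ts_orient.copy(),
            ts_trans=self.ts_trans.copy(),
            dH=None if self.dH is None else self.dH.copy(),
            mTdS=None if self.mTdS is None else self.mTdS.copy(),
            dG=None if self.dG is None else self.dG.copy(),
        )


# ---------------------------------------------------------------------------
# OpenDX I/O
# ---------------------------------------------------------------------------

def _validate_delta(delta) -> float:
    delta = np.asarray(delta, dtype=float)
    if delta.ndim == 2:
        off = delta - np.diag(np.diag(delta))
        if np.any(np.abs(off) > _GEOM_TOL):
            bad = np.argwhere(np.abs(off) > _GEOM_TOL)[0]
            raise ValueError(
                f"non-orthogonal grid delta: off-diagonal element {tuple(bad)} = "
                f"{delta[tuple(bad)]:g}; only axis-aligned cubic voxels are supported"
            )
        delta = np.diag(delta)
    if np.ptp(delta) > _GEOM_TOL:
        raise ValueError(
            f"anisotropic grid deltas {tuple(delta)}: voxels must be cubic"
        )
    return float(delta[0])


def read_dx(path) -> tuple[GridGeometry, np.ndarray]:
    """Read one OpenDX scalar grid ("regular positions, regular connections").

    Returns the geometry and the per-voxel field in canonical (x-slowest,
    z-fastest) C order, as the DX convention prescribes.
    """
    g = _DXGrid(str(path))
    spacing = _validate_delta(g.delta)
    values = np.asarray(g.grid, dtype=float)
    geometry = GridGeometry(tuple(np.asarray(g.origin, dtype=float)), spacing, values.shape)
    return geometry, values


def write_dx(geometry: GridGeometry, values: np.ndarray, path) -> None:
    """Write a per-voxel field as an OpenDX scalar grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.dims:
        raise ValueError(f"values shape {values.shape} != geometry dims {geometry.dims}")
    g = _DXGrid(values, origin=np.asarray(geometry.origin), delta=geometry.spacing)
    g.export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# cpptraj-style per-voxel table
# ---------------------------------------------------------------------------

#: canonical field -> column name in the table dialect written by this package
DEFAULT_COLUMN_MAP = {
    "voxel": "voxel",
    "x": "x",
    "y": "y",
    "z": "z",
    "rho": "rho",
    "e_sw": "e_sw",
    "e_ww": "e_ww",
    "ts_orient": "ts_orient",
    "ts_trans": "ts_trans",
}


def read_gist_table(
    path,
    column_map: dict[str, str] | None = None,
    density_unit: str = "bulk",
    bulk_density: float = BULK_NUMBER_DENSITY,
    e_bulk_ww: float | None = None,
) -> GISTGrid:
    """Read a whitespace-delimited per-voxel GIST table into a :class:`GISTGrid`.

    The table must have one row per voxel with a header line naming the
    columns; ``column_map`` maps the canonical names (``voxel, x, y, z, rho,
    e_sw, e_ww, ts_orient, ts_trans``) to the file's column names, for tables
    written by other tools.  ``density_unit`` is ``"bulk"`` (ρ already in bulk
    units) or ``"molecules_A3"`` (absolute number density, converted by
    ``bulk_density``).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", comment="#", float_precision="round_trip")
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} is missing columns {missing}")

    vox = df[cmap["voxel"]].to_numpy(dtype=int)
    if len(np.unique(vox)) != len(vox):
        dup = vox[pd.Series(vox).duplicated()][0]
        raise ValueError(f"duplicate voxel index {dup} in {path}")

    coords = df[[cmap["x"], cmap["y"], cmap["z"]]].to_numpy(dtype=float)
    geometry = _infer_geometry(coords)
    n = geometry.n_voxels
    if len(df) != n:
        raise ValueError(
            f"table has {len(df)} rows but inferred geometry {geometry.dims} "
            f"needs {n} voxels (missing or extra rows)"
        )

    # place rows by coordinate-derived index; reject rows off the lattice
    rel = (coords - np.asarray(geometry.origin)) / geometry.spacing
    idx = np.rint(rel).astype(int)
    err = np.abs(coords - (np.asarray(geometry.origin) + idx * geometry.spacing))
    if np.any(err > geometry.spacing / 2):
        bad = int(np.argwhere(err > geometry.spacing / 2)[0][0])
        raise ValueError(
            f"row {bad}: coordinate {tuple(coords[bad])} deviates from the "
            f"inferred lattice by more than spacing/2"
        )
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), geometry.dims)
    if len(np.unique(flat)) != n:
        raise ValueError(f"table rows do not cover every voxel of {geometry.dims}")

    def place(col: str) -> np.ndarray:
        out = np.empty(n, dtype=float)
        out[flat] = df[cmap[col]].to_numpy(dtype=float)
        return out.reshape(geometry.dims)

    rho = place("rho")
    if density_unit == "molecules_A3":
        rho = rho / bulk_density
    elif density_unit != "bulk":
        raise ValueError(f"unknown density_unit {density_unit!r}")

    return GISTGrid(
        geometry=geometry,
        rho=rho,
        e_sw=place("e_sw"),
        e_ww=place("e_ww"),
        ts_orient=place("ts_orient"),
        ts_trans=place("ts_trans"),
        e_bulk_ww=e_bulk_ww,
    )


def _infer_geometry(coords: np.ndarray) -> GridGeometry:
    axes = []
    for d in range(3):
        vals = np.unique(np.round(coords[:, d], 9))
        axes.append(vals)
    spacings = [np.diff(a) for a in axes if len(a) > 1]
    if not spacings:
        spacing = 1.0  # single-voxel table: spacing is arbitrary
    else:
        all_d = np.concatenate(spacings)
        spacing = float(np.min(all_d))
        if np.any(np.abs(all_d - spacing) > 1e-6):
            raise ValueError("voxel coordinates are not on a uniform cubic lattice")
    origin = tuple(float(a[0]) for a in axes)
    dims = tuple(len(a) for a in axes)
    return GridGeometry(origin, spacing, dims)


def write_gist_table(grid: GISTGrid, path) -> None:
    """Write the five raw fields as a whitespace-delimited per-voxel table."""
    geo = grid.geometry
    centers = geo.centers()
    df = pd.DataFrame(
        {
            "voxel": np.arange(geo.n_voxels),
            "x": centers[:, 0],
            "y": centers[:, 1],
            "z": centers[:, 2],
            "rho": grid.rho.ravel(),
            "e_sw": grid.e_sw.ravel(),
            "e_ww": grid.e_ww.ravel(),
            "ts_orient": grid.ts_orient.ravel(),
            "ts_trans": grid.ts_trans.ravel(),
        }
    )
    # %.17g keeps doubles bitwise across a write/read cycle
    with open(path, "w") as fh:
        fh.write(df.to_string(index=False, float_format=lambda v: f"{v:.17g}"))
        fh.write("\n")


# ---------------------------------------------------------------------------
# Derived thermodynamics
# ---------------------------------------------------------------------------

def derive_thermo(grid: GISTGrid) -> GISTGrid:
    """Populate ΔH, −TΔS and ΔG per voxel.

    ΔH = e_sw + 2·(e_ww − e_bulk_ww); −TΔS = ts_orient + ts_trans;
    ΔG = ΔH + (−TΔS).  Idempotent; returns a new grid, inputs untouched.
    Low-occupancy voxels are *not* masked here — the density cutoff applied
    when building the unfavorable-water map is what suppresses their noise.
    """
    if grid.e_bulk_ww is None:
        raise ValueError(
            "e_bulk_ww is unset: supply the bulk water-water reference energy "
            f"(conventional TIP3P value: {DEFAULT_BULK_EWW} kcal/mol/water)"
        )
    out = grid.copy()
    out.dH = out.e_sw + 2.0 * (out.e_ww - grid.e_bulk_ww)
    out.mTdS = out.ts_orient + out.ts_trans
    out.dG = out.dH + out.mTdS
    return out
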