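"""Per-atom-type gain maps: the displacement term as AutoGrid lookup tables.

AutoDock evaluates its force field during the conformational search by
trilinear interpolation of precomputed per-atom-type affinity maps.  To let an
external docking engine apply the water-displacement gain on the fly, the
binary unfavorable-water mask is dilated by each atom type's vdW radius and
scaled by ΔG_aff: a grid point carries the full gain wherever an atom of that
type centered there would cover at least one unfavorable voxel, and 0
elsewhere.  Summing interpolated map values over a pose's heavy atoms then
reproduces ΔG_watdisp exactly for grid-aligned atoms (interpolation softens
the step at region boundaries).

Map files follow the AutoGrid text format: six header lines
(GRID_PARAMETER_FILE, GRID_DATA_FILE, MACROMOLECULE, SPACING, NELEMENTS,
CENTER) then one value per line with x varying fastest.  NELEMENTS counts
intervals per axis (points − 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .grids import GridGeometry, write_dx
from .watermap import UnfavorableWaterMap

__all__ = [
    "AffinityMap",
    "gain_map",
    "write_autogrid_map",
    "read_autogrid_map",
    "add_to_existing_map",
    "interpolate_map",
    "pose_gain_from_maps",
]


@dataclass(frozen=True)
class AffinityMap:
    """One per-atom-type energy grid (kcal/mol at each grid point)."""

    geometry: GridGeometry
    atom_type: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.geometry.dims:
            raise ValueError(f"values shape {values.shape} != dims {self.geometry.dims}")
        if not np.all(np.isfinite(values)):
            raise ValueError("map values must be finite")
        object.__setattr__(self, "values", values)


def gain_map(
    wmap: UnfavorableWaterMap,
    atom_type: str,
    radius: float,
    dG_aff: float | None = None,
) -> AffinityMap:
    """Spherical dilation of the unfavorable mask by ``radius``, scaled by ΔG_aff.

    Grid points of the map coincide with the voxel centers of the mask's
    geometry.  Value = ΔG_aff where any unfavorable voxel center lies within
    ``radius`` (inclusive), else 0 — the full, not fractional, gain at every
    covered point, matching the binary per-atom indicator.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if dG_aff is None:
        dG_aff = wmap.params.dG_aff
    geo = wmap.geometry
    values = np.zeros(geo.dims)
    centers = wmap.true_centers()
    if len(centers):
        tree = cKDTree(centers)
        pts = geo.centers()
        hit = np.array([len(x) > 0 for x in tree.query_ball_point(pts, radius)])
        values = np.where(hit, dG_aff, 0.0).reshape(geo.dims)
    return AffinityMap(geo, atom_type, values)


# ---------------------------------------------------------------------------
# AutoGrid .map text format
# ---------------------------------------------------------------------------

def _default_header(geo: GridGeometry) -> list[str]:
    nel = tuple(d - 1 for d in geo.dims)
    center = np.asarray(geo.origin) + geo.spacing * (np.asarray(geo.dims) - 1) / 2.0
    return [
        "GRID_PARAMETER_FILE gistdock.gpf",
        "GRID_DATA_FILE gistdock.maps.fld",
        "MACROMOLECULE receptor.pdbqt",
        f"SPACING {geo.spacing:g}",
        f"NELEMENTS {nel[0]} {nel[1]} {nel[2]}",
        f"CENTER {center[0]:.3f} {center[1]:.3f} {center[2]:.3f}",
    ]


def write_autogrid_map(amap: AffinityMap, path, header_lines: list[str] | None = None) -> None:
    """Write an AutoGrid map: 6 header lines, then one value per line, x fastest.

    ``header_lines`` allows bit-faithful passthrough of a base map's header.
    """
    header = header_lines if header_lines is not None else _default_header(amap.geometry)
    if len(header) != 6:
        raise ValueError(f"AutoGrid header must be 6 lines, got {len(header)}")
    # transpose to z-slowest so that x is the innermost loop on ravel
    flat = amap.values.transpose(2, 1, 0).ravel()
    with open(path, "w") as fh:
        for line in header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("\n".join(f"{v:.3f}" for v in flat))
        fh.write("\n")


def _parse_header(header: list[str]) -> GridGeometry:
    spacing = nel = center = None
    for line in header:
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "SPACING":
            spacing = float(tok[1])
        elif tok[0] == "NELEMENTS":
            nel = tuple(int(t) for t in tok[1:4])
        elif tok[0] == "CENTER":
            center = np.array([float(t) for t in tok[1:4]])
    if spacing is None or nel is None or center is None:
        raise ValueError("map header lacks SPACING/NELEMENTS/CENTER records")
    dims = tuple(n + 1 for n in nel)
    origin = center - spacing * (np.asarray(dims) - 1) / 2.0
    return GridGeometry(tuple(origin), spacing, dims)


def read_autogrid_map(path, atom_type: str = "") -> tuple[AffinityMap, list[str]]:
    """Read an AutoGrid map; returns the map and its verbatim header lines."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header, body = lines[:6], lines[6:]
    geo = _parse_header(header)
    values = np.array([float(v) for v in body if v.strip()], dtype=float)
    if values.size != geo.n_voxels:
        raise ValueError(
            f"{path}: {values.size} values for geometry {geo.dims} ({geo.n_voxels} points)"
        )
    values = values.reshape(geo.dims[2], geo.dims[1], geo.dims[0]).transpose(2, 1, 0)
    return AffinityMap(geo, atom_type, values), header


def add_to_existing_map(base_path, gain: AffinityMap, out_path) -> None:
    """Add a gain map elementwise onto an existing AutoGrid map file.

    The base file's header lines are passed through verbatim; geometries must
    match (spacing/dims exactly, centers to header precision).
    """
    base, header = read_autogrid_map(base_path, gain.atom_type)
    if not base.geometry.close_to(gain.geometry, tol=1e-3):
        raise ValueError(
            f"geometry mismatch: base {base.geometry.dims} @ {base.geometry.spacing} Å vs "
            f"gain {gain.geometry.dims} @ {gain.geometry.spacing} Å"
        )
    combined = AffinityMap(base.geometry, gain.atom_type, base.values + gain.values)
    write_autogrid_map(combined, out_path, header_lines=header)


def export_map_dx(amap: AffinityMap, path) -> None:
    write_dx(amap.geometry, amap.values, path)


# ---------------------------------------------------------------------------
# Interpolation (what a docking engine does with the maps)
# ---------------------------------------------------------------------------

def interpolate_map(amap: AffinityMap, points) -> np.ndarray:
    """Trilinear interpolation of map values at Cartesian points (Å)."""
    geo = amap.geometry
    axes = [np.asarray(geo.origin)[d] + geo.spacing * np.arange(geo.dims[d]) for d in range(3)]
    itp = RegularGridInterpolator(axes, amap.values, method="linear", bounds_error=False, fill_value=0.0)
    return itp(np.atleast_2d(np.asarray(points, dtype=float)))


def pose_gain_from_maps(maps: dict[str, AffinityMap], ligand) -> float:
    """Sum interpolated gain-map values over a pose's heavy atoms."""
    total = 0.0
    for atom in ligand.heavy_atoms:
        try:
            amap = maps[atom.ad_type]
        except KeyError:
            raise KeyError(f"no gain map for AutoDock type {atom.ad_type!r}") from None
        total += float(interpolate_map(amap, atom.coord)[0])
    return total
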