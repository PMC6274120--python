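"""Synthetic fixtures: GIST grids, toy complexes, calibration and screening sets.

Everything downstream of an MD engine can be exercised without one: these
generators emulate the *structure* of GIST output and docking data — pockets
of high-occupancy, high-free-energy water against a bulk-like background,
receptor/ligand structures with AutoDock types and charges, affinity tables
with a known planted displacement signal, and ranked screening lists with a
controllable separation between actives and decoys.  They do not emulate MD
statistics (spatial autocorrelation, realistic water networks, chemistry).

All generators are deterministic functions of their arguments and a seed, and
their file output is written through the production writers so that fixtures
always round-trip the production readers.

Planted free energies are decomposed into solute–water, water–water and
entropy parts consistently with the grid thermodynamics identities, with a
per-region ``dominance`` flag steering the excess into ΔH or −TΔS so both
branches of the enthalpy/entropy decomposition are exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fitting import Dataset, LigandRecord, ScanGrid
from .grids import (
    DEFAULT_BULK_EWW,
    GISTGrid,
    GridGeometry,
    derive_thermo,
    write_dx,
    write_gist_table,
)
from .scoring import Atom, Structure, ad4_score, default_forcefield, displacement_score, write_pdbqt
from .screening import ScreeningResult
from .watermap import AFFINITY_PARAMS, CutoffParams, build_map

__all__ = [
    "PlantedRegion",
    "FixtureSpec",
    "make_gist_fixture",
    "ToyComplex",
    "make_toy_complex",
    "make_affinity_dataset",
    "make_screening_set",
    "write_fixture_dir",
    "PROBE_RADII",
]

#: Displacement radius (Å) of the point-like probe atoms used by the planted
#: calibration dataset: small enough that a probe centred on a voxel covers
#: exactly that voxel (< spacing/2 for the default 0.375 Å lattice).
PROBE_RADII = {"C": 0.15}


# ---------------------------------------------------------------------------
# GIST grid fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRegion:
    """A rectangular block of unfavorable water planted in a fixture grid."""

    corner: tuple[int, int, int]     # lowest voxel index of the block
    extent: tuple[int, int, int]     # voxels per axis
    rho: float = 5.0                 # bulk units, above the density cutoff
    dG: float = 2.0                  # kcal/mol/water, above the ΔG cutoff
    dominance: str = "enthalpy"      # "enthalpy" or "entropy"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    dims: tuple[int, int, int] = (12, 12, 12)
    spacing: float = 0.375
    regions: tuple[PlantedRegion, ...] = (PlantedRegion((4, 4, 4), (3, 3, 3)),)
    background_rho: float = 1.0
    background_rho_sd: float = 0.05
    background_dG_sd: float = 0.05
    e_bulk_ww: float = DEFAULT_BULK_EWW


def _decompose_dG(dG: np.ndarray, dominance, e_bulk_ww: float) -> dict[str, np.ndarray]:
    """Split target ΔG values into the five raw fields.

    ``dominance`` is "enthalpy" (ΔH = 0.75 ΔG > −TΔS) or "entropy"
    (ΔH = 0.25 ΔG < −TΔS), scalar or per-voxel array of the two strings.
    The split satisfies ΔH = e_sw + 2 (e_ww − e_bulk) and −TΔS = ts_or + ts_tr
    by construction.
    """
    frac = np.where(np.asarray(dominance) == "enthalpy", 0.75, 0.25)
    dH = frac * dG
    mTdS = dG - dH
    e_ww = e_bulk_ww + 0.25 * dH
    e_sw = dH - 2.0 * (e_ww - e_bulk_ww)
    return {
        "e_sw": e_sw,
        "e_ww": np.broadcast_to(e_ww, dG.shape).copy(),
        "ts_orient": mTdS / 2.0,
        "ts_trans": mTdS / 2.0,
    }


def make_gist_fixture(spec: FixtureSpec = FixtureSpec()) -> GISTGrid:
    """Synthetic raw GIST grid: bulk-like background plus planted regions.

    Background voxels sit near ρ = 1, ΔG = 0; planted blocks take the levels
    of their :class:`PlantedRegion`.  The returned grid holds the five raw
    fields plus ``e_bulk_ww`` (derive thermodynamics downstream, as with real
    GIST output).
    """
    rng = np.random.default_rng(spec.seed)
    geo = GridGeometry.from_box((0.0, 0.0, 0.0), spec.spacing * spec.dims[0], spec.spacing)
    if geo.dims != tuple(spec.dims):
        geo = GridGeometry(geo.origin, spec.spacing, tuple(spec.dims))
    rho = np.clip(rng.normal(spec.background_rho, spec.background_rho_sd, spec.dims), 0.0, None)
    dG = rng.normal(0.0, spec.background_dG_sd, spec.dims)
    dom = np.full(spec.dims, "entropy", dtype=object)
    for reg in spec.regions:
        sl = tuple(slice(c, c + e) for c, e in zip(reg.corner, reg.extent))
        rho[sl] = reg.rho
        dG[sl] = reg.dG
        dom[sl] = reg.dominance
    parts = _decompose_dG(dG, dom, spec.e_bulk_ww)
    return GISTGrid(geometry=geo, rho=rho, e_bulk_ww=spec.e_bulk_ww, **parts)


# ---------------------------------------------------------------------------
# Toy receptor/ligand complexes
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    receptor: Structure
    native: Structure
    poses: list[Structure]       # native first, then perturbations and decoys
    pose_rmsds: list[float]      # exact heavy-atom RMSD of each pose vs native


def _ring_receptor(radius: float = 6.0, n: int = 12) -> Structure:
    """A ring of typed, charged atoms around the origin in the z = 0 plane."""
    types = ["C", "OA", "N", "C", "HD", "C"]
    atoms = []
    for i in range(n):
        ang = 2 * np.pi * i / n
        t = types[i % len(types)]
        q = {"C": 0.05, "OA": -0.35, "N": -0.25, "HD": 0.20}[t]
        el = "H" if t == "HD" else t[0]
        atoms.append(
            Atom(i + 1, el, t, (radius * np.cos(ang), radius * np.sin(ang), 0.0), q)
        )
    return Structure(atoms, n_tor=0, name="receptor")


def make_toy_complex(
    seed: int = 0,
    perturbations: tuple[float, ...] = (0.5, 1.0, 1.5),
    decoys: tuple[float, ...] = (3.0, 4.5),
) -> ToyComplex:
    """Small receptor + ligand pose set with exactly known RMSDs.

    The ligand has 6 heavy atoms and 2 hydrogens; candidate poses are rigid
    translations of the native pose along random unit vectors, so the
    heavy-atom RMSD of each pose equals its translation length exactly.
    ``perturbations`` are near-native (< 2 Å), ``decoys`` beyond 2 Å.
    """
    rng = np.random.default_rng(seed)
    receptor = _ring_receptor()
    heavy = [
        ("C", 0.04), ("C", 0.02), ("OA", -0.38), ("N", -0.30), ("C", 0.10), ("A", 0.01),
    ]
    coords = rng.uniform(-1.5, 1.5, size=(len(heavy), 3))
    atoms = [
        Atom(i + 1, "C" if t == "A" else t[0], t, tuple(c), q)
        for i, ((t, q), c) in enumerate(zip(heavy, coords))
    ]
    for j, parent in enumerate((2, 3)):  # hydrogens riding on OA and N
        base = np.asarray(atoms[parent].coord)
        atoms.append(
            Atom(len(heavy) + j + 1, "H", "HD", tuple(base + [0.0, 0.0, 1.0]), 0.21)
        )
    native = Structure(atoms, n_tor=2, name="native")

    poses = [native]
    rmsds = [0.0]
    for d in list(perturbations) + list(decoys):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        poses.append(native.translated(d * u))
        rmsds.append(float(d))
    return ToyComplex(receptor, native, poses, rmsds)


# ---------------------------------------------------------------------------
# Planted calibration dataset
# ---------------------------------------------------------------------------

def make_affinity_dataset(
    seed: int = 0,
    n_ligands: int = 20,
    dims: tuple[int, int, int] = (12, 12, 12),
    spacing: float = 0.375,
    planted: CutoffParams = AFFINITY_PARAMS,
    noise_sd: float = 0.02,
    scan_grid: ScanGrid | None = None,
) -> tuple[GISTGrid, Dataset]:
    """Grid + ligand set in which the planted parameters maximize the R² objective.

    Experimental affinities are manufactured as
    ``dG_exp = AD4(native) + ΔGaff* · n_disp*(native) + N(0, noise_sd)``
    with the displacement count taken under the planted cutoffs, so the
    planted combination maximizes R² in expectation.

    To make the maximizer *identifiable* on the scan lattice (not just a
    member of a plateau of equivalent masks), the grid carries one marker
    voxel per scan step of each cutoff: a ρ-marker at level r has
    ρ = r + Δ/2 with ΔG above the whole ΔGco range, so it enters or leaves
    the mask exactly when ρco crosses r; ΔG-markers mirror this for ΔGco.
    Markers are attached as point-like probe atoms (:data:`PROBE_RADII`) to
    randomly drawn ligands 1..n−1; ligand 0 is a marker-free sentinel.  Any
    cutoff pair other than the planted one flips a nonempty block of markers
    relative to the planted mask, and because every marker belongs to some
    marked ligand while the sentinel holds none, the flip can never shift all
    displacement counts uniformly (and the random assignment keeps level
    blocks from hitting the marked ligands uniformly) — so no other lattice
    point reproduces the planted count vector up to an affine map, and R²
    identifies the planted pair.  Remaining exact ties (if any) resolve to
    the planted values through the scan's conservative tie-break.

    ``noise_sd`` defaults to 0.02 kcal/mol, the small-noise regime in which
    the planted parameters stay recoverable to one scan step: the recovered
    gain behaves like a regression coefficient with standard error about
    noise_sd / (sd(n_disp)·√n_ligands) ≈ noise_sd/5, which the finest scan
    step (0.01 kcal/mol on the ΔGaff axis) bounds from above at ≈ 0.02.
    Larger values are useful to study degradation, not recovery.
    """
    sg = scan_grid or ScanGrid()
    rng = np.random.default_rng(seed)
    geo = GridGeometry.from_box((0.0, 0.0, 0.0), spacing * dims[0], spacing)
    geo = GridGeometry(geo.origin, spacing, tuple(dims))
    n_vox = geo.n_voxels

    rho_levels = np.asarray(sg.rho_co_values, dtype=float)
    dgco_levels = np.asarray(sg.dG_co_values, dtype=float)
    rho_step = float(np.min(np.diff(rho_levels))) if len(rho_levels) > 1 else 0.1
    dg_step = float(np.min(np.diff(dgco_levels))) if len(dgco_levels) > 1 else 0.1
    rho_top = float(rho_levels.max()) + rho_step  # above every density cutoff
    dg_top = float(dgco_levels.max()) + dg_step   # above every ΔG cutoff

    # background: occupied below bulk and *favorable* (ΔG < 0), so background
    # voxels never satisfy the free-energy criterion at any scanned cutoff
    rho = np.clip(rng.normal(0.5, 0.05, n_vox), 0.0, None)
    dG = rng.normal(-0.5, 0.1, n_vox)
    dG = np.minimum(dG, -0.05)

    signal_counts = rng.integers(0, 3, size=n_ligands)
    n_markers = len(rho_levels) + len(dgco_levels)
    n_special = n_markers + int(signal_counts.sum()) + n_ligands  # + background probes
    special = rng.choice(n_vox, size=n_special, replace=False)
    it = iter(special)

    centers = geo.centers()
    lig_atoms: list[list[Atom]] = [[] for _ in range(n_ligands)]

    def add_probe(lig: int, voxel: int) -> None:
        serial = len(lig_atoms[lig]) + 1
        q = float(rng.uniform(-0.1, 0.1))
        lig_atoms[lig].append(Atom(serial, "C", "C", tuple(centers[voxel]), q))

    # ligand 0 stays marker-free (sentinel); marker-to-ligand assignment is
    # drawn at random so no block of scan levels hits all ligands uniformly
    # (a regular round-robin would, making whole blocks cancel affinely)
    n_marked = n_ligands - 1
    for r in rho_levels:                     # ρ-markers, one per scan step
        v = next(it)
        rho[v] = r + rho_step / 2.0
        dG[v] = dg_top
        add_probe(1 + int(rng.integers(n_marked)), v)
    for g in dgco_levels:                    # ΔG-markers, one per scan step
        v = next(it)
        rho[v] = rho_top
        dG[v] = g + dg_step / 2.0
        add_probe(1 + int(rng.integers(n_marked)), v)
    for lig in range(n_ligands):             # always-displaced signal voxels
        for _ in range(signal_counts[lig]):
            v = next(it)
            rho[v] = rho_top
            dG[v] = dg_top
            add_probe(lig, v)
        add_probe(lig, next(it))             # background probe, never displaced

    dom = np.where(rng.random(n_vox) < 0.5, "enthalpy", "entropy")
    parts = _decompose_dG(dG, dom, DEFAULT_BULK_EWW)
    grid = GISTGrid(
        geometry=geo,
        rho=rho.reshape(dims),
        e_bulk_ww=DEFAULT_BULK_EWW,
        **{k: v.reshape(dims) for k, v in parts.items()},
    )
    grid = derive_thermo(grid)

    receptor = _ring_receptor(radius=5.5, n=8)
    ff = default_forcefield()
    wmap = build_map(grid, planted)
    records = []
    for lig in range(n_ligands):
        native = Structure(lig_atoms[lig], n_tor=0, name=f"probe{lig:02d}")
        watdisp, _ = displacement_score(native, wmap, dG_aff=planted.dG_aff, radii=PROBE_RADII)
        base = ad4_score(receptor, native, ff).total_ad4
        dg_exp = base + watdisp + float(rng.normal(0.0, noise_sd))
        records.append(LigandRecord(f"probe{lig:02d}", native, [native], dg_exp))
    return grid, Dataset(receptor, records, displacement_radii=dict(PROBE_RADII))


# ---------------------------------------------------------------------------
# Screening sets
# ---------------------------------------------------------------------------

def make_screening_set(
    n_actives: int, n_decoys: int, signal: float, seed: int = 0
) -> ScreeningResult:
    """Two-Gaussian screening scores (unit variance, actives shifted by −signal).

    The expected AUC is Φ(signal/√2); signal 0 gives 0.5 in expectation,
    large signal approaches 1.
    """
    rng = np.random.default_rng(seed)
    scores = np.concatenate(
        [rng.normal(-signal, 1.0, n_actives), rng.normal(0.0, 1.0, n_decoys)]
    )
    labels = ["active"] * n_actives + ["decoy"] * n_decoys
    ids = [f"cmpd{i:06d}" for i in range(n_actives + n_decoys)]
    return ScreeningResult(tuple(ids), tuple(scores), tuple(labels))


# ---------------------------------------------------------------------------
# Self-contained fixture directory
# ---------------------------------------------------------------------------

def write_fixture_dir(outdir, seed: int = 0) -> dict:
    """Emit a self-contained fixture directory through the production writers.

    Contents: the five raw GIST fields as OpenDX files plus the per-voxel
    table, a toy receptor and ligand pose set as PDBQT, the planted
    calibration affinities as CSV, and a screening list as CSV, with a
    manifest recording the seed and file roles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(seed=seed)
    grid = make_gist_fixture(spec)
    for name in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans"):
        write_dx(grid.geometry, getattr(grid, name), outdir / f"gist-{name}.dx")
    write_gist_table(grid, outdir / "gist-table.dat")

    toy = make_toy_complex(seed=seed)
    write_pdbqt(toy.receptor, outdir / "receptor.pdbqt")
    write_pdbqt(toy.poses, outdir / "ligand-poses.pdbqt")

    caldir = outdir / "calibration"
    caldir.mkdir(exist_ok=True)
    agrid, dataset = make_affinity_dataset(seed=seed)
    write_gist_table(agrid, caldir / "gist-table.dat")
    write_pdbqt(dataset.receptor, caldir / "receptor.pdbqt")
    for rec in dataset.ligands:
        write_pdbqt(rec.poses, caldir / f"{rec.id}.pdbqt")
    with open(caldir / "affinities.csv", "w") as fh:
        fh.write("id,dG_exp\n")
        for rec in dataset.ligands:
            fh.write(f"{rec.id},{rec.dG_exp:.6f}\n")

    screen = make_screening_set(50, 500, signal=1.0, seed=seed)
    screen.to_csv(outdir / "screening.csv")

    manifest = {
        "seed": seed,
        "gist_fields": [f"gist-{n}.dx" for n in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans")],
        "gist_table": "gist-table.dat",
        "receptor": "receptor.pdbqt",
        "ligand_poses": "ligand-poses.pdbqt",
        "pose_rmsds": toy.pose_rmsds,
        "calibration": {
            "gist_table": "calibration/gist-table.dat",
            "receptor": "calibration/receptor.pdbqt",
            "affinities": "calibration/affinities.csv",
            "ligands": [f"calibration/{rec.id}.pdbqt" for rec in dataset.ligands],
            "probe_radii": PROBE_RADII,
        },
        "screening": "screening.csv",
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
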