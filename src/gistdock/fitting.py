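"""Calibration of the three water-displacement parameters (ρco, ΔGco, ΔGaff).

The three parameters are fitted by exhaustive scan against two objectives over
a set of ligands with known experimental affinities and native poses:

* **affinity** — maximize R² (squared Pearson correlation) between the
  combined score of each ligand's *native* pose and its experimental ΔG;
* **pose** — maximize the fraction of ligands whose best-scored candidate
  pose lies within 2 Å RMSD of the native pose.

The published scan covers ΔGco from 0.0 to 4.0 kcal/mol in 0.1 steps (41
values), ΔGaff from 0.0 to −2.0 kcal/mol in −0.01 steps (201 values) and 61
density-cutoff values in 0.1 steps; endpoints are inclusive.  The scan
exploits two structural facts: only the (ρco, ΔGco) pair determines the mask
(61 × 41 = 2,501 distinct masks), and for a fixed mask ΔG_watdisp is linear
in ΔGaff — so per-structure displacement *counts* are tabulated once per
cutoff pair and every ΔGaff value is then a vectorized rescale.

Objective ties break toward the more conservative model: smaller |ΔGaff|,
then larger ΔGco, then larger ρco.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import GISTGrid
from .scoring import ForceFieldParams, Structure, ad4_score, combined_score, default_forcefield, vdw_radii
from .watermap import CutoffParams, build_map

__all__ = [
    "LigandRecord",
    "Dataset",
    "ScanGrid",
    "ScanResult",
    "pearson_r2",
    "rmsd",
    "evaluate_params",
    "scan",
    "RMSD_SUCCESS_CUTOFF",
]

#: A docked pose within this RMSD (Å) of the native pose counts as a success.
RMSD_SUCCESS_CUTOFF = 2.0


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class LigandRecord:
    """One ligand: native pose, candidate poses, experimental affinity (kcal/mol)."""

    id: str
    native: Structure
    poses: list[Structure]
    dG_exp: float

    def __post_init__(self):
        if not np.isfinite(self.dG_exp):
            raise ValueError(f"ligand {self.id}: dG_exp must be finite")
        if not self.poses:
            raise ValueError(f"ligand {self.id}: at least one candidate pose required")


@dataclass
class Dataset:
    """Receptor plus ligand records sharing one coordinate frame.

    ``displacement_radii`` overrides the per-type vdW radii used for the
    displacement indicator (defaults to the force-field Rii/2 radii).
    """

    receptor: Structure
    ligands: list[LigandRecord]
    displacement_radii: dict[str, float] | None = None

    def __post_init__(self):
        if not self.ligands:
            raise ValueError("dataset has no ligands")


@dataclass(frozen=True)
class ScanGrid:
    """Inclusive-endpoint parameter lattice for the exhaustive scan.

    Defaults reproduce the published 61 × 41 × 201 grid: ΔGco 0.0→4.0 step
    0.1, ΔGaff 0.0→−2.0 step −0.01, and 61 density-cutoff values in 0.1
    steps from the neutral value 0.0 up to 6.0 (all three parameters start
    at their "off" setting).
    """

    rho_co_values: tuple = tuple(np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10))
    dG_co_values: tuple = tuple(np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10))
    dG_aff_values: tuple = tuple(np.round(np.arange(0.0, -2.0 - 1e-9, -0.01), 10))

    @property
    def n_combinations(self) -> int:
        return len(self.rho_co_values) * len(self.dG_co_values) * len(self.dG_aff_values)

    def combinations(self):
        for r in self.rho_co_values:
            for g in self.dG_co_values:
                for a in self.dG_aff_values:
                    yield CutoffParams(r, g, a)


# ---------------------------------------------------------------------------
# Elementary metrics
# ---------------------------------------------------------------------------

def pearson_r2(x, y) -> float:
    """Squared Pearson correlation; sign-agnostic, in [0, 1].

    Raises on fewer than 3 points or zero variance (undefined, not 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def rmsd(a: Structure, b: Structure) -> float:
    """Heavy-atom RMSD (Å) between two poses in the same receptor frame.

    No re-superposition and no symmetry correction: docking output shares the
    receptor frame and atom ordering with the native pose.
    """
    ca = np.array([at.coord for at in a.heavy_atoms], dtype=float)
    cb = np.array([at.coord for at in b.heavy_atoms], dtype=float)
    if ca.shape != cb.shape:
        raise ValueError(f"heavy-atom count mismatch: {len(ca)} vs {len(cb)}")
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Direct (uncached) evaluation of one parameter combination
# ---------------------------------------------------------------------------

def evaluate_params(
    dataset: Dataset,
    grid: GISTGrid,
    params: CutoffParams,
    ff: ForceFieldParams | None = None,
) -> tuple[float, float]:
    """(affinity R², pose success rate) for one parameter combination.

    The affinity objective correlates the combined score of each ligand's
    native pose with its experimental ΔG; the pose objective picks each
    ligand's lowest-total candidate pose and tests RMSD < 2 Å against the
    native pose.  The affinity R² is NaN when the correlation is undefined
    (fewer than 3 ligands, or zero variance in scores or affinities); the
    pose rate is always defined.
    """
    ff = ff or default_forcefield()
    radii = dataset.displacement_radii or vdw_radii(ff)
    wmap = build_map(grid, params)

    native_scores = []
    successes = []
    for rec in dataset.ligands:
        s = combined_score(dataset.receptor, rec.native, wmap, ff, radii=radii)
        native_scores.append(s.total)
        totals = [
            combined_score(dataset.receptor, pose, wmap, ff, radii=radii).total
            for pose in rec.poses
        ]
        best = rec.poses[int(np.argmin(totals))]
        successes.append(rmsd(best, rec.native) < RMSD_SUCCESS_CUTOFF)

    try:
        r2 = pearson_r2(native_scores, [rec.dG_exp for rec in dataset.ligands])
    except ValueError:
        r2 = float("nan")
    return r2, float(np.mean(successes))


# ---------------------------------------------------------------------------
# Exhaustive scan (cached masks, linear ΔGaff)
# ---------------------------------------------------------------------------

def _ndisp_table(
    struct: Structure,
    grid: GISTGrid,
    rho_vals: np.ndarray,
    dgco_vals: np.ndarray,
    radii: dict[str, float],
) -> np.ndarray:
    """Displaced-heavy-atom counts for one pose over the (ρco, ΔGco) lattice.

    For each heavy atom the covered voxels are fixed; over them the largest ΔG
    among voxels passing each density cutoff decides displacement for every
    ΔGco at once.  Returns an (n_rho, n_dgco) integer array.
    """
    centers = grid.geometry.centers()
    rho_flat = grid.rho.ravel()
    dg_flat = grid.dG.ravel()
    out = np.zeros((len(rho_vals), len(dgco_vals)), dtype=np.int32)
    for atom in struct.heavy_atoms:
        try:
            radius = radii[atom.ad_type]
        except KeyError:
            raise KeyError(f"no displacement radius for AutoDock type {atom.ad_type!r}") from None
        d2 = np.sum((centers - np.asarray(atom.coord)) ** 2, axis=1)
        cov = d2 <= radius * radius
        if not cov.any():
            continue
        cov_rho = rho_flat[cov]
        cov_dg = dg_flat[cov]
        passes = cov_rho[None, :] > rho_vals[:, None]  # (n_rho, K)
        max_dg = np.where(passes, cov_dg[None, :], -np.inf).max(axis=1)  # (n_rho,)
        out += max_dg[:, None] > dgco_vals[None, :]
    return out


def _r2_vector(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """R² of each row block of ``scores`` (..., L) against y (L,); NaN where degenerate."""
    s = scores - scores.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((s ** 2).sum(axis=-1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s * yc).sum(axis=-1) / denom
    r2 = r * r
    r2[denom == 0] = np.nan
    return r2


@dataclass
class ScanResult:
    scan_grid: ScanGrid
    r2: np.ndarray        # (n_rho, n_dgco, n_aff)
    success: np.ndarray   # (n_rho, n_dgco, n_aff)
    affinity_params: CutoffParams
    pose_params: CutoffParams

    def to_frame(self) -> pd.DataFrame:
        """One row per combination: parameters, R², pose success rate."""
        g = self.scan_grid
        rr, gg, aa = np.meshgrid(
            g.rho_co_values, g.dG_co_values, g.dG_aff_values, indexing="ij"
        )
        return pd.DataFrame(
            {
                "rho_co": rr.ravel(),
                "dG_co": gg.ravel(),
                "dG_aff": aa.ravel(),
                "r2": self.r2.ravel(),
                "success_rate": self.success.ravel(),
            }
        )

    def write_report(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _select(objective: np.ndarray, sg: ScanGrid) -> CutoffParams:
    """Argmax with conservative tie-breaks (smaller |ΔGaff|, larger ΔGco, larger ρco)."""
    best = np.nanmax(objective)
    tied = np.argwhere(objective == best)
    rho = np.asarray(sg.rho_co_values)[tied[:, 0]]
    dgc = np.asarray(sg.dG_co_values)[tied[:, 1]]
    aff = np.asarray(sg.dG_aff_values)[tied[:, 2]]
    order = np.lexsort((-rho, -dgc, np.abs(aff)))
    i = order[0]
    return CutoffParams(float(rho[i]), float(dgc[i]), float(aff[i]))


def scan(
    dataset: Dataset,
    grid: GISTGrid,
    scan_grid: ScanGrid | None = None,
    ff: ForceFieldParams | None = None,
) -> ScanResult:
    """Exhaustively evaluate every parameter combination of ``scan_grid``.

    Equivalent to calling :func:`evaluate_params` per combination, but the
    AD4 part of every score is computed once per pose, displacement counts
    are tabulated once per (ρco, ΔGco) pair, and the ΔGaff axis is applied as
    a linear rescale.
    """
    sg = scan_grid or ScanGrid()
    ff = ff or default_forcefield()
    if not grid.has_thermo:
        raise ValueError("grid has no derived dG; run derive_thermo first")
    radii = dataset.displacement_radii or vdw_radii(ff)
    rho_vals = np.asarray(sg.rho_co_values, dtype=float)
    dgco_vals = np.asarray(sg.dG_co_values, dtype=float)
    aff_vals = np.asarray(sg.dG_aff_values, dtype=float)

    L = len(dataset.ligands)
    y = np.array([rec.dG_exp for rec in dataset.ligands])
    native_ad4 = np.empty(L)
    native_nd = np.empty((len(rho_vals), len(dgco_vals), L), dtype=np.int32)
    max_p = max(len(rec.poses) for rec in dataset.ligands)
    pose_ad4 = np.full((L, max_p), np.inf)
    pose_nd = np.zeros((len(rho_vals), len(dgco_vals), L, max_p), dtype=np.int32)
    pose_ok = np.zeros((L, max_p), dtype=bool)

    for li, rec in enumerate(dataset.ligands):
        native_ad4[li] = ad4_score(dataset.receptor, rec.native, ff).total_ad4
        native_nd[:, :, li] = _ndisp_table(rec.native, grid, rho_vals, dgco_vals, radii)
        for pi, pose in enumerate(rec.poses):
            pose_ad4[li, pi] = ad4_score(dataset.receptor, pose, ff).total_ad4
            pose_nd[:, :, li, pi] = _ndisp_table(pose, grid, rho_vals, dgco_vals, radii)
            pose_ok[li, pi] = rmsd(pose, rec.native) < RMSD_SUCCESS_CUTOFF

    shape = (len(rho_vals), len(dgco_vals), len(aff_vals))
    r2 = np.empty(shape)
    success = np.empty(shape)
    for ai, a in enumerate(aff_vals):
        scores = native_ad4[None, None, :] + a * native_nd  # (R, G, L)
        r2[:, :, ai] = _r2_vector(scores, y)
        totals = pose_ad4[None, None, :, :] + a * pose_nd  # (R, G, L, P)
        best = np.argmin(totals, axis=-1)  # (R, G, L)
        ok = np.take_along_axis(
            np.broadcast_to(pose_ok, best.shape + (max_p,)), best[..., None], axis=-1
        )[..., 0]
        success[:, :, ai] = ok.mean(axis=-1)

    return ScanResult(
        scan_grid=sg,
        r2=r2,
        success=success,
        affinity_params=_select(r2, sg),
        pose_params=_select(success, sg),
    )
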