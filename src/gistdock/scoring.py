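"""Pose scoring: AutoDock4.2 semiempirical force field plus water-displacement gain.

The combined score of a fixed ligand pose against a rigid receptor is

    ΔG_bind = ΔG_AD4 + ΔG_watdisp

where ΔG_AD4 is the five-term AutoDock4.2 free-energy force field

    ΔG_AD4 = W_vdW  Σ (A/r¹² − B/r⁶)
           + W_hb   Σ E(θ) (C/r¹² − D/r¹⁰)
           + W_elec Σ q_i q_j / (ε(r) r)
           + W_conf N_tor
           + W_dsol Σ (S_i V_j + S_j V_i) exp(−r²/2σ²)

summed over intermolecular ligand–receptor atom pairs, and ΔG_watdisp is the
displacement gain: ΔG_aff per ligand *heavy* atom whose van der Waals sphere
covers (contains the center of) at least one unfavorable-water voxel.  The two
desolvation descriptions deliberately coexist: the AD4 term is a continuum
penalty, the displacement term a discrete gain, and they do not conflict.

Structures are read from PDBQT, the AutoDock dialect of PDB carrying partial
charges and AutoDock atom types; TORSDOF records give the ligand's
rotatable-bond count N_tor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .watermap import UnfavorableWaterMap

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "AtomTypeParams",
    "ForceFieldParams",
    "ScoreBreakdown",
    "default_forcefield",
    "vdw_radii",
    "read_pdbqt",
    "read_pdbqt_poses",
    "write_pdbqt",
    "displacement_score",
    "ad4_score",
    "combined_score",
]

#: Coulomb constant converting e²/Å to kcal/mol.
ELEC_CONSTANT = 332.06363

#: Charge-dependent part of the atomic solvation parameter (per |e|).
QASP = 0.01097

#: Minimum pair distance, Å; shorter distances are clamped with a warning.
MIN_PAIR_DISTANCE = 0.01


# ---------------------------------------------------------------------------
# Atoms and structures
# ---------------------------------------------------------------------------

_TYPE_TO_ELEMENT = {
    "H": "H", "HD": "H", "HS": "H",
    "C": "C", "A": "C",
    "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "F": "F", "Cl": "Cl", "CL": "Cl", "Br": "Br", "BR": "Br", "I": "I",
    "P": "P", "Mg": "Mg", "MG": "Mg", "Ca": "Ca", "CA": "Ca",
    "Mn": "Mn", "MN": "Mn", "Fe": "Fe", "FE": "Fe", "Zn": "Zn", "ZN": "Zn",
}


def element_of(ad_type: str) -> str:
    """Chemical element for an AutoDock atom-type code."""
    try:
        return _TYPE_TO_ELEMENT[ad_type]
    except KeyError:
        # fall back on the leading alphabetic characters
        return ad_type[:2].capitalize() if len(ad_type) > 1 and ad_type[1].islower() else ad_type[0]


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str
    ad_type: str
    coord: tuple[float, float, float]
    charge: float
    name: str = ""

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.coord):
            raise ValueError(f"atom {self.serial}: non-finite coordinate {self.coord}")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Structure:
    """Ordered atom records of a receptor or one ligand pose.

    ``n_tor`` is the ligand's rotatable-bond count (0 for receptors).
    """

    atoms: list[Atom]
    n_tor: int = 0
    name: str = ""

    def __post_init__(self):
        if self.n_tor < 0:
            raise ValueError(f"n_tor must be >= 0, got {self.n_tor}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def ad_types(self) -> list[str]:
        return [a.ad_type for a in self.atoms]

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def translated(self, shift) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        atoms = [
            Atom(a.serial, a.element, a.ad_type, tuple(np.asarray(a.coord) + shift), a.charge, a.name)
            for a in self.atoms
        ]
        return Structure(atoms, self.n_tor, self.name)


# ---------------------------------------------------------------------------
# PDBQT I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str) -> Atom:
    serial = int(line[6:11])
    name = line[12:16].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    charge = float(line[70:76])
    ad_type = line[77:79].strip()
    return Atom(serial, element_of(ad_type), ad_type, (x, y, z), charge, name)


def read_pdbqt(path) -> Structure:
    """Read a single-model PDBQT file (receptor or one ligand pose)."""
    poses = read_pdbqt_poses(path)
    if len(poses) != 1:
        raise ValueError(f"{path} holds {len(poses)} models; expected one")
    return poses[0]


def read_pdbqt_poses(path) -> list[Structure]:
    """Read a PDBQT file, honoring MODEL/ENDMDL blocks (AutoDock pose sets).

    ATOM/HETATM records supply coordinates, partial charge (columns 71–76)
    and AutoDock atom type (columns 78–79); a TORSDOF record supplies the
    rotatable-bond count.  ROOT/BRANCH tree records are accepted and ignored
    (poses are scored rigid).
    """
    path = Path(path)
    poses: list[Structure] = []
    atoms: list[Atom] = []
    n_tor = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line.split(maxsplit=1)[0] if line.strip() else ""
            if rec == "MODEL":
                in_model = True
                atoms, n_tor = [], 0
            elif rec in ("ATOM", "HETATM"):
                atoms.append(_parse_atom_line(line))
            elif rec == "TORSDOF":
                n_tor = int(line.split()[1])
            elif rec == "ENDMDL":
                poses.append(Structure(atoms, n_tor, name=path.stem))
                atoms, n_tor = [], 0
                in_model = False
    if atoms and not in_model:
        poses.append(Structure(atoms, n_tor, name=path.stem))
    if not poses:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return poses


def write_pdbqt(structures: Structure | list[Structure], path) -> None:
    """Write one structure (flat) or several (MODEL blocks) as PDBQT."""
    multi = isinstance(structures, (list, tuple))
    models = list(structures) if multi else [structures]
    with open(path, "w") as fh:
        for n, s in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL {n:>8}\n")
            fh.write("ROOT\n")
            for a in s.atoms:
                name = (a.name or a.element)[:4]
                x, y, z = a.coord
                fh.write(
                    f"ATOM  {a.serial:>5} {name:<4} LIG A   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}    "
                    f"{a.charge:6.3f} {a.ad_type:<2}\n"
                )
            fh.write("ENDROOT\n")
            fh.write(f"TORSDOF {s.n_tor}\n")
            if multi:
                fh.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# Force-field parameters (AutoDock4.2 free-energy model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomTypeParams:
    """Per-type constants: Rii is the like-pair equilibrium distance (Å), so
    the per-atom vdW radius is Rii/2; eps the well depth (kcal/mol); vol and
    solpar the desolvation volume (Å³) and solvation parameter; hb_eps/hb_req
    the 12-10 hydrogen-bond well for acceptor types (0 where inapplicable)."""

    rii: float
    eps: float
    vol: float
    solpar: float
    hb_eps: float = 0.0
    hb_req: float = 0.0
    donor: bool = False
    acceptor: bool = False


_AD4_TYPES: dict[str, AtomTypeParams] = {
    "C":  AtomTypeParams(4.00, 0.150, 33.5103, -0.00143),
    "A":  AtomTypeParams(4.00, 0.150, 33.5103, -0.00052),
    "N":  AtomTypeParams(3.50, 0.160, 22.4493, -0.00162),
    "NA": AtomTypeParams(3.50, 0.160, 22.4493, -0.00162, 5.0, 1.9, acceptor=True),
    "NS": AtomTypeParams(3.50, 0.160, 22.4493, -0.00162, 5.0, 1.9, acceptor=True),
    "OA": AtomTypeParams(3.20, 0.200, 17.1573, -0.00251, 5.0, 1.9, acceptor=True),
    "OS": AtomTypeParams(3.20, 0.200, 17.1573, -0.00251, 5.0, 1.9, acceptor=True),
    "S":  AtomTypeParams(4.00, 0.200, 33.5103, -0.00214),
    "SA": AtomTypeParams(4.00, 0.200, 33.5103, -0.00214, 1.0, 2.5, acceptor=True),
    "H":  AtomTypeParams(2.00, 0.020, 0.0000, 0.00051),
    "HD": AtomTypeParams(2.00, 0.020, 0.0000, 0.00051, donor=True),
    "HS": AtomTypeParams(2.00, 0.020, 0.0000, 0.00051, donor=True),
    "F":  AtomTypeParams(3.09, 0.080, 15.4480, -0.00110),
    "Cl": AtomTypeParams(4.09, 0.276, 35.8235, -0.00110),
    "Br": AtomTypeParams(4.33, 0.389, 42.5661, -0.00110),
    "I":  AtomTypeParams(4.72, 0.550, 55.0585, -0.00110),
    "P":  AtomTypeParams(4.20, 0.200, 38.7924, -0.00110),
    "Mg": AtomTypeParams(1.30, 0.875, 1.5600, -0.00110),
    "Ca": AtomTypeParams(1.98, 0.550, 2.7700, -0.00110),
    "Mn": AtomTypeParams(1.30, 0.875, 2.1400, -0.00110),
    "Fe": AtomTypeParams(1.30, 0.010, 1.8400, -0.00110),
    "Zn": AtomTypeParams(1.48, 0.550, 1.7000, -0.00110),
}


@dataclass(frozen=True)
class ForceFieldParams:
    """Weights and per-type tables of the AutoDock4.2 free-energy model.

    The five weights are the published AutoDock4.2 calibration; note the vdW
    weight is 1.37× the hydrogen-bond weight (0.1662/0.1209), a mild implicit
    bias toward hydrophobic contacts.  ``sigma`` is the desolvation Gaussian width (Å);
    ``cutoff`` the nonbonded cutoff (Å, ``None`` disables it).  E(θ) of the
    hydrogen-bond term defaults to 1 (orientation-independent well): this
    rescoring path evaluates fixed poses where the directional machinery has
    little leverage; ``hbond_directionality`` is the extension hook.
    """

    w_vdw: float = 0.1662
    w_hbond: float = 0.1209
    w_elec: float = 0.1406
    w_conf: float = 0.2983
    w_desolv: float = 0.1322
    sigma: float = 3.5
    cutoff: float | None = 8.0
    atom_types: dict[str, AtomTypeParams] = field(default_factory=lambda: dict(_AD4_TYPES))
    hbond_directionality: object = None  # callable(pair geometry) -> E(θ); None = 1

    def type_params(self, ad_type: str) -> AtomTypeParams:
        try:
            return self.atom_types[ad_type]
        except KeyError:
            raise KeyError(f"no force-field parameters for AutoDock type {ad_type!r}") from None


def default_forcefield() -> ForceFieldParams:
    return ForceFieldParams()


def vdw_radii(ff: ForceFieldParams | None = None) -> dict[str, float]:
    """Per-type van der Waals radii (Rii/2, Å), used for water displacement."""
    ff = ff or default_forcefield()
    return {t: p.rii / 2.0 for t, p in ff.atom_types.items()}


def _epsilon_r(r: np.ndarray) -> np.ndarray:
    """Distance-dependent dielectric (Mehler–Solmajer sigmoidal screening)."""
    A = -8.5525
    lam = 0.003627
    k = 7.7839
    eps0 = 78.4
    B = eps0 - A
    return A + B / (1.0 + k * np.exp(-lam * B * r))


# ---------------------------------------------------------------------------
# Score container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-term energies (kcal/mol) for one pose."""

    vdw: float
    hbond: float
    elec: float
    conf: float
    desolv: float
    watdisp: float = 0.0
    displaced_atom_serials: tuple[int, ...] = ()

    @property
    def total_ad4(self) -> float:
        return self.vdw + self.hbond + self.elec + self.conf + self.desolv

    @property
    def total(self) -> float:
        return self.total_ad4 + self.watdisp

    def as_dict(self) -> dict[str, float]:
        return {
            "vdw": self.vdw,
            "hbond": self.hbond,
            "elec": self.elec,
            "conf": self.conf,
            "desolv": self.desolv,
            "total_ad4": self.total_ad4,
            "watdisp": self.watdisp,
            "total": self.total,
            "n_displaced": len(self.displaced_atom_serials),
        }


# ---------------------------------------------------------------------------
# Water-displacement gain
# ---------------------------------------------------------------------------

def displacement_score(
    ligand: Structure,
    wmap: UnfavorableWaterMap,
    dG_aff: float | None = None,
    radii: dict[str, float] | None = None,
) -> tuple[float, tuple[int, ...]]:
    """ΔG_watdisp for one pose: ΔG_aff per displacing heavy atom.

    A heavy atom displaces when at least one unfavorable voxel *center* lies
    within its vdW radius (inclusive).  The gain is flat per atom no matter
    how many voxels it covers, and two atoms covering the same voxel both
    earn it.  Hydrogens never displace.  Returns (watdisp, serials of
    displacing atoms).
    """
    if dG_aff is None:
        dG_aff = wmap.params.dG_aff
    radii = radii if radii is not None else vdw_radii()
    heavy = ligand.heavy_atoms
    if not heavy:
        return 0.0, ()
    unknown = sorted({a.ad_type for a in heavy if a.ad_type not in radii})
    if unknown:
        raise KeyError(f"no displacement radius for AutoDock type(s) {unknown}")
    centers = wmap.true_centers()
    if len(centers) == 0:
        return 0.0, ()
    coords = np.array([a.coord for a in heavy], dtype=float)
    r = np.array([radii[a.ad_type] for a in heavy], dtype=float)
    d = cdist(coords, centers)
    displaced = (d <= r[:, None]).any(axis=1)
    serials = tuple(a.serial for a, hit in zip(heavy, displaced) if hit)
    return dG_aff * len(serials), serials


# ---------------------------------------------------------------------------
# AutoDock4.2 force field
# ---------------------------------------------------------------------------

def ad4_score(receptor: Structure, ligand: Structure, ff: ForceFieldParams | None = None) -> ScoreBreakdown:
    """Evaluate the five AD4.2 terms over intermolecular pairs (continuous,
    no grid interpolation; pairs beyond the nonbonded cutoff contribute 0)."""
    ff = ff or default_forcefield()
    lp = [ff.type_params(t) for t in ligand.ad_types]
    rp = [ff.type_params(t) for t in receptor.ad_types]

    r = cdist(ligand.coords, receptor.coords)
    n_clash = int((r < MIN_PAIR_DISTANCE).sum())
    if n_clash:
        logger.warning(
            "%d atom pair(s) closer than %.2f Å; distances clamped", n_clash, MIN_PAIR_DISTANCE
        )
        r = np.maximum(r, MIN_PAIR_DISTANCE)
    within = np.ones_like(r, dtype=bool) if ff.cutoff is None else (r <= ff.cutoff)

    l_eps = np.array([p.eps for p in lp]); l_rii = np.array([p.rii for p in lp])
    r_eps = np.array([p.eps for p in rp]); r_rii = np.array([p.rii for p in rp])
    req = (l_rii[:, None] + r_rii[None, :]) / 2.0
    eps = np.sqrt(l_eps[:, None] * r_eps[None, :])

    # hydrogen-bond pairs: donor hydrogen (HD/HS) against acceptor (OA/NA/SA…)
    l_don = np.array([p.donor for p in lp]); l_acc = np.array([p.acceptor for p in lp])
    r_don = np.array([p.donor for p in rp]); r_acc = np.array([p.acceptor for p in rp])
    hb_pair = (l_don[:, None] & r_acc[None, :]) | (l_acc[:, None] & r_don[None, :])
    l_hbe = np.array([p.hb_eps for p in lp]); l_hbr = np.array([p.hb_req for p in lp])
    r_hbe = np.array([p.hb_eps for p in rp]); r_hbr = np.array([p.hb_req for p in rp])
    # the acceptor member of the pair defines the 12-10 well
    hb_eps = np.where(l_acc[:, None], l_hbe[:, None], r_hbe[None, :])
    hb_req = np.where(l_acc[:, None], l_hbr[:, None], r_hbr[None, :])

    inv_r6 = r ** -6
    vdw_pair = eps * (req ** 12 * inv_r6 ** 2 - 2.0 * req ** 6 * inv_r6)
    with np.errstate(invalid="ignore"):
        C = 5.0 * hb_eps * hb_req ** 12
        D = 6.0 * hb_eps * hb_req ** 10
        hb_pair_e = C * inv_r6 ** 2 - D * r ** -10
    etheta = 1.0 if ff.hbond_directionality is None else ff.hbond_directionality
    vdw = float((vdw_pair * ~hb_pair * within).sum())
    hbond = float((etheta * hb_pair_e * hb_pair * within).sum())

    q_lr = ligand.charges[:, None] * receptor.charges[None, :]
    elec = float((ELEC_CONSTANT * q_lr / (_epsilon_r(r) * r) * within).sum())

    l_vol = np.array([p.vol for p in lp]); l_sol = np.array([p.solpar for p in lp])
    r_vol = np.array([p.vol for p in rp]); r_sol = np.array([p.solpar for p in rp])
    l_S = l_sol + QASP * np.abs(ligand.charges)
    r_S = r_sol + QASP * np.abs(receptor.charges)
    dsol_pair = (l_S[:, None] * r_vol[None, :] + r_S[None, :] * l_vol[:, None]) * np.exp(
        -(r ** 2) / (2.0 * ff.sigma ** 2)
    )
    desolv = float((dsol_pair * within).sum())

    return ScoreBreakdown(
        vdw=ff.w_vdw * vdw,
        hbond=ff.w_hbond * hbond,
        elec=ff.w_elec * elec,
        conf=ff.w_conf * ligand.n_tor,
        desolv=ff.w_desolv * desolv,
    )


def combined_score(
    receptor: Structure,
    ligand: Structure,
    wmap: UnfavorableWaterMap,
    ff: ForceFieldParams | None = None,
    dG_aff: float | None = None,
    radii: dict[str, float] | None = None,
) -> ScoreBreakdown:
    """AD4.2 terms plus the water-displacement gain for one fixed pose."""
    base = ad4_score(receptor, ligand, ff)
    watdisp, serials = displacement_score(ligand, wmap, dG_aff=dG_aff, radii=radii)
    return ScoreBreakdown(
        vdw=base.vdw,
        hbond=base.hbond,
        elec=base.elec,
        conf=base.conf,
        desolv=base.desolv,
        watdisp=watdisp,
        displaced_atom_serials=serials,
    )
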