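# Methods

## Model

`gistdock` scores rigid ligand poses against a rigid receptor as the sum of
the AutoDock4.2 semiempirical force field and a water-displacement gain
derived from grid inhomogeneous solvation theory (GIST).

**Per-voxel water thermodynamics.** GIST output supplies five per-water
("normalized") quantities on a lattice of cubic voxels: number density ρ_k in
bulk units, solute–water interaction energy ΔE^norm_k,sw, one-half the
water–water interaction energy E^norm_k,ww, and the orientational and
translational first-order entropy terms stored as −TΔS (kcal/mol/water; the
absolute temperature is folded into the entropy values). Relative to bulk,

    ΔH_k = ΔE_k,sw + 2 (E_k,ww − E_bulk,ww),
    −TΔS_k = −TΔS_k,orient − TΔS_k,trans,
    ΔG_k = ΔH_k − TΔS_k.

The bulk water–water reference E_bulk,ww is a required scalar with default
−9.533 kcal/mol/water, the conventional value for neat TIP3P water under the
one-half convention; override it if the simulation used another water model.
No masking is applied to low-occupancy voxels when deriving ΔH/ΔG — their
noisy normalized values are suppressed downstream by the density cutoff.

**Unfavorable-water map.** A voxel is flagged when, strictly,
ΔG_k > ΔG_co *and* ρ_k > ρ_co. Strict inequalities follow the criteria's
"higher/greater than" phrasing; boundary voxels are excluded (measure-zero on
real data, and the sensitivity to this convention is one scan step at most).
The mask is frozen at build time together with the cutoffs that produced it;
scoring never re-reads the thermodynamic grid. Flagged voxels decompose into
enthalpy-dominant (ΔH > −TΔS) and entropy-dominant (ΔH < −TΔS) regions;
exact ties are labelled entropy-dominant (arbitrary but fixed).

**Displacement gain.** Each ligand *heavy* atom earns the flat gain ΔG_aff
(≤ 0) if at least one flagged voxel center lies within its van der Waals
radius (inclusive distance test; radii default to the AutoDock Rii/2 values).
"Covers" means the voxel *center* is inside the sphere, not cube–sphere
intersection — the simplest reading consistent with the binary per-atom
indicator. The gain is per atom, not per voxel: an atom covering ten voxels
earns ΔG_aff once, and two atoms covering the same voxel both earn it.
Hydrogens never displace. All non-hydrogen elements count as heavy atoms,
halogens included.

**Force field.** The five AutoDock4.2 terms are evaluated continuously over
intermolecular pairs (no grid interpolation, no internal-energy smoothing —
this is fixed-pose rescoring, not search):

* 12-6 van der Waals with A = ε·r_eq¹², B = 2ε·r_eq⁶, Lorentz–Berthelot-style
  combination (arithmetic mean of Rii, geometric mean of ε);
* 12-10 hydrogen bond for donor-hydrogen/acceptor pairs (C = 5ε_hb·r_hb¹²,
  D = 6ε_hb·r_hb¹⁰; OA/NA: 5.0 kcal/mol at 1.9 Å, SA: 1.0 at 2.5). The
  angular factor E(θ) defaults to 1 — an orientation-independent well. The
  full directional machinery matters for conformational search, not for
  rescoring fixed poses, and no calibrated quantity here depends on it; a
  `hbond_directionality` hook accepts a replacement factor.
* screened Coulomb with the Mehler–Solmajer sigmoidal distance-dependent
  dielectric (A = −8.5525, λ = 0.003627, k = 7.7839, ε₀ = 78.4) and the
  332.06363 kcal·Å/mol·e² conversion;
* torsional entropy W_conf · N_tor, with N_tor read from PDBQT TORSDOF
  records;
* Gaussian-shell desolvation (S_i V_j + S_j V_i)·exp(−r²/2σ²) with
  S = solpar + 0.01097·|q| and σ = 3.5 Å.

Weights are the published AutoDock4.2 calibration (W_vdW = 0.1662,
W_hbond = 0.1209, W_elec = 0.1406, W_conf = 0.2983, W_desolv = 0.1322;
W_vdW/W_hbond = 1.37). Pairs beyond the nonbonded cutoff (default 8 Å,
disableable) contribute zero. Pair distances are floored at 0.01 Å with a
logged warning so pathological poses stay finite. The combined score keeps
the continuum desolvation term alongside the displacement gain — one is a
penalty for burying polar atoms, the other a reward for expelling unstable
water; they describe different physics and are summed, not exchanged.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| ρ_co | bulk density | 4.8 (affinity) / 4.3 (pose) | occupancy floor for "real" water sites |
| ΔG_co | kcal/mol/water | 1.0 (affinity) / 1.9 (pose) | instability floor |
| ΔG_aff | kcal/mol/atom | −0.50 (affinity) / −0.25 (pose) | flat displacement gain |
| E_bulk,ww | kcal/mol/water | −9.533 | bulk reference of the enthalpy identity |
| σ | Å | 3.5 | desolvation Gaussian width |
| cutoff | Å | 8.0 | nonbonded truncation |

The two presets are the published factor-Xa calibration; for any other target
they are starting points, and `fit` rescans them against that target's data.

## Calibration scan

The scan lattice is inclusive on both ends: ΔG_co 0.0→4.0 step 0.1 (41
values), ΔG_aff 0.0→−2.0 step −0.01 (201 values), and 61 density-cutoff
values in 0.1 steps, 0.0→6.0 — all three axes start at the parameter's
neutral ("off") value — for 61×41×201 = 502,701 combinations. Two structural
facts make the exhaustive scan cheap: the mask depends only on (ρ_co, ΔG_co)
(2,501 distinct masks), and for a fixed mask the displacement term is linear
in ΔG_aff, so per-pose displacement *counts* are tabulated once per cutoff
pair and the ΔG_aff axis is a vectorized rescale. A property test checks the
cached path against direct per-combination recomputation.

Objective ties break toward the more conservative model: smallest |ΔG_aff|,
then largest ΔG_co, then largest ρ_co. The tie-break is an invented, fixed
convention for reproducibility; the published description does not state one.

RMSD uses heavy atoms only, no re-superposition (docking and native poses
share the receptor frame) and no symmetry correction; a pose under 2.0 Å
counts as a docking success. The pose objective rescores a *fixed* pose pool
per combination rather than re-docking — with an on-the-fly search the scan
would also reshape the sampled poses, which is outside rescoring scope.

## Grid and file conventions

Arrays are C-ordered with x slowest and z fastest; both the OpenDX reader
(via GridDataFormats) and the whitespace table reader normalize to this
order, so masks from either source are comparable. Geometry counts voxels
and addresses their centers: a 22.5 Å box at 0.375 Å spacing is 60 voxels
per axis. Only axis-aligned cubic voxels are accepted; anisotropic or
non-orthogonal deltas are rejected with the offending value named. Table
densities may be given in molecules/Å³ (converted by ρ_bulk = 0.0334).

AutoGrid gain maps put the full ΔG_aff at every grid point within the type
radius of a flagged voxel center (a spherical dilation of the mask — binary,
not fractional, matching the per-atom indicator) and use the real AutoGrid
text layout: six header lines, then one fixed-decimal value per line with x
varying fastest; NELEMENTS counts intervals. Trilinear interpolation of such
maps reproduces the pairwise displacement term exactly for grid-aligned
atoms and softens it near region boundaries by at most |ΔG_aff| per atom.

PDBQT I/O is a compact fixed-column implementation (ATOM/HETATM with charge
columns 71–76 and type columns 78–79, MODEL blocks for pose sets, TORSDOF
for N_tor); tree records (ROOT/BRANCH) are accepted and ignored since poses
are scored rigid.

## Synthetic data: what it does and does not emulate

The generators produce the *structure* of the real inputs, not their physics:

* `make_gist_fixture` — bulk-like background (ρ ≈ 1, ΔG ≈ 0, Gaussian
  jitter) with planted rectangular blocks of high-ρ, high-ΔG water. Target
  ΔG values are decomposed into the five raw fields consistently with the
  thermodynamic identities, with a dominance flag steering the excess into
  ΔH (0.75/0.25 split) or −TΔS so both decomposition branches occur.
* `make_toy_complex` — a ring receptor and an 8-atom ligand with typed,
  charged atoms; candidate poses are rigid translations, so their heavy-atom
  RMSDs are known exactly.
* `make_affinity_dataset` — the calibration testbed. Affinities are
  manufactured as AD4(native) + ΔG_aff*·n*(native) + N(0, σ) under planted
  cutoffs, which makes the planted combination the R² maximizer in
  expectation. Identifiability *on the scan lattice* is engineered: the grid
  carries one marker voxel per scan step of each cutoff axis (ρ = level +
  half-step with ΔG above the whole ΔG_co range, and vice versa), markers are
  attached as point-like probe atoms (radius 0.15 Å < half the voxel
  spacing, so a probe reports exactly one voxel) to randomly chosen ligands,
  and one sentinel ligand carries no markers. Any non-planted cutoff pair
  flips a nonempty marker block, and since the sentinel holds none of them
  the flip can never shift all displacement counts uniformly — so no other
  lattice point reproduces the planted count vector affinely. The default
  noise σ = 0.02 kcal/mol is the small-noise regime derived from the scan
  resolution: the recovered gain behaves like a regression coefficient with
  standard error ≈ σ/(sd(n)·√L) ≈ σ/5, which the 0.01 kcal/mol ΔG_aff step
  bounds at ≈ 0.02. Larger σ values are for studying degradation.
* `make_screening_set` — unit-variance Gaussian scores with actives shifted
  by −signal; expected AUC is Φ(signal/√2).

None of this emulates MD statistics — no spatial autocorrelation, no
realistic water networks, no chemistry in the toy structures. Passing tests
therefore demonstrate that the machinery (mask logic, scoring algebra, scan
selection, metrics) is correct, not that the calibration transfers to any
particular protein.

## Problem sizes

The shipped tests and the acceptance script run at sizes a laptop handles in
seconds: 12³ calibration grids with 20 probe ligands for the full 502,701-
combination scan, 5³–10³ grids for I/O and oracle batteries, 100 replicates
of 2,000-compound screening sets for the null-AUC average, and the
21,211-compound constructed ranking for the enrichment-factor arithmetic.

## Known limitations

* Fixed poses only: no conformational search, no intramolecular ligand
  energy, no flexible receptor.
* E(θ) = 1 in the hydrogen-bond term (hook provided).
* RMSD ignores molecular symmetry; symmetric fragments can inflate RMSD.
* Continuous pair evaluation may differ slightly from engines that
  trilinearly interpolate potential grids.
* The displacement model is deliberately crude (binary, flat gain): it
  rewards expelling unstable water but carries no penalty for displacing
  strongly bound water and no treatment of bridging water.
* Non-cubic or non-orthogonal grids and higher-order entropy terms are out
  of scope.
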