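"""Force-field terms, displacement gain, combined score, PDBQT I/O."""

import numpy as np
import pytest

from gistdock import (
    Atom,
    CutoffParams,
    GridGeometry,
    Structure,
    UnfavorableWaterMap,
    ad4_score,
    combined_score,
    default_forcefield,
    displacement_score,
    read_pdbqt_poses,
    vdw_radii,
    write_pdbqt,
)


def single_atom(ad_type="C", coord=(0.0, 0.0, 0.0), charge=0.0, serial=1):
    el = "H" if ad_type.startswith("H") else ad_type[0]
    return Atom(serial, el, ad_type, coord, charge)


def mask_with_true(dims, true_idx, spacing=0.375, dG_aff=-0.5):
    mask = np.zeros(dims, dtype=bool)
    for idx in true_idx:
        mask[idx] = True
    geo = GridGeometry((0.0, 0.0, 0.0), spacing, dims)
    return UnfavorableWaterMap(geo, mask, CutoffParams(4.8, 1.0, dG_aff))


class TestDisplacement:
    def test_empty_mask_scores_zero(self):
        lig = Structure([single_atom()])
        m = mask_with_true((3, 3, 3), [])
        w, serials = displacement_score(lig, m)
        assert w == 0.0 and serials == ()

    def test_toy_three_atoms(self):
        # atoms 1 and 2 sit on unfavorable voxel centers, atom 3 far away
        m = mask_with_true((4, 4, 4), [(0, 0, 0), (1, 1, 1)], dG_aff=-0.25)
        c1 = m.geometry.voxel_center(0, 0, 0)
        c2 = m.geometry.voxel_center(1, 1, 1)
        lig = Structure(
            [
                single_atom("C", tuple(c1), serial=1),
                single_atom("C", tuple(c2), serial=2),
                single_atom("C", (30.0, 30.0, 30.0), serial=3),
            ]
        )
        w, serials = displacement_score(lig, m)
        assert w == pytest.approx(-0.50)
        assert serials == (1, 2)

    def test_hydrogens_never_displace(self):
        m = mask_with_true((2, 2, 2), [(0, 0, 0)])
        lig = Structure([single_atom("HD", (0.0, 0.0, 0.0))])
        w, serials = displacement_score(lig, m)
        assert w == 0.0 and serials == ()

    def test_unknown_type_radius_reported(self):
        m = mask_with_true((2, 2, 2), [(0, 0, 0)])
        lig = Structure([single_atom("Xx", (0.0, 0.0, 0.0))])
        with pytest.raises(KeyError, match="Xx"):
            displacement_score(lig, m, radii={"C": 2.0})

    def test_printed_gain_arithmetic(self):
        # under the affinity gain −0.50 kcal/mol per atom, a pose whose 35
        # heavy atoms each cover an unfavorable voxel scores −17.5 kcal/mol
        idx = [(i, j, 0) for i in range(7) for j in range(5)]
        m = mask_with_true((7, 5, 1), idx, dG_aff=AFFINITY_GAIN)
        atoms = [
            single_atom("C", tuple(m.geometry.voxel_center(*ij)), serial=n + 1)
            for n, ij in enumerate(idx)
        ]
        w, serials = displacement_score(Structure(atoms), m)
        assert len(serials) == 35
        assert w == pytest.approx(-17.5)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        dims = (5, 5, 5)
        mask_idx = [
            tuple(i) for i in rng.integers(0, 5, size=(rng.integers(0, 10), 3))
        ]
        m = mask_with_true(dims, mask_idx)
        radii = vdw_radii()
        types = rng.choice(["C", "OA", "N", "HD"], size=6)
        coords = rng.uniform(-0.5, 2.0, size=(6, 3))
        lig = Structure(
            [single_atom(t, tuple(c), serial=i + 1) for i, (t, c) in enumerate(zip(types, coords))]
        )
        w, serials = displacement_score(lig, m, radii=radii)
        # independent double loop over (heavy atom, true voxel)
        expect = set()
        for a in lig.atoms:
            if not a.is_heavy:
                continue
            for idx in set(mask_idx):
                c = m.geometry.voxel_center(*idx)
                if np.linalg.norm(np.asarray(a.coord) - c) <= radii[a.ad_type]:
                    expect.add(a.serial)
        assert set(serials) == expect
        assert w == pytest.approx(m.params.dG_aff * len(expect))

    def test_monotone_under_mask_growth(self):
        rng = np.random.default_rng(77)
        coords = rng.uniform(0, 1.5, size=(5, 3))
        lig = Structure([single_atom("C", tuple(c), serial=i + 1) for i, c in enumerate(coords)])
        small = mask_with_true((4, 4, 4), [(0, 0, 0)])
        big = mask_with_true((4, 4, 4), [(0, 0, 0), (1, 1, 1), (2, 2, 2)])
        w_small, _ = displacement_score(lig, small)
        w_big, _ = displacement_score(lig, big)
        assert w_big <= w_small


AFFINITY_GAIN = -0.50


class TestAD4:
    def test_distant_pair_decays(self):
        rec = Structure([single_atom("C", (0, 0, 0))])
        lig = Structure([single_atom("C", (50.0, 0, 0), charge=0.3)], n_tor=0)
        ff = default_forcefield()
        s = ad4_score(rec, lig, ff)
        for term in (s.vdw, s.hbond, s.elec, s.desolv):
            assert abs(term) < 1e-6
        assert s.conf == 0.0

    def test_lj_minimum_at_equilibrium(self):
        # two like nonpolar atoms at r = req: unweighted 12-6 equals −eps
        ff = default_forcefield()
        p = ff.type_params("C")
        rec = Structure([single_atom("C", (0, 0, 0))])
        lig = Structure([single_atom("C", (p.rii, 0, 0))])
        s = ad4_score(rec, lig, ff)
        assert s.vdw == pytest.approx(-ff.w_vdw * p.eps, rel=1e-10)
        assert s.hbond == 0.0

    def test_conf_term_counts_rotatable_bonds(self):
        ff = default_forcefield()
        rec = Structure([single_atom("C", (0, 0, 0))])
        lig = Structure([single_atom("C", (4.0, 0, 0))], n_tor=4)
        assert ad4_score(rec, lig, ff).conf == pytest.approx(4 * ff.w_conf)

    def test_hbond_pair_uses_12_10_well(self):
        ff = default_forcefield()
        p = ff.type_params("OA")
        rec = Structure([single_atom("HD", (0, 0, 0), charge=0.0)])
        lig = Structure([single_atom("OA", (p.hb_req, 0, 0), charge=0.0)])
        s = ad4_score(rec, lig, ff)
        assert s.hbond == pytest.approx(-ff.w_hbond * p.hb_eps, rel=1e-10)
        assert s.vdw == 0.0

    def test_translation_invariance(self, toy):
        ff = default_forcefield()
        s0 = ad4_score(toy.receptor, toy.native, ff)
        shift = (3.1, -2.2, 0.7)
        s1 = ad4_score(toy.receptor.translated(shift), toy.native.translated(shift), ff)
        for t in ("vdw", "hbond", "elec", "conf", "desolv"):
            assert getattr(s1, t) == pytest.approx(getattr(s0, t), abs=1e-9)

    def test_atom_order_invariance(self, toy):
        ff = default_forcefield()
        s0 = ad4_score(toy.receptor, toy.native, ff)
        rev_rec = Structure(list(reversed(toy.receptor.atoms)), 0)
        rev_lig = Structure(list(reversed(toy.native.atoms)), toy.native.n_tor)
        s1 = ad4_score(rev_rec, rev_lig, ff)
        assert s1.total_ad4 == pytest.approx(s0.total_ad4, abs=1e-9)

    def test_clash_clamped_finite(self, caplog):
        rec = Structure([single_atom("C", (0, 0, 0))])
        lig = Structure([single_atom("C", (0.001, 0, 0))])
        s = ad4_score(rec, lig, default_forcefield())
        assert np.isfinite(s.total_ad4)

    def test_weight_ratio_vdw_to_hbond(self):
        ff = default_forcefield()
        assert round(ff.w_vdw / ff.w_hbond, 2) == 1.37


class TestCombined:
    def test_zero_gain_reduces_to_ad4(self, toy):
        m = mask_with_true((4, 4, 4), [(1, 1, 1)], dG_aff=0.0)
        s = combined_score(toy.receptor, toy.native, m, dG_aff=0.0)
        assert s.total == pytest.approx(s.total_ad4)

    def test_additivity(self, toy):
        m = mask_with_true((4, 4, 4), [(1, 1, 1), (2, 2, 2)], dG_aff=-0.5)
        s = combined_score(toy.receptor, toy.native, m)
        assert s.total - s.total_ad4 == pytest.approx(s.watdisp)
        assert s.watdisp == pytest.approx(-0.5 * len(s.displaced_atom_serials))

    def test_retains_ad4_desolvation_term(self, toy):
        m = mask_with_true((4, 4, 4), [(1, 1, 1)])
        base = ad4_score(toy.receptor, toy.native)
        s = combined_score(toy.receptor, toy.native, m)
        assert s.desolv == base.desolv != 0.0


class TestPDBQT:
    def test_round_trip_multi_model(self, tmp_path, toy):
        path = tmp_path / "poses.pdbqt"
        write_pdbqt(toy.poses, path)
        back = read_pdbqt_poses(path)
        assert len(back) == len(toy.poses)
        for orig, rt in zip(toy.poses, back):
            assert rt.n_tor == orig.n_tor
            assert [a.ad_type for a in rt.atoms] == [a.ad_type for a in orig.atoms]
            np.testing.assert_allclose(rt.coords, orig.coords, atol=5e-4)
            np.testing.assert_allclose(rt.charges, orig.charges, atol=5e-4)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdbqt"
        path.write_text("REMARK nothing\n")
        with pytest.raises(ValueError, match="no ATOM"):
            read_pdbqt_poses(path)
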