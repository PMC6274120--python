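"""GIST grid I/O and per-voxel thermodynamics."""

import numpy as np
import pytest

from gistdock import (
    BULK_NUMBER_DENSITY,
    DEFAULT_BULK_EWW,
    GISTGrid,
    GridGeometry,
    derive_thermo,
    read_dx,
    read_gist_table,
    write_dx,
    write_gist_table,
)
from gistdock.grids import _infer_geometry

from conftest import random_raw_grid


class TestGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), -0.1, (2, 2, 2))
        with pytest.raises(ValueError):
            GridGeometry((0, 0, 0), 0.375, (2, 0, 2))

    def test_center_index_round_trip(self):
        geo = GridGeometry((1.0, -2.0, 0.5), 0.375, (4, 5, 6))
        for idx in [(0, 0, 0), (3, 4, 5), (1, 2, 3)]:
            assert geo.index_of(geo.voxel_center(*idx)) == idx

    def test_centers_canonical_order(self):
        geo = GridGeometry((0, 0, 0), 1.0, (2, 2, 2))
        # x slowest, z fastest
        np.testing.assert_allclose(geo.centers()[:3], [[0, 0, 0], [0, 0, 1], [0, 1, 0]])

    def test_paper_convention_box(self):
        # a 22.5 Å cubic docking box at the default 0.375 Å spacing is a
        # 60-voxel-per-axis lattice
        geo = GridGeometry.from_box((0, 0, 0), 22.5, 0.375)
        assert geo.dims == (60, 60, 60)


class TestDX:
    def test_single_voxel(self, tmp_path):
        geo = GridGeometry((0, 0, 0), 0.375, (1, 1, 1))
        write_dx(geo, np.array([[[2.5]]]), tmp_path / "one.dx")
        geo2, vals = read_dx(tmp_path / "one.dx")
        assert geo2.dims == (1, 1, 1)
        assert vals[0, 0, 0] == pytest.approx(2.5)

    def test_round_trip_random_543(self, tmp_path):
        rng = np.random.default_rng(42)
        geo = GridGeometry((1.0, 2.0, 3.0), 0.5, (5, 4, 3))
        field = rng.normal(size=(5, 4, 3))
        write_dx(geo, field, tmp_path / "f.dx")
        geo2, back = read_dx(tmp_path / "f.dx")
        assert geo2.close_to(geo)
        np.testing.assert_allclose(back, field, atol=1e-6)

    def test_anisotropic_delta_rejected(self, tmp_path):
        path = tmp_path / "aniso.dx"
        path.write_text(
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0 0 0\n"
            "delta 0.375 0 0\ndelta 0 0.5 0\ndelta 0 0 0.375\n"
            "object 2 class gridconnections counts 2 2 2\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "0 1 2\n3 4 5\n6 7\n"
        )
        with pytest.raises(ValueError, match="0.5"):
            read_dx(path)


class TestTable:
    def test_direct_placement_2x2x2(self, tmp_path):
        header = "voxel x y z rho e_sw e_ww ts_orient ts_trans\n"
        rows = []
        vals = np.arange(8, dtype=float)
        n = 0
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    rows.append(
                        f"{n} {i*0.5} {j*0.5} {k*0.5} {1+vals[n]} {vals[n]} -9.5 0.1 0.2"
                    )
                    n += 1
        path = tmp_path / "t.dat"
        path.write_text(header + "\n".join(rows) + "\n")
        g = read_gist_table(path)
        assert g.geometry.dims == (2, 2, 2)
        np.testing.assert_array_equal(g.rho.ravel(), 1 + vals)
        np.testing.assert_array_equal(g.e_sw.ravel(), vals)

    def test_round_trip_bitwise(self, tmp_path):
        grid = random_raw_grid(3, dims=(10, 10, 10))
        write_gist_table(grid, tmp_path / "g.dat")
        back = read_gist_table(tmp_path / "g.dat")
        for f in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans"):
            np.testing.assert_array_equal(getattr(back, f), getattr(grid, f))

    def test_density_unit_conversion(self, tmp_path):
        path = tmp_path / "t.dat"
        path.write_text(
            "voxel x y z rho e_sw e_ww ts_orient ts_trans\n"
            "0 0 0 0 0.0668 0 -9.5 0 0\n"
        )
        g = read_gist_table(path, density_unit="molecules_A3")
        assert g.rho[0, 0, 0] == pytest.approx(0.0668 / BULK_NUMBER_DENSITY)
        assert g.rho[0, 0, 0] == pytest.approx(2.0)

    def test_duplicate_voxel_rejected(self, tmp_path):
        path = tmp_path / "t.dat"
        path.write_text(
            "voxel x y z rho e_sw e_ww ts_orient ts_trans\n"
            "0 0 0 0 1 0 -9.5 0 0\n0 0 0 0 1 0 -9.5 0 0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_gist_table(path)

    def test_off_lattice_coordinate_rejected(self, tmp_path):
        path = tmp_path / "t.dat"
        path.write_text(
            "voxel x y z rho e_sw e_ww ts_orient ts_trans\n"
            "0 0 0 0 1 0 -9.5 0 0\n"
            "1 0 0 0.5 1 0 -9.5 0 0\n"
            "2 0 0 1.2 1 0 -9.5 0 0\n"
        )
        with pytest.raises(ValueError):
            read_gist_table(path)

    def test_readers_agree_on_same_grid(self, tmp_path):
        grid = random_raw_grid(5, dims=(4, 4, 4))
        write_gist_table(grid, tmp_path / "g.dat")
        for f in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans"):
            write_dx(grid.geometry, getattr(grid, f), tmp_path / f"{f}.dx")
        from_table = read_gist_table(tmp_path / "g.dat")
        for f in ("rho", "e_sw", "e_ww", "ts_orient", "ts_trans"):
            geo, vals = read_dx(tmp_path / f"{f}.dx")
            assert geo.close_to(from_table.geometry)
            np.testing.assert_allclose(vals, getattr(from_table, f), atol=1e-7)


class TestDeriveThermo:
    def test_bulk_like_voxel_is_zero(self):
        geo = GridGeometry((0, 0, 0), 0.375, (1, 1, 1))
        g = GISTGrid(geo, np.ones((1, 1, 1)), np.zeros((1, 1, 1)),
                     np.full((1, 1, 1), -9.5), np.zeros((1, 1, 1)),
                     np.zeros((1, 1, 1)), e_bulk_ww=-9.5)
        d = derive_thermo(g)
        assert d.dH[0, 0, 0] == 0.0
        assert d.dG[0, 0, 0] == 0.0

    def test_hand_arithmetic(self):
        geo = GridGeometry((0, 0, 0), 0.375, (1, 1, 1))
        g = GISTGrid(geo, np.ones((1, 1, 1)), np.full((1, 1, 1), -1.0),
                     np.full((1, 1, 1), -8.0), np.full((1, 1, 1), 0.3),
                     np.full((1, 1, 1), 0.4), e_bulk_ww=-9.5)
        d = derive_thermo(g)
        assert d.dH[0, 0, 0] == pytest.approx(2.0)
        assert d.mTdS[0, 0, 0] == pytest.approx(0.7)
        assert d.dG[0, 0, 0] == pytest.approx(2.7)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_free_energy_identity(self, seed):
        d = derive_thermo(random_raw_grid(seed))
        np.testing.assert_allclose(d.dG, d.dH + d.mTdS, atol=1e-9)

    def test_idempotent(self):
        g = random_raw_grid(9)
        once = derive_thermo(g)
        twice = derive_thermo(once)
        np.testing.assert_array_equal(once.dG, twice.dG)
        np.testing.assert_array_equal(once.dH, twice.dH)

    def test_scaling_e_sw_is_linear(self):
        g = random_raw_grid(13)
        d1 = derive_thermo(g)
        g2 = g.copy()
        g2.e_sw = 3.0 * g2.e_sw
        d2 = derive_thermo(g2)
        # dH minus the water-water part is exactly the solute-water term
        np.testing.assert_allclose(
            d2.dH - 2 * (g2.e_ww - g2.e_bulk_ww),
            3.0 * (d1.dH - 2 * (g.e_ww - g.e_bulk_ww)),
            atol=1e-9,
        )

    def test_missing_bulk_reference(self):
        g = random_raw_grid(1)
        g.e_bulk_ww = None
        with pytest.raises(ValueError, match="bulk"):
            derive_thermo(g)
        assert f"{DEFAULT_BULK_EWW}" in str(pytest.raises(ValueError, derive_thermo, g).value)


def test_infer_geometry_uniformity():
    coords = np.array([[0, 0, 0], [0, 0, 0.5], [0, 0, 1.1]])
    with pytest.raises(ValueError, match="lattice"):
        _infer_geometry(coords)
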