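import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from reefscape.habitat import (
    compute_abundance,
    degrade_composition,
    fragment,
    grid_habitat,
    load_typology,
)
from reefscape.raster import HA_PER_KM2, KM_PER_DEG, Raster

from conftest import make_grid


class TestTypology:
    def test_variable_depth_density_is_shallow_over_hundred(self, typology_l3):
        shallow = typology_l3.classes["fringing_s"]
        deep = typology_l3.classes["fringing_v"]
        assert (shallow.density_mean, shallow.density_sd) == (256.0, 272.0)
        assert (deep.density_mean, deep.density_sd) == (2.56, 2.72)
        # hundred-fold rule holds for every variable-depth class
        for cid, c in typology_l3.classes.items():
            if c.depth_stratum != "variable_depth":
                continue
            twin = next(t for t in typology_l3.classes.values()
                        if t.name == c.name and t.depth_stratum == "shallow")
            assert c.density_mean == pytest.approx(twin.density_mean / 100.0)

    def test_l1_is_single_reef_class(self):
        t = load_typology(level="L1")
        (c,) = t.classes.values()
        assert c.name == "Reef"
        assert (c.density_mean, c.density_sd) == (224.0, 193.0)

    def test_hierarchy_links(self, typology_l3):
        l1_id = next(cid for cid, c in typology_l3.all_classes.items()
                     if c.level == "L1")
        for cid, c in typology_l3.classes.items():
            parent = typology_l3.parent_map[cid]
            assert typology_l3.all_classes[parent].level == "L2"
            assert typology_l3.parent_map[parent] == l1_id

    def test_missing_shallow_density_is_error(self, tmp_path):
        p = tmp_path / "typ.csv"
        p.write_text(
            "class_id,level3,level2,level1,depth_stratum,density_mean,density_sd\n"
            "x_s,X reef,Shallow reefs,Reef,shallow,,\n"
            "sh,,Shallow reefs,Reef,shallow,224,193\n"
            "re,,,Reef,shallow,224,193\n"
        )
        with pytest.raises(ValueError, match="missing density"):
            load_typology(p, level="L3")

    def test_negative_density_is_error(self, tmp_path):
        p = tmp_path / "typ.csv"
        p.write_text(
            "class_id,level3,level2,level1,depth_stratum,density_mean,density_sd\n"
            "x_s,X reef,Shallow reefs,Reef,shallow,-5,1\n"
            "sh,,Shallow reefs,Reef,shallow,224,193\n"
            "re,,,Reef,shallow,224,193\n"
        )
        with pytest.raises(ValueError, match="negative density"):
            load_typology(p, level="L3")

    def test_empty_class_list_is_error(self, tmp_path):
        p = tmp_path / "typ.csv"
        p.write_text(
            "class_id,level3,level2,level1,depth_stratum,density_mean,density_sd\n"
            "re,,,Reef,shallow,224,193\n"
        )
        with pytest.raises(ValueError):
            load_typology(p, level="L3")


class TestGridHabitat:
    def test_polygon_inside_one_cell(self):
        poly = box(10.05, 0.05, 10.15, 0.15)  # strictly inside cell [10, 10.25)
        grid = grid_habitat([(poly, "fringing_s")], resolution=0.25)
        assert grid.n_patches == 1
        lat_c = 0.125
        expect = poly.area * KM_PER_DEG ** 2 * np.cos(np.deg2rad(lat_c)) * HA_PER_KM2
        assert grid.total_area_ha == pytest.approx(expect, rel=1e-9)

    def test_polygon_straddling_two_cells_conserves_area(self):
        poly = box(10.2, 0.05, 10.35, 0.15)  # crosses the 10.25 boundary
        grid = grid_habitat([(poly, "fringing_s")], resolution=0.25)
        assert grid.n_patches == 2
        expect = poly.area * KM_PER_DEG ** 2 * np.cos(np.deg2rad(0.125)) * HA_PER_KM2
        assert grid.total_area_ha == pytest.approx(expect, rel=1e-3)

    def test_raster_patch_count_by_construction(self):
        vals = np.zeros((10, 10), dtype=int)
        # 7 scattered reef pixels, one per 0.25-degree cell at 0.25 pixel size
        hits = [(0, 0), (1, 2), (2, 4), (3, 6), (5, 1), (7, 7), (9, 3)]
        for r, c in hits:
            vals[r, c] = 1
        hab = Raster(vals, west=0.0, south=0.0, resolution=0.25)
        grid = grid_habitat(hab, resolution=0.25, code_map={1: "fringing_s"})
        assert grid.n_patches == 7

    def test_area_conservation_raster_vs_fine_grid(self):
        rng = np.random.default_rng(5)
        vals = (rng.random((40, 40)) < 0.3).astype(int)
        hab = Raster(vals, west=160.0, south=-20.0, resolution=0.05)
        mapped = sum(hab.cell_area_ha(r) for r, c in zip(*np.nonzero(vals)))
        for res in (0.25, 0.5):
            grid = grid_habitat(hab, resolution=res, code_map={1: "fringing_s"})
            assert grid.total_area_ha == pytest.approx(mapped, rel=1e-3)

    def test_unknown_class_code_is_error(self):
        hab = Raster(np.array([[1, 9]]), west=0, south=0, resolution=0.1)
        with pytest.raises(ValueError, match="9"):
            grid_habitat(hab, resolution=0.25, code_map={1: "fringing_s"})

    def test_no_overlap_is_error(self):
        with pytest.raises(ValueError):
            grid_habitat([], resolution=0.25)


class TestAbundance:
    def test_sd_zero_is_exact_and_seed_free(self, tmp_path):
        p = tmp_path / "typ.csv"
        p.write_text(
            "class_id,level3,level2,level1,depth_stratum,density_mean,density_sd\n"
            "x_s,X reef,Shallow reefs,Reef,shallow,256,0\n"
            "sh,,Shallow reefs,Reef,shallow,224,0\n"
            "re,,,Reef,shallow,224,0\n"
        )
        typ = load_typology(p, level="L3")
        grid = make_grid([0.1], [0.1], [2.0], class_id="x_s")
        for seed in (0, 1, 99):
            out = compute_abundance(grid, typ, seed=seed)
            assert out.abundance[0] == pytest.approx(512.0)

    def test_variable_depth_class_uses_hundredth_density(self, typology_l3):
        # Atoll/Bank: shallow mean 234, sd 0 -> variable mean 2.34, sd 0
        grid = make_grid([0.1], [0.1], [100.0], class_id="atoll_bank_v")
        out = compute_abundance(grid, typology_l3, seed=3)
        assert out.abundance[0] == pytest.approx(234.0)

    def test_negative_draws_truncate_to_zero(self, tmp_path):
        p = tmp_path / "typ.csv"
        p.write_text(
            "class_id,level3,level2,level1,depth_stratum,density_mean,density_sd\n"
            "x_s,X reef,Shallow reefs,Reef,shallow,1,10000\n"
            "sh,,Shallow reefs,Reef,shallow,224,0\n"
            "re,,,Reef,shallow,224,0\n"
        )
        typ = load_typology(p, level="L3")
        grid = make_grid([0.1], [0.1], [5.0], class_id="x_s")
        draws = [compute_abundance(grid, typ, seed=s).abundance[0]
                 for s in range(40)]
        assert min(draws) == 0.0  # some Gaussian draws are negative
        assert all(d >= 0 for d in draws)

    def test_one_draw_shared_across_patches_of_a_class(self, typology_l3):
        grid = make_grid([0.1, 0.6, 1.1], [0.1, 0.1, 0.1], [1.0, 2.0, 4.0])
        out = compute_abundance(grid, typology_l3, seed=7)
        n = out.abundance
        # same density => abundance proportional to area
        assert n[1] == pytest.approx(2 * n[0])
        assert n[2] == pytest.approx(4 * n[0])


class TestDegrade:
    def test_l3_to_l1_sums_areas(self, typology_l3):
        grid = make_grid([0.1], [0.1], [10.0], class_id="fringing_s")
        grid.class_areas["atoll_bank_s"] = 5.0
        out = degrade_composition(grid, typology_l3, "L1")
        assert list(out.class_areas.columns) == ["reef"]
        assert out.class_areas.iloc[0, 0] == pytest.approx(15.0)
        assert out.n_patches == grid.n_patches

    def test_l3_to_l2_splits_by_depth(self, typology_l3):
        grid = make_grid([0.1], [0.1], [10.0], class_id="fringing_s")
        grid.class_areas["fringing_v"] = 7.0
        out = degrade_composition(grid, typology_l3, "L2")
        assert set(out.class_areas.columns) == {"shallow_reefs", "variable_reefs"}
        assert out.class_areas.loc[0, "shallow_reefs"] == pytest.approx(10.0)
        assert out.class_areas.loc[0, "variable_reefs"] == pytest.approx(7.0)

    def test_degrade_l1_grid_is_identity(self, typology_l3):
        grid = make_grid([0.1], [0.1], [10.0], class_id="reef")
        out = degrade_composition(grid, typology_l3, "L1")
        pd.testing.assert_frame_equal(out.class_areas, grid.class_areas)

    def test_l1_patches_share_one_density_draw(self, typology_l3):
        grid = make_grid([0.1, 0.6], [0.1, 0.1], [10.0, 30.0],
                         class_id="fringing_s")
        grid.class_areas["atoll_bank_s"] = [4.0, 2.0]
        out = degrade_composition(grid, typology_l3, "L1")
        t1 = typology_l3.at_level("L1")
        filled = compute_abundance(out, t1, seed=11)
        n = filled.abundance
        tot = out.class_areas.sum(axis=1).to_numpy()
        assert n[0] / tot[0] == pytest.approx(n[1] / tot[1])

    def test_orphan_class_is_error(self, typology_l3):
        grid = make_grid([0.1], [0.1], [10.0], class_id="unknown_class")
        with pytest.raises(ValueError, match="orphan"):
            degrade_composition(grid, typology_l3, "L1")


class TestFragment:
    def _grid100(self):
        lons = np.arange(100) * 0.25 + 0.1
        return make_grid(lons, np.zeros(100), np.ones(100),
                         N=np.ones(100), sites={0: "A"})

    def test_zero_removal_is_identity(self):
        g = self._grid100()
        out = fragment(g, 0.0, seed=1)
        assert list(out.patches.index) == list(g.patches.index)

    def test_eighty_percent_removal_counting(self):
        lons = np.arange(100) * 0.25 + 0.1
        g = make_grid(lons, np.zeros(100), np.ones(100), N=np.ones(100))
        out = fragment(g, 0.8, seed=3)
        assert out.n_patches in (20, 21)  # overshoot by at most one patch

    def test_protected_patches_survive(self):
        g = self._grid100()
        out = fragment(g, 0.8, seed=5)
        assert 0 in out.patches.index  # sampled site A retained

    def test_all_protected_is_error(self):
        g = make_grid([0.1, 0.6], [0.1, 0.1], [1.0, 1.0], N=[1, 1],
                      sites={0: "A", 1: "B"})
        with pytest.raises(ValueError, match="exceeds"):
            fragment(g, 0.2, seed=1)

    def test_removed_sets_nest_with_increasing_fraction(self):
        g = self._grid100()
        removed_prev: set = set()
        for frac in (0.2, 0.4, 0.6, 0.8):
            out = fragment(g, frac, seed=42)
            removed = set(g.patches.index) - set(out.patches.index)
            assert removed_prev <= removed
            removed_prev = removed
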