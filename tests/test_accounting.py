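"""Change accounting against hand counts and a brute-force per-pixel oracle."""

import numpy as np
import pandas as pd
import pytest

from palmconvert import (assign_establishment_year, conversion_accounting,
                         forest_loss_series, pixel_area_grid,
                         regional_summary, zone_overlap)
from palmconvert.grids import (EARTH_RADIUS_M, INDUSTRIAL, OTHER, SMALLHOLDER,
                               YEAR_PRE2000)


def brute_force_accounting(forest, loss, cls, est, areas):
    """Independent per-pixel classifier: loop, classify, tally."""
    rows = {}
    for r in range(forest.shape[0]):
        for c in range(forest.shape[1]):
            y, k, a = int(est[r, c]), int(cls[r, c]), float(areas[r, c])
            if k == OTHER or y <= YEAR_PRE2000:
                continue
            if forest[r, c] and loss[r, c] == y:
                fate = "rapid_ha"
            elif forest[r, c] and 0 < loss[r, c] < y:
                fate = "delayed_ha"
            else:
                fate = "old_nonforest_ha"
            key = (y, k)
            rows.setdefault(key, {"rapid_ha": 0.0, "delayed_ha": 0.0,
                                  "old_nonforest_ha": 0.0})
            rows[key][fate] += a
    return rows


class TestForestLossSeries:
    def test_loss_outside_mask_contributes_nothing(self):
        loss = np.full((3, 3), 2005)
        forest = np.zeros((3, 3), bool)
        areas = np.full((3, 3), 0.09)
        s = forest_loss_series(loss, forest, areas, years=[2005])
        assert s[2005] == 0.0

    def test_toy_hand_enumeration(self):
        forest = np.array([[1, 1, 1], [1, 0, 0], [0, 0, 0]], bool)
        loss = np.array([[2005, 2005, 2007], [0, 2007, 0], [0, 0, 0]])
        areas = np.full((3, 3), 0.09)
        s = forest_loss_series(loss, forest, areas)
        assert s[2005] == pytest.approx(0.18)
        assert s[2007] == pytest.approx(0.09)  # the (1,1) pixel is non-forest

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            forest_loss_series(np.zeros((2, 2)), np.zeros((3, 3), bool),
                               np.ones((2, 2)))


class TestAssignEstablishmentYear:
    def test_per_pixel_rules(self):
        plantation = np.array([[1, 1, 0, 1]], bool)
        loss = np.array([[2012, 0, 2010, 2025]])
        est = assign_establishment_year(plantation, loss)
        # in-map with loss -> loss year; in-map no loss -> pre-2000;
        # out-of-map -> 0; out-of-period loss -> pre-2000
        assert est.tolist() == [[2012, 2000, 0, 2000]]

    def test_matches_bruteforce_rule_on_random_grid(self, rng):
        plantation = rng.random((15, 15)) < 0.4
        loss = rng.choice([0, 2003, 2011, 2019], size=(15, 15))
        est = assign_establishment_year(plantation, loss)
        for r in range(15):
            for c in range(15):
                if not plantation[r, c]:
                    assert est[r, c] == 0
                elif 2001 <= loss[r, c] <= 2019:
                    assert est[r, c] == loss[r, c]
                else:
                    assert est[r, c] == YEAR_PRE2000


class TestConversionAccounting:
    def test_no_plantations_all_zero(self):
        forest = np.ones((4, 4), bool)
        zeros = np.zeros((4, 4), int)
        t = conversion_accounting(forest, zeros, zeros, zeros,
                                  np.full((4, 4), 0.09))
        assert t.table.empty or (t.table == 0).all().all()

    def test_toy_grid_mixes_all_fates(self):
        # 5x5: rapid, delayed, on-old-nonforest, pre-2000, untouched forest
        forest = np.zeros((5, 5), bool)
        loss = np.zeros((5, 5), int)
        cls = np.zeros((5, 5), int)
        est = np.zeros((5, 5), int)
        forest[0, 0], loss[0, 0], cls[0, 0], est[0, 0] = 1, 2010, 1, 2010  # rapid
        forest[1, 0], loss[1, 0], cls[1, 0], est[1, 0] = 1, 2005, 2, 2010  # delayed
        cls[2, 0], est[2, 0] = 1, 2012                                     # old non-forest
        cls[3, 0], est[3, 0] = 2, YEAR_PRE2000                             # pre-2000 stock
        forest[4, 0], loss[4, 0] = 1, 2016                                 # plain loss
        areas = np.full((5, 5), 1.0)
        t = conversion_accounting(forest, loss, cls, est, areas)
        assert t.table.loc[(2010, "industrial"), "rapid_ha"] == 1.0
        assert t.table.loc[(2010, "smallholder"), "delayed_ha"] == 1.0
        assert t.table.loc[(2012, "industrial"), "old_nonforest_ha"] == 1.0
        assert t.pre2000_ha["smallholder"] == 1.0
        assert t.forest_loss.sum() == pytest.approx(3.0)

    def test_impossible_state_raises(self):
        forest = np.ones((1, 1), bool)
        t = dict(forest_2000=forest, tree_loss=np.array([[2010]]),
                 plantation_class=np.array([[1]]),
                 establishment=np.array([[2005]]),
                 areas=np.ones((1, 1)))
        with pytest.raises(ValueError, match="established before"):
            conversion_accounting(**t)

    def test_equals_bruteforce_oracle_on_random_50x50(self, rng):
        """Accounting table identical to a per-pixel loop classifier."""
        shape = (50, 50)
        cls = rng.choice([OTHER, INDUSTRIAL, SMALLHOLDER], size=shape,
                         p=[0.6, 0.25, 0.15])
        est = np.zeros(shape, int)
        planted = cls != OTHER
        est[planted] = rng.choice(
            [YEAR_PRE2000] + list(range(2001, 2020)), size=planted.sum())
        forest = rng.random(shape) < 0.5
        loss = np.zeros(shape, int)
        # forest pixels may lose cover at or before the establishment year
        for r, c in np.argwhere(forest & (est > YEAR_PRE2000)):
            y = est[r, c]
            choice = rng.choice(["rapid", "delayed", "none"])
            if choice == "rapid":
                loss[r, c] = y
            elif choice == "delayed" and y > 2001:
                loss[r, c] = rng.integers(2001, y)
        loss[forest & (cls == OTHER) & (rng.random(shape) < 0.3)] = 2015
        areas = np.full(shape, 0.09)

        t = conversion_accounting(forest, loss, cls, est, areas)
        oracle = brute_force_accounting(forest, loss, cls, est, areas)
        from palmconvert.grids import CLASS_NAMES
        for (y, k), fates in oracle.items():
            row = t.table.loc[(y, CLASS_NAMES[k])]
            for fate, v in fates.items():
                assert row[fate] == pytest.approx(v), (y, k, fate)
        # and nothing extra: totals agree exactly
        total_oracle = sum(v for f in oracle.values() for v in f.values())
        assert t.table["expansion_ha"].sum() == pytest.approx(total_oracle)

    def test_row_identity_and_reconstruction(self, small_truth, small_config):
        areas = np.full(small_truth.forest_2000.shape,
                        small_config.pixel_area_ha)
        t = conversion_accounting(small_truth.forest_2000,
                                  small_truth.tree_loss_year,
                                  small_truth.plantation_class,
                                  small_truth.establishment_year, areas)
        parts = t.table[["rapid_ha", "delayed_ha", "old_nonforest_ha"]].sum(axis=1)
        np.testing.assert_allclose(t.table["expansion_ha"], parts)
        # reconstruction: expansion + pre-2000 stock = 2019 plantation area
        total_2019 = areas[small_truth.plantation_class != OTHER].sum()
        assert (t.table["expansion_ha"].sum() + t.pre2000_ha.sum()
                == pytest.approx(total_2019))
        # bounds: rapid+delayed bounded by loss and by plantation area
        conv = t.table["rapid_ha"].sum() + t.table["delayed_ha"].sum()
        assert conv <= t.forest_loss.sum() + 1e-9
        assert conv <= total_2019 + 1e-9


class TestRegionalSummary:
    def test_single_region_equals_national(self, small_truth, small_config):
        areas = np.full(small_truth.forest_2000.shape,
                        small_config.pixel_area_ha)
        args = (small_truth.forest_2000, small_truth.tree_loss_year,
                small_truth.plantation_class, small_truth.establishment_year,
                areas)
        nat = conversion_accounting(*args)
        reg = regional_summary(*args, np.ones_like(small_truth.region_id))
        assert list(reg) == [1]
        pd.testing.assert_frame_equal(reg[1].table, nat.table)

    def test_random_partition_additivity(self, small_truth, small_config, rng):
        areas = np.full(small_truth.forest_2000.shape,
                        small_config.pixel_area_ha)
        region = rng.integers(1, 4, size=small_truth.region_id.shape)
        args = (small_truth.forest_2000, small_truth.tree_loss_year,
                small_truth.plantation_class, small_truth.establishment_year,
                areas)
        years = np.arange(2001, 2020)
        nat = conversion_accounting(*args, years=years)
        reg = regional_summary(*args, region, years=years)
        summed = None
        for t in reg.values():
            summed = t if summed is None else summed + t
        pd.testing.assert_frame_equal(
            summed.table.sort_index(), nat.table.sort_index(),
            check_exact=False, rtol=1e-12)
        np.testing.assert_allclose(summed.forest_loss.sort_index(),
                                   nat.forest_loss.sort_index())


class TestZoneOverlap:
    def test_empty_zone(self):
        cls = np.full((3, 3), INDUSTRIAL)
        ha, p = zone_overlap(cls, np.zeros((3, 3), bool), np.ones((3, 3)))
        assert ha == 0.0 and p == 0.0

    def test_no_oil_palm_percent_flagged_nan(self):
        cls = np.zeros((3, 3), int)
        ha, p = zone_overlap(cls, np.ones((3, 3), bool), np.ones((3, 3)))
        assert ha == 0.0 and np.isnan(p)

    def test_toy_hand_count(self):
        cls = np.array([[1, 2, 0], [0, 1, 0]])
        zone = np.array([[1, 0, 1], [0, 1, 0]], bool)
        ha, p = zone_overlap(cls, zone, np.full((2, 3), 2.0))
        assert ha == pytest.approx(4.0)        # pixels (0,0) and (1,1)
        assert p == pytest.approx(100 * 4 / 6)  # of three oil-palm pixels


class TestPixelAreaGrid:
    def test_constant_30m_cells(self):
        a = pixel_area_grid((4, 5), cell_size_m=30.0)
        assert a.shape == (4, 5)
        np.testing.assert_allclose(a, 0.09)

    def test_cosine_law_at_60_degrees(self):
        a = pixel_area_grid((1, 1), res_deg=0.01, lat_top_deg=0.005)
        b = pixel_area_grid((1, 1), res_deg=0.01, lat_top_deg=60.005)
        assert b[0, 0] / a[0, 0] == pytest.approx(0.5, rel=1e-4)

    def test_band_total_matches_spherical_band_area(self):
        """Summed cosine-law areas match the exact sphere-band formula."""
        res = 0.05
        rows, cols = 100, 40
        lat_top = 2.0
        grid = pixel_area_grid((rows, cols), res_deg=res, lat_top_deg=lat_top)
        lam = np.deg2rad(res * cols)
        phi1 = np.deg2rad(lat_top - rows * res)
        phi2 = np.deg2rad(lat_top)
        exact_ha = EARTH_RADIUS_M ** 2 * lam * (np.sin(phi2) - np.sin(phi1)) / 1e4
        assert grid.sum() == pytest.approx(exact_ha, rel=1e-3)

    def test_missing_georeference_raises(self):
        with pytest.raises(ValueError, match="declare"):
            pixel_area_grid((2, 2))
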