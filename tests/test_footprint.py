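"""Land-footprint arithmetic and the brute-force equivalence oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dairylca.feeds import Diet, DietEntry
from dairylca.footprint import (LandLedger, annual_feed_demand,
                                crop_product_area, feed_area, herd_footprint)
from dairylca.herd import DAYS_PER_MONTH, Cohort, HerdState

from conftest import flat_feed, uniform_diet


def make_herd(*cohorts):
    return HerdState(2020, "MRT", "Traditional",
                     tuple(Cohort(n, c, w) for n, c, w in cohorts))


class TestFeedArea:
    def test_pasture_hand_value(self, feeds):
        # 1.5 Mg on the native-grass row: 1.5 / (3.0 * 0.5) = 1.0 ha
        assert feed_area(1.5, feeds["grass"]) == pytest.approx(1.0)

    def test_zero_offer(self, feeds):
        assert feed_area(0.0, feeds["napier"]) == 0.0

    def test_napier_hand_value(self, feeds):
        assert feed_area(9.78, feeds["napier"]) == pytest.approx(0.995, abs=5e-4)

    def test_zero_denominator_names_feed(self):
        bad = flat_feed("emptygrass", yield_dm=0.0)
        with pytest.raises(ValueError, match="emptygrass"):
            feed_area(1.0, bad)


class TestCropProductArea:
    def test_bran(self, feeds):
        assert crop_product_area(0.418, "maize_bran", feeds) == \
            pytest.approx(1.0)

    def test_cake(self, feeds):
        assert crop_product_area(0.342, "sunflower_cake", feeds) == \
            pytest.approx(1.0)

    def test_zero(self, feeds):
        assert crop_product_area(0.0, "maize_bran", feeds) == 0.0

    def test_unknown_product(self, feeds):
        with pytest.raises(ValueError):
            crop_product_area(1.0, "cassava_peel", feeds)


def brute_force_footprint(herd, diet, feeds):
    """Naive loop over cohorts x months x feeds evaluating the land
    footprint sum term by term (independent of the vectorized path)."""
    demand = {}
    for cohort in herd.cohorts:
        for entry in diet.entries:
            if entry.cohort != cohort.name:
                continue
            mg = cohort.count * entry.offer * DAYS_PER_MONTH / 1000.0
            demand[entry.feed_id] = demand.get(entry.feed_id, 0.0) + mg
    areas = {}
    bran = stover = 0.0
    for feed_id, mg in demand.items():
        spec = feeds[feed_id]
        a = mg / (spec.yield_dm * spec.use_efficiency)
        if feed_id == "maize_bran":
            bran += a
        elif feed_id in ("maize_stover", "maize_stover_treated"):
            stover += a
        else:
            areas[spec.land_use] = areas.get(spec.land_use, 0.0) + a
    areas["cropland_maize"] = areas.get("cropland_maize", 0.0) + max(bran, stover)
    return areas


class TestHerdFootprint:
    def test_single_cow_single_feed(self, feeds):
        herd = make_herd(("cow", 1.0, 250.0))
        diet = uniform_diet("cow", {"grass": 4.0})
        ledger = herd_footprint(herd, diet, feeds)
        expected = feed_area(4.0 * 365 / 1000, feeds["grass"])
        assert ledger.areas["grassland_native"] == pytest.approx(expected)
        assert ledger.tlu == 1.0

    def test_doubling_heads_doubles_areas_not_per_tlu(self, feeds):
        diet = uniform_diet("cow", {"grass": 3.0, "napier": 1.0})
        one = herd_footprint(make_herd(("cow", 10.0, 250.0)), diet, feeds)
        two = herd_footprint(make_herd(("cow", 20.0, 250.0)), diet, feeds)
        for cls in one.areas:
            assert two.areas[cls] == pytest.approx(2 * one.areas[cls])
        assert two.footprint_per_tlu == pytest.approx(one.footprint_per_tlu)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_brute_force_equivalence(self, data):
        from dairylca.params import default_feed_catalog
        feeds = default_feed_catalog()
        feed_ids = sorted(feeds)
        entries = []
        for cohort in ("cow", "heifer"):
            for month in range(1, 13):
                for fid in data.draw(st.lists(st.sampled_from(feed_ids),
                                              unique=True, max_size=3)):
                    offer = data.draw(st.floats(0.0, 8.0))
                    entries.append(DietEntry(cohort, month, fid, offer))
        diet = Diet(entries)
        herd = make_herd(("cow", data.draw(st.floats(1.0, 500.0)), 250.0),
                         ("heifer", data.draw(st.floats(0.0, 200.0)), 170.0))
        ledger = herd_footprint(herd, diet, feeds)
        oracle = brute_force_footprint(herd, diet, feeds)
        for cls, area in ledger.areas.items():
            assert area == pytest.approx(oracle.get(cls, 0.0),
                                         rel=1e-9, abs=1e-12)

    def test_additivity_over_cohorts_without_coproducts(self, feeds):
        diet = Diet([DietEntry("cow", m, "grass", 3.0) for m in range(1, 13)]
                    + [DietEntry("heifer", m, "pasture", 2.0)
                       for m in range(1, 13)])
        whole = herd_footprint(
            make_herd(("cow", 10.0, 250.0), ("heifer", 5.0, 170.0)),
            diet, feeds)
        parts = (herd_footprint(make_herd(("cow", 10.0, 250.0)), diet, feeds)
                 + herd_footprint(make_herd(("heifer", 5.0, 170.0)), diet,
                                  feeds))
        assert whole.total_area == pytest.approx(parts.total_area)
        assert whole.tlu == pytest.approx(parts.tlu)

    def test_homogeneity_in_offers(self, feeds):
        base = uniform_diet("cow", {"grass": 2.0, "maize_bran": 0.5,
                                    "maize_stover": 1.0})
        scaled = Diet([DietEntry(e.cohort, e.month, e.feed_id, 3.0 * e.offer)
                       for e in base.entries])
        herd = make_herd(("cow", 7.0, 250.0))
        a = herd_footprint(herd, base, feeds)
        b = herd_footprint(herd, scaled, feeds)
        for cls in a.areas:
            assert b.areas[cls] == pytest.approx(3.0 * a.areas[cls])

    def test_area_monotone_decreasing_in_yield(self, feeds):
        from dairylca.params import scale_feed_yield
        f = feeds["grass"]
        assert feed_area(2.0, scale_feed_yield(f, 1.5)) < feed_area(2.0, f)

    def test_coproduct_rule_takes_max(self, feeds):
        # bran-implied area dominates stover-implied area here
        diet = uniform_diet("cow", {"maize_bran": 1.0, "maize_stover": 1.0})
        herd = make_herd(("cow", 1.0, 250.0))
        ledger = herd_footprint(herd, diet, feeds)
        demand = annual_feed_demand(herd, diet)
        bran_area = feed_area(demand["maize_bran"], feeds["maize_bran"])
        stover_area = feed_area(demand["maize_stover"], feeds["maize_stover"])
        assert bran_area > stover_area
        assert ledger.areas["cropland_maize"] == pytest.approx(bran_area)

    def test_missing_feed_raises(self, feeds):
        diet = uniform_diet("cow", {"unknown": 1.0})
        with pytest.raises(KeyError):
            herd_footprint(make_herd(("cow", 1.0, 250.0)), diet, feeds)


class TestLandLedger:
    def test_total_is_sum_of_classes(self):
        ledger = LandLedger(areas={"cropland_maize": 1.0,
                                   "cropland_sunflower": 0.5,
                                   "grassland_sown": 2.0,
                                   "grassland_native": 3.0}, tlu=10.0)
        assert ledger.total_area == pytest.approx(6.5)
        assert ledger.footprint_per_tlu == pytest.approx(0.65)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            LandLedger(areas={"cropland_maize": -1.0,
                              "cropland_sunflower": 0.0,
                              "grassland_sown": 0.0,
                              "grassland_native": 0.0})
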