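"""Cow simulation, annualization, herd demography, offtake."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dairylca.herd import (Cohort, HerdState, NutritionCoefficients,
                           annualize, meat_output, project_herd,
                           simulate_cow, to_tlu)
from dairylca.feeds import Diet, DietEntry

from conftest import flat_feed, uniform_diet

COEFFS = NutritionCoefficients()


def _requirement_offers(breed, daily_milk, feed):
    """Offer of a single feed meeting ME and CP needs for daily_milk
    exactly on the binding nutrient (the other in surplus)."""
    lw = breed.mature_liveweight ** 0.75
    me_need = COEFFS.me_maint * lw + COEFFS.me_per_kg_milk * daily_milk
    return me_need / feed.me_density


class TestSimulateCow:
    def test_milk_is_minimum_of_energy_protein_potential(self, test_breed):
        # feed tuned so energy supports 8 kg/d, protein 9 kg/d, potential 10
        lw = test_breed.mature_liveweight ** 0.75
        offer_dm = (COEFFS.me_maint * lw + 5.0 * 8.0) / 10.0  # me=10 MJ/kg
        cp_frac = (COEFFS.cp_maint * lw + 0.078 * 9.0) / offer_dm
        feed = flat_feed(me=10.0, cp=cp_frac)
        breed = test_breed.__class__(**{**test_breed.__dict__,
                                        "potential_milk": 10.0 * 300.0})
        diet = uniform_diet("cow", {feed.feed_id: offer_dm})
        res = simulate_cow(breed, diet, {feed.feed_id: feed})
        assert res.milk_fpcm_lactation == pytest.approx(8.0 * 300.0, rel=1e-9)

    def test_zero_diet_zero_milk_zero_intake(self, test_breed, feeds):
        res = simulate_cow(test_breed, Diet([]), feeds)
        assert res.milk_fpcm_lactation == 0
        assert res.dm_intake == 0
        assert res.gross_energy_intake == 0

    def test_diet_meeting_requirements_reaches_potential(self, test_breed):
        # invert the requirement equations for the potential daily yield
        potential_daily = test_breed.potential_milk / test_breed.lactation_length
        lw = test_breed.mature_liveweight ** 0.75
        me_need = COEFFS.me_maint * lw + 5.0 * potential_daily
        cp_need = COEFFS.cp_maint * lw + 0.078 * potential_daily
        offer = me_need / 10.0
        feed = flat_feed(me=10.0, cp=cp_need / offer)
        diet = uniform_diet("cow", {feed.feed_id: offer})
        res = simulate_cow(test_breed, diet, {feed.feed_id: feed})
        assert res.milk_fpcm_lactation == pytest.approx(
            test_breed.potential_milk, rel=1e-9)

    def test_missing_feed_nutrients_raises_naming_feed(self, test_breed):
        diet = uniform_diet("cow", {"mystery_meal": 2.0})
        with pytest.raises(KeyError, match="mystery_meal"):
            simulate_cow(test_breed, diet, {})

    def test_annualization_identity(self, test_breed, feeds):
        from dairylca.synthetic import DEFAULT_COW_OFFERS
        diet = uniform_diet("cow", DEFAULT_COW_OFFERS["Traditional"]["wet"])
        res = simulate_cow(test_breed, diet, feeds)
        assert res.milk_fpcm_annual == pytest.approx(
            res.milk_fpcm_lactation * 365.0 / test_breed.calving_interval)

    @given(offers=st.dictionaries(
        st.sampled_from(["grass", "napier", "maize_bran", "maize_stover"]),
        st.floats(0.0, 6.0), max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_milk_never_exceeds_potential(self, offers):
        from dairylca.params import default_breeds, default_feed_catalog
        breed = default_breeds()["local"]
        res = simulate_cow(breed, uniform_diet("cow", offers),
                           default_feed_catalog())
        assert res.milk_fpcm_lactation <= breed.potential_milk + 1e-9

    @given(extra=st.floats(0.0, 3.0), month=st.integers(1, 12))
    @settings(max_examples=50, deadline=None)
    def test_adding_feed_never_decreases_milk(self, extra, month):
        from dairylca.params import default_breeds, default_feed_catalog
        breed = default_breeds()["local"]
        feeds = default_feed_catalog()
        base = uniform_diet("cow", {"grass": 3.0, "pasture": 2.0})
        more = Diet(
            [DietEntry(e.cohort, e.month, e.feed_id,
                       e.offer + (extra if e.month == month
                                  and e.feed_id == "grass" else 0.0))
             for e in base.entries])
        m0 = simulate_cow(breed, base, feeds).milk_fpcm_lactation
        m1 = simulate_cow(breed, more, feeds).milk_fpcm_lactation
        assert m1 >= m0 - 1e-9


class TestAnnualize:
    @pytest.mark.parametrize("milk, interval, expected", [
        (582.0, 593.6, 357.9),   # oracle: 582*365/593.6 = 357.86
        (250.0, 365.0, 250.0),
        (0.0, 500.0, 0.0),
    ])
    def test_values(self, milk, interval, expected):
        assert annualize(milk, interval) == pytest.approx(expected, abs=0.05)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            annualize(100.0, 0.0)


def _herd(counts_lw, year=2020):
    return HerdState(year, "MRT", "Traditional",
                     tuple(Cohort(n, c, w) for n, c, w in counts_lw))


class TestProjectHerd:
    def test_geometric_growth(self):
        herd = _herd([("cow", 1000.0, 250.0)])
        states = project_herd(herd, 0.055, 10)
        assert states[-1].cohort("cow").count == pytest.approx(1708.1, abs=0.05)

    def test_zero_growth_unchanged(self):
        herd = _herd([("cow", 120.0, 250.0), ("bull", 30.0, 300.0)])
        states = project_herd(herd, 0.0, 5)
        assert all(s.total_head == herd.total_head for s in states)

    def test_one_year(self):
        herd = _herd([("cow", 100.0, 250.0)])
        assert project_herd(herd, 0.045, 1)[-1].cohort("cow").count == \
            pytest.approx(104.5)

    def test_proportions_constant(self):
        herd = _herd([("cow", 100.0, 250.0), ("heifer", 40.0, 170.0)])
        last = project_herd(herd, 0.055, 8)[-1]
        assert last.cohort("heifer").count / last.cohort("cow").count == \
            pytest.approx(0.4)

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            project_herd(_herd([("cow", 1.0, 250.0)]), 0.05, -1)


class TestTluAndMeat:
    def test_tlu_definition(self):
        assert to_tlu(_herd([("cow", 1.0, 250.0)])) == 1.0

    def test_tlu_two_cohorts(self):
        herd = _herd([("cow", 10.0, 250.0), ("heifer", 10.0, 125.0)])
        assert to_tlu(herd) == pytest.approx(15.0)

    def test_tlu_empty(self):
        assert to_tlu(HerdState(2020, "MRT", "Traditional", ())) == 0.0

    def test_meat_female(self, test_breed):
        herd = _herd([("cow", 100.0, 250.0)])
        assert meat_output(herd, test_breed) == pytest.approx(1001.0)

    def test_meat_male(self, test_breed):
        herd = _herd([("bull", 100.0, 400.0)])
        assert meat_output(herd, test_breed) == pytest.approx(2912.0)

    def test_zero_culling(self, test_breed):
        breed = test_breed.__class__(**{**test_breed.__dict__,
                                        "culling_rate_female": 0.0,
                                        "culling_rate_male": 0.0})
        herd = _herd([("cow", 100.0, 250.0), ("bull", 10.0, 300.0)])
        assert meat_output(herd, breed) == 0.0
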