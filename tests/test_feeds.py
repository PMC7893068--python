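"""Feeding-strategy diet transforms: conservation, forage, concentrate."""

import pytest
from hypothesis import given, settings, strategies as st

from dairylca.feeds import (SCENARIOS, Diet, DietEntry, apply_concentrate,
                            apply_conservation, apply_forage,
                            build_scenario_diet)

from conftest import uniform_diet


def month_offers(diet, cohort, month):
    return diet.offers(cohort, month)


class TestConservation:
    def test_cow_stover_becomes_treated(self):
        diet = uniform_diet("cow", {"maize_stover": 3.0})
        out = apply_conservation(diet)
        for m in range(1, 13):
            assert month_offers(out, "cow", m) == {"maize_stover_treated": 3.0}

    def test_no_stover_unchanged(self):
        diet = uniform_diet("cow", {"grass": 2.0})
        out = apply_conservation(diet)
        assert month_offers(out, "cow", 1) == {"grass": 2.0}

    def test_non_cow_cohorts_untouched(self):
        diet = uniform_diet("heifer", {"maize_stover": 2.0})
        out = apply_conservation(diet)
        assert month_offers(out, "heifer", 5) == {"maize_stover": 2.0}

    def test_idempotent(self):
        diet = uniform_diet("cow", {"maize_stover": 3.0, "grass": 1.0})
        once = apply_conservation(diet)
        twice = apply_conservation(once)
        assert once.to_frame().sort_values(["month", "feed"]).equals(
            twice.to_frame().sort_values(["month", "feed"]))


class TestForage:
    def test_proportional_substitution(self):
        diet = uniform_diet("cow", {"napier": 1.0, "grass": 4.0,
                                    "pasture": 2.0, "maize_bran": 3.0})
        out = apply_forage(diet, 0.25)
        offers = month_offers(out, "cow", 6)
        assert offers["napier"] == pytest.approx(2.5)
        assert offers["grass"] == pytest.approx(3.0)
        assert offers["pasture"] == pytest.approx(1.5)
        assert offers["maize_bran"] == pytest.approx(3.0)

    def test_share_equal_to_current_unchanged(self):
        diet = uniform_diet("cow", {"napier": 2.5, "grass": 7.5})
        out = apply_forage(diet, 0.25)
        assert month_offers(out, "cow", 1)["napier"] == pytest.approx(2.5)
        assert month_offers(out, "cow", 1)["grass"] == pytest.approx(7.5)

    def test_substitution_exhausting_grass(self):
        diet = uniform_diet("cow", {"napier": 0.0, "grass": 5.0,
                                    "maize_bran": 5.0})
        out = apply_forage(diet, 0.5)
        offers = month_offers(out, "cow", 3)
        assert offers["napier"] == pytest.approx(5.0)
        assert offers.get("grass", 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_grass_raises_with_month(self):
        diet = uniform_diet("cow", {"napier": 0.0, "grass": 1.0,
                                    "maize_bran": 9.0})
        with pytest.raises(ValueError, match="month"):
            apply_forage(diet, 0.5)

    def test_share_below_current_raises(self):
        diet = uniform_diet("cow", {"napier": 5.0, "grass": 5.0})
        with pytest.raises(ValueError):
            apply_forage(diet, 0.25)

    @given(grass=st.floats(1.0, 8.0), pasture=st.floats(1.0, 8.0),
           napier=st.floats(0.0, 1.0), share=st.floats(0.05, 0.25))
    @settings(max_examples=50, deadline=None)
    def test_dm_conserved_and_idempotent(self, grass, pasture, napier, share):
        diet = uniform_diet("cow", {"grass": grass, "pasture": pasture,
                                    "napier": napier})
        total0 = diet.total_offer("cow", 1)
        if napier > share * total0:
            return
        once = apply_forage(diet, share)
        assert once.total_offer("cow", 1) == pytest.approx(total0)
        twice = apply_forage(once, share)
        for f, o in once.offers("cow", 1).items():
            assert twice.offers("cow", 1).get(f, 0.0) == pytest.approx(o)
        assert all(e.offer >= 0 for e in once.entries)


class TestConcentrate:
    def test_local_early_month_amounts(self):
        diet = uniform_diet("cow", {"grass": 5.0})
        out = apply_concentrate(diet, SCENARIOS["L-CnFoCo"])
        nov = month_offers(out, "cow", 11)   # lactation starts with rains
        assert nov["maize_bran"] == pytest.approx(1.34)
        assert nov["sunflower_cake"] == pytest.approx(0.66)

    def test_improved_other_month_amounts(self):
        diet = uniform_diet("cow", {"grass": 5.0})
        out = apply_concentrate(diet, SCENARIOS["I-CnFoCo"])
        may = month_offers(out, "cow", 5)    # past early lactation
        assert may["maize_bran"] == pytest.approx(1.005)
        assert may["sunflower_cake"] == pytest.approx(0.495)

    def test_zero_amounts_unchanged(self):
        diet = uniform_diet("cow", {"grass": 5.0})
        out = apply_concentrate(diet, SCENARIOS["L-Cn"])
        assert month_offers(out, "cow", 1) == {"grass": 5.0}

    def test_dry_period_not_supplemented(self):
        diet = uniform_diet("cow", {"grass": 5.0})
        out = apply_concentrate(diet, SCENARIOS["L-CnFoCo"],
                                lactation_months=9)
        # lactation Nov..Jul; Aug-Oct are dry months
        assert "maize_bran" not in month_offers(out, "cow", 9)
        assert "maize_bran" in month_offers(out, "cow", 7)

    def test_dm_increases_by_exact_concentrate(self):
        diet = uniform_diet("cow", {"grass": 5.0})
        out = apply_concentrate(diet, SCENARIOS["I-CnFoCo"])
        assert out.total_offer("cow", 11) == pytest.approx(5.0 + 5.0)
        assert out.total_offer("cow", 5) == pytest.approx(5.0 + 1.5)


class TestBuildScenarioDiet:
    @pytest.fixture()
    def base(self):
        return uniform_diet("cow", {"grass": 3.0, "pasture": 2.0,
                                    "napier": 0.5, "maize_stover": 1.5})

    def test_base_identity(self, base):
        out = build_scenario_diet(base, SCENARIOS["Base"])
        assert out.to_frame().sort_values(["month", "feed"]).reset_index(
            drop=True).equals(base.to_frame().sort_values(
                ["month", "feed"]).reset_index(drop=True))

    def test_composition_order(self, base):
        via_builder = build_scenario_diet(base, SCENARIOS["L-CnFoCo"])
        manual = apply_concentrate(
            apply_forage(apply_conservation(base), 0.25),
            SCENARIOS["L-CnFoCo"])
        a = via_builder.to_frame().sort_values(["month", "feed"]).reset_index(drop=True)
        b = manual.to_frame().sort_values(["month", "feed"]).reset_index(drop=True)
        assert a.equals(b)

    def test_cn_only_substitutes_stover(self, base):
        out = build_scenario_diet(base, SCENARIOS["I-Cn"])
        offers = out.offers("cow", 2)
        assert offers["maize_stover_treated"] == pytest.approx(1.5)
        assert offers["grass"] == pytest.approx(3.0)
        assert "maize_bran" not in offers

    def test_unknown_scenario_rejected(self, base):
        from dairylca.feeds import ScenarioSpec
        with pytest.raises(ValueError):
            build_scenario_diet(base, ScenarioSpec("X-Zz"))
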