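import pytest

from dairylca.feeds import Diet, DietEntry
from dairylca.params import (BreedParams, FeedSpec, default_breeds,
                             default_carbon_densities,
                             default_emission_factors, default_feed_catalog)


@pytest.fixture(scope="session")
def feeds():
    return default_feed_catalog()


@pytest.fixture(scope="session")
def breeds():
    return default_breeds()


@pytest.fixture(scope="session")
def carbon():
    return default_carbon_densities()


@pytest.fixture()
def ef():
    return default_emission_factors()


def uniform_diet(cohort: str, offers: dict[str, float]) -> Diet:
    """Same offers every calendar month."""
    return Diet([DietEntry(cohort, m, f, o)
                 for m in range(1, 13) for f, o in offers.items()])


@pytest.fixture(scope="session")
def test_breed():
    """250-kg cow with round numbers for requirement arithmetic."""
    return BreedParams("local", potential_milk=3000.0, lactation_length=300.0,
                       calving_interval=400.0, mature_liveweight=250.0,
                       culling_rate_female=0.077, culling_rate_male=0.14,
                       dressing_fraction=0.52)


def flat_feed(feed_id="testfeed", me=10.0, cp=0.13, ge=18.0, de=0.65,
              yield_dm=5.0, ue=0.5, land_use="grassland_native",
              flux=0.1) -> FeedSpec:
    return FeedSpec(feed_id, "grass", land_use, me_density=me, cp_fraction=cp,
                    ge_density=ge, de_fraction=de, yield_dm=yield_dm,
                    use_efficiency=ue, soil_n2o_flux=flux)
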