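"""Parameter catalogs: feeds, breeds, carbon densities, emission factors.

The default catalogs encode the biomass-productivity, N2O-flux and
carbon-density parameters of the study region (southern-highlands
Tanzania mixed rainfed systems), plus nutrient and emission-factor
defaults for quantities that are only available in supplementary or
grey literature.  Every default can be overridden through the config
layer; the tier annotation says where each number sits on the
IPCC tier ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "FeedSpec",
    "BreedParams",
    "CarbonDensity",
    "EmissionFactorSet",
    "default_feed_catalog",
    "default_breeds",
    "default_carbon_densities",
    "default_emission_factors",
    "GE_PER_KG_CH4",
    "GWP_CH4",
    "GWP_N2O",
    "N2O_N_TO_N2O",
    "CO2_PER_C",
    "TLU_KG",
]

# Physical / reporting constants
GE_PER_KG_CH4 = 55.65   # MJ gross energy per kg CH4
GWP_CH4 = 28.0          # kg CO2eq per kg CH4 (AR5, 100-yr)
GWP_N2O = 265.0         # kg CO2eq per kg N2O (AR5, 100-yr)
N2O_N_TO_N2O = 44.0 / 28.0
CO2_PER_C = 44.0 / 12.0
TLU_KG = 250.0          # liveweight of one tropical livestock unit


@dataclass(frozen=True)
class FeedSpec:
    """One feed type with its nutrient content and land-use coupling.

    ``yield_dm`` is the reference yield used in the land-footprint
    denominator (Mg DM ha^-1 yr^-1): the available-product biomass for
    crop products (bran, cake, stover) and the annual herbage yield for
    grasses.  ``use_efficiency`` is the fraction of that biomass
    actually harvested or grazed.
    """

    feed_id: str
    category: str          # primary_crop | secondary_crop | grass
    land_use: str          # cropland_maize | cropland_sunflower | grassland_sown | grassland_native | none
    me_density: float      # MJ ME per kg DM
    cp_fraction: float     # kg CP per kg DM
    ge_density: float      # MJ GE per kg DM
    de_fraction: float     # digestible-energy fraction (for VS excretion)
    yield_dm: float        # Mg DM ha^-1 yr^-1 (Eq-1 denominator yield)
    use_efficiency: float  # fraction in (0, 1]
    soil_n2o_flux: float   # kg N2O ha^-1 yr^-1 baseline flux of its land class

    def __post_init__(self) -> None:
        if not (0.0 < self.use_efficiency <= 1.0):
            raise ValueError(f"{self.feed_id}: use_efficiency must be in (0,1]")
        if self.yield_dm < 0:
            raise ValueError(f"{self.feed_id}: yield_dm must be >= 0")


@dataclass(frozen=True)
class BreedParams:
    """Genetic and demographic parameters of one cattle population."""

    breed_id: str               # local | improved
    potential_milk: float       # kg FPCM per lactation (genetic ceiling)
    lactation_length: float     # days
    calving_interval: float     # days
    mature_liveweight: float    # kg (cow)
    culling_rate_female: float  # fraction yr^-1
    culling_rate_male: float    # fraction yr^-1
    dressing_fraction: float    # carcass fraction of liveweight
    milk_fat: float = 4.0       # % fat of raw milk
    milk_protein: float = 3.3   # % protein of raw milk

    def __post_init__(self) -> None:
        if self.potential_milk <= 0:
            raise ValueError("potential_milk must be > 0")
        if not (0 < self.lactation_length < self.calving_interval):
            raise ValueError("need 0 < lactation_length < calving_interval")
        for r in (self.culling_rate_female, self.culling_rate_male):
            if not (0.0 <= r <= 1.0):
                raise ValueError("culling rates must be in [0,1]")
        if not (0.0 < self.dressing_fraction < 1.0):
            raise ValueError("dressing_fraction must be in (0,1)")


@dataclass(frozen=True)
class CarbonDensity:
    """Carbon stocks of one land-use category, Mg C ha^-1."""

    land_use: str      # cropland | grassland | wetland | shrubland | forest
    soil_c: float
    other_pools_c: float

    @property
    def total_c(self) -> float:
        return self.soil_c + self.other_pools_c


@dataclass
class EmissionFactorSet:
    """GHG emission factors with IPCC tier provenance.

    ym_ref is the methane conversion factor (fraction of gross energy
    emitted as enteric CH4) at the reference diet ME density; the
    realized Ym declines linearly with diet ME density (Tier-3-like
    behaviour) but never by more than ym_max_decline relative.
    """

    ym_ref: float = 0.065            # Tier 2 default, tropical cattle
    ym_me_ref: float = 7.5           # MJ ME kg DM^-1 at which ym = ym_ref
    ym_slope: float = 0.0024         # absolute Ym decline per MJ of ME density
    ym_max_decline: float = 0.075    # relative floor: ym >= ym_ref*(1-this)
    b0: float = 0.13                 # m3 CH4 per kg VS, Tier 2
    mcf: float = 0.02                # methane conversion factor of manure system
    ef3_manure: float = 0.02         # kg N2O-N per kg N excreted
    ef1_soil: float = 0.015          # kg N2O-N per kg N applied (fertilized feed crops)
    urinary_energy_frac: float = 0.04
    ash_frac: float = 0.08
    embodied_co2: dict = field(default_factory=lambda: {
        # kg CO2 per kg of purchased input (manufacture + transport)
        "fertilizer_n": 3.5,
        "maize_bran": 0.10,
        "sunflower_cake": 0.12,
    })
    gwp_ch4: float = GWP_CH4
    gwp_n2o: float = GWP_N2O
    allocation_lo: float = 0.85
    allocation_hi: float = 0.95

    def ym(self, me_density: float) -> float:
        """Methane conversion factor for a diet of given ME density."""
        y = self.ym_ref - self.ym_slope * (me_density - self.ym_me_ref)
        lo = self.ym_ref * (1.0 - self.ym_max_decline)
        return float(min(max(y, lo), self.ym_ref))


def default_feed_catalog() -> dict[str, FeedSpec]:
    """Feed catalog for the study region.

    Yields, use efficiencies and baseline soil N2O fluxes follow the
    regional parameter table; nutrient contents (ME, CP, GE, DE) are
    package defaults from standard tropical feed composition references
    and are config-overridable.  Treated stover carries the
    urea-molasses uplift: +0.04 absolute CP and +15% relative ME over
    untreated stover.
    """
    stover_me = 6.5
    stover_cp = 0.040
    feeds = [
        FeedSpec("maize_bran", "primary_crop", "cropland_maize",
                 me_density=11.5, cp_fraction=0.120, ge_density=18.5,
                 de_fraction=0.80, yield_dm=0.44, use_efficiency=0.95,
                 soil_n2o_flux=1.03),
        FeedSpec("sunflower_cake", "primary_crop", "cropland_sunflower",
                 me_density=10.5, cp_fraction=0.340, ge_density=19.5,
                 de_fraction=0.75, yield_dm=0.36, use_efficiency=0.95,
                 soil_n2o_flux=0.90),
        # Stover shares the maize hectare with bran: land_use none so the
        # footprint uses the co-product rule instead of a separate area.
        FeedSpec("maize_stover", "secondary_crop", "none",
                 me_density=stover_me, cp_fraction=stover_cp, ge_density=17.5,
                 de_fraction=0.55, yield_dm=2.18, use_efficiency=0.95,
                 soil_n2o_flux=0.73),
        FeedSpec("maize_stover_treated", "secondary_crop", "none",
                 me_density=stover_me * 1.15, cp_fraction=stover_cp + 0.04,
                 ge_density=17.5, de_fraction=0.60, yield_dm=2.18,
                 use_efficiency=0.95, soil_n2o_flux=0.73),
        FeedSpec("napier", "grass", "grassland_sown",
                 me_density=9.0, cp_fraction=0.100, ge_density=17.8,
                 de_fraction=0.62, yield_dm=13.10, use_efficiency=0.75,
                 soil_n2o_flux=0.51),
        FeedSpec("pasture", "grass", "grassland_native",
                 me_density=7.5, cp_fraction=0.080, ge_density=18.0,
                 de_fraction=0.57, yield_dm=10.00, use_efficiency=0.50,
                 soil_n2o_flux=0.08),
        FeedSpec("grass", "grass", "grassland_native",
                 me_density=7.0, cp_fraction=0.070, ge_density=18.0,
                 de_fraction=0.55, yield_dm=3.00, use_efficiency=0.50,
                 soil_n2o_flux=0.13),
    ]
    return {f.feed_id: f for f in feeds}


def default_breeds() -> dict[str, BreedParams]:
    """Breed parameters for the two dairy populations.

    Calving intervals are chosen so that the lactation-to-annual milk
    conversion (x 365 / interval) is internally consistent with the
    regional baseline yields: 593.5 d for local cattle (inside the
    450-600 d literature range) and 553.4 d for improved cattle (the
    printed 400-520 d range is mutually inconsistent with the reported
    lactation/annual yield pairs; consistency wins, see methods note).
    """
    return {
        "local": BreedParams(
            "local", potential_milk=900.0, lactation_length=280.0,
            calving_interval=593.5, mature_liveweight=250.0,
            culling_rate_female=0.077, culling_rate_male=0.140,
            dressing_fraction=0.52),
        "improved": BreedParams(
            "improved", potential_milk=2200.0, lactation_length=305.0,
            calving_interval=553.4, mature_liveweight=400.0,
            culling_rate_female=0.077, culling_rate_male=0.140,
            dressing_fraction=0.52),
    }


def default_carbon_densities() -> dict[str, CarbonDensity]:
    """Carbon density (soil + other pools) per land-use category."""
    rows = [
        CarbonDensity("cropland", 38.0, 3.5),    # total 41.5
        CarbonDensity("grassland", 48.0, 4.5),   # total 52.5
        CarbonDensity("wetland", 42.0, 4.4),     # total 46.4
        CarbonDensity("shrubland", 41.0, 16.6),  # total 57.6
        CarbonDensity("forest", 69.0, 37.8),     # total 106.8
    ]
    return {c.land_use: c for c in rows}


def default_emission_factors() -> EmissionFactorSet:
    return EmissionFactorSet()


def scale_feed_yield(feed: FeedSpec, factor: float) -> FeedSpec:
    """Return a copy of ``feed`` with its reference yield scaled.

    Used when feed-crop yields grow over the projection or jump under
    yield-gap closure: the available product per hectare scales with
    the crop yield.
    """
    return replace(feed, yield_dm=feed.yield_dm * factor)
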