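"""Synthetic farm-survey generator.

The original parameterization of this pipeline came from a stratified
smallholder survey that is not public.  This module generates
survey-like inputs with controllable statistical structure: per-cohort,
per-season feed-on-offer means with gamma-distributed farm-level
dispersion, herd counts per production system and sector, and a scalar
grassland-availability parameter per system x sector (standing in for
the gridded availability analysis).

The default means are the package's study conditions: they yield
baseline lactation milk inside the published plausibility bands for
the region (500-600 kg for local cows, 1350-2200 kg for improved) and
wet/dry seasonality with grass-dominated wet-season diets and
stover-heavy dry-season diets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feeds import Diet, DietEntry, WET_MONTHS, season_of
from .herd import Cohort, HerdState
from .projection import SectorInputs

__all__ = ["SurveyGenSpec", "generate", "generate_all", "fixture_small",
           "DEFAULT_COW_OFFERS", "HERD_COMPOSITION", "COHORT_LIVEWEIGHTS"]


#: mean cow feed on offer, kg DM head^-1 d^-1, by sector and season
DEFAULT_COW_OFFERS: dict[str, dict[str, dict[str, float]]] = {
    "Traditional": {
        "wet": {"grass": 2.0, "pasture": 2.2, "napier": 0.7,
                "maize_stover": 0.4, "maize_bran": 0.05},
        "dry": {"grass": 1.0, "pasture": 1.2, "napier": 0.3,
                "maize_stover": 2.6, "maize_bran": 0.05},
    },
    "Modern": {
        "wet": {"grass": 1.5, "pasture": 2.0, "napier": 3.0,
                "maize_stover": 0.5, "maize_bran": 0.8,
                "sunflower_cake": 0.2},
        "dry": {"grass": 1.0, "pasture": 1.5, "napier": 1.5,
                "maize_stover": 2.8, "maize_bran": 0.8,
                "sunflower_cake": 0.2},
    },
}

#: support-cohort roughage share of daily DM intake (2.2% of liveweight)
_SUPPORT_DMI_FRAC = 0.022
_SUPPORT_MIX = {
    "wet": {"grass": 0.45, "pasture": 0.40, "maize_stover": 0.15},
    "dry": {"grass": 0.30, "pasture": 0.35, "maize_stover": 0.35},
}

#: herd composition per 100 cows; the Traditional sector and the MRT
#: system carry the larger unproductive overhead
HERD_COMPOSITION: dict[tuple[str, str], dict[str, float]] = {
    ("MRT", "Traditional"): {"cow": 100, "bull": 18, "juvenile_male": 22,
                             "heifer": 32, "calf_f": 22, "calf_m": 22},
    ("MRH", "Traditional"): {"cow": 100, "bull": 12, "juvenile_male": 16,
                             "heifer": 30, "calf_f": 20, "calf_m": 20},
    ("MRT", "Modern"): {"cow": 100, "bull": 5, "juvenile_male": 6,
                        "heifer": 35, "calf_f": 22, "calf_m": 18},
    ("MRH", "Modern"): {"cow": 100, "bull": 4, "juvenile_male": 5,
                        "heifer": 32, "calf_f": 20, "calf_m": 16},
}

COHORT_LIVEWEIGHTS: dict[str, dict[str, float]] = {
    "Traditional": {"cow": 250, "bull": 300, "juvenile_male": 180,
                    "heifer": 170, "calf_f": 80, "calf_m": 80},
    "Modern": {"cow": 400, "bull": 480, "juvenile_male": 280,
               "heifer": 270, "calf_f": 110, "calf_m": 110},
}


@dataclass
class SurveyGenSpec:
    """Statistical specification of the synthetic survey."""

    seed: int = 0
    n_farms: int = 1000
    system: str = "MRT"
    sector: str = "Traditional"
    cows_total: float = 100_000.0        # milking cows in the system
    improved_fraction: float = 0.05      # inside the 0.02-0.10 band
    offer_cv: float = 0.30               # farm-level gamma dispersion
    mean_offers: dict | None = None      # season -> feed -> kg DM d^-1
    availability_fraction: float = 0.95  # grassland availability relative
                                         # to initial-year demand
    year: int = 2020

    def cow_offers(self) -> dict[str, dict[str, float]]:
        return self.mean_offers or DEFAULT_COW_OFFERS[self.sector]


def _gamma_draws(rng: np.random.Generator, mean: float, cv: float,
                 n: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=n)


def generate(spec: SurveyGenSpec) -> SectorInputs:
    """Generate survey-like inputs for one system x sector.

    Per-farm offers are gamma draws around the season means; the
    sector diet is their across-farm mean, so it converges to the
    specified means as n_farms grows.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    sector = spec.sector

    # herd
    n_cows = spec.cows_total * (spec.improved_fraction if sector == "Modern"
                                else 1.0 - spec.improved_fraction)
    comp = HERD_COMPOSITION[(spec.system, sector)]
    lw = COHORT_LIVEWEIGHTS[sector]
    cohorts = tuple(Cohort(name, n_cows * per100 / 100.0, lw[name])
                    for name, per100 in comp.items())
    herd = HerdState(spec.year, spec.system, sector, cohorts)

    # cow diet: across-farm mean of gamma draws per feed x season
    entries: list[DietEntry] = []
    offers = spec.cow_offers()
    farm_means: dict[tuple[str, str], float] = {}
    for season in ("wet", "dry"):
        for feed_id, mean in sorted(offers[season].items()):
            draws = _gamma_draws(rng, mean, spec.offer_cv, spec.n_farms)
            farm_means[(season, feed_id)] = float(draws.mean())
    for month in range(1, 13):
        season = season_of(month)
        for feed_id in sorted(offers[season]):
            entries.append(DietEntry("cow", month, feed_id,
                                     farm_means[(season, feed_id)]))

    # support cohorts: roughage at 2.2% liveweight with seasonal mix
    for name, per100 in comp.items():
        if name == "cow":
            continue
        dmi = _SUPPORT_DMI_FRAC * lw[name]
        for month in range(1, 13):
            mix = _SUPPORT_MIX[season_of(month)]
            for feed_id, share in mix.items():
                entries.append(DietEntry(name, month, feed_id, dmi * share))

    diet = Diet(entries)

    # grassland availability relative to the initial-year grass demand
    from .footprint import herd_footprint
    from .params import default_feed_catalog
    land0 = herd_footprint(herd, diet, default_feed_catalog())
    availability = spec.availability_fraction * land0.grassland

    return SectorInputs(herd=herd, base_diet=diet,
                        grass_availability=availability)


def generate_all(seed: int = 0, n_farms: int = 1000,
                 cows_total: dict[str, float] | None = None,
                 improved_fraction: float = 0.05,
                 availability_fraction: dict[str, float] | None = None,
                 ) -> dict[tuple[str, str], SectorInputs]:
    """Inputs for the full 2-system x 2-sector study grid.

    Seeds are derived per cell so cells are independent but the whole
    grid is reproducible from one integer.
    """
    cows_total = cows_total or {"MRT": 100_000.0, "MRH": 100_000.0}
    avail = availability_fraction or {"Traditional": 0.95, "Modern": 0.98}
    out = {}
    for i, system in enumerate(("MRT", "MRH")):
        for j, sector in enumerate(("Traditional", "Modern")):
            cell_seed = (seed * 4 + i * 2 + j) % (2**31 - 1)
            out[(system, sector)] = generate(SurveyGenSpec(
                seed=cell_seed, n_farms=n_farms, system=system, sector=sector,
                cows_total=cows_total[system],
                improved_fraction=improved_fraction,
                availability_fraction=avail[sector]))
    return out


def fixture_small() -> SectorInputs:
    """Tiny fully hand-checkable bundle: one cow, two feeds.

    The cow is offered 4.0 kg grass + 2.0 kg napier every day of the
    year.  Annual demand: 4.0 x 365 / 1000 = 1.46 Mg grass and 0.73 Mg
    napier.  Land: 1.46/(3.0 x 0.5) = 0.97333 ha native grassland and
    0.73/(13.10 x 0.75) = 0.074300 ha sown grassland; TLU = 250/250 = 1.
    """
    herd = HerdState(2020, "MRT", "Traditional",
                     (Cohort("cow", 1.0, 250.0),))
    entries = [DietEntry("cow", m, f, o)
               for m in range(1, 13)
               for f, o in (("grass", 4.0), ("napier", 2.0))]
    return SectorInputs(herd=herd, base_diet=Diet(entries),
                        grass_availability=1.2)
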