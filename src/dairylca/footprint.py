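"""Land footprint of the dairy herd.

Each feed's land requirement is annual feed on offer divided by
(reference yield x use efficiency); the herd footprint sums this over
cohorts and feeds, scaled by head counts, and is reported per land-use
class and per tropical livestock unit.

Maize bran and maize stover are co-products of the same hectare: the
maize cropland requirement is the larger of the areas implied by the
bran demand and by the stover demand, never their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .feeds import Diet
from .herd import DAYS_PER_MONTH, HerdState, to_tlu
from .params import FeedSpec

__all__ = ["LandLedger", "feed_area", "crop_product_area", "herd_footprint",
           "annual_feed_demand"]

LAND_CLASSES = ("cropland_maize", "cropland_sunflower",
                "grassland_sown", "grassland_native")

#: feeds drawing on the shared maize hectare
_MAIZE_PRODUCTS = ("maize_bran",)
_MAIZE_RESIDUES = ("maize_stover", "maize_stover_treated")


@dataclass
class LandLedger:
    """Hectares by land-use class for one herd-year."""

    areas: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in LAND_CLASSES})
    tlu: float = 0.0

    def __post_init__(self) -> None:
        for cls, a in self.areas.items():
            if a < -1e-12:
                raise ValueError(f"negative area for {cls}")

    @property
    def total_area(self) -> float:
        return sum(self.areas.values())

    @property
    def footprint_per_tlu(self) -> float:
        return self.total_area / self.tlu if self.tlu > 0 else 0.0

    @property
    def cropland(self) -> float:
        return self.areas["cropland_maize"] + self.areas["cropland_sunflower"]

    @property
    def grassland(self) -> float:
        return self.areas["grassland_sown"] + self.areas["grassland_native"]

    def __add__(self, other: "LandLedger") -> "LandLedger":
        areas = {c: self.areas.get(c, 0.0) + other.areas.get(c, 0.0)
                 for c in LAND_CLASSES}
        return LandLedger(areas=areas, tlu=self.tlu + other.tlu)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, a) for c, a in self.areas.items()],
            columns=["land_use_class", "ha"])


def feed_area(annual_offer: float, feed: FeedSpec) -> float:
    """Hectares required to supply ``annual_offer`` Mg DM of a feed."""
    denom = feed.yield_dm * feed.use_efficiency
    if denom <= 0:
        raise ValueError(
            f"feed {feed.feed_id!r} has zero available biomass x use "
            f"efficiency; cannot compute area")
    if annual_offer < 0:
        raise ValueError("annual_offer must be >= 0")
    return annual_offer / denom


def crop_product_area(product_demand: float, product: str,
                      feeds: dict[str, FeedSpec]) -> float:
    """Cropland for a purchased crop product (bran or cake)."""
    if product not in ("maize_bran", "sunflower_cake"):
        raise ValueError(f"unknown crop product {product!r}")
    if product_demand < 0:
        raise ValueError("demand must be >= 0")
    return feed_area(product_demand, feeds[product])


def annual_feed_demand(herd: HerdState, diet: Diet) -> dict[str, float]:
    """Total herd demand per feed, Mg DM yr^-1."""
    demand: dict[str, float] = {}
    for cohort in herd.cohorts:
        for month in range(1, 13):
            for feed_id, offer in diet.offers(cohort.name, month).items():
                mg = cohort.count * offer * DAYS_PER_MONTH / 1000.0
                demand[feed_id] = demand.get(feed_id, 0.0) + mg
    return demand


def herd_footprint(herd: HerdState, diet: Diet,
                   feeds: dict[str, FeedSpec]) -> LandLedger:
    """Land ledger of one herd-year under one diet.

    Applies the maize co-product rule: bran and stover demands each
    imply a maize area; the requirement is their maximum (surplus
    co-product is discarded, no double counting).
    """
    demand = annual_feed_demand(herd, diet)
    areas = {c: 0.0 for c in LAND_CLASSES}

    bran_area = stover_area = 0.0
    for feed_id, mg in demand.items():
        if feed_id not in feeds:
            raise KeyError(f"dieted feed {feed_id!r} missing from catalog")
        spec = feeds[feed_id]
        a = feed_area(mg, spec)
        if feed_id in _MAIZE_PRODUCTS:
            bran_area += a
        elif feed_id in _MAIZE_RESIDUES:
            stover_area += a
        elif spec.land_use in areas:
            areas[spec.land_use] += a
        elif spec.land_use == "none":
            pass
        else:
            raise ValueError(f"unknown land use {spec.land_use!r}")

    areas["cropland_maize"] += max(bran_area, stover_area)
    return LandLedger(areas=areas, tlu=to_tlu(herd))
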