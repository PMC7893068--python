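"""Land-use-change CO2 via the stock-change method.

Two transitions are tracked: cropland expansion (grassland converted to
cropland, carbon-stock difference 11.0 Mg C ha^-1 from the parameter
table) and grassland expansion (native shrub/forest/wetland converted
to grassland; weighted stock differences of 31.5 and 30.9 Mg C ha^-1
for the MRT and MRH systems).  Each hectare converted releases its
stock difference x 44/12 as CO2, amortized evenly over 20 years.
Cropland expansion displaces grassland one-for-one (the competition
effect); native ecosystems are converted only when grassland demand
plus displaced grassland exceeds availability.  Contraction emits and
sequesters nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CO2_PER_C, CarbonDensity

__all__ = [
    "LucTransition", "AMORTIZATION_YEARS", "CROP_GRASS_DELTA_C",
    "GRASS_EXPANSION_DELTA_C", "native_delta_c", "cropland_expansion",
    "grassland_balance", "grassland_expansion", "crop_grass_delta_c",
    "LucTracker",
]

AMORTIZATION_YEARS = 20

#: stock-change coefficients, Mg C ha^-1
CROP_GRASS_DELTA_C = 11.0
GRASS_EXPANSION_DELTA_C = {"MRT": 31.5, "MRH": 30.9}


@dataclass(frozen=True)
class LucTransition:
    kind: str        # cropland_expansion | grassland_expansion
    area: float      # ha converted this year
    delta_c: float   # Mg C ha^-1 stock difference
    system: str      # MRT | MRH

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("transition area must be >= 0")

    @property
    def annual_co2(self) -> float:
        """Amortized flux, Mg CO2 yr^-1 for 20 years."""
        return self.area * self.delta_c * CO2_PER_C / AMORTIZATION_YEARS

    @property
    def total_co2(self) -> float:
        return self.area * self.delta_c * CO2_PER_C


def crop_grass_delta_c(densities: dict[str, CarbonDensity]) -> float:
    """Grassland minus cropland total carbon density, Mg C ha^-1."""
    return densities["grassland"].total_c - densities["cropland"].total_c


def native_delta_c(shares: dict[str, float],
                   densities: dict[str, CarbonDensity]) -> float:
    """Weighted native (shrub/forest/wetland) minus grassland stock.

    ``shares`` maps the native categories to weights summing to 1.
    """
    s = sum(shares.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"native shares must sum to 1 (got {s})")
    if any(v < 0 for v in shares.values()):
        raise ValueError("shares must be >= 0")
    native = sum(w * densities[k].total_c for k, w in shares.items())
    return native - densities["grassland"].total_c


def cropland_expansion(delta_crop_area: float,
                       system: str = "MRT",
                       delta_c: float = CROP_GRASS_DELTA_C,
                       ) -> tuple[LucTransition, float]:
    """Cropland expansion transition and the grassland area it displaces.

    Negative changes (contraction) are clamped to zero: land taken out
    of feed production is not credited with sequestration.
    """
    area = max(0.0, delta_crop_area)
    return (LucTransition("cropland_expansion", area, delta_c, system), area)


def grassland_balance(grass_demand: float, availability: float,
                      displaced: float) -> float:
    """Native area converted: max(0, demand + displaced - availability)."""
    if min(grass_demand, availability, displaced) < 0:
        raise ValueError("inputs must be >= 0")
    return max(0.0, grass_demand + displaced - availability)


def grassland_expansion(area: float, system: str,
                        delta_c: dict[str, float] | None = None
                        ) -> LucTransition:
    """Grassland-expansion transition with the system's stock coefficient."""
    coeffs = delta_c or GRASS_EXPANSION_DELTA_C
    if system not in coeffs:
        raise ValueError(f"unknown production system {system!r}")
    return LucTransition("grassland_expansion", max(0.0, area),
                         coeffs[system], system)


class LucTracker:
    """Year-over-year LUC bookkeeping for one run.

    Tracks the high-water marks of cropland area and of cumulative
    native conversion so that only genuine expansion (not recovery of a
    previous contraction) opens a new 20-year amortization stream.
    """

    def __init__(self, system: str, grass_availability: float,
                 crop_delta_c: float = CROP_GRASS_DELTA_C,
                 grass_delta_c: dict[str, float] | None = None):
        self.system = system
        self.availability = grass_availability
        self.crop_delta_c = crop_delta_c
        self.grass_delta_c = grass_delta_c or GRASS_EXPANSION_DELTA_C
        self._peak_cropland = None
        self._displaced_cum = 0.0
        self._native_cum = 0.0
        self.transitions: list[tuple[int, LucTransition]] = []

    def step(self, year: int, cropland: float, grassland_demand: float
             ) -> float:
        """Advance one year; returns this year's amortized LUC flux
        (Mg CO2 yr^-1) from all streams opened so far."""
        if self._peak_cropland is None:
            # First year establishes the pre-existing land base: land
            # already in use (including any native shortfall) was
            # converted historically and is not attributed to the run.
            self._peak_cropland = cropland
            self._native_cum = grassland_balance(
                grassland_demand, self.availability, 0.0)
            return self.annual_flux()

        crop_exp = max(0.0, cropland - self._peak_cropland)
        self._peak_cropland = max(self._peak_cropland, cropland)
        trans, displaced = cropland_expansion(
            crop_exp, self.system, self.crop_delta_c)
        if trans.area > 0:
            self.transitions.append((year, trans))
        self._displaced_cum += displaced

        native_target = grassland_balance(
            grassland_demand, self.availability, self._displaced_cum)
        native_new = max(0.0, native_target - self._native_cum)
        self._native_cum = max(self._native_cum, native_target)
        if native_new > 0:
            self.transitions.append((year, grassland_expansion(
                native_new, self.system, self.grass_delta_c)))
        return self.annual_flux()

    def annual_flux(self) -> float:
        """Current-year amortized flux from all open streams, Mg CO2."""
        return sum(t.annual_co2 for _, t in self.transitions)
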