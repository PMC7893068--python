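"""Cradle-to-farm-gate greenhouse-gas inventory.

Sources: enteric CH4 (gross-energy based, Tier-2/3 Ym), manure CH4
(volatile solids x B0 x MCF) and N2O (excreted N x EF3), soil N2O
(area-based baseline fluxes plus fertilizer-induced EF1 emissions),
embodied CO2 of purchased inputs, and land-use-change CO2 computed
elsewhere.  CH4 and N2O convert to CO2-eq at GWP100 of 28 and 265.
Emissions are allocated to milk by a mass allocation factor bounded to
[0.85, 0.95] and expressed per kg fat-and-protein-corrected milk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .footprint import LandLedger
from .params import (EmissionFactorSet, FeedSpec, GE_PER_KG_CH4, GWP_CH4,
                     GWP_N2O, N2O_N_TO_N2O)

__all__ = [
    "EmissionLedger", "enteric_ch4", "manure_emissions", "soil_n2o",
    "energy_co2", "allocate_and_intensity", "fpcm", "vs_excretion",
]

SOURCES = ("enteric_ch4", "manure_ch4", "manure_n2o", "soil_n2o",
           "energy_co2", "luc_co2")
_GAS = {"enteric_ch4": ("CH4", GWP_CH4), "manure_ch4": ("CH4", GWP_CH4),
        "manure_n2o": ("N2O", GWP_N2O), "soil_n2o": ("N2O", GWP_N2O),
        "energy_co2": ("CO2", 1.0), "luc_co2": ("CO2", 1.0)}

# IDF fat-and-protein correction coefficients (to 4% fat, 3.3% protein)
_FPCM_FAT, _FPCM_PROT, _FPCM_CONST = 0.1226, 0.0776, 0.2534


@dataclass
class EmissionLedger:
    """Per-source gas masses (kg of gas) for one run-year or run."""

    gas_mass: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SOURCES})
    fpcm_out: float = 0.0     # kg FPCM
    meat_out: float = 0.0     # kg carcass
    allocation: float | None = None

    def co2eq(self, source: str) -> float:
        gas, gwp = _GAS[source]
        return self.gas_mass.get(source, 0.0) * gwp

    @property
    def total_co2eq(self) -> float:
        return sum(self.co2eq(s) for s in SOURCES)

    @property
    def direct_co2eq(self) -> float:
        return self.total_co2eq - self.co2eq("luc_co2")

    @property
    def intensity_direct(self) -> float:
        """kg CO2eq per kg FPCM, excluding land-use change."""
        self._require_allocated()
        return self.allocation * self.direct_co2eq / self.fpcm_out

    @property
    def intensity_total(self) -> float:
        """kg CO2eq per kg FPCM, including land-use change."""
        self._require_allocated()
        return self.allocation * self.total_co2eq / self.fpcm_out

    @property
    def intensity_luc(self) -> float:
        self._require_allocated()
        return self.allocation * self.co2eq("luc_co2") / self.fpcm_out

    def _require_allocated(self) -> None:
        if self.allocation is None:
            raise ValueError("call allocate_and_intensity first")
        if self.fpcm_out <= 0:
            raise ValueError("fpcm_out must be > 0 for intensities")

    def __add__(self, other: "EmissionLedger") -> "EmissionLedger":
        gm = {s: self.gas_mass.get(s, 0.0) + other.gas_mass.get(s, 0.0)
              for s in SOURCES}
        return EmissionLedger(gas_mass=gm,
                              fpcm_out=self.fpcm_out + other.fpcm_out,
                              meat_out=self.meat_out + other.meat_out)

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, _GAS[s][0], self.gas_mass[s], self.co2eq(s))
                for s in SOURCES]
        return pd.DataFrame(rows, columns=["source", "gas", "kg_gas",
                                           "kg_co2eq"])


def enteric_ch4(gei: float, ym: float) -> float:
    """Enteric CH4 (kg) from gross energy intake (MJ) and Ym."""
    if gei < 0 or not (0.0 <= ym < 1.0):
        raise ValueError("need gei >= 0 and 0 <= ym < 1")
    return gei * ym / GE_PER_KG_CH4


def vs_excretion(gei_daily: float, de_fraction: float,
                 ef: EmissionFactorSet) -> float:
    """Volatile solids excretion, kg VS d^-1 (IPCC Tier 2 form)."""
    return (gei_daily * (1.0 - de_fraction) +
            ef.urinary_energy_frac * gei_daily) * (1.0 - ef.ash_frac) / 18.45


def manure_emissions(vs: float, n_excreted: float,
                     ef: EmissionFactorSet) -> tuple[float, float]:
    """Manure (CH4 kg yr^-1, N2O kg yr^-1) from daily VS and annual N.

    CH4 = VS x 365 x B0 x 0.67 kg m^-3 x MCF; N2O = N x EF3 x 44/28.
    """
    if vs < 0 or n_excreted < 0:
        raise ValueError("inputs must be >= 0")
    ch4 = vs * 365.0 * ef.b0 * 0.67 * ef.mcf
    n2o = n_excreted * ef.ef3_manure * N2O_N_TO_N2O
    return ch4, n2o


def soil_n2o(land: LandLedger, n_applied: dict[str, float],
             feeds: dict[str, FeedSpec], ef: EmissionFactorSet) -> float:
    """Soil N2O (kg yr^-1): baseline fluxes per land class + fertilizer.

    ``n_applied`` maps land class -> kg N ha^-1 applied (fertilized feed
    crops only; empty for unfertilized baselines).
    """
    flux_by_class = {
        "cropland_maize": _class_flux(feeds, "maize_bran"),
        "cropland_sunflower": _class_flux(feeds, "sunflower_cake"),
        "grassland_sown": _class_flux(feeds, "napier"),
        "grassland_native": _native_grass_flux(feeds),
    }
    total = 0.0
    for cls, area in land.areas.items():
        if area < 0:
            raise ValueError("areas must be >= 0")
        total += area * flux_by_class.get(cls, 0.0)
        n_rate = n_applied.get(cls, 0.0)
        if n_rate:
            total += area * n_rate * ef.ef1_soil * N2O_N_TO_N2O
    return total


def _class_flux(feeds: dict[str, FeedSpec], feed_id: str) -> float:
    return feeds[feed_id].soil_n2o_flux if feed_id in feeds else 0.0


def _native_grass_flux(feeds: dict[str, FeedSpec]) -> float:
    # area-weighting between pasture and grassland fluxes is not
    # observable at ledger level; use the simple mean of the two rows
    vals = [feeds[f].soil_n2o_flux for f in ("pasture", "grass") if f in feeds]
    return sum(vals) / len(vals) if vals else 0.0


def energy_co2(purchased: dict[str, float], ef: EmissionFactorSet) -> float:
    """Embodied CO2 (kg) of purchased inputs {input: kg}."""
    total = 0.0
    for item, qty in purchased.items():
        if item not in ef.embodied_co2:
            raise KeyError(f"no embodied CO2 factor for input {item!r}")
        total += qty * ef.embodied_co2[item]
    return total


def allocate_and_intensity(ledger: EmissionLedger, milk_fpcm: float,
                           meat: float,
                           ef: EmissionFactorSet | None = None) -> EmissionLedger:
    """Set mass allocation milk/(milk+meat) clipped to [0.85, 0.95] and
    enable the per-kg-FPCM intensity properties."""
    ef = ef or EmissionFactorSet()
    if milk_fpcm <= 0:
        raise ValueError("milk_fpcm must be > 0 for allocation")
    if meat < 0:
        raise ValueError("meat must be >= 0")
    alloc = milk_fpcm / (milk_fpcm + meat)
    ledger.allocation = min(max(alloc, ef.allocation_lo), ef.allocation_hi)
    ledger.fpcm_out = milk_fpcm
    ledger.meat_out = meat
    return ledger


def fpcm(milk_raw: float, fat: float, protein: float) -> float:
    """Fat-and-protein-corrected milk (kg) from raw milk and % fat/protein."""
    if milk_raw < 0 or fat < 0 or protein < 0:
        raise ValueError("inputs must be >= 0")
    return milk_raw * (_FPCM_FAT * fat + _FPCM_PROT * protein + _FPCM_CONST)
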