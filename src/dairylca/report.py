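"""Summary tables, percent-change conventions, and regional benchmarks.

The percent-change convention for milk yields is the ratio of annual
per-cow fat-and-protein-corrected milk to the sector/system baseline,
expressed in percent.  ``REGIONAL_BENCHMARKS`` holds the published
regional simulation yields used as calibration references for this
convention (two cells of the published change column are inconsistent
with any adjacent ratio and are excluded from checks as probable
typos).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["percent_change", "REGIONAL_BENCHMARKS", "benchmark_changes",
           "matrix_summary", "sector_maxima"]


def percent_change(value: float, baseline: float) -> float:
    """(value / baseline - 1) x 100."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return (value / baseline - 1.0) * 100.0


#: published regional milk yields (kg FPCM per cow): lactation, annual
REGIONAL_BENCHMARKS: dict[tuple[str, str], tuple[float, float]] = {
    ("MRT", "Base-L"): (582, 358), ("MRT", "L-Cn"): (689, 424),
    ("MRT", "L-CnFo"): (823, 507), ("MRT", "L-CnFoCo"): (858, 528),
    ("MRH", "Base-L"): (538, 331), ("MRH", "L-Cn"): (611, 377),
    ("MRH", "L-CnFo"): (758, 466), ("MRH", "L-CnFoCo"): (813, 501),
    ("MRT", "Base-I"): (1413, 932), ("MRT", "I-Cn"): (1458, 991),
    ("MRT", "I-CnFo"): (1833, 1264), ("MRT", "I-CnFoCo"): (2163, 1492),
    ("MRH", "Base-I"): (1326, 875), ("MRH", "I-Cn"): (1387, 915),
    ("MRH", "I-CnFo"): (1580, 1059), ("MRH", "I-CnFoCo"): (1965, 1355),
}


def benchmark_changes() -> pd.DataFrame:
    """Percent changes of the benchmark annual yields vs their baselines."""
    rows = []
    for (system, scen), (_, annual) in REGIONAL_BENCHMARKS.items():
        if scen.startswith("Base"):
            continue
        base_key = (system, "Base-L" if scen.startswith("L") else "Base-I")
        base_annual = REGIONAL_BENCHMARKS[base_key][1]
        rows.append((system, scen, annual,
                     percent_change(annual, base_annual)))
    return pd.DataFrame(rows, columns=["system", "scenario", "annual_kg",
                                       "change_pct"])


def matrix_summary(results: dict[str, "RunResult"]) -> pd.DataFrame:
    """Per-run summary of the executed matrix."""
    rows = []
    for run_id, res in results.items():
        led = res.ledger
        rows.append({
            "run_id": run_id,
            "system": res.spec.system,
            "sector": res.spec.sector,
            "scenario": res.spec.scenario.scenario_id,
            "cyg": res.spec.scenario.cyg,
            "milk_lactation_kg": res.cow_milk_lactation,
            "milk_annual_kg": res.cow_milk_annual,
            "fpcm_total_kg": led.fpcm_out,
            "intensity_direct": led.intensity_direct,
            "intensity_luc": led.intensity_luc,
            "intensity_total": led.intensity_total,
            "allocation": led.allocation,
            "footprint_ha_per_tlu": res.land_final.footprint_per_tlu,
            "cropland_ha": res.land_final.cropland,
            "grassland_ha": res.land_final.grassland,
        })
    return pd.DataFrame(rows)


def sector_maxima(summary: pd.DataFrame) -> pd.DataFrame:
    """Per system x sector: largest milk gain and intensity reduction
    across the scenario runs, relative to that cell's baseline."""
    rows = []
    for (system, sector), grp in summary.groupby(["system", "sector"]):
        base = grp[grp.scenario == "Base"]
        if base.empty:
            raise ValueError(f"no baseline run for {system}/{sector}")
        base = base.iloc[0]
        scen = grp[grp.scenario != "Base"]
        if scen.empty:
            continue
        milk_gain = (scen.milk_annual_kg / base.milk_annual_kg - 1) * 100
        int_red = (1 - scen.intensity_total / base.intensity_total) * 100
        luc_share = base.intensity_luc / base.intensity_total * 100
        rows.append({
            "system": system, "sector": sector,
            "baseline_intensity_direct": base.intensity_direct,
            "baseline_intensity_luc": base.intensity_luc,
            "baseline_intensity_total": base.intensity_total,
            "baseline_luc_share_pct": luc_share,
            "max_milk_gain_pct": float(milk_gain.max()),
            "max_intensity_reduction_pct": float(int_red.max()),
            "footprint_ha_per_tlu": base.footprint_ha_per_tlu,
        })
    return pd.DataFrame(rows)
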