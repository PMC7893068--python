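"""Configuration loading and parameter-table I/O.

Config is YAML with a strict schema: unknown keys are rejected so that
typos fail loudly.  Parameter tables round-trip as CSV; the carbon
density table is cross-checked on load (soils + other pools = total).
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import pandas as pd
import yaml

from .params import (BreedParams, CarbonDensity, EmissionFactorSet, FeedSpec,
                     default_breeds, default_carbon_densities,
                     default_emission_factors, default_feed_catalog)

__all__ = ["load_config", "load_feed_table", "save_feed_table",
           "load_carbon_table", "save_carbon_table", "build_catalogs"]

_TOP_KEYS = {"seed", "n_farms", "output_dir", "feeds", "breeds",
             "carbon_densities", "emission_factors", "uncertainty_se",
             "cows_total", "improved_fraction", "availability_fraction"}

_FEED_COLS = ["feed_id", "category", "land_use", "me_density", "cp_fraction",
              "ge_density", "de_fraction", "yield_dm", "use_efficiency",
              "soil_n2o_flux"]
_CARBON_COLS = ["land_use", "soil_c", "other_pools_c", "total_c"]


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def build_catalogs(cfg: dict | None = None):
    """(feeds, breeds, carbon, ef) with config overrides applied.

    Overrides are nested mappings keyed by id, e.g.
    ``feeds: {napier: {me_density: 9.5}}``.
    """
    cfg = cfg or {}
    feeds = default_feed_catalog()
    for fid, over in (cfg.get("feeds") or {}).items():
        if fid not in feeds:
            raise ValueError(f"unknown feed {fid!r} in config")
        feeds[fid] = replace(feeds[fid], **over)
    breeds = default_breeds()
    for bid, over in (cfg.get("breeds") or {}).items():
        if bid not in breeds:
            raise ValueError(f"unknown breed {bid!r} in config")
        breeds[bid] = replace(breeds[bid], **over)
    carbon = default_carbon_densities()
    for cid, over in (cfg.get("carbon_densities") or {}).items():
        if cid not in carbon:
            raise ValueError(f"unknown land use {cid!r} in config")
        carbon[cid] = replace(carbon[cid], **over)
    ef = default_emission_factors()
    for key, val in (cfg.get("emission_factors") or {}).items():
        if not hasattr(ef, key):
            raise ValueError(f"unknown emission factor {key!r}")
        setattr(ef, key, val)
    return feeds, breeds, carbon, ef


# -- CSV round trips --------------------------------------------------------

def save_feed_table(feeds: dict[str, FeedSpec], path: str | Path) -> None:
    df = pd.DataFrame([asdict(f) for f in feeds.values()])[_FEED_COLS]
    df.to_csv(path, index=False)


def load_feed_table(path: str | Path) -> dict[str, FeedSpec]:
    df = pd.read_csv(path)
    missing = set(_FEED_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"feed table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row.feed_id] = FeedSpec(**{c: row[c] for c in _FEED_COLS})
    return out


def save_carbon_table(carbon: dict[str, CarbonDensity],
                      path: str | Path) -> None:
    df = pd.DataFrame([{"land_use": c.land_use, "soil_c": c.soil_c,
                        "other_pools_c": c.other_pools_c,
                        "total_c": c.total_c} for c in carbon.values()])
    df.to_csv(path, index=False)


def load_carbon_table(path: str | Path) -> dict[str, CarbonDensity]:
    df = pd.read_csv(path)
    missing = set(_CARBON_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"carbon table missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        cd = CarbonDensity(row.land_use, float(row.soil_c),
                           float(row.other_pools_c))
        if abs(cd.total_c - float(row.total_c)) > 1e-6:
            raise ValueError(
                f"carbon table row {row.land_use!r}: soils {row.soil_c} + "
                f"other {row.other_pools_c} != total {row.total_c}")
        out[row.land_use] = cd
    return out
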