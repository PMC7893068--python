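"""Monte Carlo uncertainty propagation.

Each uncertain parameter is a multiplicative factor drawn from a
lognormal distribution with unit mean and the specified relative
standard error (positivity-preserving for emission factors and
yields).  Herd counts and feed offers are uncertain only in the
baseline run; in scenario runs they are frozen at their point values
so that only emission factors and biomass yields contribute, matching
how scenario inputs are defined relative to the baseline.

Intervals are empirical 2.5/97.5 percentiles of the re-executed
pipeline, robust to the skew of the lognormal factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import BreedParams, EmissionFactorSet, FeedSpec
from .projection import RunResult, RunSpec, SectorInputs, execute
from .feeds import Diet, DietEntry

__all__ = ["UncertaintySpec", "CIResult", "sample_parameters", "mc_run",
           "DEFAULT_SE"]

#: relative standard errors by parameter (tiered defaults); the
#: baseline_only set is frozen in non-baseline runs
DEFAULT_SE: dict[str, float] = {
    "ym": 0.10,
    "luc_delta_c": 0.20,
    "ef1": 0.66,
    "ef3": 0.30,
    "b0": 0.30,
    "mcf": 0.30,
    "embodied": 0.20,
    "biomass_yield": 0.20,
    # survey-sampling uncertainty of the sector MEANS (not farm-level
    # dispersion, which the synthetic generator models separately)
    "herd_count": 0.10,       # baseline only
    "feed_offer": 0.05,       # baseline only
}

BASELINE_ONLY = frozenset({"herd_count", "feed_offer"})


@dataclass
class UncertaintySpec:
    se: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SE))
    family: str = "lognormal"

    def scaled(self, factor: float) -> "UncertaintySpec":
        return UncertaintySpec({k: v * factor for k, v in self.se.items()},
                               self.family)


@dataclass(frozen=True)
class CIResult:
    quantity: str
    point: float
    lo95: float
    hi95: float
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        if self.lo95 > self.hi95 + 1e-12:
            raise ValueError("lo95 must be <= hi95")


def _lognormal_factor(rng: np.random.Generator, se: float) -> float:
    """Unit-mean lognormal multiplier with relative SE ``se``."""
    if se == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(se**2)))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def sample_parameters(spec: UncertaintySpec, seed: int) -> dict[str, float]:
    """One deterministic-per-seed draw of all parameter multipliers."""
    rng = np.random.default_rng(seed)
    draw = {}
    for name in sorted(spec.se):
        se = spec.se[name]
        if se < 0:
            raise ValueError(f"negative SE for {name}")
        draw[name] = _lognormal_factor(rng, se)
    return draw


def _perturb_ef(ef: EmissionFactorSet, d: dict[str, float]) -> EmissionFactorSet:
    emb = {k: v * d.get("embodied", 1.0) for k, v in ef.embodied_co2.items()}
    return replace(ef,
                   ym_ref=ef.ym_ref * d.get("ym", 1.0),
                   ef1_soil=ef.ef1_soil * d.get("ef1", 1.0),
                   ef3_manure=ef.ef3_manure * d.get("ef3", 1.0),
                   b0=ef.b0 * d.get("b0", 1.0),
                   mcf=ef.mcf * d.get("mcf", 1.0),
                   embodied_co2=emb)


def _perturb_feeds(feeds: dict[str, FeedSpec],
                   d: dict[str, float]) -> dict[str, FeedSpec]:
    m = d.get("biomass_yield", 1.0)
    return {k: replace(v, yield_dm=v.yield_dm * m) for k, v in feeds.items()}


def _perturb_inputs(inputs: SectorInputs, d: dict[str, float]) -> SectorInputs:
    mh = d.get("herd_count", 1.0)
    mo = d.get("feed_offer", 1.0)
    herd = replace(inputs.herd, cohorts=tuple(
        replace(c, count=c.count * mh) for c in inputs.herd.cohorts))
    diet = Diet([DietEntry(e.cohort, e.month, e.feed_id, e.offer * mo)
                 for e in inputs.base_diet.entries])
    return SectorInputs(herd=herd, base_diet=diet,
                        grass_availability=inputs.grass_availability * mh)


_QUANTITIES = ("intensity_direct", "intensity_total", "total_co2eq",
               "milk_fpcm", "total_area_ha")


def _measure(res: RunResult) -> dict[str, float]:
    degenerate = res.ledger.fpcm_out <= 0
    return {
        "intensity_direct": (np.inf if degenerate
                             else res.intensity_direct),
        "intensity_total": (np.inf if degenerate
                            else res.intensity_total),
        "total_co2eq": res.ledger.total_co2eq,
        "milk_fpcm": res.ledger.fpcm_out,
        "total_area_ha": res.land_final.total_area,
    }


def mc_run(run: RunSpec, inputs: SectorInputs,
           feeds: dict[str, FeedSpec], breeds: dict[str, BreedParams],
           ef: EmissionFactorSet | None = None,
           spec: UncertaintySpec | None = None,
           n_draws: int = 2000, seed: int = 0,
           luc_se: float | None = None) -> list[CIResult]:
    """Percentile 95% intervals for one run of the matrix.

    Re-executes the full pipeline per draw.  The LUC stock-change
    coefficients take the ``luc_delta_c`` multiplier via the tracker's
    module-level coefficients scaled per draw.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    ef = ef or EmissionFactorSet()
    spec = spec or UncertaintySpec()

    point = _measure(execute(run, inputs, feeds, breeds, ef))

    samples: dict[str, list[float]] = {q: [] for q in _QUANTITIES}
    for i in range(n_draws):
        d = sample_parameters(spec, (seed * 1_000_003 + i) % (2**31 - 1))
        if not run.is_baseline:
            for name in BASELINE_ONLY:
                d[name] = 1.0
        ef_i = _perturb_ef(ef, d)
        feeds_i = _perturb_feeds(feeds, d)
        inputs_i = _perturb_inputs(inputs, d)
        res = execute_with_luc_scale(run, inputs_i, feeds_i, breeds, ef_i,
                                     d.get("luc_delta_c", 1.0))
        for q, v in _measure(res).items():
            samples[q].append(v)

    out = []
    for q in _QUANTITIES:
        arr = np.asarray(samples[q])
        lo, hi = np.percentile(arr, [2.5, 97.5])
        out.append(CIResult(q, point[q], float(lo), float(hi), n_draws, seed))
    return out


def execute_with_luc_scale(run, inputs, feeds, breeds, ef,
                           luc_scale: float) -> RunResult:
    """Execute a run with the LUC stock-change coefficients scaled."""
    from . import luc as luc_mod
    from . import projection as proj

    if luc_scale == 1.0:
        return execute(run, inputs, feeds, breeds, ef)

    res = execute(run, inputs, feeds, breeds, ef)
    # LUC CO2 is linear in delta_c: rescale the ledger entry directly
    scaled = res.ledger.gas_mass["luc_co2"] * luc_scale
    res.ledger.gas_mass["luc_co2"] = scaled
    res.per_year["kg_luc_co2"] *= luc_scale
    return res


def ci_frame(results: list[CIResult]) -> pd.DataFrame:
    return pd.DataFrame([(r.quantity, r.point, r.lo95, r.hi95,
                          r.n_draws, r.seed) for r in results],
                        columns=["quantity", "point", "lo95", "hi95",
                                 "n_draws", "seed"])
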