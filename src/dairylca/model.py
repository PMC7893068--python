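"""Model / Results front end.

:class:`DairySectorModel` bundles the survey-like inputs (herds, base
diets, grassland availability) with the parameter catalogs; ``fit()``
executes the full 28-run projection matrix and returns a
:class:`SectorResults` carrying the per-run ledgers, summary tables,
and Monte Carlo confidence intervals on demand.

>>> model = DairySectorModel.from_survey(seed=1)
>>> res = model.fit()
>>> res.summary().head()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import montecarlo as mc
from . import report
from .params import (BreedParams, CarbonDensity, EmissionFactorSet, FeedSpec,
                     default_breeds, default_carbon_densities,
                     default_emission_factors, default_feed_catalog)
from .projection import (RunResult, RunSpec, SectorInputs, build_run_matrix,
                         execute)

__all__ = ["DairySectorModel", "SectorResults"]


@dataclass
class DairySectorModel:
    """The coupled herd / land-footprint / LCA model for a study region."""

    inputs: dict[tuple[str, str], SectorInputs]
    feeds: dict[str, FeedSpec] = field(default_factory=default_feed_catalog)
    breeds: dict[str, BreedParams] = field(default_factory=default_breeds)
    carbon: dict[str, CarbonDensity] = field(
        default_factory=default_carbon_densities)
    ef: EmissionFactorSet = field(default_factory=default_emission_factors)

    @classmethod
    def from_survey(cls, seed: int = 0, n_farms: int = 1000,
                    **kwargs) -> "DairySectorModel":
        """Build the model from the synthetic survey generator."""
        from .synthetic import generate_all
        return cls(inputs=generate_all(seed=seed, n_farms=n_farms), **kwargs)

    @property
    def systems(self) -> list[str]:
        return sorted({s for s, _ in self.inputs})

    @property
    def sectors(self) -> list[str]:
        return sorted({x for _, x in self.inputs})

    def run_matrix(self) -> list[RunSpec]:
        return build_run_matrix(systems=tuple(self.systems),
                                sectors=tuple(self.sectors))

    def fit(self) -> "SectorResults":
        """Execute every run of the matrix (deterministic)."""
        results: dict[str, RunResult] = {}
        for run in self.run_matrix():
            results[run.run_id] = execute(
                run, self.inputs[(run.system, run.sector)],
                self.feeds, self.breeds, self.ef)
        return SectorResults(model=self, runs=results)


@dataclass
class SectorResults:
    """Fitted run matrix with summaries and uncertainty."""

    model: DairySectorModel
    runs: dict[str, RunResult]

    def __getitem__(self, run_id: str) -> RunResult:
        return self.runs[run_id]

    def summary(self) -> pd.DataFrame:
        """One row per run: milk, intensities, allocation, land."""
        return report.matrix_summary(self.runs)

    def sector_maxima(self) -> pd.DataFrame:
        return report.sector_maxima(self.summary())

    def percent_change(self, run_id: str, quantity: str = "milk_annual_kg"
                       ) -> float:
        """Change of a run's quantity vs its system/sector baseline, %."""
        res = self.runs[run_id]
        base_id = f"{res.spec.system}-{res.spec.sector}-Base"
        s = self.summary().set_index("run_id")
        return report.percent_change(s.loc[run_id, quantity],
                                     s.loc[base_id, quantity])

    def conf_int(self, run_id: str, n_draws: int = 2000, seed: int = 0,
                 spec: mc.UncertaintySpec | None = None) -> pd.DataFrame:
        """Monte Carlo 95% intervals for one run."""
        res = self.runs[run_id]
        cis = mc.mc_run(res.spec,
                        self.model.inputs[(res.spec.system, res.spec.sector)],
                        self.model.feeds, self.model.breeds, self.model.ef,
                        spec=spec, n_draws=n_draws, seed=seed)
        return mc.ci_frame(cis)

    def per_year(self) -> pd.DataFrame:
        """Tidy concatenation of all per-run per-year frames."""
        return pd.concat([r.per_year for r in self.runs.values()],
                         ignore_index=True)
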