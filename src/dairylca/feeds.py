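"""Diets, the feed-on-offer schedule, and the feeding-strategy transforms.

A :class:`Diet` is a per-cohort, per-calendar-month schedule of feed on
offer (kg DM head^-1 d^-1).  The three feeding strategies are applied
as pure diet transformations, composed additively in the order
conservation -> forage -> concentrate:

* **Cn** (conservation): all maize stover fed to *cows* is replaced,
  DM-for-DM, with urea-molasses treated stover.
* **Fo** (forage quality): Napier grass is raised to a target share of
  each cow-month's total DM on offer, the increment removed from grass
  and pasture in proportion to their offers.
* **Co** (concentrate): a bran/cake mix (67%/33%) is added on top of
  the existing offer - a higher rate in early lactation (first three
  lactation months) than in other months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DietEntry", "Diet", "ScenarioSpec", "SCENARIOS",
    "apply_conservation", "apply_forage", "apply_concentrate",
    "build_scenario_diet",
]

WET_MONTHS = frozenset({11, 12, 1, 2, 3, 4})   # unimodal rains Nov-Apr
EARLY_LACTATION_MONTHS = 3                      # convention shared with herd sim

CONC_SPLIT = {"maize_bran": 0.67, "sunflower_cake": 0.33}


@dataclass(frozen=True)
class DietEntry:
    cohort: str
    month: int          # calendar month 1-12
    feed_id: str
    offer: float        # kg DM head^-1 d^-1

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError("month must be in 1..12")
        if self.offer < 0:
            raise ValueError("offer must be >= 0")


def season_of(month: int) -> str:
    return "wet" if month in WET_MONTHS else "dry"


@dataclass
class Diet:
    """Feed-on-offer schedule; entries unique per (cohort, month, feed)."""

    entries: list[DietEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.cohort, e.month, e.feed_id) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (cohort, month, feed) entries in diet")

    # -- accessors ----------------------------------------------------
    def offers(self, cohort: str, month: int) -> dict[str, float]:
        return {e.feed_id: e.offer for e in self.entries
                if e.cohort == cohort and e.month == month}

    def cohorts(self) -> list[str]:
        return sorted({e.cohort for e in self.entries})

    def total_offer(self, cohort: str, month: int) -> float:
        return sum(self.offers(cohort, month).values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.cohort, e.month, e.feed_id, e.offer) for e in self.entries],
            columns=["cohort", "month", "feed", "kg_dm_per_day"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Diet":
        entries = [DietEntry(r.cohort, int(r.month), r.feed, float(r.kg_dm_per_day))
                   for r in df.itertuples()]
        return cls(entries)

    def _replaced(self, mapper) -> "Diet":
        """New diet with every entry passed through ``mapper`` (may return
        a list of replacement entries)."""
        out: dict[tuple, float] = {}
        for e in self.entries:
            for ne in mapper(e):
                key = (ne.cohort, ne.month, ne.feed_id)
                out[key] = out.get(key, 0.0) + ne.offer
        return Diet([DietEntry(c, m, f, o) for (c, m, f), o in out.items()])


@dataclass(frozen=True)
class ScenarioSpec:
    """One feeding scenario of the run matrix (Table-2-style levers)."""

    scenario_id: str       # Base | L-Cn | L-CnFo | L-CnFoCo | I-Cn | I-CnFo | I-CnFoCo
    cyg: bool = False      # crop-yield-gap closure variant
    napier_share: float = 0.0
    conc_early: float = 0.0   # kg DM d^-1, first 3 lactation months
    conc_other: float = 0.0   # kg DM d^-1, remaining lactation months

    def __post_init__(self) -> None:
        if not (0.0 <= self.napier_share <= 1.0):
            raise ValueError("napier_share must be in [0,1]")
        if self.conc_early < 0 or self.conc_other < 0:
            raise ValueError("concentrate amounts must be >= 0")

    @property
    def stages(self) -> tuple[str, ...]:
        sid = self.scenario_id
        if sid == "Base":
            return ()
        tail = sid.split("-", 1)[1]
        stages = []
        for name in ("Cn", "Fo", "Co"):
            if name in tail:
                stages.append(name)
        return tuple(stages)

    def with_cyg(self, cyg: bool = True) -> "ScenarioSpec":
        return replace(self, cyg=cyg)


#: Scenario definitions: local cattle get 25% Napier and 2.0/0.5 kg
#: concentrates; improved cattle 50% Napier and 5.0/1.5 kg.
SCENARIOS: dict[str, ScenarioSpec] = {
    "Base": ScenarioSpec("Base"),
    "L-Cn": ScenarioSpec("L-Cn"),
    "L-CnFo": ScenarioSpec("L-CnFo", napier_share=0.25),
    "L-CnFoCo": ScenarioSpec("L-CnFoCo", napier_share=0.25,
                             conc_early=2.0, conc_other=0.5),
    "I-Cn": ScenarioSpec("I-Cn"),
    "I-CnFo": ScenarioSpec("I-CnFo", napier_share=0.50),
    "I-CnFoCo": ScenarioSpec("I-CnFoCo", napier_share=0.50,
                             conc_early=5.0, conc_other=1.5),
}


# ---------------------------------------------------------------------------
# strategy transforms


def apply_conservation(diet: Diet) -> Diet:
    """Cn: cow maize stover becomes treated stover at identical DM offer."""
    def mapper(e: DietEntry):
        if e.cohort == "cow" and e.feed_id == "maize_stover":
            return [replace(e, feed_id="maize_stover_treated")]
        return [e]
    return diet._replaced(mapper)


def apply_forage(diet: Diet, napier_share: float) -> Diet:
    """Fo: per cow-month, set Napier to ``napier_share`` of total DM on
    offer, removing the increment from grass and pasture in proportion
    to their offers.  Total DM is conserved."""
    new_entries: list[DietEntry] = []
    for cohort in diet.cohorts():
        for month in range(1, 13):
            offers = diet.offers(cohort, month)
            if not offers:
                continue
            if cohort != "cow":
                new_entries += [DietEntry(cohort, month, f, o)
                                for f, o in offers.items()]
                continue
            total = sum(offers.values())
            current_napier = offers.get("napier", 0.0)
            target_napier = napier_share * total
            increment = target_napier - current_napier
            if increment < -1e-12:
                raise ValueError(
                    f"month {month}: napier share {napier_share} below current "
                    f"share {current_napier / total:.3f}")
            absorbers = {f: offers.get(f, 0.0) for f in ("grass", "pasture")}
            pool = sum(absorbers.values())
            if increment > pool + 1e-9:
                raise ValueError(
                    f"month {month}: grass+pasture ({pool:.3f} kg) cannot absorb "
                    f"napier substitution of {increment:.3f} kg")
            out = dict(offers)
            out["napier"] = target_napier
            if increment > 0 and pool > 0:
                for f, o in absorbers.items():
                    out[f] = o - increment * o / pool
            new_entries += [DietEntry(cohort, month, f, max(o, 0.0))
                            for f, o in out.items() if o > 1e-15 or f == "napier"]
    return Diet(new_entries)


def apply_concentrate(diet: Diet, spec: ScenarioSpec,
                      lactation_start_month: int = 11,
                      lactation_months: int = 12) -> Diet:
    """Co: add the bran/cake mix on top of cow offers.

    Supplementation follows the lactation (assumed to start with the
    rains, month 11): the early rate in the first three lactation
    months, the other-period rate in the remaining lactation months,
    none while dry.  Total DM increases by exactly the concentrate
    amount.
    """
    if spec.conc_early == 0 and spec.conc_other == 0:
        return Diet(list(diet.entries))
    lact = [(lactation_start_month - 1 + k) % 12 + 1
            for k in range(min(lactation_months, 12))]
    early = set(lact[:EARLY_LACTATION_MONTHS])
    add: dict[tuple, float] = {}
    cow_months = {e.month for e in diet.entries if e.cohort == "cow"}
    for month in cow_months:
        if month not in lact:
            continue
        rate = spec.conc_early if month in early else spec.conc_other
        for feed_id, frac in CONC_SPLIT.items():
            add[("cow", month, feed_id)] = rate * frac

    def mapper(e: DietEntry):
        return [e]

    base = diet._replaced(mapper)  # copy with merge semantics
    merged: dict[tuple, float] = {(e.cohort, e.month, e.feed_id): e.offer
                                  for e in base.entries}
    for key, extra in add.items():
        merged[key] = merged.get(key, 0.0) + extra
    return Diet([DietEntry(c, m, f, o) for (c, m, f), o in merged.items()])


def build_scenario_diet(base: Diet, spec: ScenarioSpec,
                        lactation_months: int = 12) -> Diet:
    """Compose the strategies named by ``spec`` in the order Cn -> Fo -> Co."""
    if spec.scenario_id != "Base" and spec.scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario_id {spec.scenario_id!r}")
    diet = base
    stages = spec.stages
    if "Cn" in stages:
        diet = apply_conservation(diet)
    if "Fo" in stages:
        diet = apply_forage(diet, spec.napier_share)
    if "Co" in stages:
        diet = apply_concentrate(diet, spec, lactation_months=lactation_months)
    return diet
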