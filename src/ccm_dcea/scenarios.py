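"""Scale-up strategies and national aggregation.

Three static strategies are compared: scaling treatment coverage to the
target in the most cost-effective regions (health maximization, ranked
by ascending ICER), in the regions with the highest reported under-five
mortality (equity), or everywhere (universal).  Non-selected regions
stay at their baseline coverage but keep contributing population weight
to the national aggregates, Gini coefficients, and weighted averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import math

import pandas as pd

from .cea import ScaleUpResult, assemble_scale_up, region_schedule
from .cohort import CohortResult, run_cohort
from .inequality import geographical_gini, pooled_interindividual_gini
from .types import FixedParams, RegionTable, ValidationError

STRATEGIES = ("health_max", "equity", "universal", "baseline")
DEFAULT_K = {"health_max": 5, "equity": 3}


@dataclass(frozen=True)
class ScenarioSpec:
    """One scale-up strategy.

    ``k`` is the number of regions selected: defaults to 5 for
    health_max and 3 for equity; ignored for universal (all regions) and
    baseline (none).
    """

    strategy: str
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValidationError(
                f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        k = self.k if self.k is not None else DEFAULT_K.get(self.strategy)
        object.__setattr__(self, "k", k)
        if self.strategy in ("health_max", "equity") and (self.k is None
                                                          or self.k < 1):
            raise ValidationError("k must be >= 1 for ranked strategies")


@dataclass(frozen=True)
class ScenarioResult:
    """National costs, effects, and inequality metrics of one scenario."""

    strategy: str
    selected_regions: Tuple[str, ...]
    total_incremental_cost: float
    weighted_le_gain: float
    national_u5mr_baseline: float   # per 1000
    national_u5mr_target: float     # per 1000
    deaths_averted: float
    cost_per_death_averted: float
    interindividual_gini: float
    geographical_gini: float


def rank_regions(table: RegionTable, key: str,
                 scale_ups: Optional[Mapping[str, ScaleUpResult]] = None
                 ) -> Tuple[str, ...]:
    """Order region names by a ranking key; ties break alphabetically.

    ``icer`` ranks ascending (most cost-effective first) and requires the
    per-region scale-up results; ``reported_u5mr`` ranks descending
    (worst-off first) and requires the reported survey U5MR.
    """
    if key == "icer":
        if scale_ups is None:
            raise ValidationError("icer ranking requires scale-up results")
        missing = [r.name for r in table if r.name not in scale_ups
                   or math.isnan(scale_ups[r.name].icer)]
        if missing:
            raise ValidationError(f"no ICER available for regions {missing}")
        return tuple(sorted(table.names,
                            key=lambda n: (scale_ups[n].icer, n)))
    if key == "reported_u5mr":
        missing = [r.name for r in table if r.reported_u5mr is None]
        if missing:
            raise ValidationError(
                f"reported_u5mr missing for regions {missing}")
        return tuple(sorted(table.names,
                            key=lambda n: (-table[n].reported_u5mr, n)))
    raise ValidationError(f"unknown ranking key {key!r}")


def _run_arms(table: RegionTable, reference_set, params: FixedParams,
              matching_source: str) -> Dict[str, Tuple[CohortResult, CohortResult]]:
    arms = {}
    for region in table:
        schedule = region_schedule(region, reference_set, matching_source)
        base = run_cohort(schedule, region, params, region.baseline_coverage)
        tgt = run_cohort(schedule, region, params, params.target_coverage)
        arms[region.name] = (base, tgt)
    return arms


def select_regions(spec: ScenarioSpec, table: RegionTable,
                   scale_ups: Optional[Mapping[str, ScaleUpResult]] = None
                   ) -> Tuple[str, ...]:
    if spec.strategy == "universal":
        return table.names
    if spec.strategy == "baseline":
        return ()
    if spec.strategy == "health_max":
        ranked = rank_regions(table, "icer", scale_ups)
    else:
        ranked = rank_regions(table, "reported_u5mr")
    if spec.k > len(table):
        raise ValidationError(
            f"k={spec.k} exceeds number of regions {len(table)}")
    return ranked[:spec.k]


def run_scenario(spec: ScenarioSpec, table: RegionTable, reference_set,
                 params: FixedParams, matching_source: str = "auto",
                 cost_table: Optional[pd.DataFrame] = None) -> ScenarioResult:
    """Evaluate one strategy over the whole country.

    Every region needs a birth-cohort weight.  If ``cost_table`` (a
    region/incremental_cost table, e.g. the published annual costs) is
    given, scenario costs are summed from it at full precision;
    otherwise they come from the cohort model's own discounted treatment
    costs.
    """
    missing = [r.name for r in table if r.birth_cohort is None]
    if missing:
        raise ValidationError(f"birth_cohort missing for regions {missing}")

    arms = _run_arms(table, reference_set, params, matching_source)
    scale_ups = {name: assemble_scale_up(table[name], base, tgt)
                 for name, (base, tgt) in arms.items()}
    selected = select_regions(spec, table, scale_ups)
    sel = set(selected)

    weights = [table[n].birth_cohort for n in table.names]
    total_births = sum(weights)
    chosen = {n: (arms[n][1] if n in sel else arms[n][0])
              for n in table.names}

    if cost_table is not None:
        costs = cost_table.set_index("region")["incremental_cost"]
        total_cost = float(sum(costs[n] for n in selected)) if selected else 0.0
    else:
        total_cost = sum(scale_ups[n].incremental_cost for n in selected)

    le_gain = sum(table[n].birth_cohort * scale_ups[n].incremental_le
                  for n in selected) / total_births
    u5_base = sum(w * arms[n][0].u5mr
                  for n, w in zip(table.names, weights)) / total_births
    u5_tgt = sum(w * chosen[n].u5mr
                 for n, w in zip(table.names, weights)) / total_births
    deaths_averted = sum(table[n].birth_cohort
                         * scale_ups[n].deaths_averted_per_child
                         for n in selected)
    cpda = total_cost / deaths_averted if deaths_averted > 0 else math.nan

    inter = pooled_interindividual_gini(
        [chosen[n] for n in table.names], weights)
    geo = geographical_gini(
        [chosen[n].life_expectancy for n in table.names], weights)

    return ScenarioResult(
        strategy=spec.strategy, selected_regions=tuple(selected),
        total_incremental_cost=total_cost, weighted_le_gain=le_gain,
        national_u5mr_baseline=u5_base * 1000.0,
        national_u5mr_target=u5_tgt * 1000.0,
        deaths_averted=deaths_averted, cost_per_death_averted=cpda,
        interindividual_gini=inter, geographical_gini=geo)


def compare_scenarios(results: Iterable[ScenarioResult]) -> pd.DataFrame:
    """Tabulate scenarios with deltas against the baseline row."""
    results = list(results)
    if len(results) < 2:
        raise ValidationError("need at least two scenarios incl. a baseline")
    baselines = [r for r in results if r.strategy == "baseline"]
    if not baselines:
        raise ValidationError("no baseline scenario provided")
    base = baselines[0]
    rows = []
    for r in results:
        rows.append({
            "strategy": r.strategy,
            "incremental_cost": r.total_incremental_cost,
            "cost_per_death_averted": r.cost_per_death_averted,
            "le_gain": r.weighted_le_gain,
            "deaths_averted": r.deaths_averted,
            "national_u5mr": r.national_u5mr_target,
            "interindividual_gini": r.interindividual_gini,
            "geographical_gini": r.geographical_gini,
            "d_interindividual_gini":
                r.interindividual_gini - base.interindividual_gini,
            "d_geographical_gini":
                r.geographical_gini - base.geographical_gini,
        })
    return pd.DataFrame(rows)
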