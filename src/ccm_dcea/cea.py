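"""Per-region scale-up economics: costs, incremental effects, ICERs.

Scaling a region from its baseline treatment coverage to the target
coverage is evaluated by running both arms of the cohort engine on the
region's matched mortality schedule and differencing the results.  The
incremental cost-effectiveness ratio (ICER) divides incremental cost by
incremental life years gained; both a discounted and an undiscounted
denominator are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .cohort import CohortResult, run_cohort, u5mr_from_rates
from .life_tables import (AbridgedLifeTable, apply_region_under5,
                          expand_to_annual, match_life_table)
from .types import FixedParams, RegionInputs, ValidationError


class DominationError(ValueError):
    """ICER undefined: no positive incremental effect."""


@dataclass(frozen=True)
class ScaleUpResult:
    """Economics of moving one region from baseline to target coverage."""

    region: str
    le_baseline: float
    le_target: float
    incremental_le: float
    incremental_discounted_ly: float
    u5mr_baseline: float
    u5mr_target: float
    deaths_averted_per_child: float
    cost_per_child_baseline: float
    cost_per_child_target: float
    total_cost_baseline: Optional[float]
    total_cost_target: Optional[float]
    incremental_cost: Optional[float]
    icer: float
    icer_undiscounted: float
    icer_note: str = ""


def cost_per_treatment(urban_fraction: float, params: FixedParams) -> float:
    """Regional average cost per treated episode from the urban share.

    cost = urban_unit_cost * x + urban_unit_cost * rural_multiplier * (1 - x)
    """
    if not (0.0 <= urban_fraction <= 1.0):
        raise ValidationError("urban_fraction must lie in [0, 1]")
    u = params.urban_unit_cost
    return u * urban_fraction + u * params.rural_multiplier * (1.0 - urban_fraction)


def icer(incremental_cost: float, incremental_effect: float) -> float:
    """Incremental cost per unit of incremental effect."""
    if incremental_effect == 0:
        raise DominationError("no incremental effect")
    if incremental_effect < 0:
        raise DominationError(
            "negative incremental effect: intervention is dominated")
    return incremental_cost / incremental_effect


def cost_effectiveness_flag(icer_value: float, params: FixedParams,
                            threshold_fraction: float = 0.5) -> bool:
    """Whether an ICER clears a GDP-fraction threshold (inclusive)."""
    if threshold_fraction <= 0:
        raise ValidationError("threshold_fraction must be > 0")
    return icer_value <= threshold_fraction * params.gdp_per_capita


def region_schedule(region: RegionInputs,
                    reference_set: Iterable[AbridgedLifeTable],
                    matching_source: str = "auto"):
    """Match, expand, and override a mortality schedule for one region.

    ``matching_source`` selects the U5MR used for life-table matching:
    "reported" (survey estimate), "derived" (from the region's own
    q_infant/q_child), or "auto" (reported when available).
    """
    if matching_source == "reported":
        if region.reported_u5mr is None:
            raise ValidationError(
                f"region {region.name!r} has no reported_u5mr")
        u5 = region.reported_u5mr
    elif matching_source == "derived":
        u5 = u5mr_from_rates(region.q_infant, region.q_child)
    elif matching_source == "auto":
        u5 = (region.reported_u5mr if region.reported_u5mr is not None
              else u5mr_from_rates(region.q_infant, region.q_child))
    else:
        raise ValueError(f"unknown matching_source {matching_source!r}")
    table = match_life_table(u5, reference_set)
    return apply_region_under5(expand_to_annual(table), region)


def scale_up_region(region: RegionInputs,
                    reference_set: Iterable[AbridgedLifeTable],
                    params: FixedParams,
                    matching_source: str = "auto") -> ScaleUpResult:
    """Run both arms for one region and assemble the economics.

    Totals (cost x birth cohort) are populated only when the region
    carries a birth-cohort weight.
    """
    target = params.target_coverage
    if target < region.baseline_coverage:
        raise ValidationError(
            f"region {region.name!r}: target coverage {target} below "
            f"baseline {region.baseline_coverage}; decremental scale-up "
            "unsupported")
    schedule = region_schedule(region, reference_set, matching_source)
    base = run_cohort(schedule, region, params, region.baseline_coverage)
    tgt = run_cohort(schedule, region, params, target)
    return assemble_scale_up(region, base, tgt)


def assemble_scale_up(region: RegionInputs, base: CohortResult,
                      tgt: CohortResult) -> ScaleUpResult:
    d_le = tgt.life_expectancy - base.life_expectancy
    d_dly = tgt.discounted_life_years - base.discounted_life_years
    d_cost = tgt.treatment_cost_per_child - base.treatment_cost_per_child

    note = ""
    if tgt.coverage == base.coverage:
        icer_d = icer_u = math.nan
        note = "no scale-up"
    elif d_dly <= 0 or d_le <= 0:
        icer_d = icer_u = math.nan
        note = "dominated" if d_cost > 0 else "no incremental effect"
    else:
        icer_d = d_cost / d_dly
        icer_u = d_cost / d_le

    n = region.birth_cohort
    totals = (None, None, None) if n is None else (
        base.treatment_cost_per_child * n,
        tgt.treatment_cost_per_child * n,
        d_cost * n,
    )
    return ScaleUpResult(
        region=region.name,
        le_baseline=base.life_expectancy, le_target=tgt.life_expectancy,
        incremental_le=d_le, incremental_discounted_ly=d_dly,
        u5mr_baseline=base.u5mr, u5mr_target=tgt.u5mr,
        deaths_averted_per_child=base.u5mr - tgt.u5mr,
        cost_per_child_baseline=base.treatment_cost_per_child,
        cost_per_child_target=tgt.treatment_cost_per_child,
        total_cost_baseline=totals[0], total_cost_target=totals[1],
        incremental_cost=totals[2],
        icer=icer_d, icer_undiscounted=icer_u, icer_note=note)
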