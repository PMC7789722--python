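"""Two-arm Markov cohort engine.

A birth cohort is followed through 120 annual cycles until extinction.
Each cycle the cohort splits between "alive and well" and "dead"; each
completed cycle alive counts one life year.  Community-based pneumonia
treatment acts only during the first ``intervention_ages`` cycles
(ages 0-4): raising treatment coverage removes the pneumonia deaths a
higher coverage would avert, at ``incidence * CFR * efficacy * dcoverage``
per child-year.  Background mortality is all-cause mortality observed at
the baseline coverage, so running the engine at baseline coverage
reproduces the input schedule exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .life_tables import (MAX_AGE, AnnualMortalitySchedule,
                          survival_from_schedule)
from .types import FixedParams, RegionInputs, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortResult:
    """Outputs of one cohort run at a given treatment coverage.

    ``survival`` is S(a) for a = 0..120; ``deaths_by_age`` the mass dying
    within cycle a (sums to 1); ``life_expectancy`` is undiscounted and
    half-cycle corrected when enabled; ``discounted_life_years`` applies
    the effect discount rate; ``treatment_cost_per_child`` is the
    discounted expected treatment spend per live birth.
    """

    survival: np.ndarray
    life_expectancy: float
    discounted_life_years: float
    u5mr: float
    deaths_by_age: np.ndarray
    treatment_cost_per_child: float
    coverage: float


def incidence_from_prevalence(prevalence: float, duration_days: float) -> float:
    """Annual episode incidence from point prevalence and episode duration.

    incidence = prevalence * 365 / duration_days
    """
    if duration_days <= 0:
        raise ValidationError("duration_days must be > 0")
    if not (0.0 <= prevalence <= 1.0):
        raise ValidationError("prevalence must lie in [0, 1]")
    return prevalence * 365.0 / duration_days


def u5mr_from_rates(q_infant: float, q_child: float) -> float:
    """Under-five mortality implied by infant and annual child mortality."""
    for v, n in ((q_infant, "q_infant"), (q_child, "q_child")):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{n} must lie in [0, 1]")
    return 1.0 - (1.0 - q_infant) * (1.0 - q_child) ** 4


def pneumonia_decomposition(q_allcause: float, region: RegionInputs,
                            params: FixedParams) -> tuple:
    """Split an all-cause annual death probability into non-pneumonia and
    pneumonia components at the region's baseline coverage.

    The pneumonia share at baseline is
    ``incidence * CFR * (1 - efficacy * baseline_coverage)``; the
    remainder is attributed to other causes, clamped at zero (with a
    warning) if the pneumonia share alone exceeds the all-cause input.
    """
    if not (0.0 <= q_allcause <= 1.0):
        raise ValidationError("q_allcause must lie in [0, 1]")
    q_pneu = (region.incidence * params.cfr_untreated
              * (1.0 - params.efficacy * region.baseline_coverage))
    q_nonpneu = q_allcause - q_pneu
    if q_nonpneu < 0:
        logger.warning(
            "region %s: baseline pneumonia mortality %.6f exceeds all-cause "
            "%.6f; non-pneumonia component clamped to 0",
            region.name, q_pneu, q_allcause)
        q_nonpneu = 0.0
    return q_nonpneu, q_pneu


def mortality_at_coverage(schedule: AnnualMortalitySchedule,
                          region: RegionInputs, params: FixedParams,
                          coverage: float) -> AnnualMortalitySchedule:
    """All-cause schedule after moving treatment coverage from baseline.

    For intervention ages, mortality shifts by
    ``-incidence * CFR * efficacy * (coverage - baseline)``; the delta
    form keeps the baseline-coverage run bit-identical to the input.
    Results are clamped to [0, 1] with a warning.
    """
    if not (0.0 <= coverage <= 1.0):
        raise ValidationError(f"coverage={coverage} must lie in [0, 1]")
    q = schedule.q.copy()
    n = params.intervention_ages
    delta = (region.incidence * params.cfr_untreated * params.efficacy
             * (coverage - region.baseline_coverage))
    p_base = (region.incidence * params.cfr_untreated
              * (1.0 - params.efficacy * region.baseline_coverage))
    p_cov = (region.incidence * params.cfr_untreated
             * (1.0 - params.efficacy * coverage))
    for a in range(n):
        if q[a] < p_base:
            # all-cause below the implied pneumonia floor: rebuild from the
            # clamped decomposition instead of shifting
            logger.warning(
                "region %s age %d: all-cause q %.6f below baseline pneumonia "
                "mortality %.6f; clamped", region.name, a, q[a], p_base)
            q[a] = min(1.0, p_cov)
        else:
            q[a] = min(1.0, max(0.0, q[a] - delta))
    return AnnualMortalitySchedule(q)


def run_cohort(schedule: AnnualMortalitySchedule, region: RegionInputs,
               params: FixedParams, coverage: float) -> CohortResult:
    """Run one arm of the cohort model at the given treatment coverage."""
    adjusted = mortality_at_coverage(schedule, region, params, coverage)
    s = survival_from_schedule(adjusted)

    ages = np.arange(1, MAX_AGE + 1)
    le = float(s[1:].sum())
    dly = float((s[1:] * (1.0 + params.discount_effects) ** (-ages)).sum())
    if params.half_cycle_correction:
        # half a cycle credited at time zero, hence undiscounted
        le += 0.5
        dly += 0.5

    deaths = s[:-1] - s[1:]
    u5 = 1.0 - s[5]

    n = params.intervention_ages
    disc = (1.0 + params.discount_costs) ** (-np.arange(n))
    cost = float((s[:n] * disc).sum()
                 * region.incidence * coverage * region.cost_per_treatment)

    return CohortResult(survival=s, life_expectancy=le,
                        discounted_life_years=dly, u5mr=u5,
                        deaths_by_age=deaths,
                        treatment_cost_per_child=cost, coverage=coverage)
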