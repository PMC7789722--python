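"""Built-in inputs for the Ethiopian base-case analysis.

These are the published 2016 region-specific inputs for the eleven major
regions: DHS-derived infant/child mortality and baseline treatment
coverage, pneumonia incidence (prevalence / 4.6-day mean episode
duration), and rural-residency-adjusted cost per treatment.  Two cells in
the source table run incidence and coverage together; they are parsed as
Harari incidence 0.044 with 45% coverage and Addis incidence 0.153 with
59% coverage, the only split in which every column stays inside its
observed range (incidence 0.04-0.46 episodes/child-year, coverage
25-60%) and Addis keeps the fully urban 45 USD unit cost.

Regional birth-cohort sizes were not published; the values here are
synthetic estimates built from 2016 regional population projections and
DHS total fertility rates (births ~ population x 7 x TFR / 1000, summing
to ~3.1 million nationally).  Reported under-five mortality is the DHS
2016 survey estimate per region, which drives the equity ranking; it is
deliberately not recomputed from the infant/child rates above.
"""

from __future__ import annotations

from typing import Tuple

import pandas as pd

from .types import FixedParams, RegionInputs, RegionTable

# region: (IMR/1000, child q/1000, cost USD, incidence, coverage %,
#          DHS U5MR/1000, synthetic birth-cohort estimate)
_REGION_ROWS = {
    "Afar":         (76.7, 11.5, 247.8, 0.244, 44.0, 125.0, 68_100),
    "Beni-Shangul": (60.2,  9.2, 271.3, 0.102, 29.0,  98.0, 31_900),
    "Somali":       (50.5,  4.3, 271.3, 0.119, 32.0,  94.0, 285_700),
    "Dire Dawa":    (16.4,  1.7, 124.8, 0.221, 50.0,  93.0, 10_100),
    "Gambela":      (60.2,  9.2, 124.8, 0.198, 29.0,  88.0, 10_700),
    "SNNP":         (64.9,  7.0, 288.0, 0.385, 43.0,  88.0, 590_400),
    "Amhara":       (57.3,  4.1, 277.7, 0.453, 29.0,  85.0, 547_400),
    "Oromia":       (56.6,  3.9, 281.6, 0.419, 26.4,  79.0, 1_340_700),
    "Harari":       (52.9,  7.8, 163.9, 0.044, 45.0,  72.0, 5_900),
    "Tigray":       (57.8,  5.6, 255.1, 0.436, 34.0,  59.0, 169_500),
    "Addis":        (30.0,  5.0,  45.0, 0.153, 59.0,  39.0, 42_200),
}

# published total annual treatment costs (USD) at baseline and 90% target
# coverage, and their difference, per region
_COST_ROWS = {
    "Addis":        (1_200_000, 1_900_000, 600_000),
    "Tigray":       (32_100_000, 86_000_000, 54_000_000),
    "Harari":       (200_000, 400_000, 200_000),
    "Amhara":       (138_400_000, 434_100_000, 295_700_000),
    "Dire Dawa":    (1_100_000, 1_900_000, 900_000),
    "Gambela":      (500_000, 1_600_000, 1_000_000),
    "Somali":       (21_000_000, 59_000_000, 38_200_000),
    "Beni-Shangul": (1_800_000, 5_600_000, 3_900_000),
    "Oromia":       (273_000_000, 943_000_000, 669_000_000),
    "SNNP":         (219_500_000, 463_500_000, 244_000_000),
    "Afar":         (12_000_000, 24_700_000, 12_700_000),
}


def ethiopia_fixture(include_birth_cohorts: bool = True
                     ) -> Tuple[RegionTable, FixedParams, pd.DataFrame]:
    """The eleven-region base case: inputs, constants, and published costs.

    Returns ``(regions, params, cost_table)`` where ``cost_table`` holds
    the published total/incremental annual treatment costs per region.
    Set ``include_birth_cohorts=False`` to leave the (synthetic
    estimate) birth-cohort column empty for user-supplied weights.
    """
    regions = []
    for name, (imr, cmr, cost, inc, cov_pct, u5mr, births) in _REGION_ROWS.items():
        regions.append(RegionInputs(
            name=name,
            q_infant=imr / 1000.0,
            q_child=cmr / 1000.0,
            cost_per_treatment=cost,
            incidence=inc,
            baseline_coverage=cov_pct / 100.0,
            birth_cohort=float(births) if include_birth_cohorts else None,
            reported_u5mr=u5mr / 1000.0,
            urban_fraction=1.0 if name == "Addis" else None,
        ))
    cost_table = pd.DataFrame(
        [{"region": n, "total_cost_baseline": b, "total_cost_target": t,
          "incremental_cost": i} for n, (b, t, i) in _COST_ROWS.items()])
    return RegionTable(tuple(regions)), FixedParams(), cost_table


def national_inputs() -> RegionInputs:
    """The published national-average row (kept apart from the 11 regions)."""
    return RegionInputs(
        name="National", q_infant=0.0485, q_child=0.0051,
        cost_per_treatment=262.1, incidence=0.397, baseline_coverage=0.33,
        reported_u5mr=0.067)
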