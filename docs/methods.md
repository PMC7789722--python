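# Methods

## Cohort model

Each region is modelled as a deterministic Markov cohort with two states,
alive and dead, over 120 annual cycles starting at birth; by construction
the final cycle closes the cohort (the last annual death probability is
forced to 1), so death masses sum to one and life expectancy equals the sum
of the survival curve. Each completed cycle alive counts one life year;
with the half-cycle correction on (default), a flat, undiscounted 0.5 years
is added to both the undiscounted and the discounted life-year totals,
crediting the half cycle lived on average in the cycle of death.

Background mortality is interpreted as **all-cause mortality observed at
the baseline treatment coverage**. Raising coverage c from its baseline c₀
removes the pneumonia deaths the additional treatment averts:

    q'(a) = q(a) − λ·CFR·e·(c − c₀)   for intervention ages a = 0…4,

with λ the annual pneumonia incidence, CFR = 0.0351 the untreated case
fatality rate and e = 0.70 the proportional CFR reduction under treatment.
This delta form makes the baseline arm bit-identical to the input schedule
and mortality strictly decreasing in coverage whenever λ·e > 0. The
interpretation matters: the alternative — treating the published rates as
pneumonia-free background and adding pneumonia deaths on top — would
inflate baseline under-five mortality well above the observed survey
values.

**Degenerate inputs.** In several regions the published child mortality
(ages 1–4) is *below* the pneumonia mortality implied by λ·CFR·(1−e·c₀)
alone — the all-cause decomposition is infeasible. There the non-pneumonia
component is clamped to zero with a logged warning and the adjusted
mortality becomes λ·CFR·(1−e·c), the pure pneumonia floor. This keeps the
coverage response strictly monotone but means the baseline arm in those
regions runs slightly above the printed child-mortality inputs; it is the
price of keeping the intervention effect at full strength for all five
intervention years, which is what the published per-region life-expectancy
gains imply.

Repeat episodes are handled linearly (expected episodes per child-year =
λ); no within-year competing-risk correction is applied, since λ·CFR
products are below 0.02 and the quadratic terms are far below the reported
precision. No morbidity states or disability weights are modelled — effects
are purely mortality-driven.

## Life tables

Mortality above age five comes from a reference abridged life table chosen
by nearest U5MR (ties broken toward the lower-U5MR table, making matching
deterministic and order-independent). Closed intervals of width n are
expanded to constant annual probabilities q = 1 − (1 − nqx)^(1/n)
(constant hazard — the standard abridged-to-single-year convention, exactly
invertible); the open terminal interval carries the last closed interval's
annual q forward. Matching can use either the externally reported
(survey) U5MR or the U5MR implied by the region's own rates
(`matching_source`); the default prefers the reported value when present.

The built-in synthetic reference family applies hazard-power transforms
nqx′ = 1 − (1 − nqx)^f (f ∈ {0.4 … 1.8}) to a schematic high-mortality base
table, spanning U5MRs from about 30 to 127 per 1000 so that every region
matches an interior table. The family preserves the *shape* of the base
table's age profile; real historical life tables also shift their
child-versus-adult mortality balance over time, so absolute life
expectancies (and hence ICER levels) computed with the synthetic family are
indicative only. The regional orderings and directions reported by the test
suite are robust to this; calibrated levels require user-supplied
historical abridged tables.

## Costs and ICERs

Treatment costs accrue at cycle start among those alive, for the five
intervention ages, at λ·c·(unit cost) per child-year, discounted at 3%.
The regional unit cost is 45·x + 324·(1−x) USD for urban share x (rural
delivery costed at 7.2× urban). Training and capital costs are excluded.
Two ICERs are reported: the headline uses life years discounted at 3% (the
stated base case); the undiscounted ICER is also exposed because the
published per-region ratios are numerically consistent with undiscounted
denominators. Cost-effectiveness is flagged against a threshold of a
configurable fraction (default 50%, inclusive) of GDP per capita (713 USD).

## Inequality metrics

The weighted Gini G = ΣᵢΣⱼ wᵢwⱼ|xᵢ−xⱼ| / (2W²μ) is computed by the sorted
O(n log n) cumulative form (verified against the O(n²) double sum to
1e−12). No small-sample correction is applied: weights are population
masses, not samples. Interindividual inequality uses ages at death credited
at cycle midpoints (a + 0.5), which keeps the mean age at death equal to
the half-cycle-corrected life expectancy; the national value pools the
birth-cohort-weighted deaths-by-age of all regions. Geographical inequality
is the Gini of regional life expectancies weighted by births. Perfectly
equal distributions return exactly 0 (guarded against cancellation error).

## Scenarios

Health-max selects the k = 5 regions with the lowest ICERs (the published
description names five regions, and their printed incremental costs sum to
within rounding of the printed scenario cost; k is configurable). Equity
selects the k = 3 regions with the highest *reported* U5MR — deliberately
the survey estimate, not the value recomputed from the infant/child inputs,
because only the survey ranking yields the published selection (Afar,
Beni-Shangul, Somali). Universal selects all regions. Non-selected regions
stay at baseline coverage but keep their population weight in national
aggregates. Ranking ties break alphabetically. Scenario costs can be summed
either from the cohort model or, at full precision, from the published
annual cost table; the published table's own SUM row (1,321.0M USD)
differs from the sum of its printed rows (1,320.2M) by rounding, and the
full-precision sum is the one reported.

## Inputs the source does not provide

Regional birth-cohort sizes were not published. The built-in fixture ships
synthetic estimates derived from 2016 regional population projections and
survey total fertility rates (births ≈ population × 7·TFR/1000), totalling
≈3.1 million — consistent in magnitude with the reported national deaths
averted. They are clearly marked as estimates and can be replaced or left
unset (`include_birth_cohorts=False`). Reported regional U5MRs are the 2016
survey estimates. Regional urban shares were not published either; the
fixture stores the printed per-treatment costs directly and leaves
`urban_fraction` empty except for fully urban Addis.

## Synthetic region generator

`synthetic_regions` draws uniform values over the observed input ranges
(incidence 0.04–0.46 episodes/child-year, coverage 25–60%, infant mortality
16–77 per 1000, child mortality 1.7–11.5 per 1000), derives each region's
cost from its drawn urban share via the unit-cost model (making the cost
parameters exactly recoverable), and sets the reported U5MR to the value
implied by the drawn rates so equity rankings are self-consistent. It
emulates the *marginal* ranges of real regional data, not their
correlations (e.g. the empirical association between low coverage and high
incidence), so synthetic results exercise the pipeline's mechanics rather
than reproduce realistic joint distributions.

## Numerical choices and problem sizes

All computations are double precision and fully deterministic; the only
randomness is the synthetic generator's seeded PRNG. Engine outputs match
geometric/annuity closed forms on constant-mortality schedules to 1e−9, and
mass conservation holds to 1e−9. The test suite and the acceptance script
each run the full eleven-region pipeline (121-point survival curves, four
scenarios) in seconds on one CPU; no down-scaling is needed.

## Known limitations

- Absolute life expectancies and ICER levels depend on the reference
  life-table set; the synthetic family reproduces patterns, not levels.
- The all-cause/clamping convention slightly inflates baseline under-five
  mortality in regions with infeasible decompositions (see above).
- Costs are provider-perspective treatment costs only: no demand
  generation, training or capital costs, and no uncertainty analysis
  (deterministic expectations throughout).
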