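"""Core domain types for the regional cost-effectiveness pipeline.

The analysis is parameterised by two kinds of inputs: per-region
epidemiology/cost/coverage rows (``RegionInputs``, collected in a
``RegionTable``) and global model constants (``FixedParams``).  All
probabilities and proportions are stored per 1 internally; readers are
responsible for converting per-1000 mortality and percent coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Optional, Sequence


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


def _check_prob(value: float, name: str, context: str = "") -> None:
    if not (0.0 <= value <= 1.0):
        where = f" in {context}" if context else ""
        raise ValidationError(f"{name}={value!r}{where} must lie in [0, 1]")


def _check_nonneg(value: float, name: str, context: str = "") -> None:
    if value < 0:
        where = f" in {context}" if context else ""
        raise ValidationError(f"{name}={value!r}{where} must be >= 0")


@dataclass(frozen=True)
class RegionInputs:
    """One region's model inputs.

    Parameters
    ----------
    name:
        Region name; must be nonempty and unique within a table.
    q_infant:
        Annual probability of death before age one (per 1).
    q_child:
        Annual probability of death at each of ages 1-4 (per 1).
    cost_per_treatment:
        USD per treated pneumonia episode.
    incidence:
        Pneumonia episodes per child-year among under-fives.
    baseline_coverage:
        Proportion of episodes treated before scale-up, in [0, 1].
    birth_cohort:
        Number of live births used as the population weight; optional for
        per-child quantities, required for totals and Gini weights.
    reported_u5mr:
        Optional externally reported under-five mortality per 1 (survey
        estimate); used for equity ranking and life-table matching.  Kept
        separate from the value implied by ``q_infant``/``q_child``.
    urban_fraction:
        Optional proportion of the population with urban residency.
    """

    name: str
    q_infant: float
    q_child: float
    cost_per_treatment: float
    incidence: float
    baseline_coverage: float
    birth_cohort: Optional[float] = None
    reported_u5mr: Optional[float] = None
    urban_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("region name must be nonempty")
        ctx = f"region {self.name!r}"
        _check_prob(self.q_infant, "q_infant", ctx)
        _check_prob(self.q_child, "q_child", ctx)
        _check_prob(self.baseline_coverage, "baseline_coverage", ctx)
        _check_nonneg(self.cost_per_treatment, "cost_per_treatment", ctx)
        _check_nonneg(self.incidence, "incidence", ctx)
        if self.birth_cohort is not None and not self.birth_cohort > 0:
            raise ValidationError(f"birth_cohort in {ctx} must be > 0")
        if self.reported_u5mr is not None:
            _check_prob(self.reported_u5mr, "reported_u5mr", ctx)
        if self.urban_fraction is not None:
            _check_prob(self.urban_fraction, "urban_fraction", ctx)

    def with_(self, **kwargs) -> "RegionInputs":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FixedParams:
    """Global model constants shared by every region.

    Defaults are the published base case: an untreated case fatality rate
    of 3.51% per episode, a 70% proportional CFR reduction under treatment,
    annual cycles over a 120-year horizon with the intervention active in
    the first five cycles (ages 0-4), 3% discounting of both costs and
    effects, a 90% target coverage, and the urban/rural unit-cost model
    (45 USD urban, 7.2x in rural settings).
    """

    cfr_untreated: float = 0.0351
    efficacy: float = 0.70
    cycles: int = 120
    discount_costs: float = 0.03
    discount_effects: float = 0.03
    target_coverage: float = 0.90
    duration_days: float = 4.6
    urban_unit_cost: float = 45.0
    rural_multiplier: float = 7.2
    gdp_per_capita: float = 713.0
    intervention_ages: int = 5
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        _check_prob(self.cfr_untreated, "cfr_untreated")
        _check_prob(self.efficacy, "efficacy")
        _check_prob(self.target_coverage, "target_coverage")
        for name in ("discount_costs", "discount_effects", "duration_days",
                     "urban_unit_cost", "rural_multiplier", "gdp_per_capita"):
            _check_nonneg(getattr(self, name), name)
        if self.cycles < self.intervention_ages:
            raise ValidationError(
                f"cycles={self.cycles} must be >= intervention_ages="
                f"{self.intervention_ages}")
        if self.intervention_ages < 0:
            raise ValidationError("intervention_ages must be >= 0")

    @classmethod
    def field_names(cls) -> Sequence[str]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class RegionTable:
    """Ordered, name-unique collection of :class:`RegionInputs`."""

    regions: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        regions = tuple(self.regions)
        object.__setattr__(self, "regions", regions)
        if not regions:
            raise ValidationError("no regions")
        names = [r.name for r in regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate region names: {sorted(dupes)}")

    def __iter__(self) -> Iterator[RegionInputs]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.regions:
                if r.name == key:
                    return r
            raise KeyError(key)
        return self.regions[key]

    @property
    def names(self) -> tuple:
        return tuple(r.name for r in self.regions)
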