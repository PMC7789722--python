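"""Abridged life tables and single-year mortality schedules.

Regional all-cause mortality above age five is proxied by a reference
abridged life table (e.g. a national table from a period with similar
under-five mortality).  The abridged intervals are expanded to
single-year probabilities under a constant-hazard assumption, the
region's own infant and child mortality overrides ages 0-4, and the
cohort is closed by forcing death in the final cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import RegionInputs, ValidationError

MAX_AGE = 120


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Mortality probabilities over age intervals (0, 1-4, 5-9, ...).

    ``intervals`` are ``(start_age, width)`` pairs, contiguous from age 0;
    the last interval is open-ended (width is nominal) and its ``nqx``
    must be 1.
    """

    label: str
    intervals: Tuple[Tuple[float, float], ...]
    nqx: Tuple[float, ...]

    def __post_init__(self) -> None:
        intervals = tuple((float(s), float(w)) for s, w in self.intervals)
        nqx = tuple(float(q) for q in self.nqx)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "nqx", nqx)
        if len(intervals) != len(nqx) or not intervals:
            raise ValidationError("intervals and nqx must align and be nonempty")
        if intervals[0][0] != 0:
            raise ValidationError("intervals must start at age 0")
        for (s0, w0), (s1, _w1) in zip(intervals, intervals[1:]):
            if s0 + w0 != s1:
                raise ValidationError(
                    f"intervals must be contiguous: {s0}+{w0} != {s1}")
        for q in nqx:
            if not (0.0 <= q <= 1.0):
                raise ValidationError(f"nqx={q} outside [0, 1]")
        if nqx[-1] != 1.0:
            raise ValidationError("terminal (open-ended) nqx must be 1")

    @property
    def terminal_start(self) -> float:
        return self.intervals[-1][0]


@dataclass(frozen=True)
class AnnualMortalitySchedule:
    """Annual death probabilities q(a) for single years of age 0..119."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.shape != (MAX_AGE,):
            raise ValidationError(f"schedule must have length {MAX_AGE}")
        if np.any((q < 0) | (q > 1)):
            raise ValidationError("annual q outside [0, 1]")
        if q[MAX_AGE - 1] != 1.0:
            raise ValidationError("q at the final age must be 1 (cohort closes)")


def _annualize(nqx: float, width: float) -> float:
    # constant hazard within the interval: exactly invertible
    return 1.0 - (1.0 - nqx) ** (1.0 / width)


def table_u5mr(table: AbridgedLifeTable) -> float:
    """Probability of death before age five implied by the abridged table.

    Intervals fully inside [0, 5) contribute their nqx directly; an
    interval straddling age 5 contributes its constant-hazard annualized
    probability for the covered years.
    """
    surv = 1.0
    covered = 0.0
    # only closed intervals carry age-specific information
    for (start, width), q in zip(table.intervals[:-1], table.nqx[:-1]):
        if start >= 5:
            break
        if start + width <= 5:
            surv *= 1.0 - q
            covered = start + width
        else:
            years = 5 - start
            surv *= (1.0 - _annualize(q, width)) ** years
            covered = 5.0
    if covered < 5:
        raise ValidationError(
            f"life table {table.label!r} does not cover ages 0-5")
    return 1.0 - surv


def match_life_table(u5mr: float,
                     reference_set: Iterable[AbridgedLifeTable]
                     ) -> AbridgedLifeTable:
    """Pick the reference table whose U5MR is closest to ``u5mr``.

    Ties are broken toward the lower-U5MR table, so the result does not
    depend on the iteration order of the reference set.
    """
    tables = list(reference_set)
    if not tables:
        raise ValidationError("empty reference set")
    return min(tables, key=lambda t: (abs(table_u5mr(t) - u5mr),
                                      table_u5mr(t)))


def expand_to_annual(table: AbridgedLifeTable,
                     max_age: int = MAX_AGE) -> AnnualMortalitySchedule:
    """Expand an abridged table into single-year probabilities to ``max_age``.

    Each closed interval of width n maps to a constant annual
    q = 1 - (1 - nqx)^(1/n); ages in the open terminal interval carry the
    last closed interval's annual q forward, and the final age is forced
    to q = 1 so that the cohort is extinct by ``max_age``.
    """
    q = np.zeros(max_age)
    last_annual = 0.0
    for (start, width), nqx in zip(table.intervals[:-1], table.nqx[:-1]):
        annual = _annualize(nqx, width)
        lo, hi = int(start), min(int(start + width), max_age)
        q[lo:hi] = annual
        last_annual = annual
    lo = min(int(table.terminal_start), max_age)
    q[lo:] = last_annual
    q[max_age - 1] = 1.0
    return AnnualMortalitySchedule(q)


def apply_region_under5(schedule: AnnualMortalitySchedule,
                        region: RegionInputs) -> AnnualMortalitySchedule:
    """Override ages 0-4 with the region's own infant/child mortality."""
    q = schedule.q.copy()
    q[0] = region.q_infant
    q[1:5] = region.q_child
    return AnnualMortalitySchedule(q)


def survival_from_schedule(schedule: AnnualMortalitySchedule) -> np.ndarray:
    """Cumulative survival S(a), a = 0..120, with S(0) = 1 and S(120) = 0."""
    s = np.empty(MAX_AGE + 1)
    s[0] = 1.0
    s[1:] = np.cumprod(1.0 - schedule.q)
    return s


def read_life_table(path: Union[str, Path]) -> AbridgedLifeTable:
    """Read one abridged table from a label,start_age,width,nqx CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"label", "start_age", "width", "nqx"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: empty life table")
    df = df.sort_values("start_age")
    return AbridgedLifeTable(
        label=str(df["label"].iloc[0]),
        intervals=tuple(zip(df["start_age"], df["width"])),
        nqx=tuple(df["nqx"]),
    )


def write_life_table(table: AbridgedLifeTable, path: Union[str, Path]) -> None:
    rows = [{"label": table.label, "start_age": s, "width": w, "nqx": q}
            for (s, w), q in zip(table.intervals, table.nqx)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_reference_set(directory: Union[str, Path]
                       ) -> Sequence[AbridgedLifeTable]:
    """Read every ``*.csv`` abridged table in a directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"reference set not found: {directory}")
    tables = [read_life_table(p) for p in sorted(directory.glob("*.csv"))]
    if not tables:
        raise ValidationError(f"no life tables in {directory}")
    return tables
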