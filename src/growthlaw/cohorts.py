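"""Year-class bookkeeping: year×age tables, cohort series, increment pairs.

Survey working groups publish mean length at age as a matrix with one row per
observation year and one column per age class. A cohort (year-class) born in
year ``b`` appears on the diagonal: it has age ``a`` in year ``b + a``.
Extracting those diagonals gives each cohort's length-at-age series, and
consecutive ages give the ``(L_a, dL_a)`` pairs — with
``dL_a = L_(a+1) - L_a`` — that the growth law is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InsufficientDataError


@dataclass
class AgeLengthTable:
    """Mean length per (year, age), with optional abundances.

    ``lengths[i, j]`` is the mean length in ``years[i]`` of fish aged
    ``ages[j]``; missing cells are NaN. ``abundance``, when present, has the
    same shape (counts per cell).
    """

    years: np.ndarray
    ages: np.ndarray
    lengths: np.ndarray
    abundance: np.ndarray | None = None
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.ages = np.asarray(self.ages, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.shape != (self.years.size, self.ages.size):
            raise DomainError(
                f"lengths shape {self.lengths.shape} does not match "
                f"{self.years.size} years x {self.ages.size} ages"
            )
        if self.years.size > 1 and not np.all(np.diff(self.years) > 0):
            raise DomainError("years must be strictly increasing")
        if not np.all(np.diff(self.ages) == 1):
            raise DomainError("ages must be contiguous increasing integers")
        present = ~np.isnan(self.lengths)
        if np.any(self.lengths[present] <= 0):
            raise DomainError("all present lengths must be > 0")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=float)
            if self.abundance.shape != self.lengths.shape:
                raise DomainError("abundance shape must match lengths shape")


@dataclass
class CohortSeries:
    """One year-class's length-at-age sequence (possibly with age gaps)."""

    birth_year: int
    ages: np.ndarray
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.ages.size != self.lengths.size:
            raise DomainError("ages and lengths must align")
        if self.ages.size > 1 and not np.all(np.diff(self.ages) > 0):
            raise DomainError("ages must be strictly increasing (no duplicates)")


@dataclass
class IncrementSet:
    """``(L_a, dL_a)`` pairs with provenance, the fitting substrate.

    ``birth_year`` is None for pooled/averaged sets that no longer belong to a
    single cohort. Negative observed increments are retained (legitimate
    survey noise around the line) and exposed via :attr:`negative_mask`.
    """

    L: np.ndarray
    dL: np.ndarray
    age: np.ndarray | None = None
    birth_year: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.dL = np.asarray(self.dL, dtype=float)
        if self.L.shape != self.dL.shape:
            raise DomainError("L and dL must have the same shape")
        for name in ("age", "birth_year"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=int)
                if v.shape != self.L.shape:
                    raise DomainError(f"{name} must align with L")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.L.size

    @property
    def negative_mask(self) -> np.ndarray:
        return self.dL < 0

    def subset(self, mask: np.ndarray) -> "IncrementSet":
        return IncrementSet(
            L=self.L[mask],
            dL=self.dL[mask],
            age=None if self.age is None else self.age[mask],
            birth_year=None if self.birth_year is None else self.birth_year[mask],
        )

    @staticmethod
    def concatenate(sets: list["IncrementSet"]) -> "IncrementSet":
        have_age = all(s.age is not None for s in sets)
        have_by = all(s.birth_year is not None for s in sets)
        return IncrementSet(
            L=np.concatenate([s.L for s in sets]),
            dL=np.concatenate([s.dL for s in sets]),
            age=np.concatenate([s.age for s in sets]) if have_age else None,
            birth_year=np.concatenate([s.birth_year for s in sets]) if have_by else None,
        )


def extract_cohorts(table: AgeLengthTable) -> list[CohortSeries]:
    """Read each year-class off the table's diagonal.

    The cohort born in year ``b`` has age ``a`` in observation year ``b + a``.
    Cohorts with fewer than two present cells are dropped (no increment can
    ever be formed from one point); two present but non-consecutive ages are
    kept — the series is simply gappy.
    """
    if table.years.size < 2 or table.ages.size < 2:
        raise InsufficientDataError(
            "need at least 2 years and 2 ages to form any cohort increment"
        )
    year_index = {int(y): i for i, y in enumerate(table.years)}
    births = range(
        int(table.years.min()) - int(table.ages.max()),
        int(table.years.max()) - int(table.ages.min()) + 1,
    )
    out: list[CohortSeries] = []
    for b in births:
        ages, lens = [], []
        for j, a in enumerate(table.ages):
            i = year_index.get(b + int(a))
            if i is None:
                continue
            L = table.lengths[i, j]
            if not np.isnan(L):
                ages.append(int(a))
                lens.append(float(L))
        if len(ages) >= 2:
            out.append(CohortSeries(birth_year=b, ages=np.array(ages), lengths=np.array(lens)))
    return out


def increments(series: CohortSeries) -> IncrementSet:
    """``dL_a = L_(a+1) - L_a`` for every consecutive-age adjacency.

    The increment is paired with the start-of-interval length ``L_a`` (the
    law is written with the length *before* the increment). Age gaps produce
    no pair; negative increments are kept.
    """
    if series.ages.size < 2:
        raise InsufficientDataError(
            f"cohort {series.birth_year} has fewer than 2 ages"
        )
    consec = np.diff(series.ages) == 1
    L = series.lengths[:-1][consec]
    dL = np.diff(series.lengths)[consec]
    age = series.ages[:-1][consec]
    return IncrementSet(
        L=L, dL=dL, age=age, birth_year=np.full(L.shape, series.birth_year, dtype=int)
    )


def normalized_increments(times: np.ndarray, lengths: np.ndarray) -> IncrementSet:
    """Increment pairs for unevenly spaced observations (sub-annual data).

    For observation times t_0 < t_1 < ... the pair is
    ``(L_i, (L_(i+1) - L_i) / (t_(i+1) - t_i))``: the increment per elapsed
    unit, paired with the start-of-interval length. ``age`` provenance holds
    the observation index. With unit spacing this reduces to
    :func:`increments` on a gap-free series.
    """
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if times.size != lengths.size:
        raise DomainError("times and lengths must align")
    if times.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise DomainError("times must be strictly increasing")
    return IncrementSet(
        L=lengths[:-1],
        dL=np.diff(lengths) / dt,
        age=np.arange(times.size - 1),
        birth_year=None,
    )


def pool_increments(
    cohorts: list[CohortSeries], mode: str = "per-age-average"
) -> IncrementSet:
    """Combine increment pairs across year-classes.

    ``per-age-average`` returns, for each age ``a``, the unweighted mean of
    ``L_a`` and of ``dL_a`` over the cohorts that have a pair at that age
    (this is the "average length increment by length in all year-classes"
    reading of pooled survey data). ``pooled`` returns the raw union of all
    pairs.
    """
    if not cohorts:
        raise InsufficientDataError("no cohorts to pool")
    if mode not in ("per-age-average", "pooled"):
        raise DomainError(f"unknown pooling mode {mode!r}")
    sets = [increments(c) for c in cohorts if c.ages.size >= 2]
    sets = [s for s in sets if len(s)]
    if not sets:
        raise InsufficientDataError("no increment pairs in any cohort")
    union = IncrementSet.concatenate(sets)
    if mode == "pooled":
        return union
    ages = np.unique(union.age)
    L_mean = np.array([union.L[union.age == a].mean() for a in ages])
    dL_mean = np.array([union.dL[union.age == a].mean() for a in ages])
    return IncrementSet(L=L_mean, dL=dL_mean, age=ages, birth_year=None)


def table_from_cohorts(
    cohorts: list[CohortSeries], unit: str = "mm"
) -> AgeLengthTable:
    """Lay cohort series back onto the year×age grid (inverse of extraction)."""
    if not cohorts:
        raise InsufficientDataError("no cohorts to tabulate")
    all_ages = np.concatenate([c.ages for c in cohorts])
    all_years = np.concatenate([c.birth_year + c.ages for c in cohorts])
    ages = np.arange(all_ages.min(), all_ages.max() + 1)
    years = np.arange(all_years.min(), all_years.max() + 1)
    grid = np.full((years.size, ages.size), np.nan)
    for c in cohorts:
        for a, L in zip(c.ages, c.lengths):
            grid[int(c.birth_year + a - years[0]), int(a - ages[0])] = L
    return AgeLengthTable(years=years, ages=ages, lengths=grid, unit=unit)
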