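"""Forward projection under time-varying environmental k, plus biomass.

Because the growth law is free of time, projecting a stock is a plain
recursion: each step applies that step's environmental coefficient,
``L_(t+1) = L_t + k_t * (L_max - L_t)``, and the biomass of all year-classes
alive in the same step can be summed directly. Weight and length convert
through Fulton's cubic condition relation ``W = c * L^3``.

Mortality and recruitment are exogenous here: an optional per-step abundance
multiplier series, applied either before or after growth within the step
(the ordering is a modelling choice the caller makes explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, UnitMismatchError
from .model import GrowthParams, trajectory_closed_form


@dataclass
class EnvironmentalKSeries:
    """Ordered per-step growth coefficients, each in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DomainError("k series must be one-dimensional")
        if np.any(~np.isfinite(self.values)):
            raise DomainError("k series contains non-finite values")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise DomainError("every k must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ConditionFactor:
    """Fulton condition factor c in ``W = c * L^3``.

    Units follow the declaration: ``weight_unit`` per ``length_unit`` cubed.
    No implicit gram/kilogram conversion is ever applied.
    """

    c: float
    weight_unit: str = "g"
    length_unit: str = "cm"

    def __post_init__(self) -> None:
        if not np.isfinite(self.c) or self.c <= 0:
            raise DomainError(f"condition factor must be > 0; got {self.c}")


@dataclass
class CohortState:
    """One year-class inside a stock: length, abundance, growth parameters."""

    birth_step: int
    length: float
    abundance: float
    params: GrowthParams

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise DomainError("abundance must be >= 0")
        if self.length < 0 or self.length > self.params.L_max + 1e-9:
            raise DomainError(
                f"length {self.length} outside [0, L_max={self.params.L_max}]"
            )


def project_cohort(
    L0: float, params: GrowthParams, k_series: EnvironmentalKSeries | np.ndarray
) -> np.ndarray:
    """Length sequence under per-step k: ``L_(t+1) = L_t + k_t*(L_max - L_t)``.

    Returns ``len(k_series) + 1`` lengths starting at ``L0``; non-decreasing,
    never above ``L_max``. A constant series reproduces the closed form.
    """
    if not isinstance(k_series, EnvironmentalKSeries):
        k_series = EnvironmentalKSeries(np.asarray(k_series))
    if L0 < 0 or L0 > params.L_max + 1e-9:
        raise DomainError(f"L0={L0} outside [0, L_max={params.L_max}]")
    out = np.empty(len(k_series) + 1)
    out[0] = L = float(L0)
    for t, k in enumerate(k_series.values):
        L = min(L + k * (params.L_max - L), params.L_max)
        out[t + 1] = L
    return out


def length_to_weight(L: float | np.ndarray, c: ConditionFactor) -> float | np.ndarray:
    """Fulton weight ``W = c * L^3``."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise DomainError("length must be >= 0")
    W = c.c * L**3
    return float(W) if W.ndim == 0 else W


def weight_to_length(W: float | np.ndarray, c: ConditionFactor) -> float | np.ndarray:
    """Exact inverse of :func:`length_to_weight`: ``L = (W/c)^(1/3)``."""
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise DomainError("weight must be >= 0")
    L = np.cbrt(W / c.c)
    return float(L) if L.ndim == 0 else L


def stock_biomass(
    cohorts: list[CohortState], c: ConditionFactor
) -> tuple[float, list[float]]:
    """Total biomass of all year-classes alive in the same step.

    Per-cohort biomass is ``abundance * c * L^3``; the total is the plain sum
    — the within-year summation a time-indexed growth curve cannot provide.
    All cohorts must share the condition factor's declared length unit.
    """
    per = []
    for st in cohorts:
        if st.params.unit != c.length_unit:
            raise UnitMismatchError(
                f"cohort unit {st.params.unit!r} != condition factor "
                f"length unit {c.length_unit!r}"
            )
        per.append(st.abundance * length_to_weight(st.length, c))
    return float(sum(per)), per


def project_stock(
    cohorts: list[CohortState],
    k_series: EnvironmentalKSeries,
    c: ConditionFactor,
    abundance_multipliers: np.ndarray | None = None,
    multiplier_order: str = "before-growth",
) -> pd.DataFrame:
    """Step a whole stock forward and tabulate biomass per step.

    ``abundance_multipliers`` (one per step) fold exogenous mortality and
    recruitment into the abundances; ``multiplier_order`` selects whether
    they apply before or after the within-step growth. A series shorter than
    the projection is an error, never recycled.

    Returns a tidy frame with one row per (step, cohort) plus the running
    totals; step 0 is the initial state.
    """
    if abundance_multipliers is not None:
        abundance_multipliers = np.asarray(abundance_multipliers, dtype=float)
        if abundance_multipliers.size != len(k_series):
            raise DomainError(
                f"abundance multiplier series has {abundance_multipliers.size} "
                f"entries but the projection has {len(k_series)} steps"
            )
    if multiplier_order not in ("before-growth", "after-growth"):
        raise DomainError(f"unknown multiplier order {multiplier_order!r}")
    lengths = np.array([st.length for st in cohorts], dtype=float)
    counts = np.array([st.abundance for st in cohorts], dtype=float)
    rows = []

    def snapshot(t: int) -> None:
        for st, L, n in zip(cohorts, lengths, counts):
            W = length_to_weight(L, c)
            rows.append(
                {
                    "step": t,
                    "birth_step": st.birth_step,
                    "length": L,
                    "weight": W,
                    "abundance": n,
                    "biomass": n * W,
                }
            )

    for st in cohorts:
        if st.params.unit != c.length_unit:
            raise UnitMismatchError(
                f"cohort unit {st.params.unit!r} != condition factor "
                f"length unit {c.length_unit!r}"
            )
    snapshot(0)
    for t, k in enumerate(k_series.values):
        if abundance_multipliers is not None and multiplier_order == "before-growth":
            counts = counts * abundance_multipliers[t]
        lengths = np.array(
            [
                min(L + k * (st.params.L_max - L), st.params.L_max)
                for st, L in zip(cohorts, lengths)
            ]
        )
        if abundance_multipliers is not None and multiplier_order == "after-growth":
            counts = counts * abundance_multipliers[t]
        snapshot(t + 1)
    return pd.DataFrame(rows)
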