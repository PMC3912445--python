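"""Least-squares estimation of (k, L_max) and linear-vs-quadratic comparison.

Rearranging the law, ``dL = k*(L_max - L_s) = -k*L_s + k*L_max``, so on a
plot of increment against length the law is a straight line with slope
``-k`` and intercept ``k * L_max``. Ordinary least squares on the
``(L, dL)`` pairs therefore yields ``k = -slope`` and
``L_max = -intercept/slope``, both defined only when the slope is negative.

The alternative model is a free second-order polynomial
``dL = c2*L^2 + c1*L + c0``; the two nested fits are compared with the
extra-sum-of-squares F-test (one extra parameter), the standard procedure
behind "model A preferred (p = ...)" statements in curve-fitting software.

Young ages sometimes fall below the line fitted to older fish (lowered
environmental k in juveniles); :func:`detect_deviating_ages` finds the
largest old-age suffix whose linear fit clears an R² threshold, and
:func:`k_by_yearclass` assigns those off-line ages an individual
``k_a = dL_a / (L_max - L_a)`` against a shared L_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohorts import CohortSeries, IncrementSet, increments
from .errors import DegenerateDesignError, DomainError, InsufficientDataError

# residual SS below this fraction of total SS counts as an exact fit when
# breaking F-test ties (pure floating-point residue of a perfect fit)
_EXACT_SS_RTOL = 1e-12


def _r_squared(ss_res: float, ss_tot: float) -> float:
    if ss_tot <= 0:  # all responses identical: any fit through them is exact
        return 1.0 if ss_res <= 0 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


@dataclass
class LinearFit:
    """OLS line through (L, dL) pairs and the derived law parameters.

    ``k``/``L_max`` (and their delta-method standard errors) are None when
    the slope is non-negative — increasing increments are incompatible with
    the law, so the parameters are undefined rather than negative.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    ss_res: float
    ss_tot: float
    r2: float
    n: int
    k: float | None = None
    L_max: float | None = None
    k_se: float | None = None
    L_max_se: float | None = None

    @property
    def df_resid(self) -> int:
        return self.n - 2

    def _ci(self, est: float, se: float, level: float) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return est - t * se, est + t * se

    def k_ci(self, level: float = 0.95) -> tuple[float, float]:
        if self.k is None:
            raise DomainError("k undefined (non-negative slope)")
        return self._ci(self.k, self.k_se, level)

    def L_max_ci(self, level: float = 0.95) -> tuple[float, float]:
        if self.L_max is None:
            raise DomainError("L_max undefined (non-negative slope)")
        return self._ci(self.L_max, self.L_max_se, level)


@dataclass
class QuadraticFit:
    """OLS parabola ``dL = c2*L^2 + c1*L + c0`` through (L, dL) pairs.

    ``inverted`` records the orientation: a positive ``c2`` opens upward,
    the inverse of the concave increment-by-length curve the law predicts —
    the pattern seen in stocks whose juveniles outgrow the line.
    """

    c2: float
    c1: float
    c0: float
    ss_res: float
    ss_tot: float
    r2: float
    n: int

    @property
    def inverted(self) -> bool:
        return self.c2 > 0


@dataclass
class ModelComparison:
    """Extra-sum-of-squares F-test verdict between the nested fits."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float
    verdict: str  # "linear-preferred" | "quadratic-preferred"
    exact_tie: bool = False  # both fits exact; simpler model wins
    criterion: str = "f-test"
    aicc_linear: float | None = None
    aicc_quadratic: float | None = None


@dataclass
class AgeKEstimate:
    """Per-age environmental k for one cohort.

    ``source`` is "on-line" when the age sat inside the cohort's core linear
    fit (k is the shared regression slope) and "off-line" when it was an
    excluded young age estimated individually against the shared L_max.
    """

    birth_year: int
    age: int
    k: float | None
    source: str
    flag: str | None = None


@dataclass
class DeviationResult:
    """Outcome of the young-age deviation screen on one cohort."""

    core_ages: np.ndarray  # series ages retained
    excluded_ages: np.ndarray  # youngest series ages dropped (possibly empty)
    fit: LinearFit  # linear fit on the core increment pairs
    threshold_met: bool


@dataclass
class YearClassK:
    """Per-age k across cohorts plus the shared L_max used off-line."""

    estimates: list[AgeKEstimate]
    shared_L_max: float | None


def _ols(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, X).fit()


def fit_linear(pairs: IncrementSet) -> LinearFit:
    """OLS of dL on L; derive k = -slope, L_max = -intercept/slope.

    R² is computed against the mean-dL null. Standard errors of the derived
    parameters come from the delta method on the (intercept, slope)
    covariance: k inherits the slope SE, and for L_max = -b0/b1 the gradient
    is (-1/b1, b0/b1²).
    """
    L, dL = pairs.L, pairs.dL
    if L.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs for a linear fit; got {L.size}")
    if np.unique(L).size < 2:
        raise DegenerateDesignError("all L identical; slope is unidentifiable")
    res = _ols(dL, sm.add_constant(L))
    b0, b1 = res.params  # intercept, slope
    ss_res = float(res.ssr)
    ss_tot = float(res.centered_tss)
    cov = np.asarray(res.cov_params())
    fit = LinearFit(
        slope=float(b1),
        intercept=float(b0),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        cov=cov,
        ss_res=ss_res,
        ss_tot=ss_tot,
        r2=_r_squared(ss_res, ss_tot),
        n=int(L.size),
    )
    if b1 < 0:
        fit.k = float(-b1)
        fit.L_max = float(-b0 / b1)
        fit.k_se = float(res.bse[1])
        grad = np.array([-1.0 / b1, b0 / b1**2])
        fit.L_max_se = float(math.sqrt(grad @ cov @ grad))
    return fit


def fit_quadratic(pairs: IncrementSet) -> QuadraticFit:
    """OLS of dL on (1, L, L²)."""
    L, dL = pairs.L, pairs.dL
    if L.size < 4:
        raise InsufficientDataError(f"need >= 4 pairs for a quadratic fit; got {L.size}")
    if np.unique(L).size < 3:
        raise DegenerateDesignError("need >= 3 distinct L for a quadratic fit")
    X = np.column_stack([np.ones_like(L), L, L**2])
    res = _ols(dL, X)
    c0, c1, c2 = res.params
    ss_res = float(res.ssr)
    ss_tot = float(res.centered_tss)
    return QuadraticFit(
        c2=float(c2),
        c1=float(c1),
        c0=float(c0),
        ss_res=ss_res,
        ss_tot=ss_tot,
        r2=_r_squared(ss_res, ss_tot),
        n=int(L.size),
    )


def _aicc(ss_res: float, n: int, n_params: int) -> float:
    # Gaussian-likelihood AICc; +1 parameter for the error variance
    p = n_params + 1
    if n - p - 1 <= 0 or ss_res <= 0:
        return math.inf if ss_res > 0 else -math.inf
    return n * math.log(ss_res / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def compare_models(
    lin: LinearFit,
    quad: QuadraticFit,
    alpha: float = 0.05,
    criterion: str = "f-test",
) -> ModelComparison:
    """Nested-model comparison of the line against the free parabola.

    F = ((SS_lin - SS_quad)/1) / (SS_quad/(n-3)), upper-tail p from
    F(1, n-3). Ties where both fits are numerically exact resolve toward the
    simpler (linear) model; an exact quadratic over an inexact line gets
    p = 0. ``criterion="aicc"`` switches the verdict to small-sample AIC
    (the F statistic and p-value are still reported).
    """
    if lin.n != quad.n:
        raise DomainError("fits must come from the same pairs (n differs)")
    n = lin.n
    if n < 5:
        raise InsufficientDataError(f"need n >= 5 for the comparison; got {n}")
    if criterion not in ("f-test", "aicc"):
        raise DomainError(f"unknown criterion {criterion!r}")
    df_num, df_den = 1, n - 3
    scale = max(lin.ss_tot, quad.ss_tot, 1.0)
    tol = _EXACT_SS_RTOL * scale
    exact_tie = False
    if quad.ss_res <= tol:
        if lin.ss_res <= tol:
            f_stat, p = 0.0, 1.0
            exact_tie = True
        else:
            f_stat, p = math.inf, 0.0
    else:
        f_stat = max(lin.ss_res - quad.ss_res, 0.0) / df_num / (quad.ss_res / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    if criterion == "f-test":
        verdict = "quadratic-preferred" if p < alpha else "linear-preferred"
    else:
        a_lin = _aicc(lin.ss_res, n, 2)
        a_quad = _aicc(quad.ss_res, n, 3)
        verdict = "quadratic-preferred" if a_quad < a_lin else "linear-preferred"
    cmpres = ModelComparison(
        f_stat=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        alpha=alpha,
        verdict=verdict,
        exact_tie=exact_tie,
        criterion=criterion,
    )
    if criterion == "aicc":
        cmpres.aicc_linear = a_lin
        cmpres.aicc_quadratic = a_quad
    return cmpres


def detect_deviating_ages(
    series: CohortSeries,
    r2_threshold: float = 0.98,
    min_points: int = 3,
) -> DeviationResult:
    """Screen a cohort for slow-growing young ages below the line.

    Drops the youngest age while the linear fit on the remaining increment
    pairs has R² below ``r2_threshold`` and at least ``min_points`` pairs
    remain; returns the largest suffix meeting the threshold. Only a prefix
    of youngest ages is ever excluded — the deviation this screens for is a
    juvenile phenomenon. If no suffix qualifies, the full series is returned
    with ``threshold_met=False``.
    """
    pairs = increments(series)
    if len(pairs) < min_points:
        raise InsufficientDataError(
            f"cohort {series.birth_year}: {len(pairs)} pairs < min_points={min_points}"
        )
    start_ages = pairs.age  # sorted ascending by construction
    for n_drop in range(len(pairs) - min_points + 1):
        sub = pairs.subset(np.arange(len(pairs)) >= n_drop)
        fit = fit_linear(sub)
        if fit.r2 >= r2_threshold:
            cut_age = start_ages[n_drop]
            keep = series.ages >= cut_age
            return DeviationResult(
                core_ages=series.ages[keep],
                excluded_ages=series.ages[~keep],
                fit=fit,
                threshold_met=True,
            )
    return DeviationResult(
        core_ages=series.ages.copy(),
        excluded_ages=np.array([], dtype=int),
        fit=fit_linear(pairs),
        threshold_met=False,
    )


def k_for_age(dL: float, L: float, L_max: float) -> float:
    """Individual-age k: the slope of the line from (L, dL) to (L_max, 0).

    ``k_a = dL_a / (L_max - L_a)``. Negative observed increments clamp to 0
    (a single-point ratio has no regression context to absorb noise).
    """
    if L >= L_max:
        raise DomainError(f"L={L} must be below L_max={L_max}")
    if dL < 0:
        return 0.0
    return dL / (L_max - L)


def k_by_yearclass(
    cohorts: list[CohortSeries],
    r2_threshold: float = 0.98,
    min_points: int = 3,
) -> YearClassK:
    """Per-age environmental k for every cohort.

    Each cohort is screened with :func:`detect_deviating_ages`; core ages
    share the core-fit k ("on-line"), and the shared L_max — the unweighted
    mean of the per-cohort core-fit L_max estimates — prices the excluded
    young ages individually via :func:`k_for_age` ("off-line"). Cohorts whose
    core fit has an undefined L_max yield flagged entries, never silent drops.
    """
    if not cohorts:
        raise InsufficientDataError("no cohorts")
    results = [(c, detect_deviating_ages(c, r2_threshold, min_points)) for c in cohorts]
    lmaxes = [d.fit.L_max for _, d in results if d.fit.L_max is not None]
    shared = float(np.mean(lmaxes)) if lmaxes else None
    estimates: list[AgeKEstimate] = []
    for series, det in results:
        pairs = increments(series)
        core_fit_ok = det.fit.k is not None
        for L, dL, a in zip(pairs.L, pairs.dL, pairs.age):
            if a in det.core_ages and core_fit_ok:
                estimates.append(
                    AgeKEstimate(series.birth_year, int(a), det.fit.k, "on-line")
                )
            elif a in det.core_ages:
                estimates.append(
                    AgeKEstimate(
                        series.birth_year, int(a), None, "on-line", flag="undefined-L_max"
                    )
                )
            else:  # excluded young age -> individual k against shared L_max
                if shared is None:
                    estimates.append(
                        AgeKEstimate(
                            series.birth_year, int(a), None, "off-line",
                            flag="undefined-L_max",
                        )
                    )
                elif L >= shared:
                    estimates.append(
                        AgeKEstimate(
                            series.birth_year, int(a), None, "off-line",
                            flag="length-above-shared-L_max",
                        )
                    )
                else:
                    k = k_for_age(float(dL), float(L), shared)
                    estimates.append(
                        AgeKEstimate(
                            series.birth_year, int(a), k, "off-line",
                            flag="negative-increment-clamped" if dL < 0 else None,
                        )
                    )
    return YearClassK(estimates=estimates, shared_L_max=shared)
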