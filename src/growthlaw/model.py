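"""The length-increment growth law.

The model states that the per-step length increment of a fish is proportional
to the gap between its current length ``L_s`` and a fixed maximal length
``L_max``::

    dL = k * (L_max - L_s)

``k`` is a dimensionless environmental growth coefficient (food availability,
temperature, ...) and the model carries no time variable: a "step" is whatever
observation interval the data use (a year for stock data, a day for
laboratory fish), recorded only as a metadata tag.

Under constant ``k`` the recursion ``L <- L + k*(L_max - L)`` has the closed
form ``L_n = L_max - (L_max - L0) * (1 - k)**n``: the remaining gap to
``L_max`` decays geometrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

#: absolute tolerance for floating comparisons against L_max, in length units
LMAX_ATOL = 1e-9


@dataclass(frozen=True)
class GrowthParams:
    """Parameter pair of the growth law.

    Parameters
    ----------
    k : float
        Dimensionless environmental growth coefficient per step. Must lie in
        [0, 1]: negative k would shrink the animal, k > 1 would overshoot
        L_max, and both are unphysical under the law.
    L_max : float
        Maximal attainable length, in ``unit``. A fixed value, not an
        asymptote: increments reach exactly zero there.
    unit : str
        Length unit tag ("mm", "cm", ...).
    step : str
        Nominal duration of one increment step ("year", "day", ...). Metadata
        only — the model itself is time-free.
    """

    k: float
    L_max: float
    unit: str = "mm"
    step: str = "year"

    def __post_init__(self) -> None:
        if not np.isfinite(self.k) or self.k < 0:
            raise DomainError(f"k must be >= 0 (the animal cannot shrink); got {self.k}")
        if self.k > 1:
            raise DomainError(
                f"k must be <= 1 (one step cannot overshoot L_max); got {self.k}"
            )
        if not np.isfinite(self.L_max) or self.L_max <= 0:
            raise DomainError(f"L_max must be positive; got {self.L_max}")


@dataclass(frozen=True)
class LengthState:
    """A current length bound to no particular parameter set.

    Validation against ``L_max`` happens where the state meets a
    :class:`GrowthParams` (see :func:`predict_increment`).
    """

    L_s: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.L_s) or self.L_s < 0:
            raise DomainError(f"length must be finite and >= 0; got {self.L_s}")


def _as_length(length: float | LengthState) -> float:
    return length.L_s if isinstance(length, LengthState) else float(length)


def predict_increment(params: GrowthParams, length: float | LengthState) -> float:
    """Pointwise increment ``dL = k * (L_max - L_s)``.

    Raises
    ------
    DomainError
        If ``length`` exceeds ``params.L_max`` (beyond a 1e-9 absolute
        tolerance): the dynamic term cannot be negative.
    """
    L = _as_length(length)
    if L < 0:
        raise DomainError(f"length must be >= 0; got {L}")
    if L > params.L_max + LMAX_ATOL:
        raise DomainError(
            f"length {L} exceeds L_max {params.L_max}; the gap term cannot be negative"
        )
    return params.k * max(params.L_max - L, 0.0)


def step(params: GrowthParams, length: float | LengthState) -> float:
    """One application of the law: ``L -> L + k*(L_max - L)``.

    Never exceeds ``L_max`` for valid parameters.
    """
    L = _as_length(length)
    return min(L + predict_increment(params, L), params.L_max)


def trajectory_closed_form(L0: float, params: GrowthParams, n: int) -> np.ndarray:
    """Length sequence after 0..n constant-k steps, by the analytic solution.

    ``L_i = L_max - (L_max - L0) * (1 - k)**i``. Element 0 is ``L0``; the
    sequence is non-decreasing and converges to ``L_max``.
    """
    if n < 0:
        raise DomainError(f"step count must be >= 0; got {n}")
    L0 = _as_length(L0)
    if L0 < 0 or L0 > params.L_max + LMAX_ATOL:
        raise DomainError(f"L0={L0} outside [0, L_max={params.L_max}]")
    i = np.arange(n + 1)
    traj = params.L_max - (params.L_max - L0) * (1.0 - params.k) ** i
    traj[0] = L0  # exact, regardless of rounding in the power
    return traj
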