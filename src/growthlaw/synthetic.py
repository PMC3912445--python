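"""Synthetic year×age tables with the structure the analysis assumes.

The generator runs the growth law forward for a run of year-classes, lays
the resulting length-at-age series onto the year×age grid the surveys use,
and optionally perturbs the observed mean lengths with additive Gaussian
noise. Per-age k overrides reproduce the juvenile growth suppression seen in
some wild stocks (young fish in colder nursery areas), which is what the
deviating-age detector must recover.

Defaults mirror a spring-spawning-herring analysis scale: ages 1–9,
L_max = 354 mm, k = 0.3, 11 year-classes. Randomness is NumPy's PCG64
(``numpy.random.default_rng``), fully determined by the spec's seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohorts import AgeLengthTable, CohortSeries, table_from_cohorts
from .errors import DomainError
from .model import GrowthParams
from .simulate import EnvironmentalKSeries

#: name of the random algorithm, recorded in truth sidecars for portability
RNG_ALGORITHM = "numpy-PCG64"


@dataclass
class SyntheticSpec:
    """Generating configuration for one synthetic table.

    ``k_overrides`` maps an age ``a`` to the coefficient used for the
    increment from ``a`` to ``a+1`` (e.g. ``{1: 0.15, 2: 0.15}`` halves
    juvenile growth under the default k=0.3). ``noise_sd`` is the SD of the
    additive Gaussian perturbation on each observed mean length, in length
    units. ``L_first`` is the mean length at the youngest age; None means one
    application of the law from zero length, ``k * L_max``.
    """

    params: GrowthParams = field(default_factory=lambda: GrowthParams(k=0.3, L_max=354.0))
    n_cohorts: int = 11
    age_min: int = 1
    age_max: int = 9
    k_overrides: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    L_first: float | None = None
    first_birth_year: int = 1985
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise DomainError("need at least one cohort")
        if self.age_max <= self.age_min:
            raise DomainError("age_max must exceed age_min")
        if self.noise_sd < 0:
            raise DomainError("noise SD must be >= 0")
        for a, k in self.k_overrides.items():
            if not 0 <= k <= 1:
                raise DomainError(f"k override for age {a} outside [0, 1]: {k}")
        if self.L_first is not None and not 0 < self.L_first <= self.params.L_max:
            raise DomainError(
                f"L_first={self.L_first} outside (0, L_max={self.params.L_max}]"
            )

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    def truth(self) -> dict:
        """Generating parameters as a plain dict (for truth sidecar files)."""
        d = dataclasses.asdict(self)
        d["params"] = dataclasses.asdict(self.params)
        d["k_overrides"] = {str(a): k for a, k in self.k_overrides.items()}
        d["rng_algorithm"] = RNG_ALGORITHM
        return d


def noiseless_lengths(spec: SyntheticSpec) -> np.ndarray:
    """Length at each age of ``spec.ages`` under the (possibly per-age) law."""
    L0 = spec.L_first if spec.L_first is not None else spec.params.k * spec.params.L_max
    out = np.empty(spec.ages.size)
    out[0] = L0
    for i, a in enumerate(spec.ages[:-1]):
        k = spec.k_overrides.get(int(a), spec.params.k)
        out[i + 1] = out[i] + k * (spec.params.L_max - out[i])
    return out


def generate_table(spec: SyntheticSpec) -> AgeLengthTable:
    """Simulate cohorts under the law and lay them on the year×age grid.

    Every cohort shares the same expected length-at-age curve (constant
    conditions apart from noise); cohort ``i`` is born in
    ``first_birth_year + i`` and occupies the corresponding diagonal. Noise
    is drawn per observed cell, clipped to a tiny positive floor so the
    table's lengths stay positive; with realistic noise levels the floor is
    never reached. Bit-identical output for identical specs.
    """
    base = noiseless_lengths(spec)
    rng = np.random.default_rng(spec.seed)
    cohorts = []
    for i in range(spec.n_cohorts):
        lens = base.copy()
        if spec.noise_sd > 0:
            lens = lens + rng.normal(0.0, spec.noise_sd, size=lens.size)
            lens = np.maximum(lens, 1e-9)
        cohorts.append(
            CohortSeries(
                birth_year=spec.first_birth_year + i,
                ages=spec.ages.copy(),
                lengths=lens,
            )
        )
    return table_from_cohorts(cohorts, unit=spec.params.unit)


def generate_k_series(
    base_k: float,
    steps: int,
    variation: str = "none",
    sigma: float = 0.0,
    seed: int = 0,
) -> EnvironmentalKSeries:
    """Environmental k series: constant, or iid lognormal around ``base_k``.

    Lognormal variation multiplies ``base_k`` by ``exp(sigma * Z)`` with
    standard-normal Z, so log(k/base_k) has mean zero; values are clamped
    into [0, 1] afterwards. ``sigma=0`` (or ``variation="none"``) gives a
    constant series. Deterministic given seed.
    """
    if not 0 < base_k <= 1:
        raise DomainError(f"base k must lie in (0, 1]; got {base_k}")
    if sigma < 0:
        raise DomainError("sigma must be >= 0")
    if steps < 0:
        raise DomainError("steps must be >= 0")
    if variation not in ("none", "lognormal"):
        raise DomainError(f"unknown variation model {variation!r}")
    if variation == "none" or sigma == 0:
        return EnvironmentalKSeries(np.full(steps, base_k))
    rng = np.random.default_rng(seed)
    vals = base_k * np.exp(sigma * rng.standard_normal(steps))
    return EnvironmentalKSeries(np.clip(vals, 0.0, 1.0))
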