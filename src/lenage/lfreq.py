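"""Forward model: growth parameters + age composition -> predicted
length-frequency histograms.

Each sampling month is modelled as a finite mixture of normals, one
component per age class.  A cohort of age class ``a`` sampled at
calendar time ``t`` has mean length given by the growth curve evaluated
at its elapsed age, and standard deviation ``sigma_a``.  Expected counts
in a 10-mm length bin are

    n_{a,i,t} = N_t * P_{a,t} * P(L_lower <= L < L_upper | N(mean, sigma_a^2))

summed over the age classes present (0-3 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

from .growth import GrowthParams, length_at_age

__all__ = [
    "BinGrid",
    "SampleMonth",
    "AgeStructure",
    "LengthHistogram",
    "cohort_age",
    "bin_mass",
    "predict_histogram",
]

N_AGE_CLASSES = 4


@dataclass(frozen=True)
class BinGrid:
    """Contiguous half-open length bins [lower, lower+width), from 0 mm.

    The default is 46 ten-mm bins covering [0, 460) mm total length.
    """

    width: float = 10.0
    n_bins: int = 46
    start: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.n_bins < 1:
            raise ValueError("bin width must be > 0 and n_bins >= 1")

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.width * np.arange(self.n_bins + 1)

    @property
    def lower_edges(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def upper_edges(self) -> np.ndarray:
        return self.edges[1:]

    @property
    def max_length(self) -> float:
        return float(self.edges[-1])


@dataclass(frozen=True)
class SampleMonth:
    """One sampling occasion: a label, a within-year time, a sample size.

    ``sample_time`` is the calendar year fraction of the (assumed
    mid-month) collection date; ``year_index`` orders months that span a
    calendar-year boundary within one sampling series (January 2015
    belongs to the 2014 series with year_index 1).
    """

    label: str
    sample_time: float
    N_t: int
    year_index: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sample_time < 1.0:
            raise ValueError("sample_time must lie in [0, 1)")
        if self.N_t < 0:
            raise ValueError("N_t must be >= 0")


@dataclass(frozen=True)
class AgeStructure:
    """Proportions-at-age for one month (ages 0..3).

    Stored as given (possibly unnormalized); ``normalized()`` projects
    onto the simplex for reporting.
    """

    P: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = tuple(float(p) for p in self.P)
        if len(arr) != N_AGE_CLASSES:
            raise ValueError(f"expected {N_AGE_CLASSES} age proportions")
        if any(p < 0 for p in arr):
            raise ValueError("proportions must be >= 0")
        object.__setattr__(self, "P", arr)

    def normalized(self) -> tuple[float, ...]:
        s = sum(self.P)
        if s == 0:
            return self.P
        return tuple(p / s for p in self.P)


@dataclass(frozen=True)
class LengthHistogram:
    """Observed or predicted counts on a bin grid for one month."""

    grid: BinGrid
    counts: np.ndarray
    month: SampleMonth

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts must have shape ({self.grid.n_bins},), got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def cohort_age(month: SampleMonth, t_b: float, age_class: int) -> float:
    """Elapsed age (yr) of the ``age_class`` cohort at the sampling time.

    A cohort's age class increments at its birthday, so a month sampled
    before t_b in the calendar year sees the cohort one year into its
    current class: age = (sample_time - t_b) + age_class, plus 1 when
    sample_time < t_b.
    """
    if age_class not in range(N_AGE_CLASSES):
        raise ValueError(f"age_class must be in 0..{N_AGE_CLASSES - 1}")
    age = (month.sample_time - t_b) + age_class
    if month.sample_time < t_b:
        age += 1.0
    return age


def bin_mass(mean: float, sd: float, lower, upper):
    """Probability mass of N(mean, sd^2) on [lower, upper). Vectorised."""
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    return norm.cdf(upper, loc=mean, scale=sd) - norm.cdf(lower, loc=mean, scale=sd)


def age_means_and_masses(
    params: GrowthParams,
    month: SampleMonth,
    grid: BinGrid,
    sigmas,
    *,
    seasonal: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean length per age class and per-age bin-mass matrix (ages x bins)."""
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (N_AGE_CLASSES,))
    if np.any(sig <= 0):
        raise ValueError("sigmas must be > 0")
    ages = np.array(
        [cohort_age(month, params.t_b, a) for a in range(N_AGE_CLASSES)]
    )
    means = np.asarray(length_at_age(params, ages, seasonal=seasonal), dtype=float)
    # ndtr on the standardized edge grid: one cdf evaluation per edge,
    # differenced to bin masses (ages x bins)
    z = (grid.edges[None, :] - means[:, None]) / sig[:, None]
    cdf = ndtr(z)
    masses = np.diff(cdf, axis=1)
    return means, masses


def masses_stack(
    params: GrowthParams,
    months,
    grid: BinGrid,
    sigmas,
    *,
    seasonal: bool = True,
) -> np.ndarray:
    """Bin-mass tensor (months x ages x bins) in one vectorized pass."""
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (N_AGE_CLASSES,))
    if np.any(sig <= 0):
        raise ValueError("sigmas must be > 0")
    ages = np.array(
        [
            [cohort_age(m, params.t_b, a) for a in range(N_AGE_CLASSES)]
            for m in months
        ]
    )
    means = np.asarray(length_at_age(params, ages, seasonal=seasonal))
    z = (grid.edges[None, None, :] - means[:, :, None]) / sig[None, :, None]
    return np.diff(ndtr(z), axis=2)


def predict_histogram(
    params: GrowthParams,
    ages: AgeStructure,
    month: SampleMonth,
    grid: BinGrid,
    sigmas,
    *,
    seasonal: bool = True,
) -> LengthHistogram:
    """Expected length-frequency histogram for one sampling month.

    ``sigmas`` is either one shared standard deviation or one per age
    class.  Totals fall short of N_t only by the normal tail mass
    outside the grid.
    """
    _, masses = age_means_and_masses(
        params, month, grid, sigmas, seasonal=seasonal
    )
    P = np.asarray(ages.P, dtype=float)
    counts = month.N_t * (P[:, None] * masses).sum(axis=0)
    return LengthHistogram(grid=grid, counts=counts, month=month)
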