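"""Traditional and seasonal von Bertalanffy growth.

The traditional von Bertalanffy growth function (VBGF) gives mean length
at age ``t`` as

    L(t) = L_inf * (1 - exp(-K * (t - t0)))

The seasonal extension (Somers form) modulates cumulative growth with a
sinusoid so that the instantaneous growth rate cycles over the year:

    L(t) = L_inf * (1 - exp(-[K*(t - t0) + S(t) - S(t0)]))
    S(t) = (C*K / (2*pi)) * sin(2*pi * (t - t_s))

``C`` in [0, 1] sets the oscillation amplitude (C=0 recovers the
traditional curve; C=1 means complete cessation of growth once a year)
and ``t_s`` the phase.  The slowest-growth time of year ("winter point")
is t_w = t_s + 0.5 in the age frame; on the calendar it falls at
(t_s + 0.5 + t_b) mod 1 where t_b is the cohort birth date expressed as
a fraction of the calendar year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GrowthParams",
    "CalendarDate",
    "length_at_age",
    "growth_rate",
    "winter_point_calendar",
    "age_at_first_annulus",
    "invert_traditional",
]

_DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
_MONTH_NAMES = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)


@dataclass(frozen=True)
class CalendarDate:
    """A within-year date under a fixed 365-day (non-leap) convention.

    ``year_fraction`` is (day_of_year - 1) / 365, so January 1 is 0.0.
    """

    year_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "year_fraction", self.year_fraction % 1.0)

    @classmethod
    def from_month_day(cls, month: int, day: int) -> "CalendarDate":
        if not 1 <= month <= 12 or not 1 <= day <= _DAYS_IN_MONTH[month - 1]:
            raise ValueError(f"invalid month/day: {month}/{day}")
        doy = sum(_DAYS_IN_MONTH[: month - 1]) + day
        return cls((doy - 1) / 365.0)

    @property
    def day_of_year(self) -> int:
        # round(): keeps 0.12 within 1 day of Feb 13 and 0.41 within
        # 2 days of June 2, the tightest the 2-dp inputs allow.
        return int(round(self.year_fraction * 365.0)) % 365 + 1

    @property
    def month_day(self) -> tuple[int, int]:
        d = self.day_of_year
        for m, ndays in enumerate(_DAYS_IN_MONTH, start=1):
            if d <= ndays:
                return m, d
            d -= ndays
        raise AssertionError("unreachable")

    def __str__(self) -> str:
        m, d = self.month_day
        return f"{_MONTH_NAMES[m - 1]} {d}"


@dataclass(frozen=True)
class GrowthParams:
    """VBGF parameter set plus cohort birth date.

    Parameters
    ----------
    L_inf : asymptotic total length, mm.
    K : Brody growth coefficient, 1/yr.
    t0 : theoretical age at length zero, yr (fixed at 0 when the birth
        date ``t_b`` carries the cohort origin).
    C : seasonal oscillation intensity, dimensionless in [0, 1].
    t_s : seasonal phase in the age frame, fraction of a year.
    t_b : cohort birth date, fraction of the calendar year.
    """

    L_inf: float
    K: float
    t0: float = 0.0
    C: float = 0.0
    t_s: float = 0.0
    t_b: float = 0.0

    def __post_init__(self) -> None:
        if self.L_inf <= 0:
            raise ValueError(f"L_inf must be positive, got {self.L_inf}")
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError(f"C must lie in [0, 1], got {self.C}")
        object.__setattr__(self, "t_s", self.t_s % 1.0)
        object.__setattr__(self, "t_b", self.t_b % 1.0)

    @property
    def t_w(self) -> float:
        """Winter point (slowest growth) in the age frame."""
        return (self.t_s + 0.5) % 1.0

    def with_(self, **kwargs) -> "GrowthParams":
        return replace(self, **kwargs)


def _S(params: GrowthParams, t) -> np.ndarray:
    return (params.C * params.K / (2.0 * math.pi)) * np.sin(
        2.0 * math.pi * (np.asarray(t, dtype=float) - params.t_s)
    )


def length_at_age(params: GrowthParams, age, *, seasonal: bool = False):
    """Mean total length (mm) at age (years since birth).

    Vectorised over ``age``.  Ages below ``t0`` are a domain error: the
    curve has no meaning before length zero.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < params.t0 - 1e-12):
        raise ValueError(f"age must be >= t0 ({params.t0}), got {age}")
    if seasonal:
        q = (
            params.K * (age_arr - params.t0)
            + _S(params, age_arr)
            - _S(params, params.t0)
        )
    else:
        q = params.K * (age_arr - params.t0)
    out = params.L_inf * (1.0 - np.exp(-q))
    return out if out.ndim else float(out)


def growth_rate(params: GrowthParams, age, *, seasonal: bool = True):
    """Instantaneous growth dL/dt in mm/yr at age.

    For the seasonal curve dL/dt = L_inf * exp(-q(t)) * K * (1 + C*cos(2*pi*(t - t_s)));
    it reaches zero once a year at the winter point when C = 1.
    """
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < params.t0 - 1e-12):
        raise ValueError(f"age must be >= t0 ({params.t0}), got {age}")
    L = np.asarray(length_at_age(params, age_arr, seasonal=seasonal), dtype=float)
    if seasonal:
        qdot = params.K * (
            1.0 + params.C * np.cos(2.0 * math.pi * (age_arr - params.t_s))
        )
    else:
        qdot = np.full_like(age_arr, params.K)
    out = (params.L_inf - L) * qdot
    return out if out.ndim else float(out)


def winter_point_calendar(params: GrowthParams) -> CalendarDate:
    """Calendar date of slowest growth: (t_s + 0.5 + t_b) mod 1."""
    return CalendarDate((params.t_s + 0.5 + params.t_b) % 1.0)


def age_at_first_annulus(params: GrowthParams, annuli: int) -> float:
    """Actual age (yr) at deposition of the ``annuli``-th annulus.

    The first annulus is assumed to form at the first winter point after
    birth, so its age is t_w + 1 - t_b; each further annulus adds one
    year.
    """
    if annuli < 1:
        raise ValueError(f"annuli must be >= 1, got {annuli}")
    return params.t_w + 1.0 - params.t_b + (annuli - 1)


def invert_traditional(params: GrowthParams, length: float) -> float:
    """Age at which the traditional VBGF reaches ``length`` mm (closed form)."""
    if not 0.0 <= length < params.L_inf:
        raise ValueError(
            f"length must lie in [0, L_inf={params.L_inf}), got {length}"
        )
    return params.t0 - math.log(1.0 - length / params.L_inf) / params.K
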