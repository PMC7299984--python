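"""Newtonian cooling model and the thermal decay rate estimator.

Vegetated land surfaces heat radiatively during the day and cool after the
diurnal peak mainly by conduction, convection and evapotranspiration, for
which Newton's law of cooling applies: the surface temperature relaxes
exponentially toward an ambient temperature ``T_a`` with rate constant
``R_dk``.  Dense vegetation (large thermal mass ``rho * c * V/A``) cools
slowly (small ``R_dk``); sparse vegetation and bare soil cool fast.

The remote sensing estimator approximates ``R_dk`` from one daytime and one
nighttime land-surface-temperature (LST) observation as

    R_dk = ln(T_day / T_night) / delta_t        [hr^-1]

with temperatures in Kelvin (the ratio is meaningless on a relative scale
such as Celsius).  The approximation drops the ambient-temperature term of
the exact solution and is exact only in the limit ``T_a -> 0``;
:func:`approximation_bias` quantifies the resulting bias.

All numerical functions accept scalars or numpy arrays and propagate NaN as
the missing-value sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CoolingState",
    "TemperaturePair",
    "DecayRateEstimate",
    "ThermalProperties",
    "WarmNightWarning",
    "exact_cooling",
    "estimate_rdk",
    "annual_mean_rdk",
    "theoretical_rdk",
    "approximation_bias",
    "dtr",
    "annual_mean_dtr",
]

#: Default elapsed time between day and night acquisitions, hours.
#: Aqua (~13:30 / ~01:30) and Terra (~10:30 / ~22:30) both imply 12 h.
DEFAULT_DELTA_T_HOURS = 12.0

#: Default minimum number of valid pairs for a finite annual mean.
#: 8-day composites give at most 46 pairs per year.
DEFAULT_MIN_PAIRS = 10


class WarmNightWarning(UserWarning):
    """Raised when T_night > T_day, which yields a negative decay rate."""


@dataclass(frozen=True)
class CoolingState:
    """Parameters of one exact Newtonian cooling trajectory.

    Parameters
    ----------
    t0
        Initial temperature at elapsed time zero, Kelvin (> 0).
    t_ambient
        Ambient temperature the surface relaxes toward, Kelvin (>= 0).
    k
        True decay constant; units must match the elapsed-time units
        passed to :func:`exact_cooling` (>= 0).
    """

    t0: float
    t_ambient: float
    k: float

    def __post_init__(self) -> None:
        if not self.t0 > 0:
            raise ValueError(f"t0 must be positive, got {self.t0}")
        if self.t_ambient < 0:
            raise ValueError(f"t_ambient must be >= 0, got {self.t_ambient}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


@dataclass(frozen=True)
class TemperaturePair:
    """One co-located day/night LST observation.

    ``t_day`` and ``t_night`` are Kelvin; ``delta_t`` is the elapsed time
    from the day to the night acquisition in hours.  ``valid`` marks
    observation quality (cloud/QC); invalid pairs are excluded from all
    aggregations and yield NaN estimates.
    """

    t_day: float
    t_night: float
    delta_t: float = DEFAULT_DELTA_T_HOURS
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not (self.t_day > 0 and self.t_night > 0):
                raise ValueError(
                    "valid pairs require absolute (Kelvin) temperatures > 0; "
                    f"got t_day={self.t_day}, t_night={self.t_night}"
                )
        if not self.delta_t > 0:
            raise ValueError(f"delta_t must be positive, got {self.delta_t}")


@dataclass(frozen=True)
class DecayRateEstimate:
    """An aggregated decay rate with its support.

    ``rdk`` is in hr^-1 (NaN when fewer than ``min_pairs`` valid pairs
    contributed); ``n_pairs`` counts the valid pairs actually aggregated;
    ``warm_night_fraction`` is the fraction of valid pairs with
    T_night > T_day.
    """

    rdk: float
    n_pairs: int
    period: str = ""
    warm_night_fraction: float = 0.0


@dataclass(frozen=True)
class ThermalProperties:
    """Bulk thermal properties governing the theoretical decay rate.

    ``alpha_tot`` is the effective heat transfer coefficient combining
    conduction, convection and radiation (W m^-2 K^-1 semantics); ``rho``
    the density (kg m^-3); ``c`` the specific heat, treated as an opaque
    positive factor; ``v_over_a`` the volume-to-surface-area ratio (m).
    """

    alpha_tot: float
    rho: float
    c: float
    v_over_a: float

    def __post_init__(self) -> None:
        for name in ("alpha_tot", "rho", "c", "v_over_a"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def exact_cooling(state: CoolingState, t):
    """Exact Newtonian cooling temperature at elapsed time ``t``.

    T(t) = T_a + (T_0 - T_a) * exp(-k * t)

    ``t`` may be a scalar or array; negative elapsed times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("elapsed time t must be >= 0")
    out = state.t_ambient + (state.t0 - state.t_ambient) * np.exp(-state.k * t)
    return float(out) if out.ndim == 0 else out


def estimate_rdk(t_day, t_night, delta_t=DEFAULT_DELTA_T_HOURS, *,
                 mask_warm_nights: bool = False, warn: bool = True):
    """Per-pair thermal decay rate, ln(T_day/T_night)/delta_t.

    Temperatures must be Kelvin.  NaN inputs propagate to NaN.  Warm
    nights (T_night > T_day) yield negative rates, which are returned as
    is (and flagged via :class:`WarmNightWarning`) unless
    ``mask_warm_nights`` converts them to NaN.

    Raises
    ------
    ValueError
        If any finite temperature or ``delta_t`` is non-positive.
    """
    t_day = np.asarray(t_day, dtype=float)
    t_night = np.asarray(t_night, dtype=float)
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t <= 0):
        raise ValueError("delta_t must be positive")
    finite = np.isfinite(t_day) & np.isfinite(t_night)
    if np.any(finite & (t_day <= 0)) or np.any(finite & (t_night <= 0)):
        raise ValueError("temperatures must be positive (Kelvin scale)")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.log(t_day / t_night) / delta_t
    warm = finite & (t_night > t_day)
    if np.any(warm):
        if warn:
            frac = float(np.mean(warm[finite])) if warm.ndim else 1.0
            warnings.warn(
                f"warm-night pairs (T_night > T_day): fraction {frac:.3f}; "
                "negative decay rates returned",
                WarmNightWarning,
                stacklevel=2,
            )
        if mask_warm_nights:
            r = np.where(warm, np.nan, r)
    return float(r) if r.ndim == 0 else r


def estimate_rdk_pair(pair: TemperaturePair, **kw) -> float:
    """:func:`estimate_rdk` on one :class:`TemperaturePair` (NaN if invalid)."""
    if not pair.valid:
        return float("nan")
    return estimate_rdk(pair.t_day, pair.t_night, pair.delta_t, **kw)


def annual_mean_rdk(
    pairs: Sequence[TemperaturePair],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    period: str = "",
    *,
    mask_warm_nights: bool = False,
) -> DecayRateEstimate:
    """Arithmetic mean of per-pair decay rates over the valid pairs.

    Invalid (cloudy/missing) pairs are excluded.  If fewer than
    ``min_pairs`` valid pairs remain, ``rdk`` is NaN but ``n_pairs`` still
    records the count.
    """
    rates = []
    warm = 0
    for p in pairs:
        if not p.valid:
            continue
        r = estimate_rdk(p.t_day, p.t_night, p.delta_t, warn=False,
                         mask_warm_nights=mask_warm_nights)
        if p.t_night > p.t_day:
            warm += 1
        rates.append(r)
    n = len(rates)
    wfrac = warm / n if n else 0.0
    finite = [r for r in rates if np.isfinite(r)]
    if len(finite) < min_pairs:
        return DecayRateEstimate(float("nan"), n_pairs=len(finite),
                                 period=period, warm_night_fraction=wfrac)
    return DecayRateEstimate(float(np.mean(finite)), n_pairs=len(finite),
                             period=period, warm_night_fraction=wfrac)


def theoretical_rdk(props: ThermalProperties) -> float:
    """Decay rate implied by bulk thermal properties.

    R_dk = alpha_tot / (rho * c * (V/A)): increasing linearly with the
    heat transfer coefficient and inversely with each thermal-mass factor.
    """
    return props.alpha_tot / (props.rho * props.c * props.v_over_a)


def approximation_bias(state: CoolingState, delta_t: float) -> float:
    """Bias of the ratio estimator on one exact cooling trajectory.

    Samples the exact solution at elapsed times 0 and ``delta_t``, applies
    the ln-ratio estimator, and returns (estimate - true k).  Exactly zero
    when ``t_ambient == 0``; otherwise negative (the estimator understates
    the decay rate because the neglected ambient term keeps the night
    temperature above the pure exponential), with magnitude growing with
    ``t_ambient / t0``.
    """
    if not delta_t > 0:
        raise ValueError("delta_t must be positive")
    t_d = exact_cooling(state, 0.0)
    t_n = exact_cooling(state, delta_t)
    return estimate_rdk(t_d, t_n, delta_t, warn=False) - state.k


def dtr(pair: TemperaturePair) -> float:
    """Diurnal temperature range of one pair: T_day - T_night, Kelvin."""
    if not pair.valid:
        return float("nan")
    return pair.t_day - pair.t_night


def annual_mean_dtr(
    pairs: Sequence[TemperaturePair],
    min_pairs: int = DEFAULT_MIN_PAIRS,
    period: str = "",
) -> DecayRateEstimate:
    """Annual mean DTR under the same averaging contract as the decay rate."""
    vals = [dtr(p) for p in pairs if p.valid]
    finite = [v for v in vals if np.isfinite(v)]
    if len(finite) < min_pairs:
        return DecayRateEstimate(float("nan"), n_pairs=len(finite), period=period)
    return DecayRateEstimate(float(np.mean(finite)), n_pairs=len(finite), period=period)
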