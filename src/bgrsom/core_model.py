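"""Forward model of fresh-organic-matter (FOM) decay during incubation.

Carbon added with a biogas residue (BGR) is treated as a single FOM pool
decaying by first-order kinetics on the Biological Active Time (BAT) axis.
Two parameters characterize a residue:

``k``
    turnover coefficient (BAT-day⁻¹): first-order decay rate of the FOM.
``eta`` (η)
    synthesis coefficient (dimensionless, in [0, 1]): the fraction of
    decomposed FOM carbon transferred into the active soil-organic-matter
    pool (the carbon reproduction flux, C_rep). The complement ``1 - eta``
    is respired as CO₂.

Soil-specific biological activity enters only through a multiplicative
``bat_factor`` (BAT-days per calendar day), so doubling the factor is
exactly equivalent to doubling ``k``.

All quantities are expressed as fractions of the carbon added, and time is
continuous in days; evaluation is closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TurnoverParams",
    "SoilContext",
    "IncubationCurve",
    "InvalidParameterError",
    "cumulative_mineralization",
    "fom_remaining",
    "crep_fraction",
]


class InvalidParameterError(ValueError):
    """Raised when turnover parameters are outside their physical domain."""


@dataclass(frozen=True)
class TurnoverParams:
    """Fitted (k, η) pair with optional uncertainty.

    Parameters
    ----------
    k : float
        Turnover coefficient, per BAT-day; must be > 0 and finite.
    eta : float
        Synthesis coefficient, fraction in [0, 1].
    sd_k, sd_eta : float, optional
        Standard deviations of the fitted parameters (≥ 0 when present).
    cov_k_eta : float, optional
        Covariance between the two estimates.
    """

    k: float
    eta: float
    sd_k: Optional[float] = None
    sd_eta: Optional[float] = None
    cov_k_eta: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k) and np.isfinite(self.eta)):
            raise InvalidParameterError(
                f"non-finite parameters k={self.k}, eta={self.eta}"
            )
        if self.k <= 0:
            raise InvalidParameterError(f"k must be > 0, got {self.k}")
        if not 0.0 <= self.eta <= 1.0:
            raise InvalidParameterError(f"eta must be in [0, 1], got {self.eta}")
        for name in ("sd_k", "sd_eta"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise InvalidParameterError(f"{name} must be ≥ 0, got {v}")


@dataclass(frozen=True)
class SoilContext:
    """Incubation soil with its biological-activity multiplier.

    ``bat_factor`` is the number of BAT-days elapsing per calendar day under
    the incubation conditions. It defaults to 1.0, in which case fitted k
    values are effective rates on the calendar-day axis.
    """

    soil_id: str
    bat_factor: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.bat_factor) or self.bat_factor <= 0:
            raise InvalidParameterError(
                f"bat_factor must be > 0, got {self.bat_factor}"
            )


@dataclass
class IncubationCurve:
    """Mean cumulative mineralization curve for one BGR–soil combination.

    ``values`` are cumulative net CO₂-C emissions as a fraction of added
    carbon; ``variances`` is the total variance of each mean value. Raw
    noise may make observed values dip; monotonicity is enforced only on
    model output, never on data.
    """

    times: np.ndarray
    values: np.ndarray
    variances: np.ndarray
    bgr_id: str = ""
    soil_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.times) == len(self.values) == len(self.variances)):
            raise ValueError("times, values and variances must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("observation times must be ≥ 0")
        if np.any(self.variances < 0):
            raise ValueError("variances must be ≥ 0")

    def __len__(self) -> int:
        return len(self.times)


def _bat_times(times, soil: SoilContext) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError(f"times must be ≥ 0, got min {t.min()}")
    return t * soil.bat_factor


def fom_remaining(params: TurnoverParams, times, soil: SoilContext) -> np.ndarray:
    """Fraction of added FOM carbon still undecomposed at each time.

    Closed form ``exp(-k·b·t)`` with ``b = soil.bat_factor``; always in
    (0, 1].
    """
    tb = _bat_times(times, soil)
    return np.exp(-params.k * tb)


def cumulative_mineralization(
    params: TurnoverParams,
    times,
    soil: SoilContext,
    active_turnover: float = 0.0,
) -> np.ndarray:
    """Cumulative CO₂-C emitted as a fraction of added carbon.

    One-pool closed form ``m(t) = (1 - η)(1 - exp(-k·b·t))``: non-decreasing,
    m(0) = 0, supremum ``1 - η``.

    ``active_turnover`` (κ, per BAT-day) optionally remineralizes the newly
    formed active SOM; it defaults to 0 because within the ≤ 41-day
    incubation window the active pool turns over orders of magnitude slower
    than the FOM itself, and the observed emission asymptote matches
    ``1 - η``.
    """
    tb = _bat_times(times, soil)
    if active_turnover < 0:
        raise InvalidParameterError("active_turnover must be ≥ 0")
    base = (1.0 - params.eta) * (1.0 - np.exp(-params.k * tb))
    if active_turnover == 0.0:
        return base
    # mass balance: emitted = 1 - FOM - active
    return 1.0 - np.exp(-params.k * tb) - _active_pool(params, tb, active_turnover)


def crep_fraction(
    params: TurnoverParams,
    times,
    soil: SoilContext,
    active_turnover: float = 0.0,
) -> np.ndarray:
    """Carbon reproduction flux: FOM-derived carbon residing in active SOM.

    With the default ``active_turnover = 0`` this is ``η(1 - exp(-k·b·t))``,
    and at every t the three fluxes conserve carbon:
    ``fom_remaining + crep_fraction + cumulative_mineralization = 1``.
    """
    tb = _bat_times(times, soil)
    if active_turnover == 0.0:
        return params.eta * (1.0 - np.exp(-params.k * tb))
    return _active_pool(params, tb, active_turnover)


def _active_pool(params: TurnoverParams, tb: np.ndarray, kappa: float) -> np.ndarray:
    """Active-pool content under FOM inflow η·k·e^{-kt} and decay κ."""
    k = params.k
    if abs(kappa - k) < 1e-12 * max(k, 1.0):
        return params.eta * k * tb * np.exp(-k * tb)
    return params.eta * k / (kappa - k) * (np.exp(-k * tb) - np.exp(-kappa * tb))
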