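"""Synthetic incubation datasets and digestate panels.

The raw replicate measurements behind the study's incubation curves are
not distributed with the package, so this module generates datasets with
the same statistical structure: the standard observation schedule (daily
on days 1–20, then days 22, 24, 27, 30, 34, 36, 41), four replicates of
each amended jar, separate unamended controls measured on a sparser
schedule, a polynomial basal-respiration term shared by samples and
controls, and additive Gaussian noise on the per-step increments.

Every generator is deterministic under its seed; the same spec and seed
reproduce the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import SoilContext, TurnoverParams, cumulative_mineralization
from .incubation_prep import RawSeries
from .property_regression import BGRProperties

__all__ = [
    "STANDARD_SCHEDULE",
    "SyntheticSpec",
    "generate_incubation",
    "generate_bgr_panel",
    "raw_series_to_frame",
]

#: daily days 1–20 followed by the sparse tail of the six-week incubation
STANDARD_SCHEDULE = tuple(range(1, 21)) + (22, 24, 27, 30, 34, 36, 41)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic incubation experiment.

    ``true_params`` maps BGR ids to their generating (k, η); ``soils`` maps
    soil ids to BAT factors. ``noise_sd`` is the standard deviation of the
    additive Gaussian measurement noise per observation, in fraction-of-
    added-carbon units. ``noise_on`` places that noise either on each
    replicate's cumulative emission reading ("cumulative", the default:
    every sampling re-measures the accumulated CO₂, so errors are
    independent across observation times — the structure the downstream
    variance and Fisher-information machinery assumes) or on the per-step
    increments ("increments": trap-exchange designs, where cumulative
    errors accumulate as a random walk). ``control_poly`` gives the
    coefficients (ascending powers of day) of the basal daily respiration
    flux shared by amended and control jars. Controls are observed every
    ``control_stride`` days to exercise the interpolation path.
    """

    true_params: dict
    soils: dict = field(default_factory=lambda: {"silty": 1.0, "sandy": 1.0})
    schedule: tuple = STANDARD_SCHEDULE
    replicates: int = 4
    noise_sd: float = 0.005
    noise_on: str = "cumulative"
    control_poly: tuple = (2e-4, 1e-4, -2e-6)
    control_stride: int = 4
    added_carbon: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be ≥ 0")
        if self.replicates < 2:
            raise ValueError("need ≥ 2 replicates")
        if self.noise_on not in ("cumulative", "increments"):
            raise ValueError("noise_on must be 'cumulative' or 'increments'")

    @property
    def control_days(self) -> np.ndarray:
        last = int(max(self.schedule))
        return np.arange(self.control_stride, last + 1, self.control_stride, dtype=float)


def _basal_cumulative(days: np.ndarray, coeffs: Sequence[float]) -> np.ndarray:
    """Cumulative basal respiration B(d) = ∫₀ᵈ Σ cᵢ·xⁱ dx."""
    integ = [0.0] + [c / (i + 1) for i, c in enumerate(coeffs)]
    return np.polyval(integ[::-1], days)


def _steps_with_noise(
    cum_signal: np.ndarray, days: np.ndarray, sd: float, noise_on: str, rng
) -> np.ndarray:
    """Per-step observed CO₂ given the noise placement."""
    if noise_on == "cumulative":
        noisy = cum_signal + rng.normal(0.0, sd, len(days))
        return np.diff(np.concatenate([[0.0], noisy]))
    inc = np.diff(np.concatenate([[0.0], cum_signal]))
    return inc + rng.normal(0.0, sd, len(days))


def generate_incubation(spec: SyntheticSpec) -> list[RawSeries]:
    """Generate amended-jar and control replicates for every BGR × soil.

    Each amended jar's cumulative emission is the model curve (times the
    added carbon) plus the cumulative basal term; controls carry the basal
    term alone on their sparser schedule. Measurement noise is placed
    according to ``spec.noise_on``; per-step co2 values are the differences
    of consecutive readings, so cumulating them downstream reproduces the
    jar's reading sequence exactly.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.schedule, dtype=float)
    sd = spec.noise_sd * spec.added_carbon
    out: list[RawSeries] = []
    for soil_id, bat in sorted(spec.soils.items()):
        soil = SoilContext(soil_id, bat)
        basal_cum = _basal_cumulative(days, spec.control_poly) * spec.added_carbon
        for bgr_id, params in sorted(spec.true_params.items()):
            cum = cumulative_mineralization(params, days, soil) * spec.added_carbon
            for r in range(spec.replicates):
                co2 = _steps_with_noise(cum + basal_cum, days, sd, spec.noise_on, rng)
                out.append(
                    RawSeries(
                        bgr_id, soil_id, f"r{r + 1}", days, co2,
                        is_control=False, units="mass",
                    )
                )
        cdays = spec.control_days
        ccum = _basal_cumulative(cdays, spec.control_poly) * spec.added_carbon
        for r in range(spec.replicates):
            co2 = _steps_with_noise(ccum, cdays, sd, spec.noise_on, rng)
            out.append(
                RawSeries(
                    "control", soil_id, f"r{r + 1}", cdays, co2,
                    is_control=True, units="mass",
                )
            )
    return out


def raw_series_to_frame(series: Sequence[RawSeries]) -> pd.DataFrame:
    """Tidy long frame matching the preprocessing module's CSV schema."""
    rows = [
        {
            "bgr": s.bgr_id, "soil": s.soil_id, "replicate": s.replicate_id,
            "day": d, "co2": v, "is_control": s.is_control, "units": s.units,
        }
        for s in series
        for d, v in zip(s.days, s.co2)
    ]
    return pd.DataFrame(rows)


#: default property ranges spanning the study digestates and the wider
#: literature (pH 7.2–9.3, C_t/N_org 5.9–26.4)
DEFAULT_RANGES = {
    "dm": (5.0, 10.0),
    "dm_org": (27.0, 35.0),
    "ph": (7.2, 9.3),
    "ct": (38.0, 44.0),
    "nt": (5.0, 8.5),
    "nh4n_frac_of_nt": (0.3, 0.7),   # keeps nt > nh4n by construction
}

#: generating pedotransfer relations: k from pH, η from C_t/N_org
DEFAULT_TRUTH = {
    "k": ("ph", -0.710, 5.996),
    "eta": ("ct_norg", -0.013, 1.016),
}


def generate_bgr_panel(
    n: int,
    property_ranges: Optional[dict] = None,
    regression_truth: Optional[dict] = None,
    residual_sd: float = 0.0,
    seed: int = 0,
):
    """Draw a panel of digestates with parameters tied to their chemistry.

    Properties are uniform within their ranges; ammonium is drawn as a
    fraction of total N so organic N stays positive. True k and η follow
    the configured linear relations plus Gaussian residuals
    (``residual_sd`` may be a scalar applied to both or a dict per
    parameter). k is floored at 0.01 and η clipped to [0, 1].

    Returns ``(list[BGRProperties], DataFrame)`` with the parameter frame
    indexed by bgr_id (columns k, eta).
    """
    from .property_regression import derive_ratios

    ranges = dict(DEFAULT_RANGES, **(property_ranges or {}))
    truth = dict(DEFAULT_TRUTH, **(regression_truth or {}))
    if np.isscalar(residual_sd):
        residual_sd = {"k": float(residual_sd), "eta": float(residual_sd)}
    rng = np.random.default_rng(seed)
    props, rows = [], []
    for i in range(n):
        u = {key: rng.uniform(*bounds) for key, bounds in ranges.items()}
        nh4n = u.pop("nh4n_frac_of_nt") * u["nt"]
        p = derive_ratios(
            BGRProperties(bgr_id=f"S{i + 1:03d}", nh4n=nh4n, **u)
        )
        props.append(p)
        row = {"bgr_id": p.bgr_id}
        for param in ("k", "eta"):
            prop_name, slope, intercept = truth[param]
            val = slope * getattr(p, prop_name) + intercept
            val += rng.normal(0.0, residual_sd[param])
            row[param] = val
        row["k"] = max(row["k"], 0.01)
        row["eta"] = min(max(row["eta"], 0.0), 1.0)
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("bgr_id")
    return props, frame
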