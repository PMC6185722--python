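"""Preprocessing of raw incubation CO₂ measurements.

Amended jars and unamended controls are incubated in parallel (four
replicates each); the controls are measured on a sparser schedule, so the
missing control values are interpolated with a least-squares polynomial.
Per observation step, the control value is subtracted from each amended
replicate, the net increments are cumulated, normalized by the added
carbon, and the replicates are aggregated into a mean cumulative
mineralization curve with a per-timepoint total variance. Only the daily
window (days ≤ 20 by default) is kept for parameter fitting.

Negative net increments are retained, not clipped: zeroing them would bias
the cumulative curve upward and hence the fitted parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import IncubationCurve

__all__ = [
    "RawSeries",
    "AlignmentError",
    "interpolate_control",
    "net_mineralization",
    "aggregate_replicates",
    "truncate_to_window",
    "read_raw_csv",
    "write_curves_csv",
    "prepare_curves",
]


class AlignmentError(ValueError):
    """Sample and control observations are not on the same day grid."""


@dataclass
class RawSeries:
    """One replicate jar's CO₂-C evolution per observation step.

    ``co2`` holds the per-step (not cumulative) CO₂-C, either as mass per
    jar or already as fraction of added carbon; ``units`` declares which
    ("mass" or "fraction").
    """

    bgr_id: str
    soil_id: str
    replicate_id: str
    days: np.ndarray
    co2: np.ndarray
    is_control: bool = False
    units: str = "mass"

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        if len(self.days) != len(self.co2):
            raise ValueError("days and co2 must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.co2)):
            raise ValueError("co2 values must be finite")


@dataclass
class ControlFit:
    """Polynomial fitted to the control mean, with prediction variance."""

    values: np.ndarray
    variances: np.ndarray
    degree: int
    day_range: tuple


def interpolate_control(
    controls: Sequence[RawSeries],
    target_days: Sequence[float],
    degree: int = 3,
) -> ControlFit:
    """Fit a polynomial to the mean control flux and evaluate it.

    A least-squares polynomial of the given degree is fitted to the mean of
    the control replicates at their (sparser) observation days and
    evaluated at ``target_days``. Extrapolation beyond the observed control
    range by more than one scheduled interval is refused.

    Returns the fitted values together with the OLS prediction variance of
    each fitted value (from the polynomial design matrix), used downstream
    in the total-variance budget.
    """
    if degree < 1:
        raise ValueError("degree must be ≥ 1")
    if not controls:
        raise ValueError("need at least one control series")
    days = controls[0].days
    for c in controls[1:]:
        if not np.array_equal(c.days, days):
            raise AlignmentError("control replicates must share one day grid")
    if len(np.unique(days)) < degree + 1:
        raise ValueError(
            f"polynomial degree {degree} needs ≥ {degree + 1} distinct control "
            f"days, got {len(np.unique(days))}"
        )
    mean_control = np.mean([c.co2 for c in controls], axis=0)

    target = np.asarray(target_days, dtype=float)
    intervals = np.diff(days)
    slack = float(intervals.max()) if len(intervals) else 0.0
    lo, hi = float(days.min()) - slack, float(days.max()) + slack
    if np.any(target < lo) or np.any(target > hi):
        raise ValueError(
            f"target days outside control range [{days.min()}, {days.max()}] "
            f"by more than one interval ({slack} d)"
        )

    # centered/scaled Vandermonde for conditioning
    scale = max(float(days.max()), 1.0)
    X = np.vander(days / scale, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, mean_control, rcond=None)
    resid = mean_control - X @ coef
    dof = len(days) - (degree + 1)
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    XtX_inv = np.linalg.pinv(X.T @ X)
    X0 = np.vander(target / scale, degree + 1, increasing=True)
    pred = X0 @ coef
    pred_var = s2 * np.einsum("ij,jk,ik->i", X0, XtX_inv, X0)
    return ControlFit(pred, np.maximum(pred_var, 0.0), degree, (lo, hi))


def net_mineralization(sample: RawSeries, control_at_days: np.ndarray) -> np.ndarray:
    """Sample minus control per time step; negatives are kept (noise)."""
    control_at_days = np.asarray(control_at_days, dtype=float)
    if len(control_at_days) != len(sample.days):
        raise AlignmentError(
            f"control values ({len(control_at_days)}) do not align with "
            f"sample days ({len(sample.days)})"
        )
    return sample.co2 - control_at_days


def aggregate_replicates(
    net_series: Sequence[np.ndarray],
    days: Sequence[float],
    added_carbon: float,
    control_variances: Optional[np.ndarray] = None,
    bgr_id: str = "",
    soil_id: str = "",
) -> IncubationCurve:
    """Cumulate net increments per replicate and aggregate across replicates.

    Each replicate's net increments are cumulated and normalized by the
    added carbon. The curve value is the replicate mean; its total variance
    is the sample variance (ddof = 1) of the replicate cumulative values at
    that timepoint — the between-jar scatter, deliberately not divided by
    the replicate count, so it remains a conservative per-observation error
    scale — plus the prediction variance of the fitted cumulative control
    at that day.
    """
    if added_carbon <= 0:
        raise ValueError("added_carbon must be > 0")
    if len(net_series) < 2:
        raise ValueError("need ≥ 2 replicates to define a variance")
    days = np.asarray(days, dtype=float)
    cum = np.vstack([np.cumsum(np.asarray(s, float)) for s in net_series])
    if cum.shape[1] != len(days):
        raise AlignmentError("replicates and day grid have unequal lengths")
    cum /= added_carbon
    mean = cum.mean(axis=0)
    var = cum.var(axis=0, ddof=1)
    if control_variances is not None:
        var = var + np.asarray(control_variances, float) / added_carbon**2
    return IncubationCurve(days, mean, var, bgr_id=bgr_id, soil_id=soil_id)


def truncate_to_window(curve: IncubationCurve, max_day: int = 20) -> IncubationCurve:
    """Keep only observations with day ≤ ``max_day`` (daily window)."""
    keep = curve.times <= max_day
    if not np.any(keep):
        raise ValueError(f"no observations at or before day {max_day}")
    return IncubationCurve(
        curve.times[keep],
        curve.values[keep],
        curve.variances[keep],
        bgr_id=curve.bgr_id,
        soil_id=curve.soil_id,
    )


# ---------------------------------------------------------------------------
# tidy CSV interface


def read_raw_csv(path) -> list[RawSeries]:
    """Read a tidy long CSV (bgr, soil, replicate, day, co2, is_control)."""
    df = pd.read_csv(path)
    required = {"bgr", "soil", "replicate", "day", "co2", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw CSV missing columns: {sorted(missing)}")
    units = str(df["units"].iloc[0]) if "units" in df.columns else "mass"
    out = []
    for (bgr, soil, rep, ctrl), grp in df.groupby(
        ["bgr", "soil", "replicate", "is_control"], sort=True
    ):
        grp = grp.sort_values("day")
        out.append(
            RawSeries(
                str(bgr), str(soil), str(rep),
                grp["day"].to_numpy(), grp["co2"].to_numpy(),
                is_control=bool(ctrl), units=units,
            )
        )
    return out


def write_curves_csv(curves: Iterable[IncubationCurve], path) -> None:
    rows = [
        {
            "bgr": c.bgr_id, "soil": c.soil_id, "day": t,
            "mean_cum_fraction": v, "variance": s,
        }
        for c in curves
        for t, v, s in zip(c.times, c.values, c.variances)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def prepare_curves(
    series: Sequence[RawSeries],
    added_carbon: float = 1.0,
    degree: int = 3,
    max_day: int = 20,
) -> list[IncubationCurve]:
    """Full preprocessing pipeline: control fit → subtraction → aggregation.

    Controls are matched to samples by soil. The polynomial is fitted to
    the cumulated control mean and differenced back to per-step control
    increments on each sample's day grid, so subtracting control per step
    and cumulating equals subtracting the fitted cumulative control — the
    interpolation error enters each curve value once instead of being
    accumulated over the window.
    """
    controls: dict[str, list[RawSeries]] = {}
    samples: dict[tuple, list[RawSeries]] = {}
    for s in series:
        if s.is_control:
            controls.setdefault(s.soil_id, []).append(s)
        else:
            samples.setdefault((s.bgr_id, s.soil_id), []).append(s)
    curves = []
    for (bgr, soil), reps in sorted(samples.items()):
        if soil not in controls:
            raise ValueError(f"no control series for soil {soil!r}")
        days = reps[0].days
        for r in reps[1:]:
            if not np.array_equal(r.days, days):
                raise AlignmentError(f"replicates of {bgr}/{soil} disagree on days")
        cum_controls = [
            RawSeries(
                c.bgr_id, c.soil_id, c.replicate_id, c.days, np.cumsum(c.co2),
                is_control=True, units=c.units,
            )
            for c in controls[soil]
        ]
        grid = np.concatenate([[0.0], days])
        ctrl = interpolate_control(cum_controls, grid, degree=degree)
        ctrl_steps = np.diff(ctrl.values)
        nets = [net_mineralization(r, ctrl_steps) for r in reps]
        curve = aggregate_replicates(
            nets, days, added_carbon, control_variances=ctrl.variances[1:],
            bgr_id=bgr, soil_id=soil,
        )
        curves.append(truncate_to_window(curve, max_day=max_day))
    return curves
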