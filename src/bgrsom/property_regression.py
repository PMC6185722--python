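"""Pedotransfer-style regressions: turnover parameters from BGR chemistry.

An incubation takes six weeks; a chemical characterization of a digestate
takes a day. If the fitted turnover parameters can be predicted from
routinely measured properties — dry matter, carbon and nitrogen fractions,
pH — then model parameterization no longer requires the incubation. Each
candidate property is screened with a simple linear regression
f(x) = m·x + n against each parameter, the best predictor is selected by
R², and a multiple regression is only permitted when the candidate
predictors are mutually uncorrelated (all pairwise |r| below a threshold).

Predicted parameters carry a star (k*, η*) and an OLS prediction standard
error; predictions outside the calibration range are flagged as
extrapolation, not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BGRProperties",
    "RegressionResult",
    "ModelSelection",
    "PROPERTY_ORDER",
    "derive_ratios",
    "fit_simple_regression",
    "screen_predictors",
    "select_model",
    "predict_parameters",
    "range_coverage",
]

# canonical screening order; also the documented tie-break on equal R²
PROPERTY_ORDER = (
    "dm", "dm_org", "ct", "nh4n", "norg", "nt", "ct_nt", "ct_norg", "ph",
)


@dataclass
class BGRProperties:
    """Chemistry of one digestate (concentrations in % of dry matter).

    ``norg`` (organic nitrogen), ``ct_nt`` and ``ct_norg`` are derived via
    :func:`derive_ratios`; ``norg = nt − nh4n``.
    """

    bgr_id: str
    dm: float            # dry matter, % fresh mass
    dm_org: float        # organic dry matter, %
    ph: float
    ct: float            # total carbon, % DM
    nh4n: float          # ammonium nitrogen, % DM
    nt: float            # total Kjeldahl nitrogen, % DM
    norg: Optional[float] = None
    ct_nt: Optional[float] = None
    ct_norg: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("dm", "dm_org", "ct", "nh4n", "nt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not 0 < self.ph < 14:
            raise ValueError(f"pH must be in (0, 14), got {self.ph}")


def derive_ratios(props: BGRProperties) -> BGRProperties:
    """Complete a property record with N_org = N_t − NH₄-N and the C/N ratios."""
    norg = props.nt - props.nh4n
    if norg <= 0:
        raise ValueError(
            f"{props.bgr_id}: N_t ({props.nt}) must exceed NH4-N ({props.nh4n})"
        )
    return replace(
        props, norg=norg, ct_nt=props.ct / props.nt, ct_norg=props.ct / norg
    )


@dataclass
class RegressionResult:
    """One simple linear fit y = m·x + n with its calibration statistics."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    # calibration data statistics needed for the prediction standard error
    x_mean: float = np.nan
    x_ss: float = np.nan          # Σ(x − x̄)²
    resid_var: float = np.nan     # residual variance, ddof = 2
    x_min: float = np.nan
    x_max: float = np.nan

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept

    def prediction_se(self, x: float) -> float:
        """Standard error of a new prediction at x (OLS prediction interval)."""
        return float(
            np.sqrt(
                self.resid_var
                * (1.0 + 1.0 / self.n_points + (x - self.x_mean) ** 2 / self.x_ss)
            )
        )


def fit_simple_regression(x, y, predictor_name: str = "") -> RegressionResult:
    """Ordinary least squares of y on a single predictor x.

    R² is the squared Pearson correlation; the p-value is the two-sided
    t-test on the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need ≥ 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor {predictor_name!r}: singular design")
    res = stats.linregress(x, y)
    n = len(x)
    resid = y - (res.slope * x + res.intercept)
    return RegressionResult(
        predictor=predictor_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=n,
        x_mean=float(x.mean()),
        x_ss=float(np.sum((x - x.mean()) ** 2)),
        resid_var=float(resid @ resid / (n - 2)),
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def _property_frame(props: Sequence[BGRProperties]) -> pd.DataFrame:
    rows = []
    for p in props:
        if p.ct_norg is None:
            p = derive_ratios(p)
        rows.append({name: getattr(p, name) for name in ("bgr_id",) + PROPERTY_ORDER})
    return pd.DataFrame(rows).set_index("bgr_id")


def screen_predictors(
    props: Sequence[BGRProperties],
    params: pd.DataFrame,
) -> pd.DataFrame:
    """Regress each parameter on each property; one row per (parameter, property).

    ``params`` must be indexed by bgr_id with columns ``k`` and ``eta``.
    Rows are sorted by parameter then descending R² (ties resolved by the
    canonical property order).
    """
    X = _property_frame(props)
    missing = set(X.index) ^ set(params.index)
    if missing:
        raise ValueError(f"property/parameter tables disagree on BGRs: {sorted(missing)}")
    X = X.loc[params.index]
    rows = []
    for target in ("k", "eta"):
        y = params[target].to_numpy()
        for rank, prop in enumerate(PROPERTY_ORDER):
            x = X[prop].to_numpy()
            if np.ptp(x) == 0:
                continue  # constant property carries no information
            r = fit_simple_regression(x, y, predictor_name=prop)
            rows.append(
                {
                    "parameter": target, "property": prop, "slope": r.slope,
                    "intercept": r.intercept, "r_squared": r.r_squared,
                    "p_value": r.p_value, "_order": rank, "_result": r,
                }
            )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["parameter", "r_squared", "_order"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


@dataclass
class ModelSelection:
    """Chosen single-predictor models and the multiple-regression verdict."""

    k_model: RegressionResult
    eta_model: RegressionResult
    multiple_allowed: bool
    blocking_correlations: list  # [(prop_a, prop_b, r), ...] with |r| ≥ threshold
    collinearity_threshold: float


def select_model(
    screen: pd.DataFrame,
    props: Sequence[BGRProperties],
    collinearity_threshold: float = 0.4,
) -> ModelSelection:
    """Pick the top-R² predictor per parameter; gate the multiple regression.

    A multiple regression combining the two chosen predictors is offered
    only if every pairwise correlation among them (and with N_org, the
    runner-up in both screens) stays below the threshold in absolute value;
    otherwise it is refused and the offending correlations are reported.
    """
    top = {
        target: screen[screen["parameter"] == target].iloc[0]["_result"]
        for target in ("k", "eta")
    }
    X = _property_frame(props)
    candidates = sorted({top["k"].predictor, top["eta"].predictor, "norg"})
    blocking = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            r = float(np.corrcoef(X[a], X[b])[0, 1])
            if abs(r) >= collinearity_threshold:
                blocking.append((a, b, r))
    return ModelSelection(
        k_model=top["k"],
        eta_model=top["eta"],
        multiple_allowed=not blocking,
        blocking_correlations=blocking,
        collinearity_threshold=collinearity_threshold,
    )


def predict_parameters(
    props: BGRProperties,
    k_model: RegressionResult,
    eta_model: RegressionResult,
    k_floor: float = 0.01,
):
    """Predict (k*, η*) for a new digestate from the fitted models.

    η* is clamped to [0, 1] and k* floored at ``k_floor`` (a vanishing or
    negative decay rate is physically meaningless). Returns the prediction
    and a list of extrapolation warnings for properties outside the
    calibration range.

    The import of :class:`~bgrsom.core_model.TurnoverParams` is local to
    avoid a cycle at module import time.
    """
    from .core_model import TurnoverParams

    if props.ct_norg is None:
        props = derive_ratios(props)
    warnings = []
    values = {}
    for label, model in (("k", k_model), ("eta", eta_model)):
        x = getattr(props, model.predictor)
        if not model.x_min <= x <= model.x_max:
            warnings.append(
                f"{label}: {model.predictor} = {x} outside calibration range "
                f"[{model.x_min}, {model.x_max}] (extrapolation)"
            )
        values[label] = (model.predict(x), model.prediction_se(x))
    k_star = max(values["k"][0], k_floor)
    eta_star = min(max(values["eta"][0], 0.0), 1.0)
    params = TurnoverParams(
        k=k_star, eta=eta_star, sd_k=values["k"][1], sd_eta=values["eta"][1]
    )
    return params, warnings


def range_coverage(study_values, reference_min: float, reference_max: float) -> float:
    """Percent of a literature reference range spanned by the study values."""
    study = np.asarray(study_values, dtype=float)
    if study.size == 0:
        raise ValueError("study values must be non-empty")
    if reference_max <= reference_min:
        raise ValueError("reference range must have positive width")
    return float(100.0 * np.ptp(study) / (reference_max - reference_min))
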