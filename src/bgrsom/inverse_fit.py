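"""Inverse estimation of the turnover parameters (k, η).

For each BGR–soil combination the pair (k, η) is found by minimizing the
root mean square error (RMSE) between observed and modeled cumulative
mineralization with a Nelder–Mead simplex search. The search runs in a
transformed space (log k, logit η) so the physical constraints k > 0 and
η ∈ [0, 1] hold by construction. Parameter uncertainty comes from the
Fisher Information Matrix (FIM): the sensitivity of the model output at
each observation point weighted by the inverse measurement variance.

The objective is the unweighted RMSE while the FIM uses the measured
variances — an intentional asymmetry: the point estimate treats every
observation alike, the uncertainty honors the error budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .core_model import IncubationCurve, SoilContext, TurnoverParams

__all__ = [
    "FitResult",
    "FitConfig",
    "UnidentifiableError",
    "rmse",
    "fit_parameters",
    "fim_uncertainty",
    "pool_across_soils",
]


class UnidentifiableError(RuntimeError):
    """The data do not constrain the parameters (flat curve, singular FIM)."""


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the simplex search and the FIM finite differences."""

    k_init: float = 0.3
    eta_init: float = 0.8
    n_restarts: int = 2          # extra starts besides (k_init, eta_init)
    max_iter: int = 2000
    fatol: float = 1e-10         # objective convergence
    xatol: float = 1e-8          # simplex size convergence
    fd_rel_step: float = 1e-5    # central-difference relative step for the FIM


@dataclass
class FitResult:
    params: TurnoverParams
    rmse: float
    n_obs: int
    converged: bool
    objective_evaluations: int
    bgr_id: str = ""
    soil_id: str = ""


def rmse(observed, modeled) -> float:
    """Root mean square error between two equal-length vectors."""
    observed = np.asarray(observed, dtype=float)
    modeled = np.asarray(modeled, dtype=float)
    if observed.shape != modeled.shape:
        raise ValueError("observed and modeled must have equal length")
    if observed.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((observed - modeled) ** 2)))


def _model(theta: np.ndarray, tb: np.ndarray) -> np.ndarray:
    # theta = (log k, logit eta); cumulative mineralization on BAT times tb
    k = np.exp(theta[0])
    eta = 1.0 / (1.0 + np.exp(-theta[1]))
    return (1.0 - eta) * (1.0 - np.exp(-k * tb))


def _to_theta(k: float, eta: float) -> np.ndarray:
    eta = min(max(eta, 1e-9), 1 - 1e-9)
    return np.array([np.log(k), np.log(eta / (1.0 - eta))])


def fit_parameters(
    curve: IncubationCurve,
    soil: SoilContext,
    init: Optional[TurnoverParams] = None,
    config: FitConfig = FitConfig(),
) -> FitResult:
    """Nelder–Mead fit of (k, η) to a cumulative mineralization curve.

    Multiple starts are tried (the configured initial guess plus
    deterministic perturbations of it); the lowest final RMSE wins, ties
    broken by the lower k. Non-convergence within the iteration budget is
    flagged on the result, and the best point found is still returned.
    """
    if len(curve) < 3:
        raise ValueError("need ≥ 3 observations to fit two parameters")
    if np.allclose(curve.values, 0.0):
        raise UnidentifiableError(
            f"flat all-zero curve for {curve.bgr_id or '?'}: (k, η) unidentifiable"
        )
    tb = curve.times * soil.bat_factor
    obs = curve.values

    def objective(theta: np.ndarray) -> float:
        return rmse(obs, _model(theta, tb))

    k0 = init.k if init is not None else config.k_init
    e0 = init.eta if init is not None else config.eta_init
    starts = [(k0, e0), (k0 * 1.8, min(e0 + 0.07, 0.99)), (k0 * 0.5, max(e0 - 0.07, 0.01))]
    starts = starts[: 1 + config.n_restarts]

    best = None
    n_evals = 0
    for k_s, e_s in starts:
        res = minimize(
            objective,
            _to_theta(k_s, e_s),
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter,
                "fatol": config.fatol,
                "xatol": config.xatol,
            },
        )
        n_evals += res.nfev
        k_hat = float(np.exp(res.x[0]))
        key = (res.fun, k_hat)
        if best is None or key < (best[0], best[1]):
            best = (res.fun, k_hat, res)
    final_rmse, k_hat, res = best
    eta_hat = float(1.0 / (1.0 + np.exp(-res.x[1])))
    return FitResult(
        params=TurnoverParams(k=k_hat, eta=eta_hat),
        rmse=float(final_rmse),
        n_obs=len(curve),
        converged=bool(res.success),
        objective_evaluations=n_evals,
        bgr_id=curve.bgr_id,
        soil_id=curve.soil_id,
    )


def _sensitivity(
    params: TurnoverParams,
    tb: np.ndarray,
    rel_step: float,
) -> np.ndarray:
    """Central-difference Jacobian ∂m(tᵢ)/∂(k, η) on the natural scale."""

    def m(k: float, eta: float) -> np.ndarray:
        return (1.0 - eta) * (1.0 - np.exp(-k * tb))

    hk = rel_step * max(abs(params.k), 1e-8)
    he = rel_step * max(abs(params.eta), 1e-8)
    dk = (m(params.k + hk, params.eta) - m(params.k - hk, params.eta)) / (2 * hk)
    de = (m(params.k, params.eta + he) - m(params.k, params.eta - he)) / (2 * he)
    return np.column_stack([dk, de])


def fim_uncertainty(
    fit: FitResult,
    curve: IncubationCurve,
    soil: SoilContext,
    config: FitConfig = FitConfig(),
) -> TurnoverParams:
    """Parameter standard deviations and covariance from the FIM.

    FIM = Jᵀ·diag(1/σᵢ²)·J with J the output sensitivity at each
    observation and σᵢ² the measured variance there; the covariance matrix
    of the estimates is FIM⁻¹.
    """
    if np.any(curve.variances <= 0):
        raise ValueError("all observation variances must be > 0 for the FIM")
    tb = curve.times * soil.bat_factor
    J = _sensitivity(fit.params, tb, config.fd_rel_step)
    W = 1.0 / curve.variances
    fim = J.T @ (J * W[:, None])
    cond = np.linalg.cond(fim)
    if not np.isfinite(cond) or cond > 1e12:
        eigvals, eigvecs = np.linalg.eigh(fim)
        direction = eigvecs[:, np.argmin(eigvals)]
        raise UnidentifiableError(
            "singular Fisher information: ill-determined direction "
            f"({direction[0]:+.3f}·k, {direction[1]:+.3f}·η)"
        )
    cov = np.linalg.inv(fim)
    return TurnoverParams(
        k=fit.params.k,
        eta=fit.params.eta,
        sd_k=float(np.sqrt(cov[0, 0])),
        sd_eta=float(np.sqrt(cov[1, 1])),
        cov_k_eta=float(cov[0, 1]),
    )


def pool_across_soils(fits: Sequence[TurnoverParams]) -> TurnoverParams:
    """Mean (k, η) across soils for one BGR.

    k and η characterize the residue itself — soil conditions enter only
    through BAT — so per-soil estimates are averaged. The pooled sd is
    sqrt(mean of variances)/√n (sd of the mean of independent estimates).
    """
    if len(fits) == 0:
        raise ValueError("cannot pool an empty list of fits")
    ks = np.array([f.k for f in fits])
    etas = np.array([f.eta for f in fits])
    n = len(fits)
    sd_k = sd_eta = None
    if all(f.sd_k is not None for f in fits):
        sd_k = float(np.sqrt(np.mean([f.sd_k**2 for f in fits])) / np.sqrt(n))
    if all(f.sd_eta is not None for f in fits):
        sd_eta = float(np.sqrt(np.mean([f.sd_eta**2 for f in fits])) / np.sqrt(n))
    return TurnoverParams(
        k=float(ks.mean()), eta=float(etas.mean()), sd_k=sd_k, sd_eta=sd_eta
    )
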