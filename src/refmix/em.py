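"""EM benchmark: two-component Gaussian location-scale mixture regression.

Each component m has mean mu_m(x) = d(x)'beta_m and scale
sigma_m(x) = exp(d(x)'gamma_m) with d(x) the intercept-plus-tanh-basis
design vector; the mixture weights are constants alpha_m — the structural
limitation (no covariate-dependent weights) that the mixture density
network removes.

The M-step solves the weighted Gaussian location-scale maximum-likelihood
problem per component by direct numerical optimization with analytic
gradients, warm-started at the previous iteration's coefficients, and
updates alpha_m to the mean responsibility.  The observed-data NLL is
nonincreasing across iterations — the module's central audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .basis import BasisSpec, design_matrix
from .data import LabeledDataset, StandardizationConstants
from .mixture import (
    SIGMA_FLOOR,
    MixtureParameterSurface,
    mixture_nll,
    responsibilities as posterior_responsibilities,
)
from .network import FittedModel

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class EMParameters:
    """Constant weights plus per-component mean/log-scale coefficients."""

    mean_coefficients: np.ndarray  # (M, B+1)
    logscale_coefficients: np.ndarray  # (M, B+1)
    weights: np.ndarray  # (M,), sums to 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("component weights must be positive and sum to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "mean_coefficients", np.asarray(self.mean_coefficients, dtype=float)
        )
        object.__setattr__(
            self,
            "logscale_coefficients",
            np.asarray(self.logscale_coefficients, dtype=float),
        )

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    def permuted(self, order) -> "EMParameters":
        order = list(order)
        return EMParameters(
            self.mean_coefficients[order],
            self.logscale_coefficients[order],
            self.weights[order],
        )

    def surface(self, design: np.ndarray) -> MixtureParameterSurface:
        mu = design @ self.mean_coefficients.T
        sigma = np.exp(design @ self.logscale_coefficients.T)
        alpha = np.broadcast_to(self.weights, mu.shape).copy()
        return MixtureParameterSurface(alpha, mu, np.maximum(sigma, SIGMA_FLOOR))


def e_step(
    data: LabeledDataset, params: EMParameters, spec: BasisSpec
) -> np.ndarray:
    """Posterior responsibilities pi_im, computed on the log scale."""
    surface = params.surface(design_matrix(data.covariate, spec))
    return posterior_responsibilities(surface, data.outcome)


def _weighted_nll_and_grad(coef, design, y, w):
    """Weighted Gaussian location-scale NLL in (beta, gamma), with gradient."""
    p = design.shape[1]
    beta, gamma = coef[:p], coef[p:]
    mu = design @ beta
    log_sd = design @ gamma
    log_sd = np.clip(log_sd, -30.0, 30.0)  # keeps exp representable
    sd = np.exp(log_sd)
    z = (y - mu) / sd
    nll = float(np.sum(w * (0.5 * _LOG_2PI + log_sd + 0.5 * z * z)))
    g_beta = design.T @ (w * (mu - y) / sd**2)
    g_gamma = design.T @ (w * (1.0 - z * z))
    return nll, np.concatenate([g_beta, g_gamma])


def _fit_component(design, y, w, start):
    res = minimize(
        _weighted_nll_and_grad,
        start,
        args=(design, y, w),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": 200},
    )
    return res


def m_step(
    data: LabeledDataset,
    resp: np.ndarray,
    spec: BasisSpec,
    previous: Optional[EMParameters] = None,
) -> EMParameters:
    """Weighted maximum-likelihood update of all component parameters.

    ``resp`` is the (n, M) responsibility matrix; weights update in closed
    form to the responsibility column means.  If the inner optimizer fails
    for a component, that component keeps its previous coefficients.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.ndim != 2 or resp.shape[0] != data.n_obs:
        raise ValueError("responsibility matrix must be (n, M)")
    if np.any(resp < 0) or np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("responsibility rows must be nonnegative and sum to 1")
    n, M = resp.shape
    design = design_matrix(data.covariate, spec)
    p = design.shape[1]
    y = data.outcome
    alpha = resp.mean(axis=0)
    alpha = np.maximum(alpha, 1e-12)
    alpha = alpha / alpha.sum()

    betas = np.empty((M, p))
    gammas = np.empty((M, p))
    for m in range(M):
        w = resp[:, m]
        if previous is not None:
            start = np.concatenate(
                [previous.mean_coefficients[m], previous.logscale_coefficients[m]]
            )
        else:
            # weighted OLS for the mean, log residual sd for the scale intercept
            wd = design * w[:, None]
            beta0, *_ = np.linalg.lstsq(wd.T @ design, wd.T @ y, rcond=None)
            resid = y - design @ beta0
            wsum = max(w.sum(), 1e-12)
            sd0 = np.sqrt(max(np.sum(w * resid**2) / wsum, 1e-6))
            gamma0 = np.zeros(p)
            gamma0[0] = np.log(sd0)
            start = np.concatenate([beta0, gamma0])
        res = _fit_component(design, y, w, start)
        if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
            betas[m], gammas[m] = res.x[:p], res.x[p:]
        elif previous is not None:  # flagged, keep previous params
            betas[m] = previous.mean_coefficients[m]
            gammas[m] = previous.logscale_coefficients[m]
        else:
            betas[m], gammas[m] = start[:p], start[p:]
    return EMParameters(betas, gammas, alpha)


def fit_em(
    data: LabeledDataset,
    init: np.ndarray,
    spec: Optional[BasisSpec] = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    standardization: Optional[StandardizationConstants] = None,
    init_kind: str = "custom",
    seed=None,
) -> FittedModel:
    """Alternate M- and E-steps from initial observation responsibilities.

    The initializer supplies responsibilities, so the loop starts with an
    M-step.  Iteration stops when the observed-data NLL improves by less
    than ``tol`` or at ``max_iter``.
    """
    spec = spec or BasisSpec.from_covariate(data.covariate)
    design = design_matrix(data.covariate, spec)
    resp = np.asarray(init, dtype=float)
    params = None
    nll_prev = np.inf
    nll_path = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        params = m_step(data, resp, spec, previous=params)
        nll = mixture_nll(params.surface(design), data.outcome)
        nll_path.append(nll)
        if abs(nll_prev - nll) < tol:
            converged = True
            break
        nll_prev = nll
        resp = e_step(data, params, spec)
    return FittedModel(
        method="em",
        weights_or_params=(params, spec),
        loss=float(nll_path[-1]),
        standardization=standardization or StandardizationConstants.identity(),
        converged=converged,
        init_kind=init_kind,
        seed=seed,
        n_iter=iteration,
        history={"nll_path": np.array(nll_path)},
    )


def em_surface(model: FittedModel, covariate: np.ndarray) -> MixtureParameterSurface:
    """Evaluate a fitted EM model's parameter surface at (standardized) covariates."""
    params, spec = model.weights_or_params
    return params.surface(design_matrix(covariate, spec))
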