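"""Conditional finite Gaussian mixture density, likelihood and quantiles.

The conditional mixture density

    f(y | x) = sum_m alpha_m(x) * N(y; mu_m(x), sigma_m(x)),

with per-observation weights, means and scales, is the mathematical
substrate shared by every estimator in this package.  A
:class:`MixtureParameterSurface` stores the three ``n x M`` parameter
matrices evaluated at the observed covariate values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, logsumexp
from scipy.stats import norm

#: Floor applied to scales when evaluating densities; guards against
#: optimizer excursions toward sigma -> 0.  Configurable per call.
SIGMA_FLOOR = 1e-8

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class MixtureParameterSurface:
    """Per-observation conditional mixture parameters.

    Parameters
    ----------
    weights : ndarray, shape (n, M)
        Mixture weights alpha_m(x_i); each row sums to one.
    means : ndarray, shape (n, M)
        Component means mu_m(x_i), in outcome units.
    scales : ndarray, shape (n, M)
        Component standard deviations sigma_m(x_i); strictly positive.
    """

    weights: np.ndarray
    means: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.scales, dtype=float)
        if w.ndim != 2 or w.shape != mu.shape or w.shape != sd.shape:
            raise ValueError(
                f"weights/means/scales must share an (n, M) shape; got "
                f"{w.shape}, {mu.shape}, {sd.shape}"
            )
        if w.shape[0] < 1:
            raise ValueError("surface needs at least one observation")
        if np.any(w < 0):
            raise ValueError("mixture weights must be nonnegative")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each row of mixture weights must sum to 1")
        if np.any(sd <= 0):
            raise ValueError("scales must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "scales", sd)

    @property
    def n_obs(self) -> int:
        return self.weights.shape[0]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def permuted(self, order) -> "MixtureParameterSurface":
        """Return a surface with component columns reordered."""
        order = list(order)
        return MixtureParameterSurface(
            self.weights[:, order], self.means[:, order], self.scales[:, order]
        )


def _log_component_densities(
    surface: MixtureParameterSurface, outcome: np.ndarray, sigma_floor: float
) -> np.ndarray:
    """log N(y_i; mu_m, sigma_m) as an (n, M) matrix."""
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or y.shape[0] != surface.n_obs:
        raise ValueError(
            f"outcome length {y.shape} does not match surface rows {surface.n_obs}"
        )
    sd = np.maximum(surface.scales, sigma_floor)
    z = (y[:, None] - surface.means) / sd
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z


def log_mixture_pdf(
    surface: MixtureParameterSurface,
    outcome: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Per-observation log-density of the mixture, via log-sum-exp."""
    log_f = _log_component_densities(surface, outcome, sigma_floor)
    with np.errstate(divide="ignore"):  # alpha = 0 is a legal degenerate weight
        log_w = np.log(surface.weights)
    return logsumexp(log_w + log_f, axis=1)


def mixture_pdf(
    surface: MixtureParameterSurface,
    outcome: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Mixture density sum_m alpha_m N(y; mu_m, sigma_m) per observation."""
    return np.exp(log_mixture_pdf(surface, outcome, sigma_floor))


def mixture_nll(
    surface: MixtureParameterSurface,
    outcome: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> float:
    """Negative log-likelihood -sum_i ln f(y_i | x_i).

    Evaluated on the log scale throughout, so the raw product likelihood
    (which underflows at laboratory-database sample sizes) is never formed.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size == 0:
        raise ValueError("cannot evaluate the likelihood of an empty dataset")
    return float(-np.sum(log_mixture_pdf(surface, y, sigma_floor)))


def responsibilities(
    surface: MixtureParameterSurface,
    outcome: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> np.ndarray:
    """Posterior component probabilities pi_im, computed on the log scale."""
    log_f = _log_component_densities(surface, outcome, sigma_floor)
    with np.errstate(divide="ignore"):
        log_w = np.log(surface.weights)
    return np.exp(log_softmax(log_w + log_f, axis=1))


def component_quantile(
    surface: MixtureParameterSurface, component: int, p: float
) -> np.ndarray:
    """Quantile curve mu_m(x) + sigma_m(x) * Phi^{-1}(p) of one component.

    The p = 0.95 curve of the physiological component is the age-dependent
    upper reference threshold; p in {0.025, 0.975} bound the conventional
    central 95% reference interval.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"quantile level must lie strictly in (0, 1); got {p}")
    return surface.means[:, component] + surface.scales[:, component] * norm.ppf(p)
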