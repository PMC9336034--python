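"""Deterministic tanh basis and the two bespoke initialization schemes.

The tanh basis replaces the cubic B-splines usually found in additive
location-scale models so that the EM benchmark and the mixture density
network share the same function class: basis b of B is

    tanh(a_b + c_b * x),   with
    a_b = -B * (min(x) + (b-1)/(B-1) * (max(x)-min(x))) / (max(x)-min(x)),
    c_b =  B / (max(x)-min(x)),

i.e. B equally spaced sigmoidal ramps of common slope spanning the
covariate range.  (The offsets are conventionally written alpha_b — not to
be confused with the mixture weights, which are also called alpha.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .data import LabeledDataset


@dataclass(frozen=True)
class BasisSpec:
    """Number of tanh bases and the covariate range that anchors them."""

    count: int
    lower: float
    upper: float

    def __post_init__(self):
        if self.count < 2:
            raise ValueError("need at least B=2 bases (offset formula divides by B-1)")
        if not self.upper > self.lower:
            raise ValueError("upper must exceed lower strictly")

    @classmethod
    def from_covariate(cls, covariate: np.ndarray, count: int = 5) -> "BasisSpec":
        x = np.asarray(covariate, dtype=float)
        return cls(count, float(x.min()), float(x.max()))

    @property
    def offsets(self) -> np.ndarray:
        """a_b for b = 1..B."""
        b = np.arange(1, self.count + 1, dtype=float)
        span = self.upper - self.lower
        knots = self.lower + (b - 1.0) / (self.count - 1.0) * span
        return -self.count * knots / span

    @property
    def slope(self) -> float:
        """c_b, shared by all bases."""
        return self.count / (self.upper - self.lower)


def tanh_basis(covariate: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate the B tanh bases at each covariate value (n x B matrix)."""
    x = np.asarray(covariate, dtype=float)
    return np.tanh(spec.offsets[None, :] + spec.slope * x[:, None])


def design_matrix(covariate: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Intercept column prepended to the tanh basis (n x (B+1))."""
    basis = tanh_basis(covariate, spec)
    return np.column_stack([np.ones(basis.shape[0]), basis])


def custom_mdn_init(
    data: LabeledDataset, spec: BasisSpec, seed, n_components: int = 2, **weight_kwargs
):
    """Partially customized network starting weights.

    Positions the two component location curves above each other from the
    start: an OLS fit of the (standardized) outcome on the tanh basis gives
    a common shape, the empirical 10% and 90% residual quantiles are added
    to its intercept, and the two shifted curves seed the location output
    heads while the basis parameters seed the hidden layer.  Scale and
    mixture-weight heads stay randomly (glorot-uniform) initialized.

    Component 1 receives the lower intercept, so the initial location gap
    mu_2 - mu_1 = q90 - q10 >= 0 is constant in x: no initial crossing by
    construction.
    """
    from .network import NetworkWeights, glorot_uniform_init

    if n_components != 2:
        raise ValueError("the custom initialization targets the two-component model")
    design = design_matrix(data.covariate, spec)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "tanh basis design matrix is rank deficient; the covariate does not "
            f"support B={spec.count} bases (n={data.n_obs}, distinct x="
            f"{np.unique(data.covariate).size})"
        )
    ols = sm.OLS(data.outcome, design).fit()
    coefs = np.asarray(ols.params)
    q10, q90 = np.quantile(ols.resid, [0.10, 0.90])  # linear interpolation

    weights = glorot_uniform_init(
        hidden_units=spec.count, n_components=2, seed=seed, **weight_kwargs
    )
    hidden_w = np.full((1, spec.count), spec.slope)
    hidden_b = spec.offsets.copy()
    mu_w = np.tile(coefs[1:, None], (1, 2))
    mu_b = np.array([coefs[0] + q10, coefs[0] + q90])
    return NetworkWeights(
        hidden_w=hidden_w,
        hidden_b=hidden_b,
        alpha_w=weights.alpha_w,
        alpha_b=weights.alpha_b,
        mu_w=mu_w,
        mu_b=mu_b,
        sigma_w=weights.sigma_w,
        sigma_b=weights.sigma_b,
        alpha_connected=weights.alpha_connected,
        scale_activation=weights.scale_activation,
    )


def em_initial_responsibilities(outcome: np.ndarray, ascending: bool = True) -> np.ndarray:
    """CDF-based initial observation weights for the EM algorithm.

    With (mu_hat, sigma_hat) the single-Gaussian maximum-likelihood fit to
    the pooled outcome, the upper (pathological) component receives
    responsibility Phi((y - mu_hat)/sigma_hat) and the lower (physiological)
    component the complement — a soft assignment increasing in y, so high
    values lean pathological.  Set ``ascending=False`` to flip the mapping.

    Returns an (n, 2) row-stochastic matrix, lower component first.
    """
    y = np.asarray(outcome, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    mu_hat = float(np.mean(y))
    sigma_hat = float(np.std(y))  # ddof=0: the maximum-likelihood scale
    if sigma_hat == 0.0:
        raise ValueError("outcome has zero variance; cannot place components")
    upper = norm.cdf((y - mu_hat) / sigma_hat)
    if not ascending:
        upper = 1.0 - upper
    return np.column_stack([1.0 - upper, upper])
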