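"""The mixture density network: forward pass, analytic gradients, training.

A single hidden layer of H tanh units feeds (K+1)M output neurons for an
M-component Gaussian mixture (K = 2 parameters per component): M softmax
units for the mixture weights alpha_m(x), M identity units for the means
mu_m(x) and M positive-transformed units for the scales sigma_m(x).  The
loss is the mixture negative log-likelihood; its gradient with respect to
the output pre-activations has the classical closed form

    dE/da_alpha,m = alpha_m - pi_m
    dE/da_mu,m    = pi_m (mu_m - y) / sigma_m^2
    dE/da_sigma,m = pi_m (1 - (y - mu_m)^2 / sigma_m^2)        (exponential)
                  = pi_m (1/sigma_m - (y-mu_m)^2/sigma_m^3) * s'(a)  (softplus)

with pi_m the posterior responsibilities; the rest is ordinary
backpropagation through the tanh layer.

Two training regimes are provided: quasi-Newton (BFGS) minimization run to
convergence, and ADAM with a 20%-validation early-stopping rule
(patience 20).  Each supports the fully connected network and a reduced
variant whose mixture-weight outputs are cut off from the hidden layer,
yielding constant (input-independent) weights — the middle ground between
the EM benchmark and the full network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .data import LabeledDataset, StandardizationConstants
from .mixture import SIGMA_FLOOR, MixtureParameterSurface, _LOG_2PI

_BAD_LOSS = 1e12  # returned when a trial point yields a non-finite NLL


@dataclass(frozen=True)
class NetworkWeights:
    """All connection weights and biases of the one-hidden-layer MDN.

    When ``alpha_connected`` is False the hidden-to-alpha matrix is frozen
    at zero and excluded from the trainable parameter vector; only the
    alpha biases are trained, so the softmax weights are constant in x.
    """

    hidden_w: np.ndarray  # (d, H)
    hidden_b: np.ndarray  # (H,)
    alpha_w: np.ndarray  # (H, M)
    alpha_b: np.ndarray  # (M,)
    mu_w: np.ndarray  # (H, M)
    mu_b: np.ndarray  # (M,)
    sigma_w: np.ndarray  # (H, M)
    sigma_b: np.ndarray  # (M,)
    alpha_connected: bool = True
    scale_activation: str = "exponential"  # or "softplus"

    def __post_init__(self):
        if self.scale_activation not in ("exponential", "softplus"):
            raise ValueError(f"unknown scale activation {self.scale_activation!r}")
        if not self.alpha_connected and np.any(self.alpha_w != 0.0):
            raise ValueError("constant-weight variant requires a zero alpha matrix")

    @property
    def n_hidden(self) -> int:
        return self.hidden_b.shape[0]

    @property
    def n_components(self) -> int:
        return self.alpha_b.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.hidden_w.shape[0]

    # -- flat parameter vector contract (order is part of the API) --------

    def _blocks(self):
        blocks = [self.hidden_w, self.hidden_b]
        if self.alpha_connected:
            blocks.append(self.alpha_w)
        blocks += [self.alpha_b, self.mu_w, self.mu_b, self.sigma_w, self.sigma_b]
        return blocks

    @property
    def n_params(self) -> int:
        return sum(b.size for b in self._blocks())

    def flatten(self) -> np.ndarray:
        return np.concatenate([np.ravel(b) for b in self._blocks()])

    def unflatten(self, theta: np.ndarray) -> "NetworkWeights":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} parameters, got {theta.shape}")
        out, pos = {}, 0
        names = ["hidden_w", "hidden_b"]
        if self.alpha_connected:
            names.append("alpha_w")
        names += ["alpha_b", "mu_w", "mu_b", "sigma_w", "sigma_b"]
        for name in names:
            tmpl = getattr(self, name)
            out[name] = theta[pos : pos + tmpl.size].reshape(tmpl.shape)
            pos += tmpl.size
        return replace(self, **out)

    def permuted(self, order) -> "NetworkWeights":
        """Reorder the component output heads (label permutation)."""
        order = list(order)
        return replace(
            self,
            alpha_w=self.alpha_w[:, order],
            alpha_b=self.alpha_b[order],
            mu_w=self.mu_w[:, order],
            mu_b=self.mu_b[order],
            sigma_w=self.sigma_w[:, order],
            sigma_b=self.sigma_b[order],
        )


def glorot_uniform_init(
    hidden_units: int = 5,
    n_components: int = 2,
    n_inputs: int = 1,
    seed=None,
    alpha_connected: bool = True,
    scale_activation: str = "exponential",
) -> NetworkWeights:
    """Random glorot-uniform weights: U(+-sqrt(6/(fan_in+fan_out))), zero biases."""
    rng = np.random.default_rng(seed)

    def draw(fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    alpha_w = draw(hidden_units, n_components)
    if not alpha_connected:
        alpha_w = np.zeros_like(alpha_w)
    return NetworkWeights(
        hidden_w=draw(n_inputs, hidden_units),
        hidden_b=np.zeros(hidden_units),
        alpha_w=alpha_w,
        alpha_b=np.zeros(n_components),
        mu_w=draw(hidden_units, n_components),
        mu_b=np.zeros(n_components),
        sigma_w=draw(hidden_units, n_components),
        sigma_b=np.zeros(n_components),
        alpha_connected=alpha_connected,
        scale_activation=scale_activation,
    )


def _softplus(a: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, a)


def _row_softmax(a: np.ndarray):
    """(softmax, log-softmax) per row via the max trick."""
    shift = a - a.max(axis=1, keepdims=True)
    e = np.exp(shift)
    total = e.sum(axis=1, keepdims=True)
    return e / total, shift - np.log(total)


def _forward_raw(weights: NetworkWeights, covariate: np.ndarray):
    """Hidden activations plus output pre-activations and parameters."""
    x = np.asarray(covariate, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not all(np.all(np.isfinite(b)) for b in weights._blocks()):
        raise ValueError("network weights contain non-finite values")
    hidden = np.tanh(x @ weights.hidden_w + weights.hidden_b)
    if weights.alpha_connected:
        a_alpha = hidden @ weights.alpha_w + weights.alpha_b
    else:
        a_alpha = np.broadcast_to(
            weights.alpha_b, (hidden.shape[0], weights.n_components)
        ).copy()
    a_mu = hidden @ weights.mu_w + weights.mu_b
    a_sigma = hidden @ weights.sigma_w + weights.sigma_b
    alpha = _row_softmax(a_alpha)[0]
    if weights.scale_activation == "exponential":
        sigma = np.exp(a_sigma)
    else:
        sigma = _softplus(a_sigma)
    return x, hidden, a_alpha, a_sigma, alpha, a_mu, sigma


def forward(weights: NetworkWeights, covariate: np.ndarray) -> MixtureParameterSurface:
    """Map covariates to the conditional mixture parameter surface."""
    *_, alpha, mu, sigma = _forward_raw(weights, covariate)
    return MixtureParameterSurface(alpha, mu, np.maximum(sigma, SIGMA_FLOOR))


try:
    from ._fastgrad import fused_nll_grad as _fused_nll_grad
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _fused_nll_grad = None


def nll_and_gradient(weights: NetworkWeights, data: LabeledDataset):
    """Mixture NLL and its gradient over the flat trainable parameter vector."""
    if _fused_nll_grad is not None and weights.n_inputs == 1:
        if not all(np.all(np.isfinite(b)) for b in weights._blocks()):
            raise ValueError("network weights contain non-finite values")
        nll, grads = _fused_nll_grad(
            np.ascontiguousarray(data.covariate, dtype=np.float64),
            np.ascontiguousarray(data.outcome, dtype=np.float64),
            np.ascontiguousarray(weights.hidden_w[0]),
            np.ascontiguousarray(weights.hidden_b),
            np.ascontiguousarray(weights.alpha_w),
            np.ascontiguousarray(weights.alpha_b),
            np.ascontiguousarray(weights.mu_w),
            np.ascontiguousarray(weights.mu_b),
            np.ascontiguousarray(weights.sigma_w),
            np.ascontiguousarray(weights.sigma_b),
            weights.alpha_connected,
            weights.scale_activation == "softplus",
        )
        return nll, grads
    return _nll_and_gradient_numpy(weights, data)


def _nll_and_gradient_numpy(weights: NetworkWeights, data: LabeledDataset):
    """Pure-numpy reference path (any covariate dimension)."""
    x, hidden, a_alpha, a_sigma, alpha, mu, sigma = _forward_raw(
        weights, data.covariate
    )
    y = data.outcome
    sd = np.maximum(sigma, SIGMA_FLOOR)
    z = (y[:, None] - mu) / sd
    log_f = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z
    log_joint = _row_softmax(a_alpha)[1] + log_f
    shift = log_joint - log_joint.max(axis=1, keepdims=True)
    e = np.exp(shift)
    total = e.sum(axis=1, keepdims=True)
    log_mix = np.log(total) + log_joint.max(axis=1, keepdims=True)
    nll = float(-np.sum(log_mix))

    pi = e / total  # posterior responsibilities
    d_alpha = alpha - pi
    d_mu = pi * (mu - y[:, None]) / sd**2
    if weights.scale_activation == "exponential":
        d_sigma = pi * (1.0 - z * z)
    else:
        d_sigma = pi * (1.0 / sd - (y[:, None] - mu) ** 2 / sd**3) * expit(a_sigma)

    back = d_mu @ weights.mu_w.T + d_sigma @ weights.sigma_w.T
    if weights.alpha_connected:
        back = back + d_alpha @ weights.alpha_w.T
    d_hidden = back * (1.0 - hidden**2)

    grads = [x.T @ d_hidden, d_hidden.sum(axis=0)]
    if weights.alpha_connected:
        grads.append(hidden.T @ d_alpha)
    grads += [
        d_alpha.sum(axis=0),
        hidden.T @ d_mu,
        d_mu.sum(axis=0),
        hidden.T @ d_sigma,
        d_sigma.sum(axis=0),
    ]
    return nll, np.concatenate([np.ravel(g) for g in grads])


@dataclass
class FitConfig:
    """Optimizer settings shared by the two training regimes."""

    max_iter: int = 500  # BFGS iteration cap (ADAM epoch cap is separate)
    max_epochs: int = 2000
    gtol: float = 1e-6  # BFGS projected-gradient tolerance
    ftol: float = 1e-9  # BFGS relative objective-decrease tolerance
    learning_rate: float = 0.01  # ADAM
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 20
    validation_fraction: float = 0.2
    seed: Optional[int] = None  # governs the ADAM train/validation split


@dataclass
class FittedModel:
    """Estimation result: parameters, scale constants, loss, diagnostics."""

    method: str  # em | bfgs_const | bfgs_full | adam
    weights_or_params: object
    loss: float
    standardization: StandardizationConstants
    converged: bool
    init_kind: str = "random"
    seed: Optional[int] = None
    n_iter: int = 0
    history: dict = field(default_factory=dict)
    relabeled: bool = False


def _objective(theta, template: NetworkWeights, data: LabeledDataset):
    w = template.unflatten(theta)
    try:
        nll, grad = nll_and_gradient(w, data)
    except (FloatingPointError, ValueError):
        return _BAD_LOSS, np.zeros(template.n_params)
    if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
        return _BAD_LOSS, np.zeros(template.n_params)
    return nll, grad


def _make_objective(template: NetworkWeights, data: LabeledDataset):
    """Closure over (template, data) evaluating the NLL and gradient.

    When the compiled kernel is available the flat parameter vector is
    sliced straight into kernel arguments, skipping per-call dataclass
    construction — the difference matters for full-batch epoch loops.
    """
    if _fused_nll_grad is None or template.n_inputs != 1:
        return lambda theta: _objective(theta, template, data)
    x = np.ascontiguousarray(data.covariate, dtype=np.float64)
    y = np.ascontiguousarray(data.outcome, dtype=np.float64)
    H, M = template.n_hidden, template.n_components
    conn = template.alpha_connected
    softplus = template.scale_activation == "softplus"
    zeros_aw = np.zeros((H, M))
    n_params = template.n_params

    def obj(theta):
        theta = np.ascontiguousarray(theta, dtype=np.float64)
        if theta.shape != (n_params,):
            raise ValueError(f"expected {n_params} parameters, got {theta.shape}")
        if not np.all(np.isfinite(theta)):
            return _BAD_LOSS, np.zeros(n_params)
        pos = 0
        hw = theta[pos : pos + H]; pos += H
        hb = theta[pos : pos + H]; pos += H
        if conn:
            aw = theta[pos : pos + H * M].reshape(H, M); pos += H * M
        else:
            aw = zeros_aw
        ab = theta[pos : pos + M]; pos += M
        mw = theta[pos : pos + H * M].reshape(H, M); pos += H * M
        mb = theta[pos : pos + M]; pos += M
        sw = theta[pos : pos + H * M].reshape(H, M); pos += H * M
        sb = theta[pos : pos + M]
        nll, grad = _fused_nll_grad(
            x, y, hw, hb, aw, ab, mw, mb, sw, sb, conn, softplus
        )
        if not np.isfinite(nll) or not np.all(np.isfinite(grad)):
            return _BAD_LOSS, np.zeros(n_params)
        return nll, grad

    return obj


def train_bfgs(
    data: LabeledDataset,
    init: NetworkWeights,
    config: FitConfig | None = None,
    standardization: StandardizationConstants | None = None,
    init_kind: str = "random",
    seed=None,
) -> FittedModel:
    """Quasi-Newton minimization of the mixture NLL, run to convergence.

    Uses the L-BFGS-B flavor of the BFGS family: it stops on a relative
    objective-decrease criterion (``ftol``) as well as the projected
    gradient norm, matching the objective-change convergence semantics of
    classical BFGS optimizer implementations.
    """
    config = config or FitConfig()
    obj = _make_objective(init, data)
    res = minimize(
        obj,
        init.flatten(),
        method="L-BFGS-B",
        jac=True,
        options={
            "maxiter": config.max_iter,
            "gtol": config.gtol,
            "ftol": config.ftol,
        },
    )
    final = init.unflatten(res.x)
    nll0, _ = obj(init.flatten())
    loss = float(res.fun)
    if loss > nll0:  # line-search failure on the first step; keep the init
        final, loss = init, float(nll0)
    method = "bfgs_full" if init.alpha_connected else "bfgs_const"
    return FittedModel(
        method=method,
        weights_or_params=final,
        loss=loss,
        standardization=standardization or StandardizationConstants.identity(),
        converged=bool(res.success),
        init_kind=init_kind,
        seed=seed,
        n_iter=int(res.nit),
        history={"initial_loss": float(nll0)},
    )


def train_adam(
    data: LabeledDataset,
    init: NetworkWeights,
    config: FitConfig | None = None,
    standardization: StandardizationConstants | None = None,
    init_kind: str = "random",
    seed=None,
) -> FittedModel:
    """Full-batch ADAM with early stopping on a 20% validation split.

    Training stops once the best validation NLL has not improved for
    ``patience`` consecutive epochs (or at the epoch cap); the weights at
    the best validation epoch are restored.
    """
    config = config or FitConfig()
    if data.n_obs < 10:
        raise ValueError("early-stopping training needs at least 10 observations")
    split_seed = config.seed if config.seed is not None else seed
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(data.n_obs)
    n_val = max(1, int(round(config.validation_fraction * data.n_obs)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    d_train = LabeledDataset(data.covariate[train_idx], data.outcome[train_idx])
    d_val = LabeledDataset(data.covariate[val_idx], data.outcome[val_idx])
    train_obj = _make_objective(init, d_train)
    val_obj = _make_objective(init, d_val)

    theta = init.flatten()
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    best_theta = theta.copy()
    best_val = val_obj(theta)[0]
    since_best = 0
    val_history = [best_val]
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        _, grad = train_obj(theta)
        m = config.beta1 * m + (1 - config.beta1) * grad
        v = config.beta2 * v + (1 - config.beta2) * grad**2
        m_hat = m / (1 - config.beta1**epoch)
        v_hat = v / (1 - config.beta2**epoch)
        theta = theta - config.learning_rate * m_hat / (np.sqrt(v_hat) + config.eps)
        val_nll = val_obj(theta)[0]
        val_history.append(val_nll)
        if val_nll < best_val:
            best_val, best_theta, since_best = val_nll, theta.copy(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    final = init.unflatten(best_theta)
    loss = _make_objective(init, LabeledDataset(data.covariate, data.outcome))(best_theta)[0]
    return FittedModel(
        method="adam",
        weights_or_params=final,
        loss=float(loss),
        standardization=standardization or StandardizationConstants.identity(),
        converged=since_best >= config.patience,
        init_kind=init_kind,
        seed=seed,
        n_iter=epoch,
        history={"validation_nll": np.array(val_history), "best_validation": best_val},
    )
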