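"""Model/Results layer: fit conditional mixtures to unlabeled lab data.

Two model classes share one results interface:

``MixtureDensityNetwork``
    One-hidden-layer tanh network parameterizing all mixture parameters —
    weights, means, scales — as functions of the covariate.  Trained by
    BFGS (to convergence) or ADAM (early stopping); the mixture-weight
    outputs can be disconnected from the hidden layer to force constant
    weights.

``TanhMixtureEM``
    The EM benchmark: tanh-basis location-scale regression per component
    with constant mixture weights.

Both standardize covariate and outcome internally before fitting and
report everything back on the original scale.  ``fit`` returns a
:class:`MixtureResults`; ``fit_with_restarts`` repeats the fit over seeds
and keeps the minimum-loss non-degenerate solution, the protocol used for
real analyte data where a single random initialization is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .basis import BasisSpec, custom_mdn_init, em_initial_responsibilities
from .data import (
    LabeledDataset,
    StandardizationConstants,
    destandardize_surface,
    standardize,
)
from .em import em_surface, fit_em
from .mixture import MixtureParameterSurface, component_quantile
from .network import (
    FitConfig,
    FittedModel,
    forward,
    glorot_uniform_init,
    train_adam,
    train_bfgs,
)

#: Quantile levels of the reference-interval table (central 95%, 90%, 80%
#: and 50% band edges).
DEFAULT_PROBABILITIES = (0.025, 0.05, 0.1, 0.25, 0.75, 0.9, 0.95, 0.975)


def surface_on_grid(model: FittedModel, covariate) -> MixtureParameterSurface:
    """Fitted conditional mixture parameters at original-scale covariates."""
    x_std = model.standardization.standardize_x(np.asarray(covariate, dtype=float))
    if model.method == "em":
        surf = em_surface(model, x_std)
    else:
        surf = forward(model.weights_or_params, x_std)
    return destandardize_surface(surf, model.standardization)


@dataclass(frozen=True)
class ReferenceIntervalTable:
    """Main-component quantile curves plus the healthy-fraction curve."""

    grid: np.ndarray
    probabilities: tuple
    quantiles: np.ndarray  # (len(grid), len(probabilities))
    alpha1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"grid": self.grid, "alpha1": self.alpha1})
        for j, p in enumerate(self.probabilities):
            df[f"q{p:g}"] = self.quantiles[:, j]
        return df


def reference_intervals(
    model: FittedModel,
    grid,
    probabilities: Sequence[float] = DEFAULT_PROBABILITIES,
) -> ReferenceIntervalTable:
    """Main-component Gaussian quantiles on the original scale.

    Requires a relabeled model (main component first); quantile columns are
    pointwise nondecreasing in p by construction.
    """
    if not model.relabeled:
        raise ValueError(
            "model must be relabeled (main component first) before extracting "
            "reference intervals; call relabel_main"
        )
    grid = np.asarray(grid, dtype=float)
    probabilities = tuple(sorted(probabilities))
    surf = surface_on_grid(model, grid)
    q = np.column_stack([component_quantile(surf, 0, p) for p in probabilities])
    return ReferenceIntervalTable(grid, probabilities, q, surf.weights[:, 0].copy())


class MixtureResults:
    """Estimation results for a fitted conditional mixture model."""

    def __init__(self, model, fitted: FittedModel):
        self.model = model
        self.fitted = fitted

    # -- passthrough diagnostics -----------------------------------------
    @property
    def loss(self) -> float:
        """Final negative log-likelihood on the standardized training data."""
        return self.fitted.loss

    @property
    def converged(self) -> bool:
        return self.fitted.converged

    @property
    def method(self) -> str:
        return self.fitted.method

    @property
    def n_iter(self) -> int:
        return self.fitted.n_iter

    @property
    def standardization(self) -> StandardizationConstants:
        return self.fitted.standardization

    @property
    def params(self):
        return self.fitted.weights_or_params

    def predict(self, exog=None) -> MixtureParameterSurface:
        """Conditional mixture parameters, original scale (default: training x)."""
        if exog is None:
            exog = self.model.exog
        return surface_on_grid(self.fitted, exog)

    def relabel_main(self) -> "MixtureResults":
        """Order components so the mainly-lower one is component 1."""
        from .evaluation import relabel_main

        return MixtureResults(self.model, relabel_main(self.fitted, self.model.exog))

    def reference_intervals(
        self, grid=None, probabilities: Sequence[float] = DEFAULT_PROBABILITIES
    ) -> ReferenceIntervalTable:
        fitted = self.fitted
        if not fitted.relabeled:
            fitted = self.relabel_main().fitted
        if grid is None:
            lo, hi = float(np.min(self.model.exog)), float(np.max(self.model.exog))
            grid = np.linspace(lo, hi, 201)
        return reference_intervals(fitted, grid, probabilities)

    def summary(self) -> str:
        surf = self.predict()
        mean_alpha = surf.weights.mean(axis=0)
        lines = [
            "Conditional Gaussian mixture fit",
            "=" * 46,
            f"estimator:       {self.method}",
            f"initialization:  {self.fitted.init_kind}",
            f"n observations:  {self.model.endog.shape[0]}",
            f"components:      {surf.n_components}",
            f"final NLL:       {self.loss:.4f}  (standardized scale)",
            f"converged:       {self.converged}   iterations: {self.n_iter}",
            "mean mixture weights: "
            + ", ".join(f"{a:.3f}" for a in mean_alpha),
            "mean component means: "
            + ", ".join(f"{m:.3f}" for m in surf.means.mean(axis=0)),
            "mean component sds:   "
            + ", ".join(f"{s:.3f}" for s in surf.scales.mean(axis=0)),
        ]
        return "\n".join(lines)


class _MixtureModelBase:
    """Shared constructor: raw endog/exog, internal standardization."""

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        dataset = LabeledDataset(self.exog, self.endog)
        self._std_data, self._consts = standardize(dataset)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome="y", covariate="x", **kwargs):
        return cls(df[outcome].to_numpy(float), df[covariate].to_numpy(float), **kwargs)

    def fit_with_restarts(
        self, restarts: int = 100, seed: Optional[int] = None, **fit_kwargs
    ) -> MixtureResults:
        """Repeat ``fit`` over derived seeds; keep the minimum-loss clean run.

        Runs whose fitted mean mixture weight drops below 0.05 for any
        component (failure to identify two components) are discarded before
        minimum-loss selection.  Per-restart losses are kept on the result
        for stability reporting.
        """
        from .evaluation import detect_degenerate

        if restarts < 1:
            raise ValueError("restarts must be >= 1")
        rng = np.random.default_rng(seed)
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=restarts)]
        losses, results = [], []
        for s in seeds:
            res = self.fit(seed=s, **fit_kwargs)
            losses.append(res.loss)
            if restarts == 1 or not detect_degenerate(res.fitted, self.exog):
                results.append(res)
        if not results:
            raise RuntimeError(
                "all restarts failed to identify two components (mean mixture "
                "weight below 0.05)"
            )
        best = min(results, key=lambda r: r.loss)
        best.restart_losses = np.array(losses)
        best.restart_seeds = seeds
        return best


class MixtureDensityNetwork(_MixtureModelBase):
    """Mixture density network for M-component conditional Gaussian mixtures.

    Parameters
    ----------
    endog : array
        Analyte measurements (outcome).
    exog : array
        Single covariate, e.g. age.
    n_components : int
        Mixture components M; the two-component physiological/pathological
        split is the validated case.
    hidden_units : int
        Hidden tanh units H (default 5, matching the B=5 basis of the EM
        benchmark).
    alpha_connected : bool
        If False, mixture-weight outputs are cut off from the hidden layer
        and the fitted weights are constant in the covariate.
    """

    def __init__(
        self,
        endog,
        exog,
        n_components: int = 2,
        hidden_units: int = 5,
        alpha_connected: bool = True,
    ):
        super().__init__(endog, exog)
        self.n_components = n_components
        self.hidden_units = hidden_units
        self.alpha_connected = alpha_connected

    def _initial_weights(self, init_kind, seed, scale_activation):
        if init_kind == "random":
            return glorot_uniform_init(
                hidden_units=self.hidden_units,
                n_components=self.n_components,
                seed=seed,
                alpha_connected=self.alpha_connected,
                scale_activation=scale_activation,
            )
        if init_kind == "custom":
            spec = BasisSpec.from_covariate(self._std_data.covariate, self.hidden_units)
            return custom_mdn_init(
                self._std_data,
                spec,
                seed,
                n_components=self.n_components,
                alpha_connected=self.alpha_connected,
                scale_activation=scale_activation,
            )
        raise ValueError(f"unknown init kind {init_kind!r}")

    def fit(
        self,
        method: str = "bfgs",
        init_kind: str = "random",
        seed: Optional[int] = None,
        scale_activation: Optional[str] = None,
        config: Optional[FitConfig] = None,
    ) -> MixtureResults:
        """Train the network on the standardized data.

        ``method='bfgs'`` pairs with the exponential scale activation and
        runs to convergence; ``method='adam'`` pairs with softplus and early
        stopping.  Either activation can be forced via ``scale_activation``.
        """
        if method not in ("bfgs", "adam"):
            raise ValueError(f"unknown training method {method!r}")
        if scale_activation is None:
            scale_activation = "exponential" if method == "bfgs" else "softplus"
        init = self._initial_weights(init_kind, seed, scale_activation)
        trainer = train_bfgs if method == "bfgs" else train_adam
        cfg = config or FitConfig()
        if method == "adam" and cfg.seed is None:
            cfg = replace(cfg, seed=seed)
        fitted = trainer(
            self._std_data,
            init,
            cfg,
            standardization=self._consts,
            init_kind=init_kind,
            seed=seed,
        )
        return MixtureResults(self, fitted)


class TanhMixtureEM(_MixtureModelBase):
    """EM-fitted two-component location-scale mixture on a tanh basis."""

    def __init__(self, endog, exog, n_bases: int = 5):
        super().__init__(endog, exog)
        self.n_bases = n_bases

    def fit(
        self,
        init_kind: str = "custom",
        seed: Optional[int] = None,
        tol: float = 1e-6,
        max_iter: int = 500,
    ) -> MixtureResults:
        """Run EM from CDF-based (``'custom'``) or random Dirichlet weights."""
        y = self._std_data.outcome
        if init_kind == "custom":
            resp = em_initial_responsibilities(y)
        elif init_kind == "random":
            rng = np.random.default_rng(seed)
            resp = rng.dirichlet((1.0, 1.0), size=y.shape[0])
        else:
            raise ValueError(f"unknown init kind {init_kind!r}")
        spec = BasisSpec.from_covariate(self._std_data.covariate, self.n_bases)
        fitted = fit_em(
            self._std_data,
            resp,
            spec,
            tol=tol,
            max_iter=max_iter,
            standardization=self._consts,
            init_kind=init_kind,
            seed=seed,
        )
        return MixtureResults(self, fitted)


def fit_with_restarts(
    data: LabeledDataset,
    method: str = "bfgs_full",
    init_kind: str = "random",
    restarts: int = 100,
    seed: Optional[int] = None,
    **kwargs,
) -> MixtureResults:
    """Functional multi-restart entry point over the study's estimator names.

    ``method`` is one of ``em``, ``bfgs_const``, ``bfgs_full``, ``adam``.
    """
    model = make_model(data, method, **kwargs)
    fit_kwargs = {"init_kind": init_kind}
    if method in ("bfgs_const", "bfgs_full"):
        fit_kwargs["method"] = "bfgs"
    elif method == "adam":
        fit_kwargs["method"] = "adam"
    return model.fit_with_restarts(restarts=restarts, seed=seed, **fit_kwargs)


def make_model(data: LabeledDataset, method: str, **kwargs):
    """Build the model object matching a study estimator name."""
    if method == "em":
        return TanhMixtureEM(data.outcome, data.covariate, **kwargs)
    if method in ("bfgs_const", "bfgs_full", "adam"):
        return MixtureDensityNetwork(
            data.outcome,
            data.covariate,
            alpha_connected=(method != "bfgs_const"),
            **kwargs,
        )
    raise ValueError(f"unknown estimator {method!r}")


def fit_algorithm(
    data: LabeledDataset,
    algorithm: str,
    init_kind: str = "random",
    seed: Optional[int] = None,
    config: Optional[FitConfig] = None,
) -> MixtureResults:
    """Fit one study estimator (em | bfgs_const | bfgs_full | adam) once."""
    model = make_model(data, algorithm)
    if algorithm == "em":
        return model.fit(init_kind=init_kind, seed=seed)
    train_method = "adam" if algorithm == "adam" else "bfgs"
    return model.fit(method=train_method, init_kind=init_kind, seed=seed, config=config)
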