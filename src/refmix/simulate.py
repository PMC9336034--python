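"""Synthetic laboratory-style data: two-component conditional Gaussian mixture.

The generator emulates an unlabeled laboratory database with an
age-standing covariate: x ~ U(0,1), a lower "physiological" component and
an upper "pathological" component, both with nonlinearly x-dependent means
and standard deviations, and a physiological proportion alpha_1 that is
either constant ("independent" scenario) or a nonlinear function of x
("dependent" scenario).  True parameter curves are retained so estimators
can be scored by integrated squared error.

Default truth functions (package defaults, injectable):

    mu_1(x)    = 1 + 1.5 sin(pi x)        sigma_1(x) = 0.25 + 0.15 x
    mu_2(x)    = mu_1(x) + 2.5 - x        sigma_2(x) = 0.5
    alpha_1(x) = 0.70 + 0.20 sin(pi x)    (dependent)
    alpha_1    = 0.80                     (independent)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional

import numpy as np

from .data import LabeledDataset
from .mixture import MixtureParameterSurface


def _default_mu1(x):
    return 1.0 + 1.5 * np.sin(np.pi * x)


def _default_sigma1(x):
    return 0.25 + 0.15 * x


def _default_mu2(x):
    return _default_mu1(x) + 2.5 - x


def _default_sigma2(x):
    return np.full_like(np.asarray(x, dtype=float), 0.5)


def _default_weight_dependent(x):
    return 0.70 + 0.20 * np.sin(np.pi * x)


def _default_weight_independent(x):
    return np.full_like(np.asarray(x, dtype=float), 0.80)


@dataclass(frozen=True)
class DGPConfig:
    """Data-generating process for one simulation scenario."""

    setting: str = "dependent"  # or "independent"
    n: int = 5000
    mean_functions: tuple = (_default_mu1, _default_mu2)
    scale_functions: tuple = (_default_sigma1, _default_sigma2)
    weight_function: Optional[Callable] = None  # x -> alpha_1(x)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.setting not in ("dependent", "independent"):
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.weight_function is None:
            wf = (
                _default_weight_dependent
                if self.setting == "dependent"
                else _default_weight_independent
            )
            object.__setattr__(self, "weight_function", wf)
        grid = np.linspace(0.0, 1.0, 101)
        mu1, mu2 = (f(grid) for f in self.mean_functions)
        if not np.all(mu2 > mu1):
            raise ValueError("pathological mean must lie above the physiological mean")
        a1 = self.weight_function(grid)
        if np.any(a1 < 0.05) or np.any(a1 > 0.99):
            raise ValueError("alpha_1(x) must stay inside [0.05, 0.99]")

    def alpha1(self, x) -> np.ndarray:
        return np.asarray(self.weight_function(x), dtype=float)


def simulate(config: DGPConfig) -> LabeledDataset:
    """Draw one dataset from the configured mixture process.

    Labels (1 = physiological, 2 = pathological) and the config itself are
    stored on the dataset for evaluation but are never shown to estimators.
    """
    rng = np.random.default_rng(config.seed)
    x = rng.uniform(0.0, 1.0, size=config.n)
    a1 = config.alpha1(x)
    labels = np.where(rng.uniform(size=config.n) < a1, 1, 2)
    mu = np.where(
        labels == 1, config.mean_functions[0](x), config.mean_functions[1](x)
    )
    sigma = np.where(
        labels == 1, config.scale_functions[0](x), config.scale_functions[1](x)
    )
    y = rng.normal(mu, sigma)
    return LabeledDataset(x, y, labels=labels, truth=config)


def true_curves(config: DGPConfig, grid: np.ndarray) -> MixtureParameterSurface:
    """Evaluate the true parameter functions of the process on a grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0.0) or np.any(grid > 1.0):
        raise ValueError("grid must lie inside the covariate support [0, 1]")
    a1 = config.alpha1(grid)
    weights = np.column_stack([a1, 1.0 - a1])
    means = np.column_stack([f(grid) for f in config.mean_functions])
    scales = np.column_stack([f(grid) for f in config.scale_functions])
    return MixtureParameterSurface(weights, means, scales)


def study_grid(replications: int = 100) -> List[DGPConfig]:
    """The 2x2 factorial of the simulation study.

    Four scenarios — {dependent, independent} weights x {5000, 10000}
    samples — each meant to be replicated ``replications`` times (default
    100, i.e. 400 datasets in total).
    """
    return [
        DGPConfig(setting=setting, n=n)
        for n in (10000, 5000)
        for setting in ("dependent", "independent")
    ]
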