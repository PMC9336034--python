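"""Dataset container, standardization contract and scale plumbing."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .mixture import MixtureParameterSurface


@dataclass(frozen=True)
class LabeledDataset:
    """A covariate/outcome sample, optionally with generating-process truth.

    ``labels`` and ``truth`` exist only for synthetic data and are never
    visible to estimators: the fitting interfaces accept covariate and
    outcome arrays only.
    """

    covariate: np.ndarray
    outcome: np.ndarray
    labels: Optional[np.ndarray] = None
    truth: Optional[object] = None  # a DGPConfig for synthetic data

    def __post_init__(self):
        x = np.asarray(self.covariate, dtype=float)
        y = np.asarray(self.outcome, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("covariate and outcome must be equal-length vectors")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("covariate and outcome must be finite with no missing values")
        object.__setattr__(self, "covariate", x)
        object.__setattr__(self, "outcome", y)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != x.shape:
                raise ValueError("labels must match the sample length")
            if lab.min() < 1:
                raise ValueError("labels are 1-based component indices")
            object.__setattr__(self, "labels", lab.astype(int))

    @property
    def n_obs(self) -> int:
        return self.covariate.shape[0]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariate: str = "x", outcome: str = "y"
    ) -> "LabeledDataset":
        labels = None
        if "label" in df.columns:
            labels = df["label"].to_numpy()
        return cls(df[covariate].to_numpy(float), df[outcome].to_numpy(float), labels)


@dataclass(frozen=True)
class StandardizationConstants:
    """Sample means and standard deviations (ddof=1) of covariate and outcome."""

    x_mean: float
    x_sd: float
    y_mean: float
    y_sd: float

    def __post_init__(self):
        if self.x_sd <= 0 or self.y_sd <= 0:
            raise ValueError("standard deviations must be strictly positive")

    @classmethod
    def identity(cls) -> "StandardizationConstants":
        return cls(0.0, 1.0, 0.0, 1.0)

    def standardize_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_sd

    def destandardize_x(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self.x_sd + self.x_mean

    def standardize_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def destandardize_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.y_sd + self.y_mean


def standardize(data: LabeledDataset):
    """Center and scale covariate and outcome to mean 0, sd 1.

    Both variables are standardized before any model fit; all reporting
    happens back on the original scale.  Uses the n-1 (sample) convention.

    Returns
    -------
    (LabeledDataset, StandardizationConstants)
    """
    if data.n_obs < 2:
        raise ValueError("standardization needs at least two observations")
    consts = StandardizationConstants(
        float(np.mean(data.covariate)),
        float(np.std(data.covariate, ddof=1)),
        float(np.mean(data.outcome)),
        float(np.std(data.outcome, ddof=1)),
    )
    std = replace(
        data,
        covariate=consts.standardize_x(data.covariate),
        outcome=consts.standardize_y(data.outcome),
    )
    return std, consts


def destandardize_surface(
    surface: MixtureParameterSurface, consts: StandardizationConstants
) -> MixtureParameterSurface:
    """Map a surface fitted on standardized data back to original units.

    Means undergo the affine map mu*s_y + y_bar, scales the pure rescaling
    sigma*s_y; mixture weights are scale-free and pass through unchanged.
    """
    return MixtureParameterSurface(
        weights=surface.weights,
        means=surface.means * consts.y_sd + consts.y_mean,
        scales=surface.scales * consts.y_sd,
    )
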