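"""Shared builders for network test instances."""

import dataclasses

import numpy as np

from refmix.data import LabeledDataset
from refmix.network import NetworkWeights, glorot_uniform_init

VARIANTS = [
    (connected, activation)
    for connected in (True, False)
    for activation in ("exponential", "softplus")
]


def zero_weights(h=3, m=2, **kwargs):
    z = lambda *shape: np.zeros(shape)
    return NetworkWeights(
        hidden_w=z(1, h), hidden_b=z(h), alpha_w=z(h, m), alpha_b=z(m),
        mu_w=z(h, m), mu_b=z(m), sigma_w=z(h, m), sigma_b=z(m), **kwargs
    )


def random_instance(seed, n=50, h=3, connected=True, activation="exponential"):
    """Random weights (nonzero biases) plus a random small dataset."""
    rng = np.random.default_rng(seed)
    w = glorot_uniform_init(
        hidden_units=h, seed=seed, alpha_connected=connected,
        scale_activation=activation,
    )
    w = dataclasses.replace(
        w,
        hidden_b=rng.normal(0, 0.5, h),
        alpha_b=rng.normal(0, 0.5, 2),
        mu_b=rng.normal(0, 1.0, 2),
        sigma_b=rng.normal(0, 0.5, 2),
    )
    data = LabeledDataset(rng.uniform(-2, 2, n), rng.normal(0, 1.5, n))
    return w, data
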