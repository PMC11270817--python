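"""Maximum-likelihood training of one flow per metastable state.

The protocol: Adam at a fixed learning rate, minibatches drawn without
replacement (epoch-wise seeded shuffling), an evaluation callback invoked
every ``eval_stride`` batches starting at the first stride, and an optional
mid-training event at which the train/validation splits are swapped and the
flow parameters (and optimizer state) are reset to their initial values.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .flows import BaseUniform, SplineCouplingFlow
from .model_systems import ReducedPotential

__all__ = [
    "TrainConfig",
    "Adam",
    "ml_loss",
    "train_state_model",
    "energy_sanity_fraction",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the fixed protocol used throughout the package:
    learning rate 0.001, batches of 1000 examples, an evaluation event every
    50 batches (first at batch 50), and a 50:50 train/validation split.
    ``swap_at`` (in batches) triggers the split-swap-and-reset event.
    """

    learning_rate: float = 1e-3
    batch_size: int = 1000
    eval_stride: int = 50
    n_batches: int = 10000
    split_fraction: float = 0.5
    swap_at: int | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.eval_stride, self.n_batches) <= 0:
            raise ValueError("learning rate, batch size, stride and batches must be positive")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split fraction must lie in (0, 1)")
        if self.eval_stride > self.n_batches:
            raise ValueError("evaluation stride exceeds the total batch count")


class Adam:
    """Adam on a list of per-layer parameter dicts (plain NumPy)."""

    def __init__(self, params: list[dict], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    def step(self, params: list[dict], grads: list[dict]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            for k in p:
                m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g[k]
                v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * g[k] ** 2
                p[k] -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)


def ml_loss(flow: SplineCouplingFlow, base: BaseUniform, batch: np.ndarray) -> float:
    """Negative mean log-likelihood -(1/N) sum ln q(r_n) under the flow.

    Any zero-density row makes the loss +inf; it is reported, never dropped.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if len(batch) == 0:
        raise ValueError("empty batch")
    from .flows import flow_log_q

    lq = flow_log_q(flow, base, batch)
    if not np.all(np.isfinite(lq)):
        return float("inf")
    return float(-np.mean(lq))


class _EpochSampler:
    """Without-replacement minibatch stream via seeded epoch-wise shuffling.

    A partial final batch at the end of an epoch is dropped; when the data
    set is not larger than one batch, every "batch" is the full set.
    """

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch_size = min(batch_size, n)
        self.rng = rng
        self._perm = rng.permutation(n)
        self._cursor = 0

    def next_batch(self) -> np.ndarray:
        if self._cursor + self.batch_size > self.n:
            self._perm = self.rng.permutation(self.n)
            self._cursor = 0
        idx = self._perm[self._cursor : self._cursor + self.batch_size]
        self._cursor += self.batch_size
        return idx


def train_state_model(
    flow: SplineCouplingFlow,
    base: BaseUniform,
    train_data: np.ndarray,
    val_data: np.ndarray,
    config: TrainConfig,
    eval_hook: Callable[[int, SplineCouplingFlow, np.ndarray, np.ndarray], None] | None = None,
) -> SplineCouplingFlow:
    """Run the full training protocol on one state's data.

    ``eval_hook(batch_idx, flow, train_split, val_split)`` fires at every
    evaluation stride with the *current* split assignment, so downstream
    estimator evaluations automatically follow the swap.  At ``swap_at`` the
    splits are exchanged and the parameters, optimizer moments and epoch
    cursor are restored to their initial state.  Divergence (infinite loss)
    aborts with a diagnostic.
    """
    train_data = np.atleast_2d(np.asarray(train_data, dtype=float))
    val_data = np.atleast_2d(np.asarray(val_data, dtype=float))
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("empty train or validation split")

    rng = np.random.default_rng(config.seed)
    theta0 = flow.get_params()
    # operate on the flow's own arrays so the optimizer updates in place
    params = [layer.params for layer in flow.layers]
    opt = Adam(params, lr=config.learning_rate)
    sampler = _EpochSampler(len(train_data), config.batch_size, rng)
    cur_train, cur_val = train_data, val_data

    for batch_idx in range(1, config.n_batches + 1):
        if config.swap_at is not None and batch_idx == config.swap_at + 1:
            cur_train, cur_val = cur_val, cur_train
            flow.set_params(theta0)
            params = [layer.params for layer in flow.layers]
            opt = Adam(params, lr=config.learning_rate)
            sampler = _EpochSampler(len(cur_train), config.batch_size, rng)
        idx = sampler.next_batch()
        loss, grads = flow.neg_log_likelihood_and_grad(cur_train[idx], base)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged at batch {batch_idx}: non-finite likelihood"
            )
        opt.step(params, grads)
        if eval_hook is not None and batch_idx % config.eval_stride == 0:
            eval_hook(batch_idx, flow, cur_train, cur_val)
    return flow


def energy_sanity_fraction(
    samples: np.ndarray,
    potential: ReducedPotential,
    threshold: float = 100.0,
    u_min: float | None = None,
) -> float:
    """Fraction of model samples with a reasonable energy, u - u_min < threshold.

    The default threshold is 100 k_B T.  ``u_min`` defaults to the potential's
    own minimum when it exposes one, else to the sample minimum.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if len(samples) == 0:
        raise ValueError("empty batch")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    u = potential(samples)
    if u_min is None:
        u_min = potential.min_energy() if hasattr(potential, "min_energy") else float(np.min(u))
    return float(np.mean(u - u_min < threshold))
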