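"""Bayesian hyperparameter optimization with expected improvement.

A Gaussian-process surrogate (Matern-5/2 over log-scaled continuous and
rounded integer dimensions) models the mean validation loss as a function of
the hyperparameters; the expected-improvement acquisition picks the next
trial. The default search mirrors the study design: learning rate in
[1e-5, 1e-3], orthogonality strength in [1e-25, 1e-5], hidden size 50..140,
bottleneck size 35..75, and — in "complex" mode — L1 and weight decay in
[1e-25, 1e-5]; 40 trials of 100 epochs each against a fixed 5% hold-out,
then 400 extra epochs of training for the winning configuration.

The objective here is a loss to be *minimized*, so EI is taken of the
negated objective: EI(x) = (f* - mu) Phi(z) + sigma phi(z), z = (f* - mu)/sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .data_io import ExpressionMatrix
from .model import AEHyperparams, AEModel, TrainingDivergedError, TrainingHistory, train_model

logger = logging.getLogger(__name__)

N_INITIAL_POINTS = 5  # uniform-random trials before the surrogate is fitted
_N_CANDIDATES = 1024
_N_REFINE = 64


def expected_improvement(mu: float, sigma: float, f_best: float) -> float:
    """Closed-form EI for minimization: E[max(f_best - N(mu, sigma^2), 0)].

    With sigma = 0 this degenerates to max(f_best - mu, 0)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return max(f_best - mu, 0.0)
    z = (f_best - mu) / sigma
    return float((f_best - mu) * norm.cdf(z) + sigma * norm.pdf(z))


@dataclass
class Dimension:
    """One search dimension: bounds, optional log10 scaling, integerness."""

    name: str
    low: float
    high: float
    log: bool = False
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log dimension needs positive bounds")

    # surrogate-internal coordinates
    def to_internal(self, value: float) -> float:
        return float(np.log10(value)) if self.log else float(value)

    def from_internal(self, u: float) -> float:
        v = float(10.0 ** u) if self.log else float(u)
        v = min(max(v, self.low), self.high)
        if self.integer:
            v = int(round(v))
            v = min(max(v, int(np.ceil(self.low))), int(np.floor(self.high)))
        return v

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.log:
            return (float(np.log10(self.low)), float(np.log10(self.high)))
        return (self.low, self.high)


@dataclass
class SearchSpace:
    """The hyperparameter box of the study (defaults as reported)."""

    lr_range: tuple[float, float] = (1e-5, 1e-3)
    ortho_range: tuple[float, float] = (1e-25, 1e-5)
    hidden_range: tuple[int, int] = (50, 140)
    bottleneck_range: tuple[int, int] = (35, 75)
    l1_range: tuple[float, float] = (1e-25, 1e-5)
    wd_range: tuple[float, float] = (1e-25, 1e-5)

    def dimensions(self, mode: str = "simple") -> list[Dimension]:
        dims = [
            Dimension("lr", *self.lr_range, log=True),
            Dimension("lambda_ortho", *self.ortho_range, log=True),
            Dimension("hidden_size", *self.hidden_range, integer=True),
            Dimension("bottleneck_size", *self.bottleneck_range, integer=True),
        ]
        if mode == "complex":
            dims.append(Dimension("l1", *self.l1_range, log=True))
            dims.append(Dimension("weight_decay", *self.wd_range, log=True))
        elif mode != "simple":
            raise ValueError(f"unknown mode {mode!r}")
        return dims


class BayesianOptimizer:
    """Generic ask/tell EI optimizer over a list of :class:`Dimension`.

    The first :data:`N_INITIAL_POINTS` asks are uniform random in the box;
    afterwards a GP (Matern-5/2 + white noise) is refitted on all observed
    points and the EI maximizer over 1024 random candidates plus a local
    Gaussian refinement around the best candidate is returned. Deterministic
    under the seed."""

    def __init__(self, dimensions: Sequence[Dimension], seed: int = 0,
                 n_initial: int = N_INITIAL_POINTS):
        self.dimensions = list(dimensions)
        self.rng = np.random.default_rng(seed)
        self.n_initial = n_initial
        self.X: list[np.ndarray] = []  # internal coordinates
        self.y: list[float] = []

    @property
    def f_best(self) -> float:
        finite = [v for v in self.y if np.isfinite(v)]
        return min(finite) if finite else np.inf

    def _sample(self, n: int) -> np.ndarray:
        cols = []
        for d in self.dimensions:
            lo, hi = d.internal_bounds
            cols.append(self.rng.uniform(lo, hi, size=n))
        return np.column_stack(cols)

    def _to_values(self, u: np.ndarray) -> dict[str, float]:
        return {d.name: d.from_internal(ui) for d, ui in zip(self.dimensions, u)}

    def ask(self) -> dict[str, float]:
        n_obs = sum(np.isfinite(v) for v in self.y)
        if n_obs < self.n_initial:
            return self._to_values(self._sample(1)[0])

        X = np.array([x for x, v in zip(self.X, self.y) if np.isfinite(v)])
        y = np.array([v for v in self.y if np.isfinite(v)])
        scale = np.array([d.internal_bounds[1] - d.internal_bounds[0]
                          for d in self.dimensions])
        kernel = ConstantKernel(1.0) * Matern(
            length_scale=np.full(len(self.dimensions), 0.3),
            length_scale_bounds=(1e-2, 1e2),
            nu=2.5,
        ) + WhiteKernel(1e-6, (1e-10, 1e-1))
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=0, alpha=1e-10
        )
        gp.fit(X / scale, y)

        cand = self._sample(_N_CANDIDATES)
        mu, sd = gp.predict(cand / scale, return_std=True)
        f_best = float(y.min())
        ei = np.array([expected_improvement(m, s, f_best) for m, s in zip(mu, sd)])
        best = cand[int(np.argmax(ei))]

        # local refinement around the incumbent candidate
        local = best + self.rng.normal(scale=0.05 * scale,
                                       size=(_N_REFINE, len(self.dimensions)))
        for j, d in enumerate(self.dimensions):
            lo, hi = d.internal_bounds
            local[:, j] = np.clip(local[:, j], lo, hi)
        mu_l, sd_l = gp.predict(local / scale, return_std=True)
        ei_l = np.array([expected_improvement(m, s, f_best) for m, s in zip(mu_l, sd_l)])
        if ei_l.max() > ei.max():
            best = local[int(np.argmax(ei_l))]
        return self._to_values(best)

    def tell(self, values: dict[str, float], objective: float) -> None:
        u = np.array([d.to_internal(max(min(values[d.name], d.high), d.low))
                      for d in self.dimensions])
        self.X.append(u)
        self.y.append(float(objective))


def _hp_from_values(values: dict[str, float], base: AEHyperparams) -> AEHyperparams:
    fields = {k: v for k, v in values.items()}
    if "hidden_size" in fields:
        fields["hidden_size"] = int(fields["hidden_size"])
    if "bottleneck_size" in fields:
        fields["bottleneck_size"] = int(fields["bottleneck_size"])
    return replace(base, **fields)


def run_optimization(
    m: ExpressionMatrix,
    space: SearchSpace | None = None,
    n_trials: int = 40,
    trial_epochs: int = 100,
    val_fraction: float = 0.05,
    mode: str = "simple",
    seed: int = 0,
    base_hp: AEHyperparams | None = None,
) -> tuple[AEHyperparams, pd.DataFrame, AEModel]:
    """Optimize the autoencoder's hyperparameters on a normalized, filtered
    matrix.

    Each trial trains a fresh model for ``trial_epochs`` epochs and records
    the mean loss of the cells in a fixed hold-out split (stratified by
    label when labels exist, so trials are comparable). Diverged trials are
    recorded with +inf loss and the search continues. Returns the best
    hyperparameters, the full trial table, and the best trial's model.
    """
    space = space or SearchSpace()
    base_hp = base_hp or AEHyperparams()
    dims = space.dimensions(mode)
    opt = BayesianOptimizer(dims, seed=seed)
    rng = np.random.default_rng(seed)
    val_indices = _holdout_indices(m, val_fraction, rng)

    rows = []
    best_loss = np.inf
    best_hp: AEHyperparams | None = None
    best_model: AEModel | None = None
    for trial in range(n_trials):
        values = opt.ask()
        hp = _hp_from_values(values, replace(base_hp, epochs=trial_epochs,
                                             seed=seed + 1000 + trial))
        try:
            trained, history = train_model(
                m, hp, val_fraction, val_indices=val_indices
            )
            loss = float(np.min(history.val_loss)) if history.val_loss else np.inf
        except TrainingDivergedError as exc:
            logger.warning("trial %d diverged: %s", trial, exc)
            trained, loss = None, np.inf
        opt.tell(values, loss)
        rows.append({"trial": trial, **values, "mean_val_loss": loss})
        if loss < best_loss and trained is not None:
            best_loss, best_hp, best_model = loss, hp, trained
    if best_hp is None:
        raise TrainingDivergedError("every trial diverged")
    table = pd.DataFrame(rows)
    return best_hp, table, best_model


def _holdout_indices(
    m: ExpressionMatrix, val_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """5% hold-out, stratified by cell-type label when labels exist."""
    n_val = max(1, int(round(m.n_cells * val_fraction)))
    if m.labels is None:
        return rng.permutation(m.n_cells)[:n_val]
    labels = np.asarray(m.labels)
    picked: list[int] = []
    for lab in sorted(set(m.labels)):
        idx = np.flatnonzero(labels == lab)
        k = max(1, int(round(len(idx) * val_fraction)))
        picked.extend(rng.permutation(idx)[:k].tolist())
    return np.array(sorted(picked))


def finalize_model(
    m: ExpressionMatrix,
    best_hp: AEHyperparams,
    extra_epochs: int = 400,
    *,
    model: AEModel | None = None,
    val_fraction: float = 0.05,
    val_indices: np.ndarray | None = None,
) -> tuple[AEModel, TrainingHistory]:
    """Continue training the best trial's model for ``extra_epochs`` more
    epochs (early stopping active) to constitute the final model.

    When ``model`` is omitted the best trial is retrained deterministically
    from ``best_hp`` first. Pass the hold-out ``val_indices`` used by
    :func:`run_optimization` to keep the training set identical to the
    trial's."""
    history = TrainingHistory()
    if model is None:
        model, hist0 = train_model(m, best_hp, val_fraction,
                                   val_indices=val_indices)
        history.extend(hist0)
    if extra_epochs == 0:
        return model, history
    hp = replace(best_hp, epochs=extra_epochs)
    final, hist1 = train_model(m, hp, val_fraction, initial_model=model,
                               val_indices=val_indices)
    history.extend(hist1)
    return final, history
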