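"""Orthogonality-constrained Poisson autoencoder.

A fully connected network with two encoding and two decoding layers, all
with softplus activations, trained by SGD with Nesterov momentum on

    loss = mean(y - x * log(y + eps)) + lambda * ||I - W W^T||_F + l1 * sum|W|

where ``y = decode(encode(x))`` is the reconstruction (the softplus output
keeps the Poisson rate strictly positive), ``W`` is the weight matrix of the
final encoding layer (hidden -> bottleneck), and the Frobenius-norm penalty
pushes the bottleneck units toward non-redundant, orthonormal-row weight
vectors. Weight decay, when used, is the optimizer's L2 term, not part of
the reported loss. Forward and backward passes are explicit numpy; the
backward pass is verified against central finite differences in the test
suite.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .data_io import LOGCPM, ExpressionMatrix

logger = logging.getLogger(__name__)

_WEIGHT_NAMES = ("W1", "W2", "W3", "W4")
_BIAS_NAMES = ("b1", "b2", "b3", "b4")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def softplus(x: np.ndarray) -> np.ndarray:
    # overflow-safe: log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@dataclass
class AEHyperparams:
    """Hyperparameters of the autoencoder and its optimizer.

    ``lambda_ortho`` scales the soft orthogonality constraint; ``l1`` the L1
    penalty on all four weight matrices; ``weight_decay`` is the optimizer's
    L2 coefficient. ``epsilon`` stabilizes log(y + eps) in the Poisson NLL.
    """

    lr: float = 1e-3
    lambda_ortho: float = 1e-5
    hidden_size: int = 64
    bottleneck_size: int = 16
    l1: float = 0.0
    weight_decay: float = 0.0
    momentum: float = 0.9
    epochs: int = 100
    patience: int = 10
    batch_size: int = 64
    seed: int = 0
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.lambda_ortho < 0 or self.l1 < 0 or self.weight_decay < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.bottleneck_size < 1 or self.hidden_size < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.bottleneck_size > self.hidden_size:
            # allowed, but contradicts every reported optimization outcome
            logger.warning(
                "bottleneck_size %d exceeds hidden_size %d",
                self.bottleneck_size,
                self.hidden_size,
            )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    ortho_penalty: list[float] = field(default_factory=list)
    stopped_epoch: int = 0

    def extend(self, other: "TrainingHistory") -> None:
        self.train_loss.extend(other.train_loss)
        self.val_loss.extend(other.val_loss)
        self.ortho_penalty.extend(other.ortho_penalty)
        self.stopped_epoch = len(self.train_loss)


@dataclass
class AEModel:
    """Weights, biases and metadata of the 2+2-layer autoencoder.

    ``W2`` (bottleneck x hidden), the final encoding layer, is the matrix
    entering the orthogonality penalty. ``gene_ids`` records the training
    gene order, which is part of the model contract when the model is
    transferred to foreign datasets.
    """

    W1: np.ndarray  # hidden x genes
    W2: np.ndarray  # bottleneck x hidden
    W3: np.ndarray  # hidden x bottleneck
    W4: np.ndarray  # genes x hidden
    b1: np.ndarray
    b2: np.ndarray
    b3: np.ndarray
    b4: np.ndarray
    hyperparams: AEHyperparams
    gene_ids: list[str]
    trained: bool = False

    @property
    def n_genes(self) -> int:
        return self.W1.shape[1]

    @property
    def bottleneck_size(self) -> int:
        return self.W2.shape[0]

    def weights(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _WEIGHT_NAMES}

    def params(self) -> dict[str, np.ndarray]:
        return {n: getattr(self, n) for n in _WEIGHT_NAMES + _BIAS_NAMES}

    def copy(self) -> "AEModel":
        return AEModel(
            **{n: getattr(self, n).copy() for n in _WEIGHT_NAMES + _BIAS_NAMES},
            hyperparams=replace(self.hyperparams),
            gene_ids=list(self.gene_ids),
            trained=self.trained,
        )


def _xavier_normal(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_out, fan_in))


def init_model(
    hp: AEHyperparams, n_genes: int, gene_ids: Sequence[str] | None = None
) -> AEModel:
    """Xavier-normal initialized, untrained model (biases zero).

    An untrained model doubles as the "randomly initialized autoencoder"
    baseline of the transfer evaluation."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match n_genes")
    rng = np.random.default_rng(hp.seed)
    h, k = hp.hidden_size, hp.bottleneck_size
    return AEModel(
        W1=_xavier_normal(rng, h, n_genes),
        W2=_xavier_normal(rng, k, h),
        W3=_xavier_normal(rng, h, k),
        W4=_xavier_normal(rng, n_genes, h),
        b1=np.zeros(h),
        b2=np.zeros(k),
        b3=np.zeros(h),
        b4=np.zeros(n_genes),
        hyperparams=replace(hp),
        gene_ids=list(gene_ids),
    )


# ---------------------------------------------------------------------------
# forward / loss


def forward(model: AEModel, X: np.ndarray) -> dict[str, np.ndarray]:
    """Full forward pass returning pre-activations and activations of every
    layer (needed by backprop and guided backprop)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    A1 = X @ model.W1.T + model.b1
    H1 = softplus(A1)
    A2 = H1 @ model.W2.T + model.b2
    Z = softplus(A2)
    A3 = Z @ model.W3.T + model.b3
    H2 = softplus(A3)
    A4 = H2 @ model.W4.T + model.b4
    Y = softplus(A4)
    return {"X": X, "A1": A1, "H1": H1, "A2": A2, "Z": Z,
            "A3": A3, "H2": H2, "A4": A4, "Y": Y}


def _check_gene_match(model: AEModel, m: ExpressionMatrix) -> None:
    if m.gene_ids != model.gene_ids:
        raise ValueError(
            "matrix genes do not match the model's training genes; use "
            "transfer.project_dataset to align a foreign dataset"
        )


def encode(model: AEModel, m: ExpressionMatrix) -> np.ndarray:
    """Bottleneck activations (cells x bottleneck_size), strictly positive."""
    _check_gene_match(model, m)
    return forward(model, m.values)["Z"]


def reconstruct(model: AEModel, m: ExpressionMatrix) -> np.ndarray:
    """Decoded reconstruction (cells x genes), strictly positive."""
    _check_gene_match(model, m)
    return forward(model, m.values)["Y"]


def poisson_nll(x: np.ndarray, y: np.ndarray, eps: float = 1e-8) -> float:
    """mean(y - x * log(y + eps)) over all matrix entries."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean(y - x * np.log(y + eps)))


def orthogonality_penalty(W: np.ndarray, lam: float) -> float:
    """lam * ||I - W W^T||_F; zero iff W has orthonormal rows (lam > 0)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    W = np.asarray(W, dtype=np.float64)
    D = np.eye(W.shape[0]) - W @ W.T
    return float(lam * np.linalg.norm(D, "fro"))


def l1_penalty(model: AEModel, l1: float) -> float:
    return float(l1 * sum(np.abs(w).sum() for w in model.weights().values()))


def total_loss(
    X: np.ndarray,
    model: AEModel,
    lam: float | None = None,
    l1: float | None = None,
    *,
    cache: dict[str, np.ndarray] | None = None,
) -> float:
    """Poisson NLL of the reconstruction plus orthogonality and L1 penalties.

    Weight decay is deliberately absent: it is applied as the optimizer's
    L2 term during training, not as part of the reported loss."""
    hp = model.hyperparams
    lam = hp.lambda_ortho if lam is None else lam
    l1 = hp.l1 if l1 is None else l1
    if cache is None:
        cache = forward(model, X)
    nll = poisson_nll(cache["X"], cache["Y"], hp.epsilon)
    return nll + orthogonality_penalty(model.W2, lam) + l1_penalty(model, l1)


# ---------------------------------------------------------------------------
# gradients


def gradients(
    model: AEModel,
    X: np.ndarray,
    lam: float | None = None,
    l1: float | None = None,
) -> dict[str, np.ndarray]:
    """Analytic gradient of ``total_loss`` w.r.t. every weight and bias."""
    hp = model.hyperparams
    lam = hp.lambda_ortho if lam is None else lam
    l1 = hp.l1 if l1 is None else l1
    c = forward(model, X)
    X, Y = c["X"], c["Y"]
    n = X.size

    dY = (1.0 - X / (Y + hp.epsilon)) / n
    dA4 = dY * expit(c["A4"])
    g = {
        "W4": dA4.T @ c["H2"],
        "b4": dA4.sum(axis=0),
    }
    dH2 = dA4 @ model.W4
    dA3 = dH2 * expit(c["A3"])
    g["W3"] = dA3.T @ c["Z"]
    g["b3"] = dA3.sum(axis=0)
    dZ = dA3 @ model.W3
    dA2 = dZ * expit(c["A2"])
    g["W2"] = dA2.T @ c["H1"]
    g["b2"] = dA2.sum(axis=0)
    dH1 = dA2 @ model.W2
    dA1 = dH1 * expit(c["A1"])
    g["W1"] = dA1.T @ X
    g["b1"] = dA1.sum(axis=0)

    if lam > 0:
        W2 = model.W2
        D = np.eye(W2.shape[0]) - W2 @ W2.T
        fro = np.linalg.norm(D, "fro")
        if fro > 0:  # subgradient 0 at the orthonormal point
            g["W2"] += lam * (-2.0 * D @ W2) / fro
    if l1 > 0:
        for name in _WEIGHT_NAMES:
            g[name] += l1 * np.sign(getattr(model, name))
    return g


# ---------------------------------------------------------------------------
# training


def _validation_loss(model: AEModel, X_val: np.ndarray, lam: float) -> float:
    cache = forward(model, X_val)
    return poisson_nll(cache["X"], cache["Y"], model.hyperparams.epsilon) + \
        orthogonality_penalty(model.W2, lam)


def train_model(
    m: ExpressionMatrix,
    hp: AEHyperparams,
    val_fraction: float = 0.05,
    *,
    initial_model: AEModel | None = None,
    val_indices: np.ndarray | None = None,
) -> tuple[AEModel, TrainingHistory]:
    """Train by minibatch SGD with Nesterov momentum and early stopping.

    The validation split (default 5%) drives early stopping: training stops
    once the validation loss has not improved for ``hp.patience`` epochs, and
    the best-validation-epoch weights are restored. Weight decay enters as
    the optimizer's L2 term. Deterministic under ``hp.seed``; pass
    ``initial_model`` to continue training an existing model and
    ``val_indices`` to pin the hold-out cells (as the hyperparameter search
    does so its trials share one split).
    """
    if m.space != LOGCPM:
        raise ValueError("train_model expects a log-CPM matrix")
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to train")
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must be in (0, 1)")

    rng = np.random.default_rng(hp.seed)
    if val_indices is None:
        n_val = max(1, int(round(m.n_cells * val_fraction)))
        perm = rng.permutation(m.n_cells)
        val_indices = perm[:n_val]
    val_indices = np.asarray(val_indices)
    train_mask = np.ones(m.n_cells, dtype=bool)
    train_mask[val_indices] = False
    X_train = m.values[train_mask]
    X_val = m.values[val_indices]
    if X_train.shape[0] == 0:
        raise ValueError("validation split leaves no training cells")

    model = (initial_model.copy() if initial_model is not None
             else init_model(hp, m.n_genes, m.gene_ids))
    history = TrainingHistory()
    if hp.epochs == 0:
        return model, history

    lam, l1 = hp.lambda_ortho, hp.l1
    velocity = {n: np.zeros_like(p) for n, p in model.params().items()}
    best_val = np.inf
    best_params = {n: p.copy() for n, p in model.params().items()}
    epochs_since_best = 0

    n_train = X_train.shape[0]
    for epoch in range(1, hp.epochs + 1):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, hp.batch_size):
            batch = X_train[order[start : start + hp.batch_size]]
            g = gradients(model, batch, lam, l1)
            for name, grad in g.items():
                p = getattr(model, name)
                if hp.weight_decay > 0 and name in _WEIGHT_NAMES:
                    grad = grad + hp.weight_decay * p
                v = velocity[name]
                v *= hp.momentum
                v += grad
                step = grad + hp.momentum * v if hp.momentum > 0 else v
                p -= hp.lr * step
            batch_loss = total_loss(batch, model, lam, l1)
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}; try a lower lr"
                )
            epoch_loss += batch_loss
            n_batches += 1

        val_loss = _validation_loss(model, X_val, lam)
        history.train_loss.append(epoch_loss / n_batches)
        history.val_loss.append(float(val_loss))
        history.ortho_penalty.append(orthogonality_penalty(model.W2, 1.0))
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(
                f"non-finite validation loss at epoch {epoch}; try a lower lr"
            )
        if val_loss < best_val:
            best_val = val_loss
            best_params = {n: p.copy() for n, p in model.params().items()}
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= hp.patience:
                break

    for name, p in best_params.items():
        setattr(model, name, p)
    model.trained = True
    history.stopped_epoch = len(history.train_loss)
    return model, history


# ---------------------------------------------------------------------------
# serialization — a deterministic container (JSON header + raw float64
# arrays) so identical models produce bit-identical files


_MAGIC = b"ORTHOAE1"


def save_model(model: AEModel, path: str | Path) -> None:
    names = _WEIGHT_NAMES + _BIAS_NAMES
    header = {
        "format": "orthoae-model-v1",
        "hyperparams": asdict(model.hyperparams),
        "gene_ids": model.gene_ids,
        "trained": model.trained,
        "arrays": {n: list(getattr(model, n).shape) for n in names},
    }
    hdr = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(hdr)))
        fh.write(hdr)
        for n in names:
            arr = np.ascontiguousarray(getattr(model, n), dtype="<f8")
            fh.write(arr.tobytes())


def load_model(path: str | Path) -> AEModel:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a model file")
        (hdr_len,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hdr_len))
        arrays = {}
        for n in _WEIGHT_NAMES + _BIAS_NAMES:
            shape = tuple(header["arrays"][n])
            count = int(np.prod(shape)) if shape else 1
            buf = fh.read(count * 8)
            arrays[n] = np.frombuffer(buf, dtype="<f8").reshape(shape).copy()
    hp = AEHyperparams(**header["hyperparams"])
    return AEModel(**arrays, hyperparams=hp, gene_ids=header["gene_ids"],
                   trained=header["trained"])
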