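"""Foreign-model projection and kNN label-transfer evaluation.

A trained autoencoder is applied to a dataset it never saw: the foreign
dataset's genes are aligned to the model's training gene order (shared genes
mapped by exact symbol, model genes absent from the data zero-filled, extra
genes dropped), the cells are encoded, and a kNN classifier fitted on one
dataset's representation predicts cell-type labels in another. Comparing
the trained-encoded, raw, and randomly-initialized-encoded representations
against the majority-vote floor quantifies how much transferable structure
the trained model carries.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.neighbors import NearestNeighbors

from .data_io import ExpressionMatrix
from .model import AEModel, forward, init_model

logger = logging.getLogger(__name__)

MIN_COVERAGE = 0.10
WARN_COVERAGE = 0.50

REPRESENTATIONS = ("encoded", "raw", "random-init-encoded")


def align_to_model(model: AEModel, m: ExpressionMatrix) -> tuple[np.ndarray, float]:
    """Reorder ``m``'s columns to the model's gene order; zero-fill model
    genes missing from ``m``; drop extra genes. Returns the aligned matrix
    and the coverage fraction |shared| / |model genes|."""
    col = {g: j for j, g in enumerate(m.gene_ids)}
    X = np.zeros((m.n_cells, model.n_genes))
    shared = 0
    for j, g in enumerate(model.gene_ids):
        if g in col:
            X[:, j] = m.values[:, col[g]]
            shared += 1
    return X, shared / model.n_genes


def project_dataset(
    model: AEModel, m: ExpressionMatrix, *, return_coverage: bool = False
) -> np.ndarray | tuple[np.ndarray, float]:
    """Encode a (possibly foreign) dataset through the model.

    Gene spaces may differ: alignment is by exact symbol. Coverage below
    10% of the model's genes is an error (the projection would be
    meaningless); below 50% a warning."""
    X, coverage = align_to_model(model, m)
    if coverage < MIN_COVERAGE:
        raise ValueError(
            f"only {coverage:.1%} of the model's genes are present in the "
            "dataset; projection would be meaningless"
        )
    if coverage < WARN_COVERAGE:
        logger.warning("low gene coverage for projection: %.1f%%",
                       100 * coverage)
    logger.info("projection gene coverage: %.1f%%", 100 * coverage)
    latent = forward(model, X)["Z"]
    return (latent, coverage) if return_coverage else latent


def knn_classify(
    train_points: np.ndarray,
    train_labels: Sequence[str],
    test_points: np.ndarray,
    k: int,
) -> list[str]:
    """Majority label among the k Euclidean-nearest training points.

    Ties are broken deterministically: the tied label with the smaller
    summed neighbor distance wins, remaining ties lexicographically."""
    train_points = np.asarray(train_points, dtype=np.float64)
    test_points = np.asarray(test_points, dtype=np.float64)
    n_train = train_points.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_train:
        raise ValueError(f"k={k} exceeds the {n_train} training points")
    labels = np.asarray(train_labels)
    nn = NearestNeighbors(n_neighbors=k, algorithm="brute", metric="euclidean")
    nn.fit(train_points)
    dist, idx = nn.kneighbors(test_points)
    out: list[str] = []
    for d_row, i_row in zip(dist, idx):
        votes: dict[str, list[float]] = {}
        for d, i in zip(d_row, i_row):
            votes.setdefault(labels[i], []).append(float(d))
        best = min(
            votes.items(),
            key=lambda kv: (-len(kv[1]), sum(kv[1]), kv[0]),
        )
        out.append(best[0])
    return out


def score_predictions(
    pred: Sequence[str], truth: Sequence[str]
) -> tuple[float, float, float]:
    """(accuracy, macro F1, majority-vote accuracy).

    Accuracy is correct / (correct + false); macro F1 averages per-class F1
    over classes present in the truth; the majority-vote accuracy is the
    frequency of the modal truth label — the floor an informative
    representation must beat."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth lengths differ")
    if not truth:
        raise ValueError("empty input")
    correct = sum(p == t for p, t in zip(pred, truth))
    accuracy = correct / len(truth)
    classes = sorted(set(truth))
    macro = float(f1_score(truth, pred, labels=classes, average="macro",
                           zero_division=0))
    counts = pd.Series(truth).value_counts()
    majority = float(counts.iloc[0] / len(truth))
    return float(accuracy), macro, majority


def _representation_points(
    representation: str,
    model: AEModel,
    random_model: AEModel,
    train_m: ExpressionMatrix,
    test_m: ExpressionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    if representation == "encoded":
        return project_dataset(model, train_m), project_dataset(model, test_m)
    if representation == "random-init-encoded":
        return (project_dataset(random_model, train_m),
                project_dataset(random_model, test_m))
    if representation == "raw":
        # shared-gene intersection: zero-filling raw data would distort
        # distances, unlike the latent path where the model handles it
        shared = [g for g in train_m.gene_ids if g in set(test_m.gene_ids)]
        if not shared:
            raise ValueError("no shared genes for the raw representation")
        tr_idx = [train_m.gene_ids.index(g) for g in shared]
        te_idx = [test_m.gene_ids.index(g) for g in shared]
        return train_m.values[:, tr_idx], test_m.values[:, te_idx]
    raise ValueError(f"unknown representation {representation!r}")


def evaluate_representations(
    train_ds: ExpressionMatrix,
    test_datasets: Mapping[str, ExpressionMatrix],
    model: AEModel,
    k_values: Sequence[int] = tuple(range(2, 26)),
    *,
    random_seed: int = 0,
    representations: Sequence[str] = REPRESENTATIONS,
) -> pd.DataFrame:
    """Label-transfer scores for every (test dataset, representation, k).

    The kNN is fitted on the training dataset's representation and predicts
    each test dataset. Test cells whose labels never occur in the training
    dataset are excluded from scoring (only common cell-type labels are
    scorable); pairs with no overlapping labels are skipped with a logged
    reason. The random-init representation re-initializes the model's
    architecture from ``random_seed``.
    """
    if train_ds.labels is None:
        raise ValueError("training dataset has no labels")
    random_model = init_model(
        replace(model.hyperparams, seed=random_seed),
        model.n_genes,
        model.gene_ids,
    )
    train_labels = np.asarray(train_ds.labels)
    train_label_set = set(train_ds.labels)
    rows = []
    for name, test_m in test_datasets.items():
        if test_m.labels is None:
            raise ValueError(f"test dataset {name!r} has no labels")
        test_labels = np.asarray(test_m.labels)
        keep = np.array([l in train_label_set for l in test_labels])
        if not keep.any():
            logger.warning("pair %r skipped: no overlapping cell-type labels",
                           name)
            continue
        common = sorted(set(test_labels[keep]))
        for representation in representations:
            tr_pts, te_pts = _representation_points(
                representation, model, random_model, train_ds, test_m
            )
            te_pts = te_pts[keep]
            truth = list(test_labels[keep])
            for k in k_values:
                pred = knn_classify(tr_pts, train_labels, te_pts, k)
                acc, macro, majority = score_predictions(pred, truth)
                rows.append({
                    "target_dataset": name,
                    "representation": representation,
                    "k": int(k),
                    "accuracy": acc,
                    "macro_f1": macro,
                    "majority_vote_accuracy": majority,
                    "n_cells": int(keep.sum()),
                    "label_universe": ";".join(common),
                })
    return pd.DataFrame(rows)
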