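"""Guided-backpropagation saliency maps for bottleneck units.

The saliency of gene g for bottleneck unit u in a given cell is the guided
gradient of the unit's (post-softplus) activation with respect to the input
value of g. Guided backpropagation, originally defined for ReLU networks,
is adapted to the softplus layers here: at each activation layer the
backward signal is zeroed wherever the incoming backward signal is negative,
while the local derivative remains the softplus derivative (the logistic
sigmoid). For ReLU the guided rule additionally zeroes negatively
pre-activated units, but that gate is the ReLU derivative itself; a softplus
unit with negative pre-activation still passes signal, and its derivative
already downweights it smoothly, so only the "positive backward evidence"
gate is applied here. Plain gradients are available via ``guided=False``.

Per-cell-type maps are signed means over the cells of the type; the
corrected map subtracts the whole-dataset map, isolating type-specific
signal (so correction is only meaningful for signed aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data_io import ExpressionMatrix
from .model import AEModel

WHOLE_DATASET = "whole-dataset"


@dataclass
class SaliencyMap:
    """bottleneck_units x genes matrix of aggregated guided gradients."""

    values: np.ndarray
    gene_ids: list[str]
    context: str
    n_cells_aggregated: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.gene_ids):
            raise ValueError("saliency values must be units x genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("saliency values must be finite")


def _backward_unit(model: AEModel, cache: dict[str, np.ndarray], unit: int,
                   guided: bool) -> np.ndarray:
    """Gradient of bottleneck unit ``unit`` w.r.t. the input, per cell."""
    A1, A2 = cache["A1"], cache["A2"]
    n_cells = A1.shape[0]
    dZ = np.zeros((n_cells, model.bottleneck_size))
    dZ[:, unit] = 1.0  # incoming signal is the one-hot unit selector, >= 0
    dA2 = dZ * expit(A2)
    dH1 = dA2 @ model.W2
    if guided:
        dH1 = dH1 * (dH1 > 0)
    dA1 = dH1 * expit(A1)
    return dA1 @ model.W1


def guided_backprop_cell(
    model: AEModel, cell: np.ndarray, unit: int, *, guided: bool = True
) -> np.ndarray:
    """Guided gradient of one bottleneck unit's activation for one cell."""
    if not 0 <= unit < model.bottleneck_size:
        raise ValueError(
            f"unit {unit} out of range for bottleneck of {model.bottleneck_size}"
        )
    from .model import forward

    cell = np.asarray(cell, dtype=np.float64).reshape(1, -1)
    if cell.shape[1] != model.n_genes:
        raise ValueError("cell vector length does not match model genes")
    cache = forward(model, cell)
    return _backward_unit(model, cache, unit, guided)[0]


def aggregate_saliency(
    model: AEModel,
    m: ExpressionMatrix,
    cells: np.ndarray | list[int] | None = None,
    *,
    context: str | None = None,
    guided: bool = True,
) -> SaliencyMap:
    """Mean guided gradient over a cell subset, for every bottleneck unit.

    ``cells`` selects rows of ``m`` (all cells when omitted, i.e. the
    whole-dataset map). Row u of the result is the mean over selected cells
    of the unit-u input gradient."""
    from .model import forward

    if m.gene_ids != model.gene_ids:
        raise ValueError("matrix genes do not match model genes")
    if cells is None:
        idx = np.arange(m.n_cells)
        ctx = context or WHOLE_DATASET
    else:
        idx = np.asarray(cells)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        ctx = context or "subset"
    if idx.size == 0:
        raise ValueError("empty cell subset")
    X = m.values[idx]
    cache = forward(model, X)
    rows = [
        _backward_unit(model, cache, u, guided).mean(axis=0)
        for u in range(model.bottleneck_size)
    ]
    return SaliencyMap(np.vstack(rows), list(m.gene_ids), ctx, int(idx.size))


def per_type_saliency(
    model: AEModel, m: ExpressionMatrix, *, guided: bool = True
) -> dict[str, SaliencyMap]:
    """One saliency map per cell type (requires labels)."""
    if m.labels is None:
        raise ValueError("matrix has no labels")
    labels = np.asarray(m.labels)
    return {
        t: aggregate_saliency(model, m, np.flatnonzero(labels == t),
                              context=f"cell-type:{t}", guided=guided)
        for t in sorted(set(m.labels))
    }


def corrected_saliency(type_map: SaliencyMap, global_map: SaliencyMap) -> SaliencyMap:
    """Type map minus the whole-dataset map (element-wise)."""
    if type_map.gene_ids != global_map.gene_ids:
        raise ValueError("saliency maps have mismatched gene order")
    if type_map.values.shape != global_map.values.shape:
        raise ValueError("saliency maps have mismatched shapes")
    return SaliencyMap(
        type_map.values - global_map.values,
        list(type_map.gene_ids),
        f"corrected:{type_map.context}",
        type_map.n_cells_aggregated,
    )


def save_saliency(sm: SaliencyMap, path: str | Path) -> None:
    """TSV (units x genes) with a context header line."""
    with open(path, "w") as fh:
        fh.write(f"# context={sm.context}\tn_cells={sm.n_cells_aggregated}\n")
        fh.write("unit\t" + "\t".join(sm.gene_ids) + "\n")
        for u, row in enumerate(sm.values):
            fh.write(str(u) + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def load_saliency(path: str | Path) -> SaliencyMap:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# context="):
            raise ValueError(f"{path}: missing saliency context header")
        meta = dict(kv.split("=", 1) for kv in header[2:].split("\t"))
        genes = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [
            [float(v) for v in line.rstrip("\n").split("\t")[1:]] for line in fh
        ]
    return SaliencyMap(np.array(rows), genes, meta["context"],
                       int(meta["n_cells"]))
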