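"""Expression-matrix, label, and gene-set I/O plus log-CPM normalization.

The canonical in-memory orientation is cells-as-rows. External dense files
are expected as a header row of gene ids and a first column of cell ids
(transpose on read if the file is genes x cells). Sparse matrices use
MatrixMarket coordinate format with one-id-per-line gene and barcode files;
orientation is inferred from which axis length matches which id file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

COUNTS = "counts"
LOGCPM = "logcpm"

CPM_SCALE = 1e6


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass
class ExpressionMatrix:
    """A cells x genes matrix of counts or log-CPM values.

    ``values[i, j]`` is the value of gene ``gene_ids[j]`` in cell
    ``cell_ids[i]``. ``labels``, when present, are per-cell type strings
    aligned with ``cell_ids``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    labels: list[str] | None = None
    space: str = COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes matrix")
        n_cells, n_genes = self.values.shape
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"{n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"{n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        for kind, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValueError(f"duplicate {kind} ids: {dups[:10]}")
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != n_cells:
                raise ValueError("labels length does not match cell count")
        if self.space not in (COUNTS, LOGCPM):
            raise ValueError(f"unknown space tag {self.space!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values contain negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def with_labels(self, labels: dict[str, str] | Sequence[str]) -> "ExpressionMatrix":
        if isinstance(labels, dict):
            missing = [c for c in self.cell_ids if c not in labels]
            if missing:
                raise ValueError(f"no label for cells: {missing[:10]}")
            lab = [labels[c] for c in self.cell_ids]
        else:
            lab = list(labels)
        return replace(self, labels=lab)


@dataclass
class GeneSetCollection:
    """Named gene sets in the MSigDB GMT sense (name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression matrices


def _read_dense(path: Path, transpose: bool) -> tuple[np.ndarray, list[str], list[str]]:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    for j, col in enumerate(df.columns):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col].map(lambda v: isinstance(v, str)).idxmax()
            raise ValueError(
                f"non-numeric entry in {path} at row {bad!r}, column {col!r}"
            )
    if transpose:
        df = df.T
    return df.to_numpy(dtype=np.float64), [str(c) for c in df.columns], [str(i) for i in df.index]


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        # first whitespace-delimited token per line (10x-style files may
        # carry extra columns)
        return [line.split()[0] for line in fh if line.strip()]


def _read_mtx(
    path: Path, genes_path: Path, cells_path: Path
) -> tuple[np.ndarray, list[str], list[str]]:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64)
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)
    nr, nc = mat.shape
    if nr == len(cells) and nc == len(genes):
        pass  # already cells x genes
    elif nr == len(genes) and nc == len(cells):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither ({len(cells)} cells, "
            f"{len(genes)} genes) nor its transpose"
        )
    return mat, genes, cells


def read_expression_matrix(
    path: str | Path,
    format: str = "dense",
    *,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    transpose: bool = False,
    space: str = COUNTS,
) -> ExpressionMatrix:
    """Read an expression matrix from a dense delimited file or a
    MatrixMarket triplet (with companion gene/barcode id files)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense":
        values, genes, cells = _read_dense(path, transpose)
    elif format in ("mtx", "matrixmarket", "matrixmarket-triplet"):
        if genes_path is None or cells_path is None:
            raise ValueError("MatrixMarket input needs genes_path and cells_path")
        values, genes, cells = _read_mtx(path, Path(genes_path), Path(cells_path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(values, genes, cells, space=space)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def write_mtx(m: ExpressionMatrix, path: str | Path,
              genes_path: str | Path, cells_path: str | Path) -> None:
    sp = scipy.sparse.coo_matrix(m.values)
    scipy.io.mmwrite(str(path), sp)
    Path(genes_path).write_text("".join(g + "\n" for g in m.gene_ids))
    Path(cells_path).write_text("".join(c + "\n" for c in m.cell_ids))


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column delimited file: cell_id <tab> label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype=str)
    dups = _find_duplicates(list(df["cell_id"]))
    if dups:
        raise ValueError(f"duplicate cell ids in label file: {dups[:10]}")
    return dict(zip(df["cell_id"], df["label"]))


def write_labels(m: ExpressionMatrix, path: str | Path) -> None:
    if m.labels is None:
        raise ValueError("matrix has no labels")
    with open(path, "w") as fh:
        for c, l in zip(m.cell_ids, m.labels):
            fh.write(f"{c}\t{l}\n")


# ---------------------------------------------------------------------------
# normalization


def normalize_log_cpm(m: ExpressionMatrix, base: float | None = None) -> ExpressionMatrix:
    """log(CPM + 1) per cell. Natural log by default; pass ``base`` to
    change it. Each cell must have a positive total count."""
    if m.space != COUNTS:
        raise ValueError(f"expected counts, got space={m.space!r}")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [m.cell_ids[i] for i in zero[:20]]
        raise ValueError(f"cells with zero total count: {names}")
    cpm = m.values / totals[:, None] * CPM_SCALE
    out = np.log1p(cpm)
    if base is not None:
        out = out / math.log(base)
    return ExpressionMatrix(out, m.gene_ids, m.cell_ids, labels=m.labels,
                            space=LOGCPM)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a tab-delimited GMT file: name, description, >=1 gene per line.

    Duplicate genes within a set are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: set[str] = set()
            uniq: list[str] = []
            for g in genes:
                if g in seen:
                    logger.warning(
                        "GMT set %r: duplicate gene %r dropped", name, g
                    )
                    continue
                seen.add(g)
                uniq.append(g)
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            if not uniq:
                raise ValueError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gs.sets.items():
            desc = gs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_to_gene_sets(m: ExpressionMatrix, gs: GeneSetCollection) -> ExpressionMatrix:
    """Keep exactly the genes of ``m`` that appear in the union of the gene
    sets, preserving ``m``'s gene order. Matching is by exact symbol."""
    union = gs.union()
    keep = [j for j, g in enumerate(m.gene_ids) if g in union]
    if not keep:
        raise ValueError("no genes of the matrix appear in the gene sets")
    return ExpressionMatrix(
        m.values[:, keep],
        [m.gene_ids[j] for j in keep],
        m.cell_ids,
        labels=m.labels,
        space=m.space,
    )
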