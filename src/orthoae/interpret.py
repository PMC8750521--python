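"""Preranked gene-set enrichment on saliency rows and overlap statistics.

Each bottleneck unit's corrected saliency row is turned into a descending
ranked gene list (ties broken by gene id for determinism); the classic
weighted running-sum statistic tests whether a gene set concentrates at
either end of the list. Hit increments are proportional to |score|^p
(normalized to sum to one over the set's members), miss decrements are
1/(N - Nh), and the enrichment score (ES) is the signed maximum deviation of
the running sum. Significance comes from a gene-label permutation null; the
normalized ES (NES) divides by the mean |null ES| of matching sign, and the
permutation p-value is the matching-sign tail with the +1 correction (so it
is never exactly zero). FDR control is Benjamini-Hochberg over all
unit x pathway tests of a run.

The per-unit pathway-significance count matrix summarizes how many cell
types made each (unit, pathway) pair significant — the heatmap view of how
much the latent units share tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data_io import ExpressionMatrix, GeneSetCollection
from .model import AEModel
from .saliency import aggregate_saliency, corrected_saliency, per_type_saliency


@dataclass
class GseaResult:
    pathway: str
    es: float
    nes: float
    p_nominal: float
    n_perm: int
    n_hits: int
    testable: bool = True
    unit: int | None = None
    q_fdr: float = float("nan")


def rank_genes(genes: Sequence[str], scores: Sequence[float]) -> tuple[list[str], np.ndarray]:
    """Sort descending by score; ties broken ascending by gene id."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return [genes[i] for i in order], scores[order]


def enrichment_score(weights: np.ndarray, hits: np.ndarray) -> float:
    """Signed maximum deviation of the running sum for one ranked list.

    ``weights`` are |score|^p in rank order; ``hits`` is the boolean set
    membership indicator in the same order."""
    es = _es_batch(weights, hits[None, :].astype(np.float64))
    return float(es[0])


def _es_batch(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorized ES over rows of a (batch x N) hit-indicator matrix."""
    n = weights.shape[0]
    nh = hits.sum(axis=1)
    if np.any(nh == 0) or np.any(nh == n):
        raise ValueError("gene set must hit a strict, non-empty subset")
    hw = hits * weights
    denom = hw.sum(axis=1, keepdims=True)
    flat = denom[:, 0] == 0  # all in-set scores zero: fall back to equal steps
    if np.any(flat):
        hw[flat] = hits[flat]
        denom[flat, 0] = nh[flat]
    # one running sum of per-step increments, each divided before being
    # accumulated, so the result is bit-identical to a sequential loop
    steps = hw / denom - (1.0 - hits) / (n - nh)[:, None]
    dev = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(dev.shape[0]), idx]


def _null_es(
    weights: np.ndarray, n_hits: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-label permutation null: random hit positions, same set size."""
    n = weights.shape[0]
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_hits]
    hits = np.zeros((n_perm, n))
    np.put_along_axis(hits, ranks, 1.0, axis=1)
    return _es_batch(weights, hits)


def gsea_preranked(
    genes: Sequence[str],
    scores: Sequence[float],
    gene_set: Iterable[str],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
    null_cache: dict[int, np.ndarray] | None = None,
    pathway: str = "",
) -> GseaResult:
    """Preranked GSEA of one gene set against one scored gene list.

    ``null_cache`` (keyed by set size) lets callers reuse the permutation
    null across same-sized sets tested on the same ranked list."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked_genes, ranked_scores = rank_genes(genes, scores)
    members = set(gene_set)
    hits = np.array([g in members for g in ranked_genes], dtype=np.float64)
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == len(ranked_genes):
        return GseaResult(pathway, float("nan"), float("nan"), float("nan"),
                          n_perm, n_hits, testable=False)
    weights = np.abs(ranked_scores) ** weight_p

    es = enrichment_score(weights, hits.astype(bool))
    rng = rng if rng is not None else np.random.default_rng(seed)
    if null_cache is not None and n_hits in null_cache:
        null = null_cache[n_hits]
    else:
        null = _null_es(weights, n_hits, n_perm, rng)
        if null_cache is not None:
            null_cache[n_hits] = null
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = float("nan")
        p = 1.0 / (n_perm + 1)
    else:
        mean_abs = float(np.abs(null[same_sign]).mean())
        nes = es / mean_abs if mean_abs > 0 else float("nan")
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (n_extreme + 1) / (n_same + 1)
    return GseaResult(pathway, float(es), float(nes), float(p), n_perm, n_hits)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=np.float64)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    q[order] = p[order] * n / (np.arange(n) + 1)
    # enforce monotonicity from the largest p downward
    q_sorted = q[order]
    q[order] = np.minimum.accumulate(q_sorted[::-1])[::-1]
    return np.minimum(q, 1.0)


def gsea_saliency_map(
    sal_values: np.ndarray,
    gene_ids: Sequence[str],
    gs: GeneSetCollection,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> list[GseaResult]:
    """Run preranked GSEA of every gene set against every unit's saliency
    row, with BH correction over all testable unit x pathway pairs."""
    results: list[GseaResult] = []
    rng = np.random.default_rng(seed)
    for unit in range(sal_values.shape[0]):
        cache: dict[int, np.ndarray] = {}
        for name, genes in gs.sets.items():
            res = gsea_preranked(
                list(gene_ids), sal_values[unit], genes, n_perm=n_perm,
                weight_p=weight_p, rng=rng, null_cache=cache, pathway=name,
            )
            res.unit = unit
            results.append(res)
    testable = [r for r in results if r.testable]
    if testable:
        qs = benjamini_hochberg([r.p_nominal for r in testable])
        for r, q in zip(testable, qs):
            r.q_fdr = float(q)
    return results


def significant_pathway_counts(
    model: AEModel,
    m: ExpressionMatrix,
    gs: GeneSetCollection,
    alpha: float = 0.05,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count, per (unit, pathway), the cell types whose corrected saliency
    made the pathway significant at FDR q < alpha.

    Returns ``(counts, results)``: the units x pathways integer count matrix
    (bounded by the number of cell types; units with no significant pathway
    are retained) and the full per-type GSEA result table."""
    if m.labels is None:
        raise ValueError("matrix has no labels")
    global_map = aggregate_saliency(model, m)
    type_maps = per_type_saliency(model, m)
    pathways = list(gs.sets)
    counts = pd.DataFrame(
        0, index=range(model.bottleneck_size), columns=pathways, dtype=int
    )
    rows = []
    for t_idx, (t, tmap) in enumerate(sorted(type_maps.items())):
        corr = corrected_saliency(tmap, global_map)
        results = gsea_saliency_map(
            corr.values, corr.gene_ids, gs, n_perm=n_perm,
            weight_p=weight_p, seed=seed + t_idx,
        )
        for r in results:
            rows.append({
                "cell_type": t, "unit": r.unit, "pathway": r.pathway,
                "es": r.es, "nes": r.nes, "p": r.p_nominal, "q": r.q_fdr,
                "testable": r.testable,
            })
            if r.testable and r.q_fdr < alpha:
                counts.loc[r.unit, r.pathway] += 1
    return counts, pd.DataFrame(rows)


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail probability of observing at least the actual overlap when
    drawing |set_a| genes from the universe containing |set_b| successes."""
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("both sets must be subsets of the universe")
    k = len(a & b)
    return float(hypergeom.sf(k - 1, len(u), len(b), len(a)))
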