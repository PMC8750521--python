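"""End-to-end synthetic studies: module recovery and foreign-model transfer.

These functions bundle the full pipelines that the acceptance checks and the
``scripts/acceptance.py`` report both run, so the two always execute the same
study design.

Scaled study design
-------------------
The reference study searched lr in [1e-5, 1e-3] and sizes 50..140 / 35..75 on
datasets with thousands of cells. The synthetic studies here use 600 cells and
300 genes (9 SGD steps per epoch at batch 64) with a 10-trial x 20-epoch
search budget; at that budget the reference learning-rate range cannot move
the model off the constant-mean solution, and a 35..75-unit bottleneck is far
more capacity than 6 planted modules warrant. The scaled search space is
therefore lr in [1e-3, 3e-2], hidden 16..64, bottleneck 8..16, with the
orthogonality strength searched over the full reference range [1e-25, 1e-5].
Early-stopping patience is raised to 100 because the 30-cell validation split
is too noisy for patience 10 to be meaningful.

For the paired constrained-vs-unconstrained comparison, the orthogonality
strength is pinned to 1e-5 (the top of the reference range) rather than the
BO-selected value: the validation objective is insensitive to lambda across
[1e-25, 1e-5], so the selected value is arbitrary and is frequently so small
that its gradient contribution falls below float64 resolution — a lambda-vs-0
pair would then be bit-identical and the comparison vacuous. Pinning the
strongest value in the range makes the comparison test what it is meant to
test: the effect of the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection, normalize_log_cpm
from .hyperopt import (
    SearchSpace,
    _holdout_indices,
    finalize_model,
    run_optimization,
)
from .interpret import significant_pathway_counts
from .model import AEHyperparams, AEModel, train_model
from .synthetic import demo_spec, demo_transfer_specs, generate_dataset
from .transfer import evaluate_representations

#: Search space for the scaled synthetic studies (see module docstring).
SCALED_SPACE = SearchSpace(
    lr_range=(1e-3, 3e-2), hidden_range=(16, 64), bottleneck_range=(8, 16)
)

#: Base hyperparameters for the scaled studies: early-stopping patience is
#: effectively disabled because a 30-cell validation split is too noisy to
#: stop on.
SCALED_BASE_HP = AEHyperparams(patience=100)

#: Orthogonality strength pinned for the paired comparison (top of the
#: reference search range).
PAIRED_LAMBDA = 1e-5


@dataclass
class ModuleRecoveryResult:
    """Outcome of one seeded module-recovery study."""

    seed: int
    best_hp: AEHyperparams
    trial_table: pd.DataFrame
    counts_final: pd.DataFrame  # units x pathways counts, finalized model
    results_final: pd.DataFrame  # full per-(type, unit, pathway) table
    counts_constrained: pd.DataFrame  # paired run, lambda = PAIRED_LAMBDA
    counts_unconstrained: pd.DataFrame  # paired run, lambda = 0
    min_q_per_module: dict[str, float]
    modules_recovered: int
    n_modules: int
    per_unit_constrained: np.ndarray  # distinct significant pathways per unit
    per_unit_unconstrained: np.ndarray

    @property
    def all_modules_recovered(self) -> bool:
        return self.modules_recovered == self.n_modules


def _per_unit_pathway_counts(counts: pd.DataFrame) -> np.ndarray:
    """Distinct pathways significant in each unit (any cell type)."""
    return (counts.values > 0).sum(axis=1)


def module_recovery_study(
    seed: int = 0,
    *,
    n_trials: int = 10,
    trial_epochs: int = 20,
    final_epochs: int = 100,
    alpha: float = 0.05,
    n_perm: int = 10000,
) -> ModuleRecoveryResult:
    """Generate the demo dataset, optimize + finalize the autoencoder, and
    score planted-module recovery by corrected-saliency GSEA.

    Module recovery (``min_q_per_module``) is scored on the finalized
    winning-trial model. The paired constrained-vs-unconstrained comparison
    additionally retrains the winning configuration from the same seed and
    hold-out split with the orthogonality strength at :data:`PAIRED_LAMBDA`
    and at 0, so the pair differs in nothing but the constraint.

    ``n_perm`` defaults to 10000: the +1-corrected permutation estimator
    overstates p by roughly 1/n_perm, and with BH correction over the ~72
    unit-pathway tests a 12-unit bottleneck produces, a bias of 1e-3 is the
    same order as the p-values being estimated. 10000 permutations keep the
    bias an order of magnitude below the working p-values and put the p floor
    (1e-4) well under alpha / n_tests.
    """
    spec = demo_spec(seed)
    m, _, modules = generate_dataset(spec)
    ml = normalize_log_cpm(m)

    best_hp, table, best_model = run_optimization(
        ml,
        SCALED_SPACE,
        n_trials=n_trials,
        trial_epochs=trial_epochs,
        seed=seed,
        base_hp=SCALED_BASE_HP,
    )

    # the optimizer's hold-out split is reused for every subsequent run so
    # the training set (and therefore the trajectory) matches the trials
    val_idx = _holdout_indices(ml, 0.05, np.random.default_rng(seed))

    # module recovery is scored on the finalized winning trial
    final, _ = finalize_model(ml, best_hp, final_epochs, model=best_model,
                              val_indices=val_idx)
    counts_final, res_final = significant_pathway_counts(
        final, ml, modules, alpha=alpha, n_perm=n_perm, seed=seed
    )

    # the constrained-vs-unconstrained comparison retrains the winning
    # configuration from scratch (same seed, same split) at the pinned
    # lambda and at 0, so the pair differs in nothing but the constraint
    counts_pair = {}
    for label, lam in (("constrained", PAIRED_LAMBDA), ("unconstrained", 0.0)):
        hp = replace(best_hp, lambda_ortho=lam)
        model, _ = finalize_model(ml, hp, final_epochs, val_indices=val_idx)
        counts, _ = significant_pathway_counts(
            model, ml, modules, alpha=alpha, n_perm=n_perm, seed=seed
        )
        counts_pair[label] = counts

    counts_c = counts_pair["constrained"]
    counts_u = counts_pair["unconstrained"]

    testable = res_final[res_final["testable"]]
    min_q = {
        name: float(testable.loc[testable["pathway"] == name, "q"].min())
        if (testable["pathway"] == name).any()
        else float("nan")
        for name in modules.sets
    }
    recovered = sum(q < alpha for q in min_q.values() if np.isfinite(q))

    return ModuleRecoveryResult(
        seed=seed,
        best_hp=best_hp,
        trial_table=table,
        counts_final=counts_final,
        results_final=res_final,
        counts_constrained=counts_c,
        counts_unconstrained=counts_u,
        min_q_per_module=min_q,
        modules_recovered=int(recovered),
        n_modules=len(modules.sets),
        per_unit_constrained=_per_unit_pathway_counts(counts_c),
        per_unit_unconstrained=_per_unit_pathway_counts(counts_u),
    )


#: Fixed training configuration for the transfer study (drawn from the
#: scaled search space; the transfer pattern does not require re-optimizing
#: hyperparameters for every repetition).
TRANSFER_HP = AEHyperparams(
    lr=1e-2,
    lambda_ortho=PAIRED_LAMBDA,
    hidden_size=48,
    bottleneck_size=12,
    epochs=120,
    patience=100,
)


@dataclass
class TransferResult:
    """Outcome of one seeded transfer repetition."""

    seed: int
    scores: pd.DataFrame  # representation x k -> accuracy / macro F1 / majority

    def pattern_holds(self, k_values: tuple[int, ...] = (5, 15, 25)) -> bool:
        """Trained-encoded accuracy >= random-init-encoded accuracy and >=
        the majority-vote floor at every requested k."""
        s = self.scores
        for k in k_values:
            enc = s[(s.representation == "encoded") & (s.k == k)]
            rnd = s[(s.representation == "random-init-encoded") & (s.k == k)]
            if enc.empty or rnd.empty:
                raise ValueError(f"k={k} missing from transfer scores")
            acc = float(enc.accuracy.iloc[0])
            floor = float(enc.majority_vote_accuracy.iloc[0])
            if acc < float(rnd.accuracy.iloc[0]) or acc < floor:
                return False
        return True


def transfer_study(
    seed: int = 0, *, hp: AEHyperparams | None = None,
    k_values: tuple[int, ...] = (5, 15, 25)
) -> TransferResult:
    """Train on synthetic tissue A and evaluate label transfer on tissue B.

    Tissue B shares the gene universe and two of A's cell-type programs plus
    a type A never saw; labels overlap so kNN label transfer is well-posed.
    Returns accuracies for the trained-encoded, raw, and
    random-init-encoded representations at the requested neighbor counts.
    """
    spec_a, spec_b, _ = demo_transfer_specs(seed)
    m_a, _, _ = generate_dataset(spec_a)
    m_b, _, _ = generate_dataset(spec_b)
    ml_a = normalize_log_cpm(m_a)
    ml_b = normalize_log_cpm(m_b)

    hp = replace(hp or TRANSFER_HP, seed=seed)
    model, _ = train_model(ml_a, hp)
    scores = evaluate_representations(
        ml_a, {"tissue_b": ml_b}, model, k_values=list(k_values),
        random_seed=seed,
    )
    return TransferResult(seed=seed, scores=scores)


def repeated_transfer_study(
    n_reps: int = 10, *, base_seed: int = 0,
    k_values: tuple[int, ...] = (5, 15, 25)
) -> tuple[int, list[TransferResult]]:
    """Run ``n_reps`` seeded transfer repetitions; returns how many show the
    expected pattern (trained >= random-init and >= majority at every k)
    along with the per-repetition results."""
    results = [
        transfer_study(base_seed + rep, k_values=k_values)
        for rep in range(n_reps)
    ]
    n_pass = sum(r.pattern_holds(k_values) for r in results)
    return n_pass, results
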