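"""Cross-validation schemes and ROC/AUC scoring.

Three schemes are implemented over the known association matrix Y:

* LOOCV — each known association is held out in turn; the model is refit on
  the remaining associations (with every Y-derived similarity view rebuilt
  from the training matrix) and the held-out pair is scored by that model.
* k-fold CV — the known associations are shuffled and split into k
  near-equal folds; each fold is held out, views rebuilt, model refit, and
  the fold's positives scored.
* LODOCV (leave one disease out) — all associations of one disease are
  removed at once and that disease's column is ranked, yielding a
  per-disease AUC list; this probes prediction for diseases with no known
  lncRNAs.

The candidate (negative) pool for LOOCV and k-fold is every lncRNA-disease
pair never marked positive in the full Y. In k-fold, negatives are scored
under each fold's model and pooled with that fold's positives; in LOOCV,
negatives are scored under a single full-data fit (exact per-positive
refits would score them under models differing by one entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .datatypes import AssociationMatrix, DiseaseOntology
from .exceptions import ConfigError
from .optimizer import HyperParams, fit
from .similarity import build_views

__all__ = [
    "EvaluationResult",
    "roc_auc",
    "roc_points",
    "run_loocv",
    "run_kfold",
    "run_lodocv",
    "grid_search",
    "compare_auc_lists",
]

# A fold hook receives (training_matrix, held_out_pairs) right after the
# training views are built; used to instrument leakage checks.
FoldHook = Callable[[np.ndarray, list[tuple[int, int]]], None]


@dataclass
class EvaluationResult:
    """Outcome of one cross-validation run."""

    scheme: str
    auc_overall: float | None = None
    per_disease_auc: dict[str, float] = field(default_factory=dict)
    fold_assignments: list[list[tuple[int, int]]] = field(default_factory=list)
    seed: int | None = None
    scores: pd.DataFrame | None = None


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores a random negative).

    Uses midranks, so tied scores contribute 1/2 per tied positive-negative
    pair. Raises if only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("AUC is undefined with a single class")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (fpr, tpr) at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    # keep the last point of each tied-score run
    keep = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[keep] / tps[-1]]
    fpr = np.r_[0.0, fps[keep] / fps[-1]]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _positive_pairs(Y: np.ndarray) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(Y)
    return list(zip(rows.tolist(), cols.tolist()))


def _fit_on(
    assoc: AssociationMatrix,
    training: np.ndarray,
    ontology: DiseaseOntology | None,
    params: HyperParams,
    bandwidth_scale: float,
    held_out: list[tuple[int, int]],
    on_fold: FoldHook | None,
) -> np.ndarray:
    """Rebuild views from a training matrix, fit, return the score matrix."""
    train_assoc = assoc.with_values(training)
    views = build_views(train_assoc, ontology, bandwidth_scale=bandwidth_scale)
    if on_fold is not None:
        on_fold(training.copy(), list(held_out))
    return fit(train_assoc, views, params).F


def run_loocv(
    assoc: AssociationMatrix,
    ontology: DiseaseOntology | None,
    params: HyperParams | None = None,
    bandwidth_scale: float = 1.0,
    on_fold: FoldHook | None = None,
) -> EvaluationResult:
    """Leave-one-association-out cross-validation.

    Each held-out positive is scored by a model trained without it (views
    rebuilt per holdout); the never-known pairs are scored once under a
    full-data fit, and a single pooled AUC is reported.
    """
    params = params or HyperParams()
    Y = assoc.values
    positives = _positive_pairs(Y)
    if len(positives) < 2:
        raise ConfigError("LOOCV needs at least two known associations")

    pos_scores = np.empty(len(positives))
    for idx, (i, j) in enumerate(positives):
        training = Y.copy()
        training[i, j] = 0.0
        F = _fit_on(assoc, training, ontology, params, bandwidth_scale, [(i, j)], on_fold)
        pos_scores[idx] = F[i, j]

    F_full = _fit_on(assoc, Y.copy(), ontology, params, bandwidth_scale, [], None)
    neg_mask = Y == 0
    scores = np.r_[pos_scores, F_full[neg_mask]]
    labels = np.r_[np.ones(len(positives)), np.zeros(int(neg_mask.sum()))]
    return EvaluationResult(
        scheme="loocv",
        auc_overall=roc_auc(scores, labels),
        fold_assignments=[[pair] for pair in positives],
        scores=_score_frame(assoc, scores, labels, positives, neg_mask),
    )


def run_kfold(
    assoc: AssociationMatrix,
    ontology: DiseaseOntology | None,
    params: HyperParams | None = None,
    k: int = 5,
    seed: int = 42,
    bandwidth_scale: float = 1.0,
    on_fold: FoldHook | None = None,
) -> EvaluationResult:
    """k-fold cross-validation over the known associations.

    Positives are shuffled by ``seed`` and split into k folds whose sizes
    differ by at most one. Per fold the test positives are zeroed in the
    training matrix, views rebuilt, the model refit, and both the test
    positives and the full negative pool scored under that model; the AUC
    is computed over the pool of all folds.
    """
    params = params or HyperParams()
    Y = assoc.values
    positives = _positive_pairs(Y)
    if k < 2:
        raise ConfigError(f"k must be at least 2, got {k}")
    if len(positives) < k:
        raise ConfigError(f"{len(positives)} positives cannot fill {k} folds")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = [sorted(order[f::k].tolist()) for f in range(k)]
    neg_mask = Y == 0

    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    fold_pairs: list[list[tuple[int, int]]] = []
    for fold in folds:
        held_out = [positives[t] for t in fold]
        fold_pairs.append(held_out)
        training = Y.copy()
        for i, j in held_out:
            training[i, j] = 0.0
        F = _fit_on(assoc, training, ontology, params, bandwidth_scale, held_out, on_fold)
        pos_scores = np.array([F[i, j] for i, j in held_out])
        all_scores.append(np.r_[pos_scores, F[neg_mask]])
        all_labels.append(np.r_[np.ones(len(held_out)), np.zeros(int(neg_mask.sum()))])

    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    return EvaluationResult(
        scheme="kfold",
        auc_overall=roc_auc(scores, labels),
        fold_assignments=fold_pairs,
        seed=seed,
    )


def run_lodocv(
    assoc: AssociationMatrix,
    ontology: DiseaseOntology | None,
    params: HyperParams | None = None,
    bandwidth_scale: float = 1.0,
    on_fold: FoldHook | None = None,
) -> EvaluationResult:
    """Leave-one-disease-out cross-validation.

    For each disease with at least one known association, its entire column
    is zeroed, views rebuilt, the model refit, and the column's held-out
    positives ranked against that disease's non-associated lncRNAs. Returns
    one AUC per eligible disease; an all-positive column (no negatives to
    rank against) is skipped with a warning.
    """
    params = params or HyperParams()
    Y = assoc.values
    assoc_counts = Y.sum(axis=0)
    eligible = np.nonzero(assoc_counts > 0)[0]
    if eligible.size < 2:
        raise ConfigError("LODOCV needs at least two diseases with associations")

    per_disease: dict[str, float] = {}
    fold_pairs: list[list[tuple[int, int]]] = []
    for j in eligible:
        column = Y[:, j]
        if column.all():
            warnings.warn(
                f"disease {assoc.disease_ids[j]!r} has no negative lncRNAs; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        held_out = [(int(i), int(j)) for i in np.nonzero(column)[0]]
        fold_pairs.append(held_out)
        training = Y.copy()
        training[:, j] = 0.0
        F = _fit_on(assoc, training, ontology, params, bandwidth_scale, held_out, on_fold)
        per_disease[assoc.disease_ids[j]] = roc_auc(F[:, j], column)
    return EvaluationResult(
        scheme="lodocv",
        per_disease_auc=per_disease,
        fold_assignments=fold_pairs,
    )


def grid_search(
    assoc: AssociationMatrix,
    ontology: DiseaseOntology | None,
    alphas: Sequence[float],
    betas: Sequence[float],
    k: int = 5,
    seed: int = 42,
    bandwidth_scale: float = 1.0,
    base_params: HyperParams | None = None,
) -> pd.DataFrame:
    """k-fold AUC over an (alpha, beta) grid, sorted by AUC descending."""
    if not alphas or not betas:
        raise ConfigError("alpha and beta grids must be nonempty")
    base = base_params or HyperParams()
    rows = []
    for alpha in alphas:
        for beta in betas:
            params = HyperParams(
                alpha=alpha,
                beta=beta,
                inner_tol=base.inner_tol,
                outer_tol=base.outer_tol,
                max_inner=base.max_inner,
                max_outer=base.max_outer,
            )
            result = run_kfold(
                assoc, ontology, params, k=k, seed=seed, bandwidth_scale=bandwidth_scale
            )
            rows.append({"alpha": alpha, "beta": beta, "auc": result.auc_overall})
    table = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def compare_auc_lists(auc_a: Sequence[float], auc_b: Sequence[float]):
    """Wilcoxon signed-rank test between two paired per-disease AUC lists."""
    return wilcoxon(np.asarray(auc_a), np.asarray(auc_b))


def _score_frame(
    assoc: AssociationMatrix,
    scores: np.ndarray,
    labels: np.ndarray,
    positives: list[tuple[int, int]],
    neg_mask: np.ndarray,
) -> pd.DataFrame:
    neg_rows, neg_cols = np.nonzero(neg_mask)
    pairs = positives + list(zip(neg_rows.tolist(), neg_cols.tolist()))
    return pd.DataFrame(
        {
            "lncrna_id": [assoc.lncrna_ids[i] for i, _ in pairs],
            "disease_id": [assoc.disease_ids[j] for _, j in pairs],
            "score": scores,
            "known_flag": labels.astype(int),
        }
    )
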