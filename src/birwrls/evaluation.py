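"""Cross-validated evaluation and ranked candidate reports.

Known positives are split into folds at pair level. For each fold the
held-out positives are masked to 0 in the training matrix, the lncRNA
functional similarity is recomputed from the masked matrix (held-out
associations must not leak into the features), the predictor runs, and the
held-out positives are scored against every pair that is unknown in the
full matrix. Disease semantic similarity depends only on the ontology and
is computed once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .functional import lncrna_similarity_matrix
from .io import (
    AssociationMatrix,
    DiseaseRecord,
    ModelParams,
    ScoreMatrix,
    SimilarityMatrix,
    normalize_name,
    rank_lncrnas,
)
from .rls import predict
from .semantic import disease_similarity_matrix

__all__ = ["CvPlan", "CvResult", "make_folds", "auc", "cross_validate", "top_k_report"]


@dataclass(frozen=True)
class CvPlan:
    """Assignment of every known-positive pair to exactly one fold."""

    n_folds: int
    seed: int
    fold_assignment: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        sizes = np.bincount(
            list(self.fold_assignment.values()), minlength=self.n_folds
        )
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    def fold_pairs(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.fold_assignment.items() if f == fold]


@dataclass(frozen=True)
class CvResult:
    per_fold_auc: tuple[float, ...]
    mean_auc: float
    pooled_auc: float
    per_fold_n_pos: tuple[int, ...]
    n_negatives: int

    def __post_init__(self) -> None:
        if abs(self.mean_auc - float(np.mean(self.per_fold_auc))) > 1e-12:
            raise ValueError("mean_auc must be the mean of per_fold_auc")


def make_folds(Y: AssociationMatrix, n_folds: int = 5, seed: int = 42) -> CvPlan:
    """Uniform random pair-level partition of the positives, sizes within 1."""
    pos = np.argwhere(Y.values == 1)
    if len(pos) < n_folds:
        raise ValueError(f"{len(pos)} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pos))
    assignment = {
        (int(pos[k, 0]), int(pos[k, 1])): int(rank % n_folds)
        for rank, k in enumerate(order)
    }
    return CvPlan(n_folds=n_folds, seed=seed, fold_assignment=assignment)


def auc(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative, ties 1/2."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative score")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def align_records(
    records: Sequence[DiseaseRecord], disease_names: Sequence[str]
) -> list[DiseaseRecord]:
    """Reorder disease records to match an association matrix's disease axis."""
    by_key = {rec.name: rec for rec in records}
    out = []
    for name in disease_names:
        key = normalize_name(name)
        if key not in by_key:
            raise KeyError(f"no ontology record for disease {name!r}")
        out.append(by_key[key])
    return out


def cross_validate(
    records: Sequence[DiseaseRecord],
    Y: AssociationMatrix,
    params: ModelParams | None = None,
    plan: CvPlan | None = None,
    Sd: SimilarityMatrix | None = None,
    leak_lncrna_similarity: bool = False,
) -> CvResult:
    """Fold-masked cross-validation of the full prediction pipeline.

    ``leak_lncrna_similarity=True`` deliberately builds the lncRNA
    similarity from the *full* association matrix (including held-out
    positives); it exists only to demonstrate that the default leak-free
    protocol matters and should never be used for reported numbers.
    """
    params = params or ModelParams()
    plan = plan or make_folds(Y)
    if Sd is None:
        Sd = disease_similarity_matrix(align_records(records, Y.disease_names), params)

    full = Y.values
    neg_mask = full == 0
    n_neg = int(neg_mask.sum())
    if n_neg == 0:
        raise ValueError("no unknown pairs to serve as candidate negatives")

    fold_aucs: list[float] = []
    fold_npos: list[int] = []
    all_pos: list[np.ndarray] = []
    all_neg: list[np.ndarray] = []
    for fold in range(plan.n_folds):
        pairs = plan.fold_pairs(fold)
        if not pairs:
            raise ValueError(f"fold {fold} holds no test positives")
        rows, cols = zip(*pairs)
        train = full.copy()
        train[rows, cols] = 0
        Y_train = AssociationMatrix(
            list(Y.lncrna_names), list(Y.disease_names), train
        )
        Sl_source = Y if leak_lncrna_similarity else Y_train
        Sl = lncrna_similarity_matrix(Sl_source, Sd)
        scores = predict(Y_train, Sl, Sd, params).values
        pos_scores = scores[rows, cols]
        neg_scores = scores[neg_mask]
        fold_aucs.append(auc(pos_scores, neg_scores))
        fold_npos.append(len(pairs))
        all_pos.append(pos_scores)
        all_neg.append(neg_scores)

    pooled = auc(np.concatenate(all_pos), np.concatenate(all_neg))
    return CvResult(
        per_fold_auc=tuple(fold_aucs),
        mean_auc=float(np.mean(fold_aucs)),
        pooled_auc=pooled,
        per_fold_n_pos=tuple(fold_npos),
        n_negatives=n_neg,
    )


def top_k_report(
    scores: ScoreMatrix,
    Y_known: AssociationMatrix,
    disease: str,
    k: int = 30,
) -> pd.DataFrame:
    """Top-k candidates for one disease with known/novel flags."""
    return rank_lncrnas(scores, disease, k, known=Y_known)
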