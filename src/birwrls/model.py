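"""scikit-learn-style estimator wrapping the full prediction pipeline."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .evaluation import align_records
from .functional import lncrna_similarity_matrix
from .io import (
    AssociationMatrix,
    DiseaseRecord,
    ModelParams,
    ScoreMatrix,
    SimilarityMatrix,
)
from .rls import predict as _predict
from .semantic import disease_similarity_matrix

__all__ = ["BiRandomWalkRLS"]


class BiRandomWalkRLS(BaseEstimator):
    """Unbalanced bi-random walk + Laplacian-RLS link predictor.

    The model is transductive: ``fit`` takes the known lncRNA-disease
    association matrix (plus the disease ontology records, unless both
    similarity matrices are supplied precomputed) and scores *every* pair
    of the matrix. Hyperparameters mirror :class:`~birwrls.io.ModelParams`.

    Parameters
    ----------
    alpha : float, default 0.5
        Semantic decay per ontology edge.
    gamma : float, default 0.001
        Walk restart weight.
    n_l, n_d : int, defaults 31 and 1
        Step counts of the lncRNA-side and disease-side walks.
    eta_l, eta_d : float, default 0.01
        Laplacian-RLS trade-off parameters.
    contribution_variant : {"SV1", "SV2", "SV3"}, default "SV3"
    smoothing_mode : {"per_step", "final"}, default "per_step"
    cross_space_smoothing : bool, default True

    Attributes
    ----------
    Sd_ : SimilarityMatrix
        Disease semantic similarity used for scoring.
    Sl_ : SimilarityMatrix
        lncRNA functional similarity (computed from the fitted Y).
    scores_ : ScoreMatrix
        Association scores for every lncRNA-disease pair.

    Examples
    --------
    >>> from birwrls.simulate import default_paperlike_spec, generate_dataset
    >>> records, Y = generate_dataset(default_paperlike_spec(seed=1))
    >>> model = BiRandomWalkRLS().fit(Y, diseases=records)
    >>> model.scores_.values.shape
    (80, 150)
    """

    def __init__(
        self,
        alpha: float = 0.5,
        gamma: float = 0.001,
        n_l: int = 31,
        n_d: int = 1,
        eta_l: float = 0.01,
        eta_d: float = 0.01,
        contribution_variant: str = "SV3",
        smoothing_mode: str = "per_step",
        cross_space_smoothing: bool = True,
    ):
        self.alpha = alpha
        self.gamma = gamma
        self.n_l = n_l
        self.n_d = n_d
        self.eta_l = eta_l
        self.eta_d = eta_d
        self.contribution_variant = contribution_variant
        self.smoothing_mode = smoothing_mode
        self.cross_space_smoothing = cross_space_smoothing

    def _params(self) -> ModelParams:
        return ModelParams(
            alpha=self.alpha,
            gamma=self.gamma,
            n_l=self.n_l,
            n_d=self.n_d,
            eta_l=self.eta_l,
            eta_d=self.eta_d,
            contribution_variant=self.contribution_variant,
            smoothing_mode=self.smoothing_mode,
            cross_space_smoothing=self.cross_space_smoothing,
        )

    def fit(
        self,
        Y: AssociationMatrix,
        y=None,
        *,
        diseases: Sequence[DiseaseRecord] | None = None,
        Sd: SimilarityMatrix | None = None,
        Sl: SimilarityMatrix | None = None,
    ) -> "BiRandomWalkRLS":
        """Compute similarities (unless given) and score every pair."""
        if not isinstance(Y, AssociationMatrix):
            raise TypeError("Y must be an AssociationMatrix")
        params = self._params()  # validates hyperparameters
        if Sd is None:
            if diseases is None:
                raise ValueError("provide either `diseases` records or a precomputed Sd")
            Sd = disease_similarity_matrix(align_records(diseases, Y.disease_names), params)
        if Sl is None:
            Sl = lncrna_similarity_matrix(Y, Sd)
        self.Y_ = Y
        self.Sd_ = Sd
        self.Sl_ = Sl
        self.scores_ = _predict(Y, Sl, Sd, params)
        return self

    def predict(self) -> np.ndarray:
        """The fitted score matrix as an array (lncRNAs x diseases)."""
        self._check_fitted()
        return self.scores_.values

    def rank(self, disease: str, k: int = 30):
        """Top-k candidate lncRNAs for one disease, known pairs flagged."""
        from .evaluation import top_k_report

        self._check_fitted()
        return top_k_report(self.scores_, self.Y_, disease, k)

    def _check_fitted(self) -> None:
        if not hasattr(self, "scores_"):
            raise AttributeError("estimator is not fitted; call fit first")
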