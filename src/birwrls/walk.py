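"""Unbalanced bi-random walk over the lncRNA and disease similarity networks.

Both walks start from the known-association matrix Y and iterate a linear
restart recursion: the lncRNA walk multiplies by the lncRNA similarity on
the left, the disease walk by the disease similarity on the right, and each
step mixes back a (1 - gamma) share of Y. The step counts differ between
the two networks — that asymmetry is the "unbalanced" part. Similarity
matrices are used exactly as given, without row-stochastic normalization;
with the default gamma = 0.001 the iteration is strongly contractive.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .io import AssociationMatrix, ScoreMatrix, SimilarityMatrix

__all__ = ["lncrna_walk", "disease_walk", "walk_fixed_point"]

StepHook = Callable[[np.ndarray], np.ndarray]


def _check_axis(S: SimilarityMatrix, names: list[str], axis: str) -> None:
    if len(S.names) != len(names):
        raise ValueError(
            f"similarity matrix size {len(S.names)} does not match the "
            f"{axis} axis of the association matrix ({len(names)})"
        )


def _iterate(
    Y: np.ndarray,
    step: Callable[[np.ndarray], np.ndarray],
    gamma: float,
    n_steps: int,
    post_step: StepHook | None,
) -> np.ndarray:
    P = Y.astype(float).copy()
    for _ in range(n_steps):
        P = gamma * step(P) + (1.0 - gamma) * Y
        if post_step is not None:
            P = post_step(P)
    return P


def lncrna_walk(
    Y: AssociationMatrix,
    Sl: SimilarityMatrix,
    gamma: float,
    n_steps: int,
    post_step: StepHook | None = None,
) -> ScoreMatrix:
    """Walk on the lncRNA network: P <- gamma*Sl@P + (1-gamma)*Y, n_steps times.

    ``post_step`` is an optional transform applied after every iteration
    (used to interleave kernel smoothing with the walk); zero steps return Y.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    _check_axis(Sl, Y.lncrna_names, "lncRNA")
    S = Sl.values
    P = _iterate(Y.values, lambda P: S @ P, gamma, n_steps, post_step)
    return ScoreMatrix(list(Y.lncrna_names), list(Y.disease_names), P)


def disease_walk(
    Y: AssociationMatrix,
    Sd: SimilarityMatrix,
    gamma: float,
    n_steps: int,
    post_step: StepHook | None = None,
) -> ScoreMatrix:
    """Walk on the disease network: P <- gamma*P@Sd + (1-gamma)*Y."""
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    _check_axis(Sd, Y.disease_names, "disease")
    S = Sd.values
    P = _iterate(Y.values, lambda P: P @ S, gamma, n_steps, post_step)
    return ScoreMatrix(list(Y.lncrna_names), list(Y.disease_names), P)


def walk_fixed_point(
    Y: AssociationMatrix,
    S: SimilarityMatrix,
    gamma: float,
    side: str = "lncrna",
) -> ScoreMatrix:
    """Infinite-step limit (1-gamma)(I - gamma*S)^(-1) Y of the walk recursion.

    Valid when gamma * spectral_radius(S) < 1; serves as a convergence
    oracle for the iterative walks.
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0, 1)")
    rho = np.abs(np.linalg.eigvalsh((S.values + S.values.T) / 2)).max()
    if gamma * rho >= 1:
        raise ValueError(
            f"fixed point undefined: gamma * spectral_radius = {gamma * rho:.3g} >= 1"
        )
    A = np.eye(len(S.names)) - gamma * S.values
    if side == "lncrna":
        P = (1.0 - gamma) * np.linalg.solve(A, Y.values.astype(float))
    elif side == "disease":
        P = (1.0 - gamma) * np.linalg.solve(A.T, Y.values.T.astype(float)).T
    else:
        raise ValueError("side must be 'lncrna' or 'disease'")
    return ScoreMatrix(list(Y.lncrna_names), list(Y.disease_names), P)
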