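"""Laplacian-regularized least-squares smoothing and the full predictor.

Each similarity network yields a symmetrically normalized Laplacian
L = M^(-1/2) (M - S) M^(-1/2) with M = diag(row sums of S), and a smoothing
kernel K = S (S + eta * L * S)^(-1) — the closed-form minimizer of the
Laplacian-regularized least-squares objective
min_F ||P - F||_F^2 + eta * tr(F' L F) applied columnwise, which for
invertible S collapses to K = (I + eta*L)^(-1). The kernel damps score
components that vary sharply across strongly-similar nodes.

The predictor composes: Laplacians -> kernels -> unbalanced bi-random walks
with kernel smoothing -> fusion by averaging. By default each walk's scores
are smoothed in the *other* space (the disease kernel acts on the
lncRNA-walk result and vice versa); a flag switches to same-space pairing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, ModelParams, ScoreMatrix, SimilarityMatrix
from .walk import disease_walk, lncrna_walk

__all__ = [
    "normalized_laplacian",
    "rls_kernel",
    "RlsKernelPair",
    "smooth_scores",
    "fuse",
    "predict",
]

_RESIDUAL_RTOL = 1e-8


def normalized_laplacian(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Symmetric normalized Laplacian of a similarity matrix; PSD."""
    A = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    rowsums = A.sum(axis=1)
    if np.any(rowsums <= 0):
        raise ValueError("all row sums must be strictly positive")
    d = 1.0 / np.sqrt(rowsums)
    L = (np.diag(rowsums) - A) * d[:, None] * d[None, :]
    return (L + L.T) / 2.0


def rls_kernel(
    S: SimilarityMatrix | np.ndarray, L: np.ndarray, eta: float
) -> np.ndarray:
    """Smoothing kernel K = S (S + eta * L @ S)^(-1), via a linear solve.

    If the system is singular (degenerate similarity structure) a small
    ridge eps = 1e-10 * trace(S)/n is added and a warning emitted. The
    result is validated by its residual ||K (S + eta*L*S) - S||.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    A = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    n = A.shape[0]
    B = A + eta * (L @ A)

    def _solve(Bm: np.ndarray) -> np.ndarray:
        # K B = A  =>  B' K' = A'
        return np.linalg.solve(Bm.T, A.T).T

    s_norm = np.linalg.norm(A)
    try:
        K = _solve(B)
        residual = np.linalg.norm(K @ B - A)
    except np.linalg.LinAlgError:
        K, residual = None, np.inf
    if K is None or residual > _RESIDUAL_RTOL * max(s_norm, 1e-300):
        eps = 1e-10 * np.trace(A) / n
        warnings.warn(
            f"RLS system ill-conditioned (residual {residual:.3g}); "
            f"adding ridge eps={eps:.3g}"
        )
        K = _solve(B + eps * np.eye(n))
        residual = np.linalg.norm(K @ (B + eps * np.eye(n)) - A)
        if residual > _RESIDUAL_RTOL * max(s_norm, 1e-300):
            raise np.linalg.LinAlgError(
                f"RLS kernel solve failed even with ridge (residual {residual:.3g})"
            )
    return K


@dataclass(frozen=True)
class RlsKernelPair:
    """Smoothing kernels of the lncRNA and disease networks."""

    K_l: np.ndarray
    K_d: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.K_l)) and np.all(np.isfinite(self.K_d))):
            raise ValueError("kernel entries must be finite")


def build_kernels(Sl: SimilarityMatrix, Sd: SimilarityMatrix, params: ModelParams) -> RlsKernelPair:
    Ll = normalized_laplacian(Sl)
    Ld = normalized_laplacian(Sd)
    return RlsKernelPair(
        K_l=rls_kernel(Sl, Ll, params.eta_l),
        K_d=rls_kernel(Sd, Ld, params.eta_d),
    )


def smooth_scores(
    P_l: np.ndarray,
    P_d: np.ndarray,
    kernels: RlsKernelPair,
    cross_space: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One application of kernel smoothing to the two walk-score matrices.

    Cross-space (default): the lncRNA-walk scores are smoothed along the
    disease axis, P_l <- P_l @ K_d', and the disease-walk scores along the
    lncRNA axis, P_d <- K_l @ P_d. Same-space: K_l @ P_l and P_d @ K_d.
    """
    if cross_space:
        return P_l @ kernels.K_d.T, kernels.K_l @ P_d
    return kernels.K_l @ P_l, P_d @ kernels.K_d


def fuse(P_l: np.ndarray, P_d: np.ndarray) -> np.ndarray:
    """Final score: elementwise mean of the two network views."""
    if P_l.shape != P_d.shape:
        raise ValueError("walk-score matrices must share a shape")
    return (P_l + P_d) / 2.0


def predict(
    Y: AssociationMatrix,
    Sl: SimilarityMatrix,
    Sd: SimilarityMatrix,
    params: ModelParams | None = None,
) -> ScoreMatrix:
    """End-to-end deterministic score computation for every lncRNA-disease pair."""
    params = params or ModelParams()
    kernels = build_kernels(Sl, Sd, params)

    if params.cross_space_smoothing:
        hook_l = lambda P: P @ kernels.K_d.T  # noqa: E731
        hook_d = lambda P: kernels.K_l @ P  # noqa: E731
    else:
        hook_l = lambda P: kernels.K_l @ P  # noqa: E731
        hook_d = lambda P: P @ kernels.K_d  # noqa: E731

    if params.smoothing_mode == "per_step":
        P_l = lncrna_walk(Y, Sl, params.gamma, params.n_l, post_step=hook_l).values
        P_d = disease_walk(Y, Sd, params.gamma, params.n_d, post_step=hook_d).values
    else:
        P_l = hook_l(lncrna_walk(Y, Sl, params.gamma, params.n_l).values)
        P_d = hook_d(disease_walk(Y, Sd, params.gamma, params.n_d).values)

    return ScoreMatrix(list(Y.lncrna_names), list(Y.disease_names), fuse(P_l, P_d))
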