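"""lncRNA functional similarity from shared disease associations.

Two lncRNAs are functionally similar when the disease sets they are known
to associate with are semantically similar: each disease in one group is
matched to its most similar disease in the other group (best match), the
matches are summed in both directions, and the total is normalized by the
combined group size. lncRNAs with no known associations (possible after
cross-validation masking) get similarity 0 to everything except themselves.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .io import AssociationMatrix, SimilarityMatrix, normalize_name

__all__ = [
    "best_match",
    "directional_sum",
    "functional_similarity",
    "lncrna_similarity_matrix",
]


def _group_indices(Y: AssociationMatrix, Sd: SimilarityMatrix) -> list[np.ndarray]:
    """Column indices into Sd of each lncRNA's disease group DG(u)."""
    y_keys = [normalize_name(n) for n in Y.disease_names]
    s_keys = {normalize_name(n): j for j, n in enumerate(Sd.names)}
    missing = [k for k in y_keys if k not in s_keys]
    if missing:
        raise ValueError(f"diseases absent from similarity matrix: {missing[:5]}")
    col_map = np.array([s_keys[k] for k in y_keys])
    return [col_map[np.flatnonzero(Y.values[i])] for i in range(Y.n_lncrnas)]


def best_match(disease: str, group: Sequence[str], Sd: SimilarityMatrix) -> float:
    """S(d, DG): similarity of d to its closest group member; 0 if empty."""
    if not group:
        warnings.warn(f"empty disease group when matching {disease!r}")
        return 0.0
    i = Sd.index(disease)
    return float(max(Sd.values[i, Sd.index(d)] for d in group))


def directional_sum(
    group_u: Sequence[str], group_v: Sequence[str], Sd: SimilarityMatrix
) -> float:
    """Sum of best matches of every disease in DG(u) against DG(v)."""
    return float(sum(best_match(d, group_v, Sd) for d in group_u))


def functional_similarity(
    u: str, v: str, Y: AssociationMatrix, Sd: SimilarityMatrix
) -> float:
    """Best-match-average similarity of two lncRNAs' disease groups."""
    gu = Y.disease_group(u)
    gv = Y.disease_group(v)
    if not gu and not gv:
        warnings.warn(f"lncRNAs {u!r} and {v!r} both have no known associations")
        return 0.0
    if not gu or not gv:
        return 0.0
    num = directional_sum(gu, gv, Sd) + directional_sum(gv, gu, Sd)
    return float(num / (len(gu) + len(gv)))


def lncrna_similarity_matrix(Y: AssociationMatrix, Sd: SimilarityMatrix) -> SimilarityMatrix:
    """Pairwise functional similarity over all lncRNAs.

    Vectorized equivalent of the per-pair best-match computation: for the
    Sd sub-matrix restricted to DG(u) x DG(v), the two directional sums are
    the row-max and column-max totals. Diagonal forced to 1.
    """
    groups = _group_indices(Y, Sd)
    n = Y.n_lncrnas
    values = np.eye(n)
    S = Sd.values
    for i in range(n):
        gi = groups[i]
        if gi.size == 0:
            continue
        for j in range(i + 1, n):
            gj = groups[j]
            if gj.size == 0:
                continue
            sub = S[np.ix_(gi, gj)]
            values[i, j] = values[j, i] = (
                sub.max(axis=1).sum() + sub.max(axis=0).sum()
            ) / (gi.size + gj.size)
    return SimilarityMatrix(list(Y.lncrna_names), values)
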