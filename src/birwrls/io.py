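"""Shared data model and TSV input/output.

Every matrix in the package has a fixed orientation: lncRNAs are rows,
diseases are columns. All tabular artifacts are UTF-8, tab-delimited TSV
with a header row; square matrices carry their axis names in the first
column. Disease/lncRNA names are matched case- and whitespace-insensitively
but the original spelling is preserved for output.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiseaseRecord",
    "AssociationMatrix",
    "SimilarityMatrix",
    "ScoreMatrix",
    "ModelParams",
    "normalize_name",
    "read_disease_table",
    "read_associations",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_score_table",
    "write_score_table",
    "write_rankings",
    "rank_lncrnas",
]

#: dot-separated hierarchical code: nonempty segments, no leading/trailing dot
TREE_NUMBER_RE = re.compile(r"^[^.\s]+(?:\.[^.\s]+)*$")

_SYMMETRY_TOL = 1e-10


def normalize_name(name: str) -> str:
    """Canonical matching key: trim, collapse internal whitespace, lowercase."""
    return " ".join(name.split()).lower()


@dataclass(frozen=True)
class DiseaseRecord:
    """A disease with its hierarchical ontology codes.

    ``name`` is the case/whitespace-normalized matching key; ``label`` keeps
    the original spelling for output. Each tree number places the disease in
    a hierarchy; prefix truncation yields its ancestors.
    """

    name: str
    tree_numbers: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("disease name must be nonempty")
        if not self.tree_numbers:
            raise ValueError(f"disease {self.name!r} has no tree numbers")
        for code in self.tree_numbers:
            if not TREE_NUMBER_RE.match(code):
                raise ValueError(
                    f"disease {self.name!r}: malformed tree number {code!r}"
                )
        if not self.label:
            object.__setattr__(self, "label", self.name)


def _check_unique(names: Sequence[str], axis: str) -> None:
    seen: set[str] = set()
    for n in names:
        key = normalize_name(n)
        if key in seen:
            raise ValueError(f"duplicate {axis} name: {n!r}")
        seen.add(key)


@dataclass
class AssociationMatrix:
    """Binary lncRNA x disease matrix Y of known associations.

    A 1 means the pair appears in the curated association list; a 0 means
    the pair is unknown (not a verified negative).
    """

    lncrna_names: list[str]
    disease_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.lncrna_names), len(self.disease_names)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"{len(self.lncrna_names)} lncRNAs x {len(self.disease_names)} diseases"
            )
        _check_unique(self.lncrna_names, "lncRNA")
        _check_unique(self.disease_names, "disease")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_names)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    def lncrna_index(self, name: str) -> int:
        return _index_of(self.lncrna_names, name, "lncRNA")

    def disease_index(self, name: str) -> int:
        return _index_of(self.disease_names, name, "disease")

    def disease_group(self, lncrna: str | int) -> list[str]:
        """DG(u): diseases with a known association to the given lncRNA."""
        i = lncrna if isinstance(lncrna, int) else self.lncrna_index(lncrna)
        return [self.disease_names[j] for j in np.flatnonzero(self.values[i])]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.lncrna_names), list(self.disease_names), self.values.copy()
        )


def _index_of(names: Sequence[str], name: str, axis: str) -> int:
    key = normalize_name(name)
    for i, n in enumerate(names):
        if normalize_name(n) == key:
            return i
    raise KeyError(f"unknown {axis} name: {name!r}")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with unit diagonal, entries in [0,1]."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix must be {n}x{n}")
        _check_unique(self.names, "similarity-axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix has non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if n and not np.allclose(np.diag(self.values), 1.0, atol=_SYMMETRY_TOL):
            raise ValueError("similarity matrix diagonal must be 1")
        if n and (self.values.min() < -_SYMMETRY_TOL or self.values.max() > 1 + _SYMMETRY_TOL):
            raise ValueError("similarity values must lie in [0, 1]")

    def index(self, name: str) -> int:
        return _index_of(self.names, name, "similarity-axis")


@dataclass
class ScoreMatrix:
    """Real-valued lncRNA x disease association-score matrix."""

    lncrna_names: list[str]
    disease_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrna_names), len(self.disease_names)):
            raise ValueError("score matrix shape does not match axis names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix has non-finite entries")

    def disease_index(self, name: str) -> int:
        return _index_of(self.disease_names, name, "disease")

    def lncrna_index(self, name: str) -> int:
        return _index_of(self.lncrna_names, name, "lncRNA")


_VARIANTS = ("SV1", "SV2", "SV3")
_MODES = ("per_step", "final")


@dataclass
class ModelParams:
    """All tunables of the prediction pipeline.

    alpha
        Semantic decay per ontology edge, in (0, 1).
    gamma
        Walk restart weight in (0, 1); small values keep scores close to the
        known-association restart term.
    n_l, n_d
        Step counts of the lncRNA-side and disease-side walks (the walks are
        "unbalanced" because these differ).
    eta_l, eta_d
        Laplacian-RLS trade-off parameters (>= 0).
    contribution_variant
        Which semantic-contribution recursion builds disease similarity.
    smoothing_mode
        "per_step" interleaves kernel smoothing with every walk iteration;
        "final" applies it once after the last step.
    cross_space_smoothing
        Default True: the disease-space kernel smooths the lncRNA-walk scores
        and vice versa; False pairs each kernel with its own space.
    beta_at_child
        Evaluate the information-content factor at the child term instead of
        the term being scored (off by default).
    """

    alpha: float = 0.5
    gamma: float = 0.001
    n_l: int = 31
    n_d: int = 1
    eta_l: float = 0.01
    eta_d: float = 0.01
    contribution_variant: str = "SV3"
    smoothing_mode: str = "per_step"
    cross_space_smoothing: bool = True
    beta_at_child: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.n_l < 0 or self.n_d < 0:
            raise ValueError("step counts must be >= 0")
        if self.eta_l < 0 or self.eta_d < 0:
            raise ValueError("eta parameters must be >= 0")
        if self.contribution_variant not in _VARIANTS:
            raise ValueError(f"contribution_variant must be one of {_VARIANTS}")
        if self.smoothing_mode not in _MODES:
            raise ValueError(f"smoothing_mode must be one of {_MODES}")


# ---------------------------------------------------------------------------
# readers / writers


def read_disease_table(path: str | Path) -> list[DiseaseRecord]:
    """Read a TSV with columns ``disease_name`` and ``tree_numbers``.

    Tree numbers are semicolon-separated. Duplicate disease names (after
    normalization) are merged by unioning their tree numbers. Records with a
    malformed tree number are dropped with a warning naming the input line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: disease table is empty")
    missing = {"disease_name", "tree_numbers"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    merged: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        raw_name = str(row.disease_name)
        label = " ".join(raw_name.split())
        key = normalize_name(raw_name)
        if not key:
            warnings.warn(f"{path}:{line_no}: empty disease name, record dropped")
            continue
        codes = [c.strip() for c in str(row.tree_numbers).split(";") if c.strip()]
        bad = [c for c in codes if not TREE_NUMBER_RE.match(c)]
        if bad or not codes:
            warnings.warn(
                f"{path}:{line_no}: disease {label!r} rejected "
                f"(malformed tree numbers: {bad or 'none given'})"
            )
            continue
        merged.setdefault(key, set()).update(codes)
        labels.setdefault(key, label)

    if not merged:
        raise ValueError(f"{path}: no valid disease records")
    return [
        DiseaseRecord(name=key, tree_numbers=frozenset(codes), label=labels[key])
        for key, codes in merged.items()
    ]


def read_associations(
    path: str | Path,
    lncrna_names: Sequence[str] | None = None,
    disease_names: Sequence[str] | None = None,
) -> AssociationMatrix:
    """Read a TSV of (lncRNA, disease) pairs into a binary matrix.

    Name universes may be supplied explicitly (pairs naming unknown entities
    are then an error) or inferred from the file in first-seen order.
    Duplicate pairs collapse to a single 1.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected two columns (lncRNA, disease)")
    pairs = [
        (" ".join(str(a).split()), " ".join(str(b).split()))
        for a, b in zip(df[cols[0]], df[cols[1]])
    ]

    def _universe(given: Sequence[str] | None, seen: Iterable[str], axis: str) -> list[str]:
        if given is not None:
            return list(given)
        out: list[str] = []
        keys: set[str] = set()
        for name in seen:
            k = normalize_name(name)
            if k not in keys:
                keys.add(k)
                out.append(name)
        if not out:
            raise ValueError(f"{path}: no {axis} names and no explicit universe")
        return out

    lnc = _universe(lncrna_names, (a for a, _ in pairs), "lncRNA")
    dis = _universe(disease_names, (b for _, b in pairs), "disease")
    lnc_idx = {normalize_name(n): i for i, n in enumerate(lnc)}
    dis_idx = {normalize_name(n): j for j, n in enumerate(dis)}

    unknown = sorted(
        {a for a, _ in pairs if normalize_name(a) not in lnc_idx}
        | {b for _, b in pairs if normalize_name(b) not in dis_idx}
    )
    if unknown:
        raise ValueError(f"{path}: pairs name unknown entities: {unknown}")

    values = np.zeros((len(lnc), len(dis)), dtype=np.int8)
    for a, b in pairs:
        values[lnc_idx[normalize_name(a)], dis_idx[normalize_name(b)]] = 1
    return AssociationMatrix(lnc, dis, values)


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write a square matrix TSV; first column holds the axis names."""
    df = pd.DataFrame(sim.values, index=sim.names, columns=sim.names)
    df.to_csv(path, sep="\t", index_label="name", float_format="%.17g")


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_score_table(scores: ScoreMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        scores.values, index=scores.lncrna_names, columns=scores.disease_names
    )
    df.to_csv(path, sep="\t", index_label="lncRNA", float_format="%.17g")


def read_score_table(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(dtype=float)
    )


def rank_lncrnas(
    scores: ScoreMatrix,
    disease: str,
    k: int,
    known: AssociationMatrix | None = None,
) -> pd.DataFrame:
    """Top-k lncRNAs for one disease, descending score, name-ascending ties.

    Columns: rank, lncRNA, score, known_flag (1 where the pair is a known
    association, 0 otherwise; all zeros when no association matrix is given).
    """
    if k > len(scores.lncrna_names):
        raise ValueError(
            f"k={k} exceeds the number of lncRNAs ({len(scores.lncrna_names)})"
        )
    j = scores.disease_index(disease)
    col = scores.values[:, j]
    order = sorted(
        range(len(col)), key=lambda i: (-col[i], normalize_name(scores.lncrna_names[i]))
    )[:k]
    if known is not None:
        jk = known.disease_index(disease)
        flags = [int(known.values[known.lncrna_index(scores.lncrna_names[i]), jk]) for i in order]
    else:
        flags = [0] * len(order)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "lncRNA": [scores.lncrna_names[i] for i in order],
            "score": col[order],
            "known_flag": flags,
        }
    )


def write_rankings(
    scores: ScoreMatrix,
    disease: str,
    k: int,
    path: str | Path,
    known: AssociationMatrix | None = None,
) -> pd.DataFrame:
    df = rank_lncrnas(scores, disease, k, known=known)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
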