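"""Synthetic ontologies and planted association matrices.

The generator emulates the shape of curated lncRNA-disease datasets
(~80 lncRNAs x ~150 diseases, a few hundred associations) without copying
any real database. Diseases are organized into blocks that share a common
ancestor prefix in a synthetic code hierarchy, so semantic similarity
correlates with block membership; lncRNAs are split into matching blocks
and associations are drawn densely within matched blocks and sparsely
elsewhere. The planted structure is therefore recoverable by
guilt-by-association methods, giving an offline end-to-end benchmark.

One integer seed drives both generators through independent derived
streams: changing association densities never changes the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix, DiseaseRecord

__all__ = [
    "FixtureSpec",
    "generate_ontology",
    "generate_associations",
    "generate_dataset",
    "default_paperlike_spec",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_diseases: int = 150
    n_lncrnas: int = 80
    tree_depth: int = 4
    n_roots: int = 3
    n_blocks: int = 5
    density_in: float = 0.25
    density_out: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.density_out < self.density_in <= 1:
            raise ValueError("need 0 <= density_out < density_in <= 1")
        if self.n_blocks > min(self.n_diseases, self.n_lncrnas):
            raise ValueError("more blocks than diseases or lncRNAs")
        if self.n_roots < 1 or self.tree_depth < 1:
            raise ValueError("need at least one root and depth >= 1")


def _streams(spec: FixtureSpec) -> tuple[np.random.Generator, np.random.Generator]:
    onto_ss, assoc_ss = np.random.SeedSequence(spec.seed).spawn(2)
    return np.random.default_rng(onto_ss), np.random.default_rng(assoc_ss)


def _disease_blocks(spec: FixtureSpec) -> list[np.ndarray]:
    return np.array_split(np.arange(spec.n_diseases), spec.n_blocks)


def _lncrna_blocks(spec: FixtureSpec) -> list[np.ndarray]:
    return np.array_split(np.arange(spec.n_lncrnas), spec.n_blocks)


def generate_ontology(spec: FixtureSpec) -> list[DiseaseRecord]:
    """Random prefix-tree tree numbers; block members share an ancestor.

    Each disease draws 1-2 codes by random descent below its block's anchor
    prefix (the block's root, plus a block segment when depth allows), so
    within-block pairs always share at least the anchor while diseases of
    blocks on different roots may be fully disjoint.
    """
    rng, _ = _streams(spec)
    records: list[DiseaseRecord] = []
    for b, members in enumerate(_disease_blocks(spec)):
        root = f"R{b % spec.n_roots:02d}"
        anchor = [root] if spec.tree_depth < 2 else [root, f"B{b:02d}"]
        max_extra = spec.tree_depth - len(anchor)
        for i in members:
            codes = set()
            n_codes = 1 + int(rng.random() < 0.5)
            for _ in range(n_codes):
                extra = int(rng.integers(0, max_extra + 1)) if max_extra > 0 else 0
                segs = anchor + [f"{int(rng.integers(0, 1000)):03d}" for _ in range(extra)]
                codes.add(".".join(segs))
            records.append(
                DiseaseRecord(
                    name=f"disease {i:03d}",
                    tree_numbers=frozenset(codes),
                    label=f"disease {i:03d}",
                )
            )
    records.sort(key=lambda r: r.name)
    return records


def generate_associations(spec: FixtureSpec) -> AssociationMatrix:
    """Planted-block Bernoulli association matrix.

    Within matched lncRNA/disease blocks pairs are positive with probability
    ``density_in``, elsewhere ``density_out``. Any all-zero row or column is
    redrawn once from the same cell probabilities and then accepted as-is.
    """
    _, rng = _streams(spec)
    probs = np.full((spec.n_lncrnas, spec.n_diseases), spec.density_out)
    for lb, db in zip(_lncrna_blocks(spec), _disease_blocks(spec)):
        probs[np.ix_(lb, db)] = spec.density_in
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    for i in np.flatnonzero(values.sum(axis=1) == 0):
        values[i] = rng.random(spec.n_diseases) < probs[i]
    for j in np.flatnonzero(values.sum(axis=0) == 0):
        values[:, j] = rng.random(spec.n_lncrnas) < probs[:, j]
    return AssociationMatrix(
        [f"lnc-{i:03d}" for i in range(spec.n_lncrnas)],
        [f"disease {j:03d}" for j in range(spec.n_diseases)],
        values,
    )


def generate_dataset(spec: FixtureSpec) -> tuple[list[DiseaseRecord], AssociationMatrix]:
    """Matched ontology + association matrix from one spec."""
    return generate_ontology(spec), generate_associations(spec)


def default_paperlike_spec(seed: int = 0) -> FixtureSpec:
    """Dataset shaped like curated lncRNA-disease resources.

    80 lncRNAs x 150 diseases in 5 matched blocks; densities chosen so the
    expected positive count is about 700 (0.25*2400 + 0.01*9600 = 696),
    i.e. roughly 6% overall density.
    """
    return FixtureSpec(
        n_diseases=150,
        n_lncrnas=80,
        tree_depth=4,
        n_roots=3,
        n_blocks=5,
        density_in=0.25,
        density_out=0.01,
        seed=seed,
    )
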