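"""Mixed (Gower-type) functional distance between species.

Per-trait dissimilarities are simple matching for crisp blocks and half the
Manhattan distance between affinity profiles for fuzzy blocks; both are
bounded in [0, 1].  The mixed distance is the (weighted) mean over trait
blocks, optionally square-rooted, which in practice yields a
Euclidean-embeddable configuration suitable for principal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .coding import CodedTraitMatrix

__all__ = ["DistanceMatrix", "block_dissimilarity", "mixed_distance", "is_euclidean"]


@dataclass
class DistanceMatrix:
    """Symmetric species × species distance matrix with zero diagonal."""

    species: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.species):
            raise ValueError("species list does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(list(self.species), name="species")
        return pd.DataFrame(self.values, index=idx, columns=list(self.species))

    def to_csv(self, path) -> None:
        """Square CSV with species header row/column at full double precision."""
        idx = list(self.species)
        with open(Path(path), "w", encoding="utf-8") as fh:
            fh.write("species," + ",".join(idx) + "\n")
            for name, row in zip(idx, self.values):
                fh.write(name + "," + ",".join(repr(float(x)) for x in row) + "\n")


def block_dissimilarity(block: np.ndarray, coding: str,
                        species: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise dissimilarity for one trait block.

    Crisp one-hot rows → 0/1 matching dissimilarity; fuzzy frequency rows →
    half the Manhattan distance, which is matching's natural generalisation
    and shares its [0, 1] bound.  Rows must sum to one.
    """
    block = np.asarray(block, dtype=float)
    if not np.allclose(block.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("trait block rows must sum to 1")
    if coding not in ("crisp", "fuzzy"):
        raise ValueError(f"unknown coding {coding!r}")
    # for one-hot rows cityblock/2 is exactly the 0/1 matching dissimilarity
    d = cdist(block, block, metric="cityblock") / 2.0
    if species is None:
        species = tuple(f"s{i}" for i in range(block.shape[0]))
    return DistanceMatrix(tuple(species), d)


def mixed_distance(matrix: CodedTraitMatrix,
                   block_weights: Mapping[str, float] | None = None,
                   sqrt: bool = True) -> DistanceMatrix:
    """Weighted mean of per-block dissimilarities across the trait blocks.

    Parameters
    ----------
    matrix
        Bin-fuzzy coded trait matrix.
    block_weights
        Optional per-trait weights (default: each trait weighs equally,
        regardless of its number of modalities).  Must be non-negative and
        not all zero.
    sqrt
        Apply a square-root transform (default).  The mean of bounded
        per-block dissimilarities is not Euclidean-embeddable in general;
        its square root almost always is, matching downstream PCoA use.
    """
    if matrix.n_species < 2:
        raise ValueError("need at least 2 species")
    traits = matrix.schema.traits
    if block_weights is None:
        weights = np.ones(len(traits))
    else:
        weights = np.array([block_weights.get(t.name, 1.0) for t in traits], dtype=float)
        if np.any(weights < 0):
            raise ValueError("block weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("block weights sum to zero")

    acc = np.zeros((matrix.n_species, matrix.n_species))
    for trait, w in zip(traits, weights):
        if w == 0:
            continue
        d = block_dissimilarity(matrix.block(trait.name), trait.coding).values
        acc += w * d
    acc /= total
    if sqrt:
        acc = np.sqrt(acc)
    return DistanceMatrix(matrix.species, acc)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Double-centered −½ D² matrix used by classical scaling."""
    d = np.asarray(d, dtype=float)
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def is_euclidean(d: DistanceMatrix, tol: float = 1e-8) -> tuple[bool, float]:
    """Whether the distances embed exactly in Euclidean space.

    Returns ``(flag, min_eigenvalue)`` of the Gower-centered matrix; the flag
    is true when no eigenvalue falls below ``-tol`` relative to the largest
    eigenvalue magnitude.
    """
    eig = np.linalg.eigvalsh(gower_center(d.values))
    scale = max(np.abs(eig).max(), 1.0)
    return bool(eig.min() >= -tol * scale), float(eig.min())
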