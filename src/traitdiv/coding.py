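"""Bin-fuzzy coding of species trait records.

Crisp traits become one-hot blocks; fuzzy traits become rows of affinity
frequencies.  Every trait block row sums to one, so the merged matrix can be
read as one unit of "membership mass" per species per trait — the property
both the mixed trait distance and the fuzzy correspondence analysis rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import SpeciesTraitRecord, TraitSchema, validate_record

__all__ = ["CodedTraitMatrix", "code_traits", "subset_by_function", "functional_entities"]


@dataclass
class CodedTraitMatrix:
    """Species × modality block matrix with per-trait block structure.

    Attributes
    ----------
    species
        Ordered species names (rows).
    schema
        The (possibly function-restricted) trait schema defining the blocks.
    values
        ``(n_species, n_modalities)`` float array of affinities in [0, 1];
        each trait block row sums to one.
    """

    species: tuple[str, ...]
    schema: TraitSchema
    values: np.ndarray

    @property
    def columns(self) -> tuple[tuple[str, str], ...]:
        return self.schema.columns

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def block_index(self) -> dict[str, slice]:
        """Map trait name → contiguous column slice."""
        out: dict[str, slice] = {}
        start = 0
        for trait in self.schema.traits:
            stop = start + len(trait.modalities)
            out[trait.name] = slice(start, stop)
            start = stop
        return out

    def block(self, trait: str) -> np.ndarray:
        return self.values[:, self.block_index[trait]]

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.columns, names=["trait", "modality"])
        return pd.DataFrame(self.values, index=list(self.species), columns=cols)

    def to_csv(self, path) -> None:
        """Flat CSV export: one ``trait.modality`` column per modality."""
        flat = pd.DataFrame(
            self.values,
            index=pd.Index(list(self.species), name="species"),
            columns=[f"{t}.{m}" for t, m in self.columns],
        )
        flat.to_csv(Path(path), lineterminator="\n")


class CodingError(ValueError):
    """Raised when records cannot be coded; carries the violation list."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def code_traits(records: Sequence[SpeciesTraitRecord], schema: TraitSchema) -> CodedTraitMatrix:
    """Merge crisp one-hot blocks and fuzzy frequency blocks.

    Crisp traits are one-hot coded.  A fuzzy trait given as a set of k
    modalities gets frequency 1/k on each assigned item; a code→weight
    mapping is accepted and renormalised to sum to one.

    Raises
    ------
    CodingError
        If any record violates the schema or species names repeat.
    """
    if not records:
        raise CodingError(["no records"])
    violations: list[str] = []
    seen: set[str] = set()
    for rec in records:
        if rec.species in seen:
            violations.append(f"duplicate species {rec.species!r}")
        seen.add(rec.species)
        violations.extend(validate_record(rec, schema))
    if violations:
        raise CodingError(violations)

    n = len(records)
    values = np.zeros((n, schema.n_modalities))
    col_of = {col: j for j, col in enumerate(schema.columns)}
    for i, rec in enumerate(records):
        for trait in schema.traits:
            value = rec.values[trait.name]
            if trait.coding == "crisp":
                values[i, col_of[(trait.name, value)]] = 1.0
            elif isinstance(value, Mapping):
                total = sum(value.values())
                for code, w in value.items():
                    values[i, col_of[(trait.name, code)]] = w / total
            else:
                items = list(value)
                for code in items:
                    values[i, col_of[(trait.name, code)]] = 1.0 / len(items)
    return CodedTraitMatrix(tuple(r.species for r in records), schema, values)


def subset_by_function(matrix: CodedTraitMatrix, function: str) -> CodedTraitMatrix:
    """Restrict the matrix to the trait blocks informing one function.

    Traits informing several functions appear in each of their functions'
    subsets.  ``function="combined"`` returns the matrix unchanged.
    """
    if function == "combined":
        return matrix
    sub = matrix.schema.subset(function)  # validates the tag
    index = matrix.block_index
    cols = np.concatenate([np.arange(index[t.name].start, index[t.name].stop)
                           for t in sub.traits])
    return CodedTraitMatrix(matrix.species, sub, matrix.values[:, cols].copy())


def functional_entities(matrix: CodedTraitMatrix, tol: float = 1e-12) -> list[list[str]]:
    """Partition species into functional entities (identical coded rows).

    Species whose coded profiles agree entrywise within ``tol`` share an
    entity; the number of groups is the ``sing.sp`` statistic.  Groups are
    ordered by first appearance.
    """
    # exact grouping on rounded rows keeps transitivity (unlike pairwise tol)
    decimals = max(0, int(round(-np.log10(tol))))
    groups: dict[bytes, list[str]] = {}
    for name, row in zip(matrix.species, np.round(matrix.values, decimals)):
        groups.setdefault(row.tobytes(), []).append(name)
    return list(groups.values())
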