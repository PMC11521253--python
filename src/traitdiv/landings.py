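"""Landings records: reading, validation, aggregation and weight scaling.

A landings table carries one record per (species, year, month, fleet) with
the landed weight in kilograms.  Records aggregate into per-(fleet, decade)
assemblages whose species totals are min-max standardised to [0, 1] before
entering the abundance-weighted diversity metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLEETS",
    "DECADES",
    "LandingsRecord",
    "AssemblageWeights",
    "ReadReport",
    "read_landings",
    "write_landings",
    "aggregate",
    "aggregate_all",
    "minmax_standardize",
]

FLEETS = ("local", "coastal")

#: Decade labels → inclusive year ranges. 2020 folds into the 10s so the
#: 41-year series 1980–2020 is partitioned without an orphan year.
DECADES: dict[str, tuple[int, int]] = {
    "80s": (1980, 1989),
    "90s": (1990, 1999),
    "00s": (2000, 2009),
    "10s": (2010, 2020),
}

COLUMNS = ("species", "year", "month", "fleet", "weight_kg")


@dataclass(frozen=True)
class LandingsRecord:
    species: str
    year: int
    month: int
    fleet: str
    weight_kg: float


@dataclass
class ReadReport:
    """Validated records plus per-row rejection reasons (1-based line numbers)."""

    records: list[LandingsRecord]
    errors: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.errors)


def decade_of(year: int, decades: Mapping[str, tuple[int, int]] = DECADES) -> str | None:
    for label, (lo, hi) in decades.items():
        if lo <= year <= hi:
            return label
    return None


def check_decades(decades: Mapping[str, tuple[int, int]], years: tuple[int, int]) -> None:
    """Assert the decade ranges partition the year span with no gaps/overlaps."""
    covered = sorted(y for lo, hi in decades.values() for y in range(lo, hi + 1))
    expected = list(range(years[0], years[1] + 1))
    if covered != expected:
        raise ValueError("decade ranges must partition the year range exactly")


def read_landings(path, years: tuple[int, int] = (1980, 2020),
                  fleets: Sequence[str] = FLEETS) -> ReadReport:
    """Read and validate a landings CSV/TSV.

    Malformed rows are collected into the report's error list with line
    numbers and excluded from the records; missing columns raise.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    delim = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    records: list[LandingsRecord] = []
    errors: list[tuple[int, str]] = []
    fleet_set = set(fleets)
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            year = int(getattr(row, "year"))
            month = int(getattr(row, "month"))
            weight = float(getattr(row, "weight_kg"))
        except ValueError as exc:
            errors.append((i, f"unparseable numeric field: {exc}"))
            continue
        fleet = getattr(row, "fleet")
        species = getattr(row, "species").strip()
        if not species:
            errors.append((i, "empty species name"))
        elif not years[0] <= year <= years[1]:
            errors.append((i, f"year {year} outside {years[0]}-{years[1]}"))
        elif not 1 <= month <= 12:
            errors.append((i, f"month {month} outside 1-12"))
        elif fleet not in fleet_set:
            errors.append((i, f"unknown fleet {fleet!r}"))
        elif weight < 0:
            errors.append((i, f"negative weight {weight}"))
        else:
            records.append(LandingsRecord(species, year, month, fleet, weight))
    return ReadReport(records, errors)


def write_landings(records: Iterable[LandingsRecord], path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.species},{r.year},{r.month},{r.fleet},{r.weight_kg!r}\n")


def aggregate(records: Iterable[LandingsRecord], fleet: str, decade: str,
              decades: Mapping[str, tuple[int, int]] = DECADES) -> dict[str, float]:
    """Total landed weight per species within one (fleet, decade) group.

    Species not landed in the group are absent from the mapping (absence is
    not the same as a zero weight).
    """
    lo, hi = decades[decade]
    totals: dict[str, float] = {}
    for r in records:
        if r.fleet == fleet and lo <= r.year <= hi:
            totals[r.species] = totals.get(r.species, 0.0) + r.weight_kg
    return totals


def aggregate_all(records: Iterable[LandingsRecord],
                  decades: Mapping[str, tuple[int, int]] = DECADES,
                  ) -> dict[tuple[str, str], dict[str, float]]:
    """Species totals for every (fleet, decade) group present in the records."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    for r in records:
        dec = decade_of(r.year, decades)
        if dec is None:
            continue
        group = out.setdefault((r.fleet, dec), {})
        group[r.species] = group.get(r.species, 0.0) + r.weight_kg
    return out


@dataclass
class AssemblageWeights:
    """Standardised landings weights for one assemblage.

    ``weights`` are in [0, 1] after min-max scaling; the lightest species
    sits at exactly 0 but remains part of the assemblage (it still counts
    toward presence-based richness).
    """

    species: tuple[str, ...]
    weights: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.species),):
            raise ValueError("weights do not match species")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if w.size and w.max() <= 0:
            raise ValueError("need at least one positive weight")
        self.weights = w

    @property
    def relative(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def minmax_standardize(totals: Mapping[str, float],
                       bounds: tuple[float, float] | None = None) -> AssemblageWeights:
    """Min-max standardise species totals to a 0–1 scale.

    x' = (x − min)/(max − min), computed within the assemblage by default;
    pass ``bounds=(lo, hi)`` to standardise against a global range instead.
    An all-equal (or single-species) assemblage is degenerate for the
    formula and maps to all-1 weights with a ``constant-weights`` flag.
    """
    species = tuple(totals.keys())
    x = np.array([totals[s] for s in species], dtype=float)
    if np.any(x < 0):
        raise ValueError("landings totals must be non-negative")
    lo, hi = (x.min(), x.max()) if bounds is None else bounds
    if hi <= lo:
        return AssemblageWeights(species, np.ones_like(x), ("constant-weights",))
    return AssemblageWeights(species, np.clip((x - lo) / (hi - lo), 0.0, 1.0))


def assemblage_table(groups: Mapping[tuple[str, str], Mapping[str, float]],
                     scope: str = "per-assemblage") -> pd.DataFrame:
    """Long-format table (fleet, decade, species, total_kg, weight_std).

    ``scope`` is ``"per-assemblage"`` (default) or ``"global"`` (one min-max
    range across all groups).
    """
    if scope not in ("per-assemblage", "global"):
        raise ValueError("scope must be 'per-assemblage' or 'global'")
    bounds = None
    if scope == "global":
        allx = [v for g in groups.values() for v in g.values()]
        bounds = (min(allx), max(allx))
    rows = []
    for (fleet, decade), totals in sorted(groups.items()):
        aw = minmax_standardize(totals, bounds=bounds)
        for sp, w in zip(aw.species, aw.weights):
            rows.append((fleet, decade, sp, totals[sp], w))
    return pd.DataFrame(rows, columns=["fleet", "decade", "species", "total_kg", "weight_std"])
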