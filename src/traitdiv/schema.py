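"""Trait scheme registry and species trait records.

The reference scheme describes landed marine fish by 14 categorical traits
grouped into four ecosystem functions (habitat use, locomotion, feeding,
life history) for a total of 76 trait modalities.  Thirteen traits are
*crisp* (a species carries exactly one modality); the diet trait is *fuzzy*
(a species carries affinities to several prey categories).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FUNCTIONS",
    "TraitDefinition",
    "TraitSchema",
    "SpeciesTraitRecord",
    "build_reference_schema",
    "validate_record",
    "read_trait_table",
    "write_trait_table",
    "write_schema",
    "read_schema",
]

#: The four ecosystem functions a trait can inform.
FUNCTIONS = ("habitat_use", "locomotion", "feeding", "life_history")


@dataclass(frozen=True)
class TraitDefinition:
    """One trait: its coding kind, ordered modalities and function memberships.

    Parameters
    ----------
    name
        Identifier of the trait (snake_case).
    coding
        ``"crisp"`` (one-hot) or ``"fuzzy"`` (affinity frequencies).
    modalities
        Ordered modality codes, unique within the trait.
    functions
        Non-empty subset of :data:`FUNCTIONS` this trait informs.
    """

    name: str
    coding: str
    modalities: tuple[str, ...]
    functions: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.coding not in ("crisp", "fuzzy"):
            raise ValueError(f"coding must be crisp or fuzzy, got {self.coding!r}")
        if not self.modalities:
            raise ValueError(f"trait {self.name!r} has no modalities")
        if len(set(self.modalities)) != len(self.modalities):
            raise ValueError(f"trait {self.name!r} has duplicate modalities")
        if not self.functions:
            raise ValueError(f"trait {self.name!r} belongs to no function")
        unknown = set(self.functions) - set(FUNCTIONS)
        if unknown:
            raise ValueError(f"trait {self.name!r}: unknown functions {sorted(unknown)}")


@dataclass(frozen=True)
class TraitSchema:
    """Ordered registry of trait definitions."""

    traits: tuple[TraitDefinition, ...]

    def __post_init__(self) -> None:
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in schema")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    @property
    def n_modalities(self) -> int:
        return sum(len(t.modalities) for t in self.traits)

    @property
    def columns(self) -> tuple[tuple[str, str], ...]:
        """Ordered (trait, modality) column pairs in schema order."""
        return tuple((t.name, m) for t in self.traits for m in t.modalities)

    def trait(self, name: str) -> TraitDefinition:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def traits_for_function(self, function: str) -> tuple[TraitDefinition, ...]:
        if function not in FUNCTIONS:
            raise ValueError(f"unknown function {function!r}; expected one of {FUNCTIONS}")
        return tuple(t for t in self.traits if function in t.functions)

    def modalities_for_function(self, function: str) -> int:
        return sum(len(t.modalities) for t in self.traits_for_function(function))

    def subset(self, function: str) -> "TraitSchema":
        """Schema restricted to the traits informing ``function``."""
        return TraitSchema(self.traits_for_function(function))


@dataclass
class SpeciesTraitRecord:
    """Trait values for one species.

    ``values`` maps trait name to a single modality code for crisp traits and
    to a non-empty collection of modality codes (or a code→weight mapping)
    for fuzzy traits.
    """

    species: str
    values: dict = field(default_factory=dict)


# --- reference scheme ------------------------------------------------------

def build_reference_schema() -> TraitSchema:
    """Return the 14-trait / 76-modality reference scheme.

    Thirteen crisp traits plus the fuzzy diet trait; interval traits use
    canonical ASCII codes with unit suffixes.  Two printed modality labels in
    the source registry were inconsistent with exhaustive, disjoint binning
    and are encoded here so the bins tile the positive line: the first
    growth-coefficient bin is ``<0.3`` and the second fecundity bin is
    ``10-10^2``.
    """
    t = TraitDefinition
    return TraitSchema((
        t("water_column", "crisp",
          ("Batd", "Batp", "Benp", "Deme", "Pene", "Peoc", "Reas"),
          ("habitat_use",)),
        t("temperature", "crisp",
          ("<10C", "10-15C", "15-20C", "20-25C", ">25C"),
          ("habitat_use",)),
        t("max_depth", "crisp",
          ("<500m", "500-1000m", "1000-1500m", "1500-2000m", ">2000m"),
          ("habitat_use",)),
        t("swimming_mode", "crisp",
          ("Amii", "Angu", "Bali", "Cara", "Labr", "Raji", "Subc", "Tetr", "Thun"),
          ("locomotion",)),
        t("body_shape", "crisp",
          ("Eeli", "Elon", "Flat", "Fusi", "Shde"),
          ("habitat_use", "locomotion")),
        t("max_body_size", "crisp",
          ("<100cm", "100-200cm", "200-300cm", "300-400cm", ">400cm"),
          ("feeding", "life_history", "locomotion")),
        t("trophic_position", "crisp",
          ("<2.5", "2.5-3.5", "3.5-4.5", ">4.5"),
          ("habitat_use", "feeding")),
        t("diet", "fuzzy",
          ("Binv", "Ceph", "Chon", "Crde", "Detr", "Herb", "Tele", "Zoop"),
          ("habitat_use", "feeding")),
        t("generation_time", "crisp",
          ("<5y", "5-10y", "10-15y", ">15y"),
          ("life_history",)),
        t("growth_coefficient", "crisp",
          ("<0.3", "0.3-0.6", "0.6-0.9", ">0.9"),
          ("life_history",)),
        t("food_consumption", "crisp",
          ("<5QB", "5-10QB", "10-15QB", ">15QB"),
          ("habitat_use", "feeding")),
        t("maturity_size", "crisp",
          ("<50cm", "50-100cm", "100-150cm", "150-200cm", ">200cm"),
          ("life_history",)),
        t("reproductive_guild", "crisp",
          ("Bear", "Guar", "Mixe", "Ngua"),
          ("life_history",)),
        t("fecundity", "crisp",
          ("<10", "10-10^2", "10^2-10^3", "10^3-10^4", "10^4-10^5", "10^5-10^6", ">10^6"),
          ("life_history",)),
    ))


# --- validation ------------------------------------------------------------

def validate_record(record: SpeciesTraitRecord, schema: TraitSchema) -> list[str]:
    """Check a record against the schema.

    Returns a list of human-readable violation descriptions; an empty list
    means the record is valid.  Violations are data, not exceptions, so a
    table can be screened in one pass.
    """
    violations: list[str] = []
    for trait in schema.traits:
        if trait.name not in record.values:
            violations.append(f"{record.species}: missing trait {trait.name!r}")
            continue
        value = record.values[trait.name]
        if trait.coding == "crisp":
            if not isinstance(value, str):
                violations.append(
                    f"{record.species}: trait {trait.name!r} is crisp and takes a "
                    f"single modality code, got {value!r}")
                continue
            if value not in trait.modalities:
                violations.append(
                    f"{record.species}: modality {value!r} not in trait {trait.name!r}")
        else:
            items: Iterable[str]
            if isinstance(value, str):
                violations.append(
                    f"{record.species}: trait {trait.name!r} is fuzzy and takes a "
                    f"set of modality codes, got bare string {value!r}")
                continue
            items = value.keys() if isinstance(value, Mapping) else value
            items = list(items)
            if not items:
                violations.append(
                    f"{record.species}: fuzzy trait {trait.name!r} has no modalities")
            for item in items:
                if item not in trait.modalities:
                    violations.append(
                        f"{record.species}: modality {item!r} not in trait {trait.name!r}")
            if isinstance(value, Mapping):
                if any(w < 0 for w in value.values()):
                    violations.append(
                        f"{record.species}: negative affinity in trait {trait.name!r}")
                elif sum(value.values()) <= 0:
                    violations.append(
                        f"{record.species}: zero total affinity in trait {trait.name!r}")
    known = {t.name for t in schema.traits}
    for name in record.values:
        if name not in known:
            violations.append(f"{record.species}: unknown trait {name!r}")
    return violations


# --- I/O -------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_trait_table(path, schema: TraitSchema | None = None) -> list[SpeciesTraitRecord]:
    """Read a species × trait table (CSV or TSV).

    One row per species, a ``species`` column, one column per crisp trait
    holding a modality code, and one column per fuzzy trait holding
    semicolon-separated modality codes.
    """
    if schema is None:
        schema = build_reference_schema()
    path = Path(path)
    delim = _sniff_delimiter(path)
    records: list[SpeciesTraitRecord] = []
    fuzzy = {t.name for t in schema.traits if t.coding == "fuzzy"}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or "species" not in reader.fieldnames:
            raise ValueError(f"{path}: trait table needs a 'species' column")
        for row in reader:
            values: dict = {}
            for name, raw in row.items():
                if name == "species" or raw is None:
                    continue
                raw = raw.strip()
                if name in fuzzy:
                    values[name] = tuple(s.strip() for s in raw.split(";") if s.strip())
                else:
                    values[name] = raw
            records.append(SpeciesTraitRecord(row["species"].strip(), values))
    return records


def write_trait_table(records: Sequence[SpeciesTraitRecord], path,
                      schema: TraitSchema | None = None) -> None:
    """Write records in the dialect :func:`read_trait_table` consumes."""
    if schema is None:
        schema = build_reference_schema()
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["species", *schema.trait_names])
        for rec in records:
            row = [rec.species]
            for trait in schema.traits:
                value = rec.values[trait.name]
                if trait.coding == "fuzzy":
                    items = value.keys() if isinstance(value, Mapping) else value
                    row.append(";".join(items))
                else:
                    row.append(value)
            writer.writerow(row)


def write_schema(schema: TraitSchema, path) -> None:
    """Serialise a schema to a key-value text document (round-trips exactly)."""
    lines = []
    for t in schema.traits:
        lines.append(f"trait: {t.name}")
        lines.append(f"  coding: {t.coding}")
        lines.append(f"  functions: {'|'.join(t.functions)}")
        lines.append(f"  modalities: {'|'.join(t.modalities)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_schema(path) -> TraitSchema:
    """Parse the document written by :func:`write_schema`."""
    traits: list[TraitDefinition] = []
    current: dict | None = None

    def flush() -> None:
        if current is not None:
            traits.append(TraitDefinition(
                current["name"], current["coding"],
                tuple(current["modalities"]), tuple(current["functions"])))

    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        key, _, value = line.strip().partition(":")
        value = value.strip()
        if key == "trait":
            flush()
            current = {"name": value}
        elif current is not None and key in ("coding",):
            current["coding"] = value
        elif current is not None and key in ("functions", "modalities"):
            current[key] = value.split("|")
        else:
            raise ValueError(f"unrecognised schema line: {line!r}")
    flush()
    return TraitSchema(tuple(traits))
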