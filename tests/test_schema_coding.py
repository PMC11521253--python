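"""Trait scheme registry, record validation and bin-fuzzy coding."""

import numpy as np
import pytest

from traitdiv import (FUNCTIONS, ScenarioConfig, SpeciesTraitRecord, TraitDefinition,
                      TraitSchema, code_traits,
                      functional_entities, generate_species_pool, read_schema,
                      read_trait_table, subset_by_function, validate_record,
                      write_schema, write_trait_table)
from traitdiv.coding import CodingError

from oracles import brute_entities


def make_record(schema, **overrides):
    """A valid record taking the first modality of every trait."""
    species = overrides.pop("species", "sp_test")
    values = {t.name: (t.modalities[:1] if t.coding == "fuzzy" else t.modalities[0])
              for t in schema.traits}
    values.update(overrides)
    return SpeciesTraitRecord(species, values)


class TestReferenceSchema:
    def test_counts(self, schema):
        assert len(schema.traits) == 14
        assert schema.n_modalities == 76
        assert set(FUNCTIONS) == {f for t in schema.traits for f in t.functions}

    def test_every_function_covers_at_least_four_modalities(self, schema):
        for f in FUNCTIONS:
            assert schema.modalities_for_function(f) >= 4

    def test_diet_modalities(self, schema):
        diet = schema.trait("diet")
        assert diet.coding == "fuzzy"
        assert set(diet.modalities) == {"Binv", "Ceph", "Chon", "Crde",
                                        "Detr", "Herb", "Tele", "Zoop"}

    def test_multi_function_traits(self, schema):
        assert set(schema.trait("body_shape").functions) == {"habitat_use", "locomotion"}
        assert set(schema.trait("max_body_size").functions) == {
            "feeding", "life_history", "locomotion"}
        for name in ("trophic_position", "diet", "food_consumption"):
            assert set(schema.trait(name).functions) == {"habitat_use", "feeding"}

    def test_growth_and_fecundity_bins_tile_the_line(self, schema):
        assert schema.trait("growth_coefficient").modalities[0] == "<0.3"
        assert schema.trait("fecundity").modalities[1] == "10-10^2"

    def test_function_subsets_cover_all_traits(self, schema):
        union = {t.name for f in FUNCTIONS for t in schema.traits_for_function(f)}
        assert union == set(schema.trait_names)

    def test_invalid_definitions_rejected(self):
        with pytest.raises(ValueError):
            TraitDefinition("t", "crisp", (), ("feeding",))
        with pytest.raises(ValueError):
            TraitDefinition("t", "crisp", ("a", "a"), ("feeding",))
        with pytest.raises(ValueError):
            TraitDefinition("t", "ordinal", ("a",), ("feeding",))
        with pytest.raises(ValueError):
            TraitDefinition("t", "crisp", ("a",), ("swimming",))
        t = TraitDefinition("t", "crisp", ("a",), ("feeding",))
        with pytest.raises(ValueError):
            TraitSchema((t, t))


class TestValidateRecord:
    def test_modality_not_in_trait(self, schema):
        rec = make_record(schema, swimming_mode="Fusi")
        violations = validate_record(rec, schema)
        assert len(violations) == 1 and "swimming_mode" in violations[0]

    def test_missing_trait(self, schema):
        rec = make_record(schema)
        del rec.values["fecundity"]
        violations = validate_record(rec, schema)
        assert len(violations) == 1 and "fecundity" in violations[0]

    def test_valid_record(self, schema):
        assert validate_record(make_record(schema), schema) == []

    def test_fuzzy_trait_rejects_bare_string_and_empty_set(self, schema):
        assert validate_record(make_record(schema, diet="Tele"), schema)
        assert validate_record(make_record(schema, diet=()), schema)


class TestCodeTraits:
    def test_diet_split_equally(self, schema):
        rec = make_record(schema, diet=("Tele", "Ceph"))
        m = code_traits([rec], schema)
        block = dict(zip(schema.trait("diet").modalities, m.block("diet")[0]))
        assert block["Tele"] == block["Ceph"] == 0.5
        assert sum(block.values()) == 1.0

    def test_single_diet_item(self, schema):
        m = code_traits([make_record(schema, diet=("Zoop",))], schema)
        assert m.block("diet")[0][schema.trait("diet").modalities.index("Zoop")] == 1.0

    def test_user_supplied_diet_weights_renormalized(self, schema):
        rec = make_record(schema, diet={"Tele": 3.0, "Zoop": 1.0})
        m = code_traits([rec], schema)
        diet = schema.trait("diet").modalities
        assert m.block("diet")[0][diet.index("Tele")] == pytest.approx(0.75)

    def test_block_rows_sum_to_one(self, schema, pool20):
        assert pool20.values.shape == (20, 76)
        for trait in schema.traits:
            np.testing.assert_allclose(pool20.block(trait.name).sum(axis=1), 1.0,
                                       atol=1e-12)
            if trait.coding == "crisp":
                assert ((pool20.block(trait.name) == 1).sum(axis=1) == 1).all()

    def test_duplicate_species_rejected(self, schema):
        rec = make_record(schema)
        with pytest.raises(CodingError, match="duplicate"):
            code_traits([rec, rec], schema)

    def test_invalid_record_rejected_with_violations(self, schema):
        bad = make_record(schema, swimming_mode="nope")
        with pytest.raises(CodingError) as err:
            code_traits([bad], schema)
        assert any("swimming_mode" in v for v in err.value.violations)


class TestSubsetByFunction:
    def test_life_history_blocks(self, schema, pool20):
        sub = subset_by_function(pool20, "life_history")
        assert sub.schema.trait_names == ("max_body_size", "generation_time",
                                          "growth_coefficient", "maturity_size",
                                          "reproductive_guild", "fecundity")

    def test_locomotion_blocks(self, pool20):
        sub = subset_by_function(pool20, "locomotion")
        assert set(sub.schema.trait_names) == {"swimming_mode", "body_shape",
                                               "max_body_size"}

    def test_idempotent_and_block_invariants(self, pool20):
        sub = subset_by_function(pool20, "feeding")
        again = subset_by_function(sub, "feeding")
        np.testing.assert_array_equal(sub.values, again.values)
        for trait in sub.schema.traits:
            np.testing.assert_allclose(sub.block(trait.name).sum(axis=1), 1.0)

    def test_unknown_tag(self, pool20):
        with pytest.raises(ValueError, match="unknown function"):
            subset_by_function(pool20, "swimming")


class TestFunctionalEntities:
    def test_constructed_duplicates(self, schema):
        records = generate_species_pool(
            ScenarioConfig(n_species=10, n_profiles=4, seed=5), schema)
        m = code_traits(records, schema)
        assert len(functional_entities(m)) == 4

    def test_all_distinct(self, pool20):
        groups = functional_entities(pool20)
        assert sum(len(g) for g in groups) == 20

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, schema, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        base = generate_species_pool(
            ScenarioConfig(n_species=max(10, n), n_profiles=4, seed=seed), schema)
        m = code_traits(base[:max(10, n)], schema)
        assert len(functional_entities(m)) == brute_entities(m.values)


class TestRoundTrips:
    def test_schema_round_trip_bit_exact(self, schema, tmp_path):
        path = tmp_path / "schema.txt"
        write_schema(schema, path)
        again = read_schema(path)
        assert again == schema
        write_schema(again, tmp_path / "schema2.txt")
        assert path.read_bytes() == (tmp_path / "schema2.txt").read_bytes()

    def test_trait_table_round_trip(self, schema, tmp_path):
        records = generate_species_pool(ScenarioConfig(n_species=12, seed=2), schema)
        path = tmp_path / "traits.csv"
        write_trait_table(records, path, schema)
        back = read_trait_table(path, schema)
        assert code_traits(back, schema).values == pytest.approx(
            code_traits(records, schema).values)
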