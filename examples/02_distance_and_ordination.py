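"""Mixed trait distance and the PCoA trait space.

Generates a 30-species pool, builds the Gower-type mixed distance (matching
dissimilarity per crisp trait, half-Manhattan for diet, square root of the
equal-weight block mean), and embeds it by principal coordinates.
"""

from traitdiv import (ScenarioConfig, build_reference_schema, code_traits,
                      generate_species_pool, is_euclidean, mixed_distance, pcoa,
                      representation_quality, retain_axes)

schema = build_reference_schema()
pool = generate_species_pool(ScenarioConfig(n_species=30, seed=7), schema)
matrix = code_traits(pool, schema)

dist = mixed_distance(matrix)  # sqrt transform on by default
print(f"distance matrix: {dist.n} species, "
      f"range [{dist.values.min():.3f}, {dist.values.max():.3f}] "
      "(bounded in [0, 1] by construction)")

euclidean, min_eig = is_euclidean(dist)
print(f"Euclidean-embeddable: {euclidean} (smallest eigenvalue {min_eig:.2e})")

ordn = pcoa(dist)
m = retain_axes(dist.n)  # largest t with n >= 2^t
quality = representation_quality(ordn.eigenvalues, m)
print(f"PCoA: {ordn.n_positive} positive axes; retain m={m} "
      f"(2^{m} <= {dist.n}); quality of the reduced space "
      f"(quali.FRic) = {quality:.3f}")
print("first species, first 3 coordinates:",
      [round(float(x), 3) for x in ordn.coordinates[0, :3]])
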