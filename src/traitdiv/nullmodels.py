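"""Permutation null models for differences in functional diversity.

The null hypothesis is a random arrangement of species' trait profiles:
whole coded rows are shuffled against species labels, so existing trait
combinations stay intact while their link to the landings weights is
broken.  The observed |A − B| difference in a metric is compared with the
differences recomputed under 999 (by default) such shuffles, and the
p-value is the exceedance fraction.

Because shuffling whole rows only relabels which species sits at which
point of the trait space, the distance matrix and its PCoA embedding are
permutation images of the originals; each iteration therefore reassigns
species to precomputed coordinates instead of redoing the
eigendecomposition (``recompute="full"`` redoes everything and gives
identical results).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodedTraitMatrix
from .landings import FLEETS, AssemblageWeights
from .metrics import (PooledSpace, functional_dispersion, functional_divergence,
                      functional_evenness, functional_richness, hull_vertex_points,
                      standardize_fric)

__all__ = ["NullTestResult", "permute_trait_assignment", "null_test", "run_comparisons"]

METRICS = ("FRic", "FEve", "FDiv", "FDis")
DECADE_PAIRS = (("80s", "90s"), ("80s", "00s"), ("80s", "10s"),
                ("90s", "00s"), ("90s", "10s"), ("00s", "10s"))


@dataclass
class NullTestResult:
    metric: str
    function: str
    group_a: str
    group_b: str
    observed_a: float
    observed_b: float
    observed_diff: float
    simulated_diffs: np.ndarray
    p_value: float
    n_iter: int
    n_effective: int
    seed: int

    def as_row(self) -> dict:
        return {
            "metric": self.metric, "function": self.function,
            "group_A": self.group_a, "group_B": self.group_b,
            "observed_A": self.observed_a, "observed_B": self.observed_b,
            "difference": self.observed_diff, "p_value": self.p_value,
            "n_effective": self.n_effective, "seed": self.seed,
        }


def permute_trait_assignment(matrix: CodedTraitMatrix,
                             rng: np.random.Generator) -> CodedTraitMatrix:
    """Reassign whole trait profiles to species labels uniformly at random.

    The multiset of coded rows is unchanged; only which species carries
    which profile moves.
    """
    if matrix.n_species < 2:
        raise ValueError("need at least 2 species")
    perm = rng.permutation(matrix.n_species)
    return CodedTraitMatrix(matrix.species, matrix.schema, matrix.values[perm])


def _metric_value(metric: str, points: np.ndarray, weights: np.ndarray,
                  space: PooledSpace, rows: np.ndarray | None = None,
                  cache: dict | None = None) -> float:
    """One metric on one assemblage's points; NaN marks a degenerate case.

    ``rows``/``cache`` let repeated re-labelled evaluations over one point
    cloud reuse the convex hull, which depends only on the *set* of selected
    rows (for a full-pool assemblage, on nothing at all).
    """
    if metric == "FRic":
        if space.global_fric <= 0:
            return float("nan")
        key = ("fric", frozenset(rows.tolist())) if rows is not None else None
        if cache is not None and key in cache:
            raw = cache[key]
        else:
            raw, _ = functional_richness(points, space.m)
            if cache is not None:
                cache[key] = raw
        return standardize_fric(raw, space.global_fric)
    if metric == "FEve":
        value, _ = functional_evenness(points, weights)
        return value
    if metric == "FDiv":
        vertex_points = None
        if cache is not None and rows is not None:
            key = ("verts", frozenset(rows.tolist()))
            if key not in cache:
                cache[key] = hull_vertex_points(points)
            vertex_points, flag = cache[key]
            if flag is not None:
                return float("nan")
        value, _ = functional_divergence(points, weights, vertex_points)
        return value
    if metric == "FDis":
        return functional_dispersion(points, weights)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _test_rng(seed: int, metric: str, function: str,
              group_a: str, group_b: str) -> np.random.Generator:
    """Independent, order-insensitive stream per (metric, function, pair)."""
    key = zlib.crc32(f"{metric}|{function}|{group_a}|{group_b}".encode())
    return np.random.default_rng([int(seed) % (2 ** 31), key])


def null_test(pool: CodedTraitMatrix, weights_a: AssemblageWeights,
              weights_b: AssemblageWeights, metric: str,
              function: str = "combined", n_iter: int = 999,
              seed: int = 0, group_a: str = "A", group_b: str = "B",
              space: PooledSpace | None = None, recompute: str = "relabel",
              plus_one: bool = False) -> NullTestResult:
    """Randomisation test for a metric difference between two assemblages.

    The simulated statistic is |metric(A) − metric(B)| recomputed per trait
    shuffle; p = exceedances / n_iter (``plus_one=True`` adds the observed
    value to both counts).  Iterations where either group's metric is
    degenerate (NaN) are excluded and the effective denominator reported.

    Raises
    ------
    ValueError
        If the metric is undefined for either group on the observed data.
    """
    if recompute not in ("relabel", "full"):
        raise ValueError("recompute must be 'relabel' or 'full'")
    if space is None:
        space = PooledSpace.build(pool, function)
    rows_a, rows_b = space.rows(weights_a.species), space.rows(weights_b.species)

    cache: dict = {}
    obs_a = _metric_value(metric, space.coords[rows_a], weights_a.weights, space,
                          rows_a, cache)
    obs_b = _metric_value(metric, space.coords[rows_b], weights_b.weights, space,
                          rows_b, cache)
    if np.isnan(obs_a) or np.isnan(obs_b):
        raise ValueError(
            f"{metric} undefined for observed data ({group_a}={obs_a}, {group_b}={obs_b})")
    obs_diff = abs(obs_a - obs_b)

    rng = _test_rng(seed, metric, function, group_a, group_b)
    sims = np.empty(n_iter)
    n_pool = space.matrix.n_species
    for it in range(n_iter):
        perm = rng.permutation(n_pool)
        if recompute == "full":
            shuffled = CodedTraitMatrix(space.matrix.species, space.matrix.schema,
                                        space.matrix.values[perm])
            it_space = PooledSpace.build(shuffled, "combined")
            pa = it_space.coords[it_space.rows(weights_a.species)]
            pb = it_space.coords[it_space.rows(weights_b.species)]
            sim_a = _metric_value(metric, pa, weights_a.weights, it_space)
            sim_b = _metric_value(metric, pb, weights_b.weights, it_space)
        else:
            sim_a = _metric_value(metric, space.coords[perm[rows_a]],
                                  weights_a.weights, space, perm[rows_a], cache)
            sim_b = _metric_value(metric, space.coords[perm[rows_b]],
                                  weights_b.weights, space, perm[rows_b], cache)
        sims[it] = abs(sim_a - sim_b)

    valid = ~np.isnan(sims)
    n_eff = int(valid.sum())
    exceed = int(np.sum(sims[valid] >= obs_diff))
    if plus_one:
        p = (exceed + 1) / (n_eff + 1) if n_eff else 1.0
    else:
        p = exceed / n_eff if n_eff else float("nan")
    return NullTestResult(metric, function, group_a, group_b, obs_a, obs_b,
                          obs_diff, sims, float(p), n_iter, n_eff, seed)


def run_comparisons(pool: CodedTraitMatrix,
                    assemblages: Mapping[tuple[str, str], AssemblageWeights],
                    fleet_totals: Mapping[str, AssemblageWeights] | None = None,
                    functions: Sequence[str] = ("combined", "habitat_use",
                                                "locomotion", "feeding", "life_history"),
                    metrics: Sequence[str] = METRICS,
                    n_iter: int = 999, seed: int = 0,
                    fleets: Sequence[str] = FLEETS,
                    decade_pairs: Sequence[tuple[str, str]] = DECADE_PAIRS,
                    ) -> tuple[pd.DataFrame, list[NullTestResult]]:
    """All fleet and decade-pair tests per metric and function subset.

    For each function subset one global trait space is built from the pool
    and shared by every test.  Comparisons are the local-vs-coastal fleet
    pair (when ``fleet_totals`` is given) plus the six decade pairs within
    each fleet; missing assemblages skip their comparison with a reason row.
    """
    rows, results = [], []
    for function in functions:
        space = PooledSpace.build(pool, function)
        pairs: list[tuple[str, str, AssemblageWeights | None, AssemblageWeights | None]] = []
        if fleet_totals is not None:
            pairs.append((fleets[0], fleets[1],
                          fleet_totals.get(fleets[0]), fleet_totals.get(fleets[1])))
        for fleet in fleets:
            for da, db in decade_pairs:
                pairs.append((f"{fleet}:{da}", f"{fleet}:{db}",
                              assemblages.get((fleet, da)), assemblages.get((fleet, db))))
        for metric in metrics:
            for ga, gb, wa, wb in pairs:
                if wa is None or wb is None:
                    rows.append({"metric": metric, "function": function,
                                 "group_A": ga, "group_B": gb,
                                 "skipped": "missing assemblage"})
                    continue
                try:
                    res = null_test(pool, wa, wb, metric, function, n_iter, seed,
                                    ga, gb, space=space)
                except ValueError as exc:
                    rows.append({"metric": metric, "function": function,
                                 "group_A": ga, "group_B": gb, "skipped": str(exc)})
                    continue
                results.append(res)
                rows.append(res.as_row())
    return pd.DataFrame(rows), results
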