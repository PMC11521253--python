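"""Landings-weighted functional diversity metrics in the reduced trait space.

FRic is the convex-hull volume of an assemblage (presence only), reported
standardised by the hull volume of the full species pool.  FEve, FDiv and
FDis weight species by their standardised landings: FEve measures the
regularity of species spacing and weight along the minimum spanning tree,
FDiv the weight carried by species far from the hull-vertex centre of
gravity, and FDis the weighted mean distance to the weighted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .coding import CodedTraitMatrix, functional_entities, subset_by_function
from .distance import mixed_distance
from .landings import AssemblageWeights
from .ordination import pcoa, representation_quality, retain_axes

__all__ = [
    "FDResult",
    "functional_richness",
    "standardize_fric",
    "functional_evenness",
    "functional_divergence",
    "functional_dispersion",
    "hull_vertex_points",
    "compute_fd",
    "minimum_spanning_tree_edges",
]


@dataclass
class FDResult:
    """All diversity statistics for one assemblage under one function subset."""

    assemblage: str
    function: str
    nbsp: int
    sing_sp: int
    quali_fric: float
    fric_raw: float
    fric_std: float
    feve: float
    fdiv: float
    fdis: float
    retained_axes: int
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        return {
            "assemblage": self.assemblage, "function": self.function,
            "nbsp": self.nbsp, "sing.sp": self.sing_sp,
            "quali.FRic": self.quali_fric, "FRic": self.fric_std,
            "FEve": self.feve, "FDiv": self.fdiv, "FDis": self.fdis,
            "axes": self.retained_axes, "flags": ";".join(self.flags),
        }


def _unique_points(points: np.ndarray) -> np.ndarray:
    return np.unique(np.round(points, 12), axis=0)


def functional_richness(points: np.ndarray, m: int | None = None
                        ) -> tuple[float, str | None]:
    """Convex-hull volume of the assemblage in the m retained axes.

    Duplicate coordinates collapse first; fewer than m+1 distinct points (or
    a flat configuration) cannot span an m-volume and returns ``(0.0,
    "degenerate")``.  With m = 1 the "volume" is the coordinate range.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if m is None:
        m = points.shape[1]
    if m < 1:
        raise ValueError("m must be >= 1")
    pts = _unique_points(points[:, :m])
    if pts.shape[0] < m + 1:
        return 0.0, "degenerate"
    if m == 1:
        return float(pts.max() - pts.min()), None
    try:
        return float(ConvexHull(pts).volume), None
    except QhullError:
        return 0.0, "degenerate"


def standardize_fric(raw: float, global_raw: float) -> float:
    """Express a hull volume as a fraction of the full pool's hull volume."""
    if global_raw <= 0:
        raise ValueError("global FRic must be positive")
    return float(raw) / float(global_raw)


def minimum_spanning_tree_edges(points: np.ndarray) -> list[tuple[int, int, float]]:
    """Kruskal MST over Euclidean distances, ties broken by (d, i, j) order.

    Returns n−1 edges as (i, j, distance) with i < j.  The lexicographic
    tie-break makes the tree — and hence FEve on trait data, where distance
    ties are common — deterministic and order-independent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        return []
    d = squareform(pdist(points))
    ii, jj = np.triu_indices(n, k=1)
    dd = d[ii, jj]
    order = np.lexsort((jj, ii, dd))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, float(dd[k])))
            if len(edges) == n - 1:
                break
    return edges


def functional_evenness(points: np.ndarray, weights: np.ndarray
                        ) -> tuple[float, str | None]:
    """Regularity of species spacing and landings weight along the MST.

    Each branch l joining species i and j carries EW_l = d(i,j)/(w_i + w_j)
    with relative weights w; PEW_l = EW_l / Σ EW; FEve rescales
    Σ min(PEW_l, 1/(S−1)) from its minimum so the value lies in [0, 1] and
    equals 1 when every branch carries the same PEW.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    S = points.shape[0]
    if S < 3:
        return float("nan"), "feve-needs-3-species"
    w = w / w.sum()
    edges = minimum_spanning_tree_edges(points)
    ew = np.empty(len(edges))
    for k, (i, j, d) in enumerate(edges):
        denom = w[i] + w[j]
        ew[k] = d / denom if denom > 0 else np.inf
    if np.isinf(ew).any():
        # limit of vanishing weights: infinite branches share all the mass
        pew = np.where(np.isinf(ew), 1.0 / np.isinf(ew).sum(), 0.0)
        flag = "feve-zero-weight-pair"
    elif ew.sum() == 0:
        # all species at one point: spacing is trivially even
        return 1.0, "feve-zero-length-tree"
    else:
        pew = ew / ew.sum()
        flag = None
    thresh = 1.0 / (S - 1)
    feve = (np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh)
    return float(feve), flag


def _hull_vertex_rows(points: np.ndarray) -> tuple[np.ndarray, str | None]:
    """Row indices of species sitting on the convex hull of ``points``."""
    pts = _unique_points(points)
    m = points.shape[1]
    if m == 0 or pts.shape[0] < m + 1:
        return np.array([], dtype=int), "degenerate"
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return np.array([], dtype=int), "degenerate"
    vertex_pts = np.round(pts[hull.vertices], 12)
    rounded = np.round(points, 12)
    mask = (rounded[:, None, :] == vertex_pts[None, :, :]).all(axis=2).any(axis=1)
    return np.nonzero(mask)[0], None


def hull_vertex_points(points: np.ndarray) -> tuple[np.ndarray, str | None]:
    """Coordinates of the convex-hull vertices of a point cloud (deduplicated).

    Depends only on the set of points, so callers evaluating many
    re-labelled assemblages over one cloud can compute it once.
    """
    vert, flag = _hull_vertex_rows(points)
    if flag is not None:
        return np.empty((0, points.shape[1] if points.ndim == 2 else 0)), flag
    return np.unique(np.round(points[vert], 12), axis=0), None


def functional_divergence(points: np.ndarray, weights: np.ndarray,
                          vertex_points: np.ndarray | None = None
                          ) -> tuple[float, str | None]:
    """Weight carried by species far from the hull-vertex centre of gravity.

    G is the unweighted centroid of the hull-vertex species; with dG_i the
    distance of species i to G and d̄G their unweighted mean,
    Δd = Σ w_i (dG_i − d̄G) and Δ|d| = Σ w_i |dG_i − d̄G| over relative
    weights w; FDiv = (Δd + d̄G) / (Δ|d| + d̄G) ∈ [0, 1].
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if vertex_points is None:
        vertex_points, flag = hull_vertex_points(points)
        if flag is not None:
            return float("nan"), "fdiv-degenerate-hull"
    elif vertex_points.size == 0:
        return float("nan"), "fdiv-degenerate-hull"
    rounded = np.round(points, 12)
    on_vertex = (rounded[:, None, :] == vertex_points[None, :, :]).all(axis=2).any(axis=1)
    G = points[on_vertex].mean(axis=0)
    dG = np.sqrt(((points - G) ** 2).sum(axis=1))
    mean_dG = dG.mean()
    delta = float(np.sum(w * (dG - mean_dG)))
    delta_abs = float(np.sum(w * np.abs(dG - mean_dG)))
    if delta_abs + mean_dG == 0:
        return 1.0, "fdiv-point-mass"  # all species coincide with G
    return float((delta + mean_dG) / (delta_abs + mean_dG)), None


def functional_dispersion(points: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean distance of species to the weighted centroid."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(weights, dtype=float)
    if a.sum() <= 0:
        raise ValueError("need at least one positive weight")
    c = (a[:, None] * points).sum(axis=0) / a.sum()
    dist = np.sqrt(((points - c) ** 2).sum(axis=1))
    return float((a * dist).sum() / a.sum())


# --- full per-assemblage computation ---------------------------------------

@dataclass
class PooledSpace:
    """A function subset's global reduced trait space, shared by assemblages.

    Built once from the full species pool so every assemblage of a
    comparison is measured in the same coordinates, with a common axis count
    m = min(floor(log2 nbsp_pool), positive axes).
    """

    function: str
    matrix: CodedTraitMatrix          # function-restricted coded pool
    coords: np.ndarray                # pool species × m
    eigenvalues: np.ndarray
    m: int
    global_fric: float
    index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, pool: CodedTraitMatrix, function: str,
              sqrt_distance: bool = True) -> "PooledSpace":
        sub = subset_by_function(pool, function)
        ordn = pcoa(mixed_distance(sub, sqrt=sqrt_distance))
        m = min(retain_axes(sub.n_species), max(ordn.n_positive, 1))
        coords = ordn.axes(m)
        global_fric, gflag = functional_richness(coords, m)
        return cls(function, sub, coords, ordn.eigenvalues, m, global_fric,
                   {s: i for i, s in enumerate(sub.species)})

    def rows(self, species) -> np.ndarray:
        return np.array([self.index[s] for s in species], dtype=int)


def compute_fd(pool: CodedTraitMatrix, assemblage: AssemblageWeights,
               function: str = "combined", assemblage_id: str = "",
               space: PooledSpace | None = None,
               sqrt_distance: bool = True) -> FDResult:
    """Full per-assemblage computation: coding subset → distance → PCoA →
    FRic/FEve/FDiv/FDis with standardised landings weights.

    ``space`` lets callers reuse one :class:`PooledSpace` (the global
    ordination) across many assemblages; otherwise it is built here.
    """
    if space is None:
        space = PooledSpace.build(pool, function, sqrt_distance)
    missing = [s for s in assemblage.species if s not in space.index]
    if missing:
        raise ValueError(f"assemblage species not in pool: {missing[:5]}")
    rows = space.rows(assemblage.species)
    points = space.coords[rows]
    weights = assemblage.weights

    flags: list[str] = list(assemblage.flags)
    nbsp = len(assemblage.species)
    sub_rows = CodedTraitMatrix(assemblage.species, space.matrix.schema,
                                space.matrix.values[rows])
    sing_sp = len(functional_entities(sub_rows))
    quali = representation_quality(space.eigenvalues, space.m)

    fric_raw, f_flag = functional_richness(points, space.m)
    if f_flag:
        flags.append(f"fric-{f_flag}")
    fric_std = (standardize_fric(fric_raw, space.global_fric)
                if space.global_fric > 0 else float("nan"))
    if space.global_fric <= 0:
        flags.append("global-fric-degenerate")

    feve, e_flag = functional_evenness(points, weights)
    if e_flag:
        flags.append(e_flag)
    fdiv, d_flag = functional_divergence(points, weights)
    if d_flag:
        flags.append(d_flag)
    fdis = functional_dispersion(points, weights)

    return FDResult(assemblage_id, function, nbsp, sing_sp, quali,
                    fric_raw, fric_std, feve, fdiv, fdis, space.m, tuple(flags))
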