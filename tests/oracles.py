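"""Independent brute-force oracles for the diversity metrics and ordinations.

Every function here recomputes a quantity by a different route than the
package (explicit formula sums, exhaustive searches, networkx MST, Delaunay
simplex volumes, linear programming vertex tests) so agreement is evidence,
not tautology.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.optimize import linprog
from scipy.spatial import Delaunay


def brute_hull_2d(points: np.ndarray) -> list[int]:
    """O(n^3) convex hull membership: i is a vertex iff some directed edge
    (i, j) has every other point strictly to its left."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    vertices = set()
    for i, j in itertools.permutations(range(n), 2):
        edge = pts[j] - pts[i]
        rel = pts - pts[i]
        cross = edge[0] * rel[:, 1] - edge[1] * rel[:, 0]
        others = np.delete(cross, [i, j])
        if np.all(others > 1e-12):
            vertices.add(i)
            vertices.add(j)
    return sorted(vertices)


def shoelace_area(points: np.ndarray) -> float:
    """Polygon area of the 2-D hull via the shoelace formula."""
    pts = np.asarray(points, dtype=float)
    hull = brute_hull_2d(pts)
    if len(hull) < 3:
        return 0.0
    centre = pts[hull].mean(axis=0)
    angles = np.arctan2(*(pts[hull] - centre).T[::-1])
    ring = [hull[k] for k in np.argsort(angles)]
    x, y = pts[ring, 0], pts[ring, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def simplex_volume_hull(points: np.ndarray) -> float:
    """m-dimensional hull volume as the sum of Delaunay simplex volumes."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    m = pts.shape[1]
    tri = Delaunay(pts)
    total = 0.0
    for simplex in tri.simplices:
        edges = pts[simplex[1:]] - pts[simplex[0]]
        total += abs(np.linalg.det(edges)) / math.factorial(m)
    return total


def vertex_indices_lp(points: np.ndarray) -> list[int]:
    """Vertices of the convex hull in any dimension by linear programming:
    a point is a vertex iff it is not a convex combination of the others."""
    pts = np.unique(np.round(np.asarray(points, dtype=float), 12), axis=0)
    n, m = pts.shape
    out = []
    for i in range(n):
        others = np.delete(pts, i, axis=0)
        a_eq = np.vstack([others.T, np.ones(n - 1)])
        b_eq = np.append(pts[i], 1.0)
        res = linprog(np.zeros(n - 1), A_eq=a_eq, b_eq=b_eq, bounds=(0, 1),
                      method="highs")
        if not res.success:
            out.append(i)
    return out


def brute_feve(points: np.ndarray, weights: np.ndarray) -> float:
    """Functional evenness by explicit formula over a networkx MST."""
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    S = len(pts)
    g = nx.Graph()
    for i, j in itertools.combinations(range(S), 2):
        g.add_edge(i, j, weight=float(np.linalg.norm(pts[i] - pts[j])))
    mst = nx.minimum_spanning_tree(g)
    ew = [d["weight"] / (w[i] + w[j]) for i, j, d in mst.edges(data=True)]
    pew = np.array(ew) / np.sum(ew)
    thresh = 1.0 / (S - 1)
    return (sum(min(p, thresh) for p in pew) - thresh) / (1 - thresh)


def brute_fdiv(points: np.ndarray, weights: np.ndarray) -> float:
    """Functional divergence by the three explicit sums, LP vertex test."""
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    uniq = np.unique(np.round(pts, 12), axis=0)
    vert_pts = uniq[vertex_indices_lp(uniq)]
    on_vertex = np.array([
        any(np.allclose(p, v, atol=1e-12) for v in vert_pts) for p in np.round(pts, 12)])
    G = pts[on_vertex].mean(axis=0)
    dG = np.linalg.norm(pts - G, axis=1)
    mean_dG = dG.mean()
    delta = float(np.sum(w * (dG - mean_dG)))
    delta_abs = float(np.sum(w * np.abs(dG - mean_dG)))
    return (delta + mean_dG) / (delta_abs + mean_dG)


def brute_fdis(points: np.ndarray, weights: np.ndarray) -> float:
    """Weighted dispersion by the direct definition."""
    pts = np.asarray(points, dtype=float)
    a = np.asarray(weights, dtype=float)
    c = (a[:, None] * pts).sum(axis=0) / a.sum()
    return float(np.sum(a * np.linalg.norm(pts - c, axis=1)) / a.sum())


def brute_ca(x: np.ndarray):
    """Correspondence analysis via explicit eigen-decomposition of the
    residual cross-product (not SVD): eigenvalues and row coordinates."""
    x = np.asarray(x, dtype=float)
    x = x[:, x.sum(axis=0) > 0]
    P = x / x.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    resid = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    cross = resid.T @ resid
    eig, vec = np.linalg.eigh(cross)
    order = np.argsort(eig)[::-1]
    return eig[order], vec[:, order]


def brute_entities(values: np.ndarray) -> int:
    """O(n^2) pairwise row-equality grouping, counting distinct profiles."""
    n = len(values)
    labels = [-1] * n
    next_label = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = next_label
        for j in range(i + 1, n):
            if labels[j] < 0 and np.allclose(values[i], values[j], atol=1e-12):
                labels[j] = next_label
        next_label += 1
    return next_label


def mismatch_fraction(a_modalities, b_modalities) -> float:
    """Simple-matching mismatch fraction between two crisp profiles."""
    return sum(x != y for x, y in zip(a_modalities, b_modalities)) / len(a_modalities)
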