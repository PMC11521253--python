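"""Ordination of the trait space: PCoA and fuzzy correspondence analysis.

PCoA (classical metric scaling) embeds the mixed trait distance so the
convex-hull and centroid based diversity metrics can be computed in a real
coordinate space.  Fuzzy correspondence analysis (CA of the row-normalised
bin-fuzzy table) maps species and trait modalities into a shared space for
exploring which trait combinations structure the landings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .coding import CodedTraitMatrix
from .distance import DistanceMatrix, gower_center

__all__ = [
    "Ordination",
    "FCAResult",
    "pcoa",
    "retain_axes",
    "representation_quality",
    "fca",
    "modality_axis_correlation",
    "hull_vertices",
]

#: Relative tolerance below which an eigenvalue is treated as zero.
EIG_TOL = 1e-10


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Orient each axis so its largest-magnitude loading is positive."""
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


@dataclass
class Ordination:
    """Eigen-embedding of a distance matrix.

    ``eigenvalues`` is the full spectrum sorted descending (negatives are
    reported for non-Euclidean inputs but never carry coordinates);
    ``coordinates`` holds one column per positive axis, scaled so the
    column sum of squares equals the eigenvalue.
    """

    species: tuple[str, ...]
    eigenvalues: np.ndarray
    coordinates: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]

    def axes(self, m: int) -> np.ndarray:
        """First ``min(m, n_positive)`` coordinate columns."""
        return self.coordinates[:, : min(m, self.n_positive)]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.species), columns=cols)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Classical (Gower) principal coordinates analysis, all axes."""
    if d.n < 2:
        raise ValueError("need at least 2 species")
    b = gower_center(d.values)
    eig, vec = np.linalg.eigh(b)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    scale = max(np.abs(eig).max(), 1.0)
    eig = np.where(np.abs(eig) < EIG_TOL * scale, 0.0, eig)
    positive = eig > 0
    coords = vec[:, positive] * np.sqrt(eig[positive])
    return Ordination(d.species, eig, _fix_signs(coords))


def retain_axes(n_species: int) -> int:
    """Largest t with ``n_species >= 2**t`` (the "min" axis-retention rule)."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    return int(math.floor(math.log2(n_species)))


def representation_quality(eigenvalues: np.ndarray, m: int) -> float:
    """Fraction of total (absolute) inertia carried by the first m axes.

    Sum of the m largest positive eigenvalues over the sum of absolute
    values of all eigenvalues; equals 1 when the input distance is
    Euclidean and every positive axis is kept.  This is the ``quali.FRic``
    quality statistic reported alongside the hull-based metrics.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    eig = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    total = np.abs(eig).sum()
    if total == 0:
        return 1.0
    kept = np.clip(eig[:m], 0.0, None).sum()
    return float(kept / total)


# --- fuzzy correspondence analysis -----------------------------------------

@dataclass
class FCAResult:
    """Correspondence analysis of a row-normalised fuzzy trait table.

    ``eigenvalues`` are the per-axis inertias (squared singular values);
    ``inertia_contributions`` gives, per axis, each modality's fraction of
    that axis's inertia (columns sum to 1); ``modality_correlations`` holds
    the signed Pearson r (and r²) between each modality's affinity profile
    and the species scores of each axis.  ``dropped_modalities`` lists
    zero-mass columns excluded from the decomposition.
    """

    species: tuple[str, ...]
    modalities: tuple[tuple[str, str], ...]
    eigenvalues: np.ndarray
    species_coords: np.ndarray
    modality_coords: np.ndarray
    inertia_contributions: np.ndarray
    modality_correlations: pd.DataFrame
    vertex_species: dict[tuple[int, int], list[str]] = field(default_factory=dict)
    dropped_modalities: tuple[tuple[str, str], ...] = ()

    @property
    def total_inertia(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def n_axes(self) -> int:
        return self.species_coords.shape[1]


def fca(matrix: CodedTraitMatrix, n_axes: int = 4) -> FCAResult:
    """Fuzzy correspondence analysis of a bin-fuzzy coded trait table.

    The table X (rows sum to K, the number of trait blocks) is turned into a
    correspondence matrix P = X/(nK) with uniform row masses 1/n and column
    masses equal to column sums of P.  Standardised residuals are decomposed
    by SVD; eigenvalues are squared singular values; species and modalities
    get principal coordinates.  At least ``n_axes`` axes are retained when
    available.
    """
    if matrix.n_species < 3:
        raise ValueError("need at least 3 species")
    x = np.asarray(matrix.values, dtype=float)
    n, p = x.shape
    grand = x.sum()
    P = x / grand
    r = P.sum(axis=1)  # 1/n each by construction
    c = P.sum(axis=0)

    keep = c > 0
    dropped = tuple(col for col, k in zip(matrix.columns, keep) if not k)
    cols = tuple(col for col, k in zip(matrix.columns, keep) if k)
    Pk, ck = P[:, keep], c[keep]

    resid = (Pk - np.outer(r, ck)) / np.sqrt(np.outer(r, ck))
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    lam = s ** 2
    scale = max(lam.max(), 1.0) if lam.size else 1.0
    rank = int(np.sum(lam > EIG_TOL * scale))
    m = min(max(n_axes, 1), rank)

    if m == 0:
        empty = np.zeros((n, 0))
        corr = pd.DataFrame(columns=["trait", "modality", "axis", "r", "r2", "defined"])
        return FCAResult(matrix.species, cols, np.zeros(0), empty, np.zeros((len(cols), 0)),
                         np.zeros((len(cols), 0)), corr, {}, dropped)

    sk = s[:m]
    row_coords = (u[:, :m] / np.sqrt(r)[:, None]) * sk
    col_coords = (vt.T[:, :m] / np.sqrt(ck)[:, None]) * sk
    # common sign convention across rows/cols: largest species loading positive
    for k in range(m):
        j = np.argmax(np.abs(row_coords[:, k]))
        if row_coords[j, k] < 0:
            row_coords[:, k] = -row_coords[:, k]
            col_coords[:, k] = -col_coords[:, k]

    # modality j contributes c_j * g_jk^2 / lambda_k of axis k's inertia
    contrib = ck[:, None] * col_coords ** 2 / lam[:m][None, :]

    corr = modality_axis_correlation_table(row_coords, x[:, keep], cols)

    vertices: dict[tuple[int, int], list[str]] = {}
    for a, b in [(0, 1), (2, 3)]:
        if b < m:
            try:
                vertices[(a, b)] = hull_vertices(row_coords[:, [a, b]], matrix.species)
            except ValueError:
                pass

    return FCAResult(matrix.species, cols, lam[:rank], row_coords, col_coords,
                     contrib, corr, vertices, dropped)


def modality_axis_correlation_table(coords: np.ndarray, affinities: np.ndarray,
                                    columns) -> pd.DataFrame:
    """Pearson r between every modality column and every axis score vector."""
    rows = []
    for k in range(coords.shape[1]):
        axis = coords[:, k]
        axis_sd = axis.std()
        for j, (trait, modality) in enumerate(columns):
            col = affinities[:, j]
            if col.std() == 0 or axis_sd == 0:
                rows.append((trait, modality, k + 1, np.nan, np.nan, False))
            else:
                rr = float(np.corrcoef(col, axis)[0, 1])
                rows.append((trait, modality, k + 1, rr, rr ** 2, True))
    return pd.DataFrame(rows, columns=["trait", "modality", "axis", "r", "r2", "defined"])


def modality_axis_correlation(result: FCAResult, matrix: CodedTraitMatrix,
                              axis: int) -> pd.DataFrame:
    """Per-modality Pearson r (and r²) against one retained FCA axis (1-based)."""
    if not 1 <= axis <= result.n_axes:
        raise ValueError(f"axis {axis} not retained (have {result.n_axes})")
    sub = result.modality_correlations
    return sub[sub["axis"] == axis].reset_index(drop=True)


def hull_vertices(coords: np.ndarray, species) -> list[str]:
    """Species on the convex hull of a 2-D ordination scatter, in hull order.

    Degenerate (collinear) scatters return the two extreme species; fewer
    than 3 species is an error.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("expected a species × 2 coordinate matrix")
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 species")
    species = list(species)
    try:
        hull = ConvexHull(coords)
        return [species[i] for i in hull.vertices]
    except QhullError:
        # collinear: endpoints of the largest pairwise separation
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(coords))
        i, j = np.unravel_index(np.argmax(d), d.shape)
        if d[i, j] == 0:
            return [species[0]]
        return [species[min(i, j)], species[max(i, j)]]
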