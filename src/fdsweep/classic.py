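"""Distance-based functional diversity metrics.

FRich (convex-hull volume), FEve (minimum-spanning-tree partial weighted
evenness), FDis (abundance-weighted distance to the weighted centroid),
FDiv (abundance-weighted divergence from the mean distance to the
vertex centroid) and Rao's quadratic entropy.

Conventions shared by all five:

* relative abundances sum to one over the species present in a plot;
* a metric that is undefined for a community (too few species, degenerate
  geometry) returns NaN and logs why — never zero, which would bias any
  downstream regression on metric values;
* FEve and Rao's Q work on the distance matrix directly; FDis and FDiv need
  a centroid and therefore coordinates, so in distance-only use they run on
  the full set of positive PCoA axes, which preserves all pairwise distances
  for Euclidean-embeddable inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .dissimilarity import DistanceMatrix, OrdinationResult, pcoa

logger = logging.getLogger(__name__)

#: Above this dimensionality the FDiv vertex hull is not attempted (Qhull
#: cost grows ~ n^(d/2)); the centroid falls back to the all-species mean.
_MAX_HULL_DIMS = 8


@dataclass
class SpanningTree:
    """Minimum spanning tree over species in trait space."""

    species: list[str]
    branches: list[tuple[int, int, float]]  # (i, j, length), i < j

    @property
    def total_length(self) -> float:
        return float(sum(b[2] for b in self.branches))


@dataclass
class CentroidGeometry:
    """Centroid construction shared by FDis/FDiv.

    ``z`` is the per-species distance to the centroid, ``dG_bar`` the
    unweighted mean of ``z``, ``delta_d`` / ``delta_abs_d`` the
    abundance-weighted (absolute) deviation sums around ``dG_bar``.
    """

    centroid: np.ndarray
    z: np.ndarray
    dG_bar: float
    delta_d: float
    delta_abs_d: float


def _check_abund(abund: np.ndarray, n: int) -> np.ndarray:
    a = np.asarray(abund, dtype=float)
    if a.shape != (n,):
        raise ValueError(f"expected {n} abundances, got shape {a.shape}")
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError("relative abundances must sum to 1")
    return a


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[rj] = ri
        return True


def minimum_spanning_tree(d: DistanceMatrix) -> SpanningTree:
    """Kruskal's MST with ties broken by (length, i, j) lexicographic order.

    The deterministic tie-break makes FEve reproducible when several
    spanning trees share the minimal total length.
    """
    n = d.n
    edges = sorted(
        (d.values[i, j], i, j) for i in range(n) for j in range(i + 1, n)
    )
    uf = _UnionFind(n)
    branches = []
    for length, i, j in edges:
        if uf.union(i, j):
            branches.append((i, j, float(length)))
            if len(branches) == n - 1:
                break
    return SpanningTree(species=list(d.species), branches=branches)


def functional_richness(
    coords: OrdinationResult | np.ndarray,
    present: list[str] | None = None,
    dims: int = 2,
) -> float:
    """Convex-hull volume of the present species on the first ``dims`` axes.

    With ``dims=2`` this is the hull area. Needs at least ``dims + 1``
    affinely independent points; degenerate configurations (collinear points,
    too few species) are undefined and return NaN.
    """
    if dims < 2:
        raise ValueError("functional richness needs dims >= 2")
    if isinstance(coords, OrdinationResult):
        x = coords.coords_for(present) if present is not None else coords.coordinates
    else:
        x = np.asarray(coords, dtype=float)
    if x.shape[1] < dims:
        logger.warning(
            "only %d ordination axes available for dims=%d; undefined",
            x.shape[1], dims,
        )
        return float("nan")
    x = x[:, :dims]
    if x.shape[0] < dims + 1:
        logger.warning("only %d species for dims=%d hull; undefined", x.shape[0], dims)
        return float("nan")
    try:
        hull = ConvexHull(x)
    except QhullError:
        logger.warning("degenerate point configuration; hull undefined")
        return float("nan")
    return float(hull.volume)


def functional_evenness(tree: SpanningTree, abund: np.ndarray) -> float:
    """FEve from MST branch lengths and relative abundances.

    Each branch l joining species i and j gets a weighted evenness
    ``EW_l = dist(i, j) / (w_i + w_j)``, normalised over branches to partial
    weighted evenness ``PEW_l``; then

        FEve = [sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)] / [1 - 1/(S-1)].

    Perfectly regular spacing and abundance gives 1. Undefined for S < 3
    (the denominator vanishes) or when every branch has zero length.
    """
    s = len(tree.species)
    a = _check_abund(abund, s)
    if s < 3:
        logger.warning("FEve undefined for S=%d < 3", s)
        return float("nan")
    ew = np.array([length / (a[i] + a[j]) for i, j, length in tree.branches])
    if ew.sum() == 0:
        logger.warning("all MST branches zero length; FEve undefined")
        return float("nan")
    pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def _as_coords(x: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(x, DistanceMatrix):
        return pcoa(x).coordinates
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def functional_dispersion(
    x: DistanceMatrix | np.ndarray, abund: np.ndarray
) -> float:
    """FDis: abundance-weighted mean distance to the weighted centroid.

    ``x`` is either a coordinate matrix (species x axes) or a
    DistanceMatrix, in which case coordinates come from PCoA on all positive
    axes. A single species has dispersion 0.
    """
    coords = _as_coords(x)
    a = _check_abund(abund, coords.shape[0])
    if coords.shape[0] == 1 or coords.size == 0:
        return 0.0
    centroid = a @ coords
    z = np.linalg.norm(coords - centroid, axis=1)
    return float(a @ z)


def centroid_geometry(
    coords: np.ndarray, abund: np.ndarray, vertex_centroid: bool = True
) -> CentroidGeometry:
    """Geometry underlying FDiv.

    The centroid is the unweighted mean of the convex-hull vertex species
    when a hull is constructible (the standard construction); otherwise the
    unweighted mean of all species.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n, d = coords.shape
    a = _check_abund(abund, n)
    verts = None
    if vertex_centroid:
        if d == 1:
            verts = [int(np.argmin(coords[:, 0])), int(np.argmax(coords[:, 0]))]
        elif n <= d + 1:
            # at most d+1 points in d dimensions: every point is a vertex
            verts = list(range(n))
        elif d <= _MAX_HULL_DIMS:
            try:
                verts = ConvexHull(coords).vertices.tolist()
            except QhullError:
                verts = None
        # d > _MAX_HULL_DIMS: Qhull cost grows ~ n^(d/2) and in such
        # near-full-rank PCoA spaces essentially all points are vertices;
        # fall through to the all-species mean
    centroid = coords[verts].mean(axis=0) if verts else coords.mean(axis=0)
    z = np.linalg.norm(coords - centroid, axis=1)
    dg = float(z.mean())
    dev = z - dg
    return CentroidGeometry(
        centroid=centroid,
        z=z,
        dG_bar=dg,
        delta_d=float(a @ dev),
        delta_abs_d=float(a @ np.abs(dev)),
    )


def functional_divergence(
    x: CentroidGeometry | DistanceMatrix | np.ndarray, abund: np.ndarray
) -> float:
    """FDiv = (delta_d + dG_bar) / (delta_abs_d + dG_bar), in [0, 1].

    High values mean abundance concentrates on species far from the centroid
    of the occupied trait space. Undefined when all species coincide
    (denominator zero) or with fewer than 3 species.
    """
    if isinstance(x, CentroidGeometry):
        geom = x
        n = len(geom.z)
    else:
        coords = _as_coords(x)
        n = coords.shape[0]
        if n < 3:
            logger.warning("FDiv undefined for S=%d < 3", n)
            return float("nan")
        geom = centroid_geometry(coords, abund)
    denom = geom.delta_abs_d + geom.dG_bar
    if denom == 0:
        logger.warning("all species coincident; FDiv undefined")
        return float("nan")
    return float((geom.delta_d + geom.dG_bar) / denom)


def raos_q(d: DistanceMatrix, abund: np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_{i<j} d_ij p_i p_j.

    The expected trait distance between two individuals drawn at random
    (without self-pairing correction) from the community.
    """
    a = _check_abund(abund, d.n)
    return float(0.5 * a @ d.values @ a)
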