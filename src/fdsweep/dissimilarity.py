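"""Species dissimilarities (Gower, Euclidean) and principal coordinates.

Gower handles mixed continuous/categorical traits by averaging
range-normalised differences and 0/1 mismatches; Euclidean is reserved for
all-continuous subsets, by default on z-scored columns because traits carry
incommensurate units. PCoA eigendecomposes the double-centred Gram matrix of
a distance matrix; negative eigenvalues (possible for Gower matrices that are
not Euclidean-embeddable) are dropped with the discarded inertia reported, not
corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import CATEGORICAL, CONTINUOUS, TraitTable

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise species dissimilarity with a fixed species order."""

    species: list[str]
    values: np.ndarray
    kind: str = "unknown"  # "gower" | "euclidean" | ...

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.species):
            raise ValueError("distance matrix shape does not match species list")
        if not np.allclose(d, d.T, atol=_SYM_TOL):
            raise ValueError("distance matrix is not symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix diagonal must be exactly zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = d

    @property
    def n(self) -> int:
        return len(self.species)

    def submatrix(self, species: Sequence[str]) -> "DistanceMatrix":
        idx = [self.species.index(s) for s in species]
        return DistanceMatrix(list(species), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species")

    @classmethod
    def from_csv(cls, path, kind: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        d = df.to_numpy(dtype=float)
        d = 0.5 * (d + d.T)  # wash out round-trip asymmetry
        np.fill_diagonal(d, 0.0)
        return cls([str(s) for s in df.index], d, kind)


@dataclass
class OrdinationResult:
    """PCoA coordinates on the retained positive axes.

    ``eigenvalues`` holds the full descending spectrum;
    ``negative_inertia`` the total magnitude of dropped negative eigenvalues,
    so the distortion of a non-Euclidean input can be judged.
    """

    species: list[str]
    coordinates: np.ndarray  # species x axes_retained
    eigenvalues: np.ndarray  # full spectrum, descending
    axes_retained: int
    negative_inertia: float = 0.0

    def coords_for(self, species: Sequence[str]) -> np.ndarray:
        idx = [self.species.index(s) for s in species]
        return self.coordinates[idx]


def gower_distance(traits: TraitTable, subset: Sequence[str]) -> DistanceMatrix:
    """Gower dissimilarity on species-mean traits restricted to ``subset``.

    Per-trait contribution is ``|x_i - x_j| / range`` for continuous traits
    (range taken over all species in the table, so distances are comparable
    across plots) and 0/1 match/mismatch for categorical traits; the distance
    is the unweighted mean over the subset. All species must be complete on
    the subset — coverage filtering happens upstream.
    """
    subset = list(subset)
    wide = traits.to_wide(subset)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"species with missing traits in subset: {bad}")
    kinds = traits.kinds()
    n = len(wide)
    total = np.zeros((n, n))
    for t in subset:
        col = wide[t].to_numpy()
        if kinds[t] == CONTINUOUS:
            col = col.astype(float)
            rng = np.ptp(col)
            if rng == 0:
                logger.warning("trait %r has zero range; contributes 0 to Gower", t)
                contrib = np.zeros((n, n))
            else:
                contrib = np.abs(col[:, None] - col[None, :]) / rng
        else:
            contrib = (col[:, None] != col[None, :]).astype(float)
        total += contrib
    d = total / len(subset)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(wide.index), 0.5 * (d + d.T), kind="gower")


def euclidean_distance(
    traits: TraitTable, subset: Sequence[str], standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distance on continuous species-mean traits.

    ``standardize`` z-scores each column (sample SD) first; raw columns mix
    units like cm and %N, so this is the default.
    """
    subset = list(subset)
    kinds = traits.kinds()
    cat = [t for t in subset if kinds.get(t) == CATEGORICAL]
    if cat:
        raise ValueError(
            f"categorical traits {cat} in Euclidean subset; use gower_distance"
        )
    wide = traits.to_wide(subset)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"species with missing traits in subset: {bad}")
    x = wide.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1) if len(x) > 1 else np.ones(x.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - x.mean(axis=0)) / sd
    if len(x) == 1:
        d = np.zeros((1, 1))
    else:
        d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(list(wide.index), d, kind="euclidean")


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposes ``B = -0.5 * J D^2 J`` (J the centring matrix); axes are
    eigenvectors scaled by sqrt(eigenvalue), descending. Axes with eigenvalue
    at or below numerical zero are dropped before truncation to ``n_axes``;
    if fewer positive axes exist than requested, the available ones are
    returned with a warning. For a Euclidean-embeddable input the pairwise
    distances of the full positive-axis coordinates reproduce ``d``.
    """
    n = d.n
    dd = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ dd @ j
    b = 0.5 * (b + b.T)
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    neg_inertia = float(-eigval[eigval < -tol].sum())
    if neg_inertia > 0:
        logger.warning(
            "dropping %.3g of negative inertia (non-Euclidean distances)",
            neg_inertia,
        )
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    if n_axes is not None:
        if n_axes < 1:
            raise ValueError("n_axes must be >= 1")
        if n_axes > coords.shape[1]:
            logger.warning(
                "requested %d axes but only %d positive; returning %d",
                n_axes, coords.shape[1], coords.shape[1],
            )
        coords = coords[:, : min(n_axes, coords.shape[1])]
    return OrdinationResult(
        species=list(d.species),
        coordinates=coords,
        eigenvalues=eigval,
        axes_retained=coords.shape[1],
        negative_inertia=neg_inertia,
    )
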