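"""Synthetic grassland communities and trait tables.

Stands in for plot-level cover data and locally measured traits from three
US grassland sites: a planted 16-species tallgrass prairie experiment
sampled in 48 plots with 10 continuous traits; a species-rich tallgrass
watershed sampled along 4 transects with 12 traits of which two are
categorical (photosynthetic pathway, growth form); and a desert grassland
with strong single-species dominance, 60 quadrats and 10 traits including
one categorical.

Continuous traits come from a Gaussian copula with a target correlation
matrix — including a "leaf-economics-like" block of strongly correlated
traits — and are pushed through monotone marginal transforms (lognormal for
sizes, logit-normal for fractions, affine for the rest) so values live on
realistic scales while pairwise correlations stay close to their targets.
Abundances follow a lognormal or geometric rank-abundance model, plots draw
random species subsets weighted by regional abundance, and missing trait
values fall preferentially on rare species, as they do in real trait
campaigns. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CATEGORICAL, CONTINUOUS, CommunityMatrix, TraitTable

logger = logging.getLogger(__name__)


@dataclass
class SyntheticStudySpec:
    """Generator parameters for one study-like dataset.

    abundance_model is ("lognormal", mu, sigma) — species base abundances
    exp(N(mu, sigma)) — or ("geometric", ratio) with base abundance
    ratio**rank. ``categorical_levels`` gives the number of levels of each
    categorical trait. ``missingness`` is the average probability that a
    (species, trait) value is unmeasured; it is tilted toward rare species.
    """

    study_id: str
    n_species: int
    n_plots: int
    n_traits_continuous: int
    categorical_levels: tuple[int, ...] = ()
    correlation: np.ndarray | None = None
    abundance_model: tuple = ("lognormal", 0.0, 1.0)
    richness_range: tuple[int, int] = (5, 10)
    missingness: float = 0.0
    replicates: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2 or self.n_plots < 1 or self.n_traits_continuous < 1:
            raise ValueError("species, plots and continuous traits must be positive")
        lo, hi = self.richness_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid richness range")
        if hi > self.n_species:
            raise ValueError(
                f"richness {hi} exceeds species pool {self.n_species}"
            )
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be a probability")
        if self.correlation is None:
            self.correlation = np.eye(self.n_traits_continuous)
        c = np.asarray(self.correlation, dtype=float)
        p = self.n_traits_continuous
        if c.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
        if not np.allclose(c, c.T, atol=1e-10) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        eigmin = float(np.linalg.eigvalsh(c).min())
        if eigmin < -1e-10:
            ev, vec = np.linalg.eigh(c)
            near = vec @ np.diag(np.clip(ev, 0, None)) @ vec.T
            dd = np.sqrt(np.diag(near))
            near = near / np.outer(dd, dd)
            raise ValueError(
                "correlation target is not positive semidefinite "
                f"(min eigenvalue {eigmin:.3g}); nearest PSD candidate:\n{near}"
            )
        self.correlation = c

    @property
    def trait_names(self) -> list[str]:
        cont = [f"t{i+1:02d}" for i in range(self.n_traits_continuous)]
        cat = [f"c{i+1}" for i in range(len(self.categorical_levels))]
        return cont + cat

    def species_names(self) -> list[str]:
        return [f"{self.study_id}_sp{i+1:03d}" for i in range(self.n_species)]


def _base_abundances(spec: SyntheticStudySpec, rng: np.random.Generator) -> np.ndarray:
    """Regional rank-abundance profile, descending, summing to one."""
    model = spec.abundance_model
    if model[0] == "lognormal":
        _, mu, sigma = model
        raw = np.sort(np.exp(rng.normal(mu, sigma, spec.n_species)))[::-1]
    elif model[0] == "geometric":
        ratio = float(model[1])
        if not 0 < ratio <= 1:
            raise ValueError("geometric ratio must be in (0, 1]")
        raw = ratio ** np.arange(spec.n_species)
    else:
        raise ValueError(f"unknown abundance model {model[0]!r}")
    return raw / raw.sum()


def _marginal_transform(z: np.ndarray, trait_index: int) -> np.ndarray:
    """Monotone map from a standard-normal margin to a realistic trait scale.

    Cycles through three families: lognormal (sizes, masses; sigma kept at
    0.3 so Pearson correlations survive the curvature), logit-normal
    (fractions such as dry-matter content), and affine (contents, isotope
    ratios). Monotonicity preserves the copula's rank structure.
    """
    family = trait_index % 3
    if family == 0:
        return np.exp(2.0 + 0.3 * z)
    if family == 1:
        return 1.0 / (1.0 + np.exp(-0.8 * z))
    return 20.0 + 5.0 * z


def generate_traits(spec: SyntheticStudySpec) -> TraitTable:
    """Raw trait measurements (with replicates and missingness) for a spec.

    Species-level true values come from the Gaussian copula; each measured
    (species, trait) gets 1..r replicate measurements with 2% measurement
    noise so downstream averaging has work to do. Missingness hits rare
    species hardest: the per-species missing probability ramps linearly from
    0 for the most abundant to twice the nominal rate for the rarest.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_species, spec.n_traits_continuous
    chol = np.linalg.cholesky(spec.correlation + 1e-12 * np.eye(p))
    z = rng.standard_normal((n, p)) @ chol.T
    values = np.column_stack(
        [_marginal_transform(z[:, j], j) for j in range(p)]
    )

    base = _base_abundances(spec, np.random.default_rng(spec.seed + 1))
    # species index == regional abundance rank (0 = dominant)
    rank_frac = (
        np.arange(n) / (n - 1) if n > 1 else np.zeros(n)
    )
    p_miss = np.clip(2.0 * spec.missingness * rank_frac, 0, 0.95)

    species = spec.species_names()
    cont_names = [f"t{j+1:02d}" for j in range(p)]
    rows = []
    lo_rep, hi_rep = spec.replicates
    for i, sp in enumerate(species):
        for j, trait in enumerate(cont_names):
            if rng.random() < p_miss[i]:
                continue
            n_rep = int(rng.integers(lo_rep, hi_rep + 1))
            scale = abs(values[i, j]) * 0.02 + 1e-9
            for _ in range(n_rep):
                rows.append({
                    "species": sp, "trait": trait,
                    "value": values[i, j] + rng.normal(0, scale),
                    "kind": CONTINUOUS,
                })
        for ci, n_levels in enumerate(spec.categorical_levels):
            if rng.random() < p_miss[i]:
                continue
            level = int(rng.integers(n_levels))
            rows.append({
                "species": sp, "trait": f"c{ci+1}",
                "value": f"L{level}", "kind": CATEGORICAL,
            })
    return TraitTable(pd.DataFrame(rows, columns=list(TraitTable.REQUIRED)))


def generate_communities(spec: SyntheticStudySpec) -> CommunityMatrix:
    """Plot-by-species relative abundances for a spec.

    Each plot samples its richness uniformly from ``richness_range``, draws
    that many species weighted by the regional profile, and assigns local
    abundances from the abundance model in regional-rank order (dominant
    species stay dominant) before normalising to relative abundance.
    """
    rng = np.random.default_rng(spec.seed + 1)
    base = _base_abundances(spec, np.random.default_rng(spec.seed + 1))
    species = np.array(spec.species_names())
    lo, hi = spec.richness_range
    model = spec.abundance_model
    rows = []
    for pi in range(spec.n_plots):
        plot = f"p{pi+1:03d}"
        r = int(rng.integers(lo, hi + 1))
        present = np.sort(rng.choice(spec.n_species, size=r, replace=False, p=base))
        if model[0] == "geometric":
            local = model[1] ** np.arange(r)
        else:
            _, mu, sigma = model
            local = np.sort(np.exp(rng.normal(mu, sigma, r)))[::-1]
        local = local / local.sum()
        for sp_idx, ab in zip(present, local):
            rows.append({
                "plot": plot, "study": spec.study_id,
                "species": species[sp_idx], "abundance": float(ab),
            })
    return CommunityMatrix(pd.DataFrame(rows))


def leaf_economics_correlation(
    n_traits: int, block: Sequence[int] = (0, 1, 2, 3), rho: float = 0.7,
    background: float = 0.1,
) -> np.ndarray:
    """A correlation target with one strongly correlated trait block.

    The block mimics the leaf economics spectrum (e.g. SLA, leaf %N,
    photosynthetic rate moving together); remaining traits share a weak
    background correlation.
    """
    c = np.full((n_traits, n_traits), background)
    for i in block:
        for j in block:
            if i != j:
                c[i, j] = rho
    np.fill_diagonal(c, 1.0)
    eigmin = np.linalg.eigvalsh(c).min()
    if eigmin < 1e-8:  # ridge the background if the block made it indefinite
        c = 0.95 * c + 0.05 * np.eye(n_traits)
        np.fill_diagonal(c, 1.0)
    return c


def benchmark_specs(seed: int = 1) -> list[SyntheticStudySpec]:
    """The three study-shaped generator specs used by the benchmark suite."""
    s = int(seed) % (2**31 - 3)
    return [
        # planted 16-species experiment: 48 plots, 10 continuous traits
        SyntheticStudySpec(
            study_id="biocon",
            n_species=16,
            n_plots=48,
            n_traits_continuous=10,
            correlation=leaf_economics_correlation(10),
            abundance_model=("lognormal", 0.0, 1.0),
            richness_range=(8, 16),
            missingness=0.05,
            seed=s,
        ),
        # species-rich watershed transects: 12 traits, 2 categorical
        SyntheticStudySpec(
            study_id="konza",
            n_species=60,
            n_plots=4,
            n_traits_continuous=10,
            categorical_levels=(2, 3),
            correlation=leaf_economics_correlation(10),
            abundance_model=("lognormal", 0.0, 1.2),
            richness_range=(25, 45),
            missingness=0.15,
            seed=s + 1,
        ),
        # desert grassland quadrats: strong dominance, 1 categorical trait
        SyntheticStudySpec(
            study_id="sevilleta",
            n_species=40,
            n_plots=60,
            n_traits_continuous=9,
            categorical_levels=(2,),
            correlation=leaf_economics_correlation(9),
            abundance_model=("geometric", 0.5),
            richness_range=(3, 10),
            missingness=0.2,
            seed=s + 2,
        ),
    ]


def make_benchmark_suite(
    seed: int = 1,
) -> dict[str, tuple[TraitTable, CommunityMatrix]]:
    """Three study-like (traits, communities) datasets for end-to-end runs."""
    out = {}
    for spec in benchmark_specs(seed):
        out[spec.study_id] = (generate_traits(spec), generate_communities(spec))
    return out
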