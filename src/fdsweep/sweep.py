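"""Trait-subset enumeration and the exhaustive metric sweep.

The sweep crosses every trait subset (all combinations of 2..n traits) with
every plot and computes the eight metrics — FRich, FEve, FDis, FDiv, Rao's Q
on Gower and (for all-continuous subsets) Euclidean distances, and the three
KDE metrics on the z-scored continuous traits of the subset. Output is a
long table, one row per (study, plot, metric, distance, subset, dims), with
undefined values recorded as missing — never silently dropped or zeroed.

For the trait-correlation analysis, 4-trait all-continuous subsets get a
summary of the minimum / maximum / mean absolute pairwise Pearson
correlation among their traits.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classic, kde
from .community import (
    CATEGORICAL,
    CONTINUOUS,
    CommunityMatrix,
    DEFAULT_MIN_ABUNDANCE_RETAINED,
    TraitTable,
    filter_trait_coverage,
)
from .dissimilarity import euclidean_distance, gower_distance, pcoa

logger = logging.getLogger(__name__)

CLASSIC_METRICS = ("FRich", "FEve", "FDis", "FDiv", "RaoQ")
KDE_METRICS = ("KDErich", "KDEeven", "KDEdisp")
ALL_METRICS = CLASSIC_METRICS + KDE_METRICS

SWEEP_COLUMNS = ["study", "plot", "metric", "distance", "subset", "k", "dims", "value"]


def enumerate_subsets(
    trait_ids: Sequence[str], k_min: int = 2, k_max: int | None = None
) -> list[tuple[str, ...]]:
    """All C(n, k) unordered trait subsets for k_min <= k <= k_max.

    Subsets are sorted internally and emitted in deterministic lexicographic
    order within each size. For 10 traits and k_min=2 this yields the full
    design: 45 pairs, 120 triples, 210 quadruples, ... 1 ten-trait set.
    """
    ids = sorted(trait_ids)
    n = len(ids)
    if k_max is None:
        k_max = n
    if not 2 <= k_min <= k_max:
        raise ValueError(f"need 2 <= k_min <= k_max, got {k_min}..{k_max}")
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds trait count {n}")
    return [tuple(c) for k in range(k_min, k_max + 1) for c in combinations(ids, k)]


def subset_label(subset: Sequence[str]) -> str:
    return ";".join(sorted(subset))


@dataclass
class SweepConfig:
    """Everything that pins down a sweep run.

    distances        distance types for the classic metrics
    frich_dims       dimension counts for the FRich sensitivity analysis;
                     "max" resolves to subset size (all-continuous) or
                     subset size - 1 (with categorical traits)
    kde_mass         boundary probability mass of hypervolumes
    kde_samples      Monte-Carlo sample size per hypervolume
    min_retained     abundance-representation cut for plot inclusion
    standardize_euclidean   z-score traits before Euclidean distances
    max_subsets_per_k       deterministic per-size subsampling of the design
                            (None = exhaustive)
    seed             master seed; per-cell KDE seeds are derived from it
    """

    distances: tuple[str, ...] = ("gower", "euclidean")
    frich_dims: tuple = (2,)
    kde_enabled: bool = True
    kde_mass: float = 0.95
    kde_samples: int = 10_000
    min_retained: float = DEFAULT_MIN_ABUNDANCE_RETAINED
    standardize_euclidean: bool = True
    max_subsets_per_k: int | None = None
    seed: int = 1

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("distances", "frich_dims"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _cell_seed(master: int, subset: Sequence[str], study: str, plot: str) -> int:
    tag = f"{master}|{subset_label(subset)}|{study}|{plot}"
    return zlib.crc32(tag.encode()) % (2**31)


def _resolve_max_dims(subset: Sequence[str], kinds: dict[str, str]) -> int:
    k = len(subset)
    has_cat = any(kinds[t] == CATEGORICAL for t in subset)
    return k - 1 if has_cat else k


def _resolved_frich_dims(subset, kinds, config) -> list[int]:
    """Resolve "max" and drop duplicates ("max" can collide with 2/3/4)."""
    resolved = [
        _resolve_max_dims(subset, kinds) if d == "max" else int(d)
        for d in config.frich_dims
    ]
    return list(dict.fromkeys(resolved))


def sample_subsets(
    subsets: Iterable[tuple[str, ...]], max_per_k: int, seed: int
) -> list[tuple[str, ...]]:
    """Deterministically subsample a design to at most max_per_k subsets per size."""
    by_k: dict[int, list] = {}
    for s in subsets:
        by_k.setdefault(len(s), []).append(s)
    rng = np.random.default_rng(seed)
    out = []
    for k in sorted(by_k):
        group = by_k[k]
        if len(group) > max_per_k:
            idx = rng.choice(len(group), size=max_per_k, replace=False)
            group = [group[i] for i in sorted(idx)]
        out.extend(group)
    return out


def run_sweep(
    comm: CommunityMatrix,
    traits: TraitTable,
    subsets: Sequence[tuple[str, ...]],
    config: SweepConfig = SweepConfig(),
    resume_from: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute every metric for every (subset, plot) cell.

    ``traits`` must already be species-mean values (one row per species and
    trait). Per subset: coverage filtering and renormalisation, then the
    distance matrices, a PCoA per distance, and the per-plot metrics. Cells
    that fail (degenerate geometry, too few species) are recorded with a
    missing value and the sweep continues. Passing a previous result as
    ``resume_from`` skips subsets already present, making interrupted runs
    resumable; with an identical config the concatenation equals a fresh run.
    """
    kinds = traits.kinds()
    done_labels = (
        set(resume_from["subset"].unique()) if resume_from is not None else set()
    )
    records: list[dict] = []

    for subset in subsets:
        subset = tuple(sorted(subset))
        label = subset_label(subset)
        if label in done_labels:
            continue
        try:
            records.extend(_sweep_one_subset(comm, traits, subset, kinds, config))
        except Exception:
            logger.exception("subset %s failed entirely; recording missing", label)
            for study, plot in comm.plots:
                records.extend(
                    _missing_records(study, plot, subset, kinds, config)
                )

    out = pd.DataFrame(records, columns=SWEEP_COLUMNS)
    if resume_from is not None:
        out = pd.concat([resume_from, out], ignore_index=True)
    return out


def _missing_records(study, plot, subset, kinds, config) -> list[dict]:
    base = {
        "study": study, "plot": plot, "subset": subset_label(subset),
        "k": len(subset), "value": np.nan,
    }
    recs = []
    has_cat = any(kinds[t] == CATEGORICAL for t in subset)
    dists = [d for d in config.distances if d == "gower" or not has_cat]
    for dist in dists:
        for m in CLASSIC_METRICS:
            if m == "FRich":
                for dd in _resolved_frich_dims(subset, kinds, config):
                    recs.append({**base, "metric": m, "distance": dist, "dims": dd})
            else:
                recs.append({**base, "metric": m, "distance": dist, "dims": np.nan})
    if config.kde_enabled:
        for m in KDE_METRICS:
            recs.append({**base, "metric": m, "distance": "traits", "dims": np.nan})
    return recs


def _sweep_one_subset(comm, traits, subset, kinds, config) -> list[dict]:
    label = subset_label(subset)
    k = len(subset)
    has_cat = any(kinds[t] == CATEGORICAL for t in subset)
    filtered, report = filter_trait_coverage(
        comm, traits, subset, min_retained=config.min_retained
    )
    records: list[dict] = []

    # flagged/excluded plots: everything missing for this subset
    for study, plot in report.plots_flagged:
        records.extend(_missing_records(study, plot, subset, kinds, config))
    if not len(filtered.data):
        return records

    pool = filtered.species
    # distances on the coverage-filtered table: Gower ranges and z-scores are
    # global over all complete species, so plots share a common trait space
    complete = traits.complete_species(subset)
    ctraits = TraitTable(traits.data[traits.data["species"].isin(complete)])
    dist_types = [d for d in config.distances if d == "gower" or not has_cat]
    matrices = {}
    for dist in dist_types:
        if dist == "gower":
            matrices[dist] = gower_distance(ctraits, subset).submatrix(pool)
        else:
            matrices[dist] = euclidean_distance(
                ctraits, subset, standardize=config.standardize_euclidean
            ).submatrix(pool)
    ordinations = {dist: pcoa(m) for dist, m in matrices.items()}

    cont = [t for t in subset if kinds[t] == CONTINUOUS]
    kde_coords = None
    if config.kde_enabled and cont:
        wide = traits.to_wide(cont).loc[pool].astype(float)
        x = wide.to_numpy()
        sd = x.std(axis=0, ddof=1) if len(x) > 1 else np.ones(x.shape[1])
        keep_dims = sd > 0
        if keep_dims.any():
            xz = (x[:, keep_dims] - x[:, keep_dims].mean(axis=0)) / sd[keep_dims]
            kde_coords = pd.DataFrame(xz, index=wide.index)
        if not keep_dims.all():
            logger.warning(
                "subset %s: dropping zero-variance traits from KDE space", label
            )

    for study, plot in filtered.plots:
        ab = filtered.plot_abundances(study, plot)
        present = list(ab.index)
        a = ab.to_numpy()
        base = {"study": study, "plot": plot, "subset": label, "k": k}

        for dist in dist_types:
            dsub = matrices[dist].submatrix(present)
            coords = ordinations[dist].coords_for(present)
            row = {**base, "distance": dist}
            for dd in _resolved_frich_dims(subset, kinds, config):
                val = _safe(classic.functional_richness, coords, None, dd)
                records.append({**row, "metric": "FRich", "dims": dd, "value": val})
            tree = classic.minimum_spanning_tree(dsub)
            records.append({
                **row, "metric": "FEve", "dims": np.nan,
                "value": _safe(classic.functional_evenness, tree, a),
            })
            records.append({
                **row, "metric": "FDis", "dims": np.nan,
                "value": _safe(classic.functional_dispersion, coords, a),
            })
            records.append({
                **row, "metric": "FDiv", "dims": np.nan,
                "value": _safe(classic.functional_divergence, coords, a),
            })
            records.append({
                **row, "metric": "RaoQ", "dims": np.nan,
                "value": _safe(classic.raos_q, dsub, a),
            })

        if config.kde_enabled:
            vals = dict.fromkeys(KDE_METRICS, np.nan)
            if kde_coords is not None and len(present) >= 2:
                pts = kde_coords.loc[present].to_numpy()
                cfg = kde.HypervolumeConfig(
                    mass=config.kde_mass,
                    n_samples=config.kde_samples,
                    seed=_cell_seed(config.seed, subset, study, plot),
                )
                try:
                    hv_u = kde.build_hypervolume(pts, None, cfg)
                    hv_w = kde.build_hypervolume(pts, a, cfg)
                    vals["KDErich"] = kde.kde_richness(hv_u)
                    vals["KDEeven"] = kde.kde_evenness(hv_w, hv_u)
                    vals["KDEdisp"] = kde.kde_dispersion(hv_w)
                except Exception as exc:
                    logger.warning(
                        "KDE failed for %s/%s subset %s: %s", study, plot, label, exc
                    )
            for m in KDE_METRICS:
                records.append({
                    **base, "metric": m, "distance": "traits",
                    "dims": np.nan, "value": vals[m],
                })
    return records


def _safe(fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        logger.warning("%s failed: %s", fn.__name__, exc)
        return np.nan


@dataclass
class CorrelationSummary:
    """Min/max/mean absolute pairwise Pearson correlation of a 4-trait subset."""

    subset: tuple[str, ...]
    min_corr: float
    max_corr: float
    mean_corr: float


def correlation_summary(
    traits: TraitTable, subset: Sequence[str], absolute: bool = True
) -> CorrelationSummary:
    """Pearson correlations over all 6 pairs of a 4-trait continuous subset.

    Computed on species-mean values of species complete on the subset.
    ``absolute=True`` (default) summarises correlation strength regardless
    of sign.
    """
    subset = tuple(sorted(subset))
    if len(subset) != 4:
        raise ValueError("correlation summary is defined for 4-trait subsets")
    kinds = traits.kinds()
    cat = [t for t in subset if kinds.get(t) == CATEGORICAL]
    if cat:
        raise ValueError(f"categorical traits {cat} have no Pearson correlation")
    wide = traits.to_wide(subset).dropna().astype(float)
    x = wide.to_numpy()
    if (x.std(axis=0) == 0).any():
        const = [t for t, s in zip(subset, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant trait(s) {const}: correlation undefined")
    corr = np.corrcoef(x, rowvar=False)
    pairs = corr[np.triu_indices(4, k=1)]
    if absolute:
        pairs = np.abs(pairs)
    return CorrelationSummary(
        subset=subset,
        min_corr=float(pairs.min()),
        max_corr=float(pairs.max()),
        mean_corr=float(pairs.mean()),
    )


def correlation_table(
    traits: TraitTable, subsets: Iterable[tuple[str, ...]], absolute: bool = True
) -> pd.DataFrame:
    """CorrelationSummary rows for every all-continuous 4-trait subset."""
    kinds = traits.kinds()
    rows = []
    for s in subsets:
        s = tuple(sorted(s))
        if len(s) != 4 or any(kinds[t] == CATEGORICAL for t in s):
            continue
        cs = correlation_summary(traits, s, absolute=absolute)
        rows.append({
            "subset": subset_label(s),
            "min_corr": cs.min_corr,
            "max_corr": cs.max_corr,
            "mean_corr": cs.mean_corr,
        })
    return pd.DataFrame(rows, columns=["subset", "min_corr", "max_corr", "mean_corr"])
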