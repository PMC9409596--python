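"""Community and trait tables: reading, validation, filtering.

Plot-by-species abundance tables (percent cover or relative abundance) and
long-format species-by-trait tables are the two raw inputs of the pipeline.
Before any metric is computed a trait subset is chosen, species with
incomplete coverage on that subset are removed, and each plot's remaining
abundances are renormalised; plots that lose too much of their original
abundance are excluded rather than analysed on an unrepresentative remnant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Minimum fraction of a plot's raw abundance that must survive trait-coverage
#: filtering for the plot to stay in the analysis.
DEFAULT_MIN_ABUNDANCE_RETAINED = 0.80


class TraitTable:
    """Long-format species x trait table.

    One row per (species, trait, replicate measurement). Continuous values
    are floats; categorical values are level labels. After
    :func:`species_mean_traits` there is exactly one row per (species, trait).

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``species``, ``trait``, ``value``, ``kind``; ``kind`` is
        ``"continuous"`` or ``"categorical"``.
    """

    REQUIRED = ("species", "trait", "value", "kind")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        data = data.loc[:, list(self.REQUIRED)].copy()
        data["species"] = data["species"].astype(str)
        data["trait"] = data["trait"].astype(str)
        data["kind"] = data["kind"].astype(str)
        bad_kind = set(data["kind"]) - {CONTINUOUS, CATEGORICAL}
        if bad_kind:
            raise ValueError(f"unknown trait kinds: {sorted(bad_kind)}")
        kinds = data.groupby("trait")["kind"].nunique()
        if (kinds > 1).any():
            conflicted = kinds.index[kinds > 1].tolist()
            raise ValueError(f"traits declared with conflicting kinds: {conflicted}")
        cont = data["kind"] == CONTINUOUS
        if cont.any():
            vals = pd.to_numeric(data.loc[cont, "value"], errors="coerce")
            present = data.loc[cont, "value"].notna()
            if (present & ~np.isfinite(vals.fillna(np.nan))).any():
                raise ValueError("continuous trait values must be finite where present")
            data.loc[cont, "value"] = vals
        self.data = data.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def kinds(self) -> dict[str, str]:
        """Map trait id -> 'continuous' | 'categorical'."""
        return dict(self.data.drop_duplicates("trait").set_index("trait")["kind"])

    def to_wide(self, subset: Sequence[str] | None = None) -> pd.DataFrame:
        """Species x trait value matrix (requires one row per pair).

        Continuous columns come back as floats, categorical as objects;
        combinations never measured are NaN.
        """
        dup = self.data.duplicated(["species", "trait"])
        if dup.any():
            raise ValueError(
                "table has replicate measurements; call species_mean_traits first"
            )
        wide = self.data.pivot(index="species", columns="trait", values="value")
        kinds = self.kinds()
        for t in wide.columns:
            if kinds[t] == CONTINUOUS:
                wide[t] = pd.to_numeric(wide[t])
        if subset is not None:
            missing = [t for t in subset if t not in wide.columns]
            if missing:
                raise KeyError(f"traits not in table: {missing}")
            wide = wide.loc[:, list(subset)]
        return wide

    def complete_species(self, subset: Sequence[str]) -> list[str]:
        """Species with a value for every trait in ``subset`` (100% coverage)."""
        wide = self.to_wide(subset)
        return sorted(wide.index[wide.notna().all(axis=1)])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TraitTable({len(self.species)} species, {len(self.traits)} traits, "
            f"{len(self.data)} rows)"
        )


class CommunityMatrix:
    """Plot x species abundances in long format.

    Columns ``plot``, ``study``, ``species``, ``abundance``. Zero-abundance
    rows are dropped on construction (they carry no weight in any metric);
    duplicate (study, plot, species) rows are summed.
    """

    REQUIRED = ("plot", "study", "species", "abundance")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"community table missing columns: {missing}")
        data = data.loc[:, list(self.REQUIRED)].copy()
        for c in ("plot", "study", "species"):
            data[c] = data[c].astype(str)
        data["abundance"] = pd.to_numeric(data["abundance"])
        neg = data.index[data["abundance"] < 0]
        if len(neg):
            row = neg[0]
            raise ValueError(
                f"negative abundance at row {row}: "
                f"{data.loc[row, ['plot', 'species', 'abundance']].to_dict()}"
            )
        data = (
            data.groupby(["study", "plot", "species"], as_index=False)["abundance"]
            .sum()
        )
        data = data[data["abundance"] > 0].reset_index(drop=True)
        self.data = data

    @property
    def plots(self) -> list[tuple[str, str]]:
        """(study, plot) keys in deterministic order."""
        return sorted(
            self.data[["study", "plot"]].drop_duplicates().itertuples(index=False)
        )

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def plot_abundances(self, study: str, plot: str) -> pd.Series:
        sub = self.data[(self.data["study"] == study) & (self.data["plot"] == plot)]
        return sub.set_index("species")["abundance"].sort_index()

    def relative(self) -> "CommunityMatrix":
        """Normalise abundances to sum to one within each (study, plot)."""
        data = self.data.copy()
        totals = data.groupby(["study", "plot"])["abundance"].transform("sum")
        data["abundance"] = data["abundance"] / totals
        return CommunityMatrix(data)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"CommunityMatrix({len(self.plots)} plots, "
            f"{len(self.species)} species)"
        )


@dataclass
class FilterReport:
    """Bookkeeping from trait-coverage filtering of one trait subset."""

    subset: tuple[str, ...]
    species_dropped: list[str]
    per_plot_abundance_retained: dict[tuple[str, str], float]
    plots_flagged: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study": s,
                "plot": p,
                "abundance_retained": f,
                "flagged": (s, p) in set(self.plots_flagged),
            }
            for (s, p), f in sorted(self.per_plot_abundance_retained.items())
        ]
        return pd.DataFrame(rows)


def read_community(path) -> CommunityMatrix:
    """Read a community CSV with header columns plot, study, species, abundance."""
    df = pd.read_csv(path)
    return CommunityMatrix(df)


def read_traits(path) -> TraitTable:
    """Read a long trait CSV with header columns species, trait, value, kind."""
    df = pd.read_csv(path)
    return TraitTable(df)


def species_mean_traits(traits: TraitTable) -> TraitTable:
    """Collapse replicate measurements to one value per (species, trait).

    Continuous traits take the arithmetic mean of all measurements; a
    categorical trait must be constant within a species and keeps its single
    level. Combinations with no measurements stay absent (missing).
    """
    rows = []
    for (sp, tr), grp in traits.data.groupby(["species", "trait"], sort=True):
        kind = grp["kind"].iloc[0]
        vals = grp["value"].dropna()
        if vals.empty:
            continue
        if kind == CONTINUOUS:
            value = float(np.mean(vals.astype(float)))
        else:
            levels = sorted(set(vals))
            if len(levels) > 1:
                raise ValueError(
                    f"categorical trait {tr!r} has conflicting levels {levels} "
                    f"for species {sp!r}"
                )
            value = levels[0]
        rows.append({"species": sp, "trait": tr, "value": value, "kind": kind})
    return TraitTable(pd.DataFrame(rows, columns=list(TraitTable.REQUIRED)))


def filter_trait_coverage(
    comm: CommunityMatrix,
    traits: TraitTable,
    subset: Sequence[str],
    min_retained: float = DEFAULT_MIN_ABUNDANCE_RETAINED,
) -> tuple[CommunityMatrix, FilterReport]:
    """Drop species with incomplete coverage on ``subset`` and renormalise.

    Species missing any trait in ``subset`` are removed from every plot.
    Remaining per-plot abundances are renormalised to relative abundances.
    Plots retaining less than ``min_retained`` of their raw abundance (or
    left empty) are flagged and excluded: a community no longer represented
    by at least that share of its abundance is not analysed for this subset.

    Returns the filtered relative-abundance matrix and a :class:`FilterReport`.
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("trait subset must be non-empty")
    keep = set(traits.complete_species(subset))
    dropped = sorted(set(comm.species) - keep)

    data = comm.data
    totals = data.groupby(["study", "plot"])["abundance"].sum()
    kept_rows = data[data["species"].isin(keep)]
    kept_totals = kept_rows.groupby(["study", "plot"])["abundance"].sum()

    retained: dict[tuple[str, str], float] = {}
    flagged: list[tuple[str, str]] = []
    for key, total in totals.items():
        frac = float(kept_totals.get(key, 0.0) / total)
        retained[key] = frac
        if frac < min_retained or frac == 0.0:
            flagged.append(key)
            logger.warning(
                "plot %s/%s retains %.3f of abundance on subset %s; excluded",
                key[0], key[1], frac, subset,
            )
    flagged_set = set(flagged)
    kept_rows = kept_rows[
        ~kept_rows.set_index(["study", "plot"]).index.isin(flagged_set)
    ]
    if kept_rows.empty:
        filtered = CommunityMatrix(
            pd.DataFrame(columns=list(CommunityMatrix.REQUIRED))
        )
    else:
        filtered = CommunityMatrix(kept_rows).relative()
    report = FilterReport(
        subset=subset,
        species_dropped=dropped,
        per_plot_abundance_retained=retained,
        plots_flagged=sorted(flagged),
    )
    return filtered, report
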