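"""End-to-end convenience: raw tables -> sweep -> correlation -> models.

Glue over the pipeline stages for the common case of analysing one study:
species-mean traits, subset enumeration (optionally subsampled), the metric
sweep, the 4-trait correlation table, and the trait-number / correlation
mixed models with a BH-adjusted family of tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .community import CommunityMatrix, TraitTable, species_mean_traits
from .inference import (
    MetricTrendResults,
    TraitCorrelationModel,
    TraitNumberModel,
    adjust_family,
)
from .sweep import (
    ALL_METRICS,
    SweepConfig,
    correlation_table,
    enumerate_subsets,
    run_sweep,
    sample_subsets,
)

logger = logging.getLogger(__name__)


@dataclass
class StudyAnalysis:
    """Everything one pipeline pass produced for a study."""

    study_id: str
    sweep: pd.DataFrame
    correlations: pd.DataFrame
    trait_number_results: dict[str, MetricTrendResults] = field(default_factory=dict)
    correlation_results: dict[tuple[str, str], MetricTrendResults] = field(
        default_factory=dict
    )
    test_table: pd.DataFrame | None = None


def analyze_study(
    traits_raw: TraitTable,
    comm: CommunityMatrix,
    study_id: str = "study",
    config: SweepConfig = SweepConfig(),
    k_min: int = 2,
    k_max: int | None = None,
    metrics_to_model: tuple[str, ...] = ALL_METRICS,
    model_distance: str = "gower",
) -> StudyAnalysis:
    """Run the full analysis for one study.

    Trait-number models are fitted per metric on the configured distance
    (KDE metrics are distance-free and always modelled from their own
    records); correlation models are fitted for min/max/mean absolute
    correlation whenever enough all-continuous 4-trait subsets exist.
    All selected models form one BH family.
    """
    traits = species_mean_traits(traits_raw)
    subsets = enumerate_subsets(traits.traits, k_min, k_max)
    if config.max_subsets_per_k is not None:
        subsets = sample_subsets(subsets, config.max_subsets_per_k, config.seed)
    sweep = run_sweep(comm, traits, subsets, config)
    corr = correlation_table(traits, [s for s in subsets if len(s) == 4])

    out = StudyAnalysis(study_id=study_id, sweep=sweep, correlations=corr)
    family = []
    for metric in metrics_to_model:
        dist = "traits" if metric.startswith("KDE") else model_distance
        try:
            res = TraitNumberModel.from_sweep(sweep, metric, distance=dist).fit()
        except (ValueError, RuntimeError) as exc:
            logger.warning("%s: trait-number model skipped (%s)", metric, exc)
            continue
        out.trait_number_results[metric] = res
        family.append(res)
    if len(corr) >= 10:
        for metric in metrics_to_model:
            dist = "traits" if metric.startswith("KDE") else model_distance
            for predictor in ("min_corr", "max_corr", "mean_corr"):
                try:
                    res = TraitCorrelationModel.from_sweep(
                        sweep, corr, metric, predictor=predictor, distance=dist
                    ).fit()
                except (ValueError, RuntimeError) as exc:
                    logger.warning(
                        "%s ~ %s skipped (%s)", metric, predictor, exc
                    )
                    continue
                out.correlation_results[(metric, predictor)] = res
                family.append(res)
    if family:
        out.test_table = adjust_family(family)
    return out
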