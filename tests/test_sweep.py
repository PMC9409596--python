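import math

import numpy as np
import pandas as pd
import pytest

from fdsweep import (
    CommunityMatrix,
    SweepConfig,
    TraitTable,
    correlation_summary,
    correlation_table,
    enumerate_subsets,
    run_sweep,
    sample_subsets,
    subset_label,
)
from fdsweep.sweep import CLASSIC_METRICS, KDE_METRICS
from helpers import random_mean_traits


class TestEnumerateSubsets:
    def test_ten_trait_design_counts(self):
        ids = [f"t{i}" for i in range(10)]
        subsets = enumerate_subsets(ids, 2, 10)
        by_k = {}
        for s in subsets:
            by_k[len(s)] = by_k.get(len(s), 0) + 1
        assert by_k[2] == 45
        assert by_k[3] == 120
        assert by_k[4] == 210
        assert by_k[9] == 10
        assert by_k[10] == 1

    def test_three_traits_exhaustive(self):
        assert enumerate_subsets(["A", "B", "C"], 2, 2) == [
            ("A", "B"), ("A", "C"), ("B", "C"),
        ]

    def test_counts_match_binomial_coefficients(self):
        for n in range(2, 13):
            ids = [f"t{i:02d}" for i in range(n)]
            for k in range(2, n + 1):
                assert len(enumerate_subsets(ids, k, k)) == math.comb(n, k)

    def test_k_max_beyond_trait_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_subsets(["A", "B"], 2, 3)

    def test_deterministic_subsampling(self):
        ids = [f"t{i}" for i in range(8)]
        subsets = enumerate_subsets(ids, 2, 4)
        s1 = sample_subsets(subsets, 5, seed=3)
        s2 = sample_subsets(subsets, 5, seed=3)
        assert s1 == s2
        assert sum(1 for s in s1 if len(s) == 3) == 5


@pytest.fixture
def mini_data(rng):
    traits = random_mean_traits(rng, n_species=6, n_cont=3, n_cat=0)
    rows = []
    for p in range(3):
        pres = rng.choice(6, size=4, replace=False)
        ab = rng.dirichlet(np.ones(4))
        for i, sp in enumerate(pres):
            rows.append({
                "plot": f"p{p}", "study": "demo",
                "species": f"s{sp}", "abundance": float(ab[i]),
            })
    return CommunityMatrix(pd.DataFrame(rows)), traits


class TestRunSweep:
    def test_record_bookkeeping(self, mini_data):
        comm, traits = mini_data
        subsets = enumerate_subsets(traits.traits, 2, 3)  # C(3,2)+C(3,3) = 4
        assert len(subsets) == 4
        cfg = SweepConfig(kde_samples=500)
        sweep = run_sweep(comm, traits, subsets, cfg)
        # per subset and plot: 5 classic metrics x 2 distances + 3 KDE
        per_cell = 5 * 2 + 3
        assert len(sweep) == 4 * 3 * per_cell
        assert set(sweep["metric"]) == set(CLASSIC_METRICS) | set(KDE_METRICS)

    def test_key_uniqueness(self, mini_data):
        comm, traits = mini_data
        sweep = run_sweep(
            comm, traits, enumerate_subsets(traits.traits, 2, 3),
            SweepConfig(kde_samples=500),
        )
        keys = sweep[["study", "plot", "metric", "distance", "subset", "dims"]]
        assert not keys.fillna(-1).duplicated().any()

    def test_determinism(self, mini_data):
        comm, traits = mini_data
        subsets = enumerate_subsets(traits.traits, 2, 2)
        cfg = SweepConfig(kde_samples=500, seed=42)
        s1 = run_sweep(comm, traits, subsets, cfg)
        s2 = run_sweep(comm, traits, subsets, cfg)
        pd.testing.assert_frame_equal(s1, s2)

    def test_subset_order_invariance(self, mini_data):
        comm, traits = mini_data
        t = traits.traits
        cfg = SweepConfig(kde_samples=500)
        fwd = run_sweep(comm, traits, [(t[0], t[1])], cfg)
        rev = run_sweep(comm, traits, [(t[1], t[0])], cfg)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_flagged_plot_records_all_missing(self, rng):
        traits = random_mean_traits(rng, n_species=4, n_cont=2, n_cat=0)
        # drop one trait value of the dominant species
        data = traits.data
        data = data[~((data["species"] == "s0") & (data["trait"] == "T1"))]
        traits = TraitTable(data)
        comm = CommunityMatrix(pd.DataFrame({
            "plot": ["p0"] * 2, "study": ["demo"] * 2,
            "species": ["s0", "s1"], "abundance": [0.9, 0.1],
        }))
        sweep = run_sweep(
            comm, traits, [("T0", "T1")], SweepConfig(kde_samples=500)
        )
        assert len(sweep) > 0
        assert sweep["value"].isna().all()

    def test_resume_skips_done_subsets(self, mini_data):
        comm, traits = mini_data
        subsets = enumerate_subsets(traits.traits, 2, 3)
        cfg = SweepConfig(kde_samples=500)
        full = run_sweep(comm, traits, subsets, cfg)
        part = run_sweep(comm, traits, subsets[:2], cfg)
        resumed = run_sweep(comm, traits, subsets, cfg, resume_from=part)
        key = ["study", "plot", "metric", "distance", "subset", "dims"]
        a = full.sort_values(key).reset_index(drop=True)
        b = resumed.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_frich_sensitivity_dims_resolution(self, rng):
        # "max" resolves to subset size (continuous) or size - 1 (with a
        # categorical trait) and collapses onto an explicit dims if equal
        traits = random_mean_traits(rng, n_species=8, n_cont=3, n_cat=1)
        rows = [{
            "plot": "p0", "study": "demo", "species": f"s{i}", "abundance": 1.0,
        } for i in range(8)]
        comm = CommunityMatrix(pd.DataFrame(rows))
        cfg = SweepConfig(kde_enabled=False, frich_dims=(2, "max"))
        cont = run_sweep(comm, traits, [("T0", "T1", "T2")], cfg)
        dims_cont = set(
            cont.loc[cont["metric"] == "FRich", "dims"].astype(int)
        )
        assert dims_cont == {2, 3}
        mixed = run_sweep(comm, traits, [("C0", "T0", "T1")], cfg)
        frich = mixed[mixed["metric"] == "FRich"]
        assert set(frich["dims"].astype(int)) == {2}
        assert len(frich) == 1  # the collision is deduplicated, not doubled

    def test_mixed_subsets_skip_euclidean(self, rng):
        traits = random_mean_traits(rng, n_species=6, n_cont=2, n_cat=1)
        rows = [{
            "plot": "p0", "study": "demo", "species": f"s{i}", "abundance": 1.0,
        } for i in range(6)]
        comm = CommunityMatrix(pd.DataFrame(rows))
        sweep = run_sweep(
            comm, traits, [("C0", "T0", "T1")], SweepConfig(kde_samples=500)
        )
        classic = sweep[sweep["metric"].isin(CLASSIC_METRICS)]
        assert set(classic["distance"]) == {"gower"}


class TestCorrelationSummary:
    def test_independent_traits_near_zero(self, rng):
        tt = random_mean_traits(rng, n_species=500, n_cont=4, n_cat=0)
        cs = correlation_summary(tt, tt.traits)
        assert cs.max_corr < 0.15
        assert cs.min_corr <= cs.mean_corr <= cs.max_corr

    def test_duplicated_trait_max_one(self, rng):
        tt = random_mean_traits(rng, n_species=30, n_cont=3, n_cat=0)
        dup = tt.data[tt.data["trait"] == "T0"].assign(trait="T0copy")
        tt = TraitTable(pd.concat([tt.data, dup]))
        cs = correlation_summary(tt, ["T0", "T0copy", "T1", "T2"])
        assert cs.max_corr == pytest.approx(1.0)

    def test_matches_direct_six_pair_computation(self, rng):
        tt = random_mean_traits(rng, n_species=5, n_cont=4, n_cat=0)
        wide = tt.to_wide(tt.traits).astype(float)
        pairs = []
        cols = list(wide.columns)
        for i in range(4):
            for j in range(i + 1, 4):
                pairs.append(abs(np.corrcoef(wide[cols[i]], wide[cols[j]])[0, 1]))
        cs = correlation_summary(tt, cols)
        assert cs.min_corr == pytest.approx(min(pairs))
        assert cs.max_corr == pytest.approx(max(pairs))
        assert cs.mean_corr == pytest.approx(np.mean(pairs))

    def test_constant_trait_rejected(self):
        rows = [(f"s{i}", t, v if t != "T0" else 1.0, "continuous")
                for i, v in enumerate([1.0, 2.0, 3.0])
                for t in ["T0", "T1", "T2", "T3"]]
        tt = TraitTable(pd.DataFrame(
            rows, columns=["species", "trait", "value", "kind"]
        ))
        with pytest.raises(ValueError, match="constant"):
            correlation_summary(tt, ["T0", "T1", "T2", "T3"])

    def test_categorical_subset_rejected(self, rng):
        tt = random_mean_traits(rng, n_species=10, n_cont=3, n_cat=1)
        with pytest.raises(ValueError, match="Pearson"):
            correlation_summary(tt, ["C0", "T0", "T1", "T2"])

    def test_wrong_size_rejected(self, rng):
        tt = random_mean_traits(rng, n_species=10, n_cont=3, n_cat=0)
        with pytest.raises(ValueError, match="4-trait"):
            correlation_summary(tt, ["T0", "T1", "T2"])

    def test_correlation_table_skips_categorical_subsets(self, rng):
        tt = random_mean_traits(rng, n_species=20, n_cont=4, n_cat=1)
        subsets = enumerate_subsets(tt.traits, 4, 4)
        table = correlation_table(tt, subsets)
        assert len(table) == 1  # only the all-continuous quadruple
        assert table["subset"].iloc[0] == subset_label(["T0", "T1", "T2", "T3"])


def test_config_yaml_round_trip(tmp_path):
    cfg = SweepConfig(frich_dims=(2, 3, "max"), kde_samples=1234, seed=9)
    p = tmp_path / "cfg.yaml"
    cfg.to_yaml(p)
    assert SweepConfig.from_yaml(p) == cfg
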