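import io

import numpy as np
import pandas as pd
import pytest

from rarescape import (
    ScenarioConfig,
    SyntheticDataset,
    load_dataset,
    simulate_dataset,
    simulate_tree_and_traits,
)
from rarescape.synthetic_data import crown_membership, crown_tree


class TestTreeAndTraits:
    def test_deterministic_under_seed(self):
        t1, z1 = simulate_tree_and_traits(50, seed=9)
        t2, z2 = simulate_tree_and_traits(50, seed=9)
        assert str(t1) == str(t2)
        pd.testing.assert_series_equal(z1, z2)

    def test_zero_rate_gives_equal_traits(self):
        _, z = simulate_tree_and_traits(20, bm_rate=0.0, seed=1)
        assert z.nunique() == 1

    def test_trait_variance_grows_with_depth(self):
        # Brownian motion: across independent trees, realized trait variance
        # scales with tree depth (positive regression slope)
        depths, variances = [], []
        for seed in range(20):
            tree, z = simulate_tree_and_traits(30, seed=seed)
            depths.append(max(tree.distance(t) for t in tree.tips()))
            variances.append(z.var())
        slope = np.polyfit(depths, variances, 1)[0]
        assert slope > 0

    def test_tip_count_and_names(self):
        tree, z = simulate_tree_and_traits(25, seed=0)
        tips = list(tree.tips())
        assert len(tips) == 25
        assert len(z) == 25
        assert set(z.index) == {t.name for t in tips}


class TestCrownTree:
    def test_structure(self):
        tree = crown_tree(60, 25, crown_depth=0.01, seed=4)
        assert sum(1 for _ in tree.tips()) == 60
        crowns = crown_membership(tree)
        assert crowns.nunique() >= 25 - 5  # most backbone tips hold a crown
        # sisters in a crown are far closer than cross-crown taxa
        from rarescape import cophenetic

        D = cophenetic(tree)
        multi = crowns.groupby(crowns).filter(lambda s: len(s) > 1)
        pair = multi.index[:2]
        cross = D.loc[pair[0]].drop(multi.index[multi == multi[pair[0]]]).min()
        assert D.loc[pair[0], pair[1]] < cross


class TestSimulateDataset:
    def test_columns_sum_to_depth(self):
        cfg = ScenarioConfig(scenario="homogeneous_selection", n_taxa=100,
                             n_stages=2, n_times=2, n_replicates=2,
                             depth=2000, seed=0)
        ds = simulate_dataset(cfg)
        assert (ds.table.counts.sum(axis=0) == 2000).all()
        assert ds.table.shape == (100, cfg.n_samples)

    def test_design_matches_metadata(self):
        cfg = ScenarioConfig(scenario="neutral_drift", n_taxa=50, n_stages=3,
                             n_times=2, n_replicates=2, depth=500, seed=1)
        ds = simulate_dataset(cfg)
        meta = ds.metadata.frame
        assert len(meta) == 12
        assert meta["stage"].nunique() == 3
        assert meta["time"].nunique() == 2
        assert list(meta.index) == list(ds.table.sample_ids)

    def test_homogeneous_scenario_shares_environment(self):
        # all samples draw from the same expected composition: stage means
        # are highly similar
        cfg = ScenarioConfig(scenario="homogeneous_selection", n_taxa=100,
                             n_stages=2, n_times=1, n_replicates=4,
                             depth=3000, seed=3, crown_noise=0.0,
                             competition_alpha=100.0)
        ds = simulate_dataset(cfg)
        rel = ds.table.relative_abundance()
        m0 = rel.loc[:, ds.metadata.frame.stage == "stage0"].mean(axis=1)
        m1 = rel.loc[:, ds.metadata.frame.stage == "stage1"].mean(axis=1)
        overlap = np.minimum(m0, m1).sum()
        assert overlap > 0.8

    def test_separated_stages_share_few_dominants(self):
        # two stages six niche widths apart: community overlap below 20%
        cfg = ScenarioConfig(scenario="variable_selection", n_taxa=200,
                             n_stages=2, n_times=1, n_replicates=5,
                             depth=3000, env_separation=6.0, seed=3)
        ds = simulate_dataset(cfg)
        rel = ds.table.relative_abundance()
        m0 = rel.loc[:, ds.metadata.frame.stage == "stage0"].mean(axis=1)
        m1 = rel.loc[:, ds.metadata.frame.stage == "stage1"].mean(axis=1)
        overlap = np.minimum(m0, m1).sum()
        assert overlap < 0.2

    def test_dispersal_pools_are_disjoint(self):
        cfg = ScenarioConfig(scenario="dispersal_limitation", n_taxa=120,
                             n_stages=4, n_times=1, n_replicates=2,
                             depth=2000, n_pools=4, seed=6)
        ds = simulate_dataset(cfg)
        meta = ds.metadata.frame
        s0 = ds.table.counts.loc[:, meta.stage == "stage0"].sum(axis=1)
        s1 = ds.table.counts.loc[:, meta.stage == "stage1"].sum(axis=1)
        assert ((s0 > 0) & (s1 > 0)).sum() == 0

    def test_truth_labels_round_trip(self, tmp_path):
        cfg = ScenarioConfig(scenario="variable_selection", n_taxa=60,
                             n_stages=2, n_times=1, n_replicates=2,
                             depth=500, seed=7)
        ds = simulate_dataset(cfg)
        ds.write(tmp_path)
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["dominant_process"] == "variable_selection"
        table, meta, tree = load_dataset(
            tmp_path / "table.tsv", tmp_path / "metadata.tsv", tmp_path / "tree.nwk"
        )
        pd.testing.assert_frame_equal(
            table.counts, ds.table.counts, check_names=False
        )
        assert {t.name for t in tree.tips()} == set(ds.table.asv_ids)

    def test_determinism(self):
        cfg = ScenarioConfig(scenario="neutral_drift", n_taxa=40, n_stages=2,
                             n_times=1, n_replicates=2, depth=300, seed=11)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        pd.testing.assert_frame_equal(a.table.counts, b.table.counts)
        assert str(a.tree) == str(b.tree)

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(scenario="nope")

    def test_long_tailed_rarity_structure(self):
        # every scenario leaves a sizable rare tail at the 0.1% cutoff
        from rarescape import CutoffSpec, partition_biospheres

        cfg = ScenarioConfig(scenario="homogeneous_selection", n_taxa=150,
                             n_stages=2, n_times=2, n_replicates=2,
                             depth=5000, seed=2)
        ds = simulate_dataset(cfg)
        part = partition_biospheres(
            ds.table, CutoffSpec(mode="fixed", value=0.001)
        )
        n_rare = (part.rare_table.counts.sum(axis=1) > 0).sum()
        assert n_rare >= 20
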