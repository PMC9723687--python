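import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescape import (
    CutoffSpec,
    FeatureTable,
    classify_rarity_types,
    partition_biospheres,
    rare_fraction,
    sample_specific_cutoff,
)


def _rarefied(counts: dict, index, depth) -> FeatureTable:
    return FeatureTable(pd.DataFrame(counts, index=index), is_rarefied=True, depth=depth)


class TestPartition:
    def test_boundary_is_rare(self):
        # at depth 1000 and cutoff 0.1%, one read sits exactly at the cutoff
        t = _rarefied({"S1": [1, 999], "S2": [2, 998]}, ["x", "y"], 1000)
        part = partition_biospheres(t, CutoffSpec(mode="fixed", value=0.001))
        assert part.rare_table.counts.loc["x", "S1"] == 1   # == cutoff: rare
        assert part.common_table.counts.loc["x", "S2"] == 2  # above: common
        assert part.rare_table.counts.loc["x", "S2"] == 0

    def test_absent_in_neither(self):
        t = _rarefied({"S1": [0, 1000], "S2": [5, 995]}, ["x", "y"], 1000)
        part = partition_biospheres(t, CutoffSpec(mode="fixed", value=0.001))
        assert part.rare_table.counts.loc["x", "S1"] == 0
        assert part.common_table.counts.loc["x", "S1"] == 0

    def test_requires_rarefied(self):
        t = FeatureTable(pd.DataFrame({"S1": [1, 2]}, index=["x", "y"]))
        from rarescape import ValidationError

        with pytest.raises(ValidationError):
            partition_biospheres(t, CutoffSpec(mode="fixed", value=0.001))

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            CutoffSpec(mode="fixed", value=1.5)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_round_trip_reconstructs_input(self, seed):
        rng = np.random.default_rng(seed)
        depth = 200
        w = rng.dirichlet(np.ones(15))
        counts = np.column_stack([rng.multinomial(depth, w) for _ in range(4)])
        t = FeatureTable(
            pd.DataFrame(counts, index=[f"T{i}" for i in range(15)],
                         columns=list("abcd")),
            is_rarefied=True, depth=depth,
        )
        part = partition_biospheres(t, CutoffSpec(mode="fixed", value=0.01))
        total = part.rare_table.counts + part.common_table.counts
        pd.testing.assert_frame_equal(total, t.counts)


class TestSampleSpecificCutoff:
    def test_hand_walked_rank_rule(self):
        counts = [500, 100, 50, 10, 5, 3, 2, 1, 1, 1]  # total 673
        # first rank r with abundance <= r is rank 5 (abundance 5)
        assert sample_specific_cutoff(counts) == pytest.approx(5 / 673)

    def test_recalibration_shrinks_by_completeness(self):
        counts = [500, 100, 50, 10, 5, 3, 2, 1, 1, 1]
        # S_obs = 10, F1 = 3, F2 = 1 -> Chao1 = 10 + 9/2 = 14.5
        expected = (5 / 673) * (10 / 14.5)
        assert sample_specific_cutoff(counts, recalibrate=True) == pytest.approx(expected)

    def test_flat_curve_degenerate(self):
        assert sample_specific_cutoff([1, 1, 1]) == pytest.approx(1 / 3)

    def test_no_crossing_falls_back_with_warning(self, caplog):
        # every abundance exceeds its rank
        frac = sample_specific_cutoff([10, 9, 8])
        assert frac == pytest.approx(8 / 27)
        assert "crossing" in caplog.text


class TestRarityTypes:
    @pytest.fixture
    def typed(self):
        # depth 10000, cutoff 0.1% = 10 reads; rows engineered per type
        counts = {
            "S1": [5, 5, 1, 50, 9939, 0],
            "S2": [20, 2, 0, 30, 9943, 5],
            "S3": [1, 0, 0, 20, 9974, 5],
        }
        idx = ["cond", "perm_rare", "trans_rare", "perm_common", "filler", "pr2"]
        t = _rarefied(counts, idx, 10000)
        part = partition_biospheres(t, CutoffSpec(mode="fixed", value=0.001))
        return classify_rarity_types(part)

    def test_worked_examples(self, typed):
        labels = typed.labels
        assert labels["cond"] == "conditionally_rare_common"
        assert labels["perm_rare"] == "permanently_rare"
        assert labels["trans_rare"] == "transiently_rare"
        assert labels["perm_common"] == "permanently_common"

    def test_types_partition_detected_asvs(self, typed):
        assert typed.counts().sum() == len(typed.labels)
        assert typed.labels.notna().all()

    def test_common_or_absent_flagged_as_conditional(self):
        t = _rarefied({"S1": [50, 950], "S2": [0, 1000]}, ["x", "y"], 1000)
        res = classify_rarity_types(
            partition_biospheres(t, CutoffSpec(mode="fixed", value=0.001))
        )
        assert res.labels["x"] == "conditionally_rare_common"
        assert "x" in res.flagged


class TestMonotonicity:
    def test_stricter_cutoff_never_grows_rare_fraction(self):
        from rarescape import ScenarioConfig, simulate_dataset

        for scenario in ("neutral_drift", "homogeneous_selection"):
            ds = simulate_dataset(
                ScenarioConfig(scenario=scenario, n_taxa=150, n_stages=2,
                               n_times=2, n_replicates=2, depth=2000, seed=5)
            )
            fracs = [
                rare_fraction(
                    partition_biospheres(ds.table, CutoffSpec(mode="fixed", value=c))
                )
                for c in (0.002, 0.001, 0.0005)
            ]
            assert fracs[0] >= fracs[1] >= fracs[2]

    def test_smaller_cutoff_moves_types_toward_commonness(self):
        # shrinking the cutoff can only flip per-sample statuses from rare
        # to common, so the never-common types can only lose members and
        # permanently_common can only gain them
        from rarescape import ScenarioConfig, simulate_dataset

        ds = simulate_dataset(
            ScenarioConfig(scenario="neutral_drift", n_taxa=150, n_stages=2,
                           n_times=2, n_replicates=2, depth=2000, seed=5)
        )
        wide = classify_rarity_types(
            partition_biospheres(ds.table, CutoffSpec(mode="fixed", value=0.002))
        ).counts()
        narrow = classify_rarity_types(
            partition_biospheres(ds.table, CutoffSpec(mode="fixed", value=0.0005))
        ).counts()
        assert narrow["permanently_common"] >= wide["permanently_common"]
        never_common_narrow = narrow["permanently_rare"] + narrow["transiently_rare"]
        never_common_wide = wide["permanently_rare"] + wide["transiently_rare"]
        assert never_common_narrow <= never_common_wide
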