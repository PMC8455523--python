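"""Gradient plans, quintilization, bias calling and the calibration null."""

import numpy as np
import pandas as pd
import pytest

import coexsweep as cx
from coexsweep.sweep import (
    GradientPlan,
    QuintileSummary,
    SweepTrajectory,
    quintile_blocks,
)


def _log2fc_frame(values, n_iter):
    genes = [f"g{i}" for i in range(len(values))]
    return pd.DataFrame(
        np.asarray(values, float),
        index=genes,
        columns=[f"iter{i}" for i in range(n_iter)],
    )


class TestGradientPlan:
    def test_population_counts_and_sizes(self, rng):
        plan = cx.build_gradient_plan([f"f{i}" for i in range(5)],
                                      [f"m{i}" for i in range(5)], 3, rng)
        assert len(plan) == 4
        female_counts = [
            sum(s.startswith("f") for s in pop) for pop in plan.populations
        ]
        assert female_counts == [3, 2, 1, 0]
        assert all(len(pop) == 3 for pop in plan.populations)

    def test_consecutive_symmetric_difference_is_two(self, rng):
        plan = cx.build_gradient_plan([f"f{i}" for i in range(10)],
                                      [f"m{i}" for i in range(10)], 8, rng)
        for a, b in zip(plan.populations, plan.populations[1:]):
            assert len(set(a) ^ set(b)) == 2

    def test_seed_determinism(self):
        f = [f"f{i}" for i in range(10)]
        m = [f"m{i}" for i in range(10)]
        p1 = cx.build_gradient_plan(f, m, 6, np.random.default_rng(5))
        p2 = cx.build_gradient_plan(f, m, 6, np.random.default_rng(5))
        p3 = cx.build_gradient_plan(f, m, 6, np.random.default_rng(6))
        assert p1 == p2
        assert p1 != p3

    def test_insufficient_samples_names_deficient_group(self, rng):
        with pytest.raises(ValueError, match="group B"):
            cx.build_gradient_plan(list("abcde"), list("xy"), 4, rng)


class TestNullPlan:
    def test_every_population_sex_balanced(self, rng):
        f = [f"f{i}" for i in range(20)]
        m = [f"m{i}" for i in range(20)]
        plan = cx.build_null_plan(f, m, 10, rng)
        assert len(plan) == 11
        for pop in plan.populations:
            assert len(pop) == 10
            assert sum(s.startswith("f") for s in pop) == 5

    def test_chained_one_in_one_out(self, rng):
        plan = cx.build_null_plan(
            [f"f{i}" for i in range(12)], [f"m{i}" for i in range(12)], 6, rng
        )
        for a, b in zip(plan.populations, plan.populations[1:]):
            assert len(set(a) ^ set(b)) == 2

    def test_overlap_structure_matches_gradient(self, rng):
        # populations j and k share exactly n - |j - k| samples
        plan = cx.build_null_plan(
            [f"f{i}" for i in range(16)], [f"m{i}" for i in range(16)], 8, rng
        )
        for j in range(len(plan)):
            for k in range(len(plan)):
                shared = len(set(plan.populations[j]) & set(plan.populations[k]))
                assert shared == 8 - abs(j - k)

    def test_small_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="pool"):
            cx.build_null_plan(list("abcd"), list("wxyz"), 5, rng)


class TestQuintilize:
    @pytest.mark.parametrize(
        "n_cols, expected_sizes",
        [(10, [2, 2, 2, 2, 2]), (11, [3, 2, 2, 2, 2]), (5, [1, 1, 1, 1, 1])],
    )
    def test_block_sizes(self, n_cols, expected_sizes):
        blocks = quintile_blocks(n_cols)
        sizes = [int((blocks == q).sum()) for q in range(5)]
        assert sizes == expected_sizes

    def test_constant_trajectory_gives_equal_medians(self):
        traj = SweepTrajectory(("g",), np.full((1, 10), 3.5))
        summary = cx.quintilize(traj)
        assert np.all(summary.medians == 3.5)

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="5 populations"):
            cx.quintilize(SweepTrajectory(("g",), np.ones((1, 4))))


class TestLog2Shift:
    @pytest.mark.parametrize(
        "q1, q5, expected", [(2.0, 8.0, 2.0), (4.0, 4.0, 0.0), (8.0, 2.0, -2.0)]
    )
    def test_known_ratios(self, q1, q5, expected):
        medians = np.array([[q1, 0, 0, 0, q5]])
        fc = cx.log2_shift(QuintileSummary(("g",), medians), epsilon=1e-6)
        assert fc[0] == pytest.approx(expected, abs=1e-5)

    def test_epsilon_guards_zero_medians(self):
        medians = np.zeros((1, 5))
        fc = cx.log2_shift(QuintileSummary(("g",), medians), epsilon=1e-6)
        assert fc[0] == 0.0


class TestCallIteration:
    @pytest.mark.parametrize(
        "fc, expected", [(1.2, "male"), (-1.5, "female"), (1.0, "none"),
                         (-1.0, "none"), (0.0, "none")],
    )
    def test_strict_threshold(self, fc, expected):
        assert cx.call_iteration(np.array([fc]), 1.0)[0] == expected


class TestSummarizeCalls:
    def test_inclusive_min_calls_boundary(self):
        fc = np.zeros((2, 100))
        fc[0, :20] = 1.5  # called in exactly 20 iterations
        fc[1, :19] = 1.5  # one short
        table = cx.summarize_calls(_log2fc_frame(fc, 100), 1.0, 20)
        assert table.loc[0, "is_sex_biased"]
        assert not table.loc[1, "is_sex_biased"]
        assert table.loc[0, "direction"] == "male"

    def test_majority_direction_and_ties(self, caplog):
        fc = np.zeros((2, 10))
        fc[0, :3] = 2.0
        fc[0, 3:8] = -2.0  # 3 male vs 5 female -> female
        fc[1, :2] = 2.0
        fc[1, 2:4] = -2.0  # 2 vs 2 -> tie
        with caplog.at_level("WARNING"):
            table = cx.summarize_calls(_log2fc_frame(fc, 10), 1.0, 2)
        assert table.loc[0, "direction"] == "female"
        assert table.loc[1, "direction"] == "none"
        assert "tied" in caplog.text


class TestRunSweep:
    def test_trajectory_shape_and_identical_populations(self, small_log):
        log, _, _ = small_log
        samples = tuple(log.columns[:10])
        plan = GradientPlan(populations=(samples,) * 6)
        traj = cx.run_sweep(log, plan)
        assert traj.values.shape == (log.shape[0], 6)
        assert np.allclose(traj.values, traj.values[:, [0]])

    def test_planted_gene_gains_connectivity_toward_male_end(self, small_log):
        log, metadata, truth = small_log
        females = metadata.loc[metadata.sex == "female", "sample_id"].tolist()
        males = metadata.loc[metadata.sex == "male", "sample_id"].tolist()
        hits = 0
        for seed in range(10):
            plan = cx.build_gradient_plan(
                females, males, 40, np.random.default_rng(seed)
            )
            traj = cx.run_sweep(log, plan)
            idx = [
                list(traj.gene_ids).index(g)
                for g in truth.module_genes("module1_male")
            ]
            hits += int(
                np.all(traj.values[idx, -1] > traj.values[idx, 0])
            )
        assert hits >= 9

    def test_reversing_the_plan_negates_log2fc(self, small_log):
        # with 40+1 -> use a 9-sample sweep (10 populations, symmetric blocks)
        log, metadata, _ = small_log
        females = metadata.loc[metadata.sex == "female", "sample_id"].tolist()
        males = metadata.loc[metadata.sex == "male", "sample_id"].tolist()
        plan = cx.build_gradient_plan(females, males, 9, np.random.default_rng(1))
        reverse = GradientPlan(populations=plan.populations[::-1])
        fc = cx.log2_shift(cx.quintilize(cx.run_sweep(log, plan)))
        fc_rev = cx.log2_shift(cx.quintilize(cx.run_sweep(log, reverse)))
        assert np.allclose(fc, -fc_rev, atol=1e-9)

    def test_missing_sample_rejected(self, small_log):
        log, _, _ = small_log
        plan = GradientPlan(populations=(("nope", "x", "y"),) * 4)
        with pytest.raises(ValueError, match="missing"):
            cx.run_sweep(log, plan)


class TestConsistencyAndNull:
    def test_bias_call_table_reproducible(self, small_log):
        log, metadata, _ = small_log
        config = cx.SweepConfig(n_iterations=4, min_calls=2, seed=123)
        r1 = cx.run_consistency(log, metadata, config)
        r2 = cx.run_consistency(log, metadata, config)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        pd.testing.assert_frame_equal(r1.log2fc, r2.log2fc)

    def test_planted_module_recovered(self, small_log):
        log, metadata, truth = small_log
        config = cx.SweepConfig(n_iterations=10, min_calls=8, seed=77)
        result = cx.run_consistency(log, metadata, config)
        table = result.table.set_index("gene")
        planted = truth.module_genes("module1_male")
        recalled = [
            g
            for g in planted
            if table.loc[g, "is_sex_biased"] and table.loc[g, "direction"] == "male"
        ]
        assert len(recalled) >= 8

    def test_null_counts_are_bounded_integers(self, small_log):
        log, metadata, _ = small_log
        config = cx.SweepConfig(n_iterations=5, min_calls=2, seed=3)
        null = cx.run_null(log, metadata, config)
        assert null.counts.dtype.kind == "i"
        assert np.all(null.counts >= 0)
        assert np.all(null.counts <= log.shape[0])
        assert null.lower <= null.upper

    def test_null_reproducible(self, small_log):
        log, metadata, _ = small_log
        config = cx.SweepConfig(n_iterations=4, min_calls=2, seed=55)
        n1 = cx.run_null(log, metadata, config)
        n2 = cx.run_null(log, metadata, config)
        assert np.array_equal(n1.counts, n2.counts)

    def test_threshold_pass_counts_shape(self, small_log):
        log, metadata, _ = small_log
        config = cx.SweepConfig(n_iterations=3, min_calls=2, seed=5)
        result = cx.run_consistency(log, metadata, config)
        counts = cx.threshold_pass_counts(result, 1.0)
        assert counts.shape == (3,)
        assert np.all(counts >= 0)


@pytest.fixture(scope="module")
def menopause_data():
    config = cx.SimulationConfig(
        n_females=120,
        n_males=5,
        n_background_genes=75,
        modules=(cx.ModuleSpec(25, "premenopause_female", rho_on=0.9),),
        age_weights={"40-49": 0.5, "50-59": 0.5},
        seed=21,
    )
    expr, metadata, truth = cx.generate_dataset(config)
    return cx.log_transform(expr), metadata, truth


class TestMenopauseSweep:
    def test_premenopause_module_recovered(self, menopause_data):
        log, metadata, truth = menopause_data
        config = cx.SweepConfig(
            population_size=45, n_iterations=25, min_calls=20, seed=8
        )
        result, _ = cx.menopause_sweep(log, metadata, config)
        table = result.table.set_index("gene")
        planted = truth.module_genes("module1_premenopause_female")
        recall = np.mean([table.loc[g, "is_sex_biased"] for g in planted])
        assert recall >= 0.8
        assert set(result.table["direction"]) <= {
            "premenopause", "postmenopause", "none"
        }

    def test_overlap_fraction_extremes(self, menopause_data):
        log, metadata, _ = menopause_data
        config = cx.SweepConfig(
            population_size=45, n_iterations=5, min_calls=4, seed=9
        )
        result, frac_disjoint = cx.menopause_sweep(
            log, metadata, config, sex_biased_genes=["not_a_gene"]
        )
        assert frac_disjoint == 0.0
        affected = result.biased_genes
        if affected:
            _, frac_identical = cx.menopause_sweep(
                log, metadata, config, sex_biased_genes=affected
            )
            assert frac_identical == 1.0

    def test_group_too_small_rejected(self, menopause_data):
        log, metadata, _ = menopause_data
        config = cx.SweepConfig(population_size=200, n_iterations=2, min_calls=1)
        with pytest.raises(ValueError, match="required"):
            cx.menopause_sweep(log, metadata, config)


def test_sweep_config_validation():
    with pytest.raises(ValueError, match="min_calls"):
        cx.SweepConfig(n_iterations=10, min_calls=20)
    with pytest.raises(ValueError, match="log2fc_threshold"):
        cx.SweepConfig(log2fc_threshold=0.0)
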