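import numpy as np
import pytest

from apf2 import (
    AlgorithmSpec,
    Direction,
    Strictness,
    analytic_optimal_threshold,
    candidate_thresholds,
    crossvalidate_threshold,
    default_config,
    get_algorithm,
    kfold_partition,
    optimize_threshold,
    simulate_labeled_scores,
)
from conftest import exhaustive_best_threshold, youden_oracle

HIGH = Direction.DELETERIOUS_IF_HIGH
SPEC_HIGH = AlgorithmSpec("toy", HIGH, Strictness.STRICT, 0.5)
SPEC_LOW = AlgorithmSpec("toy-low", Direction.DELETERIOUS_IF_LOW, Strictness.NON_STRICT, 0.5)


class TestCandidates:
    def test_midpoints_with_half_gap_ends(self):
        assert candidate_thresholds([1, 2, 3]).tolist() == [0.5, 1.5, 2.5, 3.5]

    def test_degenerate_single_value(self):
        assert candidate_thresholds([2.0, 2.0]).tolist() == [1.5, 2.5]

    def test_n_distinct_scores_give_n_plus_1_candidates(self):
        rng = np.random.default_rng(0)
        scores = rng.choice(np.linspace(0, 1, 40), size=100)
        n_distinct = len(np.unique(scores))
        assert len(candidate_thresholds(scores)) == n_distinct + 1


class TestOptimize:
    def test_perfect_separation_reaches_j_of_1(self):
        scores = np.r_[np.full(5, 0.1), np.full(5, 0.9)]
        truth = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        fit = optimize_threshold(scores, truth, SPEC_LOW)
        assert fit.J_optimized == 1.0
        assert 0.1 < fit.optimized_threshold < 0.9

    def test_twelve_point_toy_matches_exhaustive_scan(self):
        scores = np.array([0.1, 0.2, 0.25, 0.3, 0.42, 0.45, 0.5, 0.6, 0.61, 0.7, 0.8, 0.95])
        truth = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1], bool)
        fit = optimize_threshold(scores, truth, SPEC_HIGH)
        best_j, argmaxes = exhaustive_best_threshold(
            scores, truth, HIGH, Strictness.STRICT, candidate_thresholds(scores)
        )
        assert fit.J_optimized == pytest.approx(best_j)
        assert fit.optimized_threshold in argmaxes

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(10, 400))
            truth = rng.random(n) < rng.uniform(0.2, 0.8)
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.normal(truth * 0.8, 1.0), 2)
            fit = optimize_threshold(scores, truth, SPEC_HIGH)
            best_j, _ = exhaustive_best_threshold(
                scores, truth, HIGH, Strictness.STRICT, candidate_thresholds(scores)
            )
            assert fit.J_optimized == pytest.approx(best_j)
            # the returned cutoff actually achieves that J
            assert youden_oracle(
                scores, truth, fit.optimized_threshold, HIGH, Strictness.STRICT
            ) == pytest.approx(best_j)

    def test_optimized_never_below_conventional_on_fitting_data(self):
        rng = np.random.default_rng(22)
        for seed in range(10):
            scores = rng.normal(size=80)
            truth = rng.random(80) < 0.5
            if truth.all() or not truth.any():
                continue
            fit = optimize_threshold(scores, truth, SPEC_HIGH)
            assert fit.J_optimized >= fit.J_conventional - 1e-12

    def test_affine_equivariance(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=120)
        truth = rng.random(120) < 0.5
        fit = optimize_threshold(scores, truth, SPEC_HIGH)
        a, b = 2.5, -3.0
        spec2 = AlgorithmSpec("toy", HIGH, Strictness.STRICT, 0.5 * a + b)
        fit2 = optimize_threshold(a * scores + b, truth, spec2)
        assert fit2.optimized_threshold == pytest.approx(
            a * fit.optimized_threshold + b
        )
        assert fit2.J_optimized == pytest.approx(fit.J_optimized)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            optimize_threshold([0.1, 0.2], [True, True], SPEC_HIGH)

    def test_null_labels_keep_optimized_j_small(self):
        rng = np.random.default_rng(24)
        scores = rng.normal(size=5000)
        truth = rng.permutation([True] * 2500 + [False] * 2500)
        fit = optimize_threshold(scores, truth, SPEC_HIGH)
        assert fit.J_optimized <= 0.08


class TestKfold:
    def test_530_variants_split_into_equal_folds(self):
        a = kfold_partition(530, 5, seed=1)
        sizes = np.bincount(a, minlength=5)
        assert sizes.tolist() == [106] * 5

    def test_reproducible_and_sizes_within_one(self):
        labels = np.r_[np.ones(4, bool), np.zeros(3, bool)]
        a = kfold_partition(7, 5, seed=3, labels=labels)
        b = kfold_partition(7, 5, seed=3, labels=labels)
        assert (a == b).all()
        sizes = np.bincount(a, minlength=5)
        assert sorted(sizes.tolist()) == [1, 1, 1, 2, 2]

    def test_stratification_balances_classes(self):
        rng = np.random.default_rng(4)
        labels = rng.random(200) < 0.3
        a = kfold_partition(200, 5, seed=9, labels=labels)
        per_fold = [labels[a == f].sum() for f in range(5)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_n_smaller_than_k_raises(self):
        with pytest.raises(ValueError):
            kfold_partition(3, 5, seed=1)


class TestCrossValidation:
    def test_separable_data_thresholds_lie_in_gap(self, study_data):
        cfg, table, labels = study_data
        # build a perfectly separable toy on top of the study variants
        import pandas as pd
        from apf2 import ScoreTable

        truth = labels.is_deleterious().to_numpy()
        scores = np.where(truth, 0.1, 0.9) + np.random.default_rng(1).normal(
            0, 0.01, len(truth)
        )
        ids = [v.id for v in labels.variants]
        t = ScoreTable(
            list(labels.variants),
            pd.DataFrame({"toy-low": scores}, index=pd.Index(ids, name="variant")),
        )
        # conventional cutoff below all scores -> everything called
        # functional, so the optimized cutoff must improve J on held-out data
        bad_conventional = AlgorithmSpec(
            "toy-low", Direction.DELETERIOUS_IF_LOW, Strictness.NON_STRICT, 0.02
        )
        cv = crossvalidate_threshold(t, labels, bad_conventional, k=5, seed=2)
        for fold in cv.folds:
            assert 0.15 < fold.train_threshold < 0.85
            assert fold.val_delta_J > 0
        assert cv.final_fit.J_optimized == 1.0

    def test_folds_partition_the_set(self, study_data):
        cfg, table, labels = study_data
        spec = get_algorithm("VEST4")
        cv = crossvalidate_threshold(table, labels, spec, k=5, seed=7)
        assert cv.k == 5 and len(cv.folds) == 5
        for fold in cv.folds:
            assert np.isfinite(fold.val_delta_J)

    def test_leave_one_out_degenerate_runs(self):
        rng = np.random.default_rng(12)
        from apf2 import LabeledVariantSet, ScoreTable, VariantKey
        import pandas as pd

        n = 8
        variants = [VariantKey(gene="G", protein_change=f"p.A{i}V") for i in range(n)]
        truth = np.array([1, 0] * 4, bool)
        t = ScoreTable(
            variants,
            pd.DataFrame(
                {"toy": rng.normal(truth, 0.5)},
                index=pd.Index([v.id for v in variants], name="variant"),
            ),
        )
        labels = LabeledVariantSet(
            variants, ["deleterious" if x else "neutral" for x in truth]
        )
        cv = crossvalidate_threshold(t, labels, SPEC_HIGH, k=n, seed=1)
        assert len(cv.folds) == n


class TestParameterRecovery:
    def test_equal_variance_gaussians_recover_midpoint(self):
        # two Gaussian classes, equal scale: the J-optimal cutoff tends
        # to the midpoint of the means as n grows
        from apf2 import AlgorithmSim, SimulationConfig

        sim = AlgorithmSim(
            "toy", HIGH,
            deleterious_loc=0.8, deleterious_scale=0.3,
            neutral_loc=0.2, neutral_scale=0.3,
        )
        cfg = SimulationConfig(
            n_deleterious=10_000, n_neutral=10_000,
            algorithms=(sim,), n_consortium=0, seed=31,
        )
        table, labels = simulate_labeled_scores(cfg)
        fit = optimize_threshold(
            table.scores["toy"].to_numpy(),
            labels.is_deleterious().to_numpy(),
            AlgorithmSpec("toy", HIGH, Strictness.STRICT, 0.5),
        )
        assert fit.optimized_threshold == pytest.approx(0.5, abs=0.05)
        assert analytic_optimal_threshold(cfg, "toy") == 0.5
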