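import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apf2 import (
    Apf2Result,
    Direction,
    EnsembleModel,
    ThresholdFit,
    apf2_score,
    classify,
    default_model,
    fit_activity_map,
    fit_ensemble,
    predict_activity,
    score_table,
)

HIGH = Direction.DELETERIOUS_IF_HIGH
LOW = Direction.DELETERIOUS_IF_LOW


def component_scores(model, votes):
    """Raw per-algorithm scores realizing a given functional-vote pattern.

    vote 1 -> a score on the functional side of the component's cutoff,
    vote 0 -> deleterious side, None -> missing.
    """
    out = {}
    for (spec, _), v in zip(model.components, votes):
        if v is None:
            out[spec.name] = np.nan
            continue
        delta = 1.0 if spec.direction is HIGH else -1.0
        # deleterious side is threshold + delta, functional side is - delta
        out[spec.name] = spec.threshold + (-delta if v else delta)
    return out


class TestDefaultModel:
    def test_shipped_components_and_cutoffs(self):
        model = default_model()
        thr = {s.name: s.threshold for s, _ in model.components}
        assert thr == {
            "AlphaMissense": 0.152,
            "PROVEAN": -3.2925,
            "MutationAssessor": 2.08,
            "PolyPhen-2": 0.42,
            "VEST4": 0.2905,
        }
        assert model.cutoff == 0.367
        assert model.min_components == 3
        weights = [w for _, w in model.components]
        assert sum(weights) == pytest.approx(1.0)

    def test_serialization_roundtrip(self, tmp_path):
        model = default_model()
        p = tmp_path / "model.json"
        model.save(p)
        assert EnsembleModel.load(p) == model


class TestClassify:
    def test_cutoff_boundary(self):
        assert classify(0.367) == "deleterious"
        assert classify(0.368) == "neutral"
        assert classify(0.0, cutoff=0.367) == "deleterious"

    def test_score_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify(1.2)


class TestApf2Score:
    def test_unanimous_votes_hit_bounds(self):
        model = default_model()
        res0 = apf2_score(component_scores(model, [0] * 5), model)
        res1 = apf2_score(component_scores(model, [1] * 5), model)
        assert res0.score == 0.0 and res0.call == "deleterious"
        assert res1.score == 1.0 and res1.call == "neutral"

    def test_monotone_in_single_vote_flips(self):
        model = default_model()
        for votes in itertools.product([0, 1], repeat=5):
            base = apf2_score(component_scores(model, votes), model).score
            for i, v in enumerate(votes):
                if v == 1:
                    continue
                flipped = list(votes)
                flipped[i] = 1
                up = apf2_score(component_scores(model, flipped), model).score
                assert up >= base

    def test_weight_renormalization_under_missingness(self):
        model = default_model()
        weights = {s.name: w for s, w in model.components}
        for missing in itertools.chain.from_iterable(
            itertools.combinations(range(5), k) for k in (0, 1, 2)
        ):
            votes = [None if i in missing else 1 for i in range(5)]
            res = apf2_score(component_scores(model, votes), model)
            assert res.n_components_used == 5 - len(missing)
            assert res.score == pytest.approx(1.0)  # all available vote functional
            # mixed votes: functional weight mass over remaining mass
            votes = [None if i in missing else (1 if i % 2 else 0) for i in range(5)]
            res = apf2_score(component_scores(model, votes), model)
            avail = [i for i in range(5) if i not in missing]
            names = [model.components[i][0].name for i in avail]
            wsum = sum(weights[n] for n in names)
            expected = sum(
                weights[model.components[i][0].name] / wsum
                for i in avail
                if i % 2
            )
            assert res.score == pytest.approx(expected)

    def test_no_call_below_min_components(self):
        model = default_model()
        votes = [1, 1, None, None, None]
        res = apf2_score(component_scores(model, votes), model)
        assert res.call == "no_call"
        assert res.score is None
        assert res.n_components_used == 2

    def test_equal_weights_reduce_to_vote_fraction(self):
        model = default_model()
        eq = EnsembleModel(
            components=tuple((s, 1 / 5) for s, _ in model.components),
            cutoff=model.cutoff,
            weighting="uniform",
        )
        for votes in itertools.product([0, 1], repeat=5):
            res = apf2_score(component_scores(eq, votes), eq)
            assert res.score == pytest.approx(sum(votes) / 5)

    @given(st.lists(st.sampled_from([0, 1, None]), min_size=5, max_size=5))
    @settings(deadline=None, derandomize=True)
    def test_score_bounded_or_no_call(self, votes):
        model = default_model()
        res = apf2_score(component_scores(model, votes), model)
        if res.score is not None:
            assert 0.0 <= res.score <= 1.0
            assert res.call == ("deleterious" if res.score <= 0.367 else "neutral")
        else:
            assert res.call == "no_call"


class TestFitEnsemble:
    def _fit(self, name, j, direction=HIGH):
        return ThresholdFit(
            algorithm=name, optimized_threshold=0.5, direction=direction,
            J_conventional=0.1, J_optimized=j, sensitivity=0.8, specificity=0.8,
        )

    def test_j_proportional_weights(self):
        fits = [self._fit("A", 0.4), self._fit("B", 0.4), self._fit("C", 0.2)]
        model = fit_ensemble(None, None, fits)
        assert [w for _, w in model.components] == pytest.approx([0.4, 0.4, 0.2])

    def test_equal_j_gives_equal_weights(self):
        model = fit_ensemble(None, None, [self._fit("A", 0.3), self._fit("B", 0.3)])
        assert [w for _, w in model.components] == pytest.approx([0.5, 0.5])

    def test_non_positive_j_component_excluded_with_warning(self):
        fits = [self._fit("A", 0.4), self._fit("B", -0.1), self._fit("C", 0.2)]
        with pytest.warns(UserWarning, match="B"):
            model = fit_ensemble(None, None, fits)
        assert model.algorithms == ["A", "C"]
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            fit_ensemble(None, None, [self._fit("A", 0.4), self._fit("B", 0.0)])

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            fit_ensemble(None, None, [self._fit("A", 0.5)])


class TestActivityMap:
    def _results(self, scores):
        return {f"v{i}": s for i, s in enumerate(scores)}

    def test_linear_activities_give_r2_of_1(self):
        rng = np.random.default_rng(41)
        scores = rng.random(200)
        activities = {f"v{i}": 10 + 80 * s for i, s in enumerate(scores)}
        amap = fit_activity_map(self._results(scores), activities)
        # bin means of a linear function of score are approximately the
        # line at the bin-mean score, not exactly at the midpoint
        assert amap.r_squared > 0.99
        assert amap.slope == pytest.approx(80, rel=0.1)

    def test_exactly_linear_bin_means(self):
        # one variant per bin midpoint -> bin means sit exactly on the line
        mids = np.array([1, 3, 5, 7, 9, 11, 13]) / 14
        activities = {f"v{i}": 5 + 90 * m for i, m in enumerate(mids)}
        amap = fit_activity_map(self._results(mids), activities)
        assert amap.r_squared == pytest.approx(1.0)
        assert amap.intercept == pytest.approx(5.0)
        for m, mean in zip(amap.bin_midpoints, amap.bin_mean_activity):
            assert predict_activity(m, amap) == pytest.approx(mean)

    def test_constant_activities_give_zero_slope(self):
        scores = np.linspace(0, 1, 50)
        activities = {f"v{i}": 70.0 for i in range(50)}
        amap = fit_activity_map(self._results(scores), activities)
        assert amap.slope == 0.0
        assert amap.r_squared == 0.0

    def test_null_activities_rarely_significant(self):
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            scores = rng.random(500)
            activities = {f"v{i}": rng.uniform(0, 120) for i in range(500)}
            amap = fit_activity_map(self._results(scores), activities)
            rejections += amap.p_value <= 0.05
        assert rejections <= 10  # slope p > 0.05 in >=90% of replicates

    def test_prediction_clamped_to_observed_range(self):
        scores = np.linspace(0, 1, 30)
        activities = {f"v{i}": max(0.0, 100 * s - 20) for i, s in enumerate(scores)}
        amap = fit_activity_map(self._results(scores), activities)
        assert predict_activity(0.0, amap) >= 0.0
        assert predict_activity(1.0, amap) <= amap.max_activity

    def test_monotone_map_predicts_monotonically(self):
        scores = np.linspace(0, 1, 40)
        activities = {f"v{i}": 100 * s for i, s in enumerate(scores)}
        amap = fit_activity_map(self._results(scores), activities)
        grid = np.linspace(0, 1, 101)
        preds = [predict_activity(g, amap) for g in grid]
        assert (np.diff(preds) >= -1e-12).all()

    def test_too_few_bins_raise(self):
        with pytest.raises(ValueError):
            fit_activity_map({"v0": 0.1, "v1": 0.11, "v2": 0.9},
                             {"v0": 10, "v1": 12, "v2": 90})


class TestEndToEnd:
    def test_ensemble_does_not_degrade_dominant_component(self, study_data):
        from apf2 import auc, benchmark, crossvalidate_threshold, get_algorithm

        cfg, table, labels = study_data
        reports = benchmark(table, labels)
        best_single = max(r.AUC for r in reports.values())
        fits = [
            crossvalidate_threshold(table, labels, get_algorithm(a), seed=5)
            for a in table.algorithms
        ]
        model = fit_ensemble(table, labels, fits)
        calls = score_table(table, model)
        ok = calls["apf2_score"].notna()
        truth = labels.is_deleterious().reindex(calls.index[ok]).to_numpy()
        ens_auc = auc(calls.loc[ok, "apf2_score"].to_numpy(), truth, LOW)
        assert ens_auc >= best_single - 0.02
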