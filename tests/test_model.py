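import numpy as np
import pandas as pd
import pytest

from catnip.features import PairFeatureTable
from catnip.model import (
    CatnipModel,
    cross_validate,
    downsample_majority,
    evaluate,
    grid_search,
    make_folds,
    probability_to_score,
    score_to_probability,
    train,
)


def make_table(n=200, informative=True, seed=0, registry=("f0", "f1")):
    """Toy pair table: f0 separates classes when informative, f1 is noise."""
    rng = np.random.default_rng(seed)
    y = rng.random(n) < 0.3
    f0 = np.where(y, 1.0, 0.0) + rng.normal(0, 0.05, n) if informative else rng.normal(size=n)
    f1 = rng.normal(size=n)
    idx = pd.MultiIndex.from_tuples(
        [(f"A{i}", f"B{i}") for i in range(n)], names=["drug_a", "drug_b"]
    )
    feats = pd.DataFrame({"f0": f0, "f1": f1}, index=idx)[list(registry)]
    return PairFeatureTable(feats, pd.Series(y, index=idx), feats.notna(), list(registry))


class TestFolds:
    def test_partition_sizes(self):
        folds = make_folds([True, False] * 5, k=5, seed=0)
        assert sorted(np.bincount(folds)) == [2, 2, 2, 2, 2]

    def test_reproducible(self):
        y = [True] * 10 + [False] * 30
        assert np.array_equal(make_folds(y, seed=3), make_folds(y, seed=3))
        assert not np.array_equal(make_folds(y, seed=3), make_folds(y, seed=4))

    def test_stratified(self):
        y = np.array([True] * 20 + [False] * 80)
        folds = make_folds(y, k=5, seed=1)
        for f in range(5):
            assert y[folds == f].sum() == 4

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            make_folds([True, False], k=5)


class TestDownsample:
    def test_majority_to_minority(self):
        y = np.array([True] * 10 + [False] * 100)
        idx = downsample_majority(y, seed=0)
        assert len(idx) == 20
        assert y[idx].sum() == 10

    def test_balanced_identity_size(self):
        y = np.array([True, False] * 10)
        assert len(downsample_majority(y, seed=0)) == 20

    def test_seed_stable_and_single_class_error(self):
        y = np.array([True] * 5 + [False] * 50)
        assert np.array_equal(downsample_majority(y, seed=7), downsample_majority(y, seed=7))
        with pytest.raises(ValueError):
            downsample_majority([True, True])


class TestTrain:
    def test_separable_training_auc_one(self):
        t = make_table(informative=True)
        model = train(t, seed=0)
        rep = evaluate(model.score(t.features), t.labels)
        assert rep.auc == pytest.approx(1.0, abs=1e-6)

    def test_reproducible_under_seed(self):
        t = make_table()
        s1 = train(t, seed=5).score(t.features)
        s2 = train(t, seed=5).score(t.features)
        assert np.array_equal(s1, s2)

    def test_non_finite_rejected(self):
        t = make_table(n=50)
        t.features.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train(t)

    def test_label_shuffled_cv_auc_near_half(self):
        t = make_table(n=400, informative=True, seed=2)
        rng = np.random.default_rng(0)
        t.labels = pd.Series(
            rng.permutation(t.labels.to_numpy()), index=t.labels.index
        )
        scores, _, _ = cross_validate(t, k=5, seed=0)
        assert evaluate(scores, t.labels).auc == pytest.approx(0.5, abs=0.1)

    def test_wrong_dimensionality_rejected(self):
        t = make_table(n=50)
        model = train(t, seed=0)
        with pytest.raises(ValueError):
            model.score(np.zeros((3, 5)))

    def test_save_load_round_trip(self, tmp_path):
        t = make_table(n=80)
        model = train(t, seed=1)
        model.save(tmp_path / "m.ubj")
        back = CatnipModel.load(tmp_path / "m.ubj")
        assert back.registry == model.registry
        assert np.allclose(back.score(t.features), model.score(t.features))
        pd.testing.assert_series_equal(back.medians, model.medians, check_names=False)


class TestGridSearch:
    def test_single_point(self):
        t = make_table(n=60)
        point = {"learning_rate": [0.1], "max_depth": [3], "n_rounds": [20]}
        assert grid_search(t, point, k=3) == {
            "learning_rate": 0.1, "max_depth": 3, "n_rounds": 20,
        }

    def test_degenerate_learner_loses_to_sane_one(self):
        t = make_table(n=150, informative=True)
        grid = {"n_rounds": [0, 30], "max_depth": [2]}
        best = grid_search(t, grid, k=3, seed=0)
        assert best["n_rounds"] == 30

    def test_empty_grid_error(self):
        with pytest.raises(ValueError):
            grid_search(make_table(n=30), {}, k=2)

    def test_deterministic(self):
        t = make_table(n=100)
        grid = {"n_rounds": [10, 20], "max_depth": [2, 3]}
        assert grid_search(t, grid, k=3, seed=4) == grid_search(t, grid, k=3, seed=4)


class TestLogisticTransform:
    def test_fixed_points(self):
        assert score_to_probability(0.0) == pytest.approx(0.5)
        assert score_to_probability(7.4) > 0.99
        assert score_to_probability(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_increasing_and_round_trip(self):
        s = np.linspace(-20, 20, 201)
        p = score_to_probability(s)
        assert np.all(np.diff(p) > 0)
        assert np.allclose(probability_to_score(p), s, atol=1e-9)

    def test_score_monotone_with_probability(self):
        t = make_table(n=80)
        model = train(t, seed=0)
        s = model.score(t.features)
        assert np.allclose(score_to_probability(s), model.predict_proba(t.features), atol=1e-6)


class TestEvaluate:
    def test_perfect_ranking(self):
        rep = evaluate([0.1, 0.2, 0.9, 0.95], [False, False, True, True])
        assert rep.auc == 1.0 and rep.auprc == 1.0

    def test_random_scores_auprc_near_prevalence(self):
        rng = np.random.default_rng(0)
        n = 100_000
        y = rng.random(n) < 0.02
        rep = evaluate(rng.normal(size=n), y)
        assert rep.auprc == pytest.approx(0.02, abs=0.005)
        assert rep.auc == pytest.approx(0.5, abs=0.02)

    def test_all_negative_above_cutoff_fp_fraction_one(self):
        rep = evaluate([5.0, 5.0, -5.0], [False, False, True], prob_cutoffs=(0.5,))
        assert rep.fp_rates[0.5]["fp_fraction"] == 1.0

    def test_single_class_subset_undefined(self):
        rep = evaluate(
            [0.1, 0.9, 0.5], [False, True, False],
            subsets={"onlyneg": [True, False, True]},
        )
        assert rep.subset_aucs["onlyneg"] is None

    def test_subset_auc_on_filter(self):
        y = [False, True, False, True]
        s = [0.1, 0.9, 0.8, 0.2]
        rep = evaluate(s, y, subsets={"first_two": [True, True, False, False]})
        assert rep.subset_aucs["first_two"] == 1.0


class TestCrossValidate:
    def test_every_pair_scored_once_held_out(self):
        t = make_table(n=120)
        scores, folds, models = cross_validate(t, k=4, seed=0)
        assert len(scores) == 120 and not scores.isna().any()
        assert len(models) == 4
        assert set(np.unique(folds)) == {0, 1, 2, 3}

    def test_deterministic(self):
        t = make_table(n=100)
        s1, _, _ = cross_validate(t, k=4, seed=9)
        s2, _, _ = cross_validate(t, k=4, seed=9)
        pd.testing.assert_series_equal(s1, s2)

    def test_drug_level_grouping_has_no_drug_leak(self):
        from catnip.model import make_drug_level_folds

        # shared-drug pairs so grouping actually bites: pairs over 12 drugs
        drugs = [f"D{i}" for i in range(12)]
        idx = pd.MultiIndex.from_tuples(
            [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1 :]],
            names=["drug_a", "drug_b"],
        )
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"f0": rng.normal(size=len(idx)), "f1": rng.normal(size=len(idx))}, index=idx)
        from catnip.features import PairFeatureTable

        t = PairFeatureTable(feats, pd.Series(rng.random(len(idx)) < 0.5, index=idx),
                             feats.notna(), ["f0", "f1"])
        folds, drug_fold = make_drug_level_folds(idx, k=3, seed=1)
        for f in range(3):
            test_drugs = {d for pair, ff in zip(idx, folds) if ff == f for d in pair}
            assert all(drug_fold[d] == f for d in test_drugs)
        scores, folds_out, _ = cross_validate(t, k=3, seed=1, group_drugs=True)
        assert np.array_equal(folds, folds_out)
        assert scores[folds == -1].isna().all()
        assert scores[folds >= 0].notna().all()
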