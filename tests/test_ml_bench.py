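import numpy as np
import pandas as pd
import pytest

from graphmer.debruijn import FeatureMatrix, feature_names
from graphmer.fastq_io import CleanSample
from graphmer.ml_bench import (
    MODEL_FAMILIES,
    BenchConfig,
    ModelSpec,
    SplitSpec,
    evaluate,
    grid_search,
    run_benchmark,
    split,
    train_predict,
)
from graphmer.synthetic_cohort import CohortDesign, generate_cohort

from conftest import labeled_matrix

TINY_GRIDS = {
    "RF": {"n_estimators": [30]},
    "SVM": {"C": [1.0], "kernel": ["linear"]},
    "XGB": {"n_estimators": [30], "max_depth": [3]},
    "LGBM": {"n_estimators": [30], "min_child_samples": [5]},
    "GNB": {},
    "LR": {"C": [1.0]},
    "KNN": {"n_neighbors": [3]},
}


class TestSplit:
    def test_stratified_arithmetic(self, rng):
        fm = labeled_matrix(rng, n0=75, n1=25)
        train, test = split(fm, SplitSpec(seed=0))
        assert train.n_samples == 80 and test.n_samples == 20
        assert (train.labels == 0).sum() == 60 and (train.labels == 1).sum() == 20
        assert (test.labels == 0).sum() == 15 and (test.labels == 1).sum() == 5
        # disjoint and exhaustive
        assert set(train.sample_ids) | set(test.sample_ids) == set(fm.sample_ids)
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_deterministic_given_seed(self, rng):
        fm = labeled_matrix(rng, n0=30, n1=10)
        a = split(fm, SplitSpec(seed=7))
        b = split(fm, SplitSpec(seed=7))
        assert a[0].sample_ids == b[0].sample_ids
        assert a[1].sample_ids == b[1].sample_ids

    def test_unlabeled_rows_rejected(self, rng):
        fm = labeled_matrix(rng, n0=10, n1=10)
        fm.labels = None
        with pytest.raises(ValueError, match="labeled"):
            split(fm)

    def test_tiny_class_rejected(self, rng):
        fm = labeled_matrix(rng, n0=20, n1=1)
        with pytest.raises(ValueError, match="< 2 samples"):
            split(fm)


class TestGridSearch:
    def test_single_point_grid_is_identity(self, rng):
        fm = labeled_matrix(rng, n0=20, n1=20)
        spec = ModelSpec("KNN", {"n_neighbors": [5]})
        res = grid_search(spec, fm, folds=3, seed=0)
        assert res.best_params == {"n_neighbors": 5}
        assert len(res.cv_results) == 1

    def test_tie_broken_by_grid_order(self, rng):
        fm = labeled_matrix(rng, n0=20, n1=20)
        # duplicated point: identical scores, first occurrence must win
        spec = ModelSpec("KNN", {"n_neighbors": [5, 5]})
        res = grid_search(spec, fm, folds=3, seed=0)
        assert res.cv_results[0]["mean_cv_accuracy"] == res.cv_results[1][
            "mean_cv_accuracy"]
        assert res.best_params is res.cv_results[0]["params"] or (
            res.best_params == res.cv_results[0]["params"])

    def test_degenerate_point_excluded(self, rng):
        # k-NN with more neighbors than a fold's training rows cannot fit
        fm = labeled_matrix(rng, n0=6, n1=6)
        spec = ModelSpec("KNN", {"n_neighbors": [500, 3]})
        res = grid_search(spec, fm, folds=3, seed=0)
        assert res.best_params == {"n_neighbors": 3}
        assert len(res.failed_points) == 1
        assert res.failed_points[0]["params"] == {"n_neighbors": 500}

    def test_all_failed_grid_is_error(self, rng):
        fm = labeled_matrix(rng, n0=6, n1=6)
        spec = ModelSpec("KNN", {"n_neighbors": [500]})
        with pytest.raises(RuntimeError, match="every grid point failed"):
            grid_search(spec, fm, folds=3, seed=0)

    def test_bad_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search(ModelSpec("GNB"), labeled_matrix(rng), folds=1)


def _separable_matrix(rng, n=40):
    """One feature fully determines the label; the rest are noise."""
    fm = labeled_matrix(rng, n0=n // 2, n1=n // 2)
    fm.data.iloc[:, 0] = fm.labels.to_numpy() * 100
    return fm


class TestTrainPredict:
    def test_separable_data_perfect_rf(self, rng):
        fm = _separable_matrix(rng, n=60)
        train, test = split(fm, SplitSpec(seed=1))
        pred, score = train_predict("RF", {"n_estimators": 100}, train, test, seed=0)
        np.testing.assert_array_equal(pred, test.labels.to_numpy())
        assert len(score) == test.n_samples

    @pytest.mark.parametrize("family", ["RF", "GNB", "LR", "KNN"])
    def test_constant_features_predict_majority(self, rng, family):
        fm = labeled_matrix(rng, n0=30, n1=10)
        fm.data.iloc[:, :] = 1
        train, test = split(fm, SplitSpec(seed=2))
        pred, _ = train_predict(family, {}, train, test, seed=0)
        assert (pred == 0).all()  # class 0 is the training majority

    def test_deterministic_given_seed(self, rng):
        fm = labeled_matrix(rng, n0=25, n1=25)
        train, test = split(fm, SplitSpec(seed=3))
        p1, s1 = train_predict("RF", {"n_estimators": 30}, train, test, seed=5)
        p2, s2 = train_predict("RF", {"n_estimators": 30}, train, test, seed=5)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(s1, s2)

    def test_svm_scores_are_decision_values(self, rng):
        fm = _separable_matrix(rng)
        train, test = split(fm, SplitSpec(seed=1))
        _, score = train_predict("SVM", {"kernel": "linear"}, train, test)
        assert score.min() < 0 < score.max()  # signed margin, not probability


class TestEvaluate:
    def test_perfect_classifier(self):
        rep = evaluate([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (rep.accuracy, rep.precision, rep.fscore, rep.kappa, rep.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        # confusion tn=1 fp=1 fn=1 tp=1 -> accuracy .5, kappa 0
        rep = evaluate([1, 0, 1, 0], [0.6, 0.4, 0.6, 0.4], [1, 1, 0, 0])
        assert rep.accuracy == 0.5
        assert rep.kappa == 0.0
        assert (rep.tn, rep.fp, rep.fn, rep.tp) == (1, 1, 1, 1)

    def test_tied_scores_give_half_auc(self):
        rep = evaluate([1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0])
        assert rep.auc == 0.5

    def test_single_class_truth_warns(self):
        with pytest.warns(UserWarning, match="AUC"):
            rep = evaluate([1, 1], [0.9, 0.8], [1, 1])
        assert rep.auc is None

    def test_metrics_recoverable_from_confusion_counts(self, rng):
        truth = rng.integers(0, 2, size=60)
        pred = rng.integers(0, 2, size=60)
        rep = evaluate(pred, rng.random(60), truth)
        n = rep.tn + rep.fp + rep.fn + rep.tp
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / n)
        p_o = (rep.tp + rep.tn) / n
        p_e = ((rep.tp + rep.fp) * (rep.tp + rep.fn)
               + (rep.tn + rep.fn) * (rep.tn + rep.fp)) / n**2
        assert rep.kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_auc_matches_all_pairs_count(self, rng):
        truth = np.array([1] * 8 + [0] * 12)
        score = rng.random(20)
        score[3] = score[15]  # force a tie across classes
        rep = evaluate((score > 0.5).astype(int), score, truth)
        wins = sum(
            1.0 if sp > sn else 0.5 if sp == sn else 0.0
            for sp in score[truth == 1] for sn in score[truth == 0]
        )
        assert rep.auc == pytest.approx(wins / (8 * 12))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [0.5, 0.5, 0.5], [1, 0, 1])


@pytest.fixture(scope="module")
def tiny_cohort():
    design = CohortDesign(n_per_class=15, reads_per_sample=40, read_length=60,
                          order=2, delta=0.15, seed=13)
    return generate_cohort(design)


class TestRunBenchmark:
    def test_report_structure_and_pairing(self, tiny_cohort):
        config = BenchConfig(ks=[2, 3], folds=3, grids=TINY_GRIDS,
                             split=SplitSpec(seed=42))
        result = run_benchmark(tiny_cohort, config)
        assert set(result.reports) == {2, 3}
        for k in (2, 3):
            assert set(result.reports[k]) == set(MODEL_FAMILIES)
            preds = result.predictions[k]
            # paired: every model scored the identical test rows in order
            ids_by_model = [
                grp["sample_id"].tolist()
                for _, grp in preds.groupby("model", sort=False)
            ]
            assert all(ids == ids_by_model[0] for ids in ids_by_model)
            assert len(ids_by_model[0]) == 6  # 20% of 30

    def test_benchmark_is_reproducible(self, tiny_cohort):
        config = BenchConfig(ks=[2], folds=3, grids=TINY_GRIDS)
        r1 = run_benchmark(tiny_cohort, config)
        r2 = run_benchmark(tiny_cohort, config)
        assert r1.to_json_dict() == r2.to_json_dict()
        pd.testing.assert_frame_equal(r1.predictions[2], r2.predictions[2])

    def test_empty_ks_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="nonempty"):
            run_benchmark(tiny_cohort, BenchConfig(ks=[]))

    def test_save_writes_reports_and_predictions(self, tiny_cohort, tmp_path):
        config = BenchConfig(ks=[2], folds=3, grids=TINY_GRIDS)
        result = run_benchmark(tiny_cohort, config)
        result.save(tmp_path)
        assert (tmp_path / "report.json").exists()
        metrics = pd.read_csv(tmp_path / "metrics.csv")
        assert set(metrics["metric"]) == {
            "accuracy", "precision", "fscore", "kappa", "auc"}
        for fam in MODEL_FAMILIES:
            f = tmp_path / f"predictions_k2_{fam}.csv"
            assert f.exists()
            df = pd.read_csv(f)
            assert list(df.columns) == ["sample_id", "truth", "pred", "score"]
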