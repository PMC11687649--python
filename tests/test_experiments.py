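"""Classifier experiments: tuning, metrics, designs, summaries, embedding."""

import numpy as np
import pandas as pd
import pytest

from healthycore.core import CoreConfig, select_healthy_core
from healthycore.datamodel import ConfigurationError, DataError
from healthycore.experiments import (
    ExperimentSpec,
    embed_diagnostic,
    evaluate,
    fit_classifier,
    round_half_up,
    run_experiment,
    summarize,
)
from healthycore.io import split_by
from healthycore.optimize import Dimension, maximize
from healthycore.synthetic import SyntheticConfig, generate_two_site_study

from conftest import make_table


def separable_data(rng, n=60, d=8, gap=6.0):
    X = np.vstack([rng.standard_normal((n // 2, d)),
                   rng.standard_normal((n // 2, d)) + gap / np.sqrt(d)])
    y = np.repeat([0, 1], n // 2)
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestOptimizer:
    def test_deterministic(self):
        space = [Dimension("x", 0.0, 1.0), Dimension("k", 1, 10, integer=True)]

        def f(p):
            return -(p["x"] - 0.3) ** 2 - 0.01 * p["k"]

        r1 = maximize(f, space, budget=12, seed=3)
        r2 = maximize(f, space, budget=12, seed=3)
        assert r1.best_params == r2.best_params
        assert r1.best_score == r2.best_score

    def test_finds_near_optimum_in_1d(self):
        space = [Dimension("x", 0.0, 1.0)]
        res = maximize(lambda p: -(p["x"] - 0.62) ** 2, space, budget=25, seed=0)
        assert abs(res.best_params["x"] - 0.62) < 0.1

    def test_budget_floor(self):
        with pytest.raises(ConfigurationError):
            maximize(lambda p: 0.0, [Dimension("x", 0, 1)], budget=4)

    def test_log_and_integer_decoding(self):
        d = Dimension("c", 1e-3, 1e3, log=True)
        assert d.decode(0.0) == pytest.approx(1e-3)
        assert d.decode(1.0) == pytest.approx(1e3)
        assert d.decode(0.5) == pytest.approx(1.0)
        k = Dimension("n", 10, 20, integer=True)
        assert isinstance(k.decode(0.31), int)


class TestFitClassifier:
    def test_separable_case_high_validation_auc(self, rng):
        X, y = separable_data(rng)
        model, params, val_auc = fit_classifier(
            "l1_logreg", X[:40], y[:40], X[40:], y[40:], tuning_budget=6, seed=0
        )
        assert val_auc >= 0.99
        assert "C" in params

    def test_null_labels_chance_auc(self):
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.standard_normal((80, 6))
            y = r.integers(0, 2, 80)
            while len(np.unique(y[:40])) < 2 or len(np.unique(y[40:60])) < 2:
                y = r.integers(0, 2, 80)
            model, _, _ = fit_classifier(
                "l1_logreg", X[:40], y[:40], X[40:60], y[40:60],
                tuning_budget=5, seed=seed,
            )
            row = evaluate(model, X[60:], y[60:])
            if row.auc is not None:
                aucs.append(row.auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.12

    def test_same_seed_same_hyperparameters(self, rng):
        X, y = separable_data(rng, gap=2.0)
        _, p1, _ = fit_classifier("xgboost", X[:40], y[:40], X[40:], y[40:],
                                  tuning_budget=6, seed=4)
        _, p2, _ = fit_classifier("xgboost", X[:40], y[:40], X[40:], y[40:],
                                  tuning_budget=6, seed=4)
        assert p1 == p2

    def test_single_class_split_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(DataError):
            fit_classifier("svm", X, np.zeros(20), X, np.zeros(20))


class _FixedScores:
    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.scores, self.scores])


class TestEvaluate:
    def test_confusion_hand_arithmetic(self):
        # TP=8, FN=2, TN=9, FP=1
        y = np.array([1] * 10 + [0] * 10)
        scores = np.array([0.9] * 8 + [0.1] * 2 + [0.2] * 9 + [0.8] * 1)
        row = evaluate(_FixedScores(scores), np.zeros((20, 1)), y)
        assert row.sensitivity == pytest.approx(0.8)
        assert row.specificity == pytest.approx(0.9)
        assert row.accuracy == pytest.approx(0.85)
        assert row.f1 == pytest.approx(2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8), abs=1e-9)
        assert (row.tp, row.fn, row.tn, row.fp) == (8, 2, 9, 1)

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        row = evaluate(_FixedScores([0.1, 0.2, 0.8, 0.9]), np.zeros((4, 1)), y)
        assert row.auc == 1.0
        assert row.accuracy == row.sensitivity == row.specificity == row.f1 == 1.0

    def test_constant_scores_chance_auc(self):
        y = np.array([0, 1, 0, 1])
        row = evaluate(_FixedScores([0.7] * 4), np.zeros((4, 1)), y)
        assert row.auc == pytest.approx(0.5)  # midrank tie convention

    def test_single_class_test_flags_auc(self):
        y = np.ones(4, dtype=int)
        row = evaluate(_FixedScores([0.9] * 4), np.zeros((4, 1)), y)
        assert row.auc is None and row.auc_flag
        assert row.accuracy == 1.0

    def test_accuracy_consistent_with_confusion(self):
        y = np.array([1] * 7 + [0] * 13)
        scores = np.linspace(0, 1, 20)[::-1]
        row = evaluate(_FixedScores(scores), np.zeros((20, 1)), y)
        P, N = row.tp + row.fn, row.tn + row.fp
        assert row.accuracy == pytest.approx(
            (row.sensitivity * P + row.specificity * N) / (P + N), abs=1e-9
        )


class TestExperimentSpec:
    def test_design_invariants(self):
        with pytest.raises(ConfigurationError):
            ExperimentSpec(id="I", train_site="a", test_site="b", patient_group="CM")
        with pytest.raises(ConfigurationError):
            ExperimentSpec(id="II", train_site="a", test_site="a", patient_group="CM")
        with pytest.raises(ConfigurationError):
            ExperimentSpec(id="III", train_site="a", test_site="b",
                           patient_group="CM", use_core=False)
        with pytest.raises(ConfigurationError):
            ExperimentSpec(id="II", train_site="a", test_site="b",
                           patient_group="CM", use_core=True)


@pytest.fixture(scope="module")
def small_study():
    cfg = SyntheticConfig(
        seed=21, n_features=60,
        group_sizes={"DS1": {"HC": 40, "CM": 20}, "DS2": {"HC": 40, "CM": 20}},
    )
    study = generate_two_site_study(cfg)
    hc_A = split_by(study.tables["DS1"], "group")["HC"]
    hc_B = split_by(study.tables["DS2"], "group")["HC"]
    core = select_healthy_core(
        hc_A, hc_B,
        CoreConfig(stop_rule="target_size",
                   target_size=len(study.core_subject_ids()), seed=0),
    )
    return study, core


class TestRunExperiment:
    def test_within_site_separates_strong_effect(self, small_study):
        study, _ = small_study
        spec = ExperimentSpec(id="I", train_site="DS1", test_site="DS1",
                              patient_group="CM", n_repeats=2, tuning_budget=5,
                              models=("l1_logreg",), seed=0)
        res = run_experiment(study.tables, spec)
        assert res.mean_by_model()["auc"].iloc[0] > 0.7

    def test_experiment_iii_requires_core(self, small_study):
        study, _ = small_study
        spec = ExperimentSpec(id="III", train_site="DS1", test_site="DS2",
                              patient_group="CM", use_core=True, n_repeats=1,
                              tuning_budget=5, models=("l1_logreg",), seed=0)
        with pytest.raises(ConfigurationError):
            run_experiment(study.tables, spec, core=None)

    def test_seeded_determinism_end_to_end(self, small_study):
        study, core = small_study
        spec = ExperimentSpec(id="III", train_site="DS1", test_site="DS2",
                              patient_group="CM", use_core=True, n_repeats=1,
                              tuning_budget=5, models=("l1_logreg",), seed=7)
        r1 = run_experiment(study.tables, spec, core=core)
        r2 = run_experiment(study.tables, spec, core=core)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)

    def test_rows_cover_validation_and_test(self, small_study):
        study, _ = small_study
        spec = ExperimentSpec(id="II", train_site="DS1", test_site="DS2",
                              patient_group="CM", n_repeats=2, tuning_budget=5,
                              models=("l1_logreg",), seed=1)
        res = run_experiment(study.tables, spec)
        assert set(res.rows["role"]) == {"validation", "test"}
        assert len(res.rows) == 2 * 2  # repeats x roles for one model


class TestSummarize:
    def test_reported_average_convention(self):
        # four per-model AUCs published with their average: the convention
        # is the arithmetic mean rounded half-up at 4 decimals
        frame = pd.DataFrame(
            {
                "model": ["l1_logreg", "svm", "random_forest", "xgboost"],
                "role": ["test"] * 4,
                "auc": [0.7360, 0.6700, 0.7700, 0.8370],
            }
        )
        table = summarize({"exp": frame})
        assert table.loc["Average", "exp"] == pytest.approx(0.7533, abs=1e-12)

    def test_round_half_up_at_tie(self):
        assert round_half_up(0.75325, 4) == 0.7533
        assert round_half_up(0.75324, 4) == 0.7532

    def test_empty_results_no_crash(self):
        assert summarize({}).empty

    def test_csv_round_trip_identical_summary(self, tmp_path, small_study):
        study, _ = small_study
        spec = ExperimentSpec(id="I", train_site="DS1", test_site="DS1",
                              patient_group="CM", n_repeats=1, tuning_budget=5,
                              models=("l1_logreg", "svm"), seed=2)
        res = run_experiment(study.tables, spec)
        path = tmp_path / "rows.csv"
        res.to_csv(path)
        back = pd.read_csv(path)
        t1 = summarize({"I": res})
        t2 = summarize({"I": back})
        pd.testing.assert_frame_equal(t1, t2)


class TestEmbedding:
    def test_separated_blobs_cluster(self, rng):
        from sklearn.metrics import silhouette_score

        a = make_table(rng.standard_normal((30, 10)), group="HC", prefix="hc")
        b = make_table(rng.standard_normal((30, 10)) + 8.0, group="CM", prefix="cm")
        coords = embed_diagnostic([a, b], seed=0)
        labels = ["hc"] * 30 + ["cm"] * 30
        score = silhouette_score(coords[["x", "y"]].to_numpy(), labels)
        assert score > 0.5

    def test_shape_and_determinism(self, rng):
        a = make_table(rng.standard_normal((12, 5)))
        c1 = embed_diagnostic([a], seed=3)
        c2 = embed_diagnostic([a], seed=3)
        assert c1.shape == (12, 4)
        pd.testing.assert_frame_equal(c1, c2)

    def test_perplexity_lowered_for_small_samples(self, rng, caplog):
        import logging

        a = make_table(rng.standard_normal((8, 4)))
        with caplog.at_level(logging.WARNING, logger="healthycore.experiments"):
            coords = embed_diagnostic([a], seed=0, perplexity=30.0)
        assert len(coords) == 8
        assert any("perplexity" in r.message for r in caplog.records)

    def test_too_few_points_rejected(self, rng):
        a = make_table(rng.standard_normal((3, 4)))
        with pytest.raises(DataError):
            embed_diagnostic([a], seed=0)
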