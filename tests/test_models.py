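"""Splitting, screening, autoscaling and the classifier zoo."""

import numpy as np
import pandas as pd
import pytest

from lvradiomics.errors import DataError, ParameterError
from lvradiomics.models import (
    AutoScaler,
    FeatureScreener,
    ZOO_MODELS,
    confusion_metrics,
    split,
    train_zoo,
)


def _toy_table(n=40, p=5, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    if separable:
        X[:, 0] += 6.0 * y
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    df["label"] = y
    return df


class TestSplit:
    def test_nearest_count_rounding_158(self):
        table = _toy_table(n=158)
        train, test = split(table, 0.7, seed=0)
        assert len(train) == 111 and len(test) == 47  # 0.7 * 158 = 110.6

    def test_stratification_within_5_points(self):
        table = _toy_table(n=158)
        train, test = split(table, 0.7, seed=3)
        whole = table["label"].mean()
        assert abs(train["label"].mean() - whole) < 0.05
        assert abs(test["label"].mean() - whole) < 0.05

    def test_seed_determinism(self):
        table = _toy_table()
        t1, _ = split(table, 0.7, seed=5)
        t2, _ = split(table, 0.7, seed=5)
        assert list(t1.index) == list(t2.index)

    def test_single_class_raises(self):
        table = _toy_table()
        table["label"] = 1
        with pytest.raises(DataError):
            split(table, 0.7, seed=0)

    def test_bad_ratio_raises(self):
        with pytest.raises(ParameterError):
            split(_toy_table(), 1.5, seed=0)


class TestScreening:
    def test_label_mirror_removed_by_correlation(self):
        df = _toy_table(n=50)
        df["mirror"] = df["label"].astype(float)
        scr = FeatureScreener().fit(df.drop(columns="label"), df["label"])
        assert "mirror" in scr.report_.removed_by_correlation

    def test_near_constant_removed_by_stability(self):
        df = _toy_table(n=40)
        v = np.zeros(40)
        v[:2] = [1.0, 2.0]  # 95% identical values
        df["flat"] = v
        scr = FeatureScreener().fit(df.drop(columns="label"), df["label"])
        assert "flat" in scr.report_.removed_by_stability

    def test_missing_removed(self):
        df = _toy_table(n=30)
        df.loc[df.index[4], "f0"] = np.nan
        scr = FeatureScreener().fit(df.drop(columns="label"), df["label"])
        assert "f0" in scr.report_.removed_by_missing

    def test_noise_feature_with_moderate_correlation_retained(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 40)
        # noise with sample correlation comfortably inside (1e-5, 0.95)
        x = rng.normal(0, 1, 80) + 0.2 * y
        df = pd.DataFrame({"noise": x})
        scr = FeatureScreener().fit(df, y)
        assert scr.retained_ == ["noise"]

    def test_partition_is_disjoint_and_complete(self):
        df = _toy_table(n=60, p=8)
        df["mirror"] = df["label"].astype(float)
        df["flat"] = 0.0
        feats = df.drop(columns="label")
        scr = FeatureScreener().fit(feats, df["label"])
        r = scr.report_
        groups = [r.removed_by_missing, r.removed_by_stability,
                  r.removed_by_correlation, r.retained]
        all_feats = sum(groups, [])
        assert sorted(all_feats) == sorted(feats.columns)
        assert len(all_feats) == len(set(all_feats))


class TestAutoscale:
    def test_hand_example_sample_sd(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = AutoScaler().fit(train).transform(train)
        assert np.allclose(out["a"], [-1.0, 0.0, 1.0])  # sample SD = 1

    def test_test_scaled_with_train_statistics(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        scaler = AutoScaler().fit(train)
        test = pd.DataFrame({"a": [2.0, 4.0]})
        out = scaler.transform(test)
        assert out["a"].iloc[0] == 0.0  # equals train mean
        assert out["a"].iloc[1] == 2.0

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame({"a": rng.normal(5, 3, 30), "b": rng.normal(0, 1, 30)})
        scaler = AutoScaler().fit(train)
        scaled = scaler.transform(train)
        again = AutoScaler().fit(scaled).transform(scaled)
        assert np.abs(again.to_numpy() - scaled.to_numpy()).max() < 1e-12

    def test_zero_sd_feature_raises(self):
        train = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(DataError):
            AutoScaler().fit(train)


class TestZoo:
    def test_separable_data_all_models_accurate(self):
        df = _toy_table(n=80, separable=True, seed=2)
        train, test = split(df, 0.7, seed=0)
        feats = [c for c in df.columns if c != "label"]
        scaler = AutoScaler().fit(train[feats])
        results = train_zoo(scaler.transform(train[feats]), train["label"].to_numpy(),
                            scaler.transform(test[feats]), test["label"].to_numpy(),
                            cv_folds=5, seed=0)
        assert len(results) == len(ZOO_MODELS)
        for r in results:
            assert r.status == "ok", r.status
            assert r.test_metrics["accuracy"] >= 0.95, r.model_name
            assert np.all((r.test_confidence >= 0) & (r.test_confidence <= 1))

    def test_permuted_labels_cv_accuracy_near_half(self):
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(5):
            df = _toy_table(n=60, p=4, seed=100 + rep)
            df["label"] = rng.permutation(df["label"].to_numpy())
            train, test = split(df, 0.7, seed=rep)
            feats = [c for c in df.columns if c != "label"]
            scaler = AutoScaler().fit(train[feats])
            results = train_zoo(scaler.transform(train[feats]),
                                train["label"].to_numpy(),
                                scaler.transform(test[feats]),
                                test["label"].to_numpy(),
                                models=("NB", "LR", "DT", "RF"),
                                cv_folds=5, seed=rep)
            accs.extend(r.cv_accuracy for r in results)
        assert 0.4 <= float(np.mean(accs)) <= 0.6

    def test_metrics_identities(self):
        y_true = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        y_pred = np.array([1, 0, 1, 0, 1, 0, 1, 0])
        counts, m = confusion_metrics(y_true, y_pred)
        n = sum(counts.values())
        assert m["accuracy"] == (counts["TP"] + counts["TN"]) / n
        assert m["sensitivity"] == counts["TP"] / (counts["TP"] + counts["FN"])
        assert m["specificity"] == counts["TN"] / (counts["TN"] + counts["FP"])
        assert np.isclose(m["plr"], m["sensitivity"] / (1 - m["specificity"]))
        assert np.isclose(m["nlr"], (1 - m["sensitivity"]) / m["specificity"])

    def test_determinism(self):
        df = _toy_table(n=60, separable=True, seed=3)
        train, test = split(df, 0.7, seed=1)
        feats = [c for c in df.columns if c != "label"]
        scaler = AutoScaler().fit(train[feats])
        args = (scaler.transform(train[feats]), train["label"].to_numpy(),
                scaler.transform(test[feats]), test["label"].to_numpy())
        r1 = train_zoo(*args, models=("RF", "DL", "SVM"), cv_folds=5, seed=9)
        r2 = train_zoo(*args, models=("RF", "DL", "SVM"), cv_folds=5, seed=9)
        for a, b in zip(r1, r2):
            assert a.cv_accuracy == b.cv_accuracy
            assert np.array_equal(a.test_pred, b.test_pred)
            assert np.allclose(a.test_confidence, b.test_confidence)

    def test_unknown_model_raises(self):
        df = _toy_table()
        with pytest.raises(ParameterError):
            train_zoo(df.drop(columns="label"), df["label"].to_numpy(),
                      df.drop(columns="label"), df["label"].to_numpy(),
                      models=("XGBoost",))

    def test_tuning_budget_runs_grid(self):
        df = _toy_table(n=60, separable=True, seed=4)
        train, test = split(df, 0.7, seed=1)
        feats = [c for c in df.columns if c != "label"]
        scaler = AutoScaler().fit(train[feats])
        results = train_zoo(scaler.transform(train[feats]), train["label"].to_numpy(),
                            scaler.transform(test[feats]), test["label"].to_numpy(),
                            models=("DT", "LR"), cv_folds=5, tuning_budget=1, seed=0)
        assert all(r.status == "ok" for r in results)
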