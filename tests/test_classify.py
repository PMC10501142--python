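"""SVM grid search, the two-stage cascade, the ANN, and nested CV."""

import numpy as np
import pandas as pd
import pytest

from neurocascade._guard import LeakageError, RowGuard
from neurocascade.ann import AnnClassifier, select_hidden_nodes
from neurocascade.classify import (
    SvmHyperParams,
    nested_cv,
    predict_cascade,
    train_cascade,
    train_rbf_svm,
)
from neurocascade.roi import FeatureTable
from neurocascade.synthetic import CohortSpec, generate_feature_table


def _two_clusters(n=40, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    y = np.array([0, 1] * (n // 2))
    X[y == 1, 0] += sep
    return X, y


class TestSvmGridSearch:
    def test_separable_data_reaches_perfect_accuracy(self):
        X, y = _two_clusters()
        model, scaler, C, gamma, acc = train_rbf_svm(
            X, y, SvmHyperParams.reduced(), n_inner=5, seed=0
        )
        assert acc == 100.0
        assert np.all(model.predict(scaler.transform(X)) == y)

    def test_permuted_labels_near_chance(self):
        accs = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            X = rng.standard_normal((100, 10))
            y = np.array([0, 1] * 50)
            *_, acc = train_rbf_svm(X, y, SvmHyperParams.reduced(), n_inner=5, seed=s)
            accs.append(acc)
        assert np.mean(accs) == pytest.approx(50.0, abs=10.0)

    def test_degenerate_grid_equals_direct_fit(self):
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        X, y = _two_clusters(sep=2.0, seed=1)
        params = SvmHyperParams(C_grid=np.array([2.0]), gamma_grid=np.array([0.25]))
        model, scaler, C, gamma, _ = train_rbf_svm(X, y, params, n_inner=3, seed=0)
        assert (C, gamma) == (2.0, 0.25)
        ref_sc = StandardScaler().fit(X)
        ref = SVC(C=2.0, gamma=0.25).fit(ref_sc.transform(X), y)
        np.testing.assert_array_equal(
            model.predict(scaler.transform(X)), ref.predict(ref_sc.transform(X))
        )

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_rbf_svm(X, np.zeros(10), SvmHyperParams.reduced())

    def test_grid_shape_and_validation(self):
        g = SvmHyperParams()
        assert len(g.C_grid) == 33 and len(g.gamma_grid) == 33
        assert g.C_grid[0] == 2.0**-8 and g.C_grid[-1] == 2.0**8
        np.testing.assert_allclose(np.diff(np.log2(g.C_grid)), 0.5)
        with pytest.raises(ValueError):
            SvmHyperParams(C_grid=np.array([-1.0]))


class TestCascade:
    def test_separable_cohort_trains_to_perfection(self, separable_cohort):
        X, y = separable_cohort.X, separable_cohort.y.astype(str)
        model = train_cascade(
            X, y, params=SvmHyperParams.reduced(), top_m=6, n_inner=3, seed=0
        )
        pred = predict_cascade(model, X)
        assert np.mean(pred == y) == 1.0
        assert not model.stage2_fallback_used

    def test_prediction_is_a_partition(self, separable_cohort):
        X, y = separable_cohort.X, separable_cohort.y.astype(str)
        model = train_cascade(
            X, y, params=SvmHyperParams.reduced(), top_m=4, n_inner=3, seed=1
        )
        pred = predict_cascade(model, X)
        assert set(pred) <= {"AD", "MCI", "HC"}
        assert len(pred) == len(y)

    def test_planted_he_effects_concentrate_selection_in_he(self):
        labels = tuple(range(1, 41))
        picked_he = picked_total = 0
        for seed in range(5):
            spec = CohortSpec(
                n_per_class={"AD": 15, "MCI": 15, "HC": 15},
                region_labels=labels,
                effect_map=[
                    ("HE", 5, (0.0, 3.0, 6.0)),
                    ("HE", 12, (6.0, 0.0, 3.0)),
                    ("HE", 20, (3.0, 6.0, 0.0)),
                ],
                seed=seed,
            )
            t = generate_feature_table(spec)
            model = train_cascade(
                t.X, t.y.astype(str), params=SvmHyperParams.reduced(),
                top_m=4, n_inner=3, seed=seed,
            )
            keys = t.column_keys()
            for c in model.stage1.columns:
                picked_total += 1
                picked_he += keys[c][0] == "HE"
        assert picked_he >= picked_total / 2

    def test_missing_feature_columns_error(self, separable_cohort):
        X, y = separable_cohort.X, separable_cohort.y.astype(str)
        model = train_cascade(
            X, y, params=SvmHyperParams.reduced(), top_m=4, n_inner=3, seed=2
        )
        with pytest.raises(ValueError, match="columns"):
            predict_cascade(model, X[:, :10])

    def test_all_three_classes_required(self):
        X = np.random.default_rng(0).standard_normal((20, 5))
        y = np.array(["AD", "HC"] * 10)
        with pytest.raises(ValueError, match="three classes"):
            train_cascade(X, y)


class TestAnn:
    def test_xor_is_learnable_within_epoch_cap(self):
        rng = np.random.default_rng(0)
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        X = np.repeat(base, 25, axis=0) + rng.normal(0, 0.05, (100, 2))
        y = np.array([0, 1, 1, 0]).repeat(25)
        best = max(
            AnnClassifier(hidden_nodes=4, seed=s).fit(X, y).score(X, y)
            for s in range(5)
        )
        assert best == 1.0

    def test_zero_weights_output_half(self):
        clf = AnnClassifier(hidden_nodes=3, seed=0)
        clf._init_weights(2, 2, np.random.default_rng(0))
        clf.W1[:] = 0.0
        clf.W2[:] = 0.0
        _, out = clf._forward(np.random.default_rng(1).standard_normal((5, 2)))
        np.testing.assert_allclose(out, 0.5)

    def test_unfittable_data_runs_full_epoch_budget(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 3))
        y = rng.integers(0, 2, 60)  # labels independent of X: RMSE stays high
        clf = AnnClassifier(hidden_nodes=2, seed=0).fit(X, y)
        assert clf.n_epochs_ == 500
        assert clf.rmse_ >= 0.01

    def test_epoch_cap_is_enforced(self):
        with pytest.raises(ValueError):
            AnnClassifier(max_epochs=501)

    def test_hidden_node_selection_prefers_capable_width(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        y = (X[:, 0] > 0).astype(int)
        w, acc = select_hidden_nodes(X, y, node_range=[2, 4], n_folds=3, seed=0)
        assert w in (2, 4)
        assert acc > 80.0


class TestRowGuard:
    def test_forbidden_access_raises(self):
        X = np.arange(20).reshape(10, 2)
        y = np.arange(10)
        guard = RowGuard(X, y, forbidden=np.array([2, 5]))
        Xa, ya = guard.take([0, 1, 3])
        assert Xa.shape == (3, 2)
        with pytest.raises(LeakageError, match="outer-test rows"):
            guard.take([1, 5])

    def test_test_rows_returns_heldout(self):
        X = np.arange(20).reshape(10, 2)
        guard = RowGuard(X, np.arange(10), forbidden=np.array([9, 0]))
        Xt, yt = guard.test_rows()
        np.testing.assert_array_equal(yt, [0, 9])


class TestNestedCv:
    def test_every_subject_tested_exactly_once(self, small_noise_table):
        rep = nested_cv(small_noise_table, method="bayes", selector="none",
                        n_outer=3, seed=0)
        assert sorted(rep.predictions.index) == sorted(small_noise_table.values.index)
        assert rep.predictions["fold"].nunique() == 3
        assert int(rep.confusion.to_numpy().sum()) == small_noise_table.n_subjects

    def test_fixed_seed_reproduces_report(self, small_noise_table):
        a = nested_cv(small_noise_table, method="bayes", selector="mrmr-sfc",
                      top_m=3, n_outer=3, n_inner=3, seed=7)
        b = nested_cv(small_noise_table, method="bayes", selector="mrmr-sfc",
                      top_m=3, n_outer=3, n_inner=3, seed=7)
        assert a.confusion.equals(b.confusion)
        assert a.predictions.equals(b.predictions)
        assert a.per_fold_features == b.per_fold_features

    def test_accounting_identity(self, small_noise_table):
        rep = nested_cv(small_noise_table, method="forest", selector="none",
                        n_outer=3, seed=1)
        overall, per_class = rep.recompute_accuracy()
        assert overall == pytest.approx(rep.overall_acc)
        for c, v in rep.per_class_acc.items():
            assert per_class[c] == pytest.approx(v)

    def test_cascade_report_carries_stage_aucs(self, separable_cohort):
        rep = nested_cv(separable_cohort, method="svm-cascade",
                        params=SvmHyperParams.reduced(), n_outer=3, n_inner=3,
                        top_m=4, seed=3)
        assert rep.auc_stage1 is not None and rep.auc_stage1 > 0.9
        assert rep.auc_stage2["predicted_patients"] is not None
        assert rep.auc_stage2["all_patients"] is not None
        assert len(rep.per_fold_features) == 3
        assert all(set(f) == {"stage1", "stage2"} for f in rep.per_fold_features)
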