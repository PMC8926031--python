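import numpy as np
import pytest
from sklearn.svm import SVC

import jsseconn as jc
from jsseconn.classify import (
    FeatureBundle,
    _svm_dual_fit,
    beta_simplex_grid,
    consensus_connections,
    default_C_grid,
    delong_test,
    linear_kernel,
    mksvm_predict,
    mksvm_train,
    nested_loocv,
    performance,
    ttest_select,
)


def make_cohort(rng, n=12, n_regions=6, signal=0.0, n_signal=3):
    """Feature cohort with optional group signal in the first
    connection features."""
    n_conn = n_regions * (n_regions - 1) // 2
    cohort = []
    for i in range(n):
        label = 1 if i < n // 2 else -1
        conn = rng.normal(0, 1, n_conn)
        conn[:n_signal] += signal * label
        cohort.append(FeatureBundle(
            f"s{i:02d}", conn, rng.normal(0, 1, 11),
            rng.normal(0, 1, 5 * n_regions), label))
    return cohort


class TestTTestSelect:
    def test_constant_feature_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 5.0
        y = np.array([1] * 10 + [-1] * 10)
        mask = ttest_select(X, y)
        assert not mask[1]

    def test_strong_feature_included(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 20 + [-1] * 20)
        X = rng.normal(0, 0.1, (40, 2))
        X[:20, 0] += 5.0
        mask = ttest_select(X, y)
        assert mask[0] and not mask[1]

    def test_matches_scipy_per_feature(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        mask = ttest_select(X, y, alpha=0.3)
        for k in range(8):
            _, p = stats.ttest_ind(X[y == 1, k], X[y == -1, k], equal_var=True)
            assert mask[k] == (p < 0.3)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ttest_select(np.zeros((4, 2)), np.ones(4))


class TestLinearKernel:
    def test_arithmetic(self):
        assert linear_kernel([[1.0, 2.0]], [[3.0, 4.0]])[0, 0] == 11.0

    def test_orthonormal_rows_give_identity(self):
        K = linear_kernel(np.eye(4), np.eye(4))
        np.testing.assert_array_equal(K, np.eye(4))

    def test_kernel_is_psd(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 40))
        X = (X - X.mean(0)) / X.std(0)
        ev = np.linalg.eigvalsh(linear_kernel(X, X))
        assert ev.min() >= -1e-9

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            linear_kernel(np.ones((2, 3)), np.ones((2, 4)))


class TestMKSVM:
    def test_two_point_analytic_solution(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        K = [linear_kernel(X, X)] * 3
        model = mksvm_train(K, y, (1.0, 0.0, 0.0), C=10.0)
        np.testing.assert_allclose(model.alphas, [0.5, 0.5], atol=1e-6)
        assert model.bias == pytest.approx(0.0, abs=1e-6)
        # decision at x = 0 sits on the boundary
        K0 = [linear_kernel(np.array([[0.0]]), X)] * 3
        _, dec = mksvm_predict(model, K0)
        assert dec[0] == pytest.approx(0.0, abs=1e-6)

    def test_vertex_beta_equals_single_kernel_svm(self):
        rng = np.random.default_rng(4)
        X1, X2, X3 = (rng.normal(size=(20, 5)) for _ in range(3))
        y = np.array([1] * 10 + [-1] * 10)
        kernels = [linear_kernel(X, X) for X in (X1, X2, X3)]
        for vertex in ((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)):
            m = int(np.argmax(vertex))
            mk = mksvm_train(kernels, y, vertex, C=2.0)
            svc = SVC(C=2.0, kernel="precomputed").fit(kernels[m], y)
            single = np.zeros(20)
            single[svc.support_] = np.abs(svc.dual_coef_[0])
            np.testing.assert_allclose(mk.alphas, single, atol=1e-6)
            assert mk.bias == pytest.approx(float(svc.intercept_[0]), abs=1e-6)

    def test_duplicated_kernel_convex_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 6))
        y = np.array([1] * 8 + [-1] * 8)
        K = linear_kernel(X, X)
        m1 = mksvm_train([K, K, np.zeros_like(K)], y, (0.5, 0.5, 0.0), C=1.0)
        m2 = mksvm_train([K, K, np.zeros_like(K)], y, (1.0, 0.0, 0.0), C=1.0)
        Kt = [K, K, np.zeros_like(K)]
        _, d1 = mksvm_predict(m1, Kt)
        _, d2 = mksvm_predict(m2, Kt)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_dual_feasibility(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]
        K = [linear_kernel(X, X)] * 3
        for C in (0.1, 1.0, 32.0):
            model = mksvm_train(K, y, (0.3, 0.3, 0.4), C=C)
            assert np.all(model.alphas >= -1e-9)
            assert np.all(model.alphas <= C + 1e-6)
            assert abs(np.dot(model.alphas, model.train_labels)) < 1e-6

    def test_training_points_of_separable_toy_classified(self):
        X = np.array([[2.0], [1.0], [-1.0], [-2.0]])
        y = np.array([1, 1, -1, -1])
        K = [linear_kernel(X, X)] * 3
        model = mksvm_train(K, y, (0.4, 0.3, 0.3), C=10.0)
        pred, _ = mksvm_predict(model, K)
        np.testing.assert_array_equal(pred, y)

    def test_fast_dual_path_matches_svc(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(6, 25))
            X = rng.normal(size=(n, 5))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            K = linear_kernel(X, X)
            C = float(2.0 ** rng.integers(-5, 6))
            coef, bias = _svm_dual_fit(K, y, C)
            svc = SVC(C=C, kernel="precomputed").fit(K, y.astype(float))
            np.testing.assert_allclose(K @ coef + bias,
                                       svc.decision_function(K), atol=1e-6)


class TestGrids:
    def test_C_grid_is_powers_of_two(self):
        np.testing.assert_allclose(default_C_grid(),
                                   [2.0 ** k for k in range(-5, 6)])

    @pytest.mark.parametrize("step,count", [(0.1, 66), (0.25, 15), (0.5, 6)])
    def test_simplex_grid_size(self, step, count):
        grid = beta_simplex_grid(step)
        assert len(grid) == count
        for b in grid:
            assert all(x >= 0 for x in b)
            assert sum(b) == pytest.approx(1.0, abs=1e-12)


class TestNestedLOOCV:
    def test_perfectly_separating_feature_gives_full_accuracy(self):
        # one connection feature separates the classes exactly; the
        # remaining features are uninformative constants, which the
        # t-test selection must drop
        cohort = []
        for i in range(10):
            label = 1 if i < 5 else -1
            conn = np.full(15, 0.5)
            conn[0] = 2.0 * label
            cohort.append(FeatureBundle(f"s{i}", conn, np.full(11, 3.0),
                                        np.full(30, 1.0), label))
        res = nested_loocv(cohort, beta_grid=beta_simplex_grid(0.5))
        assert res.accuracy == 1.0
        assert len(res.folds) == 10
        assert res.consensus == [(0, 1)]

    def test_fold_count_equals_cohort_size(self):
        rng = np.random.default_rng(9)
        cohort = make_cohort(rng, n=8, signal=3.0)
        res = nested_loocv(cohort, beta_grid=beta_simplex_grid(0.5))
        assert len(res.folds) == len(cohort)

    def test_too_small_cohort_errors(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            nested_loocv(make_cohort(rng, n=3))

    def test_held_out_subject_cannot_change_training_fold(self):
        rng = np.random.default_rng(11)
        cohort = make_cohort(rng, n=10, signal=2.0)
        res_a = nested_loocv(cohort, beta_grid=beta_simplex_grid(0.5))
        mutated = list(cohort)
        k = 4
        mutated[k] = FeatureBundle(
            cohort[k].subject_id,
            rng.normal(0, 50, cohort[k].connection.size),
            rng.normal(0, 50, 11),
            rng.normal(0, 50, cohort[k].nodal.size),
            cohort[k].label,
        )
        res_b = nested_loocv(mutated, beta_grid=beta_simplex_grid(0.5))
        fa, fb = res_a.folds[k], res_b.folds[k]
        np.testing.assert_array_equal(fa.connection_mask, fb.connection_mask)
        np.testing.assert_array_equal(fa.nodal_mask, fb.nodal_mask)
        assert fa.C == fb.C and fa.betas == fb.betas

    def test_result_round_trips_to_json(self, tmp_path):
        rng = np.random.default_rng(12)
        res = nested_loocv(make_cohort(rng, n=8, signal=4.0),
                           beta_grid=beta_simplex_grid(0.5))
        path = tmp_path / "cv.json"
        res.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["accuracy"] == res.accuracy
        assert len(payload["folds"]) == 8


class TestKernelCombination:
    def test_combined_kernels_track_best_single_kernel(self):
        # statistical tendency over 10 seeded generator cohorts: the
        # C+G+N combination stays within 5 percentage points of the
        # best single-kernel accuracy on average
        vertex_grids = [[(1.0, 0.0, 0.0)], [(0.0, 1.0, 0.0)],
                        [(0.0, 0.0, 1.0)]]
        diffs = []
        for seed in range(10):
            pairs = jc.choose_effect_pairs(12, 2, seed=seed)
            cfg = jc.SimulationConfig(
                n_per_group=6, n_vox=60, n_regions=12,
                effect_pairs=pairs, effect_size=3.0, seed=seed)
            bundles = []
            for k, subject in enumerate(jc.simulate_cohort(cfg)):
                net = jc.build_connectome(subject)
                bundles.append(jc.bundle_from_network(
                    net, subject.group, n_nulls=5, seed=100 * seed + k))
            singles = [nested_loocv(bundles, beta_grid=grid).accuracy
                       for grid in vertex_grids]
            combined = nested_loocv(
                bundles, beta_grid=beta_simplex_grid(0.25)).accuracy
            diffs.append(combined - max(singles))
        assert np.mean(diffs) >= -0.05


class TestConsensus:
    def test_intersection_semantics(self):
        m1 = np.array([True, True, False, True, False, True])  # 4 regions
        m2 = np.array([True, False, False, True, False, True])
        out = consensus_connections([m1, m2])
        assert out == [(0, 1), (1, 2), (2, 3)]

    def test_missing_in_one_fold_excludes(self):
        m1 = np.ones(6, dtype=bool)
        m2 = np.ones(6, dtype=bool)
        m2[0] = False
        assert (0, 1) not in consensus_connections([m1, m2])

    def test_empty_intersection_allowed(self):
        m = np.zeros(6, dtype=bool)
        assert consensus_connections([m, m]) == []


class TestPerformance:
    def test_confusion_arithmetic(self):
        labels = np.array([1] * 64 + [-1] * 64)
        predictions = np.concatenate([
            np.repeat(1, 48), np.repeat(-1, 16),   # TP=48, FN=16
            np.repeat(-1, 59), np.repeat(1, 5),    # TN=59, FP=5
        ])
        decisions = predictions * 1.0
        perf = performance(predictions, decisions, labels)
        assert perf["accuracy"] == pytest.approx(0.8359, abs=5e-5)
        assert perf["sensitivity"] == pytest.approx(0.75, abs=1e-12)
        assert perf["specificity"] == pytest.approx(0.921875, abs=1e-12)

    def test_perfect_separation_auc_one(self):
        labels = np.array([1, 1, -1, -1])
        perf = performance(labels, np.array([2.0, 1.0, -1.0, -2.0]), labels)
        assert perf["auc"] == 1.0

    def test_trapezoid_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(13)
        labels = np.array([1] * 5 + [-1] * 5)
        dec = rng.normal(size=10)
        perf = performance(np.sign(dec), dec, labels)
        pos, neg = dec[:5], dec[5:]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0)
                 for a in pos for b in neg]
        assert perf["auc"] == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            performance(np.ones(4), np.ones(4), np.ones(4))


class TestDeLong:
    def test_self_comparison_is_null(self):
        rng = np.random.default_rng(14)
        labels = np.array([1] * 6 + [-1] * 6)
        dec = rng.normal(size=12)
        z, p = delong_test(dec, dec, labels)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(15)
        labels = np.array([1] * 8 + [-1] * 8)
        a, b = rng.normal(size=16), rng.normal(size=16)
        za, pa = delong_test(a, b, labels)
        zb, pb = delong_test(b, a, labels)
        assert za == pytest.approx(-zb, abs=1e-12)
        assert pa == pytest.approx(pb, abs=1e-12)

    def test_variance_against_jackknife_oracle(self):
        rng = np.random.default_rng(16)
        labels = np.array([1] * 20 + [-1] * 20)
        a = rng.normal(size=40) + 0.8 * labels
        b = rng.normal(size=40) + 0.3 * labels

        def auc_diff(idx):
            sub = np.asarray(idx)
            pa = performance(np.sign(a[sub]), a[sub], labels[sub])["auc"]
            pb = performance(np.sign(b[sub]), b[sub], labels[sub])["auc"]
            return pa - pb

        n = 40
        theta = auc_diff(range(n))
        loo = np.array([auc_diff([i for i in range(n) if i != j])
                        for j in range(n)])
        jack_var = (n - 1) / n * np.sum((loo - loo.mean()) ** 2)
        z, _ = delong_test(a, b, labels)
        delong_var = (theta / z) ** 2
        assert delong_var == pytest.approx(jack_var, rel=0.10)

    def test_large_difference_is_significant(self):
        labels = np.array([1] * 15 + [-1] * 15)
        good = labels * 1.0
        rng = np.random.default_rng(17)
        noise = rng.normal(size=30)
        _, p = delong_test(good, noise, labels)
        assert p < 0.05
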