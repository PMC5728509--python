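import numpy as np
import pytest

from crclassify import (SparseProjection, build_dictionary, classify_crc,
                        classify_src, code_sample, fit_crc, solve_omp)
from crclassify.classify import Dictionary, classify_crc_batch
from crclassify.preprocess import normalize_columns

from conftest import make_set


def ridge_oracle(X, lam, y):
    """Independent generic solver: least squares on the augmented system
    [X; sqrt(lam) I], which minimizes ||y - Xa||^2 + lam ||a||^2."""
    n = X.shape[1]
    A = np.vstack([X, np.sqrt(lam) * np.eye(n)])
    b = np.concatenate([y, np.zeros(n)])
    return np.linalg.lstsq(A, b, rcond=None)[0]


def random_dictionary(rng, m=20, n=50, k=2):
    X = normalize_columns(rng.standard_normal((m, n)))
    cuts = np.linspace(0, n, k + 1).astype(int)
    slices = [slice(int(a), int(b)) for a, b in zip(cuts[:-1], cuts[1:])]
    return Dictionary(X=X, class_slices=slices,
                      class_names=[f"c{i}" for i in range(k)])


class TestBuildDictionary:
    def test_two_classes_three_samples_each(self):
        rng = np.random.default_rng(0)
        d = make_set(rng.standard_normal((10, 6)), list("ABABAB"))
        D = build_dictionary(d)
        assert D.X.shape == (10, 6)
        assert D.class_slices == [slice(0, 3), slice(3, 6)]
        np.testing.assert_allclose(np.linalg.norm(D.X, axis=0), 1.0,
                                   atol=1e-12)
        # class A columns are the normalized A samples, original order kept
        np.testing.assert_allclose(
            D.X[:, 0], d.values[:, 0] / np.linalg.norm(d.values[:, 0]))

    def test_identity_projection_changes_nothing(self):
        rng = np.random.default_rng(1)
        d = make_set(rng.standard_normal((12, 8)), ["A"] * 4 + ["B"] * 4)
        a = build_dictionary(d)
        b = build_dictionary(d, SparseProjection.identity(12))
        # sparse matmul may reorder sums; equality holds to the last ulp
        np.testing.assert_allclose(b.X, a.X, rtol=0, atol=1e-15)

    def test_prostate_table_layout(self, table1_set):
        """Six samples become six unit columns grouped by class block."""
        D = build_dictionary(table1_set)
        assert D.class_names == ["Normal", "Cancer"]
        assert D.class_slices == [slice(0, 3), slice(3, 6)]
        x1 = table1_set.values[:, 0]
        np.testing.assert_allclose(D.X[:, 0], x1 / np.linalg.norm(x1))
        # first Cancer column is sample X2
        x2 = table1_set.values[:, 1]
        np.testing.assert_allclose(D.X[:, 3], x2 / np.linalg.norm(x2))


class TestFitCRC:
    def test_matches_ridge_solve_oracle(self):
        """P y equals the regularized least-squares minimizer, 100 cases."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            m = int(rng.integers(10, 51))
            n = int(rng.integers(20, 201))
            D = random_dictionary(rng, m, n)
            lam = float(rng.uniform(1e-4, 1.0))
            model = fit_crc(D, lam)
            y = rng.standard_normal(m)
            err = np.linalg.norm(model.P @ y - ridge_oracle(D.X, lam, y))
            assert err <= 1e-8 * (1 + np.linalg.norm(y))

    def test_orthonormal_limit_is_transpose_and_projection(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((50, 10)))
        D = Dictionary(X=Q, class_slices=[slice(0, 5), slice(5, 10)],
                       class_names=["a", "b"])
        model = fit_crc(D, 1e-12)
        y = rng.standard_normal(50)
        coef = model.P @ y
        np.testing.assert_allclose(coef, Q.T @ y, atol=1e-6)
        # y is perpendicularly projected onto span(X)
        np.testing.assert_allclose(Q @ coef, Q @ (Q.T @ y), atol=1e-6)

    def test_lambda_shrinks_coefficients(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            D = random_dictionary(rng, 15, 40)
            y = rng.standard_normal(15)
            lam = float(rng.uniform(1e-3, 1.0))
            n1 = np.linalg.norm(fit_crc(D, lam).P @ y)
            n2 = np.linalg.norm(fit_crc(D, 2 * lam).P @ y)
            assert n2 <= n1 + 1e-12

    def test_nonpositive_lambda_rejected(self):
        D = random_dictionary(np.random.default_rng(5))
        for lam in (0.0, -1.0):
            with pytest.raises(ValueError):
                fit_crc(D, lam)


class TestCodeSample:
    def test_zero_query(self):
        model = fit_crc(random_dictionary(np.random.default_rng(6)))
        cv = code_sample(model, np.zeros(20))
        assert np.all(cv.coefficients == 0)
        assert np.all(cv.residual_vector == 0)

    def test_training_column_reconstructed_at_tiny_lambda(self):
        rng = np.random.default_rng(7)
        D = random_dictionary(rng, m=30, n=10)  # independent columns
        model = fit_crc(D, 1e-12)
        cv = code_sample(model, D.X[:, 4])
        assert np.linalg.norm(cv.residual_vector) < 1e-6

    def test_by_class_concatenates_to_coefficients(self):
        rng = np.random.default_rng(8)
        model = fit_crc(random_dictionary(rng, k=3, n=51))
        cv = code_sample(model, rng.standard_normal(20))
        np.testing.assert_array_equal(np.concatenate(cv.by_class),
                                      cv.coefficients)

    def test_stored_p_equals_fresh_solve(self):
        rng = np.random.default_rng(9)
        D = random_dictionary(rng)
        model = fit_crc(D, 0.01)
        y = rng.standard_normal(20)
        np.testing.assert_allclose(code_sample(model, y).coefficients,
                                   ridge_oracle(D.X, 0.01, y), atol=1e-8)

    def test_dimension_mismatch(self):
        model = fit_crc(random_dictionary(np.random.default_rng(10)))
        with pytest.raises(ValueError):
            code_sample(model, np.zeros(19))


class TestClassifyCRC:
    def test_single_class_always_wins(self):
        rng = np.random.default_rng(11)
        X = normalize_columns(rng.standard_normal((10, 5)))
        D = Dictionary(X=X, class_slices=[slice(0, 5)], class_names=["only"])
        model = fit_crc(D)
        assert classify_crc(model, rng.standard_normal(10)).predicted_class \
            == "only"

    def test_separated_classes_all_queries_correct(self):
        """5-sigma-separated classes, nearest-class-mean as oracle."""
        rng = np.random.default_rng(12)
        base = rng.uniform(2, 8, 20)
        muA = base + 2.5 * rng.choice([-1, 1], 20)
        muB = 2 * base - muA  # mirror within positive baseline, 5-sigma gap
        train = np.hstack([muA[:, None] + rng.standard_normal((20, 10)),
                           muB[:, None] + rng.standard_normal((20, 10))])
        d = make_set(train, ["A"] * 10 + ["B"] * 10)
        model = fit_crc(build_dictionary(d), 0.01)
        correct = 0
        for i in range(50):
            truth = "A" if i % 2 == 0 else "B"
            mu = muA if truth == "A" else muB
            q = mu + rng.standard_normal(20)
            pred = classify_crc(model, q).predicted_class
            ncm = "A" if (np.linalg.norm(q - muA) < np.linalg.norm(q - muB)) \
                else "B"
            assert ncm == truth  # oracle sanity
            correct += pred == truth
        assert correct == 50

    def test_scale_robustness(self):
        rng = np.random.default_rng(13)
        model = fit_crc(random_dictionary(rng))
        y = rng.standard_normal(20)
        r1 = classify_crc(model, y)
        r2 = classify_crc(model, 37.5 * y)
        np.testing.assert_allclose(r1.per_class_residuals,
                                   r2.per_class_residuals, atol=1e-12)
        assert r1.predicted_index == r2.predicted_index

    def test_permutation_within_class_and_block_order(self):
        rng = np.random.default_rng(14)
        vals = rng.standard_normal((15, 8)) + 3
        d = make_set(vals, ["A"] * 4 + ["B"] * 4)
        y = rng.standard_normal(15)
        base = classify_crc(fit_crc(build_dictionary(d)), y)
        # shuffle samples within class A
        perm = [2, 0, 3, 1, 4, 5, 6, 7]
        dp = d.subset_samples(perm)
        rp = classify_crc(fit_crc(build_dictionary(dp)), y)
        np.testing.assert_allclose(rp.per_class_residuals,
                                   base.per_class_residuals, atol=1e-9)
        # swap class block order: report permutes accordingly
        ds = d.subset_samples([4, 5, 6, 7, 0, 1, 2, 3])
        rs = classify_crc(fit_crc(build_dictionary(ds)), y)
        np.testing.assert_allclose(rs.per_class_residuals,
                                   base.per_class_residuals[::-1], atol=1e-9)

    def test_orthogonal_query_hits_sentinel_path(self, caplog):
        # dictionary spans the first 4 coordinates; query lives in the 5th
        X = np.eye(5)[:, :4]
        D = Dictionary(X=X, class_slices=[slice(0, 2), slice(2, 4)],
                       class_names=["a", "b"])
        model = fit_crc(D, 1e-8)
        y = np.zeros(5)
        y[4] = 1.0
        with caplog.at_level("WARNING"):
            rep = classify_crc(model, y)
        assert rep.predicted_class == "a"  # fallback: lowest class index

    def test_batch_bitwise_equals_per_query(self):
        rng = np.random.default_rng(15)
        D = random_dictionary(rng)
        model = fit_crc(D, 1e-3)
        Y = rng.standard_normal((20, 12))
        batch = classify_crc_batch(model, Y)
        for j, rep in enumerate(batch):
            fresh = classify_crc(fit_crc(D, 1e-3), Y[:, j])
            assert rep.predicted_index == fresh.predicted_index
            np.testing.assert_array_equal(rep.per_class_residuals,
                                          fresh.per_class_residuals)


class TestOMP:
    def test_single_atom_signal(self):
        rng = np.random.default_rng(16)
        X = normalize_columns(rng.standard_normal((20, 10)))
        cv = solve_omp(X, 3.0 * X[:, 7], max_nonzeros=5)
        assert np.nonzero(cv.coefficients)[0].tolist() == [7]
        np.testing.assert_allclose(cv.coefficients[7], 3.0, atol=1e-10)
        assert np.linalg.norm(cv.residual_vector) < 1e-10

    def test_planted_support_recovery_rate(self):
        """Noiseless 5-sparse Gaussian codes over a 30x50 dictionary."""
        hits = 0
        for t in range(100):
            rng = np.random.default_rng(9000 + t)
            X = normalize_columns(rng.standard_normal((30, 50)))
            support = np.sort(rng.choice(50, 5, replace=False))
            a = np.zeros(50)
            a[support] = rng.standard_normal(5)
            cv = solve_omp(X, X @ a, max_nonzeros=5, residual_tol=1e-10)
            hits += set(np.nonzero(cv.coefficients)[0]) == set(support)
        assert hits >= 95

    def test_agrees_with_sklearn_omp(self):
        from sklearn.linear_model import OrthogonalMatchingPursuit

        rng = np.random.default_rng(17)
        X = normalize_columns(rng.standard_normal((25, 60)))
        y = rng.standard_normal(25)
        cv = solve_omp(X, y, max_nonzeros=8, residual_tol=0.0)
        sk = OrthogonalMatchingPursuit(n_nonzero_coefs=8,
                                       fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(cv.coefficients, sk.coef_, atol=1e-8)

    def test_full_support_bounded_by_least_squares(self):
        rng = np.random.default_rng(18)
        X = normalize_columns(rng.standard_normal((30, 12)))
        y = rng.standard_normal(30)
        cv = solve_omp(X, y, max_nonzeros=12, residual_tol=0.0)
        ls_resid = np.linalg.norm(y - X @ np.linalg.lstsq(X, y, rcond=None)[0])
        assert np.linalg.norm(cv.residual_vector) <= ls_resid + 1e-10

    def test_rank_deficient_support_flagged(self):
        X = np.array([[1.0, 1.0], [0.0, 0.0]])  # duplicate atom
        # y has a component no atom can explain, so after the first pick the
        # only remaining candidate duplicates the support
        cv = solve_omp(X, np.array([1.0, 1.0]), max_nonzeros=2,
                       residual_tol=0.0)
        assert cv.rank_deficient
        assert np.count_nonzero(cv.coefficients) == 1


class TestClassifySRC:
    def test_self_query_noiseless(self):
        rng = np.random.default_rng(19)
        d = make_set(rng.standard_normal((30, 9)) + 4,
                     ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        D = build_dictionary(d)
        rep = classify_src(D, d.values[:, 7])  # a class-c sample
        assert rep.predicted_class == "c"
        assert rep.per_class_residuals[2] < 1e-6

    def test_separable_task_and_crc_agreement(self, separable_set):
        """Train/test split of the 5-sigma synthetic task: SRC is perfect
        and agrees with CRC on at least 90% of queries."""
        d = separable_set
        train_idx = [i for i in range(40) if i % 2 == 0]
        test_idx = [i for i in range(40) if i % 2 == 1]
        train = d.subset_samples(train_idx)
        D = build_dictionary(train)
        model = fit_crc(D, 1e-3)
        agree = 0
        for j in test_idx:
            y = d.values[:, j]
            src = classify_src(D, y).predicted_class
            crc = classify_crc(model, y).predicted_class
            assert src == d.labels[j]
            agree += src == crc
        assert agree >= 0.9 * len(test_idx)
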