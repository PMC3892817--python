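"""SVM tests: dual feasibility, QP-oracle agreement, LOO validation, metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize

from drowsyhrv.classification import (
    SVMConfig,
    decision_values,
    default_grid,
    loo_single,
    loo_validate,
    metrics,
    predict,
    train,
)


def rbf_kernel(A, B, gamma):
    sq = (np.sum(A ** 2, 1)[:, None] + np.sum(B ** 2, 1)[None, :]
          - 2 * A @ B.T)
    return np.exp(-gamma * np.maximum(sq, 0.0))


def svm_dual_oracle(X, y, C, kernel, gamma=1.0):
    """Solve the soft-margin SVM dual directly with SLSQP."""
    K = X @ X.T if kernel == "linear" else rbf_kernel(X, X, gamma)
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)
    res = minimize(
        lambda lam: 0.5 * lam @ Q @ lam - lam.sum(),
        x0=np.full(n, min(C, 1.0) / 2),
        jac=lambda lam: Q @ lam - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda lam: lam @ y,
                      "jac": lambda lam: y}],
        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-14},
    )
    lam = res.x
    dec_wo_b = K @ (lam * y)
    on_margin = (lam > 1e-6) & (lam < C - 1e-6)
    if on_margin.any():
        b = float(np.mean(y[on_margin] - dec_wo_b[on_margin]))
    else:  # fall back to the KKT interval midpoint
        up = y * dec_wo_b
        lo = np.max((1 - up)[lam < C - 1e-6] * y[lam < C - 1e-6])
        b = float(lo)
    return lam, b, lambda Z: (Z @ X.T if kernel == "linear"
                              else rbf_kernel(Z, X, gamma)) @ (lam * y) + b


def separable_1d():
    X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
    y = np.array([-1.0, -1.0, 1.0, 1.0])
    return X, y


class TestTrain:
    def test_separable_1d_linear_boundary_between_classes(self):
        X, y = separable_1d()
        model = train(X, y, SVMConfig(kernel="linear", C=10.0,
                                      standardize=False))
        assert np.array_equal(predict(model, X), y)
        # boundary (zero crossing) lies strictly between the classes
        dec = decision_values(model, np.array([[-0.99], [0.99]]))
        assert dec[0] < 0 < dec[1]

    def test_xor_needs_the_rbf_kernel(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        lin = train(X, y, SVMConfig(kernel="linear", C=10.0))
        assert np.mean(predict(lin, X) == y) <= 0.75
        rbf = train(X, y, SVMConfig(kernel="rbf", C=10.0, gamma=1.0))
        assert np.mean(predict(rbf, X) == y) == 1.0

    def test_duplicating_points_keeps_the_boundary(self):
        X, y = separable_1d()
        cfg = SVMConfig(kernel="linear", C=10.0, standardize=False)
        m1 = train(X, y, cfg)
        m2 = train(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        probe = np.linspace(-3, 3, 13)[:, None]
        np.testing.assert_allclose(decision_values(m1, probe),
                                   decision_values(m2, probe), atol=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            train(np.arange(4.0)[:, None], np.ones(4))

    def test_dual_feasibility_on_every_grid_cell(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(1.5, 1, (10, 2))])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        for cfg in default_grid():
            model = train(X, y, cfg)  # train() raises if KKT is violated
            lam = model.multipliers
            assert np.all(lam >= -1e-6) and np.all(lam <= cfg.C + 1e-6)
            y_sv = np.sign(model.dual_coef)
            assert abs(np.sum(lam * y_sv)) < 1e-3

    @pytest.mark.parametrize("kernel,gamma", [("linear", 1.0), ("rbf", 0.5)])
    def test_decision_values_match_qp_oracle(self, kernel, gamma, rng):
        X = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(2.0, 1, (6, 2))])
        y = np.concatenate([-np.ones(6), np.ones(6)])
        cfg = SVMConfig(kernel=kernel, C=1.0, gamma=gamma, standardize=False)
        model = train(X, y, cfg)
        _, _, oracle_dec = svm_dual_oracle(X, y, 1.0, kernel, gamma)
        np.testing.assert_allclose(decision_values(model, X), oracle_dec(X),
                                   atol=1e-3)


class TestPredict:
    def test_margin_support_vector_keeps_its_label(self):
        X, y = separable_1d()
        model = train(X, y, SVMConfig(kernel="linear", C=10.0,
                                      standardize=False))
        lam = model.multipliers
        margin_sv = model.support_vectors[lam < 10.0 - 1e-6]
        labels = np.sign(model.dual_coef[lam < 10.0 - 1e-6])
        assert np.array_equal(predict(model, margin_sv), labels)

    def test_far_positive_point(self):
        X, y = separable_1d()
        model = train(X, y, SVMConfig(kernel="linear", C=10.0,
                                      standardize=False))
        assert predict(model, np.array([[50.0]]))[0] == 1

    def test_dimension_mismatch_rejected(self):
        X, y = separable_1d()
        model = train(X, y, SVMConfig(kernel="linear"))
        with pytest.raises(ValueError, match="dimension mismatch"):
            predict(model, np.ones((2, 3)))


class TestMetrics:
    @pytest.mark.parametrize("tp,tn,fp,fn,acc,se,sp", [
        (10, 10, 0, 0, 1.0, 1.0, 1.0),
        (0, 10, 0, 10, 0.5, 0.0, 1.0),
        (5, 5, 5, 5, 0.5, 0.5, 0.5),
        (9, 9, 1, 1, 0.9, 0.9, 0.9),
    ])
    def test_hand_computed_rates(self, tp, tn, fp, fn, acc, se, sp):
        m = metrics(tp, tn, fp, fn)
        assert (m.accuracy, m.sensitivity, m.specificity) == (acc, se, sp)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(0, 0, 0, 0)

    def test_zero_denominator_rate_is_nan(self):
        m = metrics(0, 5, 0, 0)
        assert np.isnan(m.sensitivity) and m.specificity == 1.0


class TestLOO:
    def _separable_set(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (10, 2)),
                       rng.normal(3.0, 0.3, (10, 2))])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        return X, y

    def test_separable_set_is_perfect(self, rng):
        X, y = self._separable_set(rng)
        results, best = loo_validate(X, y)
        m = results[best]
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)

    def test_grid_contains_reference_cell(self):
        grid = default_grid()
        assert any(c.kernel == "rbf" and c.gamma == 0.1 and c.C == 1.0
                   for c in grid)
        assert len(grid) == 12

    def test_permuted_labels_never_beat_chance(self, rng):
        # LOO with exactly balanced, permuted labels is pessimistically
        # biased (the training fold's majority votes against the held-out
        # sample), so the null accuracy sits at or below 0.5 on average —
        # the essential property is that no spurious skill appears
        cfg = SVMConfig(kernel="rbf", C=1.0, gamma=0.1)
        accs = []
        for _ in range(20):
            X = rng.normal(size=(20, 2))
            y = rng.permutation(np.concatenate([-np.ones(10), np.ones(10)]))
            accs.append(loo_single(X, y, cfg).accuracy)
        assert np.mean(accs) <= 0.55

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="per class"):
            loo_validate(np.arange(6.0)[:, None], np.ones(6))
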