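import math

import numpy as np
import pytest
from rdkit import Chem

from cycloqsar.chem_io import CompoundLibrary, CompoundRecord, Molecule
from cycloqsar.models import (
    PLSConfig,
    SVMConfig,
    SVRConfig,
    binarize,
    evaluate_classification,
    evaluate_regression,
    fit_binary_bayes,
    fit_pls,
    fit_svm,
    fit_svr,
    loo_cv,
    predict_bayes,
    rmse,
    squared_correlation,
)

# --------------------------------------------------------------------------
# binarization


def _library(values, cell="NCI-H446"):
    mol = Chem.MolFromSmiles("CC")
    recs = [
        CompoundRecord(Molecule(f"m{i}", mol), {cell: v})
        for i, v in enumerate(values)
    ]
    return CompoundLibrary(recs, (cell,))


def test_binarize_boundary_is_active():
    lab = binarize(_library([9.13, 9.131, 5.0, None]), "NCI-H446", 9.13)
    assert lab.labels.tolist() == [True, False, True]
    assert lab.excluded_ids == ["m3"]


def test_binarize_monotone_in_cutoff():
    vals = [1.0, 5.0, 20.0, 80.0]
    lib = _library(vals)
    prev = 0
    for cutoff in (0.5, 2.0, 10.0, 100.0):
        n_active = binarize(lib, "NCI-H446", cutoff).labels.sum()
        assert n_active >= prev
        prev = n_active


def test_binarize_single_class_warns_not_errors():
    lab = binarize(_library([1.0, 2.0]), "NCI-H446", 100.0)
    assert lab.labels.all() and lab.warnings


def test_binarize_rejects_bad_cutoff_and_empty():
    with pytest.raises(ValueError):
        binarize(_library([1.0]), "NCI-H446", 0.0)
    with pytest.raises(ValueError):
        binarize(_library([None]), "NCI-H446", 1.0)


# --------------------------------------------------------------------------
# PLS


def test_pls_recovers_noiseless_linear_response(rng):
    X = rng.normal(size=(30, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + 4.0
    model = fit_pls(X, y)
    pred = model.predict(X)
    assert squared_correlation(y, pred) >= 0.999999
    assert rmse(y, pred) <= 1e-8 * y.std()


def test_pls_predicts_out_of_sample_noiseless(rng):
    X = rng.normal(size=(30, 5))
    y = X @ np.array([2.0, 1.0, 0.0, -1.0, 0.5]) - 1.0
    model = fit_pls(X, y)
    Xt = rng.normal(size=(10, 5))
    yt = Xt @ np.array([2.0, 1.0, 0.0, -1.0, 0.5]) - 1.0
    assert rmse(yt, model.predict(Xt)) <= 1e-6 * y.std()


def test_pls_rank_one_data_uses_single_component(rng):
    t = rng.normal(size=20)
    X = np.outer(t, np.array([1.0, 2.0, -1.0]))
    y = 3.0 * t
    model = fit_pls(X, y)
    assert model.n_components == 1
    assert rmse(y, model.predict(X)) <= 1e-8


def test_pls_collinear_features_do_not_blow_up(rng):
    x = rng.normal(size=25)
    X = np.column_stack([x, x + 1e-12 * rng.normal(size=25), rng.normal(size=25)])
    y = x + 0.1 * X[:, 2]
    model = fit_pls(X, y)
    pred = model.predict(X)
    assert np.isfinite(pred).all()
    assert squared_correlation(y, pred) > 0.99


def test_pls_max_components_cap(rng):
    X = rng.normal(size=(15, 6))
    y = rng.normal(size=15)
    model = fit_pls(X, y, PLSConfig(max_components=2))
    assert model.n_components <= 2


def test_pls_rejects_constant_y_and_tiny_n(rng):
    with pytest.raises(ValueError):
        fit_pls(rng.normal(size=(10, 3)), np.ones(10))
    with pytest.raises(ValueError):
        fit_pls(rng.normal(size=(2, 3)), np.array([1.0, 2.0]))


def test_pls_deterministic(rng):
    X = rng.normal(size=(20, 4))
    y = rng.normal(size=20)
    p1 = fit_pls(X, y).predict(X)
    p2 = fit_pls(X, y).predict(X)
    assert np.array_equal(p1, p2)


# --------------------------------------------------------------------------
# SVR / SVM


def test_svr_fits_smooth_function(rng):
    X = rng.uniform(-2, 2, size=(60, 1))
    y = np.sin(X[:, 0])
    model = fit_svr(X, y, SVRConfig(cost=100.0, epsilon=0.01))
    assert rmse(y, model.predict(X)) < 0.05


def test_svr_constant_y_predicts_constant(rng):
    X = rng.normal(size=(10, 3))
    model = fit_svr(X, np.full(10, 2.5))
    assert np.allclose(model.predict(X), 2.5)


def test_svr_deterministic(rng):
    X = rng.normal(size=(30, 4))
    y = rng.normal(size=30)
    assert np.array_equal(fit_svr(X, y).predict(X), fit_svr(X, y).predict(X))


def test_svr_rejects_bad_hyperparameters():
    with pytest.raises(ValueError):
        SVRConfig(cost=0.0)
    with pytest.raises(ValueError):
        SVRConfig(epsilon=-1.0)


def test_svm_separable_perfect(rng):
    X = np.vstack([rng.normal(-3, 0.3, size=(15, 2)), rng.normal(3, 0.3, size=(15, 2))])
    y = np.array([False] * 15 + [True] * 15)
    model = fit_svm(X, y, SVMConfig(cost=10.0))
    assert (np.asarray(model.predict(X)).astype(bool) == y).all()


def test_svm_solves_xor_with_rbf():
    # a linear model cannot separate XOR; the RBF kernel must
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([False, True, True, False])
    model = fit_svm(X, y, SVMConfig(cost=10.0, gamma=1.0))
    assert np.asarray(model.predict(X)).astype(bool).tolist() == y.tolist()


def test_svm_rejects_single_class(rng):
    with pytest.raises(ValueError):
        fit_svm(rng.normal(size=(5, 2)), np.ones(5, dtype=bool))


# --------------------------------------------------------------------------
# binary Bayes


def oracle_bayes_proba(X_train, labels, X_query, n_bins=25, sigma=0.25, floor=1e-9):
    """Independent pure-Python naive-Bayes computation following the same
    histogram definition: min-max normalize per descriptor over the
    training range, equal bins, discrete Gaussian smoothing over bin
    offsets -n_bins..n_bins, floor, renormalize, naive product with class
    priors."""
    X_train = [list(map(float, r)) for r in X_train]
    labels = [bool(v) for v in labels]
    p = len(X_train[0])
    lo = [min(r[j] for r in X_train) for j in range(p)]
    hi = [max(r[j] for r in X_train) for j in range(p)]

    def to_bin(v, j):
        span = hi[j] - lo[j] if hi[j] > lo[j] else 1.0
        z = (v - lo[j]) / span
        z = min(max(z, 0.0), 1.0)
        return min(int(z * n_bins), n_bins - 1)

    sig_bins = sigma * n_bins
    kern = [math.exp(-0.5 * (k / sig_bins) ** 2) for k in range(-n_bins, n_bins + 1)]
    ksum = sum(kern)
    kern = [v / ksum for v in kern]

    pmf = {}
    for cls in (False, True):
        rows = [r for r, l in zip(X_train, labels) if l == cls]
        for j in range(p):
            hist = [0.0] * n_bins
            for r in rows:
                hist[to_bin(r[j], j)] += 1.0
            sm = [
                sum(hist[b] * kern[(i - b) + n_bins] for b in range(n_bins))
                for i in range(n_bins)
            ]
            sm = [v + floor for v in sm]
            tot = sum(sm)
            pmf[(cls, j)] = [v / tot for v in sm]

    n = len(labels)
    prior = {True: sum(labels) / n, False: (n - sum(labels)) / n}
    out = []
    for q in X_query:
        like = {}
        for cls in (False, True):
            v = prior[cls]
            for j in range(p):
                v *= pmf[(cls, j)][to_bin(float(q[j]), j)]
            like[cls] = v
        out.append(like[True] / (like[True] + like[False]))
    return out


def test_bayes_matches_oracle_on_random_instances():
    rng = np.random.default_rng(42)
    for trial in range(200):
        n = int(rng.integers(3, 9))
        p = int(rng.integers(1, 4))
        X = rng.normal(size=(n, p))
        labels = np.zeros(n, dtype=bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        Xq = rng.normal(size=(4, p))
        model = fit_binary_bayes(X, labels)
        got = model.predict_proba(Xq)
        want = oracle_bayes_proba(X, labels, Xq)
        assert np.allclose(got, want, atol=1e-9), trial


def test_bayes_probabilities_sum_to_one(rng):
    X = rng.normal(size=(20, 3))
    labels = np.array([True] * 10 + [False] * 10)
    model = fit_binary_bayes(X, labels)
    Xq = rng.normal(size=(50, 3)) * 5  # including out-of-range queries
    p_act = model.predict_proba(Xq)
    # P(inactive) from the flipped-label model must complement P(active)
    flip = fit_binary_bayes(X, ~labels)
    p_inact = flip.predict_proba(Xq)
    assert np.allclose(p_act + p_inact, 1.0, atol=1e-12)
    assert ((p_act > 0) & (p_act < 1)).all()


def test_bayes_uninformative_descriptor_returns_prior(rng):
    # identically distributed descriptor for both classes -> posterior ~ prior
    X = np.concatenate([np.linspace(0, 1, 8), np.linspace(0, 1, 8)])[:, None]
    labels = np.array([True] * 8 + [False] * 8)
    model = fit_binary_bayes(X, labels)
    assert predict_bayes(model, np.array([0.5])) == pytest.approx(0.5, abs=1e-9)


def test_bayes_separated_classes(rng):
    X = np.concatenate([rng.normal(0, 0.3, 15), rng.normal(10, 0.3, 15)])[:, None]
    labels = np.array([True] * 15 + [False] * 15)
    model = fit_binary_bayes(X, labels)
    assert predict_bayes(model, np.array([0.0])) > 0.95
    assert predict_bayes(model, np.array([10.0])) < 0.05


def test_bayes_pmf_normalized():
    rng = np.random.default_rng(3)
    model = fit_binary_bayes(rng.normal(size=(12, 2)), np.arange(12) % 2 == 0)
    assert np.allclose(model.pmf.sum(axis=2), 1.0, atol=1e-12)
    assert model.pmf.min() > 0


def test_bayes_clamps_out_of_range_queries(rng):
    X = rng.uniform(0, 1, size=(10, 1))
    labels = np.arange(10) % 2 == 0
    model = fit_binary_bayes(X, labels)
    before = model.clamp_events
    model.predict_proba(np.array([[5.0]]))
    assert model.clamp_events == before + 1
    # the clamped query scores like the extreme bin
    p_far = predict_bayes(model, np.array([5.0]))
    p_edge = predict_bayes(model, np.array([X.max()]))
    assert p_far == pytest.approx(p_edge, abs=1e-12)


def test_bayes_rejects_single_class_and_bad_bins(rng):
    X = rng.normal(size=(5, 2))
    with pytest.raises(ValueError):
        fit_binary_bayes(X, np.ones(5, dtype=bool))
    with pytest.raises(ValueError):
        fit_binary_bayes(X, np.arange(5) % 2 == 0, n_bins=1)
    with pytest.raises(ValueError):
        fit_binary_bayes(X, np.arange(5) % 2 == 0, sigma_smooth=0.0)


# --------------------------------------------------------------------------
# LOO-CV and reports


def test_loo_cv_linear_regression_is_exactable(rng):
    X = rng.normal(size=(10, 2))
    y = X @ np.array([1.0, 2.0])
    preds = loo_cv(lambda A, b: fit_pls(A, b), X, y)
    assert rmse(y, preds) < 1e-6


def test_loo_cv_classification_degenerate_fold_majority():
    # leaving out the single inactive row makes the remainder single-class;
    # the fold must predict the majority (active) without refitting
    X = np.arange(6, dtype=float)[:, None]
    y = np.array([False, True, True, True, True, True])

    def fit(A, b):
        return fit_binary_bayes(A, b, n_bins=5)

    preds = loo_cv(fit, X, y, classification=True)
    assert preds[0] == 1.0


def test_loo_cv_needs_three_rows(rng):
    with pytest.raises(ValueError):
        loo_cv(lambda A, b: fit_pls(A, b), rng.normal(size=(2, 2)), np.array([1.0, 2.0]))


def test_squared_correlation_properties(rng):
    y = rng.normal(size=30)
    assert squared_correlation(y, y) == pytest.approx(1.0)
    assert squared_correlation(y, -2 * y + 3) == pytest.approx(1.0)
    assert squared_correlation(y, np.ones(30)) == 0.0
    assert squared_correlation(np.ones(30), y) == 0.0


def test_rmse_hand_value():
    assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(
        math.sqrt(12.5)
    )


def test_evaluate_regression_reports_all_modes(rng):
    X = rng.normal(size=(20, 3))
    y = X @ np.array([1.0, -1.0, 0.5]) + 0.01 * rng.normal(size=20)
    Xt = rng.normal(size=(8, 3))
    yt = Xt @ np.array([1.0, -1.0, 0.5])
    rep = evaluate_regression(lambda A, b: fit_pls(A, b), X, y, Xt, yt)
    assert rep.R2 > 0.99 and rep.Q2 > 0.99 and rep.r2 > 0.99
    assert rep.RMSE < 0.1


def test_evaluate_classification_integer_accuracies(rng):
    X = np.vstack([rng.normal(-2, 0.3, size=(10, 2)), rng.normal(2, 0.3, size=(10, 2))])
    y = np.array([False] * 10 + [True] * 10)
    Xt = np.vstack([rng.normal(-2, 0.3, size=(4, 2)), rng.normal(2, 0.3, size=(4, 2))])
    yt = np.array([False] * 4 + [True] * 4)
    rep = evaluate_classification(lambda A, b: fit_svm(A, b), X, y, Xt, yt)
    assert rep.At.correct == 20 and rep.At.total == 20
    assert rep.Ap.value == 1.0
    assert isinstance(rep.Av.correct, int)


def test_evaluate_rejects_empty_test(rng):
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    with pytest.raises(ValueError):
        evaluate_regression(lambda A, b: fit_pls(A, b), X, y, np.empty((0, 2)), np.array([]))
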