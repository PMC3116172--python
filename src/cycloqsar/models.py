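"""Statistical back-ends for the QSAR pipeline and their evaluation.

Four models are provided: PLS regression (latent-variable linear model
with a condition limit on retained components), epsilon-insensitive RBF
support-vector regression, a binary Bayesian classifier built from
Gaussian-smoothed class-conditional descriptor histograms, and an
RBF-kernel SVM classifier.

Regression targets are log10(IC50); continuous activity is binarized for
the classifiers against the positive-control IC50 cut-off (a compound is
*active* when its IC50 is at most the cut-off, i.e. it is at least as
potent as the control).

Evaluation follows the three-mode convention: self-fit on training
(R2 / At), leave-one-out cross-validation on training (Q2, RMSE / Av) and
independent testing (r2 / Ap).  Squared correlation (Pearson) is used for
R2/Q2/r2; classification accuracies keep their integer numerators and
denominators.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVC, SVR

from cycloqsar.chem_io import CompoundLibrary


# --------------------------------------------------------------------------
# binarization

@dataclass
class BinaryLabeling:
    cell_line: str
    cutoff: float
    ids: list[str]
    labels: np.ndarray  # bool, aligned with ids; True = active
    excluded_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def binarize(library: CompoundLibrary, cell_line: str, cutoff: float) -> BinaryLabeling:
    """Label compounds active iff IC50 <= cutoff (boundary counts active).

    Compounds without a measurement for the cell line are excluded.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids, labels, excluded = [], [], []
    for rec in library:
        v = rec.ic50(cell_line)
        if v is None:
            excluded.append(rec.molecule.id)
        else:
            ids.append(rec.molecule.id)
            labels.append(v <= cutoff)
    if not ids:
        raise ValueError(f"no compound has an IC50 for {cell_line!r}")
    lab = np.array(labels, dtype=bool)
    warn = []
    if lab.all() or not lab.any():
        warn.append(f"single-class labeling for {cell_line!r} at cutoff {cutoff}")
    return BinaryLabeling(cell_line, cutoff, ids, lab, excluded, warn)


# --------------------------------------------------------------------------
# PLS

@dataclass
class PLSConfig:
    #: maximum latent components; None = no limit on the degree of the fit
    max_components: Optional[int] = None
    #: maximum condition number tolerated in the component transform
    condition_limit: float = 1.0e6


@dataclass
class PLSModel:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x k
    loadings: np.ndarray  # p x k
    coefs_q: np.ndarray  # k
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xc = (X - self.x_mean) / self.x_scale
        yhat = np.full(X.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xc @ self.weights[:, a]
            yhat = yhat + self.coefs_q[a] * t
            Xc = Xc - np.outer(t, self.loadings[:, a])
        return yhat


def fit_pls(X: np.ndarray, y: np.ndarray, config: PLSConfig | None = None) -> PLSModel:
    """NIPALS PLS1 on z-scored predictors and centered response.

    Components are added until the response is explained, the remaining
    covariance vanishes, the component limit is reached, or the ratio of
    the first to the current component's score variance exceeds the
    condition limit (ill-conditioned directions are not used).
    """
    config = config or PLSConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 training rows")
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    Xc = (X - x_mean) / x_scale
    y_mean = float(y.mean())
    yc = y - y_mean
    y_ss0 = float(yc @ yc)
    max_k = min(n - 1, p)
    if config.max_components is not None:
        max_k = min(max_k, config.max_components)
    W, P, Q = [], [], []
    t1_ss = None
    cov0 = None
    for _ in range(max_k):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if cov0 is None:
            cov0 = nw
        if nw <= 1e-12 * max(cov0, 1e-300):
            break
        w = w / nw
        t = Xc @ w
        t_ss = float(t @ t)
        if t_ss <= 1e-12:
            break
        if t1_ss is None:
            t1_ss = t_ss
        elif t1_ss / t_ss > config.condition_limit:
            break  # component beyond the conditioning of the transform
        pvec = Xc.T @ t / t_ss
        q = float(yc @ t / t_ss)
        W.append(w)
        P.append(pvec)
        Q.append(q)
        Xc = Xc - np.outer(t, pvec)
        yc = yc - q * t
        if float(yc @ yc) <= 1e-13 * y_ss0:
            break
    if not W:
        raise ValueError("no usable PLS component (X has no covariance with y)")
    return PLSModel(
        x_mean, x_scale, y_mean,
        np.column_stack(W), np.column_stack(P), np.array(Q), len(W),
    )


# --------------------------------------------------------------------------
# SVR / SVM

@dataclass
class SVRConfig:
    cost: float = 1.0
    epsilon: float = 0.1
    #: RBF kernel width gamma; None = 1/n_features on standardized data
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.epsilon < 0:
            raise ValueError("SVR hyperparameters must be positive")


@dataclass
class SVMConfig:
    cost: float = 1.0
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("SVM cost must be positive")


class _ScaledModel:
    """Wraps an sklearn estimator with the training z-scaling of X."""

    def __init__(self, est, x_mean, x_scale, constant: Optional[float] = None):
        self.est = est
        self.x_mean = x_mean
        self.x_scale = x_scale
        self.constant = constant

    def _scale(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) / self.x_scale

    def predict(self, X):
        if self.constant is not None:
            return np.full(np.asarray(X).shape[0], self.constant)
        return self.est.predict(self._scale(X))


def _zscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def fit_svr(X: np.ndarray, y: np.ndarray, config: SVRConfig | None = None) -> _ScaledModel:
    """Epsilon-insensitive RBF support-vector regression (deterministic)."""
    config = config or SVRConfig()
    y = np.asarray(y, dtype=float)
    Xs, mean, scale = _zscale(X)
    if np.ptp(y) == 0:
        return _ScaledModel(None, mean, scale, constant=float(y[0]))
    gamma = config.gamma if config.gamma is not None else 1.0 / Xs.shape[1]
    est = SVR(kernel="rbf", C=config.cost, epsilon=config.epsilon, gamma=gamma)
    est.fit(Xs, y)
    return _ScaledModel(est, mean, scale)


def fit_svm(X: np.ndarray, labels: np.ndarray, config: SVMConfig | None = None) -> _ScaledModel:
    """Soft-margin RBF support-vector classifier (deterministic)."""
    config = config or SVMConfig()
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("single-class training data")
    Xs, mean, scale = _zscale(X)
    gamma = config.gamma if config.gamma is not None else 1.0 / Xs.shape[1]
    est = SVC(kernel="rbf", C=config.cost, gamma=gamma)
    est.fit(Xs, labels.astype(int))
    return _ScaledModel(est, mean, scale)


# --------------------------------------------------------------------------
# binary Bayesian inference

@dataclass
class BayesModel:
    """Binary QSAR classifier from smoothed class-conditional histograms.

    For each descriptor, values are min-max normalized to [0, 1] over the
    training range, histogrammed per class over ``n_bins`` equal bins, and
    the histogram is convolved with a discrete Gaussian of width
    ``sigma_smooth`` (in normalized-range units) to avoid sensitivity to
    bin boundaries.  Prediction combines the per-descriptor likelihoods
    naively (independence assumption) with the class priors and labels a
    compound active when P(active) exceeds the decision threshold.
    """

    lo: np.ndarray  # per-descriptor training minimum
    hi: np.ndarray  # per-descriptor training maximum
    n_bins: int
    sigma_smooth: float
    #: log P(bin | class); shape (2, p, n_bins); class 0 = inactive, 1 = active
    log_pmf: np.ndarray
    log_prior: np.ndarray  # shape (2,)
    threshold: float = 0.5
    clamp_events: int = 0

    @property
    def pmf(self) -> np.ndarray:
        return np.exp(self.log_pmf)

    def _bins(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        z = (X - self.lo) / span
        clamped = (z < 0) | (z > 1)
        if clamped.any():
            self.clamp_events += int(clamped.sum())
        z = np.clip(z, 0.0, 1.0)
        b = np.minimum((z * self.n_bins).astype(int), self.n_bins - 1)
        return b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(active) for each row of X."""
        b = self._bins(X)
        n, p = b.shape
        ll = np.empty((n, 2))
        for c in (0, 1):
            ll[:, c] = self.log_prior[c] + self.log_pmf[c][np.arange(p), b].sum(axis=1)
        m = ll.max(axis=1, keepdims=True)
        w = np.exp(ll - m)
        return w[:, 1] / w.sum(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X) > self.threshold


def _gauss_kernel(n_bins: int, sigma_bins: float) -> np.ndarray:
    # kernel sampled at integer bin offsets, wide enough to cover the range
    half = n_bins  # offsets -n_bins..n_bins always cover every pair of bins
    off = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (off / sigma_bins) ** 2)
    return k / k.sum()


def fit_binary_bayes(
    X: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 25,
    sigma_smooth: float = 0.25,
    floor: float = 1e-9,
    threshold: float = 0.5,
) -> BayesModel:
    """Fit the binary Bayesian model.

    ``sigma_smooth`` is the Gaussian smoothing width on the [0, 1]
    normalized descriptor range.  A probability floor is applied before
    renormalization so no bin has zero mass.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=bool)
    if X.shape[0] != len(labels):
        raise ValueError("X and labels length mismatch")
    if labels.all() or not labels.any():
        raise ValueError("single-class training data")
    if n_bins < 2 or sigma_smooth <= 0:
        raise ValueError("invalid histogram specification")
    n, p = X.shape
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    z = np.clip((X - lo) / span, 0.0, 1.0)
    bins = np.minimum((z * n_bins).astype(int), n_bins - 1)
    kernel = _gauss_kernel(n_bins, sigma_smooth * n_bins)
    log_pmf = np.empty((2, p, n_bins))
    for c, mask in enumerate((~labels, labels)):
        for j in range(p):
            hist = np.bincount(bins[mask, j], minlength=n_bins).astype(float)
            # kernel has length 2*n_bins+1; the centered segment of the
            # full convolution aligns kernel offset 0 with each bin
            sm = np.convolve(hist, kernel, mode="full")[n_bins: 2 * n_bins]
            sm = sm + floor
            log_pmf[c, j] = np.log(sm / sm.sum())
    prior = np.array([(~labels).sum(), labels.sum()], dtype=float) / n
    return BayesModel(lo, hi, n_bins, sigma_smooth, log_pmf, np.log(prior), threshold)


def predict_bayes(model: BayesModel, x: np.ndarray) -> float:
    """P(active) for a single descriptor vector."""
    return float(model.predict_proba(np.atleast_2d(x))[0])


# --------------------------------------------------------------------------
# cross-validation and reports

def loo_cv(
    fit: Callable[[np.ndarray, np.ndarray], object],
    X: np.ndarray,
    y: np.ndarray,
    classification: bool = False,
) -> np.ndarray:
    """Leave-one-out predictions: refit on n-1 rows, predict the held-out row.

    For classification folds whose remaining rows are single-class, the
    fold predicts that majority class (degenerate-refit rule).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for LOO-CV")
    preds = np.empty(n, dtype=float)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yi = y[mask]
        if classification and (yi.astype(bool).all() or not yi.astype(bool).any()):
            preds[i] = float(yi.astype(bool)[0])
            continue
        model = fit(X[mask], yi)
        preds[i] = float(np.asarray(model.predict(X[i: i + 1]))[0])
    return preds


def squared_correlation(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation; 0 when either side is constant."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return 0.0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        r = stats.pearsonr(obs, pred).statistic
    return float(r * r)


def rmse(obs: np.ndarray, pred: np.ndarray) -> float:
    d = np.asarray(obs, dtype=float) - np.asarray(pred, dtype=float)
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class RegressionReport:
    R2: float  # self-fit squared correlation on training
    Q2: float  # LOO-CV squared correlation on training
    RMSE: float  # LOO-CV root-mean-square error
    r2: float  # squared correlation on the independent test set

    def as_dict(self) -> dict[str, float]:
        return {"R2": self.R2, "Q2": self.Q2, "r2": self.r2, "RMSE": self.RMSE}


@dataclass
class Accuracy:
    correct: int
    total: int

    @property
    def value(self) -> float:
        return self.correct / self.total


@dataclass
class ClassificationReport:
    At: Accuracy  # training self-fit
    Av: Accuracy  # LOO-CV on training
    Ap: Accuracy  # independent test

    def as_dict(self) -> dict[str, float]:
        return {"At": self.At.value, "Av": self.Av.value, "Ap": self.Ap.value}


def evaluate_regression(
    fit: Callable[[np.ndarray, np.ndarray], object],
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> RegressionReport:
    if len(np.atleast_1d(y_test)) == 0:
        raise ValueError("empty test set")
    model = fit(X_train, y_train)
    r2_train = squared_correlation(y_train, model.predict(X_train))
    loo = loo_cv(fit, X_train, y_train)
    return RegressionReport(
        R2=r2_train,
        Q2=squared_correlation(y_train, loo),
        RMSE=rmse(y_train, loo),
        r2=squared_correlation(y_test, model.predict(X_test)),
    )


def evaluate_classification(
    fit: Callable[[np.ndarray, np.ndarray], object],
    X_train: np.ndarray,
    labels_train: np.ndarray,
    X_test: np.ndarray,
    labels_test: np.ndarray,
) -> ClassificationReport:
    labels_train = np.asarray(labels_train, dtype=bool)
    labels_test = np.asarray(labels_test, dtype=bool)
    if len(labels_test) == 0:
        raise ValueError("empty test set")
    model = fit(X_train, labels_train)
    pred_train = np.asarray(model.predict(X_train)).astype(bool)
    loo = loo_cv(fit, X_train, labels_train, classification=True) > 0.5
    pred_test = np.asarray(model.predict(X_test)).astype(bool)
    return ClassificationReport(
        At=Accuracy(int((pred_train == labels_train).sum()), len(labels_train)),
        Av=Accuracy(int((loo == labels_train).sum()), len(labels_train)),
        Ap=Accuracy(int((pred_test == labels_test).sum()), len(labels_test)),
    )
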