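"""Classifiers and the leave-one-subject-out evaluation harness.

The workhorse classifier is an **extreme learning machine** (ELM): a single
hidden layer whose input weights and biases are drawn once, uniform on
[-1, 1], and frozen; the hidden activation is the triangular basis function
tribas(u) = max(1 - |u|, 0); only the output weights are learned, by
ridge-regularized least squares.  Features are min-max normalized to
[-1, 1] and PCA-reduced to 30 dimensions before training.  For fixed-length
per-window feature sequences a two-layer LSTM (200 and 100 units, SGD with
momentum) replaces the ELM.

Evaluation is leave-one-subject-out (LOSO): each fold trains on every other
subject's trials and tests on the held-out subject, which is the honest
protocol when trials within a subject are strongly correlated.  Accuracy
and rank-based AUC are collected per subject and summarized as mean ± std.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

#: domain labels mapped to the positive (+1) class
POSITIVE_LABELS = {"high", "hazardous", 1, 1.0, True, "1"}


def tribas(u: np.ndarray) -> np.ndarray:
    """Triangular basis activation: max(1 - |u|, 0)."""
    return np.maximum(1.0 - np.abs(u), 0.0)


def _positive_class(classes: np.ndarray):
    for c in classes:
        if c in POSITIVE_LABELS:
            return c
    return classes[-1]


def encode_labels(y) -> tuple[np.ndarray, object]:
    """Binary labels -> ±1 (high-attention / hazardous = +1); returns the
    encoded vector and the positive class label."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    pos = _positive_class(classes)
    return np.where(y == pos, 1.0, -1.0), pos


# ---------------------------------------------------------------------------
# Normalization and PCA

class SymmetricMinMaxScaler(TransformerMixin, BaseEstimator):
    """Per-column affine map sending the fitted min to -1 and max to +1.

    Constant columns map to 0.  Values outside the fitted range are *not*
    clipped, so a test value above the training max exceeds +1 — by design,
    the map is frozen at fit time.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        span = self.data_max_ - self.data_min_
        self.scale_ = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        X = check_array(X)
        return (X - self.data_min_) * self.scale_ - np.where(self.scale_ > 0, 1.0, 0.0)


def normalize_features(X: np.ndarray, fit_X: np.ndarray | None = None) -> np.ndarray:
    """Min-max normalize columns of ``X`` to [-1, 1] (fit on ``fit_X`` if given)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    scaler = SymmetricMinMaxScaler().fit(X if fit_X is None else fit_X)
    return scaler.transform(X)


def pca_reduce(X: np.ndarray, k: int, fitted: PCA | None = None
               ) -> tuple[np.ndarray, PCA]:
    """Project onto the top-``k`` principal axes (components ordered by
    decreasing explained variance); returns the projection and fitted basis."""
    X = np.asarray(X, dtype=float)
    if fitted is None:
        if k > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"k={k} exceeds min(n_samples - 1, n_features) = "
                f"{min(X.shape[0] - 1, X.shape[1])}")
        # auto solver: exact SVD on small inputs, seeded randomized SVD on
        # wide embedding matrices where a full decomposition is wasteful
        fitted = PCA(n_components=k, svd_solver="auto", random_state=0).fit(X)
    return fitted.transform(X), fitted


# ---------------------------------------------------------------------------
# Extreme learning machine

class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer extreme learning machine with tribas activation.

    Input weights and biases are drawn uniform on [-1, 1] from
    ``random_state`` and frozen; output weights solve the ridge-regularized
    least-squares problem H beta = y (y encoded ±1).  The decision rule is
    sign(H beta), with score exactly 0 assigned to the positive class.

    Parameters
    ----------
    n_hidden : hidden-layer width (170 by default).
    alpha : ridge regularization of the output-weight solve.
    random_state : seed for the frozen input layer.
    """

    def __init__(self, n_hidden: int = 170, alpha: float = 1e-6,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.alpha = alpha
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        return tribas(X @ self.input_weights_.T + self.biases_)

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("ELM needs both classes present in y")
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        self.positive_class_ = _positive_class(self.classes_)
        t = np.where(y == self.positive_class_, 1.0, -1.0)
        rng = np.random.default_rng(self.random_state)
        self.input_weights_ = rng.uniform(-1, 1, (self.n_hidden, X.shape[1]))
        self.biases_ = rng.uniform(-1, 1, self.n_hidden)
        H = self._hidden(X)
        A = H.T @ H + self.alpha * np.eye(self.n_hidden)
        self.output_weights_ = np.linalg.solve(A, H.T @ t)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with "
                f"{self.n_features_in_}")
        return self._hidden(X) @ self.output_weights_

    def predict(self, X):
        scores = self.decision_function(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(scores >= 0, self.positive_class_, neg)


# ---------------------------------------------------------------------------
# Two-layer LSTM (NumPy, SGD with momentum)

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class _LSTMLayer:
    """One LSTM layer, batch-major forward/backward with full BPTT."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in + d_hidden)
        self.Wx = rng.uniform(-s, s, (d_in, 4 * d_hidden))
        self.Wh = rng.uniform(-s, s, (d_hidden, 4 * d_hidden))
        self.b = np.zeros(4 * d_hidden)
        self.b[d_hidden:2 * d_hidden] = 1.0        # forget-gate bias init
        self.d_hidden = d_hidden
        self.v = {n: np.zeros_like(getattr(self, n)) for n in ("Wx", "Wh", "b")}

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        h = np.zeros((B, self.d_hidden))
        c = np.zeros((B, self.d_hidden))
        self._cache = []
        self._X = X
        H = np.empty((B, T, self.d_hidden))
        dh = self.d_hidden
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :dh])
            f = _sigmoid(z[:, dh:2 * dh])
            g = np.tanh(z[:, 2 * dh:3 * dh])
            o = _sigmoid(z[:, 3 * dh:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, c_new, tanh_c))
            h, c = h_new, c_new
            H[:, t] = h
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        X = self._X
        B, T, d_in = X.shape
        dh = self.d_hidden
        gWx = np.zeros_like(self.Wx)
        gWh = np.zeros_like(self.Wh)
        gb = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, dh))
        dc_next = np.zeros((B, dh))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._cache[t]
            dht = dH[:, t] + dh_next
            do = dht * tanh_c
            dc = dht * o * (1 - tanh_c ** 2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            gWx += X[:, t].T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self.grads = {"Wx": gWx, "Wh": gWh, "b": gb}
        return dX

    def sgdm_step(self, lr: float, momentum: float, batch: int):
        for n in ("Wx", "Wh", "b"):
            self.v[n] = momentum * self.v[n] - lr * self.grads[n] / batch
            setattr(self, n, getattr(self, n) + self.v[n])


class LSTMClassifier(ClassifierMixin, BaseEstimator):
    """Two-layer stacked LSTM (200, 100 units) for fixed-length sequences.

    Many-to-one readout from the final step of the second layer into a
    logistic output; trained with stochastic gradient descent with momentum
    (SGDM).  Inputs are (n_sequences, n_steps, n_features) arrays whose
    per-step features are expected PCA-reduced to ``expected_input_dim``
    (60 by default; set None to disable the width check).  Sequence
    classification requires a fixed trial duration — ragged inputs are
    rejected, since every time series must have the same length.
    """

    def __init__(self, layer_sizes: tuple[int, int] = (200, 100),
                 learning_rate: float = 0.01, momentum: float = 0.9,
                 epochs: int = 50, batch_size: int = 16,
                 expected_input_dim: int | None = 60,
                 random_state: int | None = None):
        self.layer_sizes = layer_sizes
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.expected_input_dim = expected_input_dim
        self.random_state = random_state

    def _validate_sequences(self, X) -> np.ndarray:
        if isinstance(X, (list, tuple)):
            lengths = {np.asarray(s).shape[0] for s in X}
            if len(lengths) > 1:
                raise ValueError(
                    "ragged sequence lengths: sequence classification "
                    "requires trials of fixed duration so every time series "
                    f"has the same length (got lengths {sorted(lengths)})")
            X = np.stack([np.asarray(s, dtype=float) for s in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_sequences, n_steps, n_features)")
        if (self.expected_input_dim is not None
                and X.shape[2] != self.expected_input_dim):
            raise ValueError(
                f"per-step feature width {X.shape[2]} != expected "
                f"{self.expected_input_dim} (PCA-reduce per-step features, "
                "or set expected_input_dim=None)")
        return X

    def fit(self, X, y):
        X = self._validate_sequences(X)
        y = np.asarray(y)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.positive_class_ = _positive_class(self.classes_)
        t = np.where(y == self.positive_class_, 1.0, 0.0)

        rng = np.random.default_rng(self.random_state)
        h1, h2 = self.layer_sizes
        self.layers_ = [_LSTMLayer(X.shape[2], h1, rng),
                        _LSTMLayer(h1, h2, rng)]
        s = 1.0 / np.sqrt(h2)
        self.w_out_ = rng.uniform(-s, s, h2)
        self.b_out_ = 0.0
        self._v_out = np.zeros(h2)
        self._v_b = 0.0

        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xb, tb = X[idx], t[idx]
                H1 = self.layers_[0].forward(Xb)
                H2 = self.layers_[1].forward(H1)
                hT = H2[:, -1]
                logits = hT @ self.w_out_ + self.b_out_
                p = _sigmoid(logits)
                eps = 1e-12
                epoch_loss += float(
                    -(tb * np.log(p + eps)
                      + (1 - tb) * np.log(1 - p + eps)).sum())
                dlogit = p - tb                      # dL/dlogit, per sample
                gw = hT.T @ dlogit
                gb = dlogit.sum()
                dH2 = np.zeros_like(H2)
                dH2[:, -1] = np.outer(dlogit, self.w_out_)
                dH1 = self.layers_[1].backward(dH2)
                self.layers_[0].backward(dH1)
                B = len(idx)
                self.layers_[1].sgdm_step(self.learning_rate, self.momentum, B)
                self.layers_[0].sgdm_step(self.learning_rate, self.momentum, B)
                self._v_out = (self.momentum * self._v_out
                               - self.learning_rate * gw / B)
                self.w_out_ = self.w_out_ + self._v_out
                self._v_b = self.momentum * self._v_b - self.learning_rate * gb / B
                self.b_out_ = self.b_out_ + self._v_b
            self.loss_curve_.append(epoch_loss / n)
        self.n_features_in_ = X.shape[2]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "w_out_")
        X = self._validate_sequences(X)
        H1 = self.layers_[0].forward(X)
        H2 = self.layers_[1].forward(H1)
        return H2[:, -1] @ self.w_out_ + self.b_out_

    def predict(self, X):
        scores = self.decision_function(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(scores >= 0, self.positive_class_, neg)


# ---------------------------------------------------------------------------
# Metrics and statistics

def auc(scores, labels) -> float:
    """Rank-based AUC (ties count 1/2); needs both classes present."""
    labels = np.asarray(labels)
    enc, _ = encode_labels(labels)
    if len(np.unique(enc)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score((enc + 1) / 2, np.asarray(scores, dtype=float)))


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test; zero-variance differences give p=1 + warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired t-test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        warnings.warn("zero-variance paired differences; p reported as 1",
                      RuntimeWarning, stacklevel=2)
        return 0.0, 1.0
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p across >= 2 groups."""
    if (len(groups) == 1 and isinstance(groups[0], (list, tuple))
            and all(np.ndim(g) >= 1 for g in groups[0])):
        groups = tuple(groups[0])          # called with a list of groups
    if len(groups) < 2 or any(np.ndim(g) == 0 for g in groups):
        raise ValueError("ANOVA needs at least 2 groups of observations")
    res = sp_stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


@dataclass
class CVResult:
    """Per-subject LOSO metrics plus their summary.

    ``p_value`` is the two-sided one-sample t-test of the per-subject
    accuracies against chance (0.5); folds whose test labels are
    single-class get ``nan`` AUC and are dropped from the AUC mean.
    """

    subjects: list = field(default_factory=list)
    per_subject_accuracy: list = field(default_factory=list)   # percent
    per_subject_auc: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_subject_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.per_subject_accuracy, ddof=1))

    @property
    def mean_auc(self) -> float:
        a = np.asarray(self.per_subject_auc, dtype=float)
        return float(np.nanmean(a)) if np.any(~np.isnan(a)) else float("nan")

    @property
    def std_auc(self) -> float:
        a = np.asarray(self.per_subject_auc, dtype=float)
        a = a[~np.isnan(a)]
        return float(np.std(a, ddof=1)) if len(a) > 1 else float("nan")

    @property
    def p_value(self) -> float:
        accs = np.asarray(self.per_subject_accuracy, dtype=float) / 100.0
        if np.std(accs, ddof=1) == 0:
            return 1.0 if np.mean(accs) == 0.5 else 0.0
        return float(sp_stats.ttest_1samp(accs, 0.5).pvalue)

    def summary(self) -> dict:
        return {
            "subjects": list(self.subjects),
            "per_subject_accuracy_pct": list(map(float, self.per_subject_accuracy)),
            "per_subject_auc": [None if np.isnan(v) else float(v)
                                for v in self.per_subject_auc],
            "mean_accuracy_pct": self.mean_accuracy,
            "std_accuracy_pct": self.std_accuracy,
            "mean_auc": self.mean_auc,
            "std_auc": self.std_auc,
            "p_value_vs_chance": self.p_value,
        }


def loso_cv(X, y, subjects, classifier=None, pca_k: int | None = 30,
            scaler_scope: str = "train_only", seed: int = 0) -> CVResult:
    """Leave-one-subject-out CV over a feature matrix or sequence array.

    Per fold: PCA is fit on the training subjects, then the projected
    coordinates are min-max normalized to [-1, 1] (PCA-first keeps the
    tribas hidden layer in its active range), then the classifier is
    trained and the held-out subject scored.  ``scaler_scope='global'``
    restores a fit across all subjects — the simpler protocol, but it leaks
    the held-out subject's range.  3-D input (n, steps, features) selects
    the sequence route: PCA/scaler are fit on stacked training frames and
    the classifier defaults to the LSTM.
    """
    if scaler_scope not in ("train_only", "global"):
        raise ValueError("scaler_scope must be 'train_only' or 'global'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    if not (len(X) == len(y) == len(subjects)):
        raise ValueError("X, y, subjects must be equal length")
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    sequences = X.ndim == 3
    if classifier is None:
        classifier = (LSTMClassifier(random_state=seed, expected_input_dim=None)
                      if sequences else ELMClassifier(random_state=seed))

    def prep(train_X, test_X):
        if sequences:
            ntr, T, d = train_X.shape
            tr = train_X.reshape(-1, d)
            te = test_X.reshape(-1, d)
            all_flat = X.reshape(-1, d)
            if pca_k is not None:
                fit_src = tr if scaler_scope == "train_only" else all_flat
                k = min(pca_k, fit_src.shape[0] - 1, fit_src.shape[1])
                _, basis = pca_reduce(fit_src, k)
                tr, te = basis.transform(tr), basis.transform(te)
            scaler = SymmetricMinMaxScaler().fit(
                tr if scaler_scope == "train_only"
                else np.concatenate([tr, te]))
            return (scaler.transform(tr).reshape(ntr, T, -1),
                    scaler.transform(te).reshape(test_X.shape[0], T, -1))
        tr, te = train_X, test_X
        if pca_k is not None:
            fit_src = tr if scaler_scope == "train_only" else X
            # never more components than the fold's fitting data supports
            k = min(pca_k, fit_src.shape[0] - 1, fit_src.shape[1])
            _, basis = pca_reduce(fit_src, k)
            tr, te = basis.transform(tr), basis.transform(te)
        scaler = SymmetricMinMaxScaler().fit(
            tr if scaler_scope == "train_only" else np.concatenate([tr, te]))
        return scaler.transform(tr), scaler.transform(te)

    result = CVResult()
    for held_out in uniq:
        test_mask = subjects == held_out
        tr_X, te_X = prep(X[~test_mask], X[test_mask])
        clf = clone(classifier)
        clf.fit(tr_X, y[~test_mask])
        pred = clf.predict(te_X)
        acc = float(np.mean(pred == y[test_mask])) * 100.0
        scores = clf.decision_function(te_X)
        if len(np.unique(y[test_mask])) < 2:
            fold_auc = float("nan")
        else:
            fold_auc = auc(scores, y[test_mask])
        result.subjects.append(held_out)
        result.per_subject_accuracy.append(acc)
        result.per_subject_auc.append(fold_auc)
    return result
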