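"""Spectral classifiers: the 1-D CNN core model and its six rivals.

The core model convolves the spectrum with ``r`` width-``k`` filters
(rectified linear), max-pools the resulting feature-map matrix, and feeds the
pooled feature through a dense softmax output layer, trained by minimizing
cross-entropy over original plus generated samples:

    f_l = ReLU(w . x_{l..l+k-1} + b),          l = 1 .. d-k+1
    F~  = Maxpool(F),                           F in R^{r x (d-k+1)}
    y^  = softmax(W_o F~ + b_o)

Two pooling readings are provided: ``filter`` pools across the filter axis
(output length d-k+1, matching a pooled feature of that stated size) and
``global`` pools across positions (output length r, the conventional
reading). ``filter`` is the default.

Rival families: softmax/logistic regression (LR), PCA followed by LR, linear
SVM (max 500 iterations) with logistic calibration for probabilities, PCA
followed by SVM, a (100, 32) MLP, and an LSTM over the spectrum as an ordered
sequence. All neural models train with Adam at learning rate 1e-3 for a
configurable number of epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.svm import LinearSVC

from ._nn import Adam, Dense, Param, ReLU, Sequential, minibatches, softmax
from .dataset import SpectraDataset
from .scaling import SpectrumScaler

__all__ = [
    "ClassifierSpec",
    "conv1d_map",
    "filterwise_max_pool",
    "softmax_output",
    "cross_entropy",
    "pca_reduce",
    "pca_project",
    "CNNSpectrumClassifier",
    "SoftmaxRegression",
    "MLPSpectrumClassifier",
    "LSTMSpectrumClassifier",
    "CalibratedLinearSVM",
    "make_classifier",
    "train_classifier",
    "predict_proba",
]

KINDS = ("LR", "PCA_LR", "SVM", "PCA_SVM", "MLP", "LSTM", "CNN")

_LOG_EPS = 1e-12


# ---------------------------------------------------------------------------
# elementary operations (exposed for direct testing against oracles)


def conv1d_map(x: np.ndarray, w: np.ndarray, b: float = 0.0) -> np.ndarray:
    """Rectified 1-D valid convolution of one filter with one spectrum:
    output length d - k + 1."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if w.size > x.size:
        raise ValueError(f"kernel width {w.size} exceeds spectrum length {x.size}")
    windows = sliding_window_view(x, w.size)
    return np.maximum(windows @ w + b, 0.0)


def filterwise_max_pool(F: np.ndarray, mode: str = "filter") -> np.ndarray:
    """Max-pool a feature-map matrix of r filters by d-k+1 positions.

    ``filter``: max across the filter axis (length d-k+1);
    ``global``: max across the position axis (length r).
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.size == 0:
        raise ValueError("feature map must be a non-empty 2-D matrix")
    if mode == "filter":
        return F.max(axis=0)
    if mode == "global":
        return F.max(axis=1)
    raise ValueError(f"unknown pooling mode {mode!r}")


def softmax_output(features: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Dense softmax head: softmax(features @ W + b)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if features.shape[1] != W.shape[0] or W.shape[1] != b.shape[0]:
        raise ValueError("inconsistent shapes for softmax output layer")
    out = softmax(features @ W + b)
    return out[0] if out.shape[0] == 1 else out


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean cross-entropy -(1/N) sum_i y_i . log yhat_i with clamped logs."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return float(-(y_true * np.log(np.clip(y_pred, _LOG_EPS, None))).sum(axis=1).mean())


def pca_reduce(train: SpectraDataset, n_components: int) -> PCA:
    """Fit a PCA basis from the training data only."""
    limit = min(train.n, train.d)
    if n_components > limit:
        raise ValueError(f"n_components={n_components} exceeds min(n, d)={limit}")
    return PCA(n_components=n_components, svd_solver="full").fit(train.X)


def pca_project(basis: PCA, dataset: SpectraDataset) -> np.ndarray:
    return basis.transform(dataset.X)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ClassifierSpec:
    """Hyperparameters of one classifier family (printed defaults)."""

    kind: str = "CNN"
    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 32
    filters: int = 120          # CNN: r
    kernel: int = 5             # CNN: k
    pooling: str = "filter"     # CNN: "filter" (length d-k+1) or "global" (length r)
    mlp_hidden: tuple[int, ...] = (100, 32)
    lstm_hidden: int = 100
    lstm_dense: tuple[int, ...] = (10, 500)
    lstm_window: int = 8
    pca_components: int = 100
    svm_max_iter: int = 500
    scaler: str = "minmax01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.filters < 1 or self.kernel < 1:
            raise ValueError("filters and kernel width must be >= 1")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs >= 0 and learning_rate > 0 required")


# ---------------------------------------------------------------------------
# estimators


class _SpectrumClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared scaffolding: label encoding, train-fold scaling, proba contract."""

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y)), dtype=object)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least 2 classes")
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lut[v] for v in y], dtype=int)

    def _scale_fit(self, X) -> np.ndarray:
        self.scaler_ = SpectrumScaler(self.scaler).fit(X)
        return self.scaler_.transform(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        # np.argmax breaks ties toward the lowest class index
        return self.classes_[np.argmax(proba, axis=1)]


class _AdamSoftmaxMixin:
    """Minibatch Adam training of a softmax model given forward/backward hooks."""

    def _train_loop(self, Xs, y_idx, params, forward, backward):
        n = Xs.shape[0]
        K = len(self.classes_)
        Y = np.zeros((n, K))
        Y[np.arange(n), y_idx] = 1.0
        rng = np.random.default_rng(self.seed)
        opt = Adam(params, lr=self.learning_rate)
        batch = min(self.batch_size, n)
        self.loss_history_ = []
        for _ in range(self.epochs):
            losses = []
            for idx in minibatches(n, batch, rng):
                logits = forward(idx)
                p = softmax(logits)
                losses.append(cross_entropy(Y[idx], p))
                opt.zero_grad()
                backward((p - Y[idx]) / idx.size, idx)
                opt.step()
            self.loss_history_.append(float(np.mean(losses)))
        return self


class SoftmaxRegression(_SpectrumClassifierBase, _AdamSoftmaxMixin):
    """Logistic regression as a single dense softmax layer, optionally after PCA."""

    def __init__(self, epochs=500, learning_rate=1e-3, batch_size=32,
                 pca_components=None, scaler="minmax01", seed=0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.pca_components = pca_components
        self.scaler = scaler
        self.seed = seed

    def _features(self, X, fit: bool):
        if fit:
            Xs = self._scale_fit(X)
            if self.pca_components is not None:
                self.pca_ = PCA(self.pca_components, svd_solver="full").fit(Xs)
                Xs = self.pca_.transform(Xs)
            else:
                self.pca_ = None
            return Xs
        Xs = self.scaler_.transform(X)
        return self.pca_.transform(Xs) if self.pca_ is not None else Xs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y_idx = self._encode(y)
        Xs = self._features(X, fit=True)
        rng = np.random.default_rng(self.seed)
        K = len(self.classes_)
        self.W_ = Param(rng.normal(0, 0.01, (Xs.shape[1], K)))
        self.b_ = Param(np.zeros(K))

        def forward(idx):
            return Xs[idx] @ self.W_.value + self.b_.value

        def backward(dlogits, idx):
            self.W_.grad += Xs[idx].T @ dlogits
            self.b_.grad += dlogits.sum(axis=0)

        self.n_features_in_ = X.shape[1]
        return self._train_loop(Xs, y_idx, [self.W_, self.b_], forward, backward)

    def predict_proba(self, X):
        Xs = self._features(np.asarray(X, dtype=float), fit=False)
        return softmax(Xs @ self.W_.value + self.b_.value)


class MLPSpectrumClassifier(_SpectrumClassifierBase, _AdamSoftmaxMixin):
    """Multilayer perceptron: dense (100, 32) hidden stack, ReLU, softmax head."""

    def __init__(self, hidden=(100, 32), epochs=500, learning_rate=1e-3,
                 batch_size=32, scaler="minmax01", seed=0):
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.scaler = scaler
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y_idx = self._encode(y)
        Xs = self._scale_fit(X)
        rng = np.random.default_rng(self.seed)
        K = len(self.classes_)
        layers, n_in = [], Xs.shape[1]
        for width in self.hidden:
            layers += [Dense(n_in, width, rng), ReLU()]
            n_in = width
        layers.append(Dense(n_in, K, rng))
        self.net_ = Sequential(layers)

        def forward(idx):
            return self.net_.forward(Xs[idx], train=True)

        def backward(dlogits, idx):
            self.net_.backward(dlogits)

        self.n_features_in_ = X.shape[1]
        return self._train_loop(Xs, y_idx, self.net_.params(), forward, backward)

    def predict_proba(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return softmax(self.net_.forward(Xs, train=False))


class CNNSpectrumClassifier(_SpectrumClassifierBase, _AdamSoftmaxMixin):
    """The 1-D convolutional core model: r rectified filters of width k,
    max pooling over the feature-map matrix, dense softmax output."""

    def __init__(self, filters=120, kernel=5, pooling="filter", epochs=500,
                 learning_rate=1e-3, batch_size=32, scaler="minmax01", seed=0):
        self.filters = filters
        self.kernel = kernel
        self.pooling = pooling
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.scaler = scaler
        self.seed = seed

    def _conv_pool(self, windows):
        """windows: (n, L, k) -> pre-activations, rectified maps, pooled features."""
        pre = windows @ self.Wf_.value + self.bf_.value  # (n, L, r)
        act = np.maximum(pre, 0.0)
        if self.pooling == "filter":
            pooled = act.max(axis=2)   # over filters -> (n, L)
        else:
            pooled = act.max(axis=1)   # over positions -> (n, r)
        return pre, act, pooled

    def fit(self, X, y):
        if self.pooling not in ("filter", "global"):
            raise ValueError("pooling must be 'filter' or 'global'")
        X = np.asarray(X, dtype=float)
        if self.kernel > X.shape[1]:
            raise ValueError("kernel width exceeds spectrum length")
        y_idx = self._encode(y)
        Xs = self._scale_fit(X)
        rng = np.random.default_rng(self.seed)
        K = len(self.classes_)
        k, r = self.kernel, self.filters
        L = Xs.shape[1] - k + 1
        self.Wf_ = Param(rng.normal(0, np.sqrt(2.0 / k), (k, r)))
        self.bf_ = Param(np.zeros(r))
        n_pooled = L if self.pooling == "filter" else r
        self.Wo_ = Param(rng.normal(0, 0.01, (n_pooled, K)))
        self.bo_ = Param(np.zeros(K))
        windows = sliding_window_view(Xs, k, axis=1)  # (n, L, k) view

        state = {}

        def forward(idx):
            w = windows[idx]
            pre, act, pooled = self._conv_pool(w)
            state.update(w=w, pre=pre, act=act, pooled=pooled)
            return pooled @ self.Wo_.value + self.bo_.value

        def backward(dlogits, idx):
            pooled = state["pooled"]
            self.Wo_.grad += pooled.T @ dlogits
            self.bo_.grad += dlogits.sum(axis=0)
            dpooled = dlogits @ self.Wo_.value.T
            act, pre, w = state["act"], state["pre"], state["w"]
            dact = np.zeros_like(act)
            if self.pooling == "filter":
                am = act.argmax(axis=2)  # winning filter per position
                np.put_along_axis(dact, am[:, :, None], dpooled[:, :, None], axis=2)
            else:
                am = act.argmax(axis=1)  # winning position per filter
                np.put_along_axis(dact, am[:, None, :], dpooled[:, None, :], axis=1)
            dpre = dact * (pre > 0)
            nb, L_, _ = w.shape
            self.Wf_.grad += w.reshape(nb * L_, k).T @ dpre.reshape(nb * L_, r)
            self.bf_.grad += dpre.sum(axis=(0, 1))

        params = [self.Wf_, self.bf_, self.Wo_, self.bo_]
        self.n_features_in_ = X.shape[1]
        return self._train_loop(Xs, y_idx, params, forward, backward)

    def predict_proba(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        windows = sliding_window_view(Xs, self.kernel, axis=1)
        _, _, pooled = self._conv_pool(windows)
        return softmax(pooled @ self.Wo_.value + self.bo_.value)


class LSTMSpectrumClassifier(_SpectrumClassifierBase, _AdamSoftmaxMixin):
    """LSTM over the spectrum as an ordered sequence (chunked into windows of
    ``window`` adjacent wavenumbers to keep sequences short), followed by a
    dense (10, 500) ReLU stack and a softmax head."""

    def __init__(self, hidden=100, dense=(10, 500), window=8, epochs=500,
                 learning_rate=1e-3, batch_size=32, scaler="minmax01", seed=0):
        self.hidden = hidden
        self.dense = dense
        self.window = window
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.scaler = scaler
        self.seed = seed

    def _to_sequence(self, Xs):
        n, d = Xs.shape
        T = -(-d // self.window)
        pad = T * self.window - d
        if pad:
            Xs = np.pad(Xs, ((0, 0), (0, pad)))
        return Xs.reshape(n, T, self.window).transpose(1, 0, 2)  # (T, n, window)

    def _lstm_forward(self, seq, cache: list | None):
        T, n, _ = seq.shape
        H = self.hidden
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        for t in range(T):
            zbar = seq[t] @ self.Wx_.value + h @ self.Wh_.value + self.bg_.value
            i = 1 / (1 + np.exp(-np.clip(zbar[:, :H], -60, 60)))
            f = 1 / (1 + np.exp(-np.clip(zbar[:, H:2 * H], -60, 60)))
            o = 1 / (1 + np.exp(-np.clip(zbar[:, 2 * H:3 * H], -60, 60)))
            g = np.tanh(zbar[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            if cache is not None:
                cache.append((seq[t], h, c, i, f, o, g, c_new, tc))
            h, c = h_new, c_new
        return h

    def _lstm_backward(self, dh, cache):
        H = self.hidden
        dc = np.zeros_like(dh)
        for x_t, h_prev, c_prev, i, f, o, g, c_new, tc in reversed(cache):
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (1 - g**2)],
                axis=1,
            )
            self.Wx_.grad += x_t.T @ dz
            self.Wh_.grad += h_prev.T @ dz
            self.bg_.grad += dz.sum(axis=0)
            dh = dz @ self.Wh_.value.T
            dc = dc * f

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y_idx = self._encode(y)
        Xs = self._scale_fit(X)
        rng = np.random.default_rng(self.seed)
        K = len(self.classes_)
        H, W = self.hidden, self.window
        s = 1.0 / np.sqrt(H)
        self.Wx_ = Param(rng.uniform(-s, s, (W, 4 * H)))
        self.Wh_ = Param(rng.uniform(-s, s, (H, 4 * H)))
        self.bg_ = Param(np.zeros(4 * H))
        self.bg_.value[H:2 * H] = 1.0  # forget-gate bias convention
        layers, n_in = [], H
        for width in self.dense:
            layers += [Dense(n_in, width, rng), ReLU()]
            n_in = width
        layers.append(Dense(n_in, K, rng))
        self.head_ = Sequential(layers)
        seq_all = self._to_sequence(Xs)

        state = {}

        def forward(idx):
            cache: list = []
            h = self._lstm_forward(seq_all[:, idx, :], cache)
            state["cache"] = cache
            return self.head_.forward(h, train=True)

        def backward(dlogits, idx):
            dh = self.head_.backward(dlogits)
            self._lstm_backward(dh, state["cache"])

        params = [self.Wx_, self.Wh_, self.bg_] + self.head_.params()
        self.n_features_in_ = X.shape[1]
        return self._train_loop(Xs, y_idx, params, forward, backward)

    def predict_proba(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        h = self._lstm_forward(self._to_sequence(Xs), cache=None)
        return softmax(self.head_.forward(h, train=False))


class CalibratedLinearSVM(_SpectrumClassifierBase):
    """Linear one-vs-rest SVM (iteration cap 500) with per-class logistic
    (Platt-style) calibration of decision values for probability output."""

    def __init__(self, max_iter=500, pca_components=None, scaler="minmax01", seed=0):
        self.max_iter = max_iter
        self.pca_components = pca_components
        self.scaler = scaler
        self.seed = seed

    def _features(self, X, fit: bool):
        if fit:
            Xs = self._scale_fit(X)
            if self.pca_components is not None:
                self.pca_ = PCA(self.pca_components, svd_solver="full").fit(Xs)
                Xs = self.pca_.transform(Xs)
            else:
                self.pca_ = None
            return Xs
        Xs = self.scaler_.transform(X)
        return self.pca_.transform(Xs) if self.pca_ is not None else Xs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y_idx = self._encode(y)
        Xs = self._features(X, fit=True)
        self.svm_ = LinearSVC(max_iter=self.max_iter, random_state=self.seed)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence cap is intentional
            self.svm_.fit(Xs, y_idx)
        scores = self.svm_.decision_function(Xs)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        # held-in Platt scaling: 1-D logistic fit per class by Newton steps
        self.calib_ = [
            _platt(scores[:, j], (y_idx == j).astype(float))
            for j in range(len(self.classes_))
        ]
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        Xs = self._features(np.asarray(X, dtype=float), fit=False)
        scores = self.svm_.decision_function(Xs)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        cols = [
            1.0 / (1.0 + np.exp(-(a * scores[:, j] + b)))
            for j, (a, b) in enumerate(self.calib_)
        ]
        p = np.column_stack(cols)
        return p / p.sum(axis=1, keepdims=True)


def _platt(scores: np.ndarray, targets: np.ndarray, iters: int = 50) -> tuple[float, float]:
    """Fit p = sigmoid(a*s + b) by Newton-Raphson on the log-likelihood."""
    a, b = 1.0, 0.0
    for _ in range(iters):
        z = np.clip(a * scores + b, -60, 60)
        p = 1.0 / (1.0 + np.exp(-z))
        w = np.maximum(p * (1 - p), 1e-12)
        ga = np.sum((p - targets) * scores)
        gb = np.sum(p - targets)
        haa = np.sum(w * scores * scores) + 1e-9
        hab = np.sum(w * scores)
        hbb = np.sum(w) + 1e-9
        det = haa * hbb - hab * hab
        if abs(det) < 1e-12:
            break
        da = (hbb * ga - hab * gb) / det
        db = (haa * gb - hab * ga) / det
        a, b = a - da, b - db
        if abs(da) < 1e-10 and abs(db) < 1e-10:
            break
    return float(a), float(b)


# ---------------------------------------------------------------------------
# spec-driven construction and dataset-level wrappers


def make_classifier(spec: ClassifierSpec):
    common = dict(scaler=spec.scaler, seed=spec.seed)
    if spec.kind == "LR":
        return SoftmaxRegression(epochs=spec.epochs, learning_rate=spec.learning_rate,
                                 batch_size=spec.batch_size, **common)
    if spec.kind == "PCA_LR":
        return SoftmaxRegression(epochs=spec.epochs, learning_rate=spec.learning_rate,
                                 batch_size=spec.batch_size,
                                 pca_components=spec.pca_components, **common)
    if spec.kind == "SVM":
        return CalibratedLinearSVM(max_iter=spec.svm_max_iter, **common)
    if spec.kind == "PCA_SVM":
        return CalibratedLinearSVM(max_iter=spec.svm_max_iter,
                                   pca_components=spec.pca_components, **common)
    if spec.kind == "MLP":
        return MLPSpectrumClassifier(hidden=spec.mlp_hidden, epochs=spec.epochs,
                                     learning_rate=spec.learning_rate,
                                     batch_size=spec.batch_size, **common)
    if spec.kind == "LSTM":
        return LSTMSpectrumClassifier(hidden=spec.lstm_hidden, dense=spec.lstm_dense,
                                      window=spec.lstm_window, epochs=spec.epochs,
                                      learning_rate=spec.learning_rate,
                                      batch_size=spec.batch_size, **common)
    return CNNSpectrumClassifier(filters=spec.filters, kernel=spec.kernel,
                                 pooling=spec.pooling, epochs=spec.epochs,
                                 learning_rate=spec.learning_rate,
                                 batch_size=spec.batch_size, **common)


def train_classifier(spec: ClassifierSpec, train: SpectraDataset, seed: int | None = None):
    """Fit the requested classifier family on a training dataset."""
    if train.n == 0:
        raise ValueError("training set is empty")
    if len(set(train.labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if seed is not None:
        spec = replace(spec, seed=seed)
    if spec.kind in ("PCA_LR", "PCA_SVM"):
        limit = min(train.n, train.d)
        if spec.pca_components > limit:
            raise ValueError(
                f"pca_components={spec.pca_components} exceeds min(n, d)={limit}"
            )
    model = make_classifier(spec)
    model.fit(train.X, train.labels)
    model.axis_ = train.axis
    return model


def predict_proba(model, data: SpectraDataset):
    """Probability rows plus argmax labels for a dataset; checks axis identity."""
    axis = getattr(model, "axis_", None)
    if axis is not None and axis != data.axis:
        raise ValueError("dataset axis does not match the model's training axis")
    proba = model.predict_proba(data.X)
    labels = model.classes_[np.argmax(proba, axis=1)]
    return proba, labels
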