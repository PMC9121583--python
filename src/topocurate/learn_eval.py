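"""Classifier-based quantification of topological curation.

The curation claim is operational: dropping topologically irrelevant
cohorts (or genes) should *raise* cross-validated classification
metrics.  Two probability-based classifiers (decision tree, Gaussian
naive Bayes) are evaluated over repeated stratified random 80/20
splits (Monte-Carlo cross-validation), and a small 1-D convolutional
network — conv(sigmoid) -> maxpool(2) -> dropout -> dense(ReLU) ->
dropout -> dense(ReLU) -> softmax, trained with Adam — consumes the
expression vector with genes sorted by functional annotation so that
functionally related genes are contiguous under the convolution
kernel.

No deep-learning framework is assumed: the network is a compact numpy
implementation (forward, backprop, inverted dropout, Adam) wrapped as
a scikit-learn classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .cohort_curation import ExpressionDataset, curate_cohorts
from .gene_curation import AnnotationMap

__all__ = [
    "MetricsTable",
    "CNNSpec",
    "compute_metrics",
    "evaluate_probabilistic",
    "compare_full_vs_curated",
    "sort_genes_by_function",
    "ConvNet1DClassifier",
    "train_eval_cnn",
]


def compute_metrics(confusion: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, F1) from a confusion matrix.

    Rows are true classes, columns predicted.  Precision and recall are
    macro-averaged; a class never predicted (or never occurring)
    contributes 0 to its average.  F1 is the harmonic mean of the macro
    precision and macro recall.
    """
    c = np.asarray(confusion)
    if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.number):
        raise ValueError("confusion matrix must hold non-negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    acc = np.trace(c) / total
    diag = np.diag(c).astype(float)
    pred_tot = c.sum(axis=0).astype(float)
    true_tot = c.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_c = np.where(pred_tot > 0, diag / np.maximum(pred_tot, 1e-300), 0.0)
        rec_c = np.where(true_tot > 0, diag / np.maximum(true_tot, 1e-300), 0.0)
    precision = float(prec_c.mean())
    recall = float(rec_c.mean())
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(acc), precision, recall, float(f1)


@dataclass
class MetricsTable:
    """Per-fold and mean classification metrics for one condition."""

    condition: str
    n_samples: int
    n_features: int
    folds: list[dict] = field(default_factory=list)

    def add_fold(self, accuracy, precision, recall, f1) -> None:
        self.folds.append(
            {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}
        )

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.folds]))

    @property
    def accuracy(self) -> float:
        return self.mean("accuracy")

    @property
    def precision(self) -> float:
        return self.mean("precision")

    @property
    def recall(self) -> float:
        return self.mean("recall")

    @property
    def f1(self) -> float:
        return self.mean("f1")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "mean": {m: self.mean(m) for m in ("accuracy", "precision", "recall", "f1")},
            "folds": self.folds,
        }


_MODELS = {
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "naive_bayes": lambda seed: GaussianNB(),
}


def _eval_splits(X, y, model: str, reps: int, test_frac: float, seed: int, table: MetricsTable):
    classes = np.unique(y)
    splitter = StratifiedShuffleSplit(
        n_splits=reps, test_size=test_frac, random_state=seed
    )
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        clf = _MODELS[model](seed + fold)
        clf.fit(X[tr], y[tr])
        cm = confusion_matrix(y[te], clf.predict(X[te]), labels=classes)
        table.add_fold(*compute_metrics(cm))
    return table


def evaluate_probabilistic(
    ds: ExpressionDataset,
    model: str = "decision_tree",
    reps: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
) -> MetricsTable:
    """Monte-Carlo cross-validated metrics of a probabilistic classifier.

    ``reps`` independent stratified random splits, each holding out
    ``test_frac`` (default 80/20).  Stratification guarantees every
    class is present in every training split.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}")
    if reps < 1 or not 0 < test_frac < 1:
        raise ValueError("need reps >= 1 and 0 < test_frac < 1")
    X, y = ds.values, ds.label_array()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two phenotype classes")
    table = MetricsTable("FULL", ds.n_cohorts, ds.n_genes)
    return _eval_splits(X, y, model, reps, test_frac, seed, table)


def compare_full_vs_curated(
    ds: ExpressionDataset,
    model: str = "decision_tree",
    reps: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    leakage_safe: bool = True,
    **curation_kwargs,
) -> dict[str, MetricsTable]:
    """FULL vs topo-curated metrics under a shared split schedule.

    With ``leakage_safe`` (default) the dominant-cycle curation is
    recomputed on each training split only, so the held-out cohorts
    never influence their own selection.  ``leakage_safe=False``
    reproduces the simpler protocol of curating once on all cohorts.
    """
    X, y = ds.values, ds.label_array()
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two phenotype classes")
    mode = curation_kwargs.get("mode", "h1+h2")
    classes = np.unique(y)
    full = MetricsTable("FULL", ds.n_cohorts, ds.n_genes)
    cur = MetricsTable(mode.upper(), ds.n_cohorts, ds.n_genes)
    if not leakage_safe:
        global_sel = set(curate_cohorts(ds, **curation_kwargs).selected_cohorts)
    splitter = StratifiedShuffleSplit(
        n_splits=reps, test_size=test_frac, random_state=seed
    )
    for fold, (tr, te) in enumerate(splitter.split(X, y)):
        clf = _MODELS[model](seed + fold)
        clf.fit(X[tr], y[tr])
        cm = confusion_matrix(y[te], clf.predict(X[te]), labels=classes)
        full.add_fold(*compute_metrics(cm))

        if leakage_safe:
            sub = ds.subset_cohorts([ds.cohort_ids[i] for i in tr])
            sel = set(curate_cohorts(sub, **curation_kwargs).selected_cohorts)
        else:
            sel = global_sel
        keep = [i for i in tr if ds.cohort_ids[i] in sel]
        if len(np.unique(y[keep])) < 2:
            warnings.warn(f"fold {fold}: curated training set single-class; kept full")
            keep = list(tr)
        clf = _MODELS[model](seed + fold)
        clf.fit(X[keep], y[keep])
        cm = confusion_matrix(y[te], clf.predict(X[te]), labels=classes)
        cur.add_fold(*compute_metrics(cm))
    return {"FULL": full, mode.upper(): cur}


def sort_genes_by_function(gene_ids, ann: AnnotationMap) -> list:
    """Order genes so that shared-function genes become contiguous.

    Stable sort by the lexicographically smallest annotation term of
    each gene; genes sharing that term keep their relative input order
    (in particular an all-"Not annotated" input is returned unchanged).
    """
    full = ann.for_genes(gene_ids)
    return sorted(gene_ids, key=lambda g: min(full[g]))


@dataclass
class CNNSpec:
    """Hyperparameters of the 1-D convolutional classifier.

    Defaults (32 filters, kernel 16, dropout 0.25, dense 128 -> 64) are
    manual-observation choices for desk-scale matrices; pool size 2,
    sigmoid convolution, ReLU dense layers, softmax output, Adam and 50
    epochs are fixed architecture commitments.
    """

    n_filters: int = 32
    kernel_size: int = 16
    pool_size: int = 2
    dropout_prob: float = 0.25
    dense_units: tuple[int, int] = (128, 64)
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.pool_size != 2:
            raise ValueError("pool_size is fixed at 2")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not (len(self.dense_units) == 2 and self.dense_units[0] > self.dense_units[1]):
            raise ValueError("dense_units must be two strictly decreasing sizes")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet1DClassifier(ClassifierMixin, BaseEstimator):
    """1-D CNN over expression vectors, implemented in numpy.

    Architecture: conv1d (valid, stride 1, sigmoid) -> max-pool(2) ->
    dropout -> dense(ReLU) -> dropout -> dense(ReLU) -> dense ->
    softmax, optimised by Adam on categorical cross-entropy.  All
    randomness (init, shuffling, dropout) comes from ``seed``.

    Attributes after fit: ``classes_``, ``history_`` (per-epoch train
    and, when a validation set is passed, validation loss/accuracy/F1).
    """

    def __init__(
        self,
        n_filters: int = 32,
        kernel_size: int = 16,
        dropout_prob: float = 0.25,
        dense_units: tuple[int, int] = (128, 64),
        epochs: int = 50,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        seed: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.dropout_prob = dropout_prob
        self.dense_units = dense_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    # -- layer shapes -------------------------------------------------
    def layer_shapes(self, n_features: int) -> dict:
        """Output length after each layer (valid conv, pool 2)."""
        conv_len = n_features - self.kernel_size + 1
        pool_len = conv_len // 2
        return {
            "conv": (conv_len, self.n_filters),
            "pool": (pool_len, self.n_filters),
            "flatten": pool_len * self.n_filters,
            "dense1": self.dense_units[0],
            "dense2": self.dense_units[1],
        }

    def _init_params(self, n_features: int, n_classes: int, rng: np.random.Generator):
        k, f = self.kernel_size, self.n_filters
        d1, d2 = self.dense_units
        flat = self.layer_shapes(n_features)["flatten"]
        if flat < 1:
            raise ValueError("feature count too small for kernel/pooling")

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return rng.uniform(-lim, lim, size=shape)

        self._W1, self._b1 = glorot((k, f)), np.zeros(f)
        self._W2, self._b2 = glorot((flat, d1)), np.zeros(d1)
        self._W3, self._b3 = glorot((d1, d2)), np.zeros(d2)
        self._W4, self._b4 = glorot((d2, n_classes)), np.zeros(n_classes)
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]
        self._adam_t = 0

    def _params(self):
        return [self._W1, self._b1, self._W2, self._b2,
                self._W3, self._b3, self._W4, self._b4]

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Forward pass; rng enables (inverted) dropout during training."""
        k = self.kernel_size
        Xw = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (n, L1, k)
        Z1 = Xw @ self._W1 + self._b1  # (n, L1, f)
        A1 = 1.0 / (1.0 + np.exp(-Z1))
        n, L1, f = A1.shape
        L2 = L1 // 2
        blocks = A1[:, : 2 * L2].reshape(n, L2, 2, f)
        arg = blocks.argmax(axis=2)  # (n, L2, f)
        P1 = blocks.max(axis=2)
        cache = {"Xw": Xw, "A1": A1, "arg": arg, "L2": L2}
        H = P1.reshape(n, -1)
        if rng is not None and self.dropout_prob > 0:
            m1 = (rng.random(H.shape) >= self.dropout_prob) / (1 - self.dropout_prob)
            H = H * m1
            cache["m1"] = m1
        cache["H0"] = H
        Z2 = H @ self._W2 + self._b2
        A2 = np.maximum(Z2, 0.0)
        cache["Z2"] = Z2
        if rng is not None and self.dropout_prob > 0:
            m2 = (rng.random(A2.shape) >= self.dropout_prob) / (1 - self.dropout_prob)
            A2 = A2 * m2
            cache["m2"] = m2
        cache["A2"] = A2
        Z3 = A2 @ self._W3 + self._b3
        A3 = np.maximum(Z3, 0.0)
        cache["Z3"], cache["A3"] = Z3, A3
        Z4 = A3 @ self._W4 + self._b4
        return _softmax(Z4), cache

    def _backward(self, P, Y, cache):
        n = P.shape[0]
        dZ4 = (P - Y) / n
        gW4 = cache["A3"].T @ dZ4
        gb4 = dZ4.sum(axis=0)
        dA3 = dZ4 @ self._W4.T
        dZ3 = dA3 * (cache["Z3"] > 0)
        gW3 = cache["A2"].T @ dZ3
        gb3 = dZ3.sum(axis=0)
        dA2 = dZ3 @ self._W3.T
        if "m2" in cache:
            dA2 = dA2 * cache["m2"]
        dZ2 = dA2 * (cache["Z2"] > 0)
        gW2 = cache["H0"].T @ dZ2
        gb2 = dZ2.sum(axis=0)
        dH = dZ2 @ self._W2.T
        if "m1" in cache:
            dH = dH * cache["m1"]
        L2, f = cache["L2"], self._b1.shape[0]
        dP1 = dH.reshape(n, L2, f)
        dA1 = np.zeros_like(cache["A1"])
        dblocks = np.zeros((n, L2, 2, f))
        np.put_along_axis(dblocks, cache["arg"][:, :, None, :], dP1[:, :, None, :], axis=2)
        dA1[:, : 2 * L2] = dblocks.reshape(n, 2 * L2, f)
        dZ1 = dA1 * cache["A1"] * (1 - cache["A1"])
        gW1 = np.einsum("nlk,nlf->kf", cache["Xw"], dZ1)
        gb1 = dZ1.sum(axis=(0, 1))
        return [gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4]

    def _adam_step(self, grads, lr, b1=0.9, b2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self._params(), grads, self._adam_m, self._adam_v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    @staticmethod
    def _xent(P, Y):
        return float(-(Y * np.log(np.maximum(P, 1e-12))).sum() / P.shape[0])

    def _metrics_on(self, X, Y):
        P, _ = self._forward(X, rng=None)
        y_true = Y.argmax(axis=1)
        y_pred = P.argmax(axis=1)
        cm = confusion_matrix(y_true, y_pred, labels=np.arange(Y.shape[1]))
        acc, prec, rec, f1 = compute_metrics(cm)
        return {"loss": self._xent(P, Y), "accuracy": acc, "f1": f1,
                "precision": prec, "recall": rec}

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if X.shape[1] < self.kernel_size:
            raise ValueError("feature count smaller than kernel size")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        # standardise features on the training statistics
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
        Xs = (X - self._mu) / self._sd
        n_classes = len(self.classes_)
        Y = np.eye(n_classes)[y_idx]
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], n_classes, rng)
        if X_val is not None:
            Xv = (np.asarray(X_val, dtype=float) - self._mu) / self._sd
            yv = np.asarray(y_val)
            Yv = np.eye(n_classes)[np.searchsorted(self.classes_, yv)]
        self.history_ = []
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                P, cache = self._forward(Xs[idx], rng=rng)
                grads = self._backward(P, Y[idx], cache)
                self._adam_step(grads, self.learning_rate)
            rec = {"train": self._metrics_on(Xs, Y)}
            if X_val is not None:
                rec["val"] = self._metrics_on(Xv, Yv)
            self.history_.append(rec)
        return self

    def predict_proba(self, X):
        if not hasattr(self, "classes_"):
            raise ValueError("classifier is not fitted")
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        P, _ = self._forward(Xs, rng=None)
        return P

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def train_eval_cnn(
    ds: ExpressionDataset,
    spec: CNNSpec | None = None,
    ann: AnnotationMap | None = None,
    test_frac: float = 0.2,
) -> dict:
    """Train the CNN on one stratified 80/20 split with function-sorted genes.

    Returns train/test MetricsTables plus the per-epoch history traces.
    """
    spec = spec or CNNSpec()
    ann = ann or AnnotationMap({})
    order = sort_genes_by_function(ds.gene_ids, ann)
    col = {g: j for j, g in enumerate(ds.gene_ids)}
    X = ds.values[:, [col[g] for g in order]]
    y = ds.label_array()
    if ds.n_genes < spec.kernel_size:
        raise ValueError("feature count smaller than kernel size")
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_frac, random_state=spec.seed)
    (tr, te), = splitter.split(X, y)
    clf = ConvNet1DClassifier(
        n_filters=spec.n_filters,
        kernel_size=spec.kernel_size,
        dropout_prob=spec.dropout_prob,
        dense_units=spec.dense_units,
        epochs=spec.epochs,
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        seed=spec.seed,
    )
    clf.fit(X[tr], y[tr], X_val=X[te], y_val=y[te])
    train_tbl = MetricsTable("train", len(tr), ds.n_genes)
    test_tbl = MetricsTable("test", len(te), ds.n_genes)
    last = clf.history_[-1]
    train_tbl.add_fold(last["train"]["accuracy"], last["train"]["precision"],
                       last["train"]["recall"], last["train"]["f1"])
    test_tbl.add_fold(last["val"]["accuracy"], last["val"]["precision"],
                      last["val"]["recall"], last["val"]["f1"])
    return {
        "train": train_tbl,
        "test": test_tbl,
        "history": clf.history_,
        "classifier": clf,
        "gene_order": order,
    }
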