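"""From-scratch classifiers: momentum-backprop MLP and Euclidean kNN.

The network is a single-hidden-layer perceptron with logistic (sigmoid)
units at both the hidden and output layer.  A unit's net input is the
weighted sum of its inputs plus a bias, and training is online (per-pattern)
gradient descent on the squared error ``E = 0.5 * sum((t - o)**2)`` with a
momentum term::

    dw(t) = -lr * dE/dw + momentum * dw(t-1)

Positive valence is encoded as the target pair ``[1, 0]`` and negative as
``[0, 1]``; the predicted class is the larger of the two outputs.  Defaults
follow the study configuration: learning rate 0.7, momentum 0.9.

The kNN classifier stores the training exemplars and votes among the ``k``
nearest by Euclidean distance (``k`` odd, so two-class votes cannot tie);
exact distance ties are broken by the lower exemplar index.

Features of very different scales saturate sigmoid units, so both
classifiers are normally fed z-scored features (see :func:`standardize_fit`
/ :func:`standardize_apply`, computed on training folds only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "MLPModel",
    "KNNModel",
    "sigmoid",
    "targets_from_labels",
    "mlp_forward",
    "mlp_predict",
    "mlp_gradients",
    "mlp_train",
    "euclidean",
    "knn_predict",
    "select_k_loo",
    "standardize_fit",
    "standardize_apply",
]

POSITIVE = 1  # valence rating >= 5
NEGATIVE = 0


def sigmoid(x):
    """Logistic function ``1 / (1 + exp(-x))``, overflow-safe for any x."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def targets_from_labels(labels: np.ndarray) -> np.ndarray:
    """Map binary labels to target rows: positive -> [1, 0], negative -> [0, 1]."""
    labels = np.asarray(labels)
    t = np.zeros((labels.size, 2))
    t[labels == POSITIVE, 0] = 1.0
    t[labels != POSITIVE, 1] = 1.0
    return t


@dataclass
class MLPModel:
    """Trained single-hidden-layer perceptron state.

    ``weights_in_hidden[i, j]`` connects input ``i`` to hidden unit ``j``;
    ``bias_hidden`` is the hidden units' bias term.  ``epochs_run`` and
    ``final_mse`` record the training trajectory's end point.
    """

    n_in: int
    n_hidden: int
    weights_in_hidden: np.ndarray
    bias_hidden: np.ndarray
    weights_hidden_out: np.ndarray
    bias_out: np.ndarray
    learning_rate: float = 0.7
    momentum: float = 0.9
    seed: int | None = None
    n_out: int = 2
    epochs_run: int = 0
    final_mse: float = math.nan
    mse_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.n_out != 2:
            raise ValueError("this model is a two-class (valence) classifier")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        for arr in (
            self.weights_in_hidden,
            self.bias_hidden,
            self.weights_hidden_out,
            self.bias_out,
        ):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")


def mlp_forward(model: MLPModel, x: np.ndarray) -> np.ndarray:
    """Forward pass for one feature vector; returns the two output activations."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_in,):
        raise ValueError(f"expected input of shape ({model.n_in},), got {x.shape}")
    hidden = sigmoid(x @ model.weights_in_hidden + model.bias_hidden)
    return sigmoid(hidden @ model.weights_hidden_out + model.bias_out)


def mlp_predict(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Predicted labels for a matrix of feature vectors (rows)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(X.shape[0], dtype=np.int64)
    for i, x in enumerate(X):
        o = mlp_forward(model, x)
        out[i] = POSITIVE if o[0] >= o[1] else NEGATIVE
    return out


def mlp_gradients(
    model: MLPModel, x: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic per-pattern gradients of ``E = 0.5 * sum((t - o)**2)``.

    Returns ``(dW1, db1, dW2, db2)`` matching the layout of the model's
    weight arrays.  This is the same math the training loop applies; tests
    compare it against central finite differences.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    hidden = sigmoid(x @ model.weights_in_hidden + model.bias_hidden)
    out = sigmoid(hidden @ model.weights_hidden_out + model.bias_out)
    delta_out = (out - t) * out * (1.0 - out)
    delta_hidden = (model.weights_hidden_out @ delta_out) * hidden * (1.0 - hidden)
    dW2 = np.outer(hidden, delta_out)
    dW1 = np.outer(x, delta_hidden)
    return dW1, delta_hidden, dW2, delta_out


@njit(cache=True)
def _train_online(X, T, W1, b1, W2, b2, orders, lr, mom, tol):  # pragma: no cover
    """Online momentum backprop; mutates the weight arrays in place.

    ``orders`` holds one pre-shuffled pattern order per epoch.  Returns
    ``(epochs_run, mse_history)`` where the history is per-epoch mean
    squared error over patterns and outputs.
    """
    n_pat, n_in = X.shape
    n_hidden = b1.shape[0]
    n_out = b2.shape[0]
    max_epochs = orders.shape[0]

    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    hidden = np.empty(n_hidden)
    out = np.empty(n_out)
    d_out = np.empty(n_out)
    d_hid = np.empty(n_hidden)
    mse_history = np.empty(max_epochs)

    epochs_run = 0
    for epoch in range(max_epochs):
        sse = 0.0
        for idx in range(n_pat):
            p = orders[epoch, idx]
            # forward
            for j in range(n_hidden):
                net = b1[j]
                for i in range(n_in):
                    net += X[p, i] * W1[i, j]
                if net >= 0.0:
                    hidden[j] = 1.0 / (1.0 + math.exp(-net))
                else:
                    ev = math.exp(net)
                    hidden[j] = ev / (1.0 + ev)
            for k in range(n_out):
                net = b2[k]
                for j in range(n_hidden):
                    net += hidden[j] * W2[j, k]
                if net >= 0.0:
                    out[k] = 1.0 / (1.0 + math.exp(-net))
                else:
                    ev = math.exp(net)
                    out[k] = ev / (1.0 + ev)
            # backward
            for k in range(n_out):
                err = out[k] - T[p, k]
                sse += err * err
                d_out[k] = err * out[k] * (1.0 - out[k])
            for j in range(n_hidden):
                s = 0.0
                for k in range(n_out):
                    s += W2[j, k] * d_out[k]
                d_hid[j] = s * hidden[j] * (1.0 - hidden[j])
            # momentum updates
            for j in range(n_hidden):
                for k in range(n_out):
                    vW2[j, k] = -lr * hidden[j] * d_out[k] + mom * vW2[j, k]
                    W2[j, k] += vW2[j, k]
            for k in range(n_out):
                vb2[k] = -lr * d_out[k] + mom * vb2[k]
                b2[k] += vb2[k]
            for i in range(n_in):
                for j in range(n_hidden):
                    vW1[i, j] = -lr * X[p, i] * d_hid[j] + mom * vW1[i, j]
                    W1[i, j] += vW1[i, j]
            for j in range(n_hidden):
                vb1[j] = -lr * d_hid[j] + mom * vb1[j]
                b1[j] += vb1[j]
        mse = sse / (n_pat * n_out)
        mse_history[epoch] = mse
        epochs_run = epoch + 1
        if mse < tol:
            break
    return epochs_run, mse_history[:epochs_run]


def mlp_train(
    x_train: np.ndarray,
    y_train: np.ndarray,
    n_hidden: int,
    learning_rate: float = 0.7,
    momentum: float = 0.9,
    max_epochs: int = 1000,
    tol: float = 1e-3,
    seed: int | None = None,
) -> MLPModel:
    """Train a ``n_in x n_hidden x 2`` network by online momentum backprop.

    ``y_train`` may be binary labels or ready-made ``[1,0]/[0,1]`` target
    rows; both classes must be present.  Weights start uniform in
    (-0.5, 0.5) and the pattern order is reshuffled every epoch, both driven
    by ``seed``.  Training stops when the epoch mean squared error drops
    below ``tol`` or after ``max_epochs`` epochs.
    """
    X = np.ascontiguousarray(np.atleast_2d(x_train), dtype=float)
    y_train = np.asarray(y_train)
    if y_train.ndim == 1:
        T = targets_from_labels(y_train)
    else:
        T = np.ascontiguousarray(y_train, dtype=float)
    if X.shape[0] != T.shape[0]:
        raise ValueError("x_train and y_train disagree on the number of patterns")
    if X.shape[0] < 2 or len(np.unique(T[:, 0])) < 2:
        raise ValueError("training set must contain both classes")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")

    rng = np.random.default_rng(seed)
    n_in = X.shape[1]
    W1 = rng.uniform(-0.5, 0.5, size=(n_in, n_hidden))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    W2 = rng.uniform(-0.5, 0.5, size=(n_hidden, 2))
    b2 = rng.uniform(-0.5, 0.5, size=2)
    orders = np.empty((max_epochs, X.shape[0]), dtype=np.int64)
    for e in range(max_epochs):
        orders[e] = rng.permutation(X.shape[0])

    epochs_run, mse_history = _train_online(
        X, T, W1, b1, W2, b2, orders, learning_rate, momentum, tol
    )
    return MLPModel(
        n_in=n_in,
        n_hidden=n_hidden,
        weights_in_hidden=W1,
        bias_hidden=b1,
        weights_hidden_out=W2,
        bias_out=b2,
        learning_rate=learning_rate,
        momentum=momentum,
        seed=seed,
        epochs_run=int(epochs_run),
        final_mse=float(mse_history[-1]),
        mse_history=mse_history,
    )


def euclidean(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance ``sqrt(sum((x_i - y_i)**2))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


@dataclass
class KNNModel:
    """Stored exemplars, their labels and the vote count ``k`` (odd)."""

    exemplars: np.ndarray
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.exemplars = np.atleast_2d(np.asarray(self.exemplars, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.exemplars.shape[0] != self.labels.size:
            raise ValueError("exemplars and labels disagree in length")
        if self.exemplars.shape[0] == 0:
            raise ValueError("model must store at least one exemplar")
        if self.k < 1 or self.k > self.exemplars.shape[0]:
            raise ValueError("k must satisfy 1 <= k <= number of exemplars")
        if self.k % 2 == 0:
            raise ValueError("k must be odd to preclude two-class voting ties")


def knn_predict(model: KNNModel, x: np.ndarray) -> int | np.ndarray:
    """Majority label among the ``k`` nearest exemplars.

    Accepts one query vector or a matrix of query rows.  Distance ties are
    resolved toward the lower exemplar index (stable sort), making the
    prediction independent of exemplar permutation except at exact ties.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Q = np.atleast_2d(x)
    if Q.shape[1] != model.exemplars.shape[1]:
        raise ValueError("query dimension does not match the exemplars")
    d = np.sqrt(((Q[:, None, :] - model.exemplars[None, :, :]) ** 2).sum(axis=2))
    nearest = np.argsort(d, axis=1, kind="stable")[:, : model.k]
    votes = (model.labels[nearest] == POSITIVE).sum(axis=1)
    pred = np.where(votes * 2 > model.k, POSITIVE, NEGATIVE)
    return int(pred[0]) if single else pred


def select_k_loo(
    x_train: np.ndarray, y_train: np.ndarray, k_grid: tuple[int, ...] = (1, 3)
) -> int:
    """Pick ``k`` by leave-one-out accuracy on the training fold.

    Ties go to the smallest ``k``, so equal accuracy prefers k=1.
    """
    X = np.atleast_2d(np.asarray(x_train, dtype=float))
    y = np.asarray(y_train)
    n = X.shape[0]
    best_k, best_acc = None, -1.0
    for k in k_grid:
        if k >= n:
            continue
        correct = 0
        for i in range(n):
            keep = np.arange(n) != i
            sub = KNNModel(exemplars=X[keep], labels=y[keep], k=k)
            if knn_predict(sub, X[i]) == y[i]:
                correct += 1
        acc = correct / n
        if acc > best_acc:
            best_k, best_acc = k, acc
    if best_k is None:
        raise ValueError("no k in the grid is smaller than the training-set size")
    return best_k


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and standard deviations of a training-fold matrix.

    Zero-variance columns get a unit scale so constant features pass
    through unchanged rather than dividing by zero.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    return mean, sd


def standardize_apply(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Z-score ``X`` with the supplied (training-fold) statistics."""
    return (np.asarray(X, dtype=float) - mean) / sd
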