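"""Single-hidden-layer neural network with logistic activations.

The model is f(x) = g(sum_j w_kj * g(sum_i w_ji * x_i + b_j) + b_k) with
g the logistic function, one output unit per class (one-hot targets), and
batch gradient descent on the squared error.  Training stops when the root
mean squared error drops below 0.01 or after 500 epochs, whichever comes
first.  The hidden-layer width is chosen by inner cross-validation over
2..20 nodes.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = ["AnnClassifier", "select_hidden_nodes"]


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


class AnnClassifier:
    """Batch-gradient-descent MLP with one logistic hidden layer.

    Parameters
    ----------
    hidden_nodes : width of the hidden layer (study range 2..20).
    learning_rate : gradient-descent step size.  The gradient is of the
        *mean* squared error (scales as 1/n), so the default step is of
        order a few units; 5.0 trains the classic XOR problem well inside
        the 500-epoch cap.
    max_epochs : epoch cap (500 in the study design).
    rmse_tol : early-stop threshold on training RMSE (0.01).
    seed : weight-initialisation seed.
    """

    def __init__(
        self,
        hidden_nodes: int = 8,
        learning_rate: float = 5.0,
        max_epochs: int = 500,
        rmse_tol: float = 0.01,
        seed: int = 0,
    ):
        if hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if max_epochs > 500:
            raise ValueError("epoch cap is 500 by design")
        self.hidden_nodes = hidden_nodes
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.rmse_tol = rmse_tol
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.n_epochs_: int = 0
        self.rmse_: float = np.nan

    # -- internals -----------------------------------------------------
    def _init_weights(self, n_in: int, n_out: int, rng: np.random.Generator):
        s1 = 1.0 / np.sqrt(n_in)
        s2 = 1.0 / np.sqrt(self.hidden_nodes)
        self.W1 = rng.uniform(-s1, s1, size=(n_in, self.hidden_nodes))
        self.b1 = np.zeros(self.hidden_nodes)
        self.W2 = rng.uniform(-s2, s2, size=(self.hidden_nodes, n_out))
        self.b2 = np.zeros(n_out)

    def _forward(self, X: np.ndarray):
        h = _logistic(X @ self.W1 + self.b1)
        o = _logistic(h @ self.W2 + self.b2)
        return h, o

    def _train_once(self, X: np.ndarray, T: np.ndarray, lr: float, rng) -> bool:
        """One full training run; returns False if the loss went non-finite."""
        self._init_weights(X.shape[1], T.shape[1], rng)
        n = X.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            h, o = self._forward(X)
            err = o - T
            rmse = float(np.sqrt(np.mean(err**2)))
            if not np.isfinite(rmse):
                return False
            self.n_epochs_ = epoch
            self.rmse_ = rmse
            if rmse < self.rmse_tol:
                return True
            # backprop of the mean squared error through both logistic layers
            d_out = err * o * (1.0 - o) / n
            grad_W2 = h.T @ d_out
            grad_b2 = d_out.sum(axis=0)
            d_hid = (d_out @ self.W2.T) * h * (1.0 - h)
            grad_W1 = X.T @ d_hid
            grad_b1 = d_hid.sum(axis=0)
            self.W2 -= lr * grad_W2
            self.b2 -= lr * grad_b2
            self.W1 -= lr * grad_W1
            self.b1 -= lr * grad_b1
        return True

    # -- sklearn-ish surface -------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "AnnClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        T = np.zeros((len(y), len(self.classes_)))
        T[np.arange(len(y)), codes] = 1.0
        rng = np.random.default_rng(self.seed)
        lr = self.learning_rate
        for attempt in range(4):  # halved-learning-rate retries on divergence
            if self._train_once(X, T, lr, rng):
                return self
            lr *= 0.5
        raise RuntimeError("ANN training diverged even after learning-rate halving")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        _, o = self._forward(np.asarray(X, dtype=float))
        return o

    def predict(self, X: np.ndarray) -> np.ndarray:
        o = self.decision_function(X)
        return self.classes_[np.argmax(o, axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def select_hidden_nodes(
    X: np.ndarray,
    y: np.ndarray,
    node_range: range | list[int] = range(2, 21),
    n_folds: int = 10,
    seed: int = 0,
    **ann_kwargs,
) -> tuple[int, float]:
    """Choose the hidden-layer width by stratified inner-CV accuracy.

    Ties break toward the smaller width.  Returns (best_width, cv_accuracy%).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_folds = min(n_folds, int(np.bincount(np.unique(y, return_inverse=True)[1]).min()))
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_w, best_acc = None, -1.0
    for w in node_range:
        correct = 0
        for tr, te in splits:
            clf = AnnClassifier(hidden_nodes=w, seed=seed, **ann_kwargs)
            clf.fit(X[tr], y[tr])
            correct += int(np.sum(clf.predict(X[te]) == y[te]))
        acc = 100.0 * correct / len(y)
        if acc > best_acc:
            best_w, best_acc = w, acc
    return int(best_w), float(best_acc)
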