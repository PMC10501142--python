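"""Row-level leakage guard for nested cross-validation.

All training-side code (feature selection, hyperparameter tuning, model
fitting) pulls subject rows through a :class:`RowGuard` that knows which
rows belong to the enclosing outer-test fold.  Requesting a forbidden row
raises immediately, turning any selection-leakage bug into a hard error
instead of a silently optimistic accuracy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LeakageError", "RowGuard"]


class LeakageError(RuntimeError):
    """A test-fold row was requested during training/selection."""


class RowGuard:
    """Guards a feature matrix and label vector against test-row access."""

    def __init__(self, X: np.ndarray, y: np.ndarray, forbidden: np.ndarray):
        self._X = np.asarray(X)
        self._y = np.asarray(y)
        self._forbidden = frozenset(int(i) for i in np.asarray(forbidden).ravel())
        self.accessed: set[int] = set()

    def take(self, indices) -> tuple[np.ndarray, np.ndarray]:
        """Row-subset (X, y); raises LeakageError on any forbidden index."""
        idx = np.asarray(indices, dtype=int).ravel()
        bad = [int(i) for i in idx if int(i) in self._forbidden]
        if bad:
            raise LeakageError(
                f"training-side access to outer-test rows {sorted(bad)}"
            )
        self.accessed.update(int(i) for i in idx)
        return self._X[idx], self._y[idx]

    def test_rows(self) -> tuple[np.ndarray, np.ndarray]:
        """The held-out rows, for prediction only."""
        idx = np.asarray(sorted(self._forbidden), dtype=int)
        return self._X[idx], self._y[idx]

    @property
    def n_rows(self) -> int:
        return self._X.shape[0]
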