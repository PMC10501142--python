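"""Feature selection: MRMR ranking, the SFC window search, and a PCA reducer.

The minimum-redundancy-maximum-relevance (MRMR) criterion scores a feature
set S against the class variable C as

    mean_{f in S} I(f, C)  -  (1/|S|^2) * sum_{f != g in S} I(f, g)

with plug-in mutual information on equal-frequency-binned features.  The
criterion is maximised greedily (classic incremental scheme); the first
pick is therefore always the max-relevance feature, and redundancy defers
near-duplicates of already-chosen features.

The sequential-feature-collection (SFC) search then evaluates every
contiguous window order[l..l+k-1] of the ranked top-m list (k >= 2), i.e.
sum_{j=2..m}(j-1) candidate subsets — 1225 windows for m = 50 — and keeps
the window with the best cross-validated accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RankedFeatures",
    "SfcResult",
    "bin_equal_frequency",
    "mutual_information",
    "mrmr_objective",
    "mrmr_rank",
    "sfc_search",
    "sfc_candidate_count",
    "pca_reduce",
]


def bin_equal_frequency(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Integer codes from equal-frequency binning of a continuous vector.

    Quantile edges with duplicates collapsed; a constant vector maps to a
    single bin (code 0 everywhere).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _as_codes(v: np.ndarray, discrete: bool, n_bins: int) -> np.ndarray:
    if discrete:
        _, codes = np.unique(np.asarray(v), return_inverse=True)
        return codes.astype(np.int64)
    return bin_equal_frequency(np.asarray(v, dtype=float), n_bins)


def _mi_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) from two integer code vectors."""
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    n = joint.sum()
    p = joint / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (pr @ pc)[nz])))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 4,
    x_discrete: bool = False,
    y_discrete: bool = False,
) -> float:
    """Mutual information I(x, y) in nats via binned plug-in estimation.

    Continuous inputs are discretised into ``n_bins`` equal-frequency bins;
    discrete inputs (class labels) are used as-is.  A constant vector
    carries no information: MI = 0 with a warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        warnings.warn("constant vector: mutual information is 0")
        return 0.0
    return _mi_from_codes(_as_codes(x, x_discrete, n_bins), _as_codes(y, y_discrete, n_bins))


@dataclass
class RankedFeatures:
    """Greedy MRMR ordering (best first) with the per-step objective values."""

    order: list[int]
    scores: list[float]
    top_m: int

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("ranked order contains duplicates")
        if len(self.order) != self.top_m:
            raise ValueError("order length must equal top_m")


def mrmr_objective(
    subset: Sequence[int], relevance: np.ndarray, pair_mi: np.ndarray
) -> float:
    """The MRMR set criterion for an explicit subset (used by the greedy
    step and, in tests, by exhaustive enumeration)."""
    s = list(subset)
    m = len(s)
    rel = float(relevance[s].sum()) / m
    red = 0.0
    if m > 1:
        sub = pair_mi[np.ix_(s, s)]
        red = float(sub.sum() - np.trace(sub)) / (m * m)
    return rel - red


def mrmr_rank(
    X: np.ndarray,
    y: np.ndarray,
    top_m: int = 50,
    n_bins: int = 4,
) -> RankedFeatures:
    """Greedy incremental MRMR ranking of feature columns.

    Step 1 picks argmax I(f, c); every later step adds the feature that
    maximises the criterion of the augmented set.  Ties break toward the
    lower column index, so the ranking is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if top_m > p:
        raise ValueError(f"top_m={top_m} exceeds feature count {p}")
    if top_m < 1:
        raise ValueError("top_m must be >= 1")

    y_codes = _as_codes(y, discrete=True, n_bins=n_bins)
    codes = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        codes[:, j] = bin_equal_frequency(X[:, j], n_bins)
    relevance = np.array([_mi_from_codes(codes[:, j], y_codes) for j in range(p)])

    # pairwise MI filled lazily: only rows for selected features are needed
    pair_rows: dict[int, np.ndarray] = {}

    def pair_mi_row(j: int) -> np.ndarray:
        if j not in pair_rows:
            pair_rows[j] = np.array(
                [_mi_from_codes(codes[:, j], codes[:, k]) for k in range(p)]
            )
        return pair_rows[j]

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(p)  # sum over selected s of I(f, s), per candidate f
    rel_sum = 0.0  # sum of relevance over selected
    pair_sum = 0.0  # sum of I(f_i, f_j) over ordered pairs i != j within selected
    remaining = np.ones(p, dtype=bool)
    for _ in range(top_m):
        m = len(selected) + 1
        # criterion of the augmented set: adding f contributes 2*red_sum[f]
        # new ordered pairs (MI is symmetric) on top of the existing pair_sum
        cand = (relevance + rel_sum) / m - (pair_sum + 2.0 * red_sum) / (m * m)
        cand[~remaining] = -np.inf
        best = int(np.argmax(cand))  # argmax returns the first (lowest) index on ties
        selected.append(best)
        scores.append(float(cand[best]))
        remaining[best] = False
        rel_sum += float(relevance[best])
        pair_sum += 2.0 * float(red_sum[best])
        row = pair_mi_row(best).copy()
        row[best] = 0.0  # self term never enters the i != j sum
        red_sum = red_sum + row
    return RankedFeatures(order=selected, scores=scores, top_m=top_m)


def sfc_candidate_count(m: int) -> int:
    """Number of contiguous windows of length >= 2 in a ranked list of m."""
    return m * (m - 1) // 2


@dataclass
class SfcResult:
    """Winning contiguous window of the ranked list with its CV accuracy."""

    loop_index: int
    subset_size: int
    columns: tuple[int, ...]
    cv_accuracy: float
    n_evaluated: int
    trace: list[tuple[int, int, float]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.cv_accuracy <= 100.0:
            raise ValueError("cv_accuracy must be a percentage in [0, 100]")


def sfc_search(
    ranked: RankedFeatures | Sequence[int],
    evaluator: Callable[[tuple[int, ...]], float],
    keep_trace: bool = False,
) -> SfcResult:
    """Exhaustive search over contiguous windows of the ranked list.

    For each loop l = 0..m-2 the window grows from the top 2 remaining
    features to all of them; the evaluator returns a percentage accuracy.
    Ties prefer fewer features, then the smaller loop index.  Evaluator
    failures skip that window with a logged warning.
    """
    order = list(ranked.order) if isinstance(ranked, RankedFeatures) else list(ranked)
    m = len(order)
    if m < 2:
        raise ValueError("need at least 2 ranked features")

    best: SfcResult | None = None
    trace: list[tuple[int, int, float]] = []
    n_eval = 0
    for l in range(m - 1):
        for k in range(2, m - l + 1):
            window = tuple(order[l : l + k])
            try:
                acc = float(evaluator(window))
            except Exception as exc:  # evaluator failure: skip subset
                warnings.warn(f"SFC evaluator failed on (l={l}, k={k}): {exc}")
                continue
            finally:
                n_eval += 1
            if keep_trace:
                trace.append((l, k, acc))
            if (
                best is None
                or acc > best.cv_accuracy
                or (acc == best.cv_accuracy and k < best.subset_size)
                or (
                    acc == best.cv_accuracy
                    and k == best.subset_size
                    and l < best.loop_index
                )
            ):
                best = SfcResult(
                    loop_index=l,
                    subset_size=k,
                    columns=window,
                    cv_accuracy=acc,
                    n_evaluated=0,
                )
    if best is None:
        raise RuntimeError("SFC evaluator failed on every candidate window")
    best.n_evaluated = n_eval
    best.trace = trace
    return best


def pca_reduce(
    X_train: np.ndarray,
    cvcr: float,
    X_test: np.ndarray | None = None,
):
    """PCA reduction keeping the fewest components whose cumulative
    explained variance reaches the requested rate (CVCR).

    Components are fitted on the training rows only; the same projection is
    applied to optional test rows.  Returns ``(Z_train, Z_test, n_components)``
    (``Z_test`` is None when no test rows are given).
    """
    from sklearn.decomposition import PCA

    if not 0.0 < cvcr <= 1.0:
        raise ValueError(f"cvcr must lie in (0, 1], got {cvcr}")
    X_train = np.asarray(X_train, dtype=float)
    pca = PCA()
    Z = pca.fit_transform(X_train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, cvcr - 1e-12) + 1)
    n_comp = min(n_comp, Z.shape[1])
    Z_test = None
    if X_test is not None:
        Z_test = pca.transform(np.asarray(X_test, dtype=float))[:, :n_comp]
    return Z[:, :n_comp], Z_test, n_comp
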