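"""Trial-ensemble statistics: response divergence, rank estimation,
specificity index and stimulus decoding.

All randomized procedures take explicit seeds and are deterministic given
the seed.  The response matrix convention is rows = trials, columns =
concatenated (timepoint x measure) dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

FOREST_SIZES = (10, 20, 40, 80, 160, 320)
MAX_LEAF_NODES = 20


# ---------------------------------------------------------------- divergence

@dataclass(frozen=True)
class DivergenceResult:
    rd: float
    p_value: float
    significant: bool
    d: float
    d_shuffle_mean: float


def response_divergence(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_shuffle: int = 1000,
    seed: int | None = None,
) -> DivergenceResult:
    """Shuffle-normalized distance between two stimulus-averaged responses.

    D is the Euclidean distance between the two group-mean time series;
    D_sh its distribution under random reassignment of trials to groups;
    RD = (D - <D_sh>)/<D_sh>.  The divergence is significant when D exceeds
    D_sh in more than 95% of shuffles.
    """
    a = np.asarray(trials_a, dtype=float).reshape(len(trials_a), -1)
    b = np.asarray(trials_b, dtype=float).reshape(len(trials_b), -1)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per group")
    d = float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))

    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    na = len(a)
    d_sh = np.empty(n_shuffle)
    for i in range(n_shuffle):
        perm = rng.permutation(len(pooled))
        ga = pooled[perm[:na]]
        gb = pooled[perm[na:]]
        d_sh[i] = np.linalg.norm(ga.mean(axis=0) - gb.mean(axis=0))
    mean_sh = float(d_sh.mean())
    if mean_sh == 0:
        raise ValueError("zero mean shuffle distance; divergence undefined")
    exceed = float(np.mean(d > d_sh))
    return DivergenceResult(
        rd=(d - mean_sh) / mean_sh,
        p_value=1.0 - exceed,
        significant=exceed > 0.95,
        d=d,
        d_shuffle_mean=mean_sh,
    )


# ---------------------------------------------------------------------- rank

def _rank_k_pinv(D: np.ndarray, k: int) -> np.ndarray:
    """Pseudo-inverse of the rank-k SVD truncation of D."""
    if k == 0:
        return np.zeros((D.shape[1], D.shape[0]))
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    k = min(k, s.size)
    inv = np.zeros_like(s)
    nz = s[:k] > 1e-12 * s[0] if s[0] > 0 else np.zeros(k, dtype=bool)
    inv[:k][nz] = 1.0 / s[:k][nz]
    return Vt.T @ np.diag(inv) @ U.T


def bcv_error(
    X: np.ndarray,
    k: int,
    row_groups: list[np.ndarray],
    col_groups: list[np.ndarray],
) -> float:
    """Bi-cross-validation error of the rank-k approximation for one
    (row, column) partition: each held-out block A is predicted from the
    complementary blocks as B (D_k)^+ C and the squared Frobenius errors
    are summed."""
    err = 0.0
    for rows in row_groups:
        other_rows = np.setdiff1d(np.arange(X.shape[0]), rows)
        for cols in col_groups:
            other_cols = np.setdiff1d(np.arange(X.shape[1]), cols)
            A = X[np.ix_(rows, cols)]
            B = X[np.ix_(rows, other_cols)]
            C = X[np.ix_(other_rows, cols)]
            D = X[np.ix_(other_rows, other_cols)]
            err += float(np.sum((A - B @ _rank_k_pinv(D, k) @ C) ** 2))
    return err


def bcv_rank(
    X: np.ndarray,
    k_max: int,
    h: int = 2,
    l: int = 2,
    repeats: int = 10,
    seed: int | None = None,
) -> tuple[np.ndarray, int]:
    """Estimate matrix rank by bi-cross-validation.

    Rows are split into h random groups and columns into l groups; for each
    of the h*l held-out blocks the error of the rank-k prediction from the
    complementary blocks is accumulated, averaged over ``repeats`` random
    repartitions.  Returns the error curve over k = 0..k_max and its argmin.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if m < h + 1 or n < l + 1:
        raise ValueError("matrix too small for the requested split")
    if k_max >= min(m - m // h, n - n // l):
        raise ValueError("k_max must be smaller than the retained block dims")
    rng = np.random.default_rng(seed)
    curve = np.zeros(k_max + 1)
    for _ in range(repeats):
        row_groups = np.array_split(rng.permutation(m), h)
        col_groups = np.array_split(rng.permutation(n), l)
        for k in range(k_max + 1):
            curve[k] += bcv_error(X, k, row_groups, col_groups)
    curve /= repeats
    return curve, int(np.argmin(curve))


# ----------------------------------------------------------------------- PCA

def pca_reduce(X: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and cumulative explained-variance fractions."""
    X = np.asarray(X, dtype=float)
    if d > min(X.shape):
        raise ValueError("d exceeds matrix dimensions")
    pca = PCA()
    scores = pca.fit_transform(X)
    return scores[:, :d], np.cumsum(pca.explained_variance_ratio_)


# ------------------------------------------------------------ specificity SI

@dataclass
class SpecificityResult:
    si: np.ndarray  # per-trial score in [0, 1]
    k: int
    d: int | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.si))


def specificity_index(
    scores: np.ndarray, labels: np.ndarray, k: int = 1
) -> SpecificityResult:
    """Inverse-distance-weighted fraction of same-stimulus nearest neighbours.

    For each trial i, its k nearest neighbours j (Euclidean) get weights
    w_ij = 1/dist_ij, and SI_i = sum_j w_ij 1[Y_i = Y_j] / sum_j w_ij.
    Zero-distance neighbours take the full weight (the 1/d limit): if any
    neighbour coincides with the target, SI is the label-match fraction
    over the coincident neighbours only.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    n = len(X)
    if n < k + 1:
        raise ValueError("need at least k+1 points")
    D = cdist(X, X)
    si = np.empty(n)
    for i in range(n):
        order = np.argsort(D[i])
        neigh = order[order != i][:k]
        dists = D[i, neigh]
        same = (y[neigh] == y[i]).astype(float)
        zero = dists < 1e-300
        if zero.any():
            si[i] = same[zero].mean()
        else:
            w = 1.0 / dists
            si[i] = float(np.sum(w * same) / np.sum(w))
    return SpecificityResult(si=si, k=k)


def sweep_si(
    X: np.ndarray,
    labels: np.ndarray,
    k_range: list[int],
    d_range: list[int],
) -> tuple[tuple[int, int], np.ndarray, SpecificityResult]:
    """Grid-evaluate SI over neighbour counts and PCA dimensionalities.

    Returns the (k, d) maximizing the trial-averaged SI, the full grid of
    mean SI values (k x d), and the per-trial result at the optimum.
    """
    if not k_range or not d_range:
        raise ValueError("ranges must be nonempty")
    grid = np.empty((len(k_range), len(d_range)))
    best = None
    for a, k in enumerate(k_range):
        for b, d in enumerate(d_range):
            scores, _ = pca_reduce(X, d)
            res = specificity_index(scores, labels, k)
            res.d = d
            grid[a, b] = res.mean
            if best is None or res.mean > best[1].mean:
                best = ((k, d), res)
    return best[0], grid, best[1]


# ------------------------------------------------------------------ decoding

def _knn_predict(
    train_X: np.ndarray, train_y: np.ndarray, test_X: np.ndarray, K: int
) -> np.ndarray:
    """Majority-vote KNN with ties broken by the single nearest neighbour."""
    D = cdist(test_X, train_X)
    order = np.argsort(D, axis=1)[:, :K]
    preds = np.empty(len(test_X), dtype=train_y.dtype)
    for i in range(len(test_X)):
        votes = train_y[order[i]]
        labs, counts = np.unique(votes, return_counts=True)
        winners = labs[counts == counts.max()]
        if len(winners) == 1:
            preds[i] = winners[0]
        else:
            # nearest neighbour among the tied classes decides
            for j in order[i]:
                if train_y[j] in winners:
                    preds[i] = train_y[j]
                    break
    return preds


def knn_decode(
    X: np.ndarray,
    labels: np.ndarray,
    K: int = 5,
    d: int = 10,
    folds: int = 10,
    repeats: int = 50,
    seed: int | None = None,
) -> np.ndarray:
    """Cross-validated KNN stimulus decoding accuracy.

    PCA to d dimensions is fit on the training folds only; stratified
    folds are reshuffled each repeat.  Returns the accuracy per repeat.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` trials")
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        correct = 0
        for train_idx, test_idx in skf.split(X, y):
            pca = PCA(n_components=min(d, len(train_idx), X.shape[1]))
            tr = pca.fit_transform(X[train_idx])
            te = pca.transform(X[test_idx])
            preds = _knn_predict(tr, y[train_idx], te, K)
            correct += int(np.sum(preds == y[test_idx]))
        accs[r] = correct / len(y)
    return accs


def forest_decode(
    X: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 80,
    d: int = 10,
    folds: int = 10,
    repeats: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Cross-validated random-forest decoding, trees capped at 20 leaves.

    Same protocol as ``knn_decode``; any member of the standard tree-count
    grid (10..320) is accepted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` trials")
    rng = np.random.default_rng(seed)
    accs = np.empty(repeats)
    for r in range(repeats):
        rs = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        correct = 0
        for train_idx, test_idx in skf.split(X, y):
            pca = PCA(n_components=min(d, len(train_idx), X.shape[1]))
            tr = pca.fit_transform(X[train_idx])
            te = pca.transform(X[test_idx])
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_leaf_nodes=MAX_LEAF_NODES,
                random_state=rs,
            )
            clf.fit(tr, y[train_idx])
            correct += int(np.sum(clf.predict(te) == y[test_idx]))
        accs[r] = correct / len(y)
    return accs
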