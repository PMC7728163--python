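"""Behavioral clustering and mutual-information analysis.

Trials are clustered by k-means++ on the response matrix; the statistical
dependence between stimulus class and behavioral cluster is quantified as
Shannon mutual information estimated from frequency histograms and
corrected for limited-sampling bias by quadratic extrapolation in 1/N
(plugin MI at the full sample, at halves and at quarters, fitted with a
quadratic in 1/N and read off at 1/N -> 0).  The MI-vs-cluster-count curve
is summarized by the fit MI(k) = a (1 - exp(-k/tau)) + b k, whose time
constant tau measures the extent of the high-gain region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import least_squares
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


# ------------------------------------------------------------------ k-means

@dataclass
class ClusterPartition:
    labels: np.ndarray
    inertia: float
    k: int
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.inertia < 0:
            raise ValueError("inertia must be nonnegative")
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("every cluster must be nonempty")


def cluster_responses(
    X: np.ndarray,
    k: int,
    repeats: int = 50,
    runs_per_repeat: int = 100,
    seed: int | None = None,
) -> tuple[ClusterPartition, np.ndarray]:
    """k-means++ clustering of trials; best of ``runs_per_repeat`` runs per
    repeat, overall best partition returned along with per-repeat inertias.
    """
    X = np.asarray(X, dtype=float)
    if k > len(X):
        raise ValueError("k cannot exceed the trial count")
    rng = np.random.default_rng(seed)
    inertias = np.empty(repeats)
    best: ClusterPartition | None = None
    for r in range(repeats):
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=runs_per_repeat,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X)
        inertias[r] = km.inertia_
        if best is None or km.inertia_ < best.inertia:
            best = ClusterPartition(
                labels=km.labels_, inertia=float(km.inertia_), k=k,
                centroids=km.cluster_centers_,
            )
    return best, inertias


# --------------------------------------------------------- mutual information

def _plugin_mi(G: np.ndarray, S: np.ndarray) -> float:
    """Plugin MI (bits) from the joint frequency histogram:
    H(G) - H(G|S)."""
    g_labels, g = np.unique(G, return_inverse=True)
    s_labels, s = np.unique(S, return_inverse=True)
    n = len(g)
    joint = np.zeros((len(g_labels), len(s_labels)))
    np.add.at(joint, (g, s), 1.0)
    joint /= n
    pg = joint.sum(axis=1)
    ps = joint.sum(axis=0)
    hg = -np.sum(pg[pg > 0] * np.log2(pg[pg > 0]))
    # H(G|S) = -sum p(g,s) log2 p(g|s)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = joint / ps[None, :]
    mask = joint > 0
    hgs = -np.sum(joint[mask] * np.log2(cond[mask]))
    return float(hg - hgs)


@dataclass(frozen=True)
class MIEstimate:
    mi: float  # corrected, clipped at 0
    raw: float  # corrected, unclipped
    naive: float  # plugin at full N

    def __float__(self) -> float:
        return self.mi


def mutual_information(
    G: np.ndarray,
    S: np.ndarray,
    bias: str = "quadratic",
    resamples: int = 20,
    seed: int | None = None,
) -> MIEstimate:
    """Shannon MI between cluster and stimulus labels, in bits.

    ``bias="naive"`` returns the plugin estimate.  ``bias="quadratic"``
    additionally computes the plugin MI on random disjoint halves and
    quarters of the trials (averaged within each split, over ``resamples``
    random splits), fits MI(1/N) with a quadratic and extrapolates to
    infinite sample size.  The corrected value is clipped at 0; the raw
    extrapolation is retained on the result.
    """
    G = np.asarray(G)
    S = np.asarray(S)
    if len(G) == 0 or len(G) != len(S):
        raise ValueError("G and S must be nonempty and equal length")
    naive = _plugin_mi(G, S)
    if bias == "naive":
        return MIEstimate(mi=max(naive, 0.0), raw=naive, naive=naive)
    if bias != "quadratic":
        raise ValueError("bias must be 'quadratic' or 'naive'")

    n = len(G)
    rng = np.random.default_rng(seed)
    mi_frac = {1: naive, 2: 0.0, 4: 0.0}
    for divisor in (2, 4):
        acc = 0.0
        for _ in range(resamples):
            perm = rng.permutation(n)
            parts = np.array_split(perm, divisor)
            acc += float(np.mean([_plugin_mi(G[p], S[p]) for p in parts]))
        mi_frac[divisor] = acc / resamples

    inv_n = np.array([1.0 / n, 2.0 / n, 4.0 / n])
    y = np.array([mi_frac[1], mi_frac[2], mi_frac[4]])
    coeffs = np.polyfit(inv_n, y, 2)
    raw = float(np.polyval(coeffs, 0.0))
    return MIEstimate(mi=max(raw, 0.0), raw=raw, naive=naive)


def entropy(labels: np.ndarray) -> float:
    """Shannon entropy (bits) of a label sequence's empirical distribution."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


# ----------------------------------------------------------------- MI curves

@dataclass
class MICurve:
    k_values: np.ndarray
    mi_mean: np.ndarray
    mi_sd: np.ndarray
    fit: tuple[float, float, float] | None = None  # (a, b, tau)
    fit_residual: float | None = None
    fit_converged: bool = True


def mi_vs_clusters(
    X: np.ndarray,
    stimuli: np.ndarray,
    k_range: range | list[int] = range(2, 31),
    repeats: int = 50,
    runs_per_repeat: int = 100,
    resamples: int = 20,
    seed: int | None = None,
) -> MICurve:
    """Corrected MI between stimulus and cluster label as a function of the
    cluster count; mean +/- SD over clustering repeats."""
    rng = np.random.default_rng(seed)
    k_values = np.asarray(list(k_range))
    mi_mean = np.empty(len(k_values))
    mi_sd = np.empty(len(k_values))
    for i, k in enumerate(k_values):
        vals = np.empty(repeats)
        for r in range(repeats):
            part, _ = cluster_responses(
                X, int(k), repeats=1, runs_per_repeat=runs_per_repeat,
                seed=int(rng.integers(2**31 - 1)),
            )
            vals[r] = mutual_information(
                part.labels, stimuli, resamples=resamples,
                seed=int(rng.integers(2**31 - 1)),
            ).mi
        mi_mean[i] = vals.mean()
        mi_sd[i] = vals.std()
    return MICurve(k_values=k_values, mi_mean=mi_mean, mi_sd=mi_sd)


def _mi_model(params: np.ndarray, k: np.ndarray) -> np.ndarray:
    a, b, tau = params
    return a * (1.0 - np.exp(-k / max(tau, 1e-9))) + b * k


def fit_mi_curve(curve: MICurve, n_starts: int = 5, seed: int = 0) -> MICurve:
    """Fit MI(k) = a (1 - exp(-k/tau)) + b k with a, b, tau >= 0.

    Multi-start nonlinear least squares to dodge the a/tau exchange
    degeneracy; the best-residual fit is stored on the curve.
    """
    k = np.asarray(curve.k_values, dtype=float)
    y = np.asarray(curve.mi_mean, dtype=float)
    if len(k) < 4:
        raise ValueError("need at least 4 points to fit the MI curve")
    rng = np.random.default_rng(seed)
    span = max(y.max(), 1e-6)
    tail_slope = max((y[-1] - y[len(y) // 2]) / max(k[-1] - k[len(k) // 2], 1), 0.0)
    starts = [np.array([span, tail_slope, 3.0])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array([
                span * rng.uniform(0.3, 1.5),
                tail_slope * rng.uniform(0.0, 2.0) + 1e-4,
                rng.uniform(0.5, 10.0),
            ])
        )
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: _mi_model(p, k) - y, x0,
                bounds=(np.zeros(3), np.full(3, np.inf)),
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    curve.fit_converged = best is not None and best.success
    if best is not None:
        a, b, tau = best.x
        curve.fit = (float(a), float(b), float(tau))
        curve.fit_residual = float(np.sqrt(2 * best.cost))
    return curve


# ---------------------------------------------------------------- refinement

def refine_clusters(
    X: np.ndarray,
    partition: ClusterPartition,
    remove_fraction: float = 0.3,
) -> tuple[np.ndarray, dict]:
    """Drop the trials farthest from their centroid, per cluster.

    Members of each cluster are ranked by distance to the cluster centroid
    and the farthest ``remove_fraction`` are removed (at most 0.5 and never
    emptying a cluster).  Returns the retained trial indices and goodness
    metrics (silhouette before/after, inertia before/after).
    """
    if not 0.0 <= remove_fraction <= 0.5:
        raise ValueError("remove_fraction must lie in [0, 0.5]")
    X = np.asarray(X, dtype=float)
    labels = partition.labels
    centroids = (
        partition.centroids
        if partition.centroids is not None
        else np.stack([X[labels == g].mean(axis=0) for g in np.unique(labels)])
    )
    keep: list[int] = []
    inertia_after = 0.0
    for gi, g in enumerate(np.unique(labels)):
        members = np.flatnonzero(labels == g)
        dists = np.linalg.norm(X[members] - centroids[gi], axis=1)
        n_keep = max(1, len(members) - int(np.floor(remove_fraction * len(members))))
        kept = members[np.argsort(dists)[:n_keep]]
        keep.extend(kept.tolist())
        inertia_after += float(np.sum(np.sort(dists)[:n_keep] ** 2))
    keep = np.sort(np.asarray(keep))

    metrics = {"inertia_before": partition.inertia, "inertia_after": inertia_after}
    if partition.k > 1:
        metrics["silhouette_before"] = float(silhouette_score(X, labels))
        metrics["silhouette_after"] = float(
            silhouette_score(X[keep], labels[keep])
        )
    return keep, metrics


# --------------------------------------------------------- conditional maps

def conditional_maps(
    G: np.ndarray, S: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalized frequency tables p(s|g) and p(g|s).

    Returns ``(p_s_given_g, p_g_given_s, g_labels, s_labels)``.  Rows of
    p(s|g) index clusters and sum to 1; columns of p(g|s) index stimuli.
    """
    G = np.asarray(G)
    S = np.asarray(S)
    if len(G) != len(S):
        raise ValueError("G and S must have equal length")
    g_labels, g = np.unique(G, return_inverse=True)
    s_labels, s = np.unique(S, return_inverse=True)
    joint = np.zeros((len(g_labels), len(s_labels)))
    np.add.at(joint, (g, s), 1.0)
    p_s_given_g = joint / joint.sum(axis=1, keepdims=True)
    p_g_given_s = joint / joint.sum(axis=0, keepdims=True)
    return p_s_given_g, p_g_given_s, g_labels, s_labels


def joint_pre_response(
    g_pre: np.ndarray, g_resp: np.ndarray, S: np.ndarray
) -> dict:
    """Joint probability of pre-stimulus and response clusters per stimulus."""
    out = {}
    for s in np.unique(S):
        m = S == s
        pre_l, pre = np.unique(g_pre[m], return_inverse=True)
        resp_l, resp = np.unique(g_resp[m], return_inverse=True)
        tab = np.zeros((len(pre_l), len(resp_l)))
        np.add.at(tab, (pre, resp), 1.0)
        out[s] = {"joint": tab / tab.sum(), "pre_labels": pre_l,
                  "resp_labels": resp_l}
    return out


# ------------------------------------------------- initial-position MI limit

def partition_schemes(
    n_dims: int = 5, max_per_dim: int = 8, max_total: int = 20
) -> list[tuple[int, ...]]:
    """All per-dimension partition-count arrays with product <= max_total."""
    schemes = [
        s for s in product(range(1, max_per_dim + 1), repeat=n_dims)
        if np.prod(s) <= max_total
    ]
    return schemes


def _bin_positions(positions: np.ndarray, scheme: tuple[int, ...]) -> np.ndarray:
    """Equal-count (quantile) binning per dimension; joint cell id per trial."""
    n, d = positions.shape
    cell = np.zeros(n, dtype=int)
    for j, parts in enumerate(scheme):
        if parts == 1:
            continue
        ranks = np.argsort(np.argsort(positions[:, j], kind="stable"))
        bins = np.minimum((ranks * parts) // n, parts - 1)
        cell = cell * parts + bins
    return cell


def initial_position_mi(
    positions: np.ndarray,
    G: np.ndarray,
    max_per_dim: int = 8,
    max_total: int = 20,
    resamples: int = 20,
    seed: int | None = None,
    max_match: bool = False,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Extrapolate MI(initial position; response cluster) to infinitely many
    partitions.

    Every per-dimension partition scheme (equal-count bins, product of
    counts <= ``max_total``) yields one bias-corrected MI estimate; the
    least-squares line of MI against 1/#partitions is extrapolated to
    1/#partitions -> 0.  With ``max_match=True`` the trial orders of the
    binned positions and the clusters are independently re-sorted so the
    two sequences agree maximally — an upper-bound control that should
    recover nearly the full cluster entropy under a one-to-one mapping.

    Returns ``(extrapolated_mi, n_partitions_per_scheme, mi_per_scheme)``.
    """
    positions = np.asarray(positions, dtype=float)
    G = np.asarray(G)
    if positions.ndim != 2 or len(positions) != len(G) or len(G) < 2:
        raise ValueError("positions must be trials x dims, aligned with G")
    rng = np.random.default_rng(seed)
    schemes = partition_schemes(positions.shape[1], max_per_dim, max_total)
    n_parts = np.array([int(np.prod(s)) for s in schemes], dtype=float)
    mis = np.empty(len(schemes))
    for i, scheme in enumerate(schemes):
        cells = _bin_positions(positions, scheme)
        g = G
        if max_match:
            cells = np.sort(cells)
            g = np.sort(g)
        mis[i] = mutual_information(
            cells, g, resamples=resamples, seed=int(rng.integers(2**31 - 1))
        ).mi
    # least-squares line of MI vs 1/#partitions; intercept = infinite limit
    x = 1.0 / n_parts
    slope, intercept = np.polyfit(x, mis, 1)
    return float(intercept), n_parts, mis
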