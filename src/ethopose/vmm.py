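"""Sub-second behavioral primitives and variable-order Markov models.

The response matrix (from 0.33 s before stimulus onset to 2 s after) is
tiled into fixed-duration windows; windows are clustered by k-means++ into
a small alphabet of *primitives* (run, rear, freeze-straight, freeze-bent
analogs), turning every trial into a short symbol sequence.  Per-stimulus
variable-order Markov models are trained with a Prediction-by-Partial-
Matching predictor (PPM-C escapes with exclusions) and a trial's stimulus
is decoded as the model with the highest sequence likelihood.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kruskal
from sklearn.model_selection import StratifiedKFold

from .features import BehaviorMatrix
from .infocluster import cluster_responses

PRIMITIVE_DURATIONS_S = (0.133, 0.2, 0.333, 0.4, 0.666, 1.0)
PRE_EPOCH_S = 0.33
RESPONSE_EPOCH_S = 2.0


@dataclass
class PrimitiveSequence:
    """One trial's symbol string over the primitive alphabet.

    ``n_pre`` symbols precede the stimulus onset: they supply Markov
    context but are excluded from decoding likelihoods by default.
    """

    trial: int
    symbols: np.ndarray  # int symbols in [0, alphabet_size)
    duration: float  # s per symbol
    alphabet_size: int
    n_pre: int = 0

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.alphabet_size
        ):
            raise ValueError("symbols outside alphabet")


def extract_primitives(
    matrix: BehaviorMatrix,
    duration: float,
    n_primitives: int,
    seed: int | None = None,
    runs: int = 100,
    pre_epoch: float = PRE_EPOCH_S,
    response_epoch: float = RESPONSE_EPOCH_S,
) -> tuple[list[PrimitiveSequence], np.ndarray]:
    """Tile trials into windows, cluster the windows, emit symbol sequences.

    The analysis epoch runs from ``pre_epoch`` before onset to
    ``response_epoch`` after.  The response epoch must tile exactly into
    windows of ``duration``; the pre-epoch contributes however many whole
    windows fit, ending at the onset.  Returns the per-trial sequences and
    the primitive centroids (n_primitives x window-dims) for
    interpretation.
    """
    if not 2 <= n_primitives <= 10:
        raise ValueError("n_primitives must lie in [2, 10]")
    fps = matrix.frame_rate
    w = duration * fps
    # conventional durations (0.133 s, 0.666 s, ...) are rounded frame counts
    if abs(w - round(w)) > 0.05 or round(w) < 1:
        raise ValueError(f"duration {duration}s does not align with the frame grid")
    w = int(round(w))
    n_resp_frames = int(round(response_epoch * fps))
    if n_resp_frames % w:
        raise ValueError(
            f"duration {duration}s does not tile the {response_epoch}s response epoch"
        )
    L = n_resp_frames // w
    pre_frames = int(round(pre_epoch * fps))
    n_pre = pre_frames // w

    onset = matrix.onset_index
    lo = onset - n_pre * w
    if lo < 0 or onset + n_resp_frames > matrix.n_timepoints:
        raise ValueError("analysis epoch exceeds the recorded range")

    windows = []
    for tr in range(matrix.n_trials):
        for s in range(n_pre + L):
            a = lo + s * w
            windows.append(matrix.values[tr, a : a + w, :].ravel())
    W = np.asarray(windows)

    part, _ = cluster_responses(
        W, n_primitives, repeats=1, runs_per_repeat=runs, seed=seed
    )
    labels = part.labels.reshape(matrix.n_trials, n_pre + L)
    seqs = [
        PrimitiveSequence(
            trial=tr, symbols=labels[tr], duration=duration,
            alphabet_size=n_primitives, n_pre=n_pre,
        )
        for tr in range(matrix.n_trials)
    ]
    return seqs, part.centroids


# ------------------------------------------------------------------- PPM VMM

class VMMModel:
    """Variable-order Markov model scored with PPM-C and exclusions.

    Stores symbol counts for every context of length 0..max_order seen in
    training.  The predictive probability of a symbol walks from the
    longest matching context down, paying an escape probability
    t/(n + t) at each level (t = distinct symbols seen, n = total count,
    both after excluding symbols already credited at longer contexts) and
    bottoming out at a uniform distribution over unexcluded symbols, so
    every predictive distribution sums to one and no sequence has zero
    probability.
    """

    def __init__(self, alphabet_size: int, max_order: int, stimulus=None):
        if max_order < 0:
            raise ValueError("max_order must be >= 0")
        self.alphabet_size = alphabet_size
        self.max_order = max_order
        self.stimulus = stimulus
        self.counts: dict[tuple[int, ...], dict[int, int]] = defaultdict(
            lambda: defaultdict(int)
        )

    def train(self, sequences: list[PrimitiveSequence] | list[np.ndarray]) -> "VMMModel":
        for seq in sequences:
            symbols = seq.symbols if isinstance(seq, PrimitiveSequence) else np.asarray(seq)
            if symbols.size and (symbols.min() < 0 or symbols.max() >= self.alphabet_size):
                raise ValueError("symbol outside alphabet")
            for i in range(len(symbols)):
                for d in range(0, min(self.max_order, i) + 1):
                    ctx = tuple(symbols[i - d : i])
                    self.counts[ctx][int(symbols[i])] += 1
        return self

    def predict(self, context: tuple[int, ...] | list[int]) -> np.ndarray:
        """Predictive distribution over the alphabet given a context."""
        return np.array(
            [self.symbol_prob(s, context) for s in range(self.alphabet_size)]
        )

    def symbol_prob(self, symbol: int, context) -> float:
        """P(symbol | context) under PPM-C with exclusions."""
        context = tuple(int(c) for c in context)
        context = context[len(context) - self.max_order:] if self.max_order else ()
        remaining = set(range(self.alphabet_size))
        p = 1.0
        for start in range(len(context) + 1):
            ctx = context[start:]
            table = self.counts.get(ctx)
            if table is None:
                continue
            avail = {s: c for s, c in table.items() if s in remaining}
            if not avail:
                continue
            n = sum(avail.values())
            t = len(avail)
            if t == len(remaining):
                # every candidate symbol was seen here: escape is impossible
                return p * avail.get(symbol, 0) / n
            if symbol in avail:
                return p * avail[symbol] / (n + t)
            p *= t / (n + t)
            remaining -= set(avail)
        if symbol not in remaining:
            return 0.0
        return p / len(remaining)


def train_ppm(
    sequences: list[PrimitiveSequence],
    max_order: int,
    stimulus=None,
) -> VMMModel:
    """Train one PPM model on a set of primitive sequences."""
    if not sequences:
        raise ValueError("need at least one training sequence")
    alphabet = sequences[0].alphabet_size
    return VMMModel(alphabet, max_order, stimulus=stimulus).train(sequences)


def sequence_loglik(
    model: VMMModel,
    seq: PrimitiveSequence | np.ndarray,
    include_pre: bool = False,
) -> float:
    """Log2-likelihood of a sequence; pre-onset symbols contribute context
    only unless ``include_pre`` is set."""
    if isinstance(seq, PrimitiveSequence):
        symbols = seq.symbols
        start = 0 if include_pre else seq.n_pre
    else:
        symbols = np.asarray(seq, dtype=int)
        start = 0
    ll = 0.0
    for i in range(start, len(symbols)):
        ctx = tuple(symbols[max(0, i - model.max_order) : i])
        p = model.symbol_prob(int(symbols[i]), ctx)
        ll += float(np.log2(max(p, 1e-300)))
    return ll


def decode_stimulus(
    models: list[VMMModel],
    seq: PrimitiveSequence | np.ndarray,
) -> tuple[object, bool]:
    """Maximum-likelihood stimulus; returns (label, tie_flag).

    Ties are broken by model order in ``models`` and flagged.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    lls = np.array([sequence_loglik(m, seq) for m in models])
    best = int(np.argmax(lls))
    tie = bool(np.sum(np.isclose(lls, lls[best], atol=1e-12)) > 1)
    return models[best].stimulus if models[best].stimulus is not None else best, tie


def decode_cv(
    sequences: list[PrimitiveSequence],
    stimuli: np.ndarray,
    max_order: int,
    folds: int = 10,
    seed: int | None = None,
) -> float:
    """Cross-validated stimulus-decoding accuracy for one Markov order."""
    stimuli = np.asarray(stimuli)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    idx = np.arange(len(sequences))
    correct = 0
    for train_idx, test_idx in skf.split(idx, stimuli):
        models = []
        for s in np.unique(stimuli):
            train = [sequences[i] for i in train_idx if stimuli[i] == s]
            models.append(train_ppm(train, max_order, stimulus=s))
        for i in test_idx:
            pred, _ = decode_stimulus(models, sequences[i])
            correct += int(pred == stimuli[i])
    return correct / len(sequences)


def sweep_vmm(
    matrix: BehaviorMatrix,
    stimuli: np.ndarray,
    durations: tuple[float, ...] = PRIMITIVE_DURATIONS_S,
    n_primitives_range: range | list[int] = range(2, 11),
    orders: list[int] | None = None,
    folds: int = 10,
    runs: int = 100,
    seed: int | None = None,
) -> tuple[dict, dict]:
    """Grid search over primitive duration, alphabet size and Markov order.

    For each (duration, n_primitives) the windows are re-clustered once,
    then every maximum order up to the sequence length is scored by
    ``folds``-fold cross-validated decoding.  Returns the accuracy grid
    (keyed by (duration, n_primitives, order)) and the best configuration.
    """
    rng = np.random.default_rng(seed)
    grid: dict[tuple[float, int, int], float] = {}
    best = {"accuracy": -1.0}
    for duration in durations:
        for n_prim in n_primitives_range:
            seqs, _ = extract_primitives(
                matrix, duration, int(n_prim),
                seed=int(rng.integers(2**31 - 1)), runs=runs,
            )
            L = len(seqs[0].symbols) - seqs[0].n_pre
            order_list = orders if orders is not None else list(range(0, L + 1))
            for order in order_list:
                if order > L:
                    continue
                acc = decode_cv(
                    seqs, stimuli, order, folds=folds,
                    seed=int(rng.integers(2**31 - 1)),
                )
                grid[(duration, int(n_prim), int(order))] = acc
                if acc > best["accuracy"]:
                    best = {
                        "accuracy": acc, "duration": duration,
                        "n_primitives": int(n_prim), "order": int(order),
                    }
    return grid, best


# ------------------------------------------------------------- summary stats

def primitive_stats(
    sequences: list[PrimitiveSequence],
    behavior_clusters: np.ndarray,
    test: bool = True,
) -> dict:
    """Per-primitive rate and latency across behavior clusters.

    rate: per cluster, the fraction of post-onset symbols equal to each
    primitive (rows sum to 1 over the alphabet).  latency: mean onset time
    (s from stimulus onset) of the primitive's occurrences within each
    cluster; NaN where the primitive never occurs (flagged).  Omnibus
    Kruskal-Wallis tests across clusters are delegated to scipy.
    """
    clusters = np.asarray(behavior_clusters)
    alphabet = sequences[0].alphabet_size
    duration = sequences[0].duration
    cluster_ids = np.unique(clusters)
    rates = np.zeros((len(cluster_ids), alphabet))
    latencies = np.full((len(cluster_ids), alphabet), np.nan)
    per_trial_rate = defaultdict(lambda: defaultdict(list))
    per_trial_latency = defaultdict(lambda: defaultdict(list))

    for gi, g in enumerate(cluster_ids):
        member_seqs = [s for s, c in zip(sequences, clusters) if c == g]
        all_counts = np.zeros(alphabet)
        lat_acc: list[list[float]] = [[] for _ in range(alphabet)]
        for seq in member_seqs:
            post = seq.symbols[seq.n_pre:]
            counts = np.bincount(post, minlength=alphabet)
            all_counts += counts
            for a in range(alphabet):
                per_trial_rate[g][a].append(counts[a] / len(post))
            for a in range(alphabet):
                times = np.flatnonzero(post == a) * duration
                lat_acc[a].extend(times.tolist())
                if times.size:
                    per_trial_latency[g][a].append(float(times.mean()))
        total = all_counts.sum()
        if total > 0:
            rates[gi] = all_counts / total
        for a in range(alphabet):
            if lat_acc[a]:
                latencies[gi, a] = float(np.mean(lat_acc[a]))

    result = {
        "cluster_ids": cluster_ids, "rates": rates, "latencies": latencies,
        "duration": duration,
    }
    if test and len(cluster_ids) > 1:
        rate_p = np.full(alphabet, np.nan)
        lat_p = np.full(alphabet, np.nan)
        for a in range(alphabet):
            groups = [np.asarray(per_trial_rate[g][a]) for g in cluster_ids
                      if len(per_trial_rate[g][a]) > 0]
            if len(groups) > 1 and any(np.ptp(g) > 0 for g in groups):
                rate_p[a] = kruskal(*groups).pvalue
            lgroups = [np.asarray(per_trial_latency[g][a]) for g in cluster_ids
                       if len(per_trial_latency[g][a]) > 0]
            if len(lgroups) > 1 and any(np.ptp(g) > 0 for g in lgroups):
                lat_p[a] = kruskal(*lgroups).pvalue
        result["rate_pvalues"] = rate_p
        result["latency_pvalues"] = lat_p
    return result
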