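"""Behavioral primitives and PPM variable-order Markov models."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ethopose as ep
from ethopose import synthetic as syn
from ethopose.vmm import PRIMITIVE_DURATIONS_S


@pytest.fixture(scope="module")
def two_motif_matrix():
    """Trials alternate between two very different window templates."""
    rng = np.random.default_rng(0)
    n_trials, n_t = 40, 45
    onset = 5
    values = np.zeros((n_trials, n_t, 9))
    # alternate 0.333 s (5-frame) blocks between two template vectors
    t_a, t_b = np.full(9, 0.2), np.full(9, 0.8)
    for tr in range(n_trials):
        for w in range(n_t // 5):
            values[tr, 5 * w : 5 * (w + 1), :] = t_a if w % 2 == 0 else t_b
    values += rng.normal(0, 0.02, values.shape)
    stim = np.array(["flash", "loom"] * (n_trials // 2))
    return ep.BehaviorMatrix(values=np.clip(values, 0, 1), stimulus=stim,
                             onset_index=onset)


class TestExtractPrimitives:
    @pytest.mark.parametrize(
        "duration,L", list(zip(PRIMITIVE_DURATIONS_S, [15, 10, 6, 5, 3, 2]))
    )
    def test_sequence_lengths_match_duration_grid(self, duration, L,
                                                  trial_ensemble):
        _, matrix, _, _ = trial_ensemble
        seqs, _ = extract_small(matrix, duration, 3, seed=0)
        assert len(seqs[0].symbols) - seqs[0].n_pre == L

    def test_alternating_motifs_recovered(self, two_motif_matrix):
        seqs, centroids = ep.extract_primitives(
            two_motif_matrix, 0.333, 2, seed=1, runs=10, pre_epoch=0.333,
        )
        correct = 0
        total = 0
        for s in seqs:
            post = s.symbols[s.n_pre:]
            # window parity alternates; accept either labeling
            expect = np.arange(len(post)) % 2
            correct += max(
                (post == expect).sum(), (post == 1 - expect).sum()
            )
            total += len(post)
        assert correct / total >= 0.95

    def test_non_tiling_duration_raises(self, two_motif_matrix):
        with pytest.raises(ValueError):
            ep.extract_primitives(two_motif_matrix, 0.3, 3, seed=0)


def extract_small(matrix, duration, k, seed=0):
    return ep.extract_primitives(matrix, duration, k, seed=seed, runs=5)


class TestPPM:
    def test_order0_uniform_training(self):
        rng = np.random.default_rng(2)
        model = ep.VMMModel(4, 0).train([rng.integers(0, 4, 4000)])
        p = model.predict(())
        assert np.allclose(p, 0.25, atol=0.03)

    def test_total_probability_over_all_length3_sequences(self):
        """Exhaustive enumeration of all 27 sequences on a 3-symbol
        alphabet must sum to one."""
        rng = np.random.default_rng(3)
        model = ep.VMMModel(3, 2).train([rng.integers(0, 3, 30)])
        total = 0.0
        for seq in itertools.product(range(3), repeat=3):
            p = 1.0
            for i in range(3):
                p *= model.symbol_prob(seq[i], seq[max(0, i - 2):i])
            total += p
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_deterministic_chain_probability_approaches_one(self):
        probs = []
        for n in (10, 100, 1000):
            model = ep.VMMModel(2, 1).train([np.tile([0, 1], n)])
            probs.append(model.symbol_prob(1, (0,)))
        assert probs[0] < probs[1] < probs[2]
        assert probs[2] > 0.99

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.integers(min_value=0, max_value=3), min_size=5, max_size=60
        ),
        order=st.integers(min_value=0, max_value=3),
        ctx=st.lists(st.integers(min_value=0, max_value=3), max_size=4),
    )
    def test_predictive_distribution_normalizes(self, data, order, ctx):
        model = ep.VMMModel(4, order).train([np.asarray(data)])
        assert model.predict(tuple(ctx)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_symbol_outside_alphabet_raises(self):
        with pytest.raises(ValueError):
            ep.VMMModel(2, 1).train([np.array([0, 1, 2])])


class TestSequenceLoglik:
    def test_untrained_model_is_uniform(self):
        model = ep.VMMModel(4, 0)
        seq = ep.PrimitiveSequence(0, np.array([0, 1, 2, 3, 0]), 0.133, 4)
        assert ep.sequence_loglik(model, seq) == pytest.approx(-5 * np.log2(4))

    def test_directional_chain_prefers_forward_order(self):
        # an irreversible 3-state cycle (2-state chains are always
        # reversible, so they cannot distinguish the direction)
        P = np.array([
            [0.1, 0.85, 0.05], [0.05, 0.1, 0.85], [0.85, 0.05, 0.1]
        ])
        seqs, _ = syn.simulate_markov_sequences([P], 50, 20, seed=5)
        model = ep.VMMModel(3, 1).train(seqs)
        test, _ = syn.simulate_markov_sequences([P], 20, 20, seed=6)
        fwd = np.mean([ep.sequence_loglik(model, s) for s in test])
        rev = np.mean([ep.sequence_loglik(model, s[::-1]) for s in test])
        assert fwd > rev
        # and the same ordering holds for the exact generator likelihoods
        logs = np.log2(P)
        exact = lambda s: logs[s[:-1], s[1:]].sum()
        assert np.mean([exact(s) for s in test]) > np.mean(
            [exact(s[::-1]) for s in test]
        )

    def test_loglik_monotone_in_length(self):
        rng = np.random.default_rng(7)
        model = ep.VMMModel(3, 1).train([rng.integers(0, 3, 100)])
        s = rng.integers(0, 3, 12)
        lls = [ep.sequence_loglik(model, s[:n]) for n in range(1, 13)]
        assert np.all(np.diff(lls) <= 0)

    def test_pre_onset_symbols_excluded_by_default(self):
        model = ep.VMMModel(2, 0)
        seq = ep.PrimitiveSequence(0, np.array([0, 0, 1, 1]), 0.2, 2, n_pre=2)
        assert ep.sequence_loglik(model, seq) == pytest.approx(-2.0)
        assert ep.sequence_loglik(model, seq, include_pre=True) == pytest.approx(-4.0)


class TestDecoding:
    def test_well_separated_chains_decode_above_90(self):
        P1 = np.array([[0.9, 0.1], [0.1, 0.9]])
        P2 = np.array([[0.1, 0.9], [0.9, 0.1]])
        train, ytr = syn.simulate_markov_sequences([P1, P2], 100, 15, seed=8)
        test, yte = syn.simulate_markov_sequences([P1, P2], 100, 15, seed=9)
        models = [
            ep.train_ppm(
                [ep.PrimitiveSequence(0, s, 0.133, 2) for s, l in
                 zip(train, ytr) if l == c], 1, stimulus=c)
            for c in (0, 1)
        ]
        acc = np.mean([
            ep.decode_stimulus(models, s)[0] == l for s, l in zip(test, yte)
        ])
        assert acc > 0.9

    def test_identical_generators_decode_at_chance(self):
        P = np.array([[0.6, 0.4], [0.4, 0.6]])
        train, ytr = syn.simulate_markov_sequences([P, P], 100, 15, seed=10)
        test, yte = syn.simulate_markov_sequences([P, P], 200, 15, seed=11)
        models = [
            ep.train_ppm(
                [ep.PrimitiveSequence(0, s, 0.133, 2) for s, l in
                 zip(train, ytr) if l == c], 1, stimulus=c)
            for c in (0, 1)
        ]
        acc = np.mean([
            ep.decode_stimulus(models, s)[0] == l for s, l in zip(test, yte)
        ])
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 400) + 0.05

    def test_single_model_always_wins(self):
        model = ep.VMMModel(2, 0, stimulus="only")
        label, tie = ep.decode_stimulus([model], np.array([0, 1, 0]))
        assert label == "only"

    def test_accuracy_nondecreasing_with_training_size(self):
        P1 = np.array([[0.8, 0.2], [0.2, 0.8]])
        P2 = np.array([[0.3, 0.7], [0.7, 0.3]])
        test, yte = syn.simulate_markov_sequences([P1, P2], 150, 15, seed=12)
        accs = []
        for n in (20, 50, 100):
            train, ytr = syn.simulate_markov_sequences([P1, P2], n, 15, seed=13)
            models = [
                ep.train_ppm(
                    [ep.PrimitiveSequence(0, s, 0.133, 2) for s, l in
                     zip(train, ytr) if l == c], 1, stimulus=c)
                for c in (0, 1)
            ]
            accs.append(np.mean([
                ep.decode_stimulus(models, s)[0] == l
                for s, l in zip(test, yte)
            ]))
        assert accs[2] >= accs[0] - 0.05  # tolerance for sampling noise

    def test_order0_generator_gains_nothing_from_depth(self):
        rng = np.random.default_rng(14)
        p1, p2 = np.array([0.7, 0.3]), np.array([0.3, 0.7])
        train = [rng.choice(2, 15, p=p1) for _ in range(60)] + [
            rng.choice(2, 15, p=p2) for _ in range(60)]
        ytr = np.repeat([0, 1], 60)
        test = [rng.choice(2, 15, p=p1) for _ in range(100)] + [
            rng.choice(2, 15, p=p2) for _ in range(100)]
        yte = np.repeat([0, 1], 100)

        def acc(order):
            models = [
                ep.train_ppm(
                    [ep.PrimitiveSequence(0, s, 0.133, 2) for s, l in
                     zip(train, ytr) if l == c], order, stimulus=c)
                for c in (0, 1)
            ]
            return np.mean([
                ep.decode_stimulus(models, s)[0] == l
                for s, l in zip(test, yte)
            ])

        assert acc(0) >= acc(3) - 0.07


class TestSweepVMM:
    def test_order1_structure_rewards_order1_models(self):
        """Sequences with planted first-order structure decode better with
        order >= 1 than order 0."""
        rng = np.random.default_rng(15)
        P1 = np.array([[0.9, 0.1], [0.1, 0.9]])
        P2 = np.array([[0.1, 0.9], [0.9, 0.1]])
        seqs_raw, y = syn.simulate_markov_sequences([P1, P2], 60, 15, seed=16)
        seqs = [ep.PrimitiveSequence(i, s, 0.133, 2) for i, s in enumerate(seqs_raw)]
        acc0 = ep.decode_cv(seqs, y, 0, folds=5, seed=17)
        acc1 = ep.decode_cv(seqs, y, 1, folds=5, seed=17)
        assert acc1 > acc0

    def test_duration_grid_matches_standard_set(self):
        assert PRIMITIVE_DURATIONS_S == (0.133, 0.2, 0.333, 0.4, 0.666, 1.0)


class TestPrimitiveStats:
    def test_rates_sum_to_one_per_cluster(self):
        rng = np.random.default_rng(18)
        seqs = [
            ep.PrimitiveSequence(i, rng.integers(0, 4, 15), 0.133, 4)
            for i in range(30)
        ]
        clusters = rng.integers(0, 3, 30)
        res = ep.primitive_stats(seqs, clusters)
        assert np.allclose(res["rates"].sum(axis=1), 1.0, atol=1e-12)

    def test_planted_latency_ordering_recovered(self):
        """Primitive 0 planted early and primitive 1 late: the latency
        estimates preserve that order exactly."""
        seqs = []
        for i in range(20):
            sym = np.concatenate([np.zeros(5, int), np.ones(10, int)])
            seqs.append(ep.PrimitiveSequence(i, sym, 0.133, 2))
        res = ep.primitive_stats(seqs, np.zeros(20, int), test=False)
        assert res["latencies"][0, 0] < res["latencies"][0, 1]

    def test_absent_primitive_has_zero_rate_nan_latency(self):
        seqs = [ep.PrimitiveSequence(0, np.zeros(10, int), 0.2, 3)]
        res = ep.primitive_stats(seqs, np.zeros(1, int), test=False)
        assert res["rates"][0, 2] == 0.0
        assert np.isnan(res["latencies"][0, 2])
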